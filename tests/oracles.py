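"""Independent brute-force oracles shared across test modules."""

import numpy as np


def _brute_force_masked_smooth(image, mask, fwhm, voxel):
    """Direct O(N*K) normalized convolution with the same truncated
    Gaussian kernel (truncate=4 box) as the implementation."""
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
    r = int(4.0 * sigma + 0.5)
    out = np.full(image.shape, np.nan)
    shape = image.shape
    for idx in np.argwhere(mask):
        num = 0.0
        den = 0.0
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                for dz in range(-r, r + 1):
                    p = idx + (dx, dy, dz)
                    if np.any(p < 0) or np.any(p >= shape):
                        continue
                    if not mask[tuple(p)]:
                        continue
                    w = np.exp(-(dx * dx + dy * dy + dz * dz)
                               / (2 * sigma * sigma))
                    num += w * image[tuple(p)]
                    den += w
        out[tuple(idx)] = num / den
    return out
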