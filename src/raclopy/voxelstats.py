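"""Nonparametric voxelwise inference on parametric binding-potential maps.

Implements the permutation machinery used on the ΔBP (= BP1 − BP0) maps:
paired t maps for task main effects (sign-flipping null), the 2 (group) ×
2 (time) interaction on per-subject change maps as a two-sample permutation
comparison with SnPM-style variance smoothing (pseudo-t), family-wise error
control by the permutation distribution of the maximum statistic (maxT),
and cluster-extent filtering of suprathreshold voxels.

The 2×2 mixed-design interaction on ΔBP is algebraically a two-sample
comparison of per-subject (post − pre) change scores, which makes group
relabeling an exact permutation scheme under group exchangeability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage, special

from .images import masked_gaussian_smooth

__all__ = [
    "Cluster",
    "PermutationResult",
    "paired_t_map",
    "group_time_anova",
    "cluster_filter",
]

logger = logging.getLogger("raclopy.voxelstats")


@dataclass(frozen=True)
class Cluster:
    """A connected suprathreshold component of a statistic map."""

    size: int
    peak_value: float
    peak_voxel: tuple[int, int, int]
    peak_world: tuple[float, float, float]


@dataclass
class PermutationResult:
    """Voxelwise statistic map with its permutation null and threshold."""

    stat_map: np.ndarray            # NaN outside mask
    mask: np.ndarray
    null_max: np.ndarray            # maxT null distribution (incl. identity)
    critical_value: float
    alpha: float
    n_permutations: int
    clusters: list[Cluster] = field(default_factory=list)
    p_map: np.ndarray | None = None
    exhaustive: bool = False

    @property
    def suprathreshold(self) -> np.ndarray:
        """Boolean map of family-wise significant voxels (p <= alpha)."""
        if self.p_map is not None:
            with np.errstate(invalid="ignore"):
                return np.nan_to_num(self.p_map, nan=1.0) <= self.alpha
        with np.errstate(invalid="ignore"):
            return np.abs(np.nan_to_num(self.stat_map)) \
                >= self.critical_value

    @property
    def n_suprathreshold(self) -> int:
        return int(self.suprathreshold.sum())


def _critical_from_null(null_max: np.ndarray, alpha: float) -> float:
    """Empirical (1 - alpha) quantile of the maxT null.

    Conservative convention: the critical value c is the smallest null value
    such that P(maxT >= c) <= alpha, using the ceil rank so that ties count
    against rejection.
    """
    srt = np.sort(null_max)
    n = srt.size
    k = int(np.ceil((1.0 - alpha) * n))
    k = min(max(k, 0), n - 1)
    return float(srt[k])


def _voxel_p(null_max: np.ndarray, stat: np.ndarray) -> np.ndarray:
    """Corrected voxel p-values: fraction of null maxima >= |stat| (>= ties)."""
    n = null_max.size
    order = np.sort(null_max)
    idx = np.searchsorted(order, np.abs(stat), side="left")
    return (n - idx) / n


def paired_t_map(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 5000,
    min_extent: int = 5,
    affine: np.ndarray | None = None,
    seed: int | None = None,
) -> PermutationResult:
    """Voxelwise paired t test with a sign-flipping maxT permutation null.

    ``maps_a`` and ``maps_b`` are (n_subjects, ...) stacks of co-registered
    maps, paired by position.  The statistic is the one-sample t of the
    difference maps; the null flips the sign of whole subject difference
    maps (full enumeration when 2^n <= n_perm, including the identity
    flip).  Two-sided inference on |t| with family-wise control by maxT.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape:
        raise ValueError("paired map stacks must have identical shape")
    n_sub = maps_a.shape[0]
    if n_sub < 3:
        raise ValueError("need at least 3 paired subjects")
    mask = np.asarray(mask, dtype=bool)
    diffs = (maps_a - maps_b)[:, mask]      # (n_sub, n_vox)
    if np.any(~np.isfinite(diffs)):
        # voxels with any missing subject are dropped from inference
        good = np.all(np.isfinite(diffs), axis=0)
        full = np.zeros_like(mask)
        full[mask] = good
        mask = full
        diffs = diffs[:, good]

    def tstat(d: np.ndarray) -> np.ndarray:
        m = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (sd / np.sqrt(n_sub))
        return np.where(sd > 0, t, 0.0)

    t_obs = tstat(diffs)

    if 2 ** n_sub <= n_perm:
        signs = np.array(
            [[1 if (i >> j) & 1 == 0 else -1 for j in range(n_sub)]
             for i in range(2 ** n_sub)], dtype=float)
        exhaustive = True
        logger.info("paired_t_map: full enumeration of %d sign flips",
                    signs.shape[0])
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
        signs[0] = 1.0                      # identity permutation included
        exhaustive = False
    null_max = np.empty(signs.shape[0])
    for i, s in enumerate(signs):
        null_max[i] = np.max(np.abs(tstat(diffs * s[:, None])))

    crit = _critical_from_null(null_max, alpha)
    stat_map = np.full(mask.shape, np.nan)
    stat_map[mask] = t_obs
    p_map = np.full(mask.shape, np.nan)
    p_map[mask] = _voxel_p(null_max, t_obs)
    thresholded = np.nan_to_num(p_map, nan=1.0) <= alpha
    clusters = cluster_filter(thresholded, stat_map,
                              min_extent=min_extent, affine=affine)
    return PermutationResult(
        stat_map=stat_map, mask=mask, null_max=null_max,
        critical_value=crit, alpha=alpha, n_permutations=signs.shape[0],
        clusters=clusters, p_map=p_map, exhaustive=exhaustive)


def group_time_anova(
    change_maps: np.ndarray,
    group_labels: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 5000,
    var_fwhm_mm: float = 10.0,
    voxel_size_mm: float | tuple = 1.0,
    min_extent: int = 5,
    affine: np.ndarray | None = None,
    seed: int | None = None,
) -> PermutationResult:
    """Group × time permutation interaction test on ΔBP change maps.

    ``change_maps`` is (n_subjects, ...) of per-subject (post − pre) ΔBP
    maps; ``group_labels`` is a boolean/0-1 vector (True = training group).
    The interaction statistic is a two-sample pseudo-t comparing groups on
    the change maps, with the pooled-variance image smoothed by
    ``masked_gaussian_smooth`` (``var_fwhm_mm``; 0 gives the raw t).  The
    null permutes group labels — full enumeration when the number of
    distinct relabelings is at most ``n_perm`` — and family-wise inference
    uses the maxT distribution of |pseudo-t| at level ``alpha``; clusters
    below ``min_extent`` are filtered.
    """
    change_maps = np.asarray(change_maps, dtype=float)
    labels = np.asarray(group_labels).astype(bool)
    n_sub = change_maps.shape[0]
    if labels.shape != (n_sub,):
        raise ValueError("one group label per subject required")
    n1 = int(labels.sum())
    n2 = n_sub - n1
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 subjects per group")
    mask = np.asarray(mask, dtype=bool)
    data = change_maps[:, mask]             # (n_sub, n_vox)

    def smooth_var(v: np.ndarray) -> np.ndarray:
        if var_fwhm_mm <= 0:
            return v
        vol = np.full(mask.shape, np.nan)
        vol[mask] = v
        sm = masked_gaussian_smooth(vol, mask, var_fwhm_mm, voxel_size_mm)
        return sm[mask]

    inv_n = 1.0 / n1 + 1.0 / n2
    dof = n_sub - 2

    def pseudo_t(lab: np.ndarray) -> np.ndarray:
        a = data[lab]
        b = data[~lab]
        pooled = (a.var(axis=0, ddof=1) * (n1 - 1)
                  + b.var(axis=0, ddof=1) * (n2 - 1)) / dof
        sv = smooth_var(pooled)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sv * inv_n)
        return np.where(sv > 0, t, 0.0)

    t_obs = pseudo_t(labels)

    all_combos = special.comb(n_sub, n1, exact=True)
    if all_combos <= n_perm:
        perms = []
        for combo in combinations(range(n_sub), n1):
            lab = np.zeros(n_sub, dtype=bool)
            lab[list(combo)] = True
            perms.append(lab)
        perms = np.array(perms)
        exhaustive = True
        logger.info("group_time_anova: full enumeration of %d relabelings "
                    "(requested %d)", all_combos, n_perm)
    else:
        rng = np.random.default_rng(seed)
        perms = np.empty((n_perm, n_sub), dtype=bool)
        perms[0] = labels                   # identity permutation included
        for i in range(1, n_perm):
            lab = np.zeros(n_sub, dtype=bool)
            lab[rng.choice(n_sub, size=n1, replace=False)] = True
            perms[i] = lab
        exhaustive = False
    null_max = np.empty(perms.shape[0])
    for i, lab in enumerate(perms):
        null_max[i] = np.max(np.abs(pseudo_t(lab)))

    crit = _critical_from_null(null_max, alpha)
    stat_map = np.full(mask.shape, np.nan)
    stat_map[mask] = t_obs
    p_map = np.full(mask.shape, np.nan)
    p_map[mask] = _voxel_p(null_max, t_obs)
    thresholded = np.nan_to_num(p_map, nan=1.0) <= alpha
    clusters = cluster_filter(thresholded, stat_map,
                              min_extent=min_extent, affine=affine)
    return PermutationResult(
        stat_map=stat_map, mask=mask, null_max=null_max,
        critical_value=crit, alpha=alpha, n_permutations=perms.shape[0],
        clusters=clusters, p_map=p_map, exhaustive=exhaustive)


def cluster_filter(
    thresholded: np.ndarray,
    stat_map: np.ndarray | None = None,
    min_extent: int = 5,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
) -> list[Cluster]:
    """Connected components of a suprathreshold map, filtered by extent.

    Components are kept only when their size strictly exceeds
    ``min_extent`` voxels.  26-connectivity by default (6 and 18 also
    supported).  Peaks report both 0-based voxel indices and world
    coordinates through the affine.
    """
    thresholded = np.asarray(thresholded).astype(bool)
    if connectivity == 26:
        struct = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 18:
        struct = ndimage.generate_binary_structure(3, 2)
    elif connectivity == 6:
        struct = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6, 18 or 26")
    labeled, n_comp = ndimage.label(thresholded, structure=struct)
    if affine is None:
        affine = np.eye(4)
    stat = (np.abs(np.nan_to_num(np.asarray(stat_map, dtype=float)))
            if stat_map is not None else thresholded.astype(float))
    clusters = []
    for lab in range(1, n_comp + 1):
        comp = labeled == lab
        size = int(comp.sum())
        if size <= min_extent:
            continue
        vals = np.where(comp, stat, -np.inf)
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        signed = (float(stat_map[peak]) if stat_map is not None
                  else 1.0)
        world = tuple((affine @ np.array([*peak, 1.0]))[:3])
        clusters.append(Cluster(size=size, peak_value=signed,
                                peak_voxel=tuple(int(i) for i in peak),
                                peak_world=world))
    clusters.sort(key=lambda c: -c.size)
    return clusters
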