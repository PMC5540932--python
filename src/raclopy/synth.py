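"""Phantom dynamic PET cohorts and behavioral tables.

Generates everything the downstream pipeline consumes — reference-region
time-activity curves from a bolus-plus-infusion input, 4D voxel phantoms
with a training-by-session displacement effect confined to a striatal
sub-region, 1-Hz head-motion traces, and pre/post behavioral score tables —
so that the full analysis is exercisable without any acquired data.

Every generator is a pure function of its spec and a seed.

Reference-curve model
---------------------
A bolus-plus-infusion protocol delivers a fraction of the dose as a bolus
equivalent to ``kbol`` minutes of infusion (``Kbol = 80`` min here), chosen
so that plasma activity is near-constant from the start.  The reference
tissue (a region without specific binding) then follows a one-compartment
response: an infusion term ``P*(1 - exp(-k2p*t))`` rising to a plateau plus
a bolus-mismatch transient that vanishes exactly when the bolus matches
plasma clearance (``bolus_fraction/(1-bolus_fraction) * kbol * lambda_p = 1``,
the design condition of the protocol).  The curve is continuous with
``C_R(0) = 0`` and near-constant over the last half of the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    ActivationProfile,
    FrameSchedule,
    KineticParams,
    TimeActivityCurve,
    simulate_target_tac,
)

__all__ = [
    "InputFunctionParams",
    "PhantomSpec",
    "CohortDesign",
    "PhantomSession",
    "reference_curve",
    "simulate_reference_tac",
    "simulate_phantom_scan",
    "simulate_behavior",
    "simulate_motion_trace",
    "TABLE_BEHAVIOR_DEFAULTS",
]

GROUPS = ("training", "control")
TIMES = ("pre", "post")
TASKS = ("letter_memory", "nback")

# Pre/post behavioral marginals (mean, SD) per (task, group): letter-memory
# accuracy % and 3-back target accuracy % for the training and control arms.
TABLE_BEHAVIOR_DEFAULTS = {
    ("letter_memory", "training"): ((51.54, 11.63), (83.33, 31.67)),
    ("letter_memory", "control"): ((47.57, 12.87), (56.28, 17.01)),
    ("nback", "training"): ((74.53, 18.24), (86.12, 14.51)),
    ("nback", "control"): ((79.44, 20.66), (91.10, 7.30)),
}


@dataclass(frozen=True)
class InputFunctionParams:
    """Bolus-plus-infusion reference input.

    ``plasma_clearance`` defaults to ``1/kbol`` — the protocol's design
    point, at which a 50% bolus exactly balances plasma washout and the
    reference curve rises monotonically to its plateau.
    """

    bolus_fraction: float = 0.5
    kbol: float = 80.0               # min of infusion the bolus is worth
    plateau_level: float = 20.0      # kBq/mL
    plasma_clearance: float = 1.0 / 80.0   # 1/min
    tissue_washout: float = 0.15     # reference-tissue k2', 1/min

    def __post_init__(self):
        if not (0.0 < self.bolus_fraction < 1.0):
            raise ValueError("bolus_fraction must be in (0, 1)")
        if self.kbol <= 0 or self.plasma_clearance <= 0 or \
                self.tissue_washout <= 0:
            raise ValueError("rates and kbol must be positive")
        if self.plateau_level < 0:
            raise ValueError("plateau_level must be non-negative")


def reference_curve(t, params: InputFunctionParams = InputFunctionParams()):
    """Closed-form reference TAC ``C_R(t)`` (continuous, kBq/mL).

    Sum of the infusion rise to plateau and the bolus-mismatch transient::

        C_R(t) = P * [ (1 - e^{-k t})
                       + m * k/(k - l) * (e^{-l t} - e^{-k t}) ]

    with ``k`` the tissue washout, ``l`` the plasma clearance and
    ``m = bf/(1-bf) * kbol * l - 1`` the bolus excess relative to perfect
    protocol matching (``m = 0`` at the defaults).
    """
    t = np.asarray(t, dtype=float)
    p = params
    k = p.tissue_washout
    lam = p.plasma_clearance
    m = p.bolus_fraction / (1.0 - p.bolus_fraction) * p.kbol * lam - 1.0
    infusion = 1.0 - np.exp(-k * t)
    if abs(k - lam) < 1e-12:
        transient = m * k * t * np.exp(-k * t)
    else:
        transient = m * k / (k - lam) * (np.exp(-lam * t) - np.exp(-k * t))
    return p.plateau_level * (infusion + transient)


def simulate_reference_tac(
    params: InputFunctionParams = InputFunctionParams(),
    schedule: FrameSchedule | None = None,
    seed: int | None = None,
    noise_scale: float = 0.0,
) -> TimeActivityCurve:
    """Frame-binned reference TAC; optional Gaussian frame noise.

    Frame values are analytic averages of :func:`reference_curve` over each
    frame (1-s sub-sampling).  Deterministic for a given seed.
    """
    sched = schedule if schedule is not None else FrameSchedule.default()
    values = np.empty(sched.n_frames)
    for i, (a, b) in enumerate(zip(sched.start, sched.end)):
        tt = np.linspace(a, b, max(int(round((b - a) * 60)), 2) + 1)
        values[i] = np.trapezoid(reference_curve(tt, params), tt) / (b - a)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise_scale * np.sqrt(np.maximum(values, 0.0) / sched.duration)
        values = values + rng.normal(0.0, 1.0, values.shape) * sd
    return TimeActivityCurve(schedule=sched, values=values, role="reference")


# ---------------------------------------------------------------------------
# Phantom geometry and 4D scans
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d = sum(((idx[i] - center[i]) / semi_axes[i]) ** 2 for i in range(3))
    return d <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, true kinetics, and noise of the digital phantom.

    The default striatal search mask is an ellipsoid of ~2934 voxels
    (~10 cm^3 at 1.5 mm isotropic voxels), matching the size of an MNI-space
    striatal search volume; the displacement-effect blob (~200 voxels) sits
    inside it, and a disjoint ellipsoid provides the reference region.
    """

    shape: tuple[int, int, int] = (40, 40, 30)
    voxel_size_mm: float = 1.5
    striatum_center: tuple[float, float, float] = (19.5, 19.5, 14.5)
    striatum_semi_axes: tuple[float, float, float] = (11.0, 9.0, 7.1)
    effect_center: tuple[float, float, float] = (23.0, 19.5, 14.5)
    effect_semi_axes: tuple[float, float, float] = (4.5, 3.8, 3.2)
    reference_center: tuple[float, float, float] = (19.5, 19.5, 3.5)
    reference_semi_axes: tuple[float, float, float] = (10.0, 10.0, 2.8)
    striatum_params: KineticParams = field(
        default_factory=lambda: KineticParams(r1=1.0, k2=0.35, k2a=0.1))
    task_gamma: float = 0.01         # 1/min, task-induced release, all scans
    effect_gamma_increment: float = 0.01  # extra gamma: trained x post blob
    noise_scale: float = 0.5         # frame noise: sd = scale*sqrt(C/dt)
    input_params: InputFunctionParams = field(
        default_factory=InputFunctionParams)
    schedule: FrameSchedule = field(default_factory=FrameSchedule.default)

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def striatum_mask(self) -> np.ndarray:
        return _ellipsoid_mask(self.shape, self.striatum_center,
                               self.striatum_semi_axes)

    def effect_mask(self) -> np.ndarray:
        m = _ellipsoid_mask(self.shape, self.effect_center,
                            self.effect_semi_axes)
        return m & self.striatum_mask()

    def reference_mask(self) -> np.ndarray:
        m = _ellipsoid_mask(self.shape, self.reference_center,
                            self.reference_semi_axes)
        if np.any(m & self.striatum_mask()):
            raise ValueError("reference and striatal masks overlap")
        return m

    @classmethod
    def mini(cls, noise_scale: float | None = None) -> "PhantomSpec":
        """Desk-scale phantom (~300-voxel search mask) for fast studies."""
        kwargs = {}
        if noise_scale is not None:
            kwargs["noise_scale"] = noise_scale
        return cls(
            shape=(14, 14, 10),
            voxel_size_mm=3.0,
            striatum_center=(6.5, 6.5, 5.0),
            striatum_semi_axes=(5.0, 4.2, 3.2),
            effect_center=(8.2, 6.5, 5.0),
            effect_semi_axes=(2.2, 1.9, 1.7),
            reference_center=(6.5, 6.5, 0.5),
            reference_semi_axes=(5.0, 5.0, 1.1),
            **kwargs,
        )


@dataclass
class PhantomSession:
    """One simulated scan: 4D data plus masks, truth, and motion trace."""

    data: np.ndarray            # (x, y, z, frames)
    affine: np.ndarray
    schedule: FrameSchedule
    striatum_mask: np.ndarray
    reference_mask: np.ndarray
    effect_mask: np.ndarray
    ref_tac: TimeActivityCurve  # noise-free analytic reference curve
    motion_trace: np.ndarray    # (6, seconds)
    meta: dict


def _session_gamma_map(spec: PhantomSpec, group: str, time: str) -> tuple:
    gamma_bg = spec.task_gamma
    gamma_blob = spec.task_gamma
    if group == "training" and time == "post":
        gamma_blob += spec.effect_gamma_increment
    return gamma_bg, gamma_blob


def simulate_phantom_scan(
    spec: PhantomSpec,
    group: str = "training",
    time: str = "pre",
    task: str = "letter_memory",
    seed: int = 0,
    profile: ActivationProfile | None = None,
) -> PhantomSession:
    """Simulate one 4D phantom scan for a (group, time, task) session.

    Voxels inside the striatal mask follow the LSSRM forward model with the
    region's true parameters; inside the effect blob, ``gamma`` is
    incremented for trained-group post-training sessions.  Reference-region
    voxels carry the reference curve itself; background voxels a low
    non-specific signal.  Additive Gaussian noise with per-frame variance
    proportional to signal over frame duration.
    """
    if group not in GROUPS or time not in TIMES or task not in TASKS:
        raise ValueError(f"unknown session {(group, time, task)!r}")
    prof = profile if profile is not None else ActivationProfile(
        window_end=spec.schedule.total_duration)
    sched = spec.schedule
    ref_tac = simulate_reference_tac(spec.input_params, sched)

    # Targets are simulated from the binned reference curve so the digital
    # phantom is model-true with respect to the discrete generative model
    # that voxelwise fitting inverts.
    gamma_bg, gamma_blob = _session_gamma_map(spec, group, time)
    p = spec.striatum_params
    curve_bg = simulate_target_tac(
        ref_tac, KineticParams(p.r1, p.k2, p.k2a, gamma_bg), prof).values
    if gamma_blob != gamma_bg:
        curve_blob = simulate_target_tac(
            ref_tac, KineticParams(p.r1, p.k2, p.k2a, gamma_blob),
            prof).values
    else:
        curve_blob = curve_bg

    striatum = spec.striatum_mask()
    effect = spec.effect_mask()
    reference = spec.reference_mask()

    data = np.zeros(spec.shape + (sched.n_frames,))
    background = 0.1 * ref_tac.values
    data[...] = background
    data[striatum] = curve_bg
    data[effect] = curve_blob
    data[reference] = ref_tac.values

    if spec.noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = spec.noise_scale * np.sqrt(
            np.maximum(data, 0.0) / sched.duration)
        data = data + rng.normal(0.0, 1.0, data.shape) * sd

    trace = simulate_motion_trace(
        seed=seed + 1, duration_s=int(np.ceil(sched.total_duration * 60)))
    return PhantomSession(
        data=data, affine=spec.affine(), schedule=sched,
        striatum_mask=striatum, reference_mask=reference, effect_mask=effect,
        ref_tac=ref_tac, motion_trace=trace,
        meta={"group": group, "time": time, "task": task, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Motion traces
# ---------------------------------------------------------------------------

def simulate_motion_trace(
    seed: int = 0,
    base_amplitude: float = 0.3,
    spikes: list[tuple[float, float]] | None = None,
    duration_s: int = 4794,
) -> np.ndarray:
    """6-channel (3 translations mm, 3 rotations deg) head motion at 1 Hz.

    Smooth low-amplitude wander (sum of slow random sinusoids scaled to
    ``base_amplitude``) plus optional Gaussian-shaped spikes given as
    ``(time_min, amplitude_mm)`` pairs applied to the first translation
    channel.
    """
    if base_amplitude < 0:
        raise ValueError("base_amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(duration_s, dtype=float)
    trace = np.zeros((6, duration_s))
    if base_amplitude > 0:
        for c in range(6):
            wander = np.zeros(duration_s)
            for _ in range(4):
                period = rng.uniform(300.0, 1500.0)  # 5-25 min
                phase = rng.uniform(0, 2 * np.pi)
                wander += rng.normal(0, 1) * np.sin(
                    2 * np.pi * t / period + phase)
            peak = np.max(np.abs(wander))
            if peak > 0:
                wander *= base_amplitude / peak * rng.uniform(0.5, 1.0)
            trace[c] = wander
    for time_min, amp in (spikes or []):
        center = time_min * 60.0
        trace[0] += amp * np.exp(-0.5 * ((t - center) / 3.0) ** 2)
    return trace


# ---------------------------------------------------------------------------
# Behavioral tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout: group sizes and pre/post score distributions per task.

    ``behavior`` maps ``(task, group)`` to ``((mean_pre, sd_pre),
    (mean_post, sd_post))``; defaults are the printed group marginals of the
    letter-memory and 3-back accuracy measures.
    """

    n_training: int = 14
    n_control: int = 14
    behavior: dict = field(
        default_factory=lambda: dict(TABLE_BEHAVIOR_DEFAULTS))
    pre_post_corr: float = 0.5

    def __post_init__(self):
        if self.n_training < 2 or self.n_control < 2:
            raise ValueError("need at least 2 subjects per group")
        if not (-1.0 < self.pre_post_corr < 1.0):
            raise ValueError("pre_post_corr must be in (-1, 1)")
        for key, ((m0, s0), (m1, s1)) in self.behavior.items():
            if s0 < 0 or s1 < 0:
                raise ValueError(f"negative SD for {key!r}")

    def n_for(self, group: str) -> int:
        return self.n_training if group == "training" else self.n_control


def simulate_behavior(design: CohortDesign = CohortDesign(),
                      seed: int = 0) -> pd.DataFrame:
    """Draw a long-format behavioral table (subject, group, task, time, score).

    Per-subject pre/post scores are bivariate normal with the configured
    marginals and pre-post correlation; the same subjects appear across
    tasks.  Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUPS:
        n = design.n_for(group)
        for task in sorted({k[0] for k in design.behavior}):
            if (task, group) not in design.behavior:
                continue
            (m0, s0), (m1, s1) = design.behavior[(task, group)]
            rho = design.pre_post_corr
            cov = np.array([[s0 ** 2, rho * s0 * s1],
                            [rho * s0 * s1, s1 ** 2]])
            if s0 == 0 and s1 == 0:
                scores = np.tile([m0, m1], (n, 1))
            else:
                scores = rng.multivariate_normal(
                    [m0, m1], cov, size=n, method="svd")
            for i in range(n):
                sid = f"{group[:2]}{i + 1:02d}"
                rows.append((sid, group, task, "pre", scores[i, 0]))
                rows.append((sid, group, task, "post", scores[i, 1]))
    return pd.DataFrame(
        rows, columns=["subject", "group", "task", "time", "score"])
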