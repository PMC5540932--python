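# raclopy

Task-induced striatal dopamine release from dynamic [¹¹C]raclopride PET:
kinetic modeling, parametric binding-potential maps, nonparametric
voxelwise inference, and the accompanying behavioral statistics — with a
synthetic-phantom cohort generator so the whole pipeline runs and is
testable without any scanner data.

The package is written for PET methodologists and cognitive-neuroscience
groups analyzing bolus-plus-infusion raclopride studies in which a
cognitive task is switched on partway through the scan and the question is
whether (and where) endogenous dopamine displaces the radioligand — and
whether an intervention (here, five weeks of working-memory updating
training) changes that displacement.

## The model

The simplified reference tissue model (SRTM) relates the target-tissue
time–activity curve C_T to a reference-region curve C_R through R1
(relative delivery), k2 and k2a (efflux rates). Task-induced dopamine
release is modeled as a time-varying increment to the efflux rate
(the linear extension, LSSRM):

    dC_T/dt = R1 dC_R/dt + k2 C_R − (k2a + γ·h(t)) C_T

where h(t) is a unit-peak gamma-variate switched on at task onset
(default: onset 55 min post injection, peak 8 min 20 s later, shape λ = 3)
and γ is the activation effect. Integrating from injection gives a system
linear in (R1, k2, k2a, γ):

    C_T(t) = R1 C_R(t) + k2 ∫C_R − k2a ∫C_T − γ ∫C_T·h

solved per region or per voxel by linear least squares. Binding potentials
follow as

    BP0 = k2/k2a − 1,      BP1 = k2/(k2a + γ·h̄) − 1,

with h̄ the mean of h over the activation window; displacement appears as
ΔBP = BP1 − BP0 < 0. Group-level inference on ΔBP uses SnPM-style
permutation tests: sign-flipping paired t maps for task main effects, and
the 2 (group) × 2 (time) interaction as a two-sample pseudo-t (variance
image smoothed at 10 mm FWHM) on per-subject change maps, with maxT
family-wise control and a >5-voxel cluster-extent rule.

## Worked example

```python
from raclopy import (KineticParams, simulate_reference_tac,
                     simulate_target_tac, fit_lssrm, compute_bp)

ref = simulate_reference_tac()                      # bolus-plus-infusion
true = KineticParams(r1=1.0, k2=0.35, k2a=0.10, gamma=0.02)
tac = simulate_target_tac(ref, true)                # 20-frame phantom TAC
fit = fit_lssrm(tac, ref)
bp = compute_bp(fit.params)
```

prints (noise-free round trip is exact):

    fitted params: R1=1.0000  k2=0.3500 k2a=0.1000  gamma=0.02000
    BP0=2.500  BP1=2.189  dBP=-0.311

BP0 = 2.5 is a typical striatal raclopride binding potential; γ = 0.02/min
during the task lowers the activation-phase binding to 2.19, a ~12%
displacement.

A cohort-level run on the small digital phantom (7 trained / 7 control
subjects, displacement increment confined to a ~30-voxel blob):

```python
from raclopy.synth import PhantomSpec
from raclopy.workflow import simulate_study_change_maps
from raclopy.voxelstats import group_time_anova

spec = PhantomSpec.mini()
ch, labels, mask, blob = simulate_study_change_maps(spec, 7, 7, seed=42)
res = group_time_anova(ch, labels, mask, n_perm=400, var_fwhm_mm=10.0,
                       voxel_size_mm=3.0, seed=42)
```

    pseudo-t critical value (alpha=0.05, maxT): 4.39
    cluster: 19 voxels, peak pseudo-t -7.85 at voxel (8, 7, 5)

The surviving cluster sits at the injected effect blob; the negative peak
means the trained group's ΔBP decreased after training (more dopamine
release during the task).

The shell interface runs the same stages against a dataset on disk:

```sh
raclopy -c config.yaml simulate   # phantom cohort -> NIfTI + CSV + manifest
raclopy -c config.yaml fit        # motion screen, masked smoothing, BP maps
raclopy -c config.yaml stats      # permutation maps, clusters, behavior
raclopy -c config.yaml report     # print the JSON summary
```

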