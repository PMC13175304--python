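# ntpet

Simulation and voxelwise detection of **transient neurotransmitter signals
in dynamic PET**, built around the lp-ntPET / MRTM model pair with BIC
model comparison and weighted k-nearest-neighbor (wkNN) spatial
reclassification.

The package is for PET methodologists who want to ask: *if scanner
sensitivity improved by an order of magnitude, could single-scan dynamic
[¹¹C]raclopride imaging detect and characterize brief, voxel-scale dopamine
transients?* It provides the whole simulation-and-analysis chain needed to
answer that on synthetic ground truth: gamma-variate dopamine responses,
reference- and target-tissue forward models (a linear generative mode and a
nonlinear receptor-competition ODE), scanner noise with variance
proportional to the signal, a six-region 3D limbic phantom with per-voxel
truth, the voxelwise detector, threshold classifiers for peak-time and
amplitude, and the weighted-vote spatial cleanup.

## The model

Dopamine transients are normalized gamma variates

```
h(t) = ((t-t_d)/(t_p-t_d))^alpha * exp(alpha*(1-(t-t_d)/(t_p-t_d))) * u(t-t_d)
DA(t) = G*h(t) + baseline          (baseline 100 nM)
```

with start time `t_d`, peak time `t_p`, sharpness `alpha`, and peak
amplitude `G` (reported as `G% = 100*G/baseline`).

Every voxel time-activity curve (TAC) is fitted twice against the
noiseless reference-region curve `C_R`:

* **MRTM** (null model, 3 parameters):
  `C_T = R1*C_R + k2*∫C_R − k2a*∫C_T`
* **lp-ntPET** (4 parameters), which appends a time-varying efflux term
  `− γ*∫C_T(u)·h_i(u)du` for each shape `h_i` in a 38-member basis library
  (`t_d ∈ [35,45]`, `t_p ∈ [35,70]`, `alpha = 0.5`), keeping the
  minimum-SSE basis.

Model choice uses `BIC_M = p_M·ln(n) + n·ln(SSE_M/n)` with `p = 3` for MRTM
and an *effective* count `p_eff ∈ [4,7]` for lp-ntPET; a response is
significant iff `ΔBIC = BIC_lp − BIC_MRTM < 0`. Detected voxels are
classified **early/late** by `t̂_p` against `t_p* = 45 min` and **low/high**
by the normalized magnitude `γ̂/k̂2a` against `M* = 0.8`, and both the
detection mask and the class maps are refined by one pass of a weighted
27-neighborhood vote (weights 1.00 / 1.60 / 1.14 / 0.68 for
center / face / edge / vertex neighbors).

## Worked example

```python
import numpy as np
from ntpet import (DAResponseParams, FrameSchedule, LpNtPetDetector, NoiseSpec,
                   TracerKineticParams, simulate_reference_tac, simulate_target_tac)

sched = FrameSchedule.uniform()                 # 30 x 3 min frames
tracer = TracerKineticParams()                  # R1=1, k2=0.36, k2a=0.12
ref = simulate_reference_tac(tracer, sched)     # noiseless cerebellum curve

# a late-peaking dopamine transient, 250% of the 100 nM baseline
da = DAResponseParams(t_d=35, t_p=55, alpha=0.5, G=250.0)
clean = simulate_target_tac(tracer, da, sched, ref)

# 200 noisy replicates at next-generation-scanner noise
noise = NoiseSpec("ns", hrrt_scale=1.2)
rng = np.random.default_rng(0)
sd = noise.frame_sd(clean.values, sched.frame_mid)
X = clean.values + rng.standard_normal((200, 30)) * sd

det = LpNtPetDetector(schedule=sched, p_eff=5.6).fit(X, ref=ref)
print(f"detected: {det.significant_.mean():.1%}")
print(f"median estimated peak time: {np.median(det.tp_hat_[det.significant_]):.0f} min")
m = det.gamma_[det.significant_] / det.k2a_[det.significant_]
print(f"median normalized magnitude gamma/k2a: {np.median(m):.2f}")
```

prints

```
detected: 100.0%
median estimated peak time: 50 min
median normalized magnitude gamma/k2a: 0.88
```

i.e. at next-generation noise this 250%-amplitude transient is detected in
every replicate; the estimated peak time clusters at the basis-grid values
around the true 55 min (so the voxel is classified *late*), and the
normalized magnitude sits above the 0.8 threshold (classified *high*) in
half of the replicates — amplitude is the harder axis, as the phantom
experiments show in detail.

A command-line interface mirrors the library:
`ntpet pilot1|pilot2|calibrate|phantom-build|phantom-run|sweep --help`.

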