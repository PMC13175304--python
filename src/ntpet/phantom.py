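"""Six-region 3D limbic phantom with per-voxel dopamine ground truth.

The phantom mimics the bilateral putamen, caudate and accumbens inside a
29 x 20 x 17 voxel bounding box, with the published per-region voxel counts
(L putamen 505, L accumbens 58, L caudate 368, R caudate 378, R accumbens
54, R putamen 487; 1850 voxels total).  Region shapes are grown
stochastically from seeded locations to the exact target counts (a loader
for a user-supplied NIfTI integer label volume is provided as an
alternative).  The left putamen carries only null data; every other region
is assigned one amplitude class (low/high) and one timing class
(early/late), and each voxel draws its own transient parameters from the
class distributions:

    high:  G ~ N(400, 50) nM        low:   G ~ N(200, 20) nM
    early: t_p ~ N(40, 3) min       late:  t_p ~ N(55, 10) min,
           both truncated to 35 < t_p < 75
    all:   alpha ~ N(0.7, 0.1);  t_d = t_p - N(5, 10), 35 < t_d < t_p

Tracer kinetics are identical in every voxel (no population variance in
R1, k2, k2a).  The 4D dynamic data are the per-voxel noiseless curves plus
scanner noise, then each frame is smoothed with a 3D Gaussian
(sigma = 0.2 voxels) to introduce spatial correlation.  Bounding-box voxels
outside the six regions contain no PET signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kinetics import (DAResponseParams, FrameSchedule, NoiseSpec, TAC,
                       TracerKineticParams, full_ode_forward, gamma_from_da,
                       gamma_variate, lp_forward, simulate_reference_tac)

__all__ = [
    "RegionSpec",
    "Phantom4D",
    "DEFAULT_REGIONS",
    "BOUNDING_BOX",
    "build_phantom_geometry",
    "assign_truth_classes",
    "load_label_volume",
    "sample_da_parameters",
    "simulate_phantom_4d",
    "tracer_params_are_uniform",
    "save_phantom",
    "load_phantom",
]

BOUNDING_BOX = (29, 20, 17)


@dataclass(frozen=True)
class RegionSpec:
    """One phantom region: name, label, exact voxel count, truth classes.

    ``timing_class`` may be 'early', 'late', or 'split', in which case the
    region is divided into an early and a late half along its longest
    spatial axis (anterior early, posterior late).
    """

    name: str
    label: int
    target_voxel_count: int
    amplitude_class: str | None   # 'low' | 'high' | None for null
    timing_class: str | None      # 'early' | 'late' | 'split' | None
    seed_voxel: tuple = (0, 0, 0)

    def __post_init__(self):
        if self.target_voxel_count <= 0:
            raise ValueError("voxel count must be positive")
        if (self.amplitude_class is None) != (self.timing_class is None):
            raise ValueError("amplitude and timing classes must both be set "
                             "or both be None (null region)")
        if self.amplitude_class not in (None, "low", "high"):
            raise ValueError("amplitude_class must be 'low', 'high' or None")
        if self.timing_class not in (None, "early", "late", "split"):
            raise ValueError("timing_class must be 'early', 'late', 'split' "
                             "or None")

    @property
    def is_null(self) -> bool:
        return self.amplitude_class is None


#: Default regions.  Counts are the published per-region voxel totals; the
#: class layout is a reconstruction (the source figure is an image): the
#: left putamen carries only null data, each caudate is split into an early
#: and a late half, the accumbens are high-amplitude and the right putamen
#: is low-amplitude late.
DEFAULT_REGIONS = (
    RegionSpec("l_putamen", 1, 505, None, None, seed_voxel=(4, 10, 8)),
    RegionSpec("l_accumbens", 2, 58, "high", "early", seed_voxel=(10, 4, 5)),
    RegionSpec("l_caudate", 3, 368, "low", "split", seed_voxel=(10, 13, 10)),
    RegionSpec("r_caudate", 4, 378, "high", "split", seed_voxel=(18, 13, 10)),
    RegionSpec("r_accumbens", 5, 54, "high", "late", seed_voxel=(18, 4, 5)),
    RegionSpec("r_putamen", 6, 487, "low", "late", seed_voxel=(24, 10, 8)),
)


def assign_truth_classes(labels: np.ndarray, specs=DEFAULT_REGIONS):
    """Per-voxel amplitude and timing class codes from the region layout.

    Returns (amplitude, timing) int8 volumes using the Phantom4D codes
    (0 none, 1 low/early, 2 high/late).  'split' regions are divided at the
    median of their longest-axis coordinate: the lower half is early, the
    upper half late.
    """
    amp = np.zeros(labels.shape, dtype=np.int8)
    tim = np.zeros(labels.shape, dtype=np.int8)
    for spec in specs:
        mask = labels == spec.label
        if spec.is_null or not mask.any():
            continue
        amp[mask] = Phantom4D.AMP_CODES[spec.amplitude_class]
        if spec.timing_class in ("early", "late"):
            tim[mask] = Phantom4D.TIM_CODES[spec.timing_class]
        else:
            vox = np.argwhere(mask)
            axis = int(np.argmax(vox.max(0) - vox.min(0)))
            order = np.argsort(vox[:, axis], kind="stable")
            half = len(order) // 2
            early_vox = vox[order[:half]]
            late_vox = vox[order[half:]]
            tim[tuple(early_vox.T)] = Phantom4D.TIM_CODES["early"]
            tim[tuple(late_vox.T)] = Phantom4D.TIM_CODES["late"]
    return amp, tim

_NEIGHBOR_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                     (0, 0, 1), (0, 0, -1)]


def build_phantom_geometry(specs=DEFAULT_REGIONS,
                           shape=BOUNDING_BOX,
                           rng: np.random.Generator | None = None
                           ) -> np.ndarray:
    """Grow one connected component per region to its exact voxel count.

    Stochastic 6-connected region growing from each region's seed voxel;
    regions are disjoint and the per-region counts are exact by
    construction.  Distinct regions never touch, even diagonally — the
    anatomical structures the phantom mimics are separated by white matter,
    so no voxel of one region falls inside the 27-neighborhood of another.
    A fixed default generator makes the shipped geometry reproducible.
    """
    rng = rng or np.random.default_rng(20210901)
    if sum(s.target_voxel_count for s in specs) > np.prod(shape):
        raise ValueError("requested voxel counts exceed bounding-box capacity")
    seeds = [s.seed_voxel for s in specs]
    if len(set(seeds)) != len(seeds):
        raise ValueError("overlapping region seed voxels")
    labels = np.zeros(shape, dtype=np.int16)

    def admissible(v, label):
        # free, and not adjacent (26-connectivity) to any other region
        if labels[v] != 0:
            return False
        x, y, z = v
        nb = labels[max(x - 1, 0):x + 2, max(y - 1, 0):y + 2,
                    max(z - 1, 0):z + 2]
        return bool(np.all((nb == 0) | (nb == label)))

    frontiers, counts = {}, {}
    for spec in specs:
        if not admissible(spec.seed_voxel, spec.label):
            raise ValueError(f"seed of {spec.name} falls inside or next to "
                             "another region")
        labels[spec.seed_voxel] = spec.label
        frontiers[spec.label] = [spec.seed_voxel]
        counts[spec.label] = 1

    # round-robin growth: one voxel per region per round, so no region is
    # enclosed by its neighbors before reaching its target count.  Growth
    # prefers candidates close to the seed (plus a small random jitter),
    # which produces compact blob-like shapes without peninsulas — the
    # nuclei these regions stand in for are smooth, compact structures.
    dists = {s.label: [0.0] for s in specs}

    def pick(frontier, dist, seed_voxel, label):
        while frontier:
            scores = np.asarray(dist) + 1.5 * rng.random(len(frontier))
            i = int(np.argmin(scores))
            free = [n for n in _neighbors(frontier[i], shape)
                    if admissible(n, label)]
            if free:
                nxt = free[int(rng.integers(len(free)))]
                frontier.append(nxt)
                dist.append(float(np.linalg.norm(np.subtract(nxt, seed_voxel))))
                return nxt
            frontier[i] = frontier[-1]
            frontier.pop()
            dist[i] = dist[-1]
            dist.pop()
        return None

    remaining = list(specs)
    while remaining:
        for spec in list(remaining):
            if counts[spec.label] >= spec.target_voxel_count:
                remaining.remove(spec)
                continue
            nxt = pick(frontiers[spec.label], dists[spec.label],
                       spec.seed_voxel, spec.label)
            if nxt is None:
                raise ValueError(f"region {spec.name} ran out of space")
            labels[nxt] = spec.label
            counts[spec.label] += 1
    return labels


def _neighbors(v, shape):
    for off in _NEIGHBOR_OFFSETS:
        n = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
        if all(0 <= n[i] < shape[i] for i in range(3)):
            yield n


def load_label_volume(path, specs=DEFAULT_REGIONS):
    """Ingest a user-supplied NIfTI integer label volume.

    Returns ``(labels, counts)`` where counts maps region name to the number
    of voxels carrying its label.  The volume replaces the synthetic
    geometry; counts are reported, not enforced.
    """
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    if labels.ndim != 3:
        raise ValueError("label volume must be 3D")
    counts = {s.name: int(np.sum(labels == s.label)) for s in specs}
    return labels, counts


# ---------------------------------------------------------------------------
# per-voxel dopamine parameters
# ---------------------------------------------------------------------------

_AMPLITUDE_DISTS = {"high": (400.0, 50.0), "low": (200.0, 20.0)}
_TIMING_DISTS = {"early": (40.0, 3.0), "late": (55.0, 10.0)}
_TP_BOUNDS = (35.0, 75.0)
_ALPHA_DIST = (0.7, 0.1)
_RISE_DIST = (5.0, 10.0)     # t_d = t_p - N(5, 10), truncated to 35 < t_d < t_p


def _truncated_normal(rng, mu, sigma, lo, hi):
    while True:
        x = rng.normal(mu, sigma)
        if lo < x < hi:
            return x


def sample_da_parameters(amplitude_class: str | None, timing_class: str | None,
                         rng: np.random.Generator,
                         baseline: float = 100.0) -> DAResponseParams:
    """Draw one voxel's transient parameters from its class distributions.

    Truncated normals are sampled by rejection.  A null class returns G = 0
    with a placeholder (but valid) shape.
    """
    if amplitude_class is None:
        return DAResponseParams(t_d=40.0, t_p=50.0, alpha=0.7, G=0.0,
                                baseline=baseline)
    mu_g, sd_g = _AMPLITUDE_DISTS[amplitude_class]
    mu_tp, sd_tp = _TIMING_DISTS[timing_class]
    g = _truncated_normal(rng, mu_g, sd_g, 0.0, np.inf)
    t_p = _truncated_normal(rng, mu_tp, sd_tp, *_TP_BOUNDS)
    alpha = _truncated_normal(rng, *_ALPHA_DIST, 0.0, np.inf)
    while True:
        t_d = t_p - rng.normal(*_RISE_DIST)
        if 35.0 < t_d < t_p:
            break
    return DAResponseParams(t_d=t_d, t_p=t_p, alpha=alpha, G=g,
                            baseline=baseline)


# ---------------------------------------------------------------------------
# 4D phantom
# ---------------------------------------------------------------------------

@dataclass
class Phantom4D:
    """Label volume, ground truth, and 4D noisy dynamic data."""

    labels: np.ndarray                 # (X, Y, Z) int
    schedule: FrameSchedule
    dynamic: np.ndarray                # (X, Y, Z, n_frames)
    noiseless: np.ndarray              # (X, Y, Z, n_frames), pre-noise
    truth_td: np.ndarray               # (X, Y, Z) float, NaN outside signal
    truth_tp: np.ndarray
    truth_alpha: np.ndarray
    truth_g: np.ndarray                # 0 in null regions, NaN outside regions
    truth_amplitude: np.ndarray        # (X, Y, Z) int8: 0 none, 1 low, 2 high
    truth_timing: np.ndarray           # 0 none, 1 early, 2 late
    seed: int | None = None

    AMP_CODES = {None: 0, "low": 1, "high": 2}
    TIM_CODES = {None: 0, "early": 1, "late": 2}

    @property
    def region_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def signal_mask(self) -> np.ndarray:
        return self.truth_amplitude > 0

    @property
    def null_mask(self) -> np.ndarray:
        return self.region_mask & ~self.signal_mask

    def voxel_tacs(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Dynamic data of the masked voxels as a (V, n_frames) matrix."""
        mask = self.region_mask if mask is None else mask
        return self.dynamic[mask]


def tracer_params_are_uniform(tracer: TracerKineticParams,
                              per_voxel_jitter: float = 0.0) -> bool:
    """Contract: identical tracer kinetics in every voxel.

    The simulation model deliberately carries no population variance in
    (R1, k2, k2a); requesting per-voxel jitter is rejected.
    """
    if per_voxel_jitter != 0.0:
        raise ValueError("per-voxel tracer variability is not part of the "
                         "simulation model (R1, k2, k2a are uniform)")
    return True


def simulate_phantom_4d(labels: np.ndarray,
                        specs=DEFAULT_REGIONS,
                        tracer: TracerKineticParams | None = None,
                        noise: NoiseSpec | None = None,
                        smooth_sigma: float = 0.2,
                        sched: FrameSchedule | None = None,
                        rng: np.random.Generator | None = None,
                        ref: TAC | None = None,
                        seed: int | None = None) -> Phantom4D:
    """Synthesize noisy 4D dynamic phantom data with recorded ground truth.

    Per voxel: draw class parameters, run the linear generative model
    forward, add frame noise with variance proportional to the noiseless
    value, then smooth each frame spatially (sigma in voxel units) over the
    whole bounding box.  Ground-truth volumes are recorded before noise.
    """
    tracer = tracer or TracerKineticParams()
    noise = noise or NoiseSpec()
    sched = sched or FrameSchedule.uniform()
    if rng is None:
        rng = np.random.default_rng(seed)
    if ref is None:
        ref = simulate_reference_tac(tracer, sched)
    if ref.schedule != sched:
        raise ValueError("reference schedule does not match request")
    tracer_params_are_uniform(tracer)

    shape = labels.shape
    n = sched.n_frames
    mid = sched.frame_mid
    truth_td = np.full(shape, np.nan)
    truth_tp = np.full(shape, np.nan)
    truth_alpha = np.full(shape, np.nan)
    truth_g = np.full(shape, np.nan)

    region_mask = labels > 0
    vox = np.argwhere(region_mask)
    V = len(vox)
    gammas = np.zeros(V)
    h_mid = np.zeros((V, n))
    truth_amp, truth_tim = assign_truth_classes(labels, specs)
    amp_names = {v: k for k, v in Phantom4D.AMP_CODES.items()}
    tim_names = {v: k for k, v in Phantom4D.TIM_CODES.items()}
    da_list = []
    for i, (x, y, z) in enumerate(vox):
        amp_cls = amp_names[int(truth_amp[x, y, z])]
        tim_cls = tim_names[int(truth_tim[x, y, z])]
        p = sample_da_parameters(amp_cls, tim_cls, rng)
        da_list.append(p)
        truth_td[x, y, z] = p.t_d
        truth_tp[x, y, z] = p.t_p
        truth_alpha[x, y, z] = p.alpha
        truth_g[x, y, z] = p.G
        if amp_cls is not None:
            gammas[i] = gamma_from_da(p, tracer)
            h_mid[i] = gamma_variate(mid, p)

    if tracer.mode == "full-ode":
        clean_v = full_ode_forward(tracer, da_list, sched)       # (V, n)
    else:
        clean_v = lp_forward(tracer.r1, tracer.k2, tracer.k2a, gammas, h_mid,
                             ref.values, sched)                  # (V, n)
    noiseless = np.zeros(shape + (n,))
    noiseless[tuple(vox.T)] = clean_v

    sd = noise.frame_sd(clean_v, sched.frame_mid)
    noisy = noiseless.copy()
    noisy[tuple(vox.T)] = clean_v + rng.standard_normal(clean_v.shape) * sd
    if smooth_sigma > 0:
        for f in range(n):
            noisy[..., f] = ndimage.gaussian_filter(noisy[..., f],
                                                    sigma=smooth_sigma)

    return Phantom4D(labels=labels, schedule=sched, dynamic=noisy,
                     noiseless=noiseless, truth_td=truth_td,
                     truth_tp=truth_tp, truth_alpha=truth_alpha,
                     truth_g=truth_g, truth_amplitude=truth_amp,
                     truth_timing=truth_tim, seed=seed)


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def save_phantom(phantom: Phantom4D, directory) -> None:
    """Write the phantom as NIfTI volumes plus a JSON sidecar."""
    import json
    from pathlib import Path

    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)

    def _save(name, arr):
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff),
                 str(directory / f"{name}.nii"))

    _save("dynamic", phantom.dynamic)
    _save("noiseless", phantom.noiseless)
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), aff),
             str(directory / "labels.nii"))
    for name in ("truth_td", "truth_tp", "truth_alpha", "truth_g"):
        _save(name, getattr(phantom, name))
    for name in ("truth_amplitude", "truth_timing"):
        nib.save(nib.Nifti1Image(getattr(phantom, name).astype(np.int16), aff),
                 str(directory / f"{name}.nii"))
    sidecar = dict(seed=phantom.seed,
                   frame_start=phantom.schedule.frame_start.tolist(),
                   frame_end=phantom.schedule.frame_end.tolist())
    (directory / "phantom.json").write_text(json.dumps(sidecar, indent=1))


def load_phantom(directory) -> Phantom4D:
    import json
    from pathlib import Path

    import nibabel as nib

    directory = Path(directory)
    meta = json.loads((directory / "phantom.json").read_text())
    sched = FrameSchedule(np.array(meta["frame_start"]),
                          np.array(meta["frame_end"]))

    def _load(name):
        return np.asarray(nib.load(str(directory / f"{name}.nii")).dataobj)

    return Phantom4D(
        labels=_load("labels").astype(np.int16), schedule=sched,
        dynamic=_load("dynamic"), noiseless=_load("noiseless"),
        truth_td=_load("truth_td"), truth_tp=_load("truth_tp"),
        truth_alpha=_load("truth_alpha"), truth_g=_load("truth_g"),
        truth_amplitude=_load("truth_amplitude").astype(np.int8),
        truth_timing=_load("truth_timing").astype(np.int8),
        seed=meta.get("seed"))
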