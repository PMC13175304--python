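"""Experiment orchestration: pilot studies, noise calibration, phantom runs.

The package has exactly one free scalar, the HRRT noise proportionality
constant ``hrrt_scale`` (the published simulations calibrated their noise
against human scanner data that is not reproduced here).  The protocol is
calibrate-one / predict-many: :func:`calibrate_hrrt_noise` tunes the scalar
so that whole-phantom dBIC detection sensitivity under HRRT noise matches a
stated anchor (31% by default); every other number — next-generation (NS)
sensitivity, post-reclassification sensitivity and specificity, pilot
detection and classification rates, characterization accuracy — is then a
prediction of the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import (ClassifierThresholds, MetricsReport,
                       characterization_accuracy,
                       characterization_sensitivity_m,
                       characterization_sensitivity_tp, confusion_from_labels,
                       detection_sensitivity, detection_specificity,
                       predictive_values)
from .kinetics import (DAResponseParams, FrameSchedule, NoiseSpec, TAC,
                       TracerKineticParams, simulate_reference_tac,
                       simulate_target_tac)
from .lpntpet import LpNtPetDetector
from .phantom import (DEFAULT_REGIONS, Phantom4D, build_phantom_geometry,
                      simulate_phantom_4d)
from .wknn import NeighborhoodWeights, cluster_size_threshold, wknn_reclassify

__all__ = [
    "ExperimentConfig",
    "PhantomReport",
    "simulate_condition",
    "detection_condition",
    "run_pilot1",
    "run_pilot2",
    "calibrate_hrrt_noise",
    "run_phantom_experiment",
    "run_variance_sweep",
]

_GEOMETRY_SEED = 20210901


@dataclass
class ExperimentConfig:
    """Shared experiment settings with the published defaults."""

    replicates: int = 1000
    hrrt_scale: float = 1.0
    p_eff: float = 5.0
    smooth_sigma: float = 0.2
    cst_min_size: int = 10
    seed: int = 0
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    weights: NeighborhoodWeights = field(default_factory=NeighborhoodWeights)
    # experiments generate data with the nonlinear receptor-competition
    # model; the linear generative mode remains available for exact-recovery
    # work by passing mode="lp-generative"
    tracer: TracerKineticParams = field(
        default_factory=lambda: TracerKineticParams(mode="full-ode"))

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _child_seed(seed: int, *tags: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed) % (2 ** 31)] + [int(t) for t in tags])
    return np.random.default_rng(ss)


def _scanner_noise(scanner: str, hrrt_scale: float,
                   variance_factor: float | None = None) -> NoiseSpec:
    return NoiseSpec(scanner=scanner, hrrt_scale=hrrt_scale,
                     variance_factor=variance_factor)


# ---------------------------------------------------------------------------
# single-condition Monte Carlo (pilot building block)
# ---------------------------------------------------------------------------

def simulate_condition(da: DAResponseParams, tracer: TracerKineticParams,
                       sched: FrameSchedule, ref: TAC, noise: NoiseSpec,
                       rng: np.random.Generator, reps: int) -> np.ndarray:
    """``reps`` independent noisy TACs of one DA condition, shape (reps, n)."""
    clean = simulate_target_tac(tracer, da, sched, ref)
    sd = noise.frame_sd(clean.values, sched.frame_mid)
    return clean.values + rng.standard_normal((reps, sched.n_frames)) * sd


def detection_condition(da: DAResponseParams, *, scanner: str,
                        hrrt_scale: float, reps: int = 1000,
                        seed: int = 0, p_eff: float = 5.0,
                        tracer: TracerKineticParams | None = None,
                        sched: FrameSchedule | None = None,
                        ref: TAC | None = None,
                        thresholds: ClassifierThresholds | None = None
                        ) -> dict:
    """Fit one DA condition ``reps`` times; detection and classification rates.

    Returns DS_DA (percent), the fraction of detected responses classified
    early and late at the peak-time threshold, and the per-replicate
    estimates for further analysis.

    Single-condition threshold studies default to the linear generative
    mode so that threshold performance is measured against an
    estimation-commensurate signal (the classifier sees no systematic
    shape bias from a deliberately mismatched generator); pass a
    ``full-ode`` tracer to include receptor-competition mismatch.
    """
    tracer = tracer or TracerKineticParams()
    sched = sched or FrameSchedule.uniform()
    ref = ref or simulate_reference_tac(tracer, sched)
    thresholds = thresholds or ClassifierThresholds()
    import zlib
    noise = _scanner_noise(scanner, hrrt_scale)
    rng = _child_seed(seed, zlib.crc32(scanner.encode()) % 997,
                      int(da.t_p * 10), int(da.g_percent))
    X = simulate_condition(da, tracer, sched, ref, noise, rng, reps)
    det = LpNtPetDetector(schedule=sched, p_eff=p_eff).fit(X, ref=ref)
    sig = det.significant_
    ds = 100.0 * float(np.mean(sig))
    with np.errstate(divide="ignore", invalid="ignore"):
        m_hat = np.where(det.k2a_ != 0, det.gamma_ / det.k2a_, np.inf)
    out = dict(ds_da=ds, n_detected=int(sig.sum()),
               tp_hat=det.tp_hat_, m_hat=m_hat, significant=sig,
               delta_bic=det.delta_bic_)
    if sig.any():
        early = det.tp_hat_[sig] < thresholds.tp_star
        low = m_hat[sig] < thresholds.m_star
        out["frac_early_detected"] = 100.0 * float(np.mean(early))
        out["frac_late_detected"] = 100.0 * float(np.mean(~early))
        out["frac_low_detected"] = 100.0 * float(np.mean(low))
    else:
        out["frac_early_detected"] = out["frac_late_detected"] = float("nan")
        out["frac_low_detected"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# pilot study 1: detection sensitivity over (G%, t_p)
# ---------------------------------------------------------------------------

def run_pilot1(cfg: ExperimentConfig | None = None, *,
               g_percents=tuple(range(50, 601, 50)),
               t_ps=tuple(range(40, 66, 5)),
               t_d: float = 35.0,
               scanners=("hrrt", "ns")) -> pd.DataFrame:
    """DS_DA heatmap table over amplitude and peak-time per scanner.

    Every condition starts at t_d = 35 min with alpha = 0.5; 1000 noisy
    replicates per cell by default.  Conditions are generated in the linear
    (estimation-commensurate) mode; see :func:`detection_condition`.
    """
    cfg = cfg or ExperimentConfig()
    tracer = replace(cfg.tracer, mode="lp-generative")
    sched = FrameSchedule.uniform()
    ref = simulate_reference_tac(tracer, sched)
    rows = []
    for scanner in scanners:
        for g in g_percents:
            for tp in t_ps:
                da = DAResponseParams(t_d, float(tp), 0.5, float(g))
                res = detection_condition(
                    da, scanner=scanner, hrrt_scale=cfg.hrrt_scale,
                    reps=cfg.replicates, seed=cfg.seed, p_eff=cfg.p_eff,
                    tracer=tracer, sched=sched, ref=ref,
                    thresholds=cfg.thresholds)
                rows.append(dict(scanner=scanner, g_percent=g, t_p=tp,
                                 t_d=t_d, ds_da=res["ds_da"]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pilot study 2: classification thresholds
# ---------------------------------------------------------------------------

def run_pilot2(cfg: ExperimentConfig | None = None, *,
               g_percents=(200, 250, 300, 350, 400),
               t_ds=(35.0, 38.0, 41.0, 44.0),
               t_ps=tuple(range(40, 66, 5)),
               tp_stars=(45.0, 50.0, 55.0),
               m_stars=(0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2),
               scanner: str = "ns") -> dict:
    """Classification-threshold study.

    For each (t_d, t_p, G%) condition the detected replicates are classified
    at every candidate threshold.  Characterization sensitivities pool the
    detected estimates into truth groups: true early/late by the simulated
    peak time against each t_p*, true low/high by simulated amplitude
    (lowest vs highest G% of the grid).

    Returns ``conditions`` (per-condition table), ``cs_tp`` and ``cs_m``
    (threshold tables).
    """
    cfg = cfg or ExperimentConfig()
    tracer = replace(cfg.tracer, mode="lp-generative")
    sched = FrameSchedule.uniform()
    ref = simulate_reference_tac(tracer, sched)
    records = []
    for g in g_percents:
        for td in t_ds:
            for tp in t_ps:
                if tp <= td:
                    continue
                da = DAResponseParams(float(td), float(tp), 0.5, float(g))
                res = detection_condition(
                    da, scanner=scanner, hrrt_scale=cfg.hrrt_scale,
                    reps=cfg.replicates, seed=cfg.seed, p_eff=cfg.p_eff,
                    tracer=tracer, sched=sched, ref=ref,
                    thresholds=cfg.thresholds)
                rec = dict(g_percent=g, t_d=td, t_p=tp, rise=tp - td,
                           ds_da=res["ds_da"], n_detected=res["n_detected"],
                           tp_hat=res["tp_hat"][res["significant"]],
                           m_hat=res["m_hat"][res["significant"]])
                for ts in tp_stars:
                    rec[f"frac_early_{ts:g}"] = 100.0 * float(
                        np.mean(rec["tp_hat"] < ts)) if rec["n_detected"] else np.nan
                for ms in m_stars:
                    rec[f"frac_low_{ms:g}"] = 100.0 * float(
                        np.mean(rec["m_hat"] < ms)) if rec["n_detected"] else np.nan
                records.append(rec)

    cs_tp_rows = []
    for ts in tp_stars:
        early = np.concatenate([r["tp_hat"] for r in records if r["t_p"] < ts]
                               or [np.array([])])
        late = np.concatenate([r["tp_hat"] for r in records if r["t_p"] > ts]
                              or [np.array([])])
        if early.size and late.size:
            cs = characterization_sensitivity_tp(early, late, ts)
        else:
            cs = float("nan")
        cs_tp_rows.append(dict(tp_star=ts, cs_tp=cs))

    g_low, g_high = min(g_percents), max(g_percents)
    low = np.concatenate([r["m_hat"] for r in records if r["g_percent"] == g_low]
                         or [np.array([])])
    high = np.concatenate([r["m_hat"] for r in records if r["g_percent"] == g_high]
                          or [np.array([])])
    cs_m_rows = []
    for ms in m_stars:
        if low.size and high.size:
            cs = characterization_sensitivity_m(low, high, ms)
        else:
            cs = float("nan")
        cs_m_rows.append(dict(m_star=ms, cs_m=cs))

    conditions = pd.DataFrame([{k: v for k, v in r.items()
                                if k not in ("tp_hat", "m_hat")}
                               for r in records])
    return dict(conditions=conditions, cs_tp=pd.DataFrame(cs_tp_rows),
                cs_m=pd.DataFrame(cs_m_rows))


# ---------------------------------------------------------------------------
# noise calibration
# ---------------------------------------------------------------------------

def calibrate_hrrt_noise(target_ds: float = 31.0, *, seed: int = 0,
                         tol: float = 1.0,
                         bracket=(1e-3, 100.0),
                         cfg: ExperimentConfig | None = None,
                         labels: np.ndarray | None = None,
                         max_iter: int = 60) -> dict:
    """Bisection on ``hrrt_scale`` to hit a phantom detection-sensitivity anchor.

    Builds one phantom (geometry, per-voxel DA parameters and a unit-variance
    noise field are all held fixed), then scales the noise until the
    whole-phantom dBIC < 0 detection sensitivity under HRRT noise matches
    ``target_ds`` within ``tol`` percentage points.  Sensitivity is strictly
    decreasing in the noise scale, so the bracket is expanded if needed and
    bisected.  Returns the scale, the achieved sensitivity and the iteration
    count.
    """
    from scipy import ndimage

    cfg = cfg or ExperimentConfig()
    sched = FrameSchedule.uniform()
    ref = simulate_reference_tac(cfg.tracer, sched)
    if labels is None:
        labels = build_phantom_geometry(rng=np.random.default_rng(_GEOMETRY_SEED))
    ph = simulate_phantom_4d(labels, DEFAULT_REGIONS, cfg.tracer,
                             NoiseSpec("custom", 1.0, 0.0), smooth_sigma=0.0,
                             sched=sched, rng=_child_seed(seed, 1), ref=ref)
    region = ph.region_mask
    signal = ph.signal_mask[region]
    clean = ph.noiseless[region]                       # (V, n)
    unit = _child_seed(seed, 2).standard_normal(clean.shape)
    det = LpNtPetDetector(schedule=sched, p_eff=cfg.p_eff)

    def ds(scale: float) -> float:
        sd = NoiseSpec("hrrt", scale).frame_sd(clean, sched.frame_mid)
        noisy = clean + sd * unit
        vol = np.zeros(region.shape + (sched.n_frames,))
        vol[region] = noisy
        if cfg.smooth_sigma > 0:
            for f in range(sched.n_frames):
                vol[..., f] = ndimage.gaussian_filter(vol[..., f],
                                                      cfg.smooth_sigma)
        sig = det.fit(vol[region], ref=ref).significant_
        return 100.0 * float(np.mean(sig[signal]))

    lo, hi = bracket
    ds_lo, ds_hi = ds(lo), ds(hi)
    while ds_lo < target_ds and lo > 1e-8:
        lo /= 10.0
        ds_lo = ds(lo)
    while ds_hi > target_ds and hi < 1e6:
        hi *= 10.0
        ds_hi = ds(hi)
    if not (ds_hi <= target_ds <= ds_lo):
        raise ValueError(f"target DS {target_ds}% unattainable in bracket")
    achieved, scale = ds_lo, lo
    for it in range(max_iter):
        mid = np.sqrt(lo * hi)
        val = ds(mid)
        if abs(val - target_ds) <= tol:
            scale, achieved = mid, val
            break
        if val > target_ds:
            lo = mid
        else:
            hi = mid
        scale, achieved = mid, val
    return dict(hrrt_scale=float(scale), achieved_ds=float(achieved),
                iterations=it + 1, target_ds=target_ds)


# ---------------------------------------------------------------------------
# full phantom experiment
# ---------------------------------------------------------------------------

@dataclass
class PhantomReport:
    """End-to-end detection + characterization results for one phantom."""

    scanner: str
    variance_factor: float
    ds_delta_bic: float
    ds_cst: float
    ds_wknn: float
    spec_delta_bic: float
    spec_cst: float
    spec_wknn: float
    metrics: MetricsReport
    detection_mask: np.ndarray
    wknn_mask: np.ndarray
    cst_mask: np.ndarray
    timing_pred: np.ndarray         # 0 none, 1 early, 2 late (post-wkNN)
    amplitude_pred: np.ndarray      # 0 none, 1 low, 2 high (post-wkNN)
    timing_certainty: np.ndarray
    amplitude_certainty: np.ndarray
    phantom: Phantom4D

    def summary_frame(self) -> pd.DataFrame:
        rows = [dict(class_label=c, metric=m, value=v)
                for c, m, v in self.metrics.to_rows()]
        rows = [dict(class_label="all", metric="ds_delta_bic",
                     value=self.ds_delta_bic),
                dict(class_label="all", metric="ds_cst", value=self.ds_cst),
                dict(class_label="all", metric="ds_wknn", value=self.ds_wknn),
                dict(class_label="all", metric="spec_delta_bic",
                     value=self.spec_delta_bic),
                dict(class_label="all", metric="spec_cst", value=self.spec_cst),
                dict(class_label="all", metric="spec_wknn",
                     value=self.spec_wknn)] + rows
        return pd.DataFrame(rows)


_TIM_NAMES = {0: "undetected", 1: "early", 2: "late"}
_AMP_NAMES = {0: "undetected", 1: "low", 2: "high"}


def run_phantom_experiment(cfg: ExperimentConfig | None = None, *,
                           scanner: str = "ns",
                           variance_factor: float | None = None,
                           labels: np.ndarray | None = None,
                           phantom: Phantom4D | None = None) -> PhantomReport:
    """Detection then characterization of one noisy 4D phantom.

    Detection: dBIC < 0 masking, then one weighted-vote reclassification
    pass (the cluster-size-threshold comparator is also computed).
    Characterization: threshold classification of the detected voxels by
    peak time and normalized magnitude, one weighted-vote pass per class
    map, then confusion metrics per class.  Undetected true-signal voxels
    count as negative calls for every class; detected voxels that are truly
    null (none expected after reclassification) are excluded from the
    characterization confusion.
    """
    cfg = cfg or ExperimentConfig()
    sched = FrameSchedule.uniform()
    ref = simulate_reference_tac(cfg.tracer, sched)
    noise = _scanner_noise(scanner, cfg.hrrt_scale, variance_factor)
    if phantom is None:
        if labels is None:
            labels = build_phantom_geometry(
                rng=np.random.default_rng(_GEOMETRY_SEED))
        phantom = simulate_phantom_4d(
            labels, DEFAULT_REGIONS, cfg.tracer, noise, cfg.smooth_sigma,
            sched, _child_seed(cfg.seed, 3, int(1000 * noise.variance_factor)),
            ref=ref, seed=cfg.seed)
    region = phantom.region_mask
    signal = phantom.signal_mask
    null = phantom.null_mask

    det = LpNtPetDetector(schedule=sched, p_eff=cfg.p_eff).fit(
        phantom.voxel_tacs(), ref=ref)
    sig3d = np.zeros(region.shape, dtype=bool)
    sig3d[region] = det.significant_

    ds_pre = detection_sensitivity(np.where(sig3d[signal], -1.0, 1.0))
    spec_pre = detection_specificity(sig3d[null])

    cst_mask = cluster_size_threshold(sig3d, cfg.cst_min_size)
    wknn_labels, _ = wknn_reclassify(sig3d.astype(int), cfg.weights,
                                     domain_mask=region, mode="detection")
    wknn_mask = wknn_labels == 1

    ds_cst = 100.0 * float(np.mean(cst_mask[signal]))
    ds_wknn = 100.0 * float(np.mean(wknn_mask[signal]))
    spec_cst = detection_specificity(cst_mask[null])
    spec_wknn = detection_specificity(wknn_mask[null])

    # --- characterization over the post-reclassification detection mask ---
    thr = cfg.thresholds
    tp_hat3d = np.zeros(region.shape)
    tp_hat3d[region] = det.tp_hat_
    k2a3d = np.zeros(region.shape)
    k2a3d[region] = det.k2a_
    gam3d = np.zeros(region.shape)
    gam3d[region] = det.gamma_
    m_hat3d = np.full(region.shape, np.nan)   # NaN marks k2a == 0 (invalid)
    nz = k2a3d != 0
    m_hat3d[nz] = gam3d[nz] / k2a3d[nz]

    detected = wknn_mask & region
    valid_m = detected & np.isfinite(m_hat3d)
    timing_map = np.zeros(region.shape, dtype=np.int8)
    timing_map[detected] = np.where(tp_hat3d[detected] < thr.tp_star, 1, 2)
    amplitude_map = np.zeros(region.shape, dtype=np.int8)
    amplitude_map[valid_m] = np.where(m_hat3d[valid_m] < thr.m_star, 1, 2)

    timing_post, tim_cert = wknn_reclassify(timing_map, cfg.weights,
                                            domain_mask=region,
                                            mode="characterization")
    amplitude_post, amp_cert = wknn_reclassify(amplitude_map, cfg.weights,
                                               domain_mask=region,
                                               mode="characterization")

    # confusion over true-signal voxels; undetected counts as negative
    tim_pred = np.vectorize(_TIM_NAMES.get)(timing_post[signal])
    tim_true = np.vectorize(_TIM_NAMES.get)(phantom.truth_timing[signal])
    amp_pred = np.vectorize(_AMP_NAMES.get)(amplitude_post[signal])
    amp_true = np.vectorize(_AMP_NAMES.get)(phantom.truth_amplitude[signal])

    ca, pv, conf = {}, {}, {}
    for cls, pred, true in (("early", tim_pred, tim_true),
                            ("late", tim_pred, tim_true),
                            ("low", amp_pred, amp_true),
                            ("high", amp_pred, amp_true)):
        c = confusion_from_labels(pred, true, cls)
        conf[cls] = c
        ca[cls] = characterization_accuracy(c)
        pv[cls] = predictive_values(c)

    detected_sig = signal & wknn_mask
    cs_tp = cs_m = None
    if detected_sig.any():
        e = detected_sig & (phantom.truth_timing == 1)
        l = detected_sig & (phantom.truth_timing == 2)
        if e.any() and l.any():
            cs_tp = characterization_sensitivity_tp(
                tp_hat3d[e], tp_hat3d[l], thr.tp_star)
        lo = detected_sig & (phantom.truth_amplitude == 1) & np.isfinite(m_hat3d)
        hi = detected_sig & (phantom.truth_amplitude == 2) & np.isfinite(m_hat3d)
        if lo.any() and hi.any():
            cs_m = characterization_sensitivity_m(
                m_hat3d[lo], m_hat3d[hi], thr.m_star)

    metrics = MetricsReport(ds_da=ds_wknn, detection_specificity=spec_wknn,
                            cs_tp=cs_tp, cs_m=cs_m, ca_by_class=ca,
                            predictive_by_class=pv, confusion_by_class=conf)
    return PhantomReport(
        scanner=scanner, variance_factor=noise.variance_factor,
        ds_delta_bic=ds_pre, ds_cst=ds_cst, ds_wknn=ds_wknn,
        spec_delta_bic=spec_pre, spec_cst=spec_cst, spec_wknn=spec_wknn,
        metrics=metrics, detection_mask=sig3d, wknn_mask=wknn_mask,
        cst_mask=cst_mask, timing_pred=timing_post,
        amplitude_pred=amplitude_post, timing_certainty=tim_cert,
        amplitude_certainty=amp_cert, phantom=phantom)


def run_full_study(seed: int = 0, *, reps: int = 1000, n_phantoms: int = 5,
                   target_hrrt_ds: float = 31.0, null_fpr: float = 0.10,
                   null_reps: int = 2000) -> dict:
    """Calibrate-one / predict-many reproduction of the headline experiments.

    Procedure:

    1. Calibrate the effective parameter count on ``null_reps`` simulated
       null TACs so the dBIC false-positive rate is ``null_fpr`` (the
       pre-reclassification detection specificity of roughly 90%).
    2. Calibrate ``hrrt_scale`` so whole-phantom detection sensitivity
       under HRRT noise equals ``target_hrrt_ds`` (the single anchor).
    3. Predict, with no further tuning: phantom detection sensitivity and
       specificity for both scanners before and after weighted-vote
       reclassification (averaged over ``n_phantoms`` independent
       phantoms), the single-condition detection and peak-time
       classification rates of the early (t_p = 41 min) and late
       (t_p = 55 min) G = 250% responses under NS noise, characterization
       predictive values on the NS phantom, and low-amplitude
       characterization accuracy at 1/6 of the HRRT variance.

    Returns a flat dict of the calibration outputs and every predicted
    quantity (percentages), plus the problem sizes used.
    """
    from .lpntpet import build_basis_library, calibrate_p_eff

    sched = FrameSchedule.uniform()
    tracer = TracerKineticParams(mode="full-ode")
    ref = simulate_reference_tac(tracer, sched)

    # 1. effective parameter count from null simulations
    null_clean = simulate_target_tac(
        tracer, DAResponseParams(35, 55, 0.5, 0.0), sched)
    sd = NoiseSpec("hrrt", 1.0).frame_sd(null_clean.values, sched.frame_mid)
    rng = _child_seed(seed, 10)
    lib = build_basis_library(sched=sched)
    nulls = [TAC(sched, null_clean.values + rng.standard_normal(sched.n_frames) * sd)
             for _ in range(null_reps)]
    p_eff = calibrate_p_eff(nulls, ref, lib, null_fpr)

    # 2. noise-scale calibration against the HRRT anchor; a tight bisection
    # tolerance matters because the post-vote sensitivity amplifies anchor
    # error roughly threefold around the 31% operating point
    cal = calibrate_hrrt_noise(target_hrrt_ds, seed=seed, tol=0.3,
                               cfg=ExperimentConfig(p_eff=p_eff))
    scale = cal["hrrt_scale"]

    # 3. predictions
    out = dict(p_eff=p_eff, hrrt_scale=scale,
               achieved_hrrt_ds=cal["achieved_ds"], n_phantoms=n_phantoms)
    per_scanner = {}
    spec_wknn_all = []
    for scanner in ("hrrt", "ns"):
        rows = []
        for k in range(n_phantoms):
            cfg = ExperimentConfig(hrrt_scale=scale, p_eff=p_eff,
                                   seed=seed + 1 + k)
            rep = run_phantom_experiment(cfg, scanner=scanner)
            rows.append(rep)
        per_scanner[scanner] = rows
        spec_wknn_all += [r.spec_wknn for r in rows]
        out[f"{scanner}_ds_delta_bic"] = float(
            np.mean([r.ds_delta_bic for r in rows]))
        out[f"{scanner}_ds_wknn"] = float(np.mean([r.ds_wknn for r in rows]))
        out[f"{scanner}_spec_delta_bic"] = float(
            np.mean([r.spec_delta_bic for r in rows]))
    out["detection_specificity_wknn"] = float(np.mean(spec_wknn_all))

    ns_rows = per_scanner["ns"]
    for key, cls, metric in (("ppv_high", "high", "ppv"),
                             ("ppv_early", "early", "ppv"),
                             ("npv_late", "late", "npv")):
        out[key] = float(np.mean(
            [r.metrics.predictive_by_class[cls][metric] for r in ns_rows]))

    early = detection_condition(
        DAResponseParams(35, 41, 0.5, 250.0), scanner="ns", hrrt_scale=scale,
        reps=reps, seed=seed, p_eff=p_eff)
    late = detection_condition(
        DAResponseParams(35, 55, 0.5, 250.0), scanner="ns", hrrt_scale=scale,
        reps=reps, seed=seed, p_eff=p_eff)
    out["pilot_early_ds"] = early["ds_da"]
    out["pilot_late_ds"] = late["ds_da"]
    out["pilot_early_frac_early"] = early["frac_early_detected"]
    out["pilot_late_frac_late"] = late["frac_late_detected"]
    out["pilot_early_n_detected"] = early["n_detected"]
    out["pilot_late_n_detected"] = late["n_detected"]
    out["pilot_reps"] = reps

    ca6 = []
    for k in range(n_phantoms):
        cfg = ExperimentConfig(hrrt_scale=scale, p_eff=p_eff,
                               seed=seed + 1 + k)
        rep6 = run_phantom_experiment(cfg, scanner="custom",
                                      variance_factor=1 / 6)
        ca6.append(rep6.metrics.ca_by_class["low"])
    out["ca_low_6fold"] = float(np.mean(ca6))
    out["n_signal_voxels"] = int(np.sum(
        ns_rows[0].phantom.signal_mask))
    out["n_null_voxels"] = int(np.sum(ns_rows[0].phantom.null_mask))
    return out


def run_variance_sweep(cfg: ExperimentConfig | None = None, *,
                       factors=(1 / 15, 1 / 10, 1 / 8, 1 / 6),
                       labels: np.ndarray | None = None) -> pd.DataFrame:
    """Characterization accuracy per class across scanner variance factors."""
    cfg = cfg or ExperimentConfig()
    rows = []
    for f in factors:
        rep = run_phantom_experiment(cfg, scanner="custom",
                                     variance_factor=f, labels=labels)
        row = dict(variance_factor=f, ds_wknn=rep.ds_wknn,
                   ds_delta_bic=rep.ds_delta_bic)
        for cls, ca in rep.metrics.ca_by_class.items():
            row[f"ca_{cls}"] = ca
        rows.append(row)
    return pd.DataFrame(rows)
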