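"""Basis library, MRTM / lp-ntPET least squares, and BIC model comparison."""

import numpy as np
import pytest

from ntpet.kinetics import (DAResponseParams, FrameSchedule, NoiseSpec, TAC,
                            gamma_variate, lp_forward)
from ntpet.lpntpet import (BasisGridSpec, LpNtPetDetector, bic,
                           build_basis_library, calibrate_p_eff,
                           compare_models, fit_lpntpet, fit_mrtm)


def _tac_from(values, sched):
    return TAC(sched, values)


def _make_target(tracer, sched, ref, basis, gamma):
    ct = lp_forward(tracer.r1, tracer.k2, tracer.k2a, gamma, basis.values,
                    ref.values, sched)
    return TAC(sched, ct)


class TestBasisLibrary:
    def test_default_library_has_38_bases(self, lib):
        assert len(lib) == 38

    def test_grid_ranges(self, lib):
        tds = {b.t_d for b in lib}
        tps = {b.t_p for b in lib}
        assert min(tds) == 35 and max(tds) == 45
        assert min(tps) == 40 and max(tps) == 70   # t_p=35 has no valid t_d
        assert all(b.t_p > b.t_d for b in lib)
        assert all(b.alpha == 0.5 for b in lib)

    def test_single_pair_library(self, sched):
        spec = BasisGridSpec(t_d_values=(35.0,), t_p_values=(50.0,))
        assert len(build_basis_library(spec, sched)) == 1

    def test_unit_peak_on_midpoint(self, sched):
        # 46.5 min is a frame midpoint: the evaluated basis must reach 1 there
        spec = BasisGridSpec(t_d_values=(35.0,), t_p_values=(46.5,))
        b = build_basis_library(spec, sched)[0]
        assert b.values.max() == pytest.approx(1.0)
        assert sched.frame_mid[np.argmax(b.values)] == 46.5

    def test_empty_grid_rejected(self, sched):
        spec = BasisGridSpec(t_d_values=(50.0,), t_p_values=(40.0,))
        with pytest.raises(ValueError):
            build_basis_library(spec, sched)

    def test_values_bounded(self, lib):
        m = lib.matrix
        assert np.all((m >= 0) & (m <= 1))


class TestMrtmFit:
    def test_exact_recovery_on_own_model(self, tracer, sched, ref):
        target = _make_target(tracer, sched, ref,
                              type("B", (), {"values": np.zeros(30)}), 0.0)
        fit = fit_mrtm(target, ref)
        assert fit.r1 == pytest.approx(tracer.r1, rel=1e-9)
        assert fit.k2 == pytest.approx(tracer.k2, rel=1e-9)
        assert fit.k2a == pytest.approx(tracer.k2a, rel=1e-9)
        assert fit.sse < 1e-18

    def test_residual_orthogonal_to_regressors(self, tracer, sched, ref, lib):
        rng = np.random.default_rng(0)
        target = _make_target(tracer, sched, ref, lib[10], 0.05)
        noisy = TAC(sched, target.values + rng.standard_normal(30))
        fit = fit_mrtm(noisy, ref)
        from ntpet.kinetics import cumtrapz_from_zero
        mid = sched.frame_mid
        design = np.column_stack([ref.values,
                                  cumtrapz_from_zero(ref.values, mid),
                                  -cumtrapz_from_zero(noisy.values, mid)])
        pred = design @ np.array([fit.r1, fit.k2, fit.k2a])
        resid = noisy.values - pred
        for col in design.T:
            assert abs(resid @ col) < 1e-8 * np.linalg.norm(resid) * np.linalg.norm(col)

    def test_rank_deficient_reference_rejected(self, sched):
        zero = TAC(sched, np.zeros(30))
        with pytest.raises(ValueError):
            fit_mrtm(zero, zero)

    def test_schedule_mismatch_rejected(self, tracer, sched, ref):
        other = FrameSchedule.uniform(n_frames=10, frame_minutes=9.0)
        with pytest.raises(ValueError):
            fit_mrtm(TAC(other, np.ones(10)), ref)


class TestLpFit:
    def test_noiseless_round_trip_recovers_all_parameters(self, tracer, sched,
                                                          ref, lib):
        basis = lib[17]
        gamma = 0.09
        target = _make_target(tracer, sched, ref, basis, gamma)
        fit = fit_lpntpet(target, ref, lib)
        assert fit.r1 == pytest.approx(tracer.r1, rel=1e-6)
        assert fit.k2 == pytest.approx(tracer.k2, rel=1e-6)
        assert fit.k2a == pytest.approx(tracer.k2a, rel=1e-6)
        assert fit.gamma == pytest.approx(gamma, rel=1e-6)
        assert fit.basis.index == basis.index

    def test_null_signal_gives_zero_gamma(self, tracer, sched, ref, lib):
        target = _make_target(tracer, sched, ref, lib[0], 0.0)
        fit_lp = fit_lpntpet(target, ref, lib)
        fit_m = fit_mrtm(target, ref)
        assert fit_lp.sse < 1e-16 and fit_m.sse < 1e-16
        assert abs(fit_lp.gamma) < 1e-8

    def test_reported_minimum_matches_exhaustive_search(self, tracer, sched,
                                                        ref, lib):
        # independent oracle: refit with each single-basis library in turn
        rng = np.random.default_rng(3)
        target = _make_target(tracer, sched, ref, lib[20], 0.08)
        noisy = TAC(sched, target.values
                    + rng.standard_normal(30) * 0.5 * np.sqrt(np.maximum(target.values, 0)))
        best = fit_lpntpet(noisy, ref, lib)
        sses = []
        for b in lib:
            single = build_basis_library(
                BasisGridSpec(t_d_values=(b.t_d,), t_p_values=(b.t_p,)), sched)
            sses.append(fit_lpntpet(noisy, ref, single).sse)
        assert best.sse == pytest.approx(min(sses), rel=1e-10)
        assert best.basis.index == int(np.argmin(sses))

    def test_nested_sse_inequality_on_noisy_data(self, tracer, sched, ref, lib):
        rng = np.random.default_rng(4)
        target = _make_target(tracer, sched, ref, lib[5], 0.06)
        for _ in range(25):
            noisy = TAC(sched, target.values + rng.standard_normal(30)
                        * np.sqrt(np.maximum(target.values, 0)))
            assert fit_lpntpet(noisy, ref, lib).sse <= fit_mrtm(noisy, ref).sse


class TestModelComparison:
    def test_bic_hand_value(self):
        # p=3, n=30, SSE=3.0 -> 3*ln30 + 30*ln(0.1)
        assert bic(3.0, 30, 3) == pytest.approx(-58.874, abs=5e-4)

    def test_equal_sse_penalty_gap(self, tracer, sched, ref, lib):
        fit_m = type("M", (), {"sse": 2.0})
        fit_l = type("L", (), {"r1": 1, "k2": .3, "k2a": .1, "gamma": 0.0,
                               "basis": lib[0], "sse": 2.0})
        cmp_ = compare_models(fit_l, fit_m, n=30, p_eff=5.0)
        assert cmp_.delta_bic == pytest.approx(2 * np.log(30), rel=1e-9)
        assert not cmp_.significant

    def test_significant_iff_negative_delta(self, tracer, sched, ref, lib):
        fit_m = type("M", (), {"sse": 2.0})
        fit_l = type("L", (), {"r1": 1, "k2": .3, "k2a": .1, "gamma": 0.1,
                               "basis": lib[0], "sse": 0.5})
        cmp_ = compare_models(fit_l, fit_m, n=30, p_eff=5.0)
        assert cmp_.significant and cmp_.delta_bic < 0

    @pytest.mark.parametrize("p_eff", [3.9, 7.1])
    def test_p_eff_range_enforced(self, lib, p_eff):
        fit_m = type("M", (), {"sse": 2.0})
        fit_l = type("L", (), {"r1": 1, "k2": .3, "k2a": .1, "gamma": 0.1,
                               "basis": lib[0], "sse": 1.0})
        with pytest.raises(ValueError):
            compare_models(fit_l, fit_m, n=30, p_eff=p_eff)


def _null_tacs(tracer, sched, ref, n, scale, rng):
    clean = lp_forward(tracer.r1, tracer.k2, tracer.k2a, 0.0,
                       np.zeros(sched.n_frames), ref.values, sched)
    sd = NoiseSpec("hrrt", scale).frame_sd(clean, sched.frame_mid)
    return [TAC(sched, clean + rng.standard_normal(30) * sd)
            for _ in range(n)]


class TestPEffCalibration:
    def test_trivial_target_returns_lower_bound(self, tracer, sched, ref, lib):
        tacs = _null_tacs(tracer, sched, ref, 50, 1.0,
                          np.random.default_rng(0))
        assert calibrate_p_eff(tacs, ref, lib, target_fpr=1.0) == 3.5

    def test_fpr_monotone_in_p_eff(self, tracer, sched, ref, lib):
        tacs = _null_tacs(tracer, sched, ref, 800, 1.0,
                          np.random.default_rng(1))
        ct = np.stack([t.values for t in tacs])
        det = LpNtPetDetector(schedule=sched, p_eff=4.0)
        fprs = []
        for p_eff in (4.0, 5.0, 6.0, 7.0):
            det.set_params(p_eff=p_eff)
            fprs.append(det.fit(ct, ref=ref).significant_.mean())
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))

    def test_calibrated_fpr_near_target_on_fresh_nulls(self, tracer, sched,
                                                       ref, lib):
        target = 0.10
        tacs = _null_tacs(tracer, sched, ref, 1500, 1.0,
                          np.random.default_rng(2))
        p_eff = calibrate_p_eff(tacs, ref, lib, target)
        fresh = _null_tacs(tracer, sched, ref, 1500, 1.0,
                           np.random.default_rng(3))
        det = LpNtPetDetector(schedule=sched, p_eff=p_eff).fit(
            np.stack([t.values for t in fresh]), ref=ref)
        fpr = det.significant_.mean()
        # binomial CI around the target at n=1500
        assert abs(fpr - target) < 3 * np.sqrt(target * (1 - target) / 1500)

    def test_unattainable_target_raises(self, tracer, sched, ref, lib):
        tacs = _null_tacs(tracer, sched, ref, 100, 1.0,
                          np.random.default_rng(4))
        with pytest.raises(ValueError):
            calibrate_p_eff(tacs, ref, lib, target_fpr=0.0)


class TestDetector:
    def test_detection_power_monotone_in_gamma(self, tracer, sched, ref, lib):
        rng = np.random.default_rng(5)
        reps = 400
        rates = []
        det = LpNtPetDetector(schedule=sched, p_eff=5.7)
        for gamma in (0.0, 0.04, 0.08, 0.15):
            clean = lp_forward(tracer.r1, tracer.k2, tracer.k2a, gamma,
                               lib[17].values, ref.values, sched)
            sd = NoiseSpec("ns", 1.0).frame_sd(clean, sched.frame_mid)
            X = clean + rng.standard_normal((reps, 30)) * sd
            rates.append(det.fit(X, ref=ref).significant_.mean())
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0] + 0.3

    def test_sklearn_params_round_trip(self):
        det = LpNtPetDetector(p_eff=6.0)
        params = det.get_params()
        assert params["p_eff"] == 6.0
        det.set_params(p_eff=4.5)
        assert det.p_eff == 4.5

    def test_result_frame_shape(self, tracer, sched, ref, lib):
        clean = lp_forward(tracer.r1, tracer.k2, tracer.k2a, 0.05,
                           lib[3].values, ref.values, sched)
        X = np.tile(clean, (4, 1))
        det = LpNtPetDetector(schedule=sched, p_eff=5.0).fit(X, ref=ref)
        frame = det.result_.to_frame()
        assert len(frame) == 4
        assert {"gamma", "delta_bic", "significant"} <= set(frame.columns)
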