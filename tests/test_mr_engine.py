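import math

import numpy as np
import pytest
from scipy import stats

from medax.errors import ValidationError
from medax.mr_engine import (
    bidirectional,
    cochran_q,
    egger,
    ivw,
    mode_estimate,
    mr_presso,
    run_battery,
    wald_ratio,
    weighted_median,
)
from medax.summary_io import harmonize
from medax.instruments import InstrumentSet
from medax.synthetic_data import SimulationConfig, simulate_two_sample

from conftest import make_instrument_set


def simulated_set(cfg: SimulationConfig) -> InstrumentSet:
    exp, outc, _, _ = simulate_two_sample(cfg)
    return InstrumentSet("exposure", "outcome", harmonize(exp, outc))


# -- independent oracles (explicit loop arithmetic, no linear algebra) --------

def oracle_ivw_fixed(bx, by, sy):
    num = den = 0.0
    for x, y, s in zip(bx, by, sy):
        num += (1 / s**2) * x * y
        den += (1 / s**2) * x * x
    beta = num / den
    return beta, math.sqrt(1 / den)

def oracle_wls_with_intercept(bx, by, sy):
    # 2x2 normal equations solved by Cramer's rule
    sw = swx = swxx = swy = swxy = 0.0
    for x, y, s in zip(bx, by, sy):
        w = 1 / s**2
        sw += w; swx += w * x; swxx += w * x * x; swy += w * y; swxy += w * x * y
    det = sw * swxx - swx * swx
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    return intercept, slope

def oracle_q(bx, by, sy, beta_ref):
    return sum((1 / s**2) * (y - beta_ref * x) ** 2 for x, y, s in zip(bx, by, sy))


class TestIVW:
    def test_exactly_proportional(self, proportional_set):
        est = ivw(proportional_set)
        assert est.beta == pytest.approx(0.5, abs=1e-14)
        q, _, qp = cochran_q(proportional_set, est.beta)
        assert q == pytest.approx(0.0, abs=1e-20) and qp == pytest.approx(1.0)

    def test_single_snp_is_wald_ratio(self):
        iset = make_instrument_set([0.2], [0.1], [0.05])
        est = ivw(iset)
        assert est.method == "wald"
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.25)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            bx = rng.normal(0.1, 0.05, n)
            by = rng.normal(0.05, 0.05, n)
            sy = rng.uniform(0.01, 0.2, n)
            iset = make_instrument_set(bx, by, sy)
            beta_o, se_o = oracle_ivw_fixed(bx, by, sy)
            est = ivw(iset, variant="fixed")
            assert est.beta == pytest.approx(beta_o, abs=1e-10)
            assert est.se == pytest.approx(se_o, abs=1e-10)

    def test_random_effects_se_never_smaller_than_fixed(self):
        rng = np.random.default_rng(4)
        bx = rng.normal(0.1, 0.05, 10)
        by = 0.3 * bx + rng.normal(0, 0.3, 10)
        sy = rng.uniform(0.01, 0.1, 10)
        iset = make_instrument_set(bx, by, sy)
        assert ivw(iset, "multiplicative_random").se >= ivw(iset, "fixed").se

    def test_equal_se_reduces_to_origin_least_squares(self):
        rng = np.random.default_rng(5)
        bx = rng.normal(0.2, 0.05, 8)
        by = rng.normal(0.1, 0.05, 8)
        iset = make_instrument_set(bx, by, np.full(8, 0.07))
        closed_form = float(bx @ by / (bx @ bx))  # OLS through the origin
        assert ivw(iset, "fixed").beta == pytest.approx(closed_form, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            ivw(make_instrument_set([], [], []))


class TestEgger:
    def test_perfect_proportionality(self, proportional_set):
        slope, intercept = egger(proportional_set)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_affine_data_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.02 + 0.5 * bx
        iset = make_instrument_set(bx, by, np.full(5, 0.05))
        slope, intercept = egger(iset)
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.beta == pytest.approx(0.02, abs=1e-10)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            bx = rng.uniform(0.05, 0.5, n)  # positive: orientation is a no-op
            by = rng.normal(0.05, 0.1, n)
            sy = rng.uniform(0.01, 0.2, n)
            slope, intercept = egger(make_instrument_set(bx, by, sy))
            int_o, slope_o = oracle_wls_with_intercept(bx, by, sy)
            assert slope.beta == pytest.approx(slope_o, abs=1e-10)
            assert intercept.beta == pytest.approx(int_o, abs=1e-10)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.05, 0.5, 6)
        by = 0.01 + 0.4 * bx + rng.normal(0, 0.02, 6)
        sy = np.full(6, 0.05)
        flip = np.array([1, -1, 1, -1, 1, -1.0])
        s1, i1 = egger(make_instrument_set(bx, by, sy))
        s2, i2 = egger(make_instrument_set(bx * flip, by * flip, sy))
        assert s1.beta == pytest.approx(s2.beta, abs=1e-12)
        assert i1.beta == pytest.approx(i2.beta, abs=1e-12)

    def test_two_snps_rejected(self):
        with pytest.raises(ValidationError):
            egger(make_instrument_set([0.1, 0.2], [0.05, 0.1], [0.1, 0.1]))

    def test_recovers_directional_pleiotropy(self):
        # every SNP carries pleiotropy alpha ~ N(0.05, 0.01^2), InSIDE holds
        cfg = SimulationConfig(
            seed=21, n_snps=80, true_theta=0.2,
            pleiotropy_frac=1.0, pleiotropy_mean=0.05, pleiotropy_sd=0.01,
        )
        iset = simulated_set(cfg)
        _, intercept = egger(iset)
        assert abs(intercept.beta - 0.05) < 3 * intercept.se


class TestWeightedMedian:
    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = weighted_median(make_instrument_set(bx, 0.5 * bx, [0.1, 0.1, 0.1]), seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_majority_valid_ratios(self):
        # ratios [0.5,0.5,0.5,5,5] with equal weights -> interpolated median 0.5
        bx = np.ones(5)
        by = np.array([0.5, 0.5, 0.5, 5.0, 5.0])
        est = weighted_median(make_instrument_set(bx, by, np.ones(5)), seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.1, 0.4, 10)
        by = 0.3 * bx + rng.normal(0, 0.05, 10)
        iset = make_instrument_set(bx, by, np.full(10, 0.05))
        a = weighted_median(iset, seed=42)
        b = weighted_median(iset, seed=42)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_breakdown_under_minority_invalid(self):
        # < 50% of weight invalid with a common bias: estimate near truth
        cfg = SimulationConfig(
            seed=30, n_snps=50, true_theta=0.2,
            pleiotropy_frac=0.3, pleiotropy_mean=0.1, pleiotropy_sd=0.01,
        )
        est = weighted_median(simulated_set(cfg), seed=1)
        assert abs(est.beta - 0.2) < 3 * est.se


class TestModeEstimate:
    def test_modal_cluster_found(self):
        bx = np.ones(5)
        by = np.array([0.5, 0.5, 0.5, 5.0, 5.0])
        est = mode_estimate(make_instrument_set(bx, by, np.ones(5)), seed=0)
        assert est.beta == pytest.approx(0.5, abs=0.3)

    def test_identical_ratios_exact(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = mode_estimate(make_instrument_set(bx, 0.5 * bx, [0.1] * 3), seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-9)

    def test_bandwidth_keeps_estimate_in_ratio_hull(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.1, 0.5, 8)
        by = rng.normal(0.1, 0.1, 8)
        iset = make_instrument_set(bx, by, np.full(8, 0.05))
        ratios = by / bx
        for phi in (0.5, 1.0, 2.0):
            est = mode_estimate(iset, bandwidth_factor=phi, seed=0, n_boot=50)
            assert ratios.min() - 1e-9 <= est.beta <= ratios.max() + 1e-9


class TestCochranQ:
    def test_summation_oracle(self):
        bx = [0.1, 0.25, 0.4]
        by = [0.06, 0.1, 0.25]
        sy = [0.05, 0.08, 0.1]
        q, df, p = cochran_q(make_instrument_set(bx, by, sy), beta_ref=0.5)
        q_o = oracle_q(bx, by, sy, 0.5)
        assert q == pytest.approx(q_o, abs=1e-10)
        assert df == 2
        assert p == pytest.approx(float(stats.chi2.sf(q_o, 2)), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        bx = rng.uniform(0.1, 0.4, 6)
        by = rng.normal(0.1, 0.1, 6)
        sy = rng.uniform(0.02, 0.1, 6)
        q1, _, _ = cochran_q(make_instrument_set(bx, by, sy), 0.3)
        perm = rng.permutation(6)
        q2, _, _ = cochran_q(make_instrument_set(bx[perm], by[perm], sy[perm]), 0.3)
        assert q1 == pytest.approx(q2, rel=1e-12)


class TestMRPresso:
    def test_no_pleiotropy_global_p_calibrated(self):
        # clean sets: global test should rarely reject
        hits = 0
        for seed in range(50):
            iset = simulated_set(SimulationConfig(seed=1000 + seed, n_snps=20, true_theta=0.2))
            gp, _, _ = mr_presso(iset, n_sim=300, seed=seed)
            hits += gp > 0.05
        assert hits >= 45  # >= 90% of replicates

    def test_implanted_outlier_flagged_and_corrected(self):
        iset = simulated_set(SimulationConfig(seed=77, n_snps=20, true_theta=0.2))
        pairs = list(iset.pairs)
        bad = pairs[3]
        from dataclasses import replace

        pairs[3] = replace(bad, beta_outcome=bad.beta_outcome + 10 * bad.se_outcome)
        spiked = InstrumentSet("exposure", "outcome", pairs)
        gp, outliers, corrected = mr_presso(spiked, n_sim=500, seed=5)
        assert bad.snp_id in outliers
        assert corrected is not None
        naive = ivw(spiked)
        assert abs(corrected.beta - 0.2) < abs(naive.beta - 0.2)

    def test_three_snps_rejected(self):
        with pytest.raises(ValidationError):
            mr_presso(make_instrument_set([0.1] * 3, [0.05] * 3, [0.1] * 3))


class TestRunBattery:
    def test_consistent_strong_effect_reliable(self):
        iset = simulated_set(SimulationConfig(seed=13, n_snps=30, true_theta=0.3))
        rep = run_battery(iset, seed=0, n_boot=200, presso_sims=200)
        assert rep.reliable
        signs = {np.sign(e.beta) for e in rep.estimates.values() if e.method != "egger_intercept"}
        assert signs == {1.0}

    def test_nonsignificant_ivw_never_reliable(self):
        iset = simulated_set(SimulationConfig(seed=14, n_snps=30, true_theta=0.0))
        rep = run_battery(iset, seed=0, n_boot=200, presso_sims=200)
        assert rep.ivw.pvalue > 0.05  # null model, this seed
        assert not rep.reliable

    def test_sign_disagreement_not_reliable(self):
        # strong IVW signal but Egger slope of opposite sign: constructed data
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.5 - 0.8 * bx  # big positive intercept, negative slope
        iset = make_instrument_set(bx, by, np.full(5, 0.01))
        rep = run_battery(iset, seed=0, n_boot=100, presso_sims=100)
        ivw_sign = np.sign(rep.ivw.beta)
        egger_sign = np.sign(rep.estimates["egger_slope"].beta)
        assert ivw_sign != egger_sign
        assert not rep.reliable

    def test_small_set_degrades(self):
        iset = make_instrument_set([0.2, 0.3], [0.1, 0.15], [0.05, 0.05])
        rep = run_battery(iset, seed=0)
        assert "weighted_median" in rep.degraded and "mr_presso" in rep.degraded
        assert "ivw" in rep.estimates


class TestUnitCoherence:
    def test_rescaling_exposure_rescales_estimates(self):
        rng = np.random.default_rng(15)
        bx = rng.uniform(0.1, 0.4, 10)
        by = 0.3 * bx + rng.normal(0, 0.02, 10)
        sy = np.full(10, 0.05)
        c = 4.0
        for fn in (lambda s: ivw(s).beta,
                   lambda s: egger(s)[0].beta,
                   lambda s: weighted_median(s, seed=0, n_boot=50).beta):
            base = fn(make_instrument_set(bx, by, sy))
            scaled = fn(make_instrument_set(c * bx, by, sy))
            assert scaled == pytest.approx(base / c, rel=1e-9)


class TestBidirectional:
    def test_empty_reverse_direction(self):
        fwd = simulated_set(SimulationConfig(seed=16, n_snps=20, true_theta=0.3))
        rep = bidirectional(fwd, None, seed=0, n_boot=100, presso_sims=100)
        assert rep.reverse is None
        assert rep.forward is not None and rep.forward.reliable
        assert "no instruments" in rep.interpretation

    def test_unidirectional_flag(self):
        fwd = simulated_set(SimulationConfig(seed=17, n_snps=30, true_theta=0.3))
        rev = simulated_set(SimulationConfig(seed=18, n_snps=30, true_theta=0.0))
        rep = bidirectional(fwd, rev, seed=0, n_boot=100, presso_sims=100)
        assert rep.interpretation == "unidirectional"

    def test_symmetric_null_mostly_nonsignificant(self):
        quiet = 0
        for seed in range(20):
            fwd = simulated_set(SimulationConfig(seed=500 + seed, n_snps=20, true_theta=0.0))
            rev = simulated_set(SimulationConfig(seed=700 + seed, n_snps=20, true_theta=0.0))
            rep = bidirectional(fwd, rev, seed=seed, n_boot=50, presso_sims=50)
            fwd_sig = rep.forward.ivw.pvalue < 0.05
            rev_sig = rep.reverse.ivw.pvalue < 0.05
            quiet += (not fwd_sig) and (not rev_sig)
        assert quiet >= 18  # >= 90%
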