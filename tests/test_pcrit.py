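"""SMR estimation and Pcrit breakpoint determination."""

import numpy as np
import pytest

from respcrit import (
    FishProfile,
    MO2Series,
    SmrEstimate,
    estimate_pcrit_broken_stick,
    estimate_pcrit_intersection,
    estimate_pcrit_nonlinear,
    estimate_smr,
    simulate_mo2_series,
)
from respcrit.pcrit import _fit_at_breakpoint


def brute_force_breakpoint(po2, mo2):
    """Independent oracle: exhaustive scan of every candidate breakpoint.

    Enumerates the same search space by definition (interior observed PO2
    plus midpoints of adjacent values) but solves each constrained
    two-segment fit from scratch through explicitly assembled normal
    equations, and breaks ties toward lower PO2.
    """
    xs = np.sort(np.unique(po2))
    cands = sorted(set(xs[1:-1]) | set((xs[:-1] + xs[1:]) / 2.0))
    best_bp, best_rss = None, np.inf
    for bp in cands:
        g0 = np.ones_like(po2)
        g1 = np.where(po2 < bp, po2 - bp, 0.0)
        g2 = np.where(po2 >= bp, po2 - bp, 0.0)
        G = np.empty((3, 3))
        basis = (g0, g1, g2)
        rhs = np.empty(3)
        for a in range(3):
            rhs[a] = float(basis[a] @ mo2)
            for b in range(3):
                G[a, b] = float(basis[a] @ basis[b])
        coef = np.linalg.solve(G + 1e-12 * np.eye(3), rhs)
        resid = mo2 - (coef[0] * g0 + coef[1] * g1 + coef[2] * g2)
        rss = float(resid @ resid)
        if rss < best_rss - 1e-12:
            best_rss, best_bp = rss, bp
    return best_bp, best_rss


class TestSmr:
    def test_lowest_and_mean_lowest(self):
        values = [10, 8, 12, 9, 11]
        assert estimate_smr(values, "lowest").value == 8
        assert estimate_smr(values, "mean_lowest_n", 2).value == 8.5

    def test_quantile_recovers_simulated_smr(self):
        rng = np.random.default_rng(11)
        # routine activity inflates most observations above the true SMR of 100
        mo2 = 100.0 * np.exp(np.abs(rng.normal(0.0, 0.15, size=200)))
        est = estimate_smr(mo2, "quantile", 0.15)
        assert est.value == pytest.approx(100.0, rel=0.05)

    def test_zero_speed_extrapolation_exact_on_exponential(self):
        speeds = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        mo2 = 80.0 * np.exp(0.4 * speeds)
        est = estimate_smr(mo2, "zero_speed_extrapolation", speeds=speeds)
        assert est.value == pytest.approx(80.0, rel=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            estimate_smr([1, 2, 3], "lowest")  # too few
        with pytest.raises(ValueError):
            estimate_smr([1, 2, 3, 4, 5], "quantile", 1.5)
        with pytest.raises(ValueError):
            estimate_smr([1, -2, 3], "zero_speed_extrapolation", speeds=[1, 2, 3])


def _series(po2, mo2):
    po2 = np.asarray(po2, dtype=float)
    return MO2Series(po2=po2, mo2=np.asarray(mo2, dtype=float), window_span=np.zeros_like(po2))


class TestBrokenStick:
    def test_noiseless_breakpoint_exact(self):
        po2 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0])
        mo2 = np.where(po2 >= 5.0, 100.0, 20.0 * po2)
        res = estimate_pcrit_broken_stick(_series(po2, mo2))
        assert res.classification == "oxyregulator"
        assert res.pcrit == pytest.approx(5.0, abs=1e-9)
        assert res.segment_below[0] == pytest.approx(20.0, abs=1e-8)
        assert res.segment_above[0] == pytest.approx(0.0, abs=1e-8)

    def test_proportional_data_is_oxyconformer(self):
        po2 = np.linspace(20, 1, 12)
        res = estimate_pcrit_broken_stick(_series(po2, 10.0 * po2))
        assert res.classification == "oxyconformer"
        assert res.pcrit is None

    def test_rss_ordering_invariant(self):
        rng = np.random.default_rng(5)
        po2 = np.linspace(18, 1, 25)
        mo2 = np.where(po2 > 6, 90.0, 15.0 * po2) * (1 + 0.05 * rng.standard_normal(25))
        res = estimate_pcrit_broken_stick(_series(po2, mo2))
        assert res.rss_two_segment <= res.rss_one_segment + 1e-9

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(60):
            n = int(rng.integers(10, 25))
            lo, hi = rng.uniform(0.5, 2.0), rng.uniform(12.0, 20.0)
            po2 = np.sort(np.concatenate([[lo, hi], rng.uniform(lo, hi, size=n - 2)]))[::-1]
            true_bp = rng.uniform(po2.min() + 1.0, po2.max() - 1.0)
            rmr = rng.uniform(50, 150)
            mo2 = np.where(po2 >= true_bp, rmr, rmr * po2 / true_bp)
            mo2 = mo2 * (1 + 0.05 * rng.standard_normal(n))
            series = _series(po2, mo2)
            res = estimate_pcrit_broken_stick(series)
            if res.classification != "oxyregulator":
                continue
            oracle_bp, oracle_rss = brute_force_breakpoint(po2, mo2)
            assert res.pcrit == pytest.approx(oracle_bp, abs=1e-8)
            assert res.rss_two_segment == pytest.approx(oracle_rss, rel=1e-6)
            checked += 1
        assert checked >= 50

    def test_parameter_recovery_median_error(self, regulator, descending_grid):
        errors = []
        for seed in range(200):
            series = simulate_mo2_series(regulator, descending_grid, 0.05, seed)
            res = estimate_pcrit_broken_stick(series)
            if res.pcrit is not None:
                errors.append(abs(res.pcrit - regulator.pcrit))
        assert len(errors) >= 190
        assert np.median(errors) < 0.4

    def test_bootstrap_ci_brackets_estimate(self, regulator, descending_grid):
        series = simulate_mo2_series(regulator, descending_grid, 0.05, 9)
        res = estimate_pcrit_broken_stick(series, bootstrap=200, seed=1)
        lo, hi = res.confidence_interval
        assert lo <= res.pcrit <= hi
        assert hi - lo < 5.0

    def test_insufficient_points_or_range_raises(self):
        with pytest.raises(ValueError, match="8 points"):
            estimate_pcrit_broken_stick(_series([5, 4, 3, 2], [1, 1, 1, 1]))
        po2 = np.linspace(10, 9, 10)
        with pytest.raises(ValueError, match="4-fold"):
            estimate_pcrit_broken_stick(_series(po2, po2 * 2))


class TestIntersection:
    def test_known_conforming_line_and_smr(self):
        po2 = np.array([1.0, 2.0, 3.0, 4.0, 5.5, 8.0, 12.0, 16.0, 20.0])
        mo2 = np.where(po2 >= 5.0, 100.0, 20.0 * po2)
        smr = SmrEstimate(100.0, "lowest", 1)
        res = estimate_pcrit_intersection(_series(po2, mo2), smr)
        assert res.pcrit == pytest.approx(5.0, abs=1e-6)

    def test_zero_smr_degenerate_flagged(self):
        po2 = np.array([1.0, 2.0, 3.0, 4.0, 5.5, 8.0, 12.0, 16.0, 20.0])
        mo2 = np.where(po2 >= 5.0, 100.0, 20.0 * po2)
        res = estimate_pcrit_intersection(_series(po2, mo2), SmrEstimate(0.0, "lowest", 1))
        assert res.pcrit == 0.0
        assert "degenerate_smr" in res.flags

    def test_nonpositive_conforming_slope_raises(self):
        po2 = np.linspace(20, 1, 10)
        mo2 = np.full(10, 50.0)  # flat everywhere; no conforming decline
        with pytest.raises(ValueError, match="slope"):
            estimate_pcrit_intersection(_series(po2, mo2), SmrEstimate(50.0, "lowest", 1))

    def test_recovery_close_to_truth(self, regulator, descending_grid):
        errors = []
        for seed in range(50):
            series = simulate_mo2_series(regulator, descending_grid, 0.05, seed)
            smr = SmrEstimate(regulator.rmr, "quantile", 10, 0.5)
            res = estimate_pcrit_intersection(series, smr)
            errors.append(abs(res.pcrit - regulator.pcrit))
        assert np.median(errors) < 0.7


class TestNonlinear:
    def test_exact_michaelis_menten_algebra(self):
        po2 = np.linspace(15, 0.5, 20)
        mo2 = 100.0 * po2 / (1.0 + po2)
        res = estimate_pcrit_nonlinear(_series(po2, mo2))
        assert res.extra["K"] == pytest.approx(1.0, abs=1e-6)
        assert res.pcrit == pytest.approx(9.0, abs=1e-5)
        assert res.extra["fraction"] == 0.90

    def test_fraction_recorded_and_configurable(self):
        po2 = np.linspace(15, 0.5, 20)
        mo2 = 100.0 * po2 / (2.0 + po2)
        res = estimate_pcrit_nonlinear(_series(po2, mo2), fraction=0.5)
        assert res.pcrit == pytest.approx(2.0, abs=1e-5)
        assert res.extra["fraction"] == 0.5

    def test_flat_data_flags_k_near_zero(self):
        po2 = np.linspace(20, 1, 12)
        res = estimate_pcrit_nonlinear(_series(po2, np.full(12, 80.0)))
        assert "k_near_zero" in res.flags

    def test_converges_on_broken_stick_data(self, regulator, descending_grid):
        series = simulate_mo2_series(regulator, descending_grid, 0.05, 3)
        res = estimate_pcrit_nonlinear(series)
        assert res.pcrit > 0
        assert res.extra["mo2_max"] == pytest.approx(regulator.rmr, rel=0.35)
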