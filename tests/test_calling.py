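"""Decay-curve fitting and loop-call statistics."""

import math

import numpy as np
import pytest

from ste3c.calling import (
    DecayCurve,
    benjamini_hochberg,
    call_stes,
    expected_ratio,
    fit_decay_curve,
    test_fragment as fragment_test,
)


def normal_equations_fit(x, y):
    """Independent least-squares oracle via the raw normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sd = np.sqrt(resid @ resid / (len(x) - 2))
    return beta[0], beta[1], sd


def rc_row(distance, log_ratios, target_id="t"):
    logs = np.asarray(log_ratios, dtype=float)
    return {
        "target_id": target_id,
        "distance_bp": float(distance),
        "mean_ratio": float(np.exp(logs).mean()),
        "log_mean": float(logs.mean()),
        "log_sd": float(logs.std(ddof=1)) if len(logs) > 1 else 0.0,
        "n_uncensored": len(logs),
        "status": "ok",
    }


@pytest.fixture(scope="module")
def reference_curve():
    """Curve fit from clean synthetic background: ratio = 100 * (d/1kb)^-1.2."""
    rng = np.random.default_rng(99)
    d = np.exp(rng.uniform(np.log(1_000), np.log(200_000), 500))
    ratio = 100.0 * (d / 1_000) ** -1.2 * np.exp(rng.normal(0, 0.2, 500))
    return fit_decay_curve(d, ratio)


class TestFit:
    def test_noiseless_power_law_exact(self):
        d = np.linspace(1_000, 100_000, 50)
        ratio = 100.0 * d**-1.0
        curve = fit_decay_curve(d, ratio)
        assert curve.slope == pytest.approx(-1.0, abs=1e-10)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert curve.log_a == pytest.approx(math.log(100.0), abs=1e-8)

    def test_parameter_recovery_on_noisy_background(self, reference_curve):
        assert reference_curve.slope == pytest.approx(-1.2, abs=0.1)
        assert reference_curve.residual_sd == pytest.approx(0.2, rel=0.2)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(6, 12, 20)
        y = -1.3 * x + 5 + rng.normal(0, 0.3, 20)
        curve = fit_decay_curve(np.exp(x), np.exp(y))
        a, b, sd = normal_equations_fit(x, y)
        assert curve.log_a == pytest.approx(a, rel=1e-9)
        assert curve.slope == pytest.approx(b, rel=1e-9)
        assert curve.residual_sd == pytest.approx(sd, rel=1e-9)

    def test_excluded_loop_pairs_do_not_bias_fit(self):
        d = np.linspace(1_000, 100_000, 50)
        ratio = 100.0 * d**-1.0
        ratio_loops = ratio.copy()
        ratio_loops[:5] *= 50  # five planted-loop pairs
        excl = np.zeros(50, dtype=bool)
        excl[:5] = True
        curve = fit_decay_curve(d, ratio_loops, exclude=excl)
        assert curve.slope == pytest.approx(-1.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_decay_curve([1e3, 2e3], [1.0, 0.5])

    def test_identical_distances_rank_deficient(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_decay_curve([5e3] * 12, np.linspace(1, 2, 12))


class TestExpectedRatio:
    def curve(self):
        return DecayCurve(log_a=math.log(100.0), slope=-1.0, residual_sd=0.1,
                          d_min=1e3, d_max=2e5, n_points=500, x_mean=9.0, s_xx=100.0)

    def test_closed_form(self):
        # log_a = log 100, b = -1 -> ratio 1.0 at d = 100
        c = DecayCurve(math.log(100.0), -1.0, 0.0, 10, 1_000, 500, 5.0, 100.0)
        assert expected_ratio(c, 100.0) == pytest.approx(1.0)

    def test_clamped_beyond_range_and_flagged(self):
        c = self.curve()
        at_max, f1 = expected_ratio(c, c.d_max, with_flag=True)
        beyond, f2 = expected_ratio(c, 2 * c.d_max, with_flag=True)
        assert at_max == beyond
        assert not f1 and f2

    def test_monotone_decreasing_for_negative_slope(self):
        c = self.curve()
        grid = np.linspace(c.d_min, c.d_max, 200)
        vals = [expected_ratio(c, d) for d in grid]
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            expected_ratio(self.curve(), 0.0)


class TestFragmentTest:
    def test_replicates_at_expected_give_half(self, reference_curve):
        d = 50_000.0
        mu = math.log(expected_ratio(reference_curve, d))
        call = fragment_test(rc_row(d, [mu, mu, mu]), reference_curve)
        assert call.p_value == pytest.approx(0.5)

    def test_replicates_below_expected_exceed_half(self, reference_curve):
        d = 50_000.0
        mu = math.log(expected_ratio(reference_curve, d))
        call = fragment_test(rc_row(d, [mu - 1, mu - 1.2, mu - 0.8]), reference_curve)
        assert call.p_value > 0.5

    def test_planted_tenfold_loop_detected_in_most_runs(self, reference_curve):
        # enrichment 10, sigma 0.2, 3 replicates: p < 0.05 in >= 90% of runs
        rng = np.random.default_rng(17)
        d = 100_000.0
        mu = math.log(expected_ratio(reference_curve, d)) + math.log(10.0)
        hits = 0
        n_runs = 500
        for _ in range(n_runs):
            logs = rng.normal(mu, 0.2, size=3)
            if fragment_test(rc_row(d, logs), reference_curve).p_value < 0.05:
                hits += 1
        assert hits / n_runs >= 0.90

    def test_regime_split_at_long_range_cutoff(self, reference_curve):
        mu = math.log(expected_ratio(reference_curve, 50_000.0))
        near = fragment_test(rc_row(50_000.0, [mu] * 3), reference_curve)
        far = fragment_test(rc_row(150_000.0, [mu] * 3), reference_curve)
        assert near.regime == "proximal" and far.regime == "long-range"

    def test_no_capture_scores_p_one(self, reference_curve):
        rc = rc_row(50_000.0, [0.0])
        rc.update(status="no capture", n_uncensored=0, log_mean=float("nan"))
        call = fragment_test(rc, reference_curve)
        assert call.p_value == 1.0 and call.status == "no capture"

    def test_replicate_variance_mode_uses_curve_spread_for_ties(self, reference_curve):
        # identical replicates: sd 0, the curve residual alone carries the test
        d = 50_000.0
        mu = math.log(expected_ratio(reference_curve, d))
        call = fragment_test(rc_row(d, [mu + 0.3] * 3), reference_curve,
                             variance="replicate")
        assert 0.0 < call.p_value < 0.5


class TestCallStes:
    def make_calls(self, curve, rng, loops=(), n=39):
        calls = []
        for i in range(n):
            d = float(rng.uniform(5_000, 195_000))
            mu = math.log(expected_ratio(curve, d))
            if i in loops:
                mu += math.log(5.0)
            calls.append(fragment_test(
                rc_row(d, rng.normal(mu, 0.2, 3), target_id=f"c:{i * 10}-{i * 10 + 5}"),
                curve))
        return calls

    def test_all_null_pvalues_yield_zero_stes(self, reference_curve):
        calls = self.make_calls(reference_curve, np.random.default_rng(4))
        forced = [c.__class__(**{**c.__dict__, "p_value": 1.0}) for c in calls]
        final = call_stes(forced)
        assert not any(c.is_ste for c in final)

    def test_bh_matches_direct_formula(self):
        qs = benjamini_hochberg([0.001, 0.02, 0.9])
        assert np.allclose(qs, [0.003, 0.03, 0.9])

    def test_bh_matches_brute_force_on_random_pvalues(self, rng):
        p = rng.uniform(size=25)
        # direct BH: q_i = min over j with p_j >= p_i of p_j * n / rank_j
        order = np.argsort(p)
        n = len(p)
        q_sorted = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        brute = np.empty(n)
        brute[order] = q_sorted
        assert np.allclose(benjamini_hochberg(p), brute)

    def test_planted_loops_called_and_nulls_not(self, reference_curve):
        calls = self.make_calls(reference_curve, np.random.default_rng(11), loops=(3, 17, 30))
        final = call_stes(calls)
        called = {c.target_id for c in final if c.is_ste}
        assert called == {"c:30-35", "c:170-175", "c:300-305"}

    def test_fold_gate_blocks_significance_without_magnitude(self, reference_curve):
        # many replicates of a tiny (1.3x) elevation: significant but below 2x
        rng = np.random.default_rng(2)
        d = 50_000.0
        mu = math.log(expected_ratio(reference_curve, d)) + math.log(1.3)
        strong_n = rc_row(d, rng.normal(mu, 0.05, 50))
        final = call_stes([fragment_test(strong_n, reference_curve)])
        (c,) = final
        assert c.q_value <= 0.05 and not c.is_ste

    def test_call_order_invariant_to_input_order(self, reference_curve):
        calls = self.make_calls(reference_curve, np.random.default_rng(8), loops=(5,))
        a = call_stes(calls)
        b = call_stes(calls[::-1])
        assert a == b

    def test_refit_scale_consistency(self, rng):
        """Multiplying all ratios by c multiplies the refit expectation by c."""
        d = np.exp(rng.uniform(np.log(1e3), np.log(2e5), 100))
        ratio = 50.0 * (d / 1e3) ** -1.1 * np.exp(rng.normal(0, 0.1, 100))
        c1 = fit_decay_curve(d, ratio)
        c2 = fit_decay_curve(d, ratio * 7.0)
        for q in (2e3, 2e4, 1.5e5):
            assert expected_ratio(c2, q) == pytest.approx(7.0 * expected_ratio(c1, q))
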