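import numpy as np
import pandas as pd
import pytest

from sccismr.mr_core import (
    bh_fdr,
    ivw,
    mr_egger,
    mr_presso,
    run_gene_mr,
    wald_ratio,
    weighted_median,
    _weighted_median,
)


class TestWaldRatio:
    def test_basic_ratio_and_delta_se(self, pairs_frame):
        res = wald_ratio(pairs_frame([0.5], [0.25], sey=0.1).iloc[0])
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.2)

    def test_sign(self, pairs_frame):
        res = wald_ratio(pairs_frame([-0.5], [0.25]).iloc[0])
        assert res.estimate == pytest.approx(-0.5)

    def test_null_outcome(self, pairs_frame):
        res = wald_ratio(pairs_frame([0.5], [0.0]).iloc[0])
        assert res.estimate == 0.0
        assert res.p == pytest.approx(1.0)

    def test_zero_exposure_raises(self, pairs_frame):
        with pytest.raises(ValueError):
            wald_ratio(pairs_frame([0.0], [0.1]).iloc[0])


class TestIVW:
    def test_two_identical_instruments(self, pairs_frame):
        # each instrument implies ratio 0.5 with ratio-SE 0.2
        pairs = pairs_frame([0.5, 0.5], [0.25, 0.25], sey=0.1)
        res = ivw(pairs)
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.2 / np.sqrt(2), rel=1e-9)
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_k_copies_shrink_se_by_sqrt_k(self, pairs_frame):
        single = wald_ratio(pairs_frame([0.4], [0.12], sey=0.05).iloc[0])
        for k in (2, 4):
            many = ivw(pairs_frame([0.4] * k, [0.12] * k, sey=0.05))
            assert many.estimate == pytest.approx(single.estimate)
            assert many.se == pytest.approx(single.se / np.sqrt(k), rel=1e-9)

    def test_requires_two_instruments(self, pairs_frame):
        with pytest.raises(ValueError):
            ivw(pairs_frame([0.5], [0.25]))

    def test_random_effects_inflation_only_upward(self, pairs_frame, rng):
        # heterogeneous instruments: RE se >= FE se
        pairs = pairs_frame([0.3, 0.4, 0.5], [0.2, -0.1, 0.4], sey=0.02)
        re = ivw(pairs, random_effects=True)
        fe = ivw(pairs, random_effects=False)
        assert re.estimate == fe.estimate
        assert re.se >= fe.se


class TestEgger:
    def test_exact_line_recovers_slope_and_intercept(self, pairs_frame):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        by = 0.1 + 0.5 * bx
        res = mr_egger(pairs_frame(bx, by))
        assert res.estimate == pytest.approx(0.5, abs=1e-9)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-9)

    def test_points_through_origin_have_null_intercept(self, pairs_frame):
        bx = np.array([0.2, 0.4, 0.6])
        res = mr_egger(pairs_frame(bx, 0.5 * bx))
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert res.egger_intercept_p == pytest.approx(1.0)

    def test_orientation_invariance(self, pairs_frame, rng):
        bx = rng.uniform(0.2, 0.6, 5)
        by = 0.05 + 0.4 * bx + rng.normal(0, 0.02, 5)
        flip = rng.choice([-1.0, 1.0], 5)
        a = mr_egger(pairs_frame(bx, by))
        b = mr_egger(pairs_frame(bx * flip, by * flip))
        assert a.estimate == pytest.approx(b.estimate)
        assert a.egger_intercept == pytest.approx(b.egger_intercept)

    def test_degenerate_design_raises(self, pairs_frame):
        with pytest.raises(ValueError, match="degenerate"):
            mr_egger(pairs_frame([0.3, 0.3, -0.3], [0.1, 0.1, 0.1]))

    def test_intercept_test_calibrated_under_null(self, rng):
        """Balanced-pleiotropy null: the intercept test rejects at ~5%."""
        n_rej = 0
        reps = 1000
        for _ in range(reps):
            k = 6
            bx_true = rng.uniform(0.2, 0.6, k) * rng.choice([-1.0, 1.0], k)
            sex = np.full(k, 0.01)
            sey = np.full(k, 0.02)
            pairs = pd.DataFrame({
                "bx": bx_true + rng.normal(0, sex),
                "sex": sex,
                "by": 0.0 * bx_true + rng.normal(0, sey),
                "sey": sey,
            })
            if mr_egger(pairs).egger_intercept_p <= 0.05:
                n_rej += 1
        assert 0.03 <= n_rej / reps <= 0.07


class TestWeightedMedian:
    def test_equal_weights_median(self, pairs_frame):
        # ratios 0.2, 0.5, 0.9 with equal weights
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.2, 0.5, 0.9])
        res = weighted_median(pairs_frame(bx, by), seed=3)
        assert res.estimate == pytest.approx(0.5)

    def test_outlier_with_small_weight_ignored(self, pairs_frame):
        # two precise concordant instruments, one wild outlier with a big SE
        pairs = pd.DataFrame({
            "bx": [1.0, 1.0, 1.0], "sex": 0.01,
            "by": [0.30, 0.32, 5.0],
            "sey": [0.01, 0.01, 2.0],
        })
        res = weighted_median(pairs, seed=3)
        assert 0.25 <= res.estimate <= 0.4

    def test_same_seed_same_se(self, pairs_frame):
        pairs = pairs_frame([0.3, 0.4, 0.5], [0.1, 0.2, 0.3])
        a = weighted_median(pairs, seed=11)
        b = weighted_median(pairs, seed=11)
        assert a.se == b.se
        assert weighted_median(pairs, seed=12).se != a.se

    def test_matches_bruteforce_cdf_scan_for_small_k(self, rng):
        """Oracle: weighted median = value where the standardized cumulative
        weight (with half-weight convention) crosses one half, found by a
        dense scan over the weighted empirical CDF."""
        for _ in range(25):
            k = int(rng.integers(2, 4))
            vals = np.sort(rng.normal(0, 1, k))
            w = rng.uniform(0.1, 2.0, k)
            got = _weighted_median(vals, w)
            order = np.argsort(vals)
            v, ww = vals[order], w[order]
            cum = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
            grid = np.interp(0.5, cum, v)  # piecewise-linear CDF inverse
            assert got == pytest.approx(float(grid), abs=1e-12)


class TestPresso:
    def test_injected_outlier_flagged(self, rng):
        k = 8
        bx = rng.uniform(0.3, 0.6, k)
        sey = np.full(k, 0.01)
        by = 0.4 * bx
        by[3] += 10 * sey[3]  # pleiotropic offset at 10x SE
        pairs = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(k)],
            "bx": bx, "sex": 0.005, "by": by, "sey": sey,
        })
        res = mr_presso(pairs, n_sim=600, seed=4)
        assert res.presso_global_p < 0.05
        assert "v3" in res.presso_outliers
        # outlier-corrected estimate close to the clean slope
        assert res.estimate == pytest.approx(0.4, abs=0.05)

    def test_homogeneous_instruments_not_rejected(self, rng):
        k = 6
        bx = rng.uniform(0.3, 0.6, k)
        sey = np.full(k, 0.02)
        pairs = pd.DataFrame({
            "bx": bx, "sex": 0.005,
            "by": 0.4 * bx + rng.normal(0, sey), "sey": sey,
        })
        res = mr_presso(pairs, n_sim=600, seed=4)
        assert res.presso_global_p > 0.05

    def test_global_p_never_zero(self):
        # an absurdly outlying observed RSS yields p = 1/(n_sim+1), not 0
        k = 5
        pairs = pd.DataFrame({
            "bx": [0.3, 0.4, 0.5, 0.6, 0.45],
            "sex": 1e-6,
            "by": [10.0, -10.0, 10.0, -10.0, 10.0],
            "sey": 0.01,
        })
        res = mr_presso(pairs, n_sim=500, seed=1)
        assert 0 < res.presso_global_p <= 1 / 500


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_q_at_least_p_and_rank_monotone(self, rng):
        p = np.sort(rng.uniform(0, 1, 20))
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(np.diff(q) >= -1e-12)


class TestDispatch:
    @pytest.mark.parametrize(
        "k,methods",
        [
            (1, {"wald"}),
            (2, {"ivw"}),
            (3, {"ivw", "weighted_median", "egger"}),
            (5, {"ivw", "weighted_median", "egger", "presso"}),
        ],
    )
    def test_iv_count_ladder(self, pairs_frame, rng, k, methods):
        bx = rng.uniform(0.3, 0.6, k)
        by = 0.4 * bx + rng.normal(0, 0.02, k)
        res = run_gene_mr(pairs_frame(bx, by), "G", "c", n_boot=100,
                          n_sim=500, seed=0)
        assert {r.method for r in res} == methods

    def test_empty_set_raises(self, pairs_frame):
        with pytest.raises(ValueError):
            run_gene_mr(pairs_frame([], []))

    def test_estimators_equivariant_under_joint_sign_flip(self, pairs_frame, rng):
        k = 5
        bx = rng.uniform(0.3, 0.6, k)
        by = 0.4 * bx + rng.normal(0, 0.02, k)
        a = run_gene_mr(pairs_frame(bx, by), n_boot=100, n_sim=500, seed=0)
        b = run_gene_mr(pairs_frame(-bx, -by), n_boot=100, n_sim=500, seed=0)
        for ra, rb in zip(a, b):
            assert ra.method == rb.method
            assert ra.estimate == pytest.approx(rb.estimate, rel=1e-9)
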