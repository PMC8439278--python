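"""Summary-statistic MR estimators: IVW, Egger, medians."""

import numpy as np
import pytest

from mrscore import SummaryPair, meta_fixed, mr_egger, mr_ivw, mr_median
from mrscore.estimators import weighted_percentile


def _pairs(bx, by, sy, sx=None):
    sx = sx if sx is not None else [0.01] * len(bx)
    return [SummaryPair(rsid=f"rs{i}", beta_x=float(x), se_x=float(s),
                        beta_y=float(y), se_y=float(e))
            for i, (x, s, y, e) in enumerate(zip(bx, sx, by, sy))]


class TestIvw:
    def test_exact_proportionality(self):
        bx = [0.1, 0.2, 0.3]
        pairs = _pairs(bx, [0.5 * b for b in bx], [0.02, 0.05, 0.01])
        res = mr_ivw(pairs)
        assert res.beta == pytest.approx(0.5, abs=1e-12)

    def test_null_outcome_effects(self):
        pairs = _pairs([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], [0.02, 0.05, 0.01])
        res = mr_ivw(pairs)
        assert res.beta == 0.0
        assert res.p == 1.0

    def test_matches_weighted_least_squares_oracle(self):
        """Frozen values from a zero-intercept WLS solved independently
        (lstsq on sqrt-weight-scaled data)."""
        pairs = _pairs([0.1, 0.2, 0.3], [0.06, 0.05, 0.12], [0.02, 0.03, 0.01])
        res = mr_ivw(pairs)
        assert res.beta == pytest.approx(0.3982808022922636, abs=1e-10)
        assert res.se == pytest.approx(0.03211726365433135, abs=1e-10)

    def test_no_instrument_strength_fatal(self):
        with pytest.raises(ValueError):
            mr_ivw(_pairs([0.0, 0.0], [0.1, 0.2], [0.1, 0.1]))

    def test_equals_meta_of_ratio_estimates(self):
        """IVW is algebraically the fixed-effect meta-analysis of per-SNP
        ratio estimates with first-order weights."""
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.3, 8)
        by = rng.normal(0.2 * bx, 0.05)
        sy = rng.uniform(0.02, 0.1, 8)
        pairs = _pairs(bx, by, sy)
        ivw = mr_ivw(pairs)
        ratios = [(y / x, e / abs(x)) for x, y, e in zip(bx, by, sy)]
        pooled = meta_fixed(ratios)
        assert ivw.beta == pytest.approx(pooled.beta, rel=1e-10)
        assert ivw.se == pytest.approx(pooled.se, rel=1e-10)


class TestEgger:
    def test_exact_affine_relationship(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        pairs = _pairs(bx, 0.1 + 0.5 * bx, [0.02] * 4)
        res = mr_egger(pairs)
        assert res.intercept == pytest.approx(0.1, abs=1e-10)
        assert res.beta == pytest.approx(0.5, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Frozen values from the 2x2 weighted normal equations solved by
        Cramer's rule, with the residual scale floored at 1."""
        pairs = _pairs([0.10, 0.15, 0.20, 0.30], [0.03, 0.06, 0.05, 0.10],
                       [0.02, 0.01, 0.03, 0.015])
        res = mr_egger(pairs)
        assert res.intercept == pytest.approx(0.010057443752991793, abs=1e-10)
        assert res.beta == pytest.approx(0.3005265677357589, abs=1e-10)
        assert res.intercept_se == pytest.approx(0.02075640015607154, abs=1e-10)
        assert res.se == pytest.approx(0.1058372894277491, abs=1e-10)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.3, 6)
        by = rng.normal(0.3 * bx + 0.05, 0.02)
        sy = rng.uniform(0.02, 0.08, 6)
        pairs = _pairs(bx, by, sy)
        flipped = [
            SummaryPair(rsid=p.rsid, beta_x=-p.beta_x, se_x=p.se_x,
                        beta_y=-p.beta_y, se_y=p.se_y)
            if i % 2 else p
            for i, p in enumerate(pairs)
        ]
        a, b = mr_egger(pairs), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_too_few_or_degenerate_fatal(self):
        with pytest.raises(ValueError):
            mr_egger(_pairs([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]))
        with pytest.raises(ValueError):
            mr_egger(_pairs([0.2, 0.2, 0.2], [0.1, 0.1, 0.1], [0.02] * 3))


class TestMedian:
    def test_simple_median_outlier_robust(self):
        bx = [1.0] * 5
        by = [1.0, 2.0, 3.0, 4.0, 100.0]
        res = mr_median(_pairs(bx, by, [0.1] * 5), weighted=False, seed=0)
        assert res.beta == pytest.approx(3.0)

    def test_identical_ratios_degenerate_dispersion(self):
        bx = [0.1, 0.2, 0.3]
        by = [0.05, 0.10, 0.15]
        res = mr_median(_pairs(bx, by, [1e-8] * 3, sx=[1e-8] * 3),
                        weighted=True, seed=0)
        assert res.beta == pytest.approx(0.5, abs=1e-4)
        assert res.se < 1e-4

    def test_zero_beta_x_dropped_with_warning(self):
        pairs = _pairs([0.0, 0.1, 0.2, 0.3], [0.0, 0.05, 0.1, 0.15], [0.05] * 4)
        with pytest.warns(UserWarning, match="rs0"):
            res = mr_median(pairs, weighted=False, seed=0)
        assert res.n_snps == 3

    def test_too_few_usable_pairs_fatal(self):
        pairs = _pairs([0.0, 0.0, 0.1], [0.0, 0.0, 0.05], [0.05] * 3)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                mr_median(pairs, weighted=False, seed=0)

    def test_bootstrap_seed_reproducible(self):
        pairs = _pairs([0.1, 0.2, 0.3, 0.15], [0.04, 0.11, 0.14, 0.08],
                       [0.03, 0.05, 0.04, 0.02])
        a = mr_median(pairs, weighted=True, seed=42)
        b = mr_median(pairs, weighted=True, seed=42)
        assert a.se == b.se and a.beta == b.beta

    def test_majority_valid_weighted_median_beats_ivw(self):
        """With 40% of instruments carrying strong directional pleiotropy
        the weighted median stays near the true effect while IVW is
        dragged upward."""
        rng = np.random.default_rng(7)
        m, true = 30, 0.2
        bx = rng.uniform(0.1, 0.3, m)
        sy = np.full(m, 0.01)
        alpha = np.zeros(m)
        alpha[:12] = 0.08  # 40% invalid
        by = rng.normal(true * bx + alpha, sy)
        pairs = _pairs(bx, by, sy)
        wm = mr_median(pairs, weighted=True, seed=1)
        ivw = mr_ivw(pairs)
        # IVW absorbs the directional pleiotropy wholesale; the weighted
        # median keeps only a small finite-sample bias
        assert abs(ivw.beta - true) > 2 * ivw.se
        assert abs(wm.beta - true) < 0.5 * abs(ivw.beta - true)


class TestCrossEstimatorProperties:
    def test_dominating_instrument_drives_all_estimators(self):
        bx = [0.2, 0.1, 0.25, 0.15]
        by = [0.10, 0.03, 0.02, 0.07]
        sy = [1e-5, 1.0, 1.0, 1.0]  # first instrument carries all weight
        pairs = _pairs(bx, by, sy)
        ratio = by[0] / bx[0]
        assert mr_ivw(pairs).beta == pytest.approx(ratio, abs=1e-3)
        assert mr_median(pairs, weighted=True, seed=0).beta == pytest.approx(
            ratio, abs=1e-3)
        # the Egger line is pinned through the dominating point
        egger = mr_egger(pairs)
        assert egger.intercept + egger.beta * bx[0] == pytest.approx(by[0], abs=1e-3)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.3, 6)
        by = rng.normal(0.4 * bx, 0.03)
        sy = rng.uniform(0.02, 0.06, 6)
        c = 2.5
        a = _pairs(bx, by, sy)
        b = _pairs(c * bx, by, sy)
        assert mr_ivw(b).beta == pytest.approx(mr_ivw(a).beta / c, rel=1e-10)
        assert mr_egger(b).beta == pytest.approx(mr_egger(a).beta / c, rel=1e-10)
        assert mr_median(b, weighted=True, seed=3).beta == pytest.approx(
            mr_median(a, weighted=True, seed=3).beta / c, rel=1e-6)


def test_weighted_percentile_equal_weights_is_sample_median():
    v = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
    assert weighted_percentile(v, np.ones(5)) == 3.0
    assert weighted_percentile(v[:4], np.ones(4)) == pytest.approx(2.5)
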