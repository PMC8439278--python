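"""Logistic association engine: oracle equivalence and Wald inference."""

import numpy as np
import pandas as pd
import pytest

from mrscore import cohort_summary, fit_logistic, per_snp_scan, run_association_suite
from mrscore.association import CollinearityError, SeparationWarning, Z_95


def _two_by_two(n_ec, n_eco, n_uc, n_uco):
    """exposed-case, exposed-control, unexposed-case, unexposed-control."""
    y = np.r_[np.ones(n_ec), np.zeros(n_eco), np.ones(n_uc), np.zeros(n_uco)]
    x = np.r_[np.ones(n_ec + n_eco), np.zeros(n_uc + n_uco)]
    return y, x


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        """Saturated 2x2 model: log-OR is the cross-product ratio and the
        SE is sqrt of the summed reciprocal cell counts."""
        y, x = _two_by_two(10, 20, 20, 10)
        res = fit_logistic(y, x)
        assert res.or_ == pytest.approx(0.25, abs=1e-6)
        assert res.beta == pytest.approx(np.log(0.25), abs=1e-6)
        assert res.se == pytest.approx(np.sqrt(1/10 + 1/20 + 1/20 + 1/10), abs=1e-6)
        assert res.ci_low == pytest.approx(np.exp(res.beta - Z_95 * res.se))
        assert res.ci_high == pytest.approx(np.exp(res.beta + Z_95 * res.se))

    def test_matches_statsmodels_mle(self):
        """Independent-oracle check against a generic ML fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 400
        x = rng.normal(size=n)
        C = rng.normal(size=(n, 3))
        eta = -0.3 + 0.6 * x + C @ [0.2, -0.4, 0.1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = fit_logistic(y, x, C)
        X = sm.add_constant(np.column_stack([x, C]))
        ref = sm.Logit(y, X).fit(disp=0)
        assert res.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert res.se == pytest.approx(ref.bse[1], abs=1e-6)

    def test_permutation_null_calibration(self):
        """With permuted labels the Wald p-value is uniform: about 5% of
        replicates fall below 0.05."""
        rng = np.random.default_rng(1)
        n = 500
        x = rng.binomial(2, 0.3, size=n).astype(float)
        y = rng.binomial(1, 0.4, size=n).astype(float)
        hits = 0
        reps = 200
        for _ in range(reps):
            hits += fit_logistic(rng.permutation(y), x).p < 0.05
        assert 0.01 <= hits / reps <= 0.11

    def test_duplicated_covariate_is_fatal(self):
        y, x = _two_by_two(10, 20, 20, 10)
        with pytest.raises(CollinearityError):
            fit_logistic(y, x, covariates=x[:, None])

    def test_outcome_recode_negates_beta(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        y = (rng.random(300) < 0.5).astype(float)
        a = fit_logistic(y, x)
        b = fit_logistic(1 - y, x)
        assert a.beta == pytest.approx(-b.beta, abs=1e-8)
        assert a.se == pytest.approx(b.se, abs=1e-8)

    def test_separation_flagged_not_estimated(self):
        x = np.r_[np.linspace(-2, -0.1, 25), np.linspace(0.1, 2, 25)]
        y = (x > 0).astype(float)
        with pytest.warns(SeparationWarning):
            res = fit_logistic(y, x)
        assert not res.converged
        assert np.isnan(res.beta)

    def test_degenerate_inputs_raise(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(y, np.ones(10))
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(10), np.arange(10.0))


class TestPerSnpScan:
    def test_agrees_with_single_fits(self):
        rng = np.random.default_rng(3)
        n, m = 300, 4
        D = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        C = rng.normal(size=(n, 2))
        y = (rng.random(n) < 0.4).astype(float)
        scan = per_snp_scan(y, D, C)
        for j in range(m):
            single = fit_logistic(y, D[:, j], C)
            assert scan.loc[j, "beta"] == pytest.approx(single.beta, abs=1e-6)
            assert scan.loc[j, "se"] == pytest.approx(single.se, abs=1e-6)

    def test_monomorphic_column_skipped(self):
        rng = np.random.default_rng(4)
        D = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        D[:, 1] = 2.0
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.warns(UserWarning, match="monomorphic"):
            scan = per_snp_scan(y, D)
        assert np.isnan(scan.loc[1, "beta"])


class TestAssociationSuite:
    def _cohort(self, n=600, seed=5):
        rng = np.random.default_rng(seed)
        ph = pd.DataFrame(dict(
            sample_id=[f"s{i}" for i in range(n)],
            dataset=np.where(np.arange(n) < n // 2, "D1", "D2"),
            case=rng.integers(0, 2, n),
            age_ge60=rng.integers(0, 2, n),
            sex=rng.integers(0, 2, n),
            smoker=rng.integers(0, 2, n),
            histology=pd.NA,
        ))
        for i in range(1, 11):
            ph[f"PC{i}"] = rng.normal(size=n)
        ph.loc[ph["case"] == 1, "histology"] = rng.choice(
            ["adenocarcinoma", "squamous"], size=(ph["case"] == 1).sum())
        scores = rng.normal(size=n)
        return ph, scores

    def test_strata_layout_and_covariate_drop(self):
        ph, scores = self._cohort()
        res = run_association_suite(ph, scores,
                                    strata=("overall", "smoking", "histology"))
        strata = set(res["stratum"])
        assert "overall" in strata
        # smoking strata fit without the smoker covariate (it is constant
        # within stratum; success implies it was dropped)
        assert {"smoking=0", "smoking=1"} <= strata
        assert {"histology=adenocarcinoma", "histology=squamous"} <= strata
        assert set(res["dataset"]) == {"D1", "D2"}

    def test_single_class_stratum_skipped(self):
        ph, scores = self._cohort(n=200)
        ph.loc[ph["smoker"] == 1, "case"] = 1  # smokers are all cases
        with pytest.warns(UserWarning, match="degenerate|skipped"):
            res = run_association_suite(ph, scores, strata=("smoking",))
        assert not any(res["stratum"] == "smoking=1")

    def test_per_snp_bonferroni_flag(self, small_null_cohort):
        coh = small_null_cohort
        rng = np.random.default_rng(6)
        scores = rng.normal(size=len(coh.phenotypes))
        res = run_association_suite(coh.phenotypes, scores, strata=("overall",),
                                    genotypes=coh.genotypes, per_snp=True)
        snps = res[res["term"] != "wgrs"]
        assert len(snps) == coh.genotypes.n_variants * 2  # two datasets
        # flags only set below the Bonferroni level, not the nominal level
        loose = snps[(snps["p"] < 0.05) & (snps["p"] > 0.05 / coh.genotypes.n_variants)]
        assert not loose["significant"].any()


def test_cohort_summary_percentages():
    ph = pd.DataFrame(dict(
        case=[1, 1, 1, 0, 0, 0],
        age_ge60=[1, 0, np.nan, 1, 1, 0],
        histology=["adenocarcinoma", "squamous", "adenocarcinoma",
                   None, None, None],
    ))
    out = cohort_summary(ph).set_index(["group", "characteristic"])
    assert out.loc[("case", "age_ge60"), "percent"] == 50.0
    assert out.loc[("case", "age_ge60"), "denominator"] == 2
    assert out.loc[("control", "age_ge60"), "percent"] == pytest.approx(66.67)
    assert out.loc[("case", "histology=adenocarcinoma"), "percent"] == pytest.approx(66.67)
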