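"""Genotype QC: HWE test, variant filters, sample filters."""

import numpy as np
import pandas as pd
import pytest

from mrscore import QCThresholds, apply_sample_filters, apply_variant_filters, hwe_test
from mrscore.containers import GenotypeMatrix


def _matrix(dosages, rsids=None, sample_ids=None):
    n, m = dosages.shape
    rsids = rsids or [f"rs{j}" for j in range(m)]
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        variants=pd.DataFrame(dict(rsid=rsids, chrom=["1"] * m,
                                   pos=list(range(m)), ref=["A"] * m,
                                   alt=["G"] * m)),
    )


def _counts_to_dosages(n_hom_ref, n_het, n_hom_alt):
    return np.concatenate([np.zeros(n_hom_ref), np.ones(n_het),
                           np.full(n_hom_alt, 2.0)])


class TestHwe:
    @pytest.mark.parametrize("counts,expected_p", [
        ((25, 50, 25), 1.0),          # exact HWE proportions, chi-square 0
        ((30, 40, 30), 0.04550026),   # chi-square 4.0 against (25,50,25)
    ])
    def test_hand_computed_values(self, counts, expected_p):
        assert hwe_test(*counts) == pytest.approx(expected_p, rel=1e-6)

    def test_extreme_het_deficit_fails_default_filter(self):
        # chi-square 200: all-homozygote split at allele frequency 0.5
        assert hwe_test(100, 0, 100) < 1e-5

    def test_monomorphic_returns_one(self):
        assert hwe_test(50, 0, 0) == 1.0
        assert hwe_test(0, 0, 50) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestVariantFilters:
    def _phenotypes(self, n, n_cases):
        case = np.r_[np.ones(n_cases, int), np.zeros(n - n_cases, int)]
        return pd.DataFrame(dict(sample_id=[f"s{i}" for i in range(n)],
                                 dataset="D1", case=case))

    def test_clean_matrix_is_identity(self):
        rng = np.random.default_rng(0)
        D = rng.binomial(2, 0.3, size=(400, 5)).astype(float)
        geno = _matrix(D)
        out, report = apply_variant_filters(geno, self._phenotypes(400, 200))
        assert out.n_variants == 5
        assert report["kept"].all()

    def test_low_control_maf_removed(self):
        rng = np.random.default_rng(1)
        n = 1000
        D = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        D[:, 1] = 0.0
        D[0, 1] = 1.0  # control MAF = 1/1000 < 0.005 (sample 0 is a control)
        ph = self._phenotypes(n, 0)
        out, report = apply_variant_filters(_matrix(D), ph)
        assert out.rsids == ["rs0"]
        assert report.loc[1, "rule"] == "maf_controls"

    def test_hwe_violating_variant_removed(self):
        good = _counts_to_dosages(25, 50, 25)
        bad = _counts_to_dosages(50, 0, 50)
        D = np.column_stack([np.tile(good, 2), np.tile(bad, 2)])
        ph = self._phenotypes(200, 100)
        out, report = apply_variant_filters(_matrix(D), ph)
        assert out.rsids == ["rs0"]
        assert report.loc[1, "rule"].startswith("hwe")

    def test_call_rate_attribution_first_rule_wins(self):
        # a variant failing both call rate and HWE is attributed to call rate
        bad = _counts_to_dosages(50, 0, 50).astype(float)
        bad[:10] = np.nan  # call rate 0.9 < 0.95
        D = bad[:, None]
        ph = self._phenotypes(100, 50)
        out, report = apply_variant_filters(_matrix(D), ph)
        assert out.n_variants == 0
        assert report.loc[0, "rule"] == "call_rate"

    def test_report_reconciles_and_reordering_commutes(self):
        rng = np.random.default_rng(2)
        D = rng.binomial(2, 0.25, size=(300, 8)).astype(float)
        D[:, 3] = np.where(rng.random(300) < 0.5, 0.0, 2.0)  # HWE violation
        ph = self._phenotypes(300, 150)
        out, report = apply_variant_filters(_matrix(D), ph)
        assert out.n_variants + (~report["kept"]).sum() == 8

        perm = rng.permutation(8)
        geno_p = _matrix(D[:, perm], rsids=[f"rs{j}" for j in perm])
        out_p, _ = apply_variant_filters(geno_p, ph)
        assert sorted(out_p.rsids) == sorted(out.rsids)


class TestSampleFilters:
    def test_duplicate_pair_drops_lower_call_rate(self):
        rng = np.random.default_rng(3)
        D = rng.binomial(2, 0.3, size=(4, 50)).astype(float)
        D[1, :2] = np.nan  # s1 has the lower call rate (0.96, still passing)
        geno = _matrix(D)
        pihat = pd.DataFrame(dict(id1=["s0"], id2=["s1"], pihat=[1.0]))
        out, report = apply_sample_filters(geno, pihat)
        assert "s1" not in out.sample_ids and "s0" in out.sample_ids
        assert report.set_index("sample_id").loc["s1", "rule"] == "relatedness"

    def test_high_missingness_sample_removed(self):
        rng = np.random.default_rng(4)
        D = rng.binomial(2, 0.3, size=(10, 50)).astype(float)
        D[2, :20] = np.nan  # 40% missing
        out, report = apply_sample_filters(_matrix(D), None)
        assert "s2" not in out.sample_ids
        assert report.set_index("sample_id").loc["s2", "rule"] == "call_rate"

    def test_no_threshold_hit_is_identity(self):
        rng = np.random.default_rng(5)
        D = rng.binomial(2, 0.3, size=(20, 100)).astype(float)
        out, report = apply_sample_filters(_matrix(D), None)
        assert out.sample_ids == [f"s{i}" for i in range(20)]
        assert report["kept"].all()

    def test_heterozygosity_outlier_removed(self):
        rng = np.random.default_rng(6)
        D = rng.binomial(2, 0.5, size=(40, 200)).astype(float)
        D[7, :] = 1.0  # every genotype heterozygous
        out, _ = apply_sample_filters(_matrix(D), None,
                                      QCThresholds(het_sd_max=4.0))
        assert "s7" not in out.sample_ids

    def test_unknown_pihat_sample_is_fatal(self):
        D = np.ones((3, 4))
        pihat = pd.DataFrame(dict(id1=["s0"], id2=["ghost"], pihat=[0.9]))
        with pytest.raises(ValueError, match="ghost"):
            apply_sample_filters(_matrix(D), pihat)


def test_thresholds_validated():
    with pytest.raises(ValueError):
        QCThresholds(variant_call_rate_min=0.0)
    with pytest.raises(ValueError):
        QCThresholds(hwe_all_p_min=2.0)
    # rules can be disabled
    assert QCThresholds(hwe_cases_p_min=None).hwe_cases_p_min is None
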