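"""Variant- and sample-level genotype quality control.

Filters mirror the standard GWAS pre-analysis checklist: per-variant call
rate, control minor-allele frequency, and Hardy-Weinberg equilibrium
(tested in everyone, in controls, and in cases, each with its own
threshold); per-sample call rate, relatedness (precomputed pairwise
PI_HAT), and heterozygosity outliers.  Every threshold is configurable
and any of the three HWE rules can be disabled with ``None``.

HWE is tested with the 1-df chi-square goodness of fit against the
binomial genotype expectations at the sample allele frequency; hard
genotype calls are obtained by rounding dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow common array-QC practice."""

    variant_call_rate_min: float = 0.95
    maf_min: float = 0.005
    hwe_all_p_min: Optional[float] = 1e-5
    hwe_controls_p_min: Optional[float] = 1e-7
    hwe_cases_p_min: Optional[float] = 1e-12
    sample_call_rate_min: float = 0.95
    relatedness_pihat_max: float = 0.25
    het_sd_max: float = 6.0

    def __post_init__(self) -> None:
        for name in ("variant_call_rate_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("hwe_all_p_min", "hwe_controls_p_min", "hwe_cases_p_min"):
            v = getattr(self, name)
            if v is not None and not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1) or None, got {v}")


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square (1 df) Hardy-Weinberg goodness-of-fit p-value.

    Observed genotype counts are compared with the binomial expectation
    ``(q^2, 2pq, p^2) * n`` at the sample allele frequency.  A
    monomorphic variant is in trivial equilibrium and returns p = 1.
    """
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ValueError("no genotype calls")
    p_alt = (2 * n_hom_alt + n_het) / (2 * n)
    if p_alt in (0.0, 1.0):
        logger.debug("monomorphic variant; HWE p set to 1")
        return 1.0
    q = 1.0 - p_alt
    exp = n * np.array([q * q, 2 * p_alt * q, p_alt * p_alt])
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2.sf(stat, df=1))


def _genotype_counts(dosages: np.ndarray) -> np.ndarray:
    """Hard-call genotype counts (hom_ref, het, hom_alt) per variant."""
    g = np.rint(dosages)
    counts = np.empty((dosages.shape[1], 3))
    for k in range(3):
        counts[:, k] = np.nansum(g == k, axis=0)
    return counts


def _hwe_p_per_variant(dosages: np.ndarray) -> np.ndarray:
    counts = _genotype_counts(dosages)
    return np.array([hwe_test(*row) for row in counts.astype(int)])


VARIANT_RULES = ("call_rate", "maf_controls", "hwe_all", "hwe_controls", "hwe_cases")


def apply_variant_filters(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants failing call-rate, control-MAF, or HWE rules.

    A variant failing several rules is attributed to the first failing
    rule in the order of :data:`VARIANT_RULES`.  Returns the filtered
    matrix and a per-variant report (rsid, rule, value).
    """
    if len(phenotypes) != genotypes.n_samples:
        raise ValueError("phenotype rows do not align with genotype rows")
    D = genotypes.dosages
    case = phenotypes["case"].to_numpy() == 1
    control = ~case

    call_rate = 1.0 - np.mean(np.isnan(D), axis=0)
    maf_controls = genotypes.minor_allele_freq(mask=control)

    rule = np.full(genotypes.n_variants, "", dtype=object)
    value = np.full(genotypes.n_variants, np.nan)

    def _flag(mask: np.ndarray, name: str, vals: np.ndarray) -> None:
        hit = mask & (rule == "")
        rule[hit] = name
        value[hit] = vals[hit]

    _flag(call_rate < thresholds.variant_call_rate_min, "call_rate", call_rate)
    _flag(maf_controls < thresholds.maf_min, "maf_controls", maf_controls)

    hwe_specs = [
        ("hwe_all", np.ones(len(phenotypes), bool), thresholds.hwe_all_p_min),
        ("hwe_controls", control, thresholds.hwe_controls_p_min),
        ("hwe_cases", case, thresholds.hwe_cases_p_min),
    ]
    for name, mask, cut in hwe_specs:
        if cut is None or not mask.any():
            continue
        p = _hwe_p_per_variant(D[mask, :])
        _flag(p < cut, name, p)

    keep = np.flatnonzero(rule == "")
    report = pd.DataFrame(
        dict(rsid=genotypes.rsids, rule=rule, value=value, kept=(rule == ""))
    )
    n_dropped = genotypes.n_variants - len(keep)
    if n_dropped:
        logger.info("variant QC dropped %d of %d variants", n_dropped, genotypes.n_variants)
    return genotypes.subset_variants(keep), report


def apply_sample_filters(
    genotypes: GenotypeMatrix,
    pihat: Optional[pd.DataFrame] = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples failing call-rate, relatedness, or heterozygosity rules.

    ``pihat`` is a 3-column table (id1, id2, pihat) of precomputed
    pairwise identity-by-descent estimates; from each pair above the
    threshold the member with the lower call rate is removed (ties broken
    toward id2, so output is deterministic).  Heterozygosity outliers are
    samples whose het rate deviates at least ``het_sd_max`` standard
    deviations from the cohort mean.
    """
    D = genotypes.dosages
    ids = list(genotypes.sample_ids)
    call_rate = 1.0 - np.mean(np.isnan(D), axis=1)

    rule = {sid: "" for sid in ids}
    cr = dict(zip(ids, call_rate))

    for sid, c in zip(ids, call_rate):
        if c < thresholds.sample_call_rate_min:
            rule[sid] = "call_rate"

    if pihat is not None and len(pihat):
        related = pihat[pihat["pihat"] > thresholds.relatedness_pihat_max]
        for r in related.itertuples(index=False):
            a, b = str(r.id1), str(r.id2)
            if a not in rule or b not in rule:
                raise ValueError(f"PI_HAT pair ({a}, {b}) names unknown samples")
            if rule[a] or rule[b]:
                continue  # pair already resolved by an earlier removal
            drop = a if cr[a] < cr[b] else b
            rule[drop] = "relatedness"

    # heterozygosity: fraction of het hard calls among non-missing genotypes
    g = np.rint(D)
    with np.errstate(invalid="ignore"):
        het = np.nansum(g == 1, axis=1) / np.sum(~np.isnan(g), axis=1)
    alive = np.array([rule[sid] == "" for sid in ids])
    mu, sd = float(np.mean(het[alive])), float(np.std(het[alive]))
    if sd > 0:
        for i, sid in enumerate(ids):
            if not rule[sid] and abs(het[i] - mu) >= thresholds.het_sd_max * sd:
                rule[sid] = "heterozygosity"

    keep = [i for i, sid in enumerate(ids) if rule[sid] == ""]
    report = pd.DataFrame(
        dict(sample_id=ids, rule=[rule[s] for s in ids],
             call_rate=call_rate, het_rate=het,
             kept=[rule[s] == "" for s in ids])
    )
    if len(keep) < len(ids):
        logger.info("sample QC dropped %d of %d samples", len(ids) - len(keep), len(ids))
    return genotypes.subset_samples(keep), report
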