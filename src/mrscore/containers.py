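"""Core in-memory containers shared by every pipeline stage.

Genotypes are carried as effect-allele *dosages*: the expected count, in
[0, 2], of a designated counted allele per sample.  Dosages may be
fractional (imputed data) and missing entries are NaN.  Phenotypes and
covariates travel as a plain :class:`pandas.DataFrame` with a documented
column contract (see :data:`PHENOTYPE_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Required columns of a phenotype table.  ``case`` is the outcome
#: (1 = case), ``exposure`` the binary exposure status, ``liability`` the
#: continuous exposure liability (when known, e.g. simulated cohorts),
#: ``dataset`` a label partitioning samples into genotyping batches.
#: ``age_ge60``, ``sex``, ``smoker`` are 0/1 indicators; ``histology``
#: is a string label for cases (NaN for controls); PC1..PC10 are
#: precomputed ancestry principal components.
PHENOTYPE_COLUMNS = (
    ["sample_id", "dataset", "case", "age_ge60", "sex", "smoker", "histology"]
    + [f"PC{i}" for i in range(1, 11)]
)

#: Default covariate set of the outcome model: age group, sex, smoking
#: status and the first ten principal components.
DEFAULT_COVARIATES = ["age_ge60", "sex", "smoker"] + [f"PC{i}" for i in range(1, 11)]

AUTOSOMES = {str(i) for i in range(1, 23)}


def is_autosomal(chrom: str) -> bool:
    """True for chromosome labels 1-22 (with or without a ``chr`` prefix)."""
    return str(chrom).removeprefix("chr") in AUTOSOMES


@dataclass(frozen=True)
class InstrumentRecord:
    """One exposure-associated variant with its published effect estimate.

    ``beta`` is the per-effect-allele exposure log-OR, oriented to
    ``effect_allele``.  ``proxy_of``/``proxy_r2`` are set when the record
    stands in for an unavailable variant (e.g. an indel replaced by a SNP
    in high LD).
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float
    is_indel: bool = False
    proxy_of: Optional[str] = None
    proxy_r2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: se must be positive, got {self.se}")
        if (self.proxy_of is None) != (self.proxy_r2 is None):
            raise ValueError(f"{self.rsid}: proxy_of and proxy_r2 must be set together")

    @property
    def pvalue(self) -> float:
        """Two-sided Wald p-value of the exposure association."""
        from scipy.stats import norm

        return float(2.0 * norm.sf(abs(self.beta / self.se)))


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of effect-allele dosages in [0, 2].

    ``variants`` is a DataFrame indexed 0..n_variants-1 with columns
    ``rsid``, ``chrom``, ``pos``, ``ref``, ``alt``; the dosage counts the
    ``alt`` allele.  Missing dosages are NaN.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{self.dosages.shape[0]} dosage rows but {len(self.sample_ids)} sample ids"
            )
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but {len(self.variants)} variant records"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def rsids(self) -> list[str]:
        return self.variants["rsid"].tolist()

    def column(self, rsid: str) -> np.ndarray:
        """Dosage vector of one variant by rsid."""
        idx = self.variants.index[self.variants["rsid"] == rsid]
        if len(idx) == 0:
            raise KeyError(f"variant {rsid!r} not in genotype matrix")
        return self.dosages[:, idx[0]]

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[keep].reset_index(drop=True),
        )

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            dosages=self.dosages[keep, :],
            sample_ids=[self.sample_ids[i] for i in keep],
            variants=self.variants.copy(),
        )

    def effect_allele_freq(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-variant frequency of the counted (alt) allele, ignoring NaN.

        ``mask`` restricts the computation to a boolean subset of samples
        (e.g. controls).
        """
        d = self.dosages if mask is None else self.dosages[np.asarray(mask, bool), :]
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def minor_allele_freq(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        af = self.effect_allele_freq(mask)
        return np.minimum(af, 1.0 - af)


def validate_phenotypes(phenotypes: pd.DataFrame, genotypes: GenotypeMatrix) -> None:
    """Check the phenotype table aligns row-by-row with the genotype matrix."""
    missing = [c for c in ("sample_id", "dataset", "case") if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table lacks required columns: {missing}")
    if len(phenotypes) != genotypes.n_samples:
        raise ValueError(
            f"{len(phenotypes)} phenotype rows but {genotypes.n_samples} genotype rows"
        )
    if list(phenotypes["sample_id"]) != list(genotypes.sample_ids):
        raise ValueError("phenotype sample_id order does not match genotype sample order")
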