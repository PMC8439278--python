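"""Weighted genetic risk score from instrument betas and dosages.

For sample *s* with harmonized effect-allele dosages ``d[s, i]`` and
published per-allele exposure log-ORs ``beta[i]``,

    wGRS_s = sum_i beta[i] * d[s, i]

Dosages are harmonized so that each instrument's effect allele is the
counted allele: matching may require swapping the counted allele
(``d -> 2 - d``), flipping strand (A<->T, C<->G), or both.  Palindromic
variants (A/T or C/G) cannot be resolved by allele labels alone and are
disambiguated by comparing allele frequencies, provided both are far
enough from 0.5.

Missing dosages are mean-imputed as twice the control effect-allele
frequency so the score has the same support for every sample.  The
standardized score divides by the control-group standard deviation, the
conventional reporting scale for risk-score odds ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix, InstrumentRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Palindromic variants with effect-allele frequency inside
#: (0.5 - band, 0.5 + band) are ambiguous and rejected (or dropped).
PALINDROME_EAF_BAND = 0.08


class HarmonizationError(ValueError):
    """Instrument and genotype alleles cannot be reconciled."""


@dataclass
class ScoreVector:
    """Per-sample weighted genetic risk score."""

    values: np.ndarray
    n_variants_used: int
    standardized: bool

    def __len__(self) -> int:
        return len(self.values)


def _complement(allele: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError as e:
        raise HarmonizationError(f"non-ACGT allele {allele!r}") from e


def _is_palindromic(a1: str, a2: str) -> bool:
    return len(a1) == 1 and len(a2) == 1 and _complement(a1) == a2


def harmonize_alleles(
    instrument: InstrumentRecord,
    genotype_ref_allele: str,
    genotype_alt_allele: str,
    dosage: np.ndarray,
    genotype_eaf: float | None = None,
    drop_palindromic: bool = False,
) -> tuple[np.ndarray | None, str]:
    """Orient a dosage vector to count the instrument's effect allele.

    The genotype dosage counts ``genotype_alt_allele``.  Four resolutions
    are attempted in order: identity, allele swap (dosage reflected to
    ``2 - d``), strand flip, and strand flip plus swap.  For palindromic
    variants label matching is uninformative, so the instrument EAF is
    compared with the genotype counted-allele frequency; if either is
    within :data:`PALINDROME_EAF_BAND` of 0.5 the variant is ambiguous.

    Returns ``(oriented dosage, action)`` where action is one of
    ``identity | swap | strand_flip | strand_flip_swap | dropped``.
    ``dropped`` (with a None dosage) occurs only for ambiguous
    palindromic variants when ``drop_palindromic`` is set; otherwise they
    raise :class:`HarmonizationError`.
    """
    ea = instrument.effect_allele.upper()
    oa = instrument.other_allele.upper()
    ref = genotype_ref_allele.upper()
    alt = genotype_alt_allele.upper()
    dosage = np.asarray(dosage, dtype=float)

    if _is_palindromic(ea, oa):
        if genotype_eaf is None:
            genotype_eaf = float(np.nanmean(dosage) / 2.0)
        ambiguous = (
            abs(instrument.eaf - 0.5) <= PALINDROME_EAF_BAND
            or abs(genotype_eaf - 0.5) <= PALINDROME_EAF_BAND
        )
        if ambiguous:
            if drop_palindromic:
                warnings.warn(
                    f"{instrument.rsid}: ambiguous palindromic variant dropped",
                    stacklevel=2,
                )
                return None, "dropped"
            raise HarmonizationError(
                f"{instrument.rsid}: palindromic variant with EAF near 0.5 "
                f"(instrument {instrument.eaf:.3f}, genotype {genotype_eaf:.3f})"
            )
        if {ea, oa} != {ref, alt}:
            raise HarmonizationError(
                f"{instrument.rsid}: palindromic alleles {ea}/{oa} do not match "
                f"genotype {ref}/{alt}"
            )
        # frequencies on the same side of 0.5 mean the counted alleles agree
        same_side = (instrument.eaf - 0.5) * (genotype_eaf - 0.5) > 0
        return (dosage, "identity") if same_side else (2.0 - dosage, "swap")

    if ea == alt and oa == ref:
        return dosage, "identity"
    if ea == ref and oa == alt:
        return 2.0 - dosage, "swap"
    if _complement(ea) == alt and _complement(oa) == ref:
        return dosage, "strand_flip"
    if _complement(ea) == ref and _complement(oa) == alt:
        return 2.0 - dosage, "strand_flip_swap"
    raise HarmonizationError(
        f"{instrument.rsid}: alleles {ea}/{oa} irreconcilable with genotype {ref}/{alt}"
    )


def compute_wgrs(
    genotypes: GenotypeMatrix,
    instruments: list[InstrumentRecord],
    standardize: bool = False,
    control_mask: np.ndarray | None = None,
    drop_palindromic: bool = False,
) -> ScoreVector:
    """Weighted genetic risk score per sample.

    Each instrument is matched to a genotype column by rsid and its
    dosage harmonized to the effect allele.  Missing dosages are imputed
    as ``2 * EAF`` computed in controls (or all samples when no control
    mask is given).  Instruments absent from the genotype matrix are
    excluded with a warning and reflected in ``n_variants_used``.

    With ``standardize`` the score is divided by its control-group SD, so
    downstream odds ratios are per SD of the score.
    """
    n = genotypes.n_samples
    if control_mask is None:
        control_mask = np.ones(n, dtype=bool)
    control_mask = np.asarray(control_mask, dtype=bool)

    total = np.zeros(n)
    used = 0
    rsid_to_col = {r: j for j, r in enumerate(genotypes.rsids)}
    for inst in instruments:
        j = rsid_to_col.get(inst.rsid)
        if j is None:
            warnings.warn(f"{inst.rsid}: absent from genotype matrix; excluded",
                          stacklevel=2)
            continue
        var = genotypes.variants.iloc[j]
        d, action = harmonize_alleles(
            inst, str(var["ref"]), str(var["alt"]), genotypes.dosages[:, j],
            drop_palindromic=drop_palindromic,
        )
        if d is None:
            continue
        miss = np.isnan(d)
        if miss.any():
            ctrl = d[control_mask & ~miss]
            fill = float(np.mean(ctrl)) if len(ctrl) else float(np.nanmean(d))
            d = np.where(miss, fill, d)
        total += inst.beta * d
        used += 1
        if action != "identity":
            logger.debug("%s harmonized via %s", inst.rsid, action)

    if used == 0:
        raise ValueError("no instrument could be scored")
    if standardize:
        sd = float(np.std(total[control_mask]))
        if sd == 0:
            raise ValueError("control-group score SD is zero; cannot standardize")
        total = total / sd
    return ScoreVector(values=total, n_variants_used=used, standardized=standardize)
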