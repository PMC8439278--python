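"""Instrument selection and QC for the exposure variant set.

Starting from a table of published exposure-associated loci and a
reference genotype panel, this module applies the inclusion rules of a
typical genetic-instrument pipeline:

1. drop non-autosomal variants (risk-score pipelines built on autosomal
   dosage data cannot use X-linked instruments);
2. drop variants rare in the analysis population (MAF below a floor);
3. replace indels by the best available proxy SNP in high LD (r^2 above
   a floor), carrying the indel's published effect estimate over to the
   proxy unchanged;
4. greedily prune the remainder to mutual independence (all pairwise
   r^2 below a ceiling), keeping the variant with the stronger exposure
   association from each conflicting pair.

LD is measured as the squared Pearson correlation of dosages in the
reference panel (the standard unphased composite-LD estimator).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, InstrumentRecord, is_autosomal

logger = logging.getLogger(__name__)


class UndefinedLDError(ValueError):
    """LD is undefined for a monomorphic (constant-dosage) variant."""


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries are dropped pairwise.  Raises
    :class:`UndefinedLDError` if either vector is constant after
    deletion.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and of equal length")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[ok], g2[ok]
    if len(g1) < 2:
        raise ValueError("need at least two paired observations")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise UndefinedLDError("LD undefined for a constant dosage vector")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


@dataclass
class SelectionReport:
    """Accounting of every disposition taken during instrument selection."""

    n_input: int = 0
    n_excluded_nonautosomal: int = 0
    n_excluded_maf: int = 0
    n_proxied: int = 0
    n_excluded_no_proxy: int = 0
    n_excluded_ld: int = 0
    n_unresolvable: int = 0
    n_final: int = 0
    #: per-variant (rsid, action, detail) triples, one per input record
    dispositions: list[tuple[str, str, str]] = field(default_factory=list)

    def record(self, rsid: str, action: str, detail: str = "") -> None:
        self.dispositions.append((rsid, action, detail))

    def reconciles(self) -> bool:
        dropped = (
            self.n_excluded_nonautosomal + self.n_excluded_maf
            + self.n_excluded_no_proxy + self.n_excluded_ld + self.n_unresolvable
        )
        return (
            self.n_input == self.n_final + dropped
            and len(self.dispositions) == self.n_input
        )


def _find_proxy(
    indel: InstrumentRecord,
    reference: GenotypeMatrix,
    candidate_rsids: set[str],
    r2_min: float,
) -> tuple[InstrumentRecord, float] | None:
    """Best-r^2 autosomal SNP proxy for an indel, or None."""
    try:
        g_indel = reference.column(indel.rsid)
    except KeyError:
        return None
    best: tuple[float, int] | None = None
    for j, var in reference.variants.iterrows():
        if var["rsid"] == indel.rsid or var["rsid"] in candidate_rsids:
            continue
        if not is_autosomal(var["chrom"]):
            continue
        if len(str(var["ref"])) != 1 or len(str(var["alt"])) != 1:
            continue  # proxies must themselves be SNPs
        try:
            r2 = ld_r2(g_indel, reference.dosages[:, j])
        except UndefinedLDError:
            continue
        if r2 > r2_min and (best is None or r2 > best[0]):
            best = (r2, j)
    if best is None:
        return None
    r2, j = best
    var = reference.variants.iloc[j]
    eaf = float(np.nanmean(reference.dosages[:, j]) / 2.0)
    proxy = InstrumentRecord(
        rsid=str(var["rsid"]), chrom=str(var["chrom"]), pos=int(var["pos"]),
        effect_allele=str(var["alt"]), other_allele=str(var["ref"]),
        beta=indel.beta, se=indel.se, eaf=eaf, is_indel=False,
        proxy_of=indel.rsid, proxy_r2=r2,
    )
    return proxy, r2


def select_instruments(
    candidates: list[InstrumentRecord],
    reference: GenotypeMatrix,
    maf_floor: float = 0.01,
    proxy_r2_min: float = 0.40,
    independence_r2_max: float = 0.10,
) -> tuple[list[InstrumentRecord], SelectionReport]:
    """Apply the full instrument inclusion/exclusion pipeline.

    Returns the final independent instrument list and a
    :class:`SelectionReport` whose counts reconcile to the input size.
    Candidates absent from the reference panel are recorded as
    unresolvable and excluded with a warning; an empty final set is
    fatal.
    """
    report = SelectionReport(n_input=len(candidates))
    candidate_rsids = {c.rsid for c in candidates}
    surviving: list[InstrumentRecord] = []

    for cand in candidates:
        if not is_autosomal(cand.chrom):
            report.n_excluded_nonautosomal += 1
            report.record(cand.rsid, "excluded_nonautosomal", f"chrom={cand.chrom}")
            continue
        if cand.is_indel:
            found = _find_proxy(cand, reference, candidate_rsids, proxy_r2_min)
            if found is None:
                if cand.rsid not in reference.variants["rsid"].values:
                    report.n_unresolvable += 1
                    report.record(cand.rsid, "unresolvable", "indel absent from reference")
                    warnings.warn(f"{cand.rsid}: not in reference panel; excluded",
                                  stacklevel=2)
                else:
                    report.n_excluded_no_proxy += 1
                    report.record(cand.rsid, "excluded_no_proxy",
                                  f"no SNP with r2>{proxy_r2_min}")
                continue
            proxy, r2 = found
            report.n_proxied += 1
            surviving.append(proxy)
            continue
        try:
            g = reference.column(cand.rsid)
        except KeyError:
            report.n_unresolvable += 1
            report.record(cand.rsid, "unresolvable", "absent from reference")
            warnings.warn(f"{cand.rsid}: not in reference panel; excluded", stacklevel=2)
            continue
        af = float(np.nanmean(g) / 2.0)
        maf = min(af, 1.0 - af)
        if maf < maf_floor:
            report.n_excluded_maf += 1
            report.record(cand.rsid, "excluded_maf", f"maf={maf:.4f}")
            continue
        surviving.append(cand)

    # greedy independence pruning: strongest exposure association first,
    # ties broken by rsid so output is deterministic
    order = sorted(range(len(surviving)),
                   key=lambda i: (surviving[i].pvalue, surviving[i].rsid))
    dosage = {rec.rsid: reference.column(rec.rsid) for rec in surviving}
    kept: list[int] = []
    pruned: set[int] = set()
    for i in order:
        gi = dosage[surviving[i].rsid]
        conflict = None
        for k in kept:
            r2 = ld_r2(gi, dosage[surviving[k].rsid])
            if r2 >= independence_r2_max:
                conflict = (surviving[k].rsid, r2)
                break
        if conflict is None:
            kept.append(i)
        else:
            pruned.add(i)
            rec = surviving[i]
            report.n_excluded_ld += 1
            # a pruned proxy is attributed to its original input record
            report.record(rec.proxy_of or rec.rsid, "excluded_ld",
                          f"{rec.rsid} r2={conflict[1]:.3f} with {conflict[0]}")

    final = [surviving[i] for i in sorted(kept)]
    for rec in final:
        if rec.proxy_of is not None:
            report.record(rec.proxy_of, "proxied",
                          f"{rec.rsid} r2={rec.proxy_r2:.3f}")
        else:
            report.record(rec.rsid, "kept")
    report.n_final = len(final)

    if not report.reconciles():  # pragma: no cover - internal consistency
        raise RuntimeError("selection report does not reconcile")
    if not final:
        raise ValueError("instrument selection produced an empty set")
    logger.info(
        "instrument selection: %d in, %d final (%d non-autosomal, %d low-MAF, "
        "%d proxied, %d no-proxy, %d LD-pruned, %d unresolvable)",
        report.n_input, report.n_final, report.n_excluded_nonautosomal,
        report.n_excluded_maf, report.n_proxied, report.n_excluded_no_proxy,
        report.n_excluded_ld, report.n_unresolvable,
    )
    return final, report
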