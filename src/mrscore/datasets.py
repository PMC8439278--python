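"""Programmatically generated demo data sets.

Everything here is synthetic and exists so the pipeline can be exercised
end-to-end without downloading genotype or reference data.  The main
entry point builds a candidate-instrument table together with a matching
toy reference panel, shaped like the published exposure GWAS hit lists
that instrument-selection pipelines start from: a large block of common,
mutually independent autosomal SNPs, a handful of X-linked hits, a rare
variant, and a few indels whose LD partners are present in the panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, InstrumentRecord


def demo_selection_panel(
    n_plain: int = 74,
    n_chrx: int = 5,
    n_rare: int = 1,
    n_indels: int = 8,
    n_samples: int = 600,
    proxy_copy_prob: float = 0.95,
    rare_eaf: float = 0.002,
    seed: int = 20210831,
) -> tuple[list[InstrumentRecord], GenotypeMatrix]:
    """Synthetic candidate loci plus a reference genotype panel.

    The defaults produce 88 candidates: ``n_plain`` common independent
    autosomal SNPs, ``n_chrx`` X-linked variants, ``n_rare`` autosomal
    SNPs rare in the panel, and ``n_indels`` indels, each of which has a
    dedicated proxy SNP in the panel generated by copying the indel's
    dosage per sample with probability ``proxy_copy_prob`` (yielding
    r^2 well above 0.4), while all other pairs are independent draws
    (r^2 near 0).  Default selection settings therefore retain
    ``n_plain + n_indels`` instruments.

    Returns ``(candidates, reference)``.
    """
    rng = np.random.default_rng(seed)
    candidates: list[InstrumentRecord] = []
    var_rows = []
    dosage_cols = []

    def _add_ref(rsid, chrom, pos, ref, alt, dosage):
        var_rows.append(dict(rsid=rsid, chrom=chrom, pos=pos, ref=ref, alt=alt))
        dosage_cols.append(dosage)

    def _draw(eaf):
        return rng.binomial(2, eaf, size=n_samples).astype(float)

    pos = 1_000_000
    idx = 0

    for _ in range(n_plain):
        eaf = rng.uniform(0.10, 0.50)
        chrom = str(1 + idx % 22)
        rsid = f"rs{100000 + idx}"
        g = _draw(eaf)
        _add_ref(rsid, chrom, pos, "A", "G", g)
        candidates.append(InstrumentRecord(
            rsid=rsid, chrom=chrom, pos=pos, effect_allele="G", other_allele="A",
            beta=float(rng.uniform(0.03, 0.15)), se=float(rng.uniform(0.005, 0.02)),
            eaf=float(eaf),
        ))
        pos += 50_000
        idx += 1

    for _ in range(n_chrx):
        rsid = f"rs{100000 + idx}"
        g = _draw(0.3)
        _add_ref(rsid, "X", pos, "A", "G", g)
        candidates.append(InstrumentRecord(
            rsid=rsid, chrom="X", pos=pos, effect_allele="G", other_allele="A",
            beta=float(rng.uniform(0.03, 0.15)), se=float(rng.uniform(0.005, 0.02)),
            eaf=0.3,
        ))
        pos += 50_000
        idx += 1

    for _ in range(n_rare):
        rsid = f"rs{100000 + idx}"
        chrom = str(1 + idx % 22)
        g = _draw(rare_eaf)
        _add_ref(rsid, chrom, pos, "A", "G", g)
        candidates.append(InstrumentRecord(
            rsid=rsid, chrom=chrom, pos=pos, effect_allele="G", other_allele="A",
            beta=float(rng.uniform(0.03, 0.15)), se=float(rng.uniform(0.005, 0.02)),
            eaf=rare_eaf,
        ))
        pos += 50_000
        idx += 1

    for _ in range(n_indels):
        rsid = f"rs{100000 + idx}"
        chrom = str(1 + idx % 22)
        eaf = rng.uniform(0.15, 0.45)
        g_indel = _draw(eaf)
        # proxy: per-sample copy with high probability, fresh draw otherwise
        copy = rng.random(n_samples) < proxy_copy_prob
        g_proxy = np.where(copy, g_indel, _draw(eaf))
        _add_ref(rsid, chrom, pos, "A", "AT", g_indel)
        _add_ref(f"rs{500000 + idx}", chrom, pos + 250, "C", "T", g_proxy)
        candidates.append(InstrumentRecord(
            rsid=rsid, chrom=chrom, pos=pos, effect_allele="AT", other_allele="A",
            beta=float(rng.uniform(0.03, 0.15)), se=float(rng.uniform(0.005, 0.02)),
            eaf=float(eaf), is_indel=True,
        ))
        pos += 50_000
        idx += 1

    reference = GenotypeMatrix(
        dosages=np.column_stack(dosage_cols),
        sample_ids=[f"REF{i:04d}" for i in range(n_samples)],
        variants=pd.DataFrame(var_rows),
    )
    return candidates, reference
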