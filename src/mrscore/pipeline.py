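"""End-to-end pipeline binding the analysis stages together.

The full run mirrors the canonical individual-level MR design:

1. instrument selection against a reference panel (optional when the
   instrument table is already final);
2. genotype QC (variant filters, then sample filters);
3. allele harmonization and weighted genetic risk score;
4. per-dataset covariate-adjusted logistic associations of the score
   with the outcome, overall and within strata, plus a per-variant scan;
5. fixed-effect meta-analysis across datasets and Cochran's Q between
   subgroups;
6. summary-statistic sensitivity estimators (IVW, MR-Egger, simple and
   weighted median) built from the published exposure effects and the
   cohort's own per-variant outcome effects.

Every emitted number is a deterministic function of the inputs, the
configuration, and the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io
from .association import run_association_suite, per_snp_scan, cohort_summary
from .containers import DEFAULT_COVARIATES, GenotypeMatrix, InstrumentRecord, validate_phenotypes
from .estimators import SummaryPair, run_mr_suite
from .instruments import select_instruments
from .meta import meta_fixed, meta_random, subgroup_heterogeneity, forest_table
from .qc import QCThresholds, apply_sample_filters, apply_variant_filters
from .score import compute_wgrs

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and settings of one full pipeline run."""

    instruments: str
    dosages: str
    phenotypes: str
    reference: Optional[str] = None
    pihat: Optional[str] = None
    out_dir: str = "mrscore_out"
    qc: QCThresholds = dc_field(default_factory=QCThresholds)
    strata: Sequence[str] = ("overall", "age", "sex", "smoking", "histology")
    meta_model: str = "fixed"
    mr_methods: Sequence[str] = ("ivw", "egger", "simple_median", "weighted_median")
    n_boot: int = 1000
    seed: int = 0
    standardize_score: bool = True
    drop_palindromic: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QCThresholds(**raw["qc"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("instruments", "dosages", "phenotypes", "reference", "pihat"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.meta_model not in ("fixed", "random"):
            raise ValueError("meta_model must be 'fixed' or 'random'")
        if any(m.endswith("median") for m in self.mr_methods) and self.seed is None:
            raise ValueError("median methods need a bootstrap seed")


def _read_genotypes(path: str) -> GenotypeMatrix:
    if str(path).endswith((".vcf", ".vcf.gz")):
        return io.read_vcf(path)
    return io.read_dosage_tsv(path)


def build_summary_pairs(
    instruments: Sequence[InstrumentRecord],
    outcome_scan: pd.DataFrame,
) -> list[SummaryPair]:
    """Join published exposure effects with fitted outcome effects.

    The outcome scan is keyed by rsid and must already be oriented to the
    instrument effect alleles (the score stage harmonizes dosages before
    scanning).  Instruments without a usable outcome estimate are
    dropped.
    """
    by_rsid = {r.rsid: r for r in outcome_scan.itertuples(index=False)}
    pairs = []
    for inst in instruments:
        hit = by_rsid.get(inst.rsid)
        if hit is None or not np.isfinite(hit.beta) or not np.isfinite(hit.se):
            continue
        pairs.append(SummaryPair(rsid=inst.rsid, beta_x=inst.beta, se_x=inst.se,
                                 beta_y=float(hit.beta), se_y=float(hit.se)))
    return pairs


def harmonized_dosage_matrix(
    genotypes: GenotypeMatrix,
    instruments: Sequence[InstrumentRecord],
    drop_palindromic: bool = False,
) -> tuple[GenotypeMatrix, list[InstrumentRecord]]:
    """Genotype matrix restricted to instruments, dosages counting each
    instrument's effect allele."""
    from .score import harmonize_alleles

    cols, recs, rows = [], [], []
    rsid_to_col = {r: j for j, r in enumerate(genotypes.rsids)}
    for inst in instruments:
        j = rsid_to_col.get(inst.rsid)
        if j is None:
            continue
        var = genotypes.variants.iloc[j]
        d, action = harmonize_alleles(
            inst, str(var["ref"]), str(var["alt"]), genotypes.dosages[:, j],
            drop_palindromic=drop_palindromic,
        )
        if d is None:
            continue
        cols.append(d)
        recs.append(inst)
        rows.append(dict(rsid=inst.rsid, chrom=inst.chrom, pos=inst.pos,
                         ref=inst.other_allele, alt=inst.effect_allele))
    if not cols:
        raise ValueError("no instrument present in the genotype data")
    return GenotypeMatrix(
        dosages=np.column_stack(cols), sample_ids=list(genotypes.sample_ids),
        variants=pd.DataFrame(rows),
    ), recs


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute the full pipeline; returns (and writes) all report tables."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: list[str] = []

    instruments = io.read_instruments(config.instruments)
    genotypes = _read_genotypes(config.dosages)
    phenotypes = io.read_phenotypes(config.phenotypes)
    validate_phenotypes(phenotypes, genotypes)
    counts.append(f"input: {len(instruments)} instruments, "
                  f"{genotypes.n_samples} samples, {genotypes.n_variants} variants")

    results: dict[str, pd.DataFrame] = {}

    if config.reference is not None:
        reference = _read_genotypes(config.reference)
        instruments, report = select_instruments(instruments, reference)
        results["selection_report"] = pd.DataFrame(
            report.dispositions, columns=["rsid", "action", "detail"])
        io.write_table(results["selection_report"], out / "selection_report.tsv")
        counts.append(f"selection: {report.n_input} -> {report.n_final} instruments")

    genotypes, variant_report = apply_variant_filters(genotypes, phenotypes, config.qc)
    results["variant_qc"] = variant_report
    pihat = io.read_pihat(config.pihat) if config.pihat else None
    genotypes, sample_report = apply_sample_filters(genotypes, pihat, config.qc)
    results["sample_qc"] = sample_report
    keep_ids = set(genotypes.sample_ids)
    phenotypes = phenotypes[phenotypes["sample_id"].isin(keep_ids)].reset_index(drop=True)
    counts.append(f"qc: {genotypes.n_samples} samples, "
                  f"{genotypes.n_variants} variants retained")

    harmonized, usable = harmonized_dosage_matrix(
        genotypes, instruments, drop_palindromic=config.drop_palindromic)
    control_mask = phenotypes["case"].to_numpy() == 0
    score = compute_wgrs(harmonized, usable, standardize=config.standardize_score,
                         control_mask=control_mask)
    results["scores"] = pd.DataFrame(dict(sample_id=phenotypes["sample_id"],
                                          wgrs=score.values))
    io.write_table(results["scores"], out / "scores.tsv")
    counts.append(f"score: {score.n_variants_used} variants used")

    assoc = run_association_suite(
        phenotypes, score.values, strata=config.strata,
        genotypes=harmonized, per_snp=True,
    )
    results["associations"] = assoc
    io.write_table(assoc, out / "associations.tsv")

    pool = meta_fixed if config.meta_model == "fixed" else meta_random
    wgrs = assoc[(assoc["term"] == "wgrs") & assoc["converged"]]
    meta_rows, forest_frames = [], []
    for stratum, grp in wgrs.groupby("stratum"):
        ests = list(zip(grp["beta"], grp["se"]))
        m = pool(ests)
        meta_rows.append(dict(stratum=stratum, beta=m.beta, se=m.se, or_=m.or_,
                              ci_low=m.ci_low, ci_high=m.ci_high, p=m.p,
                              Q=m.Q, df=m.df, p_het=m.p_het, k=m.k))
        ft = forest_table(list(grp["dataset"]), ests, pooled=m)
        ft.insert(0, "stratum", stratum)
        forest_frames.append(ft)
    results["meta"] = pd.DataFrame(meta_rows)
    io.write_table(results["meta"], out / "meta.tsv")
    results["forest"] = pd.concat(forest_frames, ignore_index=True)
    io.write_table(results["forest"], out / "forest.tsv")

    het_rows = []
    meta_df = results["meta"].set_index("stratum")
    for factor in config.strata:
        labels = [s for s in meta_df.index
                  if s.startswith(f"{factor}=") or (factor == "histology"
                                                    and s.startswith("histology="))]
        if len(labels) >= 2:
            Q, p_het = subgroup_heterogeneity(
                [(s, meta_df.loc[s, "beta"], meta_df.loc[s, "se"]) for s in labels])
            het_rows.append(dict(factor=factor, Q=Q, df=len(labels) - 1, p_het=p_het))
    results["subgroup_heterogeneity"] = pd.DataFrame(het_rows)
    io.write_table(results["subgroup_heterogeneity"],
                   out / "subgroup_heterogeneity.tsv")

    # sensitivity arm: published exposure betas vs fitted outcome betas
    covs = [c for c in DEFAULT_COVARIATES if c in phenotypes.columns]
    ds = pd.get_dummies(phenotypes["dataset"], drop_first=True)
    C = phenotypes[covs].to_numpy(dtype=float)
    if ds.shape[1]:
        C = np.hstack([C, ds.to_numpy(dtype=float)])
    scan = per_snp_scan(phenotypes["case"].to_numpy(dtype=float),
                        harmonized.dosages, C, rsids=harmonized.rsids)
    pairs = build_summary_pairs(usable, scan)
    mr = run_mr_suite(pairs, methods=config.mr_methods,
                      n_boot=config.n_boot, seed=config.seed)
    results["mr"] = pd.DataFrame([
        dict(method=e.method, beta=e.beta, se=e.se, or_=e.or_, ci_low=e.ci_low,
             ci_high=e.ci_high, p=e.p, n_snps=e.n_snps, intercept=e.intercept,
             intercept_se=e.intercept_se, p_intercept=e.p_intercept)
        for e in mr
    ])
    io.write_table(results["mr"], out / "mr_estimates.tsv")
    counts.append(f"mr: {len(pairs)} summary pairs, {len(mr)} methods")

    results["demographics"] = cohort_summary(phenotypes)
    io.write_table(results["demographics"], out / "demographics.tsv")

    _write_log(out / "run.log", config, counts)
    return results


def _write_log(path: Path, config: PipelineConfig, counts: list[str]) -> None:
    import importlib.metadata

    lines = ["mrscore pipeline run"]
    try:
        lines.append(f"version: {importlib.metadata.version('mrscore')}")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        lines.append("version: (not installed)")
    lines.append(f"numpy: {np.__version__}, pandas: {pd.__version__}")
    lines.append(f"seed: {config.seed}")
    lines.append("config:")
    def _plain(v):
        if isinstance(v, QCThresholds):
            return dict(vars(v))
        if isinstance(v, tuple):
            return list(v)
        return v

    cfg = {k: _plain(v) for k, v in vars(config).items()}
    lines.extend("  " + ln for ln in yaml.safe_dump(cfg, sort_keys=False).splitlines())
    lines.append("stage record counts:")
    lines.extend("  " + c for c in counts)
    path.write_text("\n".join(lines) + "\n")
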