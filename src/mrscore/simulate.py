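"""Synthetic multi-dataset case-control cohorts for pipeline testing.

The generator emulates the statistical structure the analysis assumes:

* independent biallelic SNPs in Hardy-Weinberg equilibrium — dosages
  drawn Binomial(2, EAF) per variant;
* a continuous exposure liability built from the true per-variant
  effects, ``L = sum_i beta_i g_i + c * U + eps`` with an unmeasured
  confounder ``U ~ N(0,1)`` and environmental noise ``eps``;
* binary exposure status by thresholding the liability at its upper
  decile (a realistic adult prevalence for a common metabolic disease);
* a binary outcome whose log-odds are
  ``gamma0 + causal * L + sum_i alpha_i g_i + c * U + covariate effects``
  — ``alpha_i`` are direct (pleiotropic) variant effects, zero for valid
  instruments;
* case-control ascertainment: each dataset oversamples a simulated
  superpopulation until the requested case and control counts are met
  exactly (bounded retries guard against unreachable configurations).

Covariate marginals are fixed at Bernoulli(0.5) for the age >= 60, sex
and ever-smoker indicators and standard normal for the ten principal
components; smoking, age and sex carry moderate outcome effects, the
PCs none.  Under the logistic outcome model, case-control sampling
shifts only the intercept, so covariate and score log-ORs remain
interpretable.

All randomness flows from one integer seed; per-dataset streams are
derived from fixed offsets, so partial reruns reproduce bit-identical
cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .association import per_snp_scan
from .containers import GenotypeMatrix, InstrumentRecord, DEFAULT_COVARIATES
from .estimators import SummaryPair

logger = logging.getLogger(__name__)

#: Outcome log-OR of the binary covariates (age>=60, sex, ever-smoker);
#: smoking dominates, as it does for the target outcome in practice.
COVARIATE_EFFECTS = {"age_ge60": 0.3, "sex": 0.2, "smoker": 0.9}

#: Population prevalence of the binary exposure (upper-decile liability).
EXPOSURE_PREVALENCE = 0.10

#: Approximate superpopulation prevalence of the outcome.
OUTCOME_PREVALENCE = 0.10

#: SD of the non-genetic, non-confounder liability noise.
LIABILITY_NOISE_SD = 0.5

MAX_SAMPLING_ROUNDS = 20


class SamplingExhaustedError(RuntimeError):
    """Requested case/control counts unreachable at the implied prevalence."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for one synthetic multi-dataset cohort."""

    n_variants: int = 82
    n_datasets: int = 3
    n_cases_per_dataset: int = 1000
    n_controls_per_dataset: int = 1000
    eaf_range: tuple[float, float] = (0.05, 0.50)
    beta_exposure_range: tuple[float, float] = (0.03, 0.15)
    causal_logor: float = 0.0
    confounder_strength: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_variants", "n_datasets", "n_cases_per_dataset",
                     "n_controls_per_dataset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        lo, hi = self.eaf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("eaf_range must lie within (0, 1)")
        if self.beta_exposure_range[0] > self.beta_exposure_range[1]:
            raise ValueError("beta_exposure_range must be ordered")


@dataclass
class SyntheticCohort:
    """Generated genotypes, phenotypes and the generating truth."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict = field(repr=False)

    def instrument_table(self) -> list[InstrumentRecord]:
        """The true per-variant exposure effects as a published-style
        instrument table (the weights the risk-score arm consumes)."""
        recs = []
        eaf = self.truth["eaf"]
        beta = self.truth["beta_exposure"]
        for j, row in self.genotypes.variants.iterrows():
            b = float(beta[j])
            recs.append(InstrumentRecord(
                rsid=row["rsid"], chrom=row["chrom"], pos=int(row["pos"]),
                effect_allele=row["alt"], other_allele=row["ref"],
                beta=b, se=max(abs(b) / 8.0, 0.005), eaf=float(eaf[j]),
            ))
        return recs


def _variant_frame(n_variants: int) -> pd.DataFrame:
    chroms = [str(1 + j % 22) for j in range(n_variants)]
    return pd.DataFrame(dict(
        rsid=[f"rs{900000 + j}" for j in range(n_variants)],
        chrom=chroms,
        pos=[100_000 + 10_000 * j for j in range(n_variants)],
        ref=["A"] * n_variants,
        alt=["G"] * n_variants,
    ))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one multi-dataset case-control cohort from the config.

    Deterministic given ``config.seed``.  Raises
    :class:`SamplingExhaustedError` when the requested case or control
    counts cannot be reached within a bounded number of sampling rounds.
    """
    truth_rng = np.random.default_rng([config.seed, 1_000_003])
    m = config.n_variants
    eaf = truth_rng.uniform(*config.eaf_range, size=m)
    beta = truth_rng.uniform(*config.beta_exposure_range, size=m)
    alpha = (
        truth_rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=m)
        if config.pleiotropy_sd > 0
        else np.full(m, config.pleiotropy_mean)
    )

    # theoretical liability moments -> exposure threshold and outcome intercept
    mu_l = float(np.sum(beta * 2 * eaf))
    var_l = float(
        np.sum(beta**2 * 2 * eaf * (1 - eaf))
        + config.confounder_strength**2 + LIABILITY_NOISE_SD**2
    )
    exposure_threshold = mu_l + norm.ppf(1 - EXPOSURE_PREVALENCE) * np.sqrt(var_l)
    gamma0 = float(
        logit(OUTCOME_PREVALENCE)
        - config.causal_logor * mu_l
        - np.sum(alpha * 2 * eaf)
        - 0.5 * sum(COVARIATE_EFFECTS.values())
    )

    frames, geno_blocks, conf_blocks = [], [], []
    for k in range(config.n_datasets):
        rng = np.random.default_rng([config.seed, k])
        need_cases = config.n_cases_per_dataset
        need_controls = config.n_controls_per_dataset
        got: dict[str, list] = {"case": [], "control": []}
        got_g: dict[str, list] = {"case": [], "control": []}
        got_u: dict[str, list] = {"case": [], "control": []}
        batch = 4 * (need_cases + need_controls)
        for round_no in range(MAX_SAMPLING_ROUNDS):
            # Binomial(2, eaf) as two Bernoulli allele draws (HWE by
            # construction); much faster than array-p binomial sampling
            g = (rng.random((batch, m)) < eaf).astype(float)
            g += rng.random((batch, m)) < eaf
            u = rng.normal(size=batch)
            eps = rng.normal(0.0, LIABILITY_NOISE_SD, size=batch)
            liab = g @ beta + config.confounder_strength * u + eps
            age = rng.integers(0, 2, size=batch)
            sex = rng.integers(0, 2, size=batch)
            smoker = rng.integers(0, 2, size=batch)
            pcs = rng.normal(size=(batch, 10))
            eta = (
                gamma0
                + config.causal_logor * liab
                + g @ alpha
                + config.confounder_strength * u
                + COVARIATE_EFFECTS["age_ge60"] * age
                + COVARIATE_EFFECTS["sex"] * sex
                + COVARIATE_EFFECTS["smoker"] * smoker
            )
            case = rng.random(batch) < expit(eta)
            block = pd.DataFrame(dict(
                case=case.astype(int),
                liability=liab,
                exposure=(liab > exposure_threshold).astype(int),
                age_ge60=age, sex=sex, smoker=smoker,
            ))
            for i in range(1, 11):
                block[f"PC{i}"] = pcs[:, i - 1]
            want_case = need_cases - sum(len(b) for b in got["case"])
            want_ctrl = need_controls - sum(len(b) for b in got["control"])
            idx_case = np.flatnonzero(case)[:want_case]
            idx_ctrl = np.flatnonzero(~case)[:want_ctrl]
            for name, idx in (("case", idx_case), ("control", idx_ctrl)):
                got[name].append(block.iloc[idx].reset_index(drop=True))
                got_g[name].append(g[idx])
                got_u[name].append(u[idx])
            have_cases = sum(len(b) for b in got["case"])
            have_ctrls = sum(len(b) for b in got["control"])
            if have_cases >= need_cases and have_ctrls >= need_controls:
                break
        else:
            raise SamplingExhaustedError(
                f"dataset {k}: only {have_cases}/{need_cases} cases and "
                f"{have_ctrls}/{need_controls} controls after "
                f"{MAX_SAMPLING_ROUNDS} sampling rounds"
            )
        ds = pd.concat(got["case"] + got["control"], ignore_index=True)
        ds.insert(0, "dataset", f"D{k + 1}")
        frames.append(ds)
        geno_blocks.append(np.vstack(got_g["case"] + got_g["control"]))
        conf_blocks.append(np.concatenate(got_u["case"] + got_u["control"]))

    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "sample_id", [f"S{i:06d}" for i in range(len(table))])
    geno = np.vstack(geno_blocks)
    confounder = np.concatenate(conf_blocks)
    table["histology"] = _assign_histology(table, config.seed)

    cols = ["sample_id", "dataset", "case", "exposure", "liability",
            "age_ge60", "sex", "smoker", "histology"] + [f"PC{i}" for i in range(1, 11)]
    phenotypes = table[cols]
    genotypes = GenotypeMatrix(
        dosages=geno, sample_ids=phenotypes["sample_id"].tolist(),
        variants=_variant_frame(m),
    )
    truth = dict(
        config=asdict(config),
        eaf=eaf, beta_exposure=beta, pleiotropy=alpha,
        causal_logor=config.causal_logor,
        confounder_strength=config.confounder_strength,
        confounder=confounder,
        exposure_threshold=float(exposure_threshold),
        outcome_intercept=gamma0,
        covariate_effects=dict(COVARIATE_EFFECTS),
        liability_noise_sd=LIABILITY_NOISE_SD,
    )
    return SyntheticCohort(genotypes=genotypes, phenotypes=phenotypes, truth=truth)


def _assign_histology(table: pd.DataFrame, seed: int) -> pd.Series:
    """Histological subtype labels for cases (controls get NA).

    Marginals roughly follow an East-Asian lung-cancer case series:
    adenocarcinoma dominant, then squamous, then other subtypes.
    """
    rng = np.random.default_rng([seed, 77])
    labels = rng.choice(["adenocarcinoma", "squamous", "other"],
                        p=[0.66, 0.22, 0.12], size=len(table))
    out = pd.Series(pd.NA, index=table.index, dtype="object")
    cases = table["case"].to_numpy() == 1
    out[cases] = labels[cases]
    return out


def _ols_scan(y: np.ndarray, D: np.ndarray, C: np.ndarray):
    """Per-column OLS slope and SE of ``y ~ 1 + D[:, j] + C`` via
    Frisch-Waugh residualization (vectorised across columns)."""
    n = len(y)
    X = np.hstack([np.ones((n, 1)), C])
    Q, _ = np.linalg.qr(X)
    r_y = y - Q @ (Q.T @ y)
    r_d = D - Q @ (Q.T @ D)
    ssd = np.sum(r_d**2, axis=0)
    ok = ssd > 0
    slope = np.full(D.shape[1], np.nan)
    se = np.full(D.shape[1], np.nan)
    slope[ok] = (r_d[:, ok] * r_y[:, None]).sum(axis=0) / ssd[ok]
    resid = r_y[:, None] - r_d[:, ok] * slope[ok]
    dof = n - X.shape[1] - 1
    sigma2 = np.sum(resid**2, axis=0) / dof
    se[ok] = np.sqrt(sigma2 / ssd[ok])
    return slope, se


def cohort_to_sumstats(
    cohort: SyntheticCohort,
    exposure_scale: str = "liability",
    covariates: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Per-variant exposure and outcome summary statistics.

    The outcome arm fits, per variant, a logistic regression of case
    status on dosage adjusted for the standard covariates plus dataset
    indicators.  The exposure arm is, by default, a linear regression of
    the continuous liability on dosage with the same adjustment — the
    scale on which the generator's causal effect is defined — or, with
    ``exposure_scale="binary"``, a logistic regression of exposure
    status (note the latter is attenuated relative to the liability
    scale by non-collapsibility of the odds ratio).

    Monomorphic variants are excluded with a warning.  Output columns:
    rsid, beta_x, se_x, beta_y, se_y, p_y.
    """
    if exposure_scale not in ("liability", "binary"):
        raise ValueError("exposure_scale must be 'liability' or 'binary'")
    ph = cohort.phenotypes
    if covariates is None:
        covariates = list(DEFAULT_COVARIATES)
    C = ph[covariates].to_numpy(dtype=float)
    ds = pd.get_dummies(ph["dataset"], drop_first=True)
    if ds.shape[1]:
        C = np.hstack([C, ds.to_numpy(dtype=float)])
    D = cohort.genotypes.dosages
    rsids = cohort.genotypes.rsids

    poly = np.array([np.nanstd(D[:, j]) > 0 for j in range(D.shape[1])])
    for j in np.flatnonzero(~poly):
        warnings.warn(f"{rsids[j]}: monomorphic in the cohort; excluded from "
                      "summary statistics", stacklevel=2)

    y_out = ph["case"].to_numpy(dtype=float)
    scan = per_snp_scan(y_out, D[:, poly], C,
                        rsids=[r for r, p in zip(rsids, poly) if p])

    if exposure_scale == "liability":
        liab = ph["liability"].to_numpy(dtype=float)
        bx, sx = _ols_scan(liab, D[:, poly], C)
    else:
        y_exp = ph["exposure"].to_numpy(dtype=float)
        exp_scan = per_snp_scan(y_exp, D[:, poly], C,
                                rsids=[r for r, p in zip(rsids, poly) if p])
        bx, sx = exp_scan["beta"].to_numpy(), exp_scan["se"].to_numpy()

    out = pd.DataFrame(dict(
        rsid=scan["rsid"], beta_x=bx, se_x=sx,
        beta_y=scan["beta"].to_numpy(), se_y=scan["se"].to_numpy(),
        p_y=scan["p"].to_numpy(),
    ))
    return out.dropna(subset=["beta_x", "se_x", "beta_y", "se_y"]).reset_index(drop=True)


def sumstats_to_pairs(sumstats: pd.DataFrame) -> list[SummaryPair]:
    """Convert a summary-statistics frame into estimator input pairs."""
    return [
        SummaryPair(rsid=r.rsid, beta_x=float(r.beta_x), se_x=float(r.se_x),
                    beta_y=float(r.beta_y), se_y=float(r.se_y))
        for r in sumstats.itertuples(index=False)
    ]
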