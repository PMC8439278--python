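"""Covariate-adjusted logistic regression with Wald inference.

This is the workhorse behind the per-variant and risk-score association
scans: a case/control outcome is regressed on an exposure term (a dosage
or a genetic risk score) plus covariates by maximum likelihood, and the
exposure coefficient is reported as log-OR / SE / OR / 95% CI / p.

Fitting is plain Newton-Raphson on the binomial log-likelihood
(iteratively reweighted least squares).  Standard errors come from the
inverse observed information at the optimum.  The implementation is
deliberately small and vectorised because the pipeline fits thousands of
models that share a covariate block; :func:`per_snp_scan` exploits this
with warm starts from the covariate-only fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .containers import DEFAULT_COVARIATES, GenotypeMatrix

logger = logging.getLogger(__name__)

#: 97.5% standard-normal quantile used for every 95% Wald interval.
Z_95 = 1.959964

#: Any |coefficient| beyond this during iteration is treated as a symptom
#: of (quasi-)complete separation and the fit is flagged non-converged.
SEPARATION_BOUND = 15.0

MAX_ITER = 25
LL_RTOL = 1e-8


class CollinearityError(ValueError):
    """Design matrix is rank deficient (exactly collinear columns)."""


class SeparationWarning(UserWarning):
    """Outcome is (quasi-)separable in the design; no finite MLE."""


@dataclass(frozen=True)
class AssociationResult:
    """One fitted exposure term from a logistic model."""

    term: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    converged: bool

    @classmethod
    def from_beta_se(cls, term: str, beta: float, se: float, n: int,
                     converged: bool = True) -> "AssociationResult":
        z = beta / se
        return cls(
            term=term,
            beta=float(beta),
            se=float(se),
            or_=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z_95 * se)),
            ci_high=float(np.exp(beta + Z_95 * se)),
            p=float(2.0 * norm.sf(abs(z))),
            n=int(n),
            converged=converged,
        )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify which columns break full rank by incremental QR
        bad = []
        cols: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols) + 1:
                cols.append(j)
            else:
                bad.append(names[j])
        raise CollinearityError(f"collinear design columns: {bad}")


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    beta0: Optional[np.ndarray] = None,
    max_iter: int = MAX_ITER,
    rtol: float = LL_RTOL,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson logistic fit.

    Returns (beta, covariance, converged).  ``converged`` is False when
    the likelihood did not stabilise or a coefficient ran away past the
    separation bound.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        # observed == expected information for the canonical link
        XtW = X.T * w
        info = XtW @ X
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.any(np.abs(beta) > SEPARATION_BOUND):
            warnings.warn(
                "coefficient exceeded separation bound; data may be separable",
                SeparationWarning,
                stacklevel=2,
            )
            converged = False
            break
        with np.errstate(divide="ignore"):
            eta = X @ beta
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if np.isfinite(ll_old) and abs(ll - ll_old) <= rtol * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return beta, cov, converged


def fit_logistic(
    outcome: np.ndarray,
    exposure: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    term: str = "exposure",
    covariate_names: Optional[Sequence[str]] = None,
) -> AssociationResult:
    """Logistic regression of a binary outcome on one exposure term.

    Parameters
    ----------
    outcome
        0/1 vector.
    exposure
        Real-valued vector (dosage, score, or indicator); its coefficient
        is the reported association.
    covariates
        Optional n x k matrix of adjustment covariates; an intercept is
        always added internally.

    Raises
    ------
    CollinearityError
        If the design is rank deficient (the offending columns are named).
    ValueError
        If the exposure is constant or the outcome has a single class.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and exposure must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; nothing to fit")
    if np.ptp(x) == 0:
        raise ValueError("exposure is constant; association undefined")

    blocks = [np.ones((len(y), 1)), x[:, None]]
    names = ["intercept", term]
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        blocks.append(C)
        if covariate_names is None:
            covariate_names = [f"cov{i}" for i in range(C.shape[1])]
        names.extend(covariate_names)
    X = np.hstack(blocks)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("design contains NaN; apply listwise deletion upstream")
    _check_rank(X, names)

    beta, cov, converged = _irls(X, y)
    if not converged:
        logger.warning("logistic fit for term %r did not converge", term)
        return AssociationResult(
            term=term, beta=np.nan, se=np.nan, or_=np.nan, ci_low=np.nan,
            ci_high=np.nan, p=np.nan, n=len(y), converged=False,
        )
    se = float(np.sqrt(cov[1, 1]))
    return AssociationResult.from_beta_se(term, float(beta[1]), se, len(y))


def per_snp_scan(
    outcome: np.ndarray,
    dosages: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    rsids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Logistic association of the outcome with each dosage column.

    All fits share the covariate block, so the covariate-only model is
    fitted once and used as a warm start; this makes an 82-variant scan
    cheap enough to repeat across simulation replicates.

    Monomorphic variants are skipped with a warning and reported with NaN
    estimates.
    """
    y = np.asarray(outcome, dtype=float)
    D = np.asarray(dosages, dtype=float)
    n, m = D.shape
    if rsids is None:
        rsids = [f"snp{j}" for j in range(m)]

    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        base = np.hstack([np.ones((n, 1)), C])
    else:
        base = np.ones((n, 1))
    beta_base, _, conv0 = _irls(base, y)
    if not conv0:
        beta_base = np.zeros(base.shape[1])

    rows = []
    warm = np.concatenate([beta_base[:1], [0.0], beta_base[1:]])
    X = np.empty((n, base.shape[1] + 1))
    X[:, 0] = 1.0
    X[:, 2:] = base[:, 1:]
    for j in range(m):
        d = D[:, j]
        miss = np.isnan(d)
        if d[~miss].size == 0 or np.ptp(d[~miss]) == 0:
            warnings.warn(f"variant {rsids[j]} is monomorphic; skipped", stacklevel=2)
            rows.append((rsids[j], np.nan, np.nan, np.nan, len(y), False))
            continue
        if miss.any():
            d = np.where(miss, np.mean(d[~miss]), d)
        X[:, 1] = d
        beta, cov, converged = _irls(X, y, beta0=warm)
        if converged:
            se = float(np.sqrt(cov[1, 1]))
            b = float(beta[1])
            p = float(2.0 * norm.sf(abs(b / se)))
            rows.append((rsids[j], b, se, p, len(y), True))
        else:
            rows.append((rsids[j], np.nan, np.nan, np.nan, len(y), False))
    return pd.DataFrame(rows, columns=["rsid", "beta", "se", "p", "n", "converged"])


# --- stratified association suite -------------------------------------------

#: Map of stratification factors to (phenotype column, covariate to drop).
STRATA_FACTORS = {
    "age": "age_ge60",
    "sex": "sex",
    "smoking": "smoker",
}


def _stratum_iter(phenotypes: pd.DataFrame, factor: str):
    """Yield (stratum label, boolean row mask) pairs for one factor."""
    if factor == "overall":
        yield "overall", np.ones(len(phenotypes), dtype=bool)
    elif factor in STRATA_FACTORS:
        col = STRATA_FACTORS[factor]
        for level, label in ((0, f"{factor}=0"), (1, f"{factor}=1")):
            yield label, (phenotypes[col].to_numpy() == level)
    elif factor == "histology":
        # histology partitions cases only; every stratum reuses all controls
        cases = phenotypes["case"].to_numpy() == 1
        controls = ~cases
        hist = phenotypes["histology"].astype("string")
        for level in sorted(hist[cases].dropna().unique()):
            in_level = hist.eq(level).fillna(False).to_numpy(dtype=bool)
            yield f"histology={level}", (controls | (cases & in_level))
    else:
        raise ValueError(f"unknown stratification factor {factor!r}")


def run_association_suite(
    phenotypes: pd.DataFrame,
    scores: np.ndarray,
    strata: Iterable[str] = ("overall", "age", "sex", "smoking", "histology"),
    covariate_names: Sequence[str] = tuple(DEFAULT_COVARIATES),
    genotypes: Optional[GenotypeMatrix] = None,
    per_snp: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Risk-score association per dataset x stratum, plus optional per-SNP scans.

    The stratification variable is removed from the covariate set in its
    own analysis.  Strata in which the outcome has a single class are
    skipped with a warning.  Per-SNP results get a ``significant`` flag at
    the Bonferroni level ``alpha / n_variants``.
    """
    scores = np.asarray(scores, dtype=float)
    results = []
    for dataset, idx in phenotypes.groupby("dataset").groups.items():
        sub = phenotypes.loc[idx]
        mask_ds = np.zeros(len(phenotypes), dtype=bool)
        mask_ds[phenotypes.index.get_indexer(idx)] = True
        for factor in strata:
            drop = STRATA_FACTORS.get(factor)
            covs = [c for c in covariate_names if c != drop]
            for label, mask_st in _stratum_iter(phenotypes, factor):
                mask = mask_ds & mask_st
                y = phenotypes.loc[mask, "case"].to_numpy(dtype=float)
                if len(np.unique(y)) < 2 or len(y) < len(covs) + 2:
                    warnings.warn(
                        f"stratum {label!r} in dataset {dataset!r} is degenerate; skipped",
                        stacklevel=2,
                    )
                    continue
                C = phenotypes.loc[mask, covs].to_numpy(dtype=float)
                res = fit_logistic(
                    y, scores[mask], C, term="wgrs", covariate_names=covs
                )
                results.append(
                    dict(dataset=dataset, stratum=label, term="wgrs",
                         beta=res.beta, se=res.se, or_=res.or_, ci_low=res.ci_low,
                         ci_high=res.ci_high, p=res.p, n=res.n,
                         converged=res.converged, significant=res.p < alpha)
                )
                if per_snp and genotypes is not None and factor == "overall":
                    scan = per_snp_scan(
                        y, genotypes.dosages[mask, :], C, rsids=genotypes.rsids
                    )
                    bonf = alpha / genotypes.n_variants
                    for r in scan.itertuples(index=False):
                        results.append(
                            dict(dataset=dataset, stratum=label, term=r.rsid,
                                 beta=r.beta, se=r.se,
                                 or_=np.exp(r.beta) if np.isfinite(r.beta) else np.nan,
                                 ci_low=np.nan, ci_high=np.nan, p=r.p, n=r.n,
                                 converged=r.converged,
                                 significant=bool(np.isfinite(r.p) and r.p < bonf))
                        )
    return pd.DataFrame(results)


def cohort_summary(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Descriptive counts and percentages by case status.

    Reports, per outcome group, the number and percentage of samples aged
    >= 60 and (among cases) the histology breakdown.  Percentages are
    computed over non-missing values, matching the usual presentation of
    case-control demographics tables.
    """
    rows = []
    for status, grp in phenotypes.groupby("case"):
        label = "case" if status == 1 else "control"
        age = grp["age_ge60"].dropna()
        rows.append(
            dict(group=label, characteristic="age_ge60",
                 numerator=int((age == 1).sum()), denominator=int(len(age)),
                 percent=round(100.0 * (age == 1).sum() / len(age), 2) if len(age) else np.nan)
        )
        if status == 1 and "histology" in grp.columns:
            hist = grp["histology"].dropna()
            for level in sorted(hist.unique()):
                rows.append(
                    dict(group=label, characteristic=f"histology={level}",
                         numerator=int((hist == level).sum()),
                         denominator=int(len(hist)),
                         percent=round(100.0 * (hist == level).sum() / len(hist), 2))
                )
    return pd.DataFrame(rows)
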