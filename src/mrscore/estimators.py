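"""Summary-statistic Mendelian randomization estimators.

Given per-variant harmonized summary pairs — the variant's effect on the
exposure (beta_x, se_x) and on the outcome (beta_y, se_y), both oriented
to the same effect allele — these estimators recover the causal effect
of the exposure on the outcome under different pleiotropy assumptions:

* **IVW**: zero-intercept weighted regression of beta_y on beta_x with
  weights 1/se_y^2 (equivalently, the fixed-effect meta-analysis of the
  per-variant ratio estimates beta_y/beta_x).  Consistent when every
  instrument is valid.
* **MR-Egger**: the same regression with a free intercept.  The slope is
  the causal estimate under the InSIDE assumption; the intercept
  estimates average directional pleiotropy and its Wald test is the
  pleiotropy diagnostic.  Residual over-dispersion is absorbed by a
  multiplicative scale floored at 1.
* **Simple / weighted median**: the 50% point of the per-variant ratio
  estimates under equal or inverse-variance weights; consistent when at
  least half the weight comes from valid instruments.  Standard errors
  come from a parametric bootstrap.

All estimators use first-order weights (se_y only), the convention of
the classical two-sample MR toolchain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .association import Z_95

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryPair:
    """Harmonized per-variant exposure and outcome effects."""

    rsid: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float

    def __post_init__(self) -> None:
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError(f"{self.rsid}: standard errors must be positive")


@dataclass(frozen=True)
class MREstimate:
    """Causal estimate from one summary-statistic MR method."""

    method: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    p_intercept: Optional[float] = None

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snps: int,
                     **kw) -> "MREstimate":
        return cls(
            method=method, beta=float(beta), se=float(se),
            or_=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z_95 * se)),
            ci_high=float(np.exp(beta + Z_95 * se)),
            p=float(2.0 * norm.sf(abs(beta / se))),
            n_snps=n_snps, **kw,
        )


def _arrays(pairs: Sequence[SummaryPair]):
    bx = np.array([p.beta_x for p in pairs], dtype=float)
    sx = np.array([p.se_x for p in pairs], dtype=float)
    by = np.array([p.beta_y for p in pairs], dtype=float)
    sy = np.array([p.se_y for p in pairs], dtype=float)
    return bx, sx, by, sy


def mr_ivw(pairs: Sequence[SummaryPair]) -> MREstimate:
    """Inverse-variance weighted estimate (fixed effect, first-order).

    beta = sum(bx * by / sy^2) / sum(bx^2 / sy^2);
    se   = sqrt(1 / sum(bx^2 / sy^2)).
    """
    if len(pairs) < 2:
        raise ValueError("IVW requires at least two summary pairs")
    bx, _, by, sy = _arrays(pairs)
    denom = np.sum(bx**2 / sy**2)
    if denom == 0:
        raise ValueError("all exposure effects are zero; no instrument strength")
    beta = float(np.sum(bx * by / sy**2) / denom)
    se = float(np.sqrt(1.0 / denom))
    return MREstimate.from_beta_se("ivw", beta, se, len(pairs))


def mr_egger(pairs: Sequence[SummaryPair]) -> MREstimate:
    """MR-Egger regression: slope = causal effect, intercept = pleiotropy.

    Pairs are first re-oriented so every beta_x is non-negative (the
    estimate is invariant to the input orientation of any pair).  The
    weighted regression uses 1/se_y^2 weights; coefficient variances are
    scaled by the residual dispersion, floored at 1.
    """
    if len(pairs) < 3:
        raise ValueError("MR-Egger requires at least three summary pairs")
    bx, _, by, sy = _arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise ValueError("no spread in exposure effects; Egger slope unidentified")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ by)
    resid = by - X @ coef
    df = len(pairs) - 2
    scale = max(1.0, float(np.sum(w * resid**2) / df)) if df > 0 else 1.0
    cov = scale * np.linalg.inv(A)
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return MREstimate.from_beta_se(
        "egger", slope, se_slope, len(pairs),
        intercept=inter, intercept_se=se_inter,
        p_intercept=float(2.0 * norm.sf(abs(inter / se_inter))),
    )


def weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    """Percentile by linear interpolation in cumulative weight.

    Exact for the ordinary sample percentile at equal weights; this is
    the interpolation rule of the published weighted-median estimator.
    """
    order = np.argsort(values)
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    return float(np.interp(q, cum, v))


def _median_point(bx, by, sy, weighted: bool) -> float:
    ratios = by / bx
    if weighted:
        weights = bx**2 / sy**2  # inverse of first-order ratio variance
    else:
        weights = np.ones_like(ratios)
    return weighted_percentile(ratios, weights, 0.5)


def mr_median(
    pairs: Sequence[SummaryPair],
    weighted: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Simple or weighted median of per-variant ratio estimates.

    Pairs with beta_x = 0 are dropped with a warning (their ratio is
    undefined).  The standard error is estimated by a parametric
    bootstrap: beta_x and beta_y are resampled from normal(beta, se)
    with a fixed seed and the median recomputed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    kept = [p for p in pairs if p.beta_x != 0]
    for p in pairs:
        if p.beta_x == 0:
            warnings.warn(f"{p.rsid}: beta_x = 0, ratio undefined; dropped",
                          stacklevel=2)
    if len(kept) < 3:
        raise ValueError("median estimator requires at least three usable pairs")
    bx, sx, by, sy = _arrays(kept)
    point = _median_point(bx, by, sy, weighted)

    rng = np.random.default_rng(seed)
    m = len(kept)
    bx_b = rng.normal(bx, sx, size=(n_boot, m))
    by_b = rng.normal(by, sy, size=(n_boot, m))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        nz = bx_b[b] != 0
        boots[b] = _median_point(bx_b[b][nz], by_b[b][nz], sy[nz], weighted)
    se = float(np.std(boots, ddof=1))
    method = "weighted_median" if weighted else "simple_median"
    if se == 0:
        # degenerate dispersion (all ratios identical, vanishing ses)
        return MREstimate(method=method, beta=point, se=0.0, or_=float(np.exp(point)),
                          ci_low=float(np.exp(point)), ci_high=float(np.exp(point)),
                          p=0.0 if point != 0 else 1.0, n_snps=m)
    return MREstimate.from_beta_se(method, point, se, m)


def run_mr_suite(
    pairs: Sequence[SummaryPair],
    methods: Sequence[str] = ("ivw", "egger", "simple_median", "weighted_median"),
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MREstimate]:
    """All requested summary-MR estimators on one harmonized pair set."""
    out = []
    for m in methods:
        if m == "ivw":
            out.append(mr_ivw(pairs))
        elif m == "egger":
            out.append(mr_egger(pairs))
        elif m == "simple_median":
            out.append(mr_median(pairs, weighted=False, n_boot=n_boot, seed=seed))
        elif m == "weighted_median":
            out.append(mr_median(pairs, weighted=True, n_boot=n_boot, seed=seed))
        else:
            raise ValueError(f"unknown MR method {m!r}")
    return out
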