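"""Fixed-effect inverse-variance meta-analysis and Cochran's Q.

Per-dataset (or per-stratum) log-OR estimates are pooled with weights
``w_k = 1 / se_k^2``; the pooled estimate is the weighted mean and its
variance the reciprocal total weight.  Heterogeneity between the pooled
inputs is measured by Cochran's Q, chi-square with k - 1 df under
homogeneity.  A DerSimonian-Laird random-effects variant is available
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

from .association import Z_95


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    Q: float
    df: int
    p_het: float
    k: int
    tau2: float = 0.0  # between-study variance (random-effects only)
    model: str = "fixed"


def _finish(beta: float, se: float, Q: float, k: int, tau2: float, model: str) -> MetaResult:
    df = k - 1
    p_het = float(chi2.sf(Q, df)) if df > 0 else 1.0
    z = beta / se
    return MetaResult(
        beta=float(beta), se=float(se), or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        p=float(2.0 * norm.sf(abs(z))),
        Q=float(Q), df=df, p_het=p_het, k=k, tau2=tau2, model=model,
    )


def meta_fixed(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of (beta, se) pairs.

    A single estimate passes through unchanged with Q = 0 and p_het = 1.
    """
    if len(estimates) == 0:
        raise ValueError("cannot meta-analyse an empty list of estimates")
    beta = np.array([b for b, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    Q = float(np.sum(w * (beta - pooled) ** 2))
    return _finish(pooled, pooled_se, Q, len(estimates), 0.0, "fixed")


def meta_random(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling (sensitivity analysis).

    Q is still computed with fixed-effect weights; the method-of-moments
    between-study variance tau^2 inflates the weights of the pooled
    estimate.  Reduces to the fixed-effect result when Q <= df.
    """
    fixed = meta_fixed(estimates)
    if fixed.k == 1:
        return fixed
    se = np.array([s for _, s in estimates], dtype=float)
    beta = np.array([b for b, _ in estimates], dtype=float)
    w = 1.0 / se**2
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (fixed.Q - fixed.df) / c)
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * beta) / np.sum(w_star))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_star)))
    return _finish(pooled, pooled_se, fixed.Q, fixed.k, float(tau2), "random")


def subgroup_heterogeneity(
    stratum_estimates: Sequence[tuple[str, float, float]],
) -> tuple[float, float]:
    """Cochran's Q across stratum-level estimates.

    Input is a list of (label, beta, se); at least two strata are
    required.  Returns (Q, p_het) with df = n_strata - 1.
    """
    if len(stratum_estimates) < 2:
        raise ValueError("subgroup heterogeneity needs at least two strata")
    res = meta_fixed([(b, s) for _, b, s in stratum_estimates])
    return res.Q, res.p_het


def forest_table(
    labels: Sequence[str],
    estimates: Sequence[tuple[float, float]],
    pooled: MetaResult | None = None,
):
    """Forest-plot-ready table: per-input OR/CI plus percentage weight."""
    import pandas as pd

    se = np.array([s for _, s in estimates], dtype=float)
    w = 1.0 / se**2
    w_pct = 100.0 * w / w.sum()
    rows = [
        dict(label=lab, beta=b, se=s, or_=np.exp(b),
             ci_low=np.exp(b - Z_95 * s), ci_high=np.exp(b + Z_95 * s),
             weight_pct=wp)
        for lab, (b, s), wp in zip(labels, estimates, w_pct)
    ]
    if pooled is not None:
        rows.append(dict(label=f"pooled ({pooled.model})", beta=pooled.beta,
                         se=pooled.se, or_=pooled.or_, ci_low=pooled.ci_low,
                         ci_high=pooled.ci_high, weight_pct=100.0))
    return pd.DataFrame(rows)
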