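"""Two-group differential expression screening.

A gene is called differentially expressed when both |log2 fold change|
exceeds a threshold (default 2) and its multiplicity-adjusted p-value falls
below alpha (default 0.05).  logFC is the difference of per-class means on
the log2 scale (cancer minus normal).  Two tests are offered: Welch's
unequal-variance t (default) and a moderated t with empirical-Bayes variance
shrinkage in the style of the limma pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from gwolfsel.io_prep import ExpressionDataError, ExpressionMatrix


@dataclass
class DGEConfig:
    lfc_threshold: float = 2.0
    alpha: float = 0.05
    test: str = "welch_t"        # or "moderated_t"

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.test not in ("welch_t", "moderated_t"):
            raise ValueError(f"unknown test {self.test!r}")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_dge(m: ExpressionMatrix, cfg: DGEConfig | None = None) -> pd.DataFrame:
    """Per-gene DGE table with the DEG call.

    Returns a DataFrame with columns ``gene``, ``logFC``, ``t``, ``p``,
    ``adj_p``, ``direction`` and ``is_deg`` (one row per gene, input order).
    """
    cfg = cfg or DGEConfig()
    y = m.require_labels()
    pos = m.values[:, y == 1]
    neg = m.values[:, y == 0]
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ExpressionDataError("each class needs >= 2 samples for DGE")

    logfc = pos.mean(axis=1) - neg.mean(axis=1)
    if cfg.test == "welch_t":
        t, p = stats.ttest_ind(pos, neg, axis=1, equal_var=False)
    else:
        t, p = moderated_t(pos, neg)
    # zero-variance genes give nan t/p; treat as no evidence
    p = np.where(np.isfinite(p), p, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)

    adj = bh_adjust(p)
    is_deg = (np.abs(logfc) > cfg.lfc_threshold) & (adj < cfg.alpha)
    return pd.DataFrame(
        {
            "gene": m.gene_ids,
            "logFC": logfc,
            "t": t,
            "p": p,
            "adj_p": adj,
            "direction": np.where(logfc > 0, "up", "down"),
            "is_deg": is_deg,
        }
    )


def deg_summary(table: pd.DataFrame) -> dict:
    """Counts in the shape of a DEG summary table (total/DEG/up/down)."""
    deg = table[table["is_deg"]]
    return {
        "total_genes": int(len(table)),
        "degs": int(len(deg)),
        "upregulated": int((deg["direction"] == "up").sum()),
        "downregulated": int((deg["direction"] == "down").sum()),
    }


# ---------------------------------------------------------------------------
# moderated t (empirical-Bayes variance shrinkage, two-group design)
# ---------------------------------------------------------------------------

def moderated_t(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance t with per-gene variances shrunk toward a common prior.

    The residual variances s_g^2 (pooled across the two groups, df = n-2)
    are modeled as scaled-F around a prior s0^2 with d0 prior df; the
    hyperparameters are estimated by moment matching on log s_g^2 and the
    statistic uses the posterior variance with df = d0 + (n-2).
    """
    n1, n2 = pos.shape[1], neg.shape[1]
    df_resid = n1 + n2 - 2
    if df_resid < 1:
        raise ExpressionDataError("moderated t needs n1 + n2 >= 3")
    diff = pos.mean(axis=1) - neg.mean(axis=1)
    ss = pos.var(axis=1, ddof=1) * (n1 - 1) + neg.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    d0, s02 = squeeze_var_hyperparams(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    return t, p


def squeeze_var_hyperparams(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment estimation of the variance prior (d0, s0^2) on the log scale.

    Uses E[log s^2] and Var[log s^2] of the scaled-F model: with
    z = log(s2), z - E|d0,s0 follows a difference of log-chi-square terms
    whose mean/variance involve digamma/trigamma functions.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    resid_var = e_var - special.polygamma(1, df / 2)
    if resid_var <= 0:
        # no excess spread: infinite prior df, common variance
        return np.inf, float(np.exp(e_mean))
    d0 = 2 * _trigamma_inverse(resid_var)
    s02 = np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s02)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)
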