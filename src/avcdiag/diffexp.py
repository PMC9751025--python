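"""Two-group differential expression with a moderated t-statistic.

The moderated mode shrinks each gene's residual variance toward a prior
estimated across all genes (empirical Bayes on the log sample variances,
method of moments), which stabilizes small-sample t-statistics the same way
the classic microarray linear-model approach does. A plain Welch t is
available as a fallback for very small gene sets where the prior cannot be
estimated reliably.

Fold changes are differences of group means on the log2 scale
(disease − normal). Selection uses strict inequalities on p-value and
absolute log2 fold change; by default the raw p-value is used, with
Benjamini–Hochberg adjustment available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_preprocess import DISEASE, NORMAL, ExpressionMatrix, SampleSheet

P_THRESHOLD = 0.05
LFC_THRESHOLD = 0.585  # |log2FC| > 0.585, i.e. fold change > 1.5


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # good starting point for the monotone trigamma
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x - dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Estimate prior degrees of freedom d0 and prior variance s0².

    Fits a scaled inverse-chi-square prior to the observed per-gene residual
    variances via moments of log(s²): the excess spread of log-variances over
    what df_resid alone predicts determines d0, and the adjusted mean
    determines s0². Returns (inf, geometric-mean variance) when the observed
    spread is at or below the sampling floor.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(positive)
    e_z = np.mean(z)
    v_z = np.var(z, ddof=1)
    tri_half_df = special.polygamma(1, df_resid / 2.0)
    excess = v_z - tri_half_df
    if excess <= 0:
        s0_sq = np.exp(e_z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0))
        return np.inf, float(s0_sq)
    d0 = 2.0 * float(_trigamma_inverse(np.array([excess]))[0])
    s0_sq = np.exp(
        e_z
        - special.digamma(df_resid / 2.0)
        + np.log(df_resid / 2.0)
        + special.digamma(d0 / 2.0)
        - np.log(d0 / 2.0)
    )
    return d0, float(s0_sq)


def moderated_t(
    m: ExpressionMatrix,
    s: SampleSheet,
    mode: str = "moderated",
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Per-gene two-sample test of disease vs normal.

    Returns a DataFrame with columns gene, log2fc, t, p_value, adj_p (BH).
    ``mode='moderated'`` uses the empirical-Bayes shrunken pooled variance
    s̃² = (d0·s0² + d·s²)/(d0 + d) with t on d0 + d degrees of freedom;
    ``mode='welch'`` is a standard Welch two-sample t. ``d0_override`` pins
    the prior degrees of freedom (0 recovers the ordinary pooled t).
    """
    if mode not in {"moderated", "welch"}:
        raise ValueError(f"unknown mode: {mode!r}")
    groups = s.groups_for(m.sample_ids)
    d_cols = groups == DISEASE
    n_cols = groups == NORMAL
    n1, n2 = int(d_cols.sum()), int(n_cols.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    x = m.data.to_numpy(dtype=float)
    xd, xn = x[:, d_cols], x[:, n_cols]
    log2fc = xd.mean(axis=1) - xn.mean(axis=1)

    if mode == "welch":
        t_stat, p = stats.ttest_ind(xd, xn, axis=1, equal_var=False)
        t_stat = np.asarray(t_stat, dtype=float)
        p = np.asarray(p, dtype=float)
        degenerate = ~np.isfinite(t_stat)
        t_stat[degenerate] = 0.0
        p[degenerate] = 1.0
    else:
        df_resid = n1 + n2 - 2
        ss = xd.var(axis=1, ddof=1) * (n1 - 1) + xn.var(axis=1, ddof=1) * (n2 - 1)
        s2 = ss / df_resid
        if d0_override is not None:
            d0 = float(d0_override)
            s0_sq = float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
        else:
            d0, s0_sq = estimate_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = np.where(se > 0, log2fc / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t_stat))
        else:
            p = 2.0 * stats.t.sf(np.abs(t_stat), df=df_total)
        zero_se = se == 0
        p = np.where(zero_se, 1.0, p)

    adj_p = _benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "gene": m.gene_ids,
            "log2fc": log2fc,
            "t": t_stat,
            "p_value": p,
            "adj_p": adj_p,
        }
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def filter_degs(
    records: pd.DataFrame,
    p_thr: float = P_THRESHOLD,
    lfc_thr: float = LFC_THRESHOLD,
    correction: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split significant genes into up- and down-regulated lists.

    Selection is strict: p < p_thr AND |log2fc| > lfc_thr. With
    ``correction='bh'`` the BH-adjusted p-value is thresholded instead.
    Returns (up, down) DataFrames with a ``direction`` column added.
    """
    if len(records) == 0:
        raise ValueError("no records to filter")
    if correction not in {"none", "bh"}:
        raise ValueError(f"unknown correction: {correction!r}")
    pcol = "adj_p" if correction == "bh" else "p_value"
    selected = (records[pcol] < p_thr) & (records["log2fc"].abs() > lfc_thr)
    up = records[selected & (records["log2fc"] > 0)].copy()
    down = records[selected & (records["log2fc"] < 0)].copy()
    up["direction"] = "up"
    down["direction"] = "down"
    return up, down
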