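"""Moderated-t differential expression with significance, fold-change, and
low-expression filters.

Per gene a pooled two-group linear model gives the log2 fold change
(case mean - control mean) and residual variance s_g^2 on d_g = n1 + n2 - 2
degrees of freedom. The gene variances are assumed exchangeable around a
scaled-inverse-chi-square prior (d0, s0^2), whose hyperparameters are
estimated by closed-form moment matching on log s_g^2 (the standard
empirical-Bayes treatment for microarray linear models). The posterior
variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

yields the moderated statistic t = logFC / (s~_g * sqrt(1/n1 + 1/n2)) on
d0 + d_g degrees of freedom. P-values are two-sided; BH-adjusted p-values are
reported alongside but the DEG call uses raw p (the adjustment is reserved
for enrichment testing downstream).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import ConfigurationError, DataError, ExpressionMatrix


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook definition:
    sort, take p * m / rank, then the cumulative minimum from the largest
    p down, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    return adj

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_STABLE = "stable"


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the standard monotone-convergent update on 1/y. For x <= 0 the
    solution diverges (returns inf).
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < tol:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from observed gene variances.

    Matches the mean and variance of log s_g^2 to the scaled-F distribution
    implied by the hierarchical model (closed forms via digamma/trigamma).
    Returns d0 = inf when the observed spread is no wider than sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.exp(np.log(s2[ok]).mean())) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = e.mean()
    G = len(e)
    excess = e.var(ddof=0) * G / (G - 1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_bar))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(m: ExpressionMatrix, force_d0_zero: bool = False) -> pd.DataFrame:
    """Per-gene moderated-t table.

    Columns: logFC, aveExpr, s2, t_mod, df_total, p, adj_p, plus d0/s0_sq as
    DataFrame attrs. ``force_d0_zero`` disables variance moderation, giving
    the ordinary pooled two-sample t (a limiting-case check).
    """
    if m.scale != "log2":
        raise DataError("moderated_t expects log2-scale data; apply to_log2 first")
    case = m.case_mask()
    n1, n2 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n2 < 2:
        raise DataError("each class needs at least 2 samples")

    X = m.values.to_numpy(dtype=float)
    mean1 = X[:, case].mean(axis=1)
    mean2 = X[:, ~case].mean(axis=1)
    logfc = mean1 - mean2
    ave = X.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((X[:, case] - mean1[:, None]) ** 2).sum(axis=1) + (
        (X[:, ~case] - mean2[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if force_d0_zero:
        d0, s0_sq = 0.0, np.nan
        s2_post = s2
    else:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    df_total = d0 + df_resid if np.isfinite(d0) else np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    adj_p = bh_adjust(p)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "aveExpr": ave,
            "s2": s2,
            "t_mod": t,
            "df_total": df_total,
            "p": p,
            "adj_p": adj_p,
            "status": STATUS_STABLE,
            "low_expression": False,
        },
        index=m.values.index,
    )
    table.attrs["d0"] = float(d0)
    table.attrs["s0_sq"] = float(s0_sq) if not np.isnan(s0_sq) else np.nan
    table.attrs["n_case"] = n1
    table.attrs["n_control"] = n2
    return table


def filter_degs(
    table: pd.DataFrame,
    p_cut: float = 0.01,
    lfc_cut: float = 0.26,
    low_expr_quantile: float = 0.25,
) -> pd.DataFrame:
    """Flag up/down DEGs: raw p < ``p_cut``, |logFC| > ``lfc_cut``, and not in
    the bottom ``low_expr_quantile`` of average expression.

    The low-expression filter is applied after the p/logFC cut: the table's
    attrs record both the pre-filter count (``n_pass_p_lfc``, split into
    ``n_up_prefilter``/``n_down_prefilter``) and the post-filter counts.
    """
    if not 0.0 < low_expr_quantile < 1.0:
        raise ConfigurationError("low_expr_quantile must lie in (0, 1)")
    out = table.copy()
    cutoff = out["aveExpr"].quantile(low_expr_quantile)
    out["low_expression"] = out["aveExpr"] < cutoff

    pass_p_lfc = (out["p"] < p_cut) & (out["logFC"].abs() > lfc_cut)
    retained = pass_p_lfc & ~out["low_expression"]
    out["status"] = STATUS_STABLE
    out.loc[retained & (out["logFC"] > 0), "status"] = STATUS_UP
    out.loc[retained & (out["logFC"] < 0), "status"] = STATUS_DOWN

    out.attrs.update(table.attrs)
    out.attrs["n_up_prefilter"] = int((pass_p_lfc & (out["logFC"] > 0)).sum())
    out.attrs["n_down_prefilter"] = int((pass_p_lfc & (out["logFC"] < 0)).sum())
    out.attrs["n_pass_p_lfc"] = int(pass_p_lfc.sum())
    out.attrs["n_up"] = int((out["status"] == STATUS_UP).sum())
    out.attrs["n_down"] = int((out["status"] == STATUS_DOWN).sum())
    out.attrs["n_degs"] = out.attrs["n_up"] + out.attrs["n_down"]
    return out


def deg_gene_signs(table: pd.DataFrame) -> dict[str, int]:
    """Mapping of called DEG gene id -> +1 (up) / -1 (down)."""
    signs: dict[str, int] = {}
    for gid, status in table["status"].items():
        if status == STATUS_UP:
            signs[gid] = 1
        elif status == STATUS_DOWN:
            signs[gid] = -1
    return signs
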