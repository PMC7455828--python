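"""Log transformation, dataset merging, empirical-Bayes batch adjustment,
and min-max normalization.

The batch adjustment follows the standard parametric empirical-Bayes
location/scale model (ComBat): per gene, a standardization model with an
overall gene mean and a protected class covariate is fitted, per-batch
location (gamma) and scale (delta^2) effects are estimated and shrunk toward
moment-matched priors — a normal prior on gamma and an inverse-gamma prior on
delta^2 — via iterated conditional modes, then removed. A non-parametric
variant replaces the parametric posteriors with weighted Monte-Carlo
posterior means over the empirical distribution of the other genes'
batch-effect estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CASE, DataError, ExpressionMatrix, NormalizationRanges


def to_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts -> per-sample CPM then log2(CPM + 1); identity on log2 input."""
    if m.scale == "log2":
        return m
    counts = m.values.to_numpy(dtype=float)
    if (counts < 0).any():
        raise DataError("negative counts")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise DataError("sample with zero total counts")
    cpm = counts / totals * 1e6
    out = m.copy()
    out.values = pd.DataFrame(np.log2(cpm + 1.0), index=m.values.index, columns=m.values.columns)
    out.scale = "log2"
    return out


def merge_datasets(ms: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate samples over the gene intersection; each source dataset
    becomes one batch level (``ds1``, ``ds2``, ...)."""
    if len(ms) < 2:
        raise DataError("need at least 2 matrices to merge")
    if any(m.scale != "log2" for m in ms):
        raise DataError("all matrices must be on the log2 scale; apply to_log2 first")
    common = ms[0].values.index
    for m in ms[1:]:
        common = common.intersection(m.values.index)
    if len(common) == 0:
        raise DataError("empty gene intersection")
    common = ms[0].values.index[ms[0].values.index.isin(common)]  # keep first matrix's order

    all_ids = [s for m in ms for s in m.sample_ids]
    if len(set(all_ids)) != len(all_ids):
        raise DataError("duplicate sample ids across datasets")

    values = pd.concat([m.values.loc[common] for m in ms], axis=1)
    classes = pd.concat([m.classes for m in ms])
    batches = pd.concat(
        [pd.Series(f"ds{i + 1}", index=m.values.columns) for i, m in enumerate(ms)]
    )
    return ExpressionMatrix(values=values, classes=classes, batches=batches, scale="log2")


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z_batch, g_hat, d_hat2, g_bar, t2, a, b, tol=1e-4, max_iter=1000):
    """Iterated conditional modes for one batch's (gamma*, delta2*)."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat2.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def _np_posterior(z_batch, g_hat, d_hat2):
    """Non-parametric (weighted Monte-Carlo) posterior means, leave-one-out
    over the empirical distribution of the other genes' estimates."""
    G, n = z_batch.shape
    g_star = np.empty(G)
    d_star = np.empty(G)
    for g in range(G):
        mask = np.ones(G, dtype=bool)
        mask[g] = False
        gh, dh = g_hat[mask], d_hat2[mask]
        resid2 = ((z_batch[g][None, :] - gh[:, None]) ** 2).sum(axis=1)
        log_lh = -0.5 * n * np.log(2 * np.pi * dh) - resid2 / (2.0 * dh)
        log_lh -= log_lh.max()
        w = np.exp(log_lh)
        w_sum = w.sum()
        g_star[g] = (w * gh).sum() / w_sum
        d_star[g] = (w * dh).sum() / w_sum
    return g_star, d_star


def combat_adjust(m: ExpressionMatrix, parametric: bool = True) -> ExpressionMatrix:
    """Remove batch location/scale effects while protecting the class covariate.

    Requires at least 2 batches with at least 2 samples each. Genes with zero
    pooled variance are passed through unadjusted.
    """
    if m.scale != "log2":
        raise DataError("combat_adjust expects log2-scale data")
    batches = m.batches
    levels = sorted(batches.unique())
    if len(levels) < 2:
        raise DataError("need at least 2 batches")
    sizes = batches.value_counts()
    if (sizes < 2).any():
        raise DataError("every batch needs at least 2 samples")

    X = m.values.to_numpy(dtype=float)
    G, n = X.shape
    batch_design = np.column_stack([(batches == b).to_numpy(float) for b in levels])
    covar = m.case_mask().astype(float)[:, None]
    design = np.hstack([batch_design, covar])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DataError("class is confounded with batch; adjustment is not identifiable")

    # standardization model
    B_hat = np.linalg.lstsq(design, X.T, rcond=None)[0]  # (m+1) x G
    n_batches = len(levels)
    n_per = np.array([sizes[b] for b in levels], dtype=float)
    grand_mean = (n_per / n) @ B_hat[:n_batches]  # G
    resid = X - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)

    nonzero = var_pooled > 0
    stand_mean = grand_mean[:, None] + (covar @ B_hat[n_batches:]).T  # G x n
    Z = np.zeros_like(X)
    Z[nonzero] = (X[nonzero] - stand_mean[nonzero]) / np.sqrt(var_pooled[nonzero])[:, None]

    adjusted = X.copy()
    for i, b in enumerate(levels):
        cols = (batches == b).to_numpy()
        Zb = Z[np.ix_(nonzero, cols)]
        g_hat = Zb.mean(axis=1)
        d_hat2 = Zb.var(axis=1, ddof=1)
        d_hat2 = np.maximum(d_hat2, 1e-12)
        if parametric:
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            a, bb = _aprior(d_hat2), _bprior(d_hat2)
            g_star, d_star = _it_sol(Zb, g_hat, d_hat2, g_bar, t2, a, bb)
        else:
            g_star, d_star = _np_posterior(Zb, g_hat, d_hat2)
        Zadj = (Zb - g_star[:, None]) / np.sqrt(d_star)[:, None]
        adjusted[np.ix_(nonzero, cols)] = (
            Zadj * np.sqrt(var_pooled[nonzero])[:, None] + stand_mean[np.ix_(nonzero, cols)]
        )

    out = m.copy()
    out.values = pd.DataFrame(adjusted, index=m.values.index, columns=m.values.columns)
    return out


def minmax_normalize(
    m: ExpressionMatrix, ranges: NormalizationRanges | None = None
) -> tuple[ExpressionMatrix, NormalizationRanges]:
    """Per-gene x' = (x - min) / (max - min).

    With ``ranges`` supplied (validation data), the training ranges are applied
    and values are clipped to [0, 1]. Constant genes map to 0.5.
    """
    if m.scale != "log2":
        raise DataError("minmax_normalize expects log2-scale data")
    X = m.values.to_numpy(dtype=float)
    if ranges is None:
        mins = X.min(axis=1)
        maxs = X.max(axis=1)
        ranges = NormalizationRanges(
            min=pd.Series(mins, index=m.values.index), max=pd.Series(maxs, index=m.values.index)
        )
        clip = False
    else:
        missing = [g for g in m.values.index if g not in ranges.min.index]
        if missing:
            raise DataError(f"ranges missing genes: {missing[:5]}")
        mins = ranges.min.reindex(m.values.index).to_numpy()
        maxs = ranges.max.reindex(m.values.index).to_numpy()
        clip = True

    span = maxs - mins
    degenerate = span <= 0
    safe_span = np.where(degenerate, 1.0, span)
    norm = (X - mins[:, None]) / safe_span[:, None]
    norm[degenerate] = 0.5
    if clip:
        norm = np.clip(norm, 0.0, 1.0)

    out = m.copy()
    out.values = pd.DataFrame(norm, index=m.values.index, columns=m.values.columns)
    return out, ranges
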