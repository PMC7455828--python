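"""Synthetic two-class, multi-batch expression data with planted DE genes.

The generator emulates the inputs of the diagnostic pipeline so that every
downstream stage (batch adjustment, moderated-t screening, enrichment,
random-forest selection, network scoring, ROC validation) is testable without
any external download.

Model
-----
Gene baselines mu_g ~ Normal(7, 1.5^2) on the log2 scale — a typical log2
microarray intensity range, which makes a bottom-quantile expression filter
meaningful. Gene variances follow a scaled-inverse-chi-square hierarchy
sigma_g^2 ~ d0 * s0^2 / chi2(d0), the same hierarchical form assumed by the
moderated-t prior, so prior recovery is testable. Planted DE genes are drawn
from the expressed part of the spectrum (baseline above the
``de_baseline_quantile`` of baselines, default the median): differential
signal detectable on arrays arises in expressed genes, and planting it in the
noise floor that a low-expression filter exists to discard would make the
ground truth incoherent. Planted genes shift case samples by
+/- ``effect_logfc`` (half up, half down). Each batch adds a
gene-wise Normal(0, batch_shift_sd^2) offset. In ``rnaseq`` mode the log2
signal parameterizes a negative-binomial mean and raw counts are emitted;
the log2(CPM+1) transform is applied downstream, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CASE, CONTROL, ConfigurationError, ExpressionMatrix

BASELINE_MEAN = 7.0
BASELINE_SD = 1.5


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    ``var_prior_df`` / ``var_prior_scale`` are the (d0, s0^2) of the
    scaled-inverse-chi-square gene-variance hierarchy; the defaults (10, 0.04)
    give residual sds concentrated around 0.2 log2 units, typical of
    good-quality arrays. ``nb_dispersion`` is the negative-binomial dispersion
    alpha (variance = mu + alpha * mu^2), used in ``rnaseq`` mode only.
    ``de_baseline_quantile`` restricts planted DE genes to baselines above
    that quantile (0 plants anywhere).
    """

    n_genes: int = 2000
    n_case: int = 20
    n_control: int = 20
    n_de: int = 50
    effect_logfc: float = 2.0
    n_batches: int = 1
    batch_shift_sd: float = 0.0
    mode: str = "microarray"
    var_prior_df: float = 10.0
    var_prior_scale: float = 0.04
    nb_dispersion: float = 0.1
    de_baseline_quantile: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("microarray", "rnaseq"):
            raise ConfigurationError(f"mode must be 'microarray' or 'rnaseq', got {self.mode!r}")
        for name in ("n_genes", "n_case", "n_control", "n_batches"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.n_de < 0 or self.n_de > self.n_genes:
            raise ConfigurationError("n_de must satisfy 0 <= n_de <= n_genes")
        if self.n_case + self.n_control < 4:
            raise ConfigurationError("need at least 4 samples in total")
        for name in ("effect_logfc", "batch_shift_sd", "var_prior_df", "var_prior_scale", "nb_dispersion"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v}")
        if self.effect_logfc <= 0:
            raise ConfigurationError("effect_logfc must be > 0")
        if self.batch_shift_sd < 0:
            raise ConfigurationError("batch_shift_sd must be >= 0")
        if self.var_prior_df <= 0 or self.var_prior_scale <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("var_prior_df, var_prior_scale, nb_dispersion must be > 0")
        if not 0.0 <= self.de_baseline_quantile < 1.0:
            raise ConfigurationError("de_baseline_quantile must lie in [0, 1)")


@dataclass
class SimResult:
    """A simulated matrix plus ground truth and a synthetic annotation.

    ``baselines``/``variances`` keep the gene population parameters so an
    independently seeded validation cohort can be drawn from the same study
    (same genes, same planted truth, new samples) via ``simulate_validation``.
    """

    matrix: ExpressionMatrix
    de_truth: dict[str, int]  # gene id -> +1 (up in case) / -1 (down in case)
    annotation: dict[str, list[str]] = field(default_factory=dict)
    baselines: np.ndarray | None = None
    variances: np.ndarray | None = None
    config: SimConfig | None = None


def _batch_assignment(n_case: int, n_control: int, n_batches: int) -> np.ndarray:
    """Round-robin within each class so batches stay balanced across classes."""
    labels = np.empty(n_case + n_control, dtype=object)
    for offset, n in ((0, n_case), (n_case, n_control)):
        for i in range(n):
            labels[offset + i] = f"batch{i % n_batches + 1}"
    return labels


def simulate_expression(
    cfg: SimConfig,
    de_truth: dict[str, int] | None = None,
    baselines: np.ndarray | None = None,
    variances: np.ndarray | None = None,
    sample_prefix: str = "S",
) -> SimResult:
    """Draw one study per the model above. Deterministic given ``cfg.seed``.

    ``de_truth``/``baselines``/``variances`` may be supplied to draw a new
    cohort from an existing study's gene population (see
    ``simulate_validation``); otherwise they are drawn fresh.
    """
    rng = np.random.default_rng(cfg.seed)
    g, nc, nk = cfg.n_genes, cfg.n_case, cfg.n_control
    n = nc + nk

    gene_ids = [f"G{i:05d}" for i in range(1, g + 1)]
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(1, n + 1)]
    classes = pd.Series([CASE] * nc + [CONTROL] * nk, index=sample_ids)
    batches = pd.Series(_batch_assignment(nc, nk, cfg.n_batches), index=sample_ids)

    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=g) if baselines is None else np.asarray(baselines, float)
    # scaled-inverse-chi-square: d0 * s0^2 / chi2_{d0}
    drawn_sigma2 = cfg.var_prior_df * cfg.var_prior_scale / rng.chisquare(cfg.var_prior_df, size=g)
    sigma2 = drawn_sigma2 if variances is None else np.asarray(variances, float)
    if len(mu) != g or len(sigma2) != g:
        raise ConfigurationError("baselines/variances length must equal n_genes")

    if de_truth is None:
        eligible = np.flatnonzero(mu >= np.quantile(mu, cfg.de_baseline_quantile))
        if len(eligible) < cfg.n_de:  # tiny universes: fall back to the whole gene set
            eligible = np.arange(g)
        de_idx = rng.choice(eligible, size=cfg.n_de, replace=False)
        signs = np.ones(cfg.n_de, dtype=int)
        signs[cfg.n_de // 2 :] = -1  # half up, half down
        de_truth = {gene_ids[i]: int(s) for i, s in zip(de_idx, signs)}
    else:
        stray = set(de_truth) - set(gene_ids)
        if stray:
            raise ConfigurationError(f"de_truth genes outside universe: {sorted(stray)[:5]}")
        de_idx = np.array([gene_ids.index(gid) for gid in de_truth], dtype=int)
        signs = np.array([de_truth[gid] for gid in de_truth], dtype=int)

    effect = np.zeros(g)
    effect[de_idx] = signs * cfg.effect_logfc

    signal = np.tile(mu[:, None], (1, n))
    signal[:, :nc] += effect[:, None]

    batch_levels = sorted(batches.unique())
    for b in batch_levels:
        cols = (batches == b).to_numpy()
        shift = rng.normal(0.0, cfg.batch_shift_sd, size=g) if cfg.batch_shift_sd > 0 else np.zeros(g)
        signal[:, cols] += shift[:, None]

    if cfg.mode == "microarray":
        values = signal + rng.normal(0.0, np.sqrt(sigma2)[:, None], size=(g, n))
        scale = "log2"
    else:
        mean = np.maximum(2.0**signal - 1.0, 1e-8)  # inverse of log2(x+1)
        lam = rng.gamma(shape=1.0 / cfg.nb_dispersion, scale=mean * cfg.nb_dispersion)
        values = rng.poisson(lam).astype(float)
        scale = "counts"

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        classes=classes,
        batches=batches,
        scale=scale,
    )
    annotation = simulate_annotation(
        gene_ids,
        n_terms=20,
        enriched_term_fraction_of_de=0.6 if cfg.n_de > 0 else 0.0,
        de_genes=sorted(de_truth),
        n_enriched_terms=2 if cfg.n_de > 0 else 0,
        seed=cfg.seed + 1,
    )
    return SimResult(
        matrix=matrix,
        de_truth=de_truth,
        annotation=annotation,
        baselines=mu,
        variances=sigma2,
        config=cfg,
    )


def simulate_validation(
    train: SimResult,
    seed: int,
    n_case: int | None = None,
    n_control: int | None = None,
    mode: str | None = None,
) -> SimResult:
    """Draw an independent validation cohort from the same study as ``train``:
    identical genes, baselines, variances, and planted truth, but new samples
    from a fresh random stream."""
    if train.config is None or train.baselines is None:
        raise ConfigurationError("train result lacks the population parameters needed")
    cfg = SimConfig(**{**train.config.__dict__,
                       "seed": seed,
                       "n_case": n_case or train.config.n_case,
                       "n_control": n_control or train.config.n_control,
                       "mode": mode or train.config.mode})
    return simulate_expression(
        cfg,
        de_truth=train.de_truth,
        baselines=train.baselines,
        variances=train.variances,
        sample_prefix="V",
    )


def simulate_annotation(
    genes: list[str],
    n_terms: int,
    enriched_term_fraction_of_de: float = 0.0,
    de_genes: list[str] | None = None,
    n_enriched_terms: int = 0,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 200,
) -> dict[str, list[str]]:
    """Random gene -> term annotation, GMT-writable.

    Each term holds ``min_size``..``max_size`` genes drawn uniformly from the
    universe. The first ``n_enriched_terms`` terms instead draw
    ``enriched_term_fraction_of_de`` of their members from ``de_genes``,
    planting true enrichment signal.
    """
    if not genes:
        raise ConfigurationError("gene list is empty")
    if n_terms < 1:
        raise ConfigurationError("n_terms must be >= 1")
    if not 0.0 <= enriched_term_fraction_of_de <= 1.0:
        raise ConfigurationError("enriched_term_fraction_of_de must lie in [0, 1]")
    if n_enriched_terms > 0 and enriched_term_fraction_of_de > 0 and not de_genes:
        raise ConfigurationError("enriched terms requested but de_genes is empty")

    rng = np.random.default_rng(seed)
    genes = list(genes)
    de_genes = list(de_genes or [])
    non_de = [gid for gid in genes if gid not in set(de_genes)]
    max_size = min(max_size, len(genes))
    min_size = min(min_size, max_size)

    annotation: dict[str, list[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(min_size, max_size + 1))
        term_id = f"TERM{t + 1:03d}"
        if t < n_enriched_terms and enriched_term_fraction_of_de > 0 and de_genes:
            n_from_de = min(int(round(size * enriched_term_fraction_of_de)), len(de_genes))
            members = list(rng.choice(de_genes, size=n_from_de, replace=False))
            n_rest = min(size - n_from_de, len(non_de))
            members += list(rng.choice(non_de, size=n_rest, replace=False))
        else:
            members = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
        annotation[term_id] = sorted(members)
    return annotation
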