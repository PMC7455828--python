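"""Feed-forward network training and the derived linear diagnostic score.

A single-hidden-layer network (default d inputs, 3 hidden units, 2 output
units one-hot coding control/case) with logistic activations throughout is
trained full-batch on min-max-normalized expression by resilient
backpropagation (iRprop-: per-weight adaptive step sizes driven only by
gradient signs) against a sum-of-squared-error loss. Training keeps the
best-so-far weights, so the recorded error trace is non-increasing and the
returned model is never worse than its initialization.

The per-gene weight is the network's linearized class-discriminative
contribution

    w_g = sum_h W1[g, h] * (W2[h, case] - W2[h, control]),

which is exact when activations are linear; together with the training
min/max ranges it defines the per-sample linear score

    score(x) = sum_g x_norm[g] * w_g.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CASE, ConfigurationError, DataError, ExpressionMatrix, NormalizationRanges
from .preprocess import minmax_normalize

GRAD_TOL = 0.01
MAX_EPOCHS = 100_000
_ETA_PLUS, _ETA_MINUS = 1.2, 0.5
_STEP0, _STEP_MIN, _STEP_MAX = 0.1, 1e-6, 50.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class AnnModel:
    """Trained network weights plus training provenance.

    Output unit 0 codes control ("normal"), unit 1 codes case.
    """

    W1: np.ndarray  # n_genes x n_hidden
    b1: np.ndarray  # n_hidden
    W2: np.ndarray  # n_hidden x 2
    b2: np.ndarray  # 2
    activation: str = "logistic"
    training_error_trace: list[float] = field(default_factory=list)
    seed: int = 0
    n_epochs: int = 0
    converged: bool = False

    @property
    def trained(self) -> bool:
        return self.n_epochs > 0


@dataclass
class ScoreModel:
    """Everything needed to score a new sample: gene order, weights, and the
    training min/max used for normalization."""

    gene_ids: list[str]
    weights: np.ndarray
    ranges: NormalizationRanges
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.gene_ids):
            raise ConfigurationError("one weight per gene required")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "gene_ids": list(self.gene_ids),
            "weights": [float(w) for w in self.weights],
            "ranges": self.ranges.to_dict(),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScoreModel":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        d = json.loads(text)
        return cls(
            gene_ids=d["gene_ids"],
            weights=np.array(d["weights"], dtype=float),
            ranges=NormalizationRanges.from_dict(d["ranges"]),
            provenance=d.get("provenance", {}),
        )


def _forward(X, W1, b1, W2, b2):
    H = _sigmoid(X @ W1 + b1)
    O = _sigmoid(H @ W2 + b2)
    return H, O


def _gradients(X, Y, W1, b1, W2, b2):
    H, O = _forward(X, W1, b1, W2, b2)
    err = O - Y
    loss = 0.5 * float((err**2).sum())
    dO = err * O * (1.0 - O)
    gW2 = H.T @ dO
    gb2 = dO.sum(axis=0)
    dH = (dO @ W2.T) * H * (1.0 - H)
    gW1 = X.T @ dH
    gb1 = dH.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def train_ann(X_norm, y, n_hidden: int = 3, seed: int = 0, grad_tol: float = GRAD_TOL,
              max_epochs: int = MAX_EPOCHS) -> AnnModel:
    """Train the d-``n_hidden``-2 network on min-max-normalized expression.

    ``X_norm``: samples x genes, values in [0, 1]; ``y``: per-sample
    case/control labels. Deterministic given ``seed``.
    """
    X = pd.DataFrame(X_norm).to_numpy(dtype=float)
    if X.min() < -1e-9 or X.max() > 1.0 + 1e-9:
        raise DataError("train_ann requires min-max-normalized input in [0, 1]")
    y = pd.Series(np.asarray(y))
    is_case = (y == CASE).to_numpy() if y.dtype == object else y.to_numpy().astype(bool)
    if is_case.all() or not is_case.any():
        raise DataError("both classes must be present")
    Y = np.zeros((len(y), 2))
    Y[~is_case, 0] = 1.0  # control / "normal"
    Y[is_case, 1] = 1.0  # case

    rng = np.random.default_rng(seed)
    d = X.shape[1]
    params = [
        rng.normal(0, 0.5, size=(d, n_hidden)),
        rng.normal(0, 0.5, size=n_hidden),
        rng.normal(0, 0.5, size=(n_hidden, 2)),
        rng.normal(0, 0.5, size=2),
    ]
    steps = [np.full_like(p, _STEP0) for p in params]
    prev_grads = [np.zeros_like(p) for p in params]

    best_loss = np.inf
    best_params = [p.copy() for p in params]
    trace: list[float] = []
    converged = False
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        loss, grads = _gradients(X, Y, *params)
        if loss < best_loss:
            best_loss = loss
            best_params = [p.copy() for p in params]
        if epoch == 1 or epoch % 100 == 0:
            trace.append(best_loss)
        if max(np.max(np.abs(g)) for g in grads) < grad_tol:
            converged = True
            break
        for p, g, s, pg in zip(params, grads, steps, prev_grads):
            sign_prod = g * pg
            s[sign_prod > 0] = np.minimum(s[sign_prod > 0] * _ETA_PLUS, _STEP_MAX)
            s[sign_prod < 0] = np.maximum(s[sign_prod < 0] * _ETA_MINUS, _STEP_MIN)
            g[sign_prod < 0] = 0.0  # iRprop-: forget the flipped gradient
            p -= np.sign(g) * s
            pg[:] = g
    trace.append(best_loss)

    W1, b1, W2, b2 = best_params
    return AnnModel(
        W1=W1, b1=b1, W2=W2, b2=b2,
        training_error_trace=trace, seed=seed, n_epochs=epoch, converged=converged,
    )


def predict_classes(model: AnnModel, X_norm) -> np.ndarray:
    """Hard class predictions (argmax over the two output units): array of
    ``"control"``/``"case"``."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    X = pd.DataFrame(X_norm).to_numpy(dtype=float)
    _, O = _forward(X, model.W1, model.b1, model.W2, model.b2)
    return np.where(O[:, 1] > O[:, 0], CASE, "control")


def extract_gene_weights(model: AnnModel) -> np.ndarray:
    """Linearized per-gene contribution toward the case output unit."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    return model.W1 @ (model.W2[:, 1] - model.W2[:, 0])


def neural_score(x_norm, sm: ScoreModel) -> float:
    """Score one normalized sample: sum over genes of expression x weight."""
    x = np.asarray(x_norm, dtype=float)
    if x.shape != (len(sm.gene_ids),):
        raise DataError(f"expected {len(sm.gene_ids)} normalized values, got shape {x.shape}")
    if x.min() < -1e-9 or x.max() > 1.0 + 1e-9:
        raise DataError("neural_score requires min-max-normalized input in [0, 1]")
    return float(x @ sm.weights)


def score_matrix(m: ExpressionMatrix, sm: ScoreModel, renormalize: bool = False) -> pd.Series:
    """Score every sample of a log2-scale matrix with a trained ScoreModel.

    Training min/max ranges are applied (values clipped to [0, 1]) unless
    ``renormalize`` recomputes ranges on the given data.
    """
    sub = m.subset_genes(sm.gene_ids)
    norm, _ = minmax_normalize(sub, None if renormalize else sm.ranges)
    scores = norm.values.to_numpy().T @ sm.weights
    return pd.Series(scores, index=m.sample_ids, name="neural_score")


def build_score_model(
    training: ExpressionMatrix,
    selected_genes: list[str],
    seed: int = 0,
    n_hidden: int = 3,
    max_genes: int | None = None,
) -> ScoreModel:
    """Subset to the selected genes, min-max normalize (storing the ranges),
    train the network, and extract per-gene weights.

    ``max_genes`` optionally truncates the (ordered) selection before
    training, e.g. to match a fixed input-layer size.
    """
    genes = list(selected_genes)
    if max_genes is not None:
        genes = genes[:max_genes]
    if not genes:
        raise DataError("no genes supplied to build_score_model")
    sub = training.subset_genes(genes)
    norm, ranges = minmax_normalize(sub)
    model = train_ann(norm.values.to_numpy().T, training.classes, n_hidden=n_hidden, seed=seed)
    weights = extract_gene_weights(model)
    return ScoreModel(
        gene_ids=genes,
        weights=weights,
        ranges=ranges,
        provenance={
            "seed": seed,
            "n_hidden": n_hidden,
            "n_epochs": model.n_epochs,
            "converged": model.converged,
            "topology": f"{len(genes)}-{n_hidden}-2",
            "n_train_samples": training.n_samples,
            "W1": model.W1.tolist(),
            "W2": model.W2.tolist(),
        },
    )
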