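"""ROC/AUC evaluation of the neural score against comparator gene-set scores.

Thresholds sweep the unique score values (plus infinities); a sample is
called positive (case) when its score >= threshold. AUC is the trapezoidal
area under (1 - specificity, sensitivity); the optimal threshold maximizes
Youden's J = sensitivity + specificity - 1 (ties resolved toward the lower
threshold). Comparator gene sets are scored as the unweighted sum of min-max
normalized log2 expression over their member genes — the all-weights-one
analogue of the neural score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CASE, DataError, ExpressionMatrix
from .preprocess import minmax_normalize
from .ann import ScoreModel, score_matrix


@dataclass
class ComparatorGeneSet:
    name: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise DataError(f"comparator {self.name!r} has no genes")


# Literature marker panels used as comparators: an endometrial-cell panel of
# insulin-pathway genes and a granulosa-cell steroidogenesis panel.
EC_PCOS = ComparatorGeneSet("EC-PCOS", ["IGF1", "PTEN", "IGFBP1"])
GC_PCOS = ComparatorGeneSet("GC-PCOS", ["HSD3B2", "STAR", "INHBA", "CYP19A1"])


@dataclass
class RocResult:
    model_name: str
    points: pd.DataFrame  # columns: threshold, sensitivity, specificity
    auc: float
    optimal_threshold: float
    sens_at_opt: float
    spec_at_opt: float

    def summary(self) -> dict:
        return {
            "model": self.model_name,
            "auc": self.auc,
            "optimal_threshold": self.optimal_threshold,
            "sensitivity_at_optimum": self.sens_at_opt,
            "specificity_at_optimum": self.spec_at_opt,
        }


def comparator_score(m: ExpressionMatrix, gs: ComparatorGeneSet) -> pd.Series:
    """Unweighted sum of min-max-normalized expression over the set's genes
    present in the matrix; missing genes are dropped with a warning."""
    present = [g for g in gs.gene_ids if g in m.values.index]
    missing = [g for g in gs.gene_ids if g not in m.values.index]
    if missing:
        warnings.warn(f"comparator {gs.name!r}: genes absent from matrix: {missing}")
    if not present:
        raise DataError(f"comparator {gs.name!r}: no genes present in matrix")
    norm, _ = minmax_normalize(m.subset_genes(present))
    return pd.Series(norm.values.to_numpy().sum(axis=0), index=m.sample_ids, name=gs.name)


def roc_auc(scores, labels, model_name: str = "model") -> RocResult:
    """ROC sweep, trapezoidal AUC, and the Youden-optimal operating point.

    Positive class is ``"case"`` (or truthy labels); positive call is
    score >= threshold.
    """
    s = np.asarray(pd.Series(scores), dtype=float)
    lab = pd.Series(np.asarray(labels))
    pos = (lab == CASE).to_numpy() if lab.dtype == object else lab.to_numpy().astype(bool)
    if len(s) < 2:
        raise DataError("need at least 2 samples")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes must be present")

    thresholds = np.concatenate(([-np.inf], np.unique(s), [np.inf]))
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        call = s >= t
        sens[i] = (call & pos).sum() / n_pos
        spec[i] = (~call & ~pos).sum() / n_neg

    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # vertical ROC segments contribute their top point
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    finite = np.isfinite(thresholds)
    j_max = j[finite].max()
    candidates = np.flatnonzero(finite & (j >= j_max - 1e-12))
    opt = candidates[np.argmin(thresholds[candidates])]

    points = pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec})
    return RocResult(
        model_name=model_name,
        points=points,
        auc=auc,
        optimal_threshold=float(thresholds[opt]),
        sens_at_opt=float(sens[opt]),
        spec_at_opt=float(spec[opt]),
    )


def compare_models(
    validation: ExpressionMatrix,
    sm: ScoreModel,
    comparators: list[ComparatorGeneSet] = (),
    neural_name: str = "neuralScore",
) -> list[RocResult]:
    """One RocResult per model on the validation matrix.

    A comparator whose genes are all absent is reported as a warning and
    skipped; the remaining models are still evaluated.
    """
    results = [roc_auc(score_matrix(validation, sm), validation.classes, model_name=neural_name)]
    for gs in comparators:
        try:
            scores = comparator_score(validation, gs)
        except DataError as exc:
            warnings.warn(f"comparator {gs.name!r} failed: {exc}")
            continue
        results.append(roc_auc(scores, validation.classes, model_name=gs.name))
    return results
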