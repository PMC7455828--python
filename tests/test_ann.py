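import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neuralpcos import (
    AnnModel,
    ScoreModel,
    SimConfig,
    build_score_model,
    extract_gene_weights,
    neural_score,
    simulate_expression,
    train_ann,
)
from neuralpcos.ann import predict_classes, score_matrix
from neuralpcos.datatypes import DataError, NormalizationRanges


def separable_xy(seed=0, n=20, margin=0.5):
    rng = np.random.default_rng(seed)
    y = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
    X = rng.uniform(0, 0.5 - margin / 2, size=(n, 2))
    X[y == "case", 0] += 0.5 + margin / 2
    return X, y


def test_separable_toy_reaches_full_training_accuracy():
    X, y = separable_xy()
    model = train_ann(X, y, seed=1)
    assert (predict_classes(model, X) == y).all()


def test_training_deterministic():
    X, y = separable_xy(seed=3)
    m1 = train_ann(X, y, seed=7)
    m2 = train_ann(X, y, seed=7)
    assert np.array_equal(m1.W1, m2.W1)
    assert np.array_equal(m1.W2, m2.W2)


def test_error_trace_non_increasing_and_below_init():
    for seed in range(5):
        X, y = separable_xy(seed=seed, margin=0.2)
        model = train_ann(X, y, seed=seed, max_epochs=2000)
        trace = np.array(model.training_error_trace)
        assert (np.diff(trace) <= 1e-12).all()
        assert trace[-1] <= trace[0]


def test_hand_set_weight_extraction():
    # 2 inputs, 2 hidden, 2 outputs with hand-set weights
    W1 = np.array([[1.0, 0.0], [0.0, 2.0]])
    W2 = np.array([[1.0, 0.5], [-1.0, 0.0]])  # rows: hidden; cols: (control, case)
    model = AnnModel(W1=W1, b1=np.zeros(2), W2=W2, b2=np.zeros(2), n_epochs=1)
    # w_g = sum_h W1[g,h] * (W2[h,case] - W2[h,control])
    expected = np.array([1.0 * (0.5 - 1.0), 2.0 * (0.0 - (-1.0))])
    assert np.allclose(extract_gene_weights(model), expected)


def test_symmetric_output_weights_give_zero_gene_weights():
    W2 = np.array([[0.3, 0.3], [-0.7, -0.7], [1.1, 1.1]])
    model = AnnModel(W1=np.random.default_rng(0).normal(size=(4, 3)),
                     b1=np.zeros(3), W2=W2, b2=np.zeros(2), n_epochs=1)
    assert np.allclose(extract_gene_weights(model), 0.0)


def test_extraction_invariant_to_hidden_unit_permutation():
    rng = np.random.default_rng(5)
    W1, W2 = rng.normal(size=(6, 3)), rng.normal(size=(3, 2))
    m = AnnModel(W1=W1, b1=np.zeros(3), W2=W2, b2=np.zeros(2), n_epochs=1)
    perm = [2, 0, 1]
    mp = AnnModel(W1=W1[:, perm], b1=np.zeros(3), W2=W2[perm], b2=np.zeros(2), n_epochs=1)
    assert np.allclose(extract_gene_weights(m), extract_gene_weights(mp))


def test_untrained_model_rejected():
    m = AnnModel(W1=np.zeros((2, 3)), b1=np.zeros(3), W2=np.zeros((3, 2)), b2=np.zeros(2))
    with pytest.raises(RuntimeError):
        extract_gene_weights(m)


def _score_model(weights, genes=None):
    genes = genes or [f"g{i}" for i in range(len(weights))]
    idx = pd.Index(genes)
    return ScoreModel(
        gene_ids=genes,
        weights=np.asarray(weights, float),
        ranges=NormalizationRanges(min=pd.Series(0.0, index=idx), max=pd.Series(1.0, index=idx)),
    )


class TestNeuralScore:
    def test_hand_dot_product(self):
        sm = _score_model([1.0, -2.0, 0.5])
        assert neural_score(np.array([0.5, 0.25, 1.0]), sm) == pytest.approx(0.5)

    def test_zero_vector_scores_zero(self):
        sm = _score_model([1.0, -2.0, 0.5])
        assert neural_score(np.zeros(3), sm) == 0.0

    def test_length_mismatch_rejected(self):
        sm = _score_model([1.0, -2.0])
        with pytest.raises(DataError):
            neural_score(np.zeros(3), sm)

    def test_unnormalized_input_rejected(self):
        sm = _score_model([1.0, -2.0])
        with pytest.raises(DataError):
            neural_score(np.array([0.5, 1.5]), sm)

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=3, max_size=3),
        st.lists(st.floats(min_value=0, max_value=1), min_size=3, max_size=3),
        st.floats(min_value=0, max_value=1),
    )
    def test_exact_linearity(self, x, y, a):
        sm = _score_model([1.0, -2.0, 0.5])
        x, y = np.array(x), np.array(y)
        mix = neural_score(a * x + (1 - a) * y, sm)
        assert mix == pytest.approx(a * neural_score(x, sm) + (1 - a) * neural_score(y, sm), abs=1e-9)

    def test_doubling_weights_doubles_scores(self):
        from neuralpcos import roc_auc

        rng = np.random.default_rng(2)
        x = rng.uniform(size=(20, 3))
        labels = ["case"] * 10 + ["control"] * 10
        sm1 = _score_model([1.0, -2.0, 0.5])
        sm2 = _score_model([2.0, -4.0, 1.0])
        s1 = np.array([neural_score(v, sm1) for v in x])
        s2 = np.array([neural_score(v, sm2) for v in x])
        assert np.allclose(s2, 2 * s1)
        assert roc_auc(s1, labels).auc == roc_auc(s2, labels).auc


def test_nonnormalized_training_input_rejected():
    X = np.array([[0.1, 1.8], [0.2, 0.3], [0.5, 0.2], [0.9, 0.4]])
    with pytest.raises(DataError):
        train_ann(X, ["case", "case", "control", "control"], seed=0)


def test_score_model_json_roundtrip_bit_identical(small_sim):
    sm = build_score_model(small_sim.matrix, list(small_sim.de_truth)[:5], seed=2)
    text = sm.to_json()
    back = ScoreModel.from_json(text)
    assert back.to_json() == text
    assert back.gene_ids == sm.gene_ids
    assert np.array_equal(back.weights, sm.weights)


def test_absent_gene_rejected(small_sim):
    with pytest.raises(DataError):
        build_score_model(small_sim.matrix, ["NOPE"], seed=0)


def test_max_genes_truncates_topology(small_sim):
    genes = list(small_sim.de_truth)[:6]
    sm = build_score_model(small_sim.matrix, genes, seed=2, max_genes=5)
    assert sm.gene_ids == genes[:5]
    assert sm.provenance["topology"] == "5-3-2"


def test_weight_signs_track_planted_directions():
    agree = tot = 0
    for seed in (1, 2, 3):
        sim = simulate_expression(
            SimConfig(n_genes=300, n_de=12, effect_logfc=2.0, n_case=13, n_control=13, seed=seed)
        )
        genes = sorted(sim.de_truth)
        sm = build_score_model(sim.matrix, genes, seed=seed)
        for g, w in zip(sm.gene_ids, sm.weights):
            tot += 1
            agree += int(np.sign(w) == sim.de_truth[g])
    assert agree / tot >= 0.8


def test_score_matrix_uses_training_ranges(small_sim):
    genes = list(small_sim.de_truth)[:4]
    sm = build_score_model(small_sim.matrix, genes, seed=1)
    scores = score_matrix(small_sim.matrix, sm)
    assert list(scores.index) == small_sim.matrix.sample_ids
    # manual recomputation for the first sample
    sub = small_sim.matrix.subset_genes(genes)
    from neuralpcos import minmax_normalize

    norm, _ = minmax_normalize(sub, sm.ranges)
    manual = float(norm.values.iloc[:, 0] @ sm.weights)
    assert scores.iloc[0] == pytest.approx(manual)
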