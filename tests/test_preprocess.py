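import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuralpcos import (
    SimConfig,
    combat_adjust,
    merge_datasets,
    minmax_normalize,
    simulate_expression,
    to_log2,
)
from neuralpcos.datatypes import DataError, NormalizationRanges

from conftest import make_matrix


class TestToLog2:
    def test_cpm_hand_computation(self):
        # one sample totalling 1e6 counts, one gene with 1024 of them
        counts = np.zeros((2, 1))
        counts[0, 0] = 1024
        counts[1, 0] = 1e6 - 1024
        m = make_matrix(counts, ["case"], scale="counts")
        out = to_log2(m)
        assert out.scale == "log2"
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(1025), abs=1e-12)

    def test_zero_count_maps_to_zero(self):
        m = make_matrix([[0.0, 5.0], [10.0, 5.0]], ["case", "control"], scale="counts")
        assert to_log2(m).values.iloc[0, 0] == 0.0

    def test_idempotent_on_log2(self, small_sim):
        m = small_sim.matrix
        assert to_log2(m) is m

    def test_negative_counts_rejected(self):
        m = make_matrix([[-1.0, 2.0], [3.0, 4.0]], ["case", "control"], scale="counts")
        with pytest.raises(DataError):
            to_log2(m)


class TestMerge:
    def _mat(self, genes, samples, classes, seed=0):
        rng = np.random.default_rng(seed)
        from neuralpcos.datatypes import ExpressionMatrix

        return ExpressionMatrix(
            values=pd.DataFrame(rng.normal(7, 1, (len(genes), len(samples))), index=genes, columns=samples),
            classes=pd.Series(classes, index=samples),
            batches=pd.Series(["x"] * len(samples), index=samples),
        )

    def test_gene_intersection(self):
        a = self._mat([f"g{i}" for i in range(120)], ["a1", "a2"], ["case", "control"])
        b = self._mat([f"g{i}" for i in range(20, 140)], ["b1", "b2"], ["case", "control"])
        merged = merge_datasets([a, b])
        assert merged.n_genes == 100
        assert merged.n_samples == 4

    def test_self_merge_doubles_samples(self):
        genes = [f"g{i}" for i in range(30)]
        a = self._mat(genes, ["a1", "a2"], ["case", "control"])
        b = self._mat(genes, ["b1", "b2"], ["case", "control"])
        b.values.loc[:] = a.values.to_numpy()
        merged = merge_datasets([a, b])
        assert merged.n_samples == 4
        assert merged.gene_ids == genes

    def test_three_sources_three_batches(self):
        genes = [f"g{i}" for i in range(25)]
        ms = [
            self._mat(genes, [f"d{j}s{i}" for i in range(3 + j)], (["case", "control"] * 4)[: 3 + j], seed=j)
            for j in range(3)
        ]
        merged = merge_datasets(ms)
        counts = merged.batches.value_counts()
        assert sorted(counts.index) == ["ds1", "ds2", "ds3"]
        assert counts.tolist() == [5, 4, 3] or sorted(counts.tolist()) == [3, 4, 5]

    def test_order_insensitive_up_to_columns(self):
        genes = [f"g{i}" for i in range(25)]
        a = self._mat(genes, ["a1", "a2"], ["case", "control"], seed=1)
        b = self._mat(genes, ["b1", "b2"], ["case", "control"], seed=2)
        m1 = merge_datasets([a, b])
        m2 = merge_datasets([b, a])
        assert m1.values[sorted(m1.sample_ids)].equals(m2.values[sorted(m2.sample_ids)])

    def test_empty_intersection_rejected(self):
        a = self._mat(["g1", "g2"], ["a1", "a2"], ["case", "control"])
        b = self._mat(["h1", "h2"], ["b1", "b2"], ["case", "control"])
        with pytest.raises(DataError):
            merge_datasets([a, b])


def _median_batch_f(m):
    X = m.values.to_numpy()
    groups = [X[:, (m.batches == b).to_numpy()].T for b in sorted(m.batches.unique())]
    return float(np.median(stats.f_oneway(*groups, axis=0).statistic))


class TestCombat:
    def test_no_batch_effect_is_near_identity(self):
        # with identical batch distributions the adjustment should only move
        # values at the scale of the noise in the per-batch estimates, which
        # at 20 samples/batch and residual sd ~0.2 is well under 0.15
        sim = simulate_expression(
            SimConfig(n_genes=400, n_de=0, n_case=20, n_control=20, n_batches=2, batch_shift_sd=0.0, seed=11)
        )
        adj = combat_adjust(sim.matrix)
        dev = np.abs(adj.values.to_numpy() - sim.matrix.values.to_numpy())
        assert dev.max() < 0.15
        assert np.median(dev) < 0.02

    def test_removes_planted_batch_shift(self):
        sim = simulate_expression(
            SimConfig(n_genes=400, n_de=20, effect_logfc=2.0, n_batches=2, batch_shift_sd=2.0, seed=12)
        )
        before = _median_batch_f(sim.matrix)
        adj = combat_adjust(sim.matrix)
        after = _median_batch_f(adj)
        assert before > 50
        assert after < 2

    def test_class_effect_protected(self):
        sim = simulate_expression(
            SimConfig(n_genes=400, n_de=20, effect_logfc=2.0, n_batches=2, batch_shift_sd=2.0, seed=13)
        )
        adj = combat_adjust(sim.matrix)
        case = adj.case_mask()
        X = adj.values
        lfc = X.loc[:, case].mean(axis=1) - X.loc[:, ~case].mean(axis=1)
        signed = np.array([lfc[g] * s for g, s in sim.de_truth.items()])
        assert abs(signed.mean() - 2.0) < 0.2

    def test_matches_scanpy_parametric(self):
        sim = simulate_expression(
            SimConfig(n_genes=300, n_de=10, effect_logfc=1.5, n_batches=2, batch_shift_sd=1.5,
                      n_case=12, n_control=12, seed=42)
        )
        m = sim.matrix
        mine = combat_adjust(m, parametric=True).values.to_numpy()

        import anndata
        import scanpy as sc

        ad = anndata.AnnData(
            X=m.values.to_numpy().T.copy(),
            obs=pd.DataFrame(
                {"batch": m.batches.to_numpy(), "cls": m.case_mask().astype(float)},
                index=m.sample_ids,
            ),
        )
        ad.obs["batch"] = ad.obs["batch"].astype("category")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.combat(ad, key="batch", covariates=["cls"])
        assert np.abs(mine - ad.X.T).max() < 1e-3

    def test_nonparametric_also_removes_shift(self):
        sim = simulate_expression(
            SimConfig(n_genes=150, n_de=5, effect_logfc=1.5, n_batches=2, batch_shift_sd=2.0,
                      n_case=8, n_control=8, seed=21)
        )
        adj = combat_adjust(sim.matrix, parametric=False)
        assert _median_batch_f(adj) < 2

    def test_preserves_dimensions_and_gene_order(self, small_sim):
        sim = simulate_expression(
            SimConfig(n_genes=100, n_de=0, n_batches=2, batch_shift_sd=1.0, seed=1)
        )
        adj = combat_adjust(sim.matrix)
        assert adj.gene_ids == sim.matrix.gene_ids
        assert adj.sample_ids == sim.matrix.sample_ids

    def test_single_sample_batch_rejected(self):
        m = make_matrix(
            np.random.default_rng(0).normal(size=(10, 5)),
            ["case", "case", "control", "control", "case"],
            batches=["b1", "b1", "b1", "b1", "b2"],
        )
        with pytest.raises(DataError):
            combat_adjust(m)

    def test_single_batch_rejected(self, small_sim):
        with pytest.raises(DataError):
            combat_adjust(small_sim.matrix)


class TestMinMax:
    def test_training_bounds_attained(self, small_sim):
        norm, ranges = minmax_normalize(small_sim.matrix)
        X = norm.values.to_numpy()
        assert X.min() >= 0 and X.max() <= 1
        assert np.allclose(X.min(axis=1), 0)
        assert np.allclose(X.max(axis=1), 1)

    def test_midpoint(self):
        m = make_matrix([[5.0, 7.0, 9.0]], ["case", "control", "case"])
        norm, _ = minmax_normalize(m)
        assert norm.values.iloc[0, 1] == pytest.approx(0.5)

    def test_validation_clipping(self):
        train = make_matrix([[5.0, 9.0]], ["case", "control"])
        _, ranges = minmax_normalize(train)
        val = make_matrix([[4.0, 10.0]], ["case", "control"])
        norm, _ = minmax_normalize(val, ranges)
        assert norm.values.iloc[0, 0] == 0.0
        assert norm.values.iloc[0, 1] == 1.0

    def test_constant_gene_maps_to_center(self):
        m = make_matrix([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]], ["case", "control", "case"])
        norm, _ = minmax_normalize(m)
        assert (norm.values.iloc[0] == 0.5).all()

    def test_idempotent(self, small_sim):
        once, _ = minmax_normalize(small_sim.matrix)
        twice, _ = minmax_normalize(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())

    def test_ranges_validate(self):
        with pytest.raises(Exception):
            NormalizationRanges(min=pd.Series([2.0], index=["g"]), max=pd.Series([1.0], index=["g"]))
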