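"""Coexpression module detection on planted block structure, TOM properties,
module-cluster association, and hub-gene ranking."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pathstrat import (
    ExpressionMatrix,
    detect_modules,
    hub_genes,
    module_cluster_association,
)
from pathstrat.coexpression import tom_similarity


def exact_blocks(n_blocks=2, block=12, n_samples=16, seed=0):
    """Blocks of perfectly correlated genes, independent across blocks."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_blocks, n_samples))
    rows, names, truth = [], [], []
    for b in range(n_blocks):
        for g in range(block):
            rows.append(base[b] * (1 + 0.1 * g) + g)  # same pattern, r = 1 within
            names.append(f"B{b}G{g:02d}")
            truth.append(b)
    return (
        ExpressionMatrix(values=pd.DataFrame(rows, index=names,
                                             columns=[f"s{i}" for i in range(n_samples)])),
        truth,
    )


def noisy_blocks(n_blocks=3, block=30, n_samples=20, rho=0.8, seed=7):
    rng = np.random.default_rng(seed)
    # orthogonalize the block factors so the planted modules are independent
    q, _ = np.linalg.qr(rng.normal(size=(n_samples, n_blocks)))
    factors = (q * np.sqrt(n_samples)).T
    rows, names, truth = [], [], []
    for b in range(n_blocks):
        for g in range(block):
            rows.append(np.sqrt(rho) * factors[b] + np.sqrt(1 - rho) * rng.normal(size=n_samples))
            names.append(f"B{b}G{g:02d}")
            truth.append(b)
    return (
        ExpressionMatrix(values=pd.DataFrame(rows, index=names,
                                             columns=[f"s{i}" for i in range(n_samples)])),
        truth,
    )


class TestTom:
    def test_tom_symmetric_unit_interval_unit_diagonal(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 15))
        a = np.abs(np.corrcoef(x)) ** 6
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12
        assert np.allclose(np.diag(tom), 1.0)

    def test_raising_power_weakly_decreases_mean_adjacency(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 10))
        corr = np.abs(np.corrcoef(x))
        means = [(corr**b).mean() for b in (1, 3, 6, 12)]
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestModuleDetection:
    def test_exact_blocks_recovered_with_unit_kme(self):
        matrix, truth = exact_blocks()
        mods = detect_modules(matrix, power=6, min_module_size=5)
        assert len(mods.module_ids()) == 2
        assert adjusted_rand_score(truth, mods.assignments.to_numpy()) == 1.0
        for mod in mods.module_ids():
            members = mods.genes_in(mod)
            np.testing.assert_allclose(mods.kme.loc[members, mod].to_numpy(), 1.0, atol=1e-9)

    def test_noisy_planted_modules_recovered(self):
        matrix, truth = noisy_blocks()
        mods = detect_modules(matrix, power=6, min_module_size=10)
        assert adjusted_rand_score(truth, mods.assignments.to_numpy()) >= 0.9

    def test_gene_order_permutation_gives_same_partition(self):
        matrix, truth = noisy_blocks(seed=9)
        perm_values = matrix.values.sample(frac=1, random_state=3)
        mods_a = detect_modules(matrix, power=6, min_module_size=10)
        mods_b = detect_modules(ExpressionMatrix(values=perm_values), power=6, min_module_size=10)
        joined = pd.concat([mods_a.assignments.rename("a"), mods_b.assignments.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_constant_rows_dropped(self):
        matrix, _ = exact_blocks()
        v = matrix.values.copy()
        v.loc["FLAT"] = 1.0
        mods = detect_modules(ExpressionMatrix(values=v), power=6, min_module_size=5)
        assert "FLAT" not in mods.assignments.index

    def test_eigengene_unit_norm_and_positive_with_mean(self):
        matrix, _ = noisy_blocks(seed=4)
        mods = detect_modules(matrix, power=6, min_module_size=10)
        for mod in mods.module_ids():
            eg = mods.eigengenes[mod].to_numpy()
            assert np.linalg.norm(eg) == pytest.approx(1.0)
            mean_expr = matrix.values.loc[mods.genes_in(mod)].mean(axis=0).to_numpy()
            assert np.corrcoef(eg, mean_expr)[0, 1] > 0


class TestModuleClusterAssociation:
    def test_module_planted_in_one_cluster_assigned_there(self):
        rng = np.random.default_rng(5)
        n_s = 20
        labels = pd.Series([1] * 10 + [2] * 10, index=[f"s{i}" for i in range(n_s)])
        pattern = np.array([2.0] * 10 + [0.0] * 10)
        rows = [pattern + rng.normal(scale=0.3, size=n_s) for _ in range(15)]
        rows += [rng.normal(size=n_s) for _ in range(15)]
        names = [f"M{i:02d}" for i in range(15)] + [f"R{i:02d}" for i in range(15)]
        m = ExpressionMatrix(values=pd.DataFrame(rows, index=names, columns=labels.index))
        mods = detect_modules(m, power=6, min_module_size=8)
        assoc = module_cluster_association(mods, labels)
        planted_mod = mods.assignments["M00"]
        assert planted_mod != 0
        assert assoc.loc[planted_mod, "cluster"] == 1
        assert assoc.loc[planted_mod, "r"] > 0.9

    def test_association_invariant_to_label_renaming(self):
        matrix, truth = noisy_blocks(seed=6)
        labels = pd.Series(
            np.where(np.arange(20) < 10, "alpha", "beta"), index=matrix.values.columns
        )
        mods = detect_modules(matrix, power=6, min_module_size=10)
        a = module_cluster_association(mods, labels)
        renamed = labels.map({"alpha": "X", "beta": "Y"})
        b = module_cluster_association(mods, renamed)
        np.testing.assert_allclose(a["r"].to_numpy(), b["r"].to_numpy())

    def test_single_cluster_rejected(self):
        matrix, _ = exact_blocks()
        mods = detect_modules(matrix, power=6, min_module_size=5)
        labels = pd.Series(1, index=matrix.values.columns)
        with pytest.raises(ValueError, match="two clusters"):
            module_cluster_association(mods, labels)


class TestHubGenes:
    def test_identical_genes_tie_break_by_symbol(self):
        matrix, _ = exact_blocks(n_blocks=1, block=15)
        mods = detect_modules(matrix, power=6, min_module_size=5)
        report = hub_genes(mods, top_k=5, kme_min=0.8)
        mod = mods.module_ids()[0]
        assert list(report.hubs[mod].index) == sorted(mods.genes_in(mod))[:5]

    def test_strongest_correlated_gene_ranks_first(self):
        rng = np.random.default_rng(8)
        n_s = 30
        factor = rng.normal(size=n_s)
        rows = {"HUB": factor + rng.normal(scale=0.2, size=n_s)}
        for i in range(12):
            rows[f"G{i:02d}"] = factor + rng.normal(scale=0.9, size=n_s)
        m = ExpressionMatrix(values=pd.DataFrame(rows, index=[f"s{i}" for i in range(n_s)]).T)
        mods = detect_modules(m, power=6, min_module_size=5)
        report = hub_genes(mods, top_k=3, kme_min=0.0)
        mod = mods.assignments["HUB"]
        assert report.hubs[mod].index[0] == "HUB"

    def test_unattainable_threshold_yields_empty_lists(self):
        matrix, _ = exact_blocks()
        mods = detect_modules(matrix, power=6, min_module_size=5)
        report = hub_genes(mods, kme_min=1.01)
        assert all(len(s) == 0 for s in report.hubs.values())
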