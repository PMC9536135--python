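"""PCA contributions, the signature naming convention, and overlap-based
signature synthesis from constructed fixtures."""

import numpy as np
import pandas as pd
import pytest

from pathstrat import (
    EnrichmentProfile,
    GeneSet,
    GeneSetCollection,
    pca_decompose,
    score_signature_matrix,
    synthesize_signature,
)
from pathstrat.signatures import GeneSignature


def profile_from(nes: pd.DataFrame) -> EnrichmentProfile:
    return EnrichmentProfile(nes=nes, es=nes, pvals=nes * 0 + 0.5, n_perm=100, seed=0)


class TestPCA:
    def test_two_perfectly_correlated_variables_split_contribution_evenly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        nes = pd.DataFrame({"A": x, "B": 2 * x + 1}, index=[f"s{i}" for i in range(30)])
        res = pca_decompose(profile_from(nes), n_components=1)
        np.testing.assert_allclose(res.contributions["PC1"], [50.0, 50.0], atol=1e-9)

    def test_contributions_sum_to_100_per_component(self):
        rng = np.random.default_rng(1)
        nes = pd.DataFrame(rng.normal(size=(25, 6)), columns=list("ABCDEF"))
        res = pca_decompose(profile_from(nes), n_components=3)
        np.testing.assert_allclose(res.contributions.sum(axis=0), 100.0, atol=1e-9)

    def test_loadings_match_eigendecomposition_of_correlation_matrix(self):
        rng = np.random.default_rng(2)
        nes = pd.DataFrame(rng.normal(size=(40, 3)) @ rng.normal(size=(3, 3)),
                           columns=["A", "B", "C"])
        res = pca_decompose(profile_from(nes), n_components=2)
        corr = np.corrcoef(nes.to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        for k in range(2):
            v = evecs[:, order[k]]
            got = res.loadings.iloc[:, k].to_numpy()
            # same axis up to sign
            assert min(np.abs(got - v).max(), np.abs(got + v).max()) < 1e-8

    def test_contributions_invariant_to_sample_and_variable_order(self):
        rng = np.random.default_rng(3)
        nes = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("ABCD"),
                           index=[f"s{i}" for i in range(20)])
        base = pca_decompose(profile_from(nes), n_components=2).contributions
        shuffled = nes.sample(frac=1, axis=0, random_state=1).sample(frac=1, axis=1, random_state=2)
        perm = pca_decompose(profile_from(shuffled), n_components=2).contributions
        pd.testing.assert_frame_equal(base.sort_index(), perm.sort_index(),
                                      atol=1e-9, rtol=0, check_like=True)

    def test_constant_variable_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        nes = pd.DataFrame(rng.normal(size=(15, 3)), columns=["A", "B", "C"])
        nes["C"] = 1.0
        res = pca_decompose(profile_from(nes), n_components=1)
        assert "C" not in res.loadings.index


class TestSynthesis:
    def _pca_with(self, names, loadings, contribs):
        comp = pd.DataFrame({"PC1": loadings}, index=names)
        contrib = pd.DataFrame({"PC1": contribs}, index=names)
        scores = pd.DataFrame({"PC1": [0.0, 0.0]}, index=["s1", "s2"])
        return __import__("pathstrat").signatures.PCAResult(
            scores=scores, loadings=comp, explained_variance_ratio=np.array([1.0]),
            contributions=contrib,
        )

    def test_naming_convention_tcga_canonical_pc1_negative(self):
        sets = [GeneSet(f"S{i}", "d", ("A", "B", "C", "D", "E")) for i in range(6)]
        coll = GeneSetCollection(sets, label="canonical")
        names = [s.name for s in sets]
        pca = self._pca_with(names, [-0.5] * 6, [100 / 6] * 6)
        sig = synthesize_signature(pca, coll, 1, "negative", "T", top_n=6, min_overlap=5)
        assert sig.name == "T2-1N"

    def test_identical_source_sets_give_that_gene_list(self):
        sets = [GeneSet(f"S{i}", "d", ("X", "Y", "Z")) for i in range(20)]
        coll = GeneSetCollection(sets, label="oncogenic")
        pca = self._pca_with([s.name for s in sets], [0.3] * 20, [5.0] * 20)
        sig = synthesize_signature(pca, coll, 1, "positive", "G", top_n=20, min_overlap=5)
        assert set(sig.genes) == {"X", "Y", "Z"}
        assert all(c == 20 for c in sig.membership_counts.values())
        assert sig.name == "G6-1P"

    def test_min_overlap_threshold_is_inclusive_at_five(self):
        # gene X sits in exactly 5 of the top sets, gene Y in exactly 4
        sets = []
        for i in range(5):
            genes = ("X", "Y", f"F{i}") if i < 4 else ("X", f"F{i}")
            sets.append(GeneSet(f"S{i}", "d", genes))
        sets.append(GeneSet("S5", "d", ("Q", "R")))
        coll = GeneSetCollection(sets, label="canonical")
        pca = self._pca_with([s.name for s in sets], [0.4] * 6, [100 / 6] * 6)
        sig = synthesize_signature(pca, coll, 1, "positive", "T", top_n=6, min_overlap=5)
        assert "X" in sig.genes and "Y" not in sig.genes
        assert sig.membership_counts["X"] == 5

    def test_empty_signature_advises_threshold_change(self):
        sets = [GeneSet(f"S{i}", "d", (f"G{i}",)) for i in range(6)]
        coll = GeneSetCollection(sets, label="canonical")
        pca = self._pca_with([s.name for s in sets], [0.4] * 6, [100 / 6] * 6)
        with pytest.raises(ValueError, match="min_overlap"):
            synthesize_signature(pca, coll, 1, "positive", "T", top_n=6, min_overlap=5)

    def test_direction_flip_swaps_p_and_n_signatures(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i:02d}" for i in range(30)]
        sets = [GeneSet(f"S{i}", "d", tuple(rng.choice(genes, 10, replace=False)))
                for i in range(12)]
        coll = GeneSetCollection(sets, label="canonical")
        names = [s.name for s in sets]
        load = rng.normal(size=12)
        contrib = 100 * load**2 / (load**2).sum()
        pca = self._pca_with(names, load, contrib)
        flipped = self._pca_with(names, -load, contrib)
        for d, d_flip in (("positive", "negative"), ("negative", "positive")):
            try:
                a = synthesize_signature(pca, coll, 1, d, "T", top_n=6, min_overlap=2)
                b = synthesize_signature(flipped, coll, 1, d_flip, "T", top_n=6, min_overlap=2)
                assert a.genes == b.genes and a.source_sets == b.source_sets
            except ValueError:
                pass


class TestSignatureScoring:
    def test_random_signature_nes_centers_near_zero(self, small_cohort):
        matrix, _, _, _ = small_cohort
        rng = np.random.default_rng(9)
        sig = GeneSignature(
            name="RND", genes=tuple(sorted(rng.choice(matrix.genes, 30, replace=False))),
            component=1, direction="positive", source_sets=("x",) * 5,
            membership_counts={},
        )
        prof = score_signature_matrix(matrix, [sig], n_perm=150, seed=9)
        assert abs(prof.nes["RND"].mean()) < 0.2

    def test_cluster_samples_score_highest_for_own_signature(self, small_cohort):
        matrix, _, _, truth = small_cohort
        sigs = [
            GeneSignature(
                name=f"SIG_C{c}", genes=tuple(truth.program_genes[c]), component=1,
                direction="positive", source_sets=("x",) * 5, membership_counts={},
            )
            for c in sorted(truth.program_genes)
        ]
        prof = score_signature_matrix(matrix, sigs, n_perm=150, seed=3)
        correct = 0
        for sample, cluster in truth.labels.items():
            best = prof.nes.loc[sample].idxmax()
            correct += best == f"SIG_C{cluster}"
        assert correct / len(truth.labels) > 0.5

    def test_deterministic_given_seed(self, small_cohort):
        matrix, _, _, truth = small_cohort
        sig = GeneSignature(
            name="SIG", genes=tuple(truth.program_genes[0]), component=1,
            direction="positive", source_sets=("x",) * 5, membership_counts={},
        )
        p1 = score_signature_matrix(matrix, [sig], n_perm=120, seed=11)
        p2 = score_signature_matrix(matrix, [sig], n_perm=120, seed=11)
        pd.testing.assert_frame_equal(p1.nes, p2.nes)
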