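"""The weighted running-sum enrichment score against a brute-force oracle,
cohort-mean ranking arithmetic, and permutation-NES behavior on planted data."""

import numpy as np
import pandas as pd
import pytest

from pathstrat import (
    ExpressionMatrix,
    GeneSet,
    RankedList,
    enrichment_score,
    normalize_es,
    rank_vs_cohort_mean,
    simulate_bulk,
    SimulationConfig,
)


def es_oracle(genes, stats, set_genes, weight):
    """Literal position-by-position running sum; independent of the implementation."""
    in_set = [g in set_genes for g in genes]
    n_hit = sum(in_set)
    n = len(genes)
    denom = sum(abs(s) ** weight for s, h in zip(stats, in_set) if h)
    running = 0.0
    best = 0.0
    for g, s, h in zip(genes, stats, in_set):
        if h:
            if denom == 0:
                running += 1.0 / n_hit
            else:
                running += abs(s) ** weight / denom
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


class TestRanking:
    def test_hand_arithmetic_two_by_two(self):
        m = ExpressionMatrix(
            values=pd.DataFrame([[2.0, 0.0], [0.0, 2.0]], index=["GA", "GB"], columns=["s1", "s2"])
        )
        r = rank_vs_cohort_mean(m, "s1")
        assert list(r.genes) == ["GA", "GB"]
        np.testing.assert_allclose(r.stat, [1.0, -1.0])

    def test_all_ties_fall_back_to_lexicographic_order(self):
        m = ExpressionMatrix(
            values=pd.DataFrame(
                np.ones((3, 2)), index=["GC", "GA", "GB"], columns=["s1", "s2"]
            )
        )
        r = rank_vs_cohort_mean(m, "s1")
        assert list(r.genes) == ["GA", "GB", "GC"]
        np.testing.assert_allclose(r.stat, 0.0)

    def test_constant_shift_of_a_gene_row_leaves_its_stat_unchanged(self, tiny_matrix):
        r1 = rank_vs_cohort_mean(tiny_matrix, "s1")
        shifted = ExpressionMatrix(values=tiny_matrix.values.copy())
        shifted.values.loc["GB"] += 5.0
        r2 = rank_vs_cohort_mean(shifted, "s1")
        i1 = list(r1.genes).index("GB")
        i2 = list(r2.genes).index("GB")
        assert r1.stat[i1] == pytest.approx(r2.stat[i2])

    def test_missing_sample_is_an_error(self, tiny_matrix):
        with pytest.raises(KeyError):
            rank_vs_cohort_mean(tiny_matrix, "nope")


class TestEnrichmentScore:
    @pytest.fixture
    def ranked4(self):
        return RankedList(
            sample="x", genes=np.array(["G1", "G2", "G3", "G4"]), stat=np.array([3.0, 2.0, 1.0, 0.5])
        )

    @pytest.mark.parametrize(
        "set_genes,expected",
        [(("G1",), 1.0), (("G1", "G3"), 0.5), (("G4",), -1.0)],
    )
    def test_closed_form_cases_weight_zero(self, ranked4, set_genes, expected):
        es, _ = enrichment_score(ranked4, GeneSet("S", "d", set_genes), weight=0)
        assert es == pytest.approx(expected, abs=1e-15)

    def test_running_sum_trace_matches_hand_computation(self, ranked4):
        _, rs = enrichment_score(ranked4, GeneSet("S", "d", ("G1", "G3")), weight=0)
        np.testing.assert_allclose(rs, [0.5, 0.0, 0.5, 0.0], atol=1e-15)

    def test_no_overlap_raises(self, ranked4):
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(ranked4, GeneSet("S", "d", ("NOPE",)))

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_matches_bruteforce_oracle_on_random_instances(self, weight):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            genes = np.array([f"G{i:03d}" for i in range(n)])
            stat = np.sort(rng.normal(size=n))[::-1]
            m = int(rng.integers(1, min(10, n - 1) + 1))
            chosen = set(rng.choice(genes, size=m, replace=False))
            ranked = RankedList("x", genes, stat)
            es, _ = enrichment_score(ranked, GeneSet("S", "d", tuple(sorted(chosen))), weight)
            assert es == pytest.approx(es_oracle(genes, stat, chosen, weight), abs=1e-12)

    def test_antisymmetry_under_list_reversal_weight_zero(self):
        rng = np.random.default_rng(5)
        genes = np.array([f"G{i}" for i in range(20)])
        stat = np.sort(rng.normal(size=20))[::-1]
        gs = GeneSet("S", "d", tuple(rng.choice(genes, size=5, replace=False)))
        es_fwd, _ = enrichment_score(RankedList("x", genes, stat), gs, weight=0)
        es_rev, _ = enrichment_score(RankedList("x", genes[::-1], -stat[::-1]), gs, weight=0)
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)


@pytest.fixture(scope="module")
def planted_profile():
    cfg = SimulationConfig(
        n_genes=400, n_samples=20, k_clusters=2, programs_per_cluster=3,
        program_size=30, effect=2.0, noise_sd=1.0,
        hazard_by_cluster=(0.05, 0.1), seed=7, n_decoys=12,
    )
    matrix, _, collection, truth = simulate_bulk(cfg)
    profile = normalize_es(matrix, collection, n_perm=200, seed=7)
    return profile, collection, truth


class TestNormalizedScores:
    def test_same_seed_reproduces_identical_nes(self, planted_profile):
        profile, collection, truth = planted_profile
        cfg = SimulationConfig(
            n_genes=400, n_samples=20, k_clusters=2, programs_per_cluster=3,
            program_size=30, effect=2.0, noise_sd=1.0,
            hazard_by_cluster=(0.05, 0.1), seed=7, n_decoys=12,
        )
        matrix, _, collection2, _ = simulate_bulk(cfg)
        again = normalize_es(matrix, collection2, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(profile.nes, again.nes)

    def test_planted_sets_exceed_decoy_quantile_in_own_cluster(self, planted_profile):
        profile, collection, truth = planted_profile
        decoy_cols = [n for n in profile.gene_sets if n.startswith("DECOY")]
        hits = 0
        total = 0
        for sample, cluster in truth.labels.items():
            decoy_q = np.nanpercentile(profile.nes.loc[sample, decoy_cols], 95)
            for gs in truth.planted_sets[cluster]:
                total += 1
                nes = profile.nes.loc[sample, gs.name]
                hits += (nes > 0) and (nes > decoy_q)
        assert hits / total > 0.9

    def test_nes_sign_matches_es_sign(self, planted_profile):
        profile, _, _ = planted_profile
        both = profile.nes.notna()
        assert (
            np.sign(profile.nes[both].fillna(0)) == np.sign(profile.es[both].fillna(0))
        ).all().all()

    def test_nes_monotone_in_planted_effect(self):
        means = []
        for effect in (0.0, 1.0, 2.0):
            vals = []
            for seed in range(3):
                cfg = SimulationConfig(
                    n_genes=300, n_samples=16, k_clusters=2, programs_per_cluster=2,
                    program_size=25, effect=effect, noise_sd=1.0,
                    hazard_by_cluster=(0.05, 0.1), seed=50 + seed, n_decoys=8,
                )
                matrix, _, collection, truth = simulate_bulk(cfg)
                profile = normalize_es(matrix, collection, n_perm=150, seed=seed)
                for sample, cluster in truth.labels.items():
                    for gs in truth.planted_sets[cluster]:
                        vals.append(profile.nes.loc[sample, gs.name])
            means.append(np.nanmean(vals))
        assert means[0] < means[1] < means[2]
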