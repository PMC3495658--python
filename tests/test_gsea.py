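"""GSEA engine: running-sum oracle, permutation null, leading edge, ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crestmeta import simulate
from crestmeta.gsea import (
    cytogenetic_overlap,
    enrichment_score,
    fisher_ora,
    gene_set_permutation_test,
    leading_edge,
    rank_by_signal_to_noise,
)

from conftest import planted_by_direction


def running_sum_oracle(ranked, gene_set, weight):
    """Literal gene-by-gene running sum, returned as (es, profile, peak)."""
    members = set(gene_set)
    scores = ranked.to_numpy(float)
    n = len(scores)
    hits = [g in members for g in ranked.index]
    n_hit = sum(hits)
    w_total = sum(abs(scores[i]) ** weight for i in range(n) if hits[i])
    value, profile = 0.0, []
    for i in range(n):
        if hits[i]:
            value += (abs(scores[i]) ** weight) / w_total if w_total > 0 else 1.0 / n_hit
        else:
            value -= 1.0 / (n - n_hit)
        profile.append(value)
    profile = np.array(profile)
    peak = int(np.argmax(np.abs(profile)))
    return profile[peak], profile, peak


def toy_ranked():
    scores = [5.0, 4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0, -5.0]
    return pd.Series(scores, index=[f"g{i+1}" for i in range(10)])


class TestEnrichmentScore:
    def test_single_gene_at_rank_one_gives_es_one(self):
        res = enrichment_score(toy_ranked(), ["g1"])
        assert res.es == 1.0
        assert res.peak_index == 0

    @pytest.mark.parametrize("weight", [0.0, 1.0, 2.0])
    @pytest.mark.parametrize("members", [["g1", "g2", "g5"], ["g3", "g8"], ["g10"], ["g2", "g9", "g10"]])
    def test_matches_running_sum_oracle(self, weight, members):
        ranked = toy_ranked()
        res = enrichment_score(ranked, members, weight=weight)
        es_o, profile_o, peak_o = running_sum_oracle(ranked, members, weight)
        assert res.es == pytest.approx(es_o, abs=1e-12)
        assert np.allclose(res.running, profile_o, atol=1e-12)
        assert res.peak_index == peak_o

    def test_telescoping_and_bounds_on_random_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(20, 200))
            ranked = pd.Series(
                np.sort(rng.standard_normal(n))[::-1], index=[f"g{i:03d}" for i in range(n)]
            )
            k = int(rng.integers(1, n // 2))
            members = list(rng.choice(ranked.index, size=k, replace=False))
            res = enrichment_score(ranked, members, weight=float(rng.choice([0.0, 1.0])))
            assert abs(res.running[-1]) < 1e-9  # running sum returns to zero
            assert abs(res.es) <= 1.0 + 1e-12

    def test_reversal_negates_unweighted_es(self):
        ranked = toy_ranked()
        members = ["g2", "g3", "g7"]
        fwd = enrichment_score(ranked, members, weight=0.0).es
        rev = enrichment_score(ranked.iloc[::-1], members, weight=0.0).es
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_random_placement_has_zero_mean_es(self):
        rng = np.random.default_rng(7)
        ranked = pd.Series(np.linspace(3, -3, 100), index=[f"g{i:03d}" for i in range(100)])
        es = [
            enrichment_score(ranked, list(rng.choice(ranked.index, 10, replace=False)), weight=0.0).es
            for _ in range(1000)
        ]
        assert abs(np.mean(es)) < 3 * np.std(es) / np.sqrt(len(es)) + 0.02

    def test_disjoint_and_full_sets_rejected(self):
        ranked = toy_ranked()
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(ranked, ["nope"])
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, list(ranked.index))


class TestLeadingEdge:
    def test_single_gene_set(self):
        ranked = toy_ranked()
        res = enrichment_score(ranked, ["g1"])
        assert leading_edge(ranked, ["g1"], res) == ["g1"]

    def test_toy_peak_after_second_hit(self):
        # hits at ranks 1, 2 and 9: the peak falls after the second hit,
        # so the leading edge is the first two hits
        ranked = toy_ranked()
        members = ["g1", "g2", "g9"]
        res = enrichment_score(ranked, members, weight=0.0)
        _, profile, peak = running_sum_oracle(ranked, members, 0.0)
        assert res.peak_index == peak == 1
        assert leading_edge(ranked, members, res) == ["g1", "g2"]

    def test_negative_es_takes_tail(self):
        ranked = toy_ranked()
        members = ["g8", "g9", "g10"]
        res = enrichment_score(ranked, members, weight=0.0)
        assert res.es < 0
        assert leading_edge(ranked, members, res) == ["g8", "g9", "g10"]

    def test_subset_property_random(self):
        rng = np.random.default_rng(3)
        ranked = pd.Series(np.linspace(2, -2, 60), index=[f"g{i:02d}" for i in range(60)])
        for _ in range(30):
            members = list(rng.choice(ranked.index, 8, replace=False))
            res = enrichment_score(ranked, members)
            assert set(leading_edge(ranked, members, res)) <= set(members)


class TestRanking:
    def test_swapping_groups_negates_scores(self, default_sim):
        _, expr, annot, _, _ = default_sim
        fwd = rank_by_signal_to_noise(expr, annot, ("grp1", "grp2"))
        rev = rank_by_signal_to_noise(expr, annot, ("grp2", "grp1"))
        assert np.allclose(fwd.sort_index(), -rev.sort_index(), atol=1e-12)

    def test_planted_up_genes_rank_in_top_decile(self, default_sim):
        cfg, expr, annot, _, truth = default_sim
        up, _ = planted_by_direction(truth)
        ranked = rank_by_signal_to_noise(expr, annot, ("grp1", "grp2"))
        top = set(ranked.index[: len(ranked) // 10])
        assert len(set(up) & top) / len(up) >= 0.9

    def test_small_groups_advise_tstat(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)), columns=list("abcd"))
        annot = pd.DataFrame(
            {"sample": list("abcd"), "group": ["g1", "g1", "g2", "g2"], "study": "s", "platform": "p"}
        ).set_index("sample", drop=False)
        with pytest.raises(ValueError, match="tstat"):
            rank_by_signal_to_noise(expr, annot, ("g1", "g2"))


class TestPermutationTest:
    def test_same_seed_identical_results(self, default_sim):
        _, expr, annot, _, _ = default_sim
        ranked = rank_by_signal_to_noise(expr, annot, ("grp1", "grp2"))
        sets = simulate.positional_sets(list(expr.index), 40)
        r1 = gene_set_permutation_test(ranked, sets, n_perm=100, seed=5)
        r2 = gene_set_permutation_test(ranked, sets, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(r1.drop(columns="leading_edge"), r2.drop(columns="leading_edge"))

    def test_planted_set_significant_with_correct_sign(self, default_sim):
        _, expr, annot, _, truth = default_sim
        up, down = planted_by_direction(truth)
        ranked = rank_by_signal_to_noise(expr, annot, ("grp1", "grp2"))
        sets = {"planted_up": up, "planted_down": down}
        sets.update({f"rand{i}": list(expr.index[200 + 10 * i : 210 + 10 * i]) for i in range(5)})
        res = gene_set_permutation_test(ranked, sets, n_perm=200, seed=4)
        assert res.loc["planted_up", "significant"] and res.loc["planted_up", "es"] > 0
        assert res.loc["planted_down", "significant"] and res.loc["planted_down", "es"] < 0
        assert res.loc["planted_up", "p"] == 1 / 200  # never reported as zero

    def test_leading_edge_captures_planted_genes(self, default_sim):
        _, expr, annot, _, truth = default_sim
        up, _ = planted_by_direction(truth)
        ranked = rank_by_signal_to_noise(expr, annot, ("grp1", "grp2"))
        res = gene_set_permutation_test(ranked, {"planted_up": up}, n_perm=150, seed=2)
        le = res.loc["planted_up", "leading_edge"]
        assert len(set(le) & set(up)) / len(up) >= 0.8

    def test_small_sets_skipped_with_warning(self, default_sim):
        _, expr, annot, _, _ = default_sim
        ranked = rank_by_signal_to_noise(expr, annot, ("grp1", "grp2"))
        with pytest.warns(UserWarning, match="skipped"):
            res = gene_set_permutation_test(ranked, {"tiny": [expr.index[0]]}, n_perm=100, seed=1)
        assert res.empty

    def test_nominal_p_calibrated_on_null(self):
        rates = []
        for seed in range(5):
            cfg = simulate.SimulationConfig(
                n_genes=200, n_de_genes=0, n_stable_genes=0, samples_per_group=10, seed=70 + seed
            )
            expr, annot, _ = simulate.simulate_expression(cfg)
            ranked = rank_by_signal_to_noise(expr, annot, ("grp1", "grp2"))
            sets = simulate.positional_sets(list(expr.index), 10)
            res = gene_set_permutation_test(ranked, sets, n_perm=100, seed=seed)
            rates.append((res["p"] < 0.05).mean())
        assert abs(np.mean(rates) - 0.05) < 0.04


class TestCytogeneticOverlap:
    @staticmethod
    def _enriched(default_sim, bands=25):
        _, expr, annot, _, truth = default_sim
        ranked = rank_by_signal_to_noise(expr, annot, ("grp1", "grp2"))
        sets = simulate.positional_sets(list(expr.index), bands)
        return gene_set_permutation_test(ranked, sets, n_perm=150, seed=9)

    def test_empty_aberration_list(self, default_sim):
        res = self._enriched(default_sim)
        out = cytogenetic_overlap(res, pd.DataFrame(columns=["region", "direction"]))
        assert out.empty

    def test_gained_band_recovered(self, default_sim):
        # band size 25 aligns chr1p with the planted up-regulated block
        res = self._enriched(default_sim)
        ab = pd.DataFrame({"region": ["chr1p"], "direction": ["gain"]})
        out = cytogenetic_overlap(res, ab)
        assert list(out["region"]) == ["chr1p"]
        assert len(out["leading_edge"].iloc[0]) >= 1

    def test_discordant_direction_excluded(self, default_sim):
        res = self._enriched(default_sim)
        ab = pd.DataFrame({"region": ["chr1p"], "direction": ["loss"]})
        assert cytogenetic_overlap(res, ab).empty

    def test_no_label_overlap_warns(self, default_sim):
        res = self._enriched(default_sim)
        ab = pd.DataFrame({"region": ["chr99q"], "direction": ["gain"]})
        with pytest.warns(UserWarning, match="no aberration label"):
            out = cytogenetic_overlap(res, ab)
        assert out.empty


class TestFisherORA:
    def test_counts_match_hypergeometric_oracle(self):
        # 2x2 table (10, 90, 40, 860): list of 100 from a universe of 1000
        universe = [f"g{i}" for i in range(1000)]
        gene_set = universe[:50]
        gene_list = universe[:10] + universe[50:140]
        res = fisher_ora(gene_list, universe, {"s": gene_set})
        # hypergeometric tail: P(X >= 10) drawing 100 from 1000 with 50 marked
        p_oracle = stats.hypergeom.sf(9, 1000, 50, 100)
        assert res.loc["s", "p"] == pytest.approx(p_oracle, rel=1e-9)
        assert res.loc["s", "n_overlap"] == 10

    def test_full_set_has_minimal_p(self):
        universe = [f"g{i}" for i in range(300)]
        sets = {"hit": universe[:20], "other": universe[100:150], "other2": universe[200:230]}
        res = fisher_ora(universe[:20], universe, sets)
        assert res["p"].idxmin() == "hit"

    def test_empty_list_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        res = fisher_ora([], universe, {"s": universe[:10]})
        assert (res["p"] == 1.0).all()

    def test_random_lists_calibrated(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(400)]
        sets = {f"s{j}": list(rng.choice(universe, 30, replace=False)) for j in range(20)}
        hits = 0
        total = 0
        for _ in range(50):
            lst = list(rng.choice(universe, 40, replace=False))
            res = fisher_ora(lst, universe, sets)
            hits += (res["p"] < 0.05).sum()
            total += len(res)
        assert hits / total < 0.07  # Fisher is conservative at small counts
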