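"""Microarray-game Shapley values: worked examples, axioms, oracle sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crestmeta import simulate
from crestmeta.diffexp import ComparisonSpec, two_group_test
from crestmeta.game_theory import (
    BooleanGameMatrix,
    build_boolean_matrix,
    reciprocal_select,
    reciprocal_select_groups,
    shapley_bruteforce,
    shapley_index,
)

from conftest import planted_by_direction, split_groups


def _mat(rows, genes=None):
    arr = np.asarray(rows)
    genes = genes or [f"g{i+1}" for i in range(arr.shape[0])]
    cols = [f"s{j+1}" for j in range(arr.shape[1])]
    return BooleanGameMatrix(pd.DataFrame(arr, index=genes, columns=cols))


def random_matrix(rng, n_genes=None, n_samples=None, density=None):
    n_genes = n_genes or rng.integers(2, 11)
    n_samples = n_samples or rng.integers(1, 9)
    density = density or rng.uniform(0.1, 0.7)
    return _mat((rng.random((n_genes, n_samples)) < density).astype(int))


class TestWorkedExamples:
    def test_three_gene_two_sample_example(self):
        # supports {g1} and {g1, g2}: g1 earns 1 + 1/2 over 2 samples
        m = _mat([[1, 1], [0, 1], [0, 0]])
        res = shapley_index(m)
        assert np.allclose(res["raw"], [0.75, 0.25, 0.0])
        assert np.allclose(res["normalized"], [1.0, 1 / 3, 0.0])

    def test_single_player_efficiency(self):
        res = shapley_index(_mat([[1]]))
        assert res["raw"].iloc[0] == 1.0 and res["normalized"].iloc[0] == 1.0

    def test_identical_rows_get_identical_indices(self):
        res = shapley_index(_mat([[1, 0, 1], [1, 0, 1], [0, 1, 0]]))
        assert res["raw"].iloc[0] == res["raw"].iloc[1]

    def test_all_empty_matrix_flagged(self):
        res = shapley_index(_mat([[0, 0], [0, 0]]))
        assert (res["raw"] == 0).all() and (res["normalized"] == 0).all()
        assert res.attrs["all_empty"]

    def test_empty_columns_reported_and_efficiency_scaled(self):
        m = _mat([[1, 0], [0, 0]])
        res = shapley_index(m)
        assert res.attrs["empty_columns"] == ["s2"]
        assert res["raw"].sum() == pytest.approx(0.5)  # 1 non-empty of 2 columns
        renorm = shapley_index(m, empty_column_policy="renormalize")
        assert renorm["raw"].sum() == pytest.approx(1.0)


class TestOracleEquivalence:
    def test_brute_force_on_worked_example(self):
        bf = shapley_bruteforce(_mat([[1, 1], [0, 1], [0, 0]]))
        assert np.allclose(bf["raw"], [0.75, 0.25, 0.0], atol=1e-12)

    def test_all_zero_matrix_is_null_game(self):
        bf = shapley_bruteforce(_mat([[0, 0], [0, 0]]))
        assert (bf["raw"] == 0).all()

    def test_closed_form_equals_brute_force_random_sweep(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            m = random_matrix(rng, n_genes=int(rng.integers(2, 9)), n_samples=6)
            diff = np.abs(shapley_index(m)["raw"].values - shapley_bruteforce(m)["raw"].values)
            assert diff.max() < 1e-10

    def test_brute_force_refuses_large_matrices(self):
        with pytest.raises(ValueError, match="capped"):
            shapley_bruteforce(_mat(np.ones((16, 2), dtype=int)))


class TestAxioms:
    def test_efficiency_symmetry_null_player_randomized(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            m = random_matrix(rng)
            x = m.values.to_numpy()
            res = shapley_index(m)
            colsum = x.sum(axis=0)
            worth = (colsum > 0).sum() / x.shape[1]
            assert res["raw"].sum() == pytest.approx(worth, abs=1e-12)  # efficiency
            zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
            assert (res["raw"].iloc[zero_rows] == 0).all()  # null player
            # symmetry: permuting rows permutes values; permuting columns is a no-op
            perm = rng.permutation(x.shape[0])
            res_p = shapley_index(_mat(x[perm]))
            assert np.allclose(res_p["raw"].values, res["raw"].values[perm], atol=1e-14)
            cperm = rng.permutation(x.shape[1])
            res_c = shapley_index(_mat(x[:, cperm]))
            assert np.allclose(res_c["raw"].values, res["raw"].values, atol=1e-14)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_monotonicity_adding_support_never_decreases(self, data):
        n_g = data.draw(st.integers(2, 6))
        n_s = data.draw(st.integers(1, 5))
        bits = data.draw(st.lists(st.booleans(), min_size=n_g * n_s, max_size=n_g * n_s))
        x = np.array(bits, dtype=int).reshape(n_g, n_s)
        zeros = np.argwhere(x == 0)
        if len(zeros) == 0:
            return
        i, j = zeros[data.draw(st.integers(0, len(zeros) - 1))]
        before = shapley_index(_mat(x))["raw"].iloc[i]
        x2 = x.copy()
        x2[i, j] = 1
        after = shapley_index(_mat(x2))["raw"].iloc[i]
        assert after >= before - 1e-12


class TestBuildBooleanMatrix:
    def test_constant_gene_gives_zero_row(self):
        a = pd.DataFrame(np.full((1, 4), 7.0), index=["g"], columns=list("abcd"))
        b = pd.DataFrame(np.full((1, 3), 7.0), index=["g"], columns=list("xyz"))
        m = build_boolean_matrix(a, b)
        assert m.values.to_numpy().sum() == 0

    def test_threshold_arithmetic_at_two_fold(self):
        # B mean at log2 = 5; A sample at 6.1 means 2**1.1 > 2-fold
        b = pd.DataFrame([[5.0, 5.0]], index=["g"], columns=["b1", "b2"])
        a = pd.DataFrame([[6.1, 5.9]], index=["g"], columns=["a1", "a2"])
        m = build_boolean_matrix(a, b, fc_threshold=2.0)
        assert m.values.loc["g"].tolist() == [1, 0]

    def test_gene_universe_mismatch_lists_genes(self):
        a = pd.DataFrame([[1.0]], index=["g1"], columns=["a1"])
        b = pd.DataFrame([[1.0]], index=["g2"], columns=["b1"])
        with pytest.raises(ValueError, match="universes differ"):
            build_boolean_matrix(a, b)

    def test_planted_gene_row_density(self, default_sim):
        cfg, expr, annot, _, truth = default_sim
        up, _ = planted_by_direction(truth)
        ea, eb = split_groups(expr, annot)
        m = build_boolean_matrix(eb, ea, fc_threshold=2.0)  # up genes flagged in grp2 samples
        density = m.values.loc[up].mean(axis=1)
        assert (density >= 0.9).all()


class TestReciprocalSelect:
    def test_planted_genes_selected_with_direction(self, default_sim):
        cfg, expr, annot, _, truth = default_sim
        up, down = planted_by_direction(truth)
        sel = reciprocal_select_groups(expr, annot, "grp1", "grp2")
        assert sel.loc[up, "selected"].mean() >= 0.8
        assert (sel.loc[up][sel.loc[up, "selected"]]["direction"] == "up_in_grp2").all()
        assert (sel.loc[down][sel.loc[down, "selected"]]["direction"] == "up_in_grp1").all()

    def test_null_selection_rate_is_tiny(self):
        rates = []
        for seed in range(5):
            cfg = simulate.SimulationConfig(
                n_genes=300, n_de_genes=0, n_stable_genes=0, samples_per_group=15, seed=60 + seed
            )
            expr, annot, _ = simulate.simulate_expression(cfg)
            sel = reciprocal_select_groups(expr, annot, "grp1", "grp2")
            rates.append(sel["selected"].mean())
        assert np.mean(rates) <= 0.01

    def test_cutoff_one_keeps_only_maximal_genes(self, default_sim):
        _, expr, annot, _, _ = default_sim
        ea, eb = split_groups(expr, annot)
        sel = reciprocal_select(ea, eb, cutoff=1.0)
        for _, row in sel[sel["selected"]].iterrows():
            tag = row["direction"].replace("up_in_", "")
            assert row[f"norm_up_{tag}"] == 1.0 and row[f"norm_up_{tag}_reciprocal"] == 1.0

    def test_invalid_cutoff(self, default_sim):
        _, expr, annot, _, _ = default_sim
        ea, eb = split_groups(expr, annot)
        with pytest.raises(ValueError):
            reciprocal_select(ea, eb, cutoff=0.0)


def test_concordance_with_diffexp(default_sim):
    """Shapley-selected genes cover well over 40% of the BH-significant 2-fold calls."""
    _, expr, annot, _, _ = default_sim
    de = two_group_test(expr, annot, ComparisonSpec())
    sel = reciprocal_select_groups(expr, annot, "grp1", "grp2")
    sig = set(de.index[de["significant"]])
    assert sig, "planted simulation must produce significant genes"
    overlap = len(sig & set(sel.index[sel["selected"]])) / len(sig)
    assert overlap > 0.4
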