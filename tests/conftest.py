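import numpy as np
import pandas as pd
import pytest

from crestmeta import simulate


@pytest.fixture(scope="session")
def default_sim():
    """One moderately sized two-group compendium with every planted feature."""
    cfg = simulate.SimulationConfig(
        n_genes=400,
        n_groups=2,
        samples_per_group=20,
        n_de_genes=40,
        de_log2fc=3.0,
        n_stable_genes=40,
        n_floor_genes=20,
        n_mirnas=4,
        targets_per_mirna=10,
        mirna_coupling=0.9,
        seed=11,
    )
    expr, annot, truth = simulate.simulate_expression(cfg)
    mirna_expr, truth = simulate.simulate_mirna(cfg, expr, truth)
    return cfg, expr, annot, mirna_expr, truth


@pytest.fixture(scope="session")
def null_sim():
    """A null compendium: no planted structure at all."""
    cfg = simulate.SimulationConfig(
        n_genes=300, n_groups=2, samples_per_group=15, n_de_genes=0, n_stable_genes=0, n_mirnas=0, seed=5
    )
    expr, annot, truth = simulate.simulate_expression(cfg)
    return cfg, expr, annot, truth


def split_groups(expr: pd.DataFrame, annot: pd.DataFrame, a="grp1", b="grp2"):
    return expr[annot.index[annot["group"] == a]], expr[annot.index[annot["group"] == b]]


def planted_by_direction(truth, pair=("grp1", "grp2")):
    up = [g for g, d in truth.de_genes[pair] if d == "up"]
    down = [g for g, d in truth.de_genes[pair] if d == "down"]
    return up, down
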