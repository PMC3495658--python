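"""Tissue-specific miRNA-target integration via inverse-expression enrichment.

The procedure links differential miRNA expression to its mRNA consequences:

1. merge target-prediction exports from several databases (union with a
   per-pair source count; a minimum source count makes the merge stricter),
2. drop predicted targets that are not expressed in the tissue under study
   (intensity below the per-sample 20th percentile in at least 20% of the
   samples of *both* groups),
3. test each miRNA for differential expression between the groups with
   one-way ANOVA and Scheffé post-hoc contrasts,
4. for every significantly changed miRNA, run GSEA of its filtered target
   set against the mRNA ranking of the same contrast and keep sets whose
   enrichment is *inverse* to the miRNA's change (miRNA up => targets
   enriched among down-regulated genes, negative ES); the leading-edge
   targets of those sets are the selected miRNA-target pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from crestmeta.diffexp import signed_fold_change
from crestmeta.gsea import gene_set_permutation_test
from crestmeta.reference_genes import presence_mask


def merge_targets(tables: list[pd.DataFrame], min_sources: int = 1) -> dict[str, list[str]]:
    """Merge per-database (miRNA, target) prediction tables.

    Each table needs columns ``mirna``/``target``/``source`` (see
    :func:`crestmeta.io.read_target_table`).  Predictions are unioned with a
    per-pair count of distinct supporting databases; pairs backed by fewer
    than ``min_sources`` databases are dropped.  Returns an ordered mapping
    miRNA -> sorted target list.
    """
    if not tables:
        raise ValueError("merge_targets needs at least one prediction table")
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    combined = pd.concat(tables, ignore_index=True).drop_duplicates(["mirna", "target", "source"])
    counts = combined.groupby(["mirna", "target"], sort=True)["source"].nunique()
    kept = counts[counts >= min_sources]
    out: dict[str, list[str]] = {}
    for (mirna, target), _cnt in kept.items():
        out.setdefault(mirna, []).append(target)
    return {m: sorted(t) for m, t in out.items()}


def filter_unexpressed(
    targets: dict[str, list[str]],
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    groups: tuple[str, str],
    percentile: float = 20.0,
    max_low_fraction: float = 0.2,
    study: str | None = None,
) -> dict[str, list[str]]:
    """Prune predicted targets that are unexpressed in this contrast.

    A gene is deemed unexpressed when its linear intensity is below the
    per-sample ``percentile`` cutoff in at least ``max_low_fraction`` of
    the samples of *both* groups.  Target genes absent from the expression
    matrix are dropped with a warning, as are miRNAs whose target set
    becomes empty.  Idempotent: re-filtering a filtered map is the
    identity.
    """
    ga, gb = groups

    def _cols(g: str) -> list[str]:
        mask = annot["group"] == g
        if study is not None:
            mask &= annot["study"] == study
        cols = list(annot.index[mask])
        if not cols:
            raise ValueError(f"group {g!r} has no samples")
        return cols

    cols_a, cols_b = _cols(ga), _cols(gb)
    linear = np.exp2(expr[cols_a + cols_b].to_numpy(dtype=float))
    below = ~presence_mask(linear, percentile)
    na = len(cols_a)
    low_a = below[:, :na].mean(axis=1) >= max_low_fraction
    low_b = below[:, na:].mean(axis=1) >= max_low_fraction
    unexpressed = set(expr.index[low_a & low_b])

    measured = set(expr.index)
    out: dict[str, list[str]] = {}
    n_unmeasured = 0
    for mirna, genes in targets.items():
        unmeasured = [g for g in genes if g not in measured]
        n_unmeasured += len(unmeasured)
        kept = [g for g in genes if g in measured and g not in unexpressed]
        if kept:
            out[mirna] = kept
        else:
            warnings.warn(f"miRNA {mirna!r}: no expressed targets remain; dropped")
    if n_unmeasured:
        warnings.warn(f"{n_unmeasured} predicted target(s) not covered by the expression matrix; dropped")
    return out


def mirna_de(
    mirna_expr: pd.DataFrame,
    annot: pd.DataFrame,
    groups: list[str],
    alpha: float = 0.05,
    study: str | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """One-way ANOVA per miRNA with Scheffé post-hoc pairwise contrasts.

    Scheffé's test evaluates each pairwise contrast against the F
    distribution with (k-1, N-k) degrees of freedom, making it valid for
    arbitrary post-hoc contrasts and conservative relative to the omnibus
    ANOVA (pairwise p >= ANOVA p always; with two groups they coincide).
    Returns one table per group pair with columns ``anova_p``,
    ``scheffe_p``, ``log2_fc``, ``fold_change``, ``direction`` and
    ``significant`` (Scheffé p < alpha), fold change signed with positive =
    up in the second group of the pair.
    """
    if len(groups) < 2:
        raise ValueError("mirna_de needs at least 2 groups")

    def _cols(g: str) -> list[str]:
        mask = annot["group"] == g
        if study is not None:
            mask &= annot["study"] == study
        cols = list(annot.index[mask])
        if len(cols) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        return cols

    arrays = [mirna_expr[_cols(g)].to_numpy(dtype=float) for g in groups]
    with np.errstate(invalid="ignore", divide="ignore"):
        anova_p = np.asarray(stats.f_oneway(*arrays, axis=1).pvalue, dtype=float)

    counts = np.array([arr.shape[1] for arr in arrays], dtype=float)
    k = len(groups)
    df_err = int(counts.sum()) - k
    means = np.column_stack([arr.mean(axis=1) for arr in arrays])
    ss_within = sum(((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for arr in arrays)
    mse = ss_within / df_err
    spread = means.max(axis=1) - means.min(axis=1)
    anova_p[(mse == 0) & (spread == 0)] = 1.0
    anova_p[(mse == 0) & (spread > 0)] = 0.0

    results: dict[tuple[str, str], pd.DataFrame] = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[:, j] - means[:, i]
            with np.errstate(invalid="ignore", divide="ignore"):
                f_contrast = diff**2 / (mse * (1.0 / counts[i] + 1.0 / counts[j])) / (k - 1)
            p = np.ones_like(f_contrast)
            finite = np.isfinite(f_contrast)
            p[finite] = stats.f.sf(f_contrast[finite], k - 1, df_err)
            p[~finite & (np.abs(diff) > 0)] = 0.0
            tab = pd.DataFrame(
                {
                    "anova_p": anova_p,
                    "scheffe_p": np.clip(p, 0.0, 1.0),
                    "log2_fc": diff,
                    "fold_change": signed_fold_change(diff),
                },
                index=mirna_expr.index,
            )
            tab["direction"] = np.where(diff >= 0, "up", "down")
            tab["significant"] = tab["scheffe_p"] < alpha
            results[(groups[i], groups[j])] = tab
    return results


def inverse_target_selection(
    ranked: pd.Series,
    mirna_result: pd.DataFrame,
    targets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    q_threshold: float = 0.25,
    min_size: int = 3,
) -> pd.DataFrame:
    """Select miRNA-target pairs with inverse expression changes.

    ``ranked`` is the mRNA ranking of a contrast (positive scores = up in
    the second group); ``mirna_result`` is the matching pair table from
    :func:`mirna_de`; ``targets`` the filtered per-miRNA target map.  For
    each significantly changed miRNA, its target set is tested by GSEA with
    gene-set permutation, and kept only when significant *and* enriched on
    the side opposite to the miRNA's change (miRNA up => negative ES).

    Returns one row per (miRNA, target) of the retained sets with the set's
    ES and q and a ``leading_edge`` flag; the leading-edge rows are the
    selected inverse pairs.
    """
    cols = ["mirna", "target", "es", "q", "leading_edge", "mirna_direction"]
    sig = mirna_result[mirna_result["significant"]]
    sets = {m: targets[m] for m in sig.index if m in targets}
    if not sets:
        return pd.DataFrame(columns=cols)

    enr = gene_set_permutation_test(
        ranked, sets, n_perm=n_perm, seed=seed, alpha=alpha, q_threshold=q_threshold, min_size=min_size
    )
    rows = []
    for mirna in enr.index:
        r = enr.loc[mirna]
        direction = str(sig.loc[mirna, "direction"])
        inverse = (direction == "up" and r["es"] < 0) or (direction == "down" and r["es"] > 0)
        if not (bool(r["significant"]) and inverse):
            continue
        le = set(r["leading_edge"])
        for target in sets[mirna]:
            rows.append(
                {
                    "mirna": mirna,
                    "target": target,
                    "es": r["es"],
                    "q": r["q"],
                    "leading_edge": target in le,
                    "mirna_direction": direction,
                }
            )
    return pd.DataFrame(rows, columns=cols)


def selected_pairs(table: pd.DataFrame) -> set[tuple[str, str]]:
    """The (miRNA, target) pairs in the leading edge of an inverse set."""
    if table.empty:
        return set()
    le = table[table["leading_edge"]]
    return set(zip(le["mirna"], le["target"]))
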