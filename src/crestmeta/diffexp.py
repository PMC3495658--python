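"""Per-study differential expression and cross-study intersection.

Group comparisons follow classic microarray practice: tests are computed on
log2 intensities (unpaired t-test for two groups, one-way ANOVA with Tukey
HSD post-hoc contrasts for more), fold changes are reported on the linear
scale as ratios of group geometric means, a fold-change filter is combined
with Benjamini-Hochberg control of the false discovery rate, and gene lists
from independent studies are intersected requiring direction consistency.

Fold-change sign convention: positive values mark genes up-regulated in the
second group of a comparison, negative values genes down-regulated there
(the signed convention of cross-study supplementary tables); ``|fold_change|``
is always the linear ratio of the higher group over the lower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

VALID_TESTS = ("ttest", "anova_tukey")


@dataclass
class ComparisonSpec:
    """One directed two-group comparison within a study."""

    study: str = "study1"
    group_a: str = "grp1"
    group_b: str = "grp2"
    test: str = "ttest"
    fc_threshold: float = 2.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be a linear fold change > 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.test not in VALID_TESTS:
            raise ValueError(f"test must be one of {VALID_TESTS}")


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (statsmodels fdr_bh)."""
    p = np.asarray(pvals, dtype=float)
    out = np.ones_like(p)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def signed_fold_change(log2_diff: np.ndarray) -> np.ndarray:
    """Signed linear fold change from a log2 mean difference (B minus A).

    ``+r`` for genes ``r``-fold up in B, ``-r`` for genes ``r``-fold down;
    magnitude is always >= 1.
    """
    ratio = np.exp2(np.asarray(log2_diff, dtype=float))
    return np.where(ratio >= 1.0, ratio, -1.0 / ratio)


def _group_columns(annot: pd.DataFrame, group: str, study: str | None = None) -> list[str]:
    mask = annot["group"] == group
    if study is not None:
        mask &= annot["study"] == study
    cols = list(annot.index[mask])
    if not cols:
        where = f" in study {study!r}" if study else ""
        raise ValueError(f"group {group!r} has no samples{where}")
    return cols


def two_group_test(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    spec: ComparisonSpec,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene unpaired two-sided t-test of group B against group A.

    Returns a DataFrame indexed by gene with columns ``fold_change`` (signed
    linear, positive = up in B), ``log2_fc``, ``p``, ``adj_p`` (BH across all
    genes), ``significant`` (adj_p < alpha and |FC| >= threshold) and
    ``zero_variance``.  A gene constant at the same value in every sample of
    both groups is assigned p = 1 and flagged rather than raising.

    ``equal_var=False`` switches to Welch's unequal-variance statistic.
    """
    study = spec.study if "study" in annot.columns and spec.study in set(annot["study"]) else None
    a = expr[_group_columns(annot, spec.group_a, study)].to_numpy()
    b = expr[_group_columns(annot, spec.group_b, study)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    diff = b.mean(axis=1) - a.mean(axis=1)
    zero_var = (var_a == 0) & (var_b == 0)
    # degenerate genes: no within-group variability at all
    p[zero_var & (diff == 0)] = 1.0
    p[zero_var & (diff != 0)] = 0.0

    adj = benjamini_hochberg(p)
    fc = signed_fold_change(diff)
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "log2_fc": diff,
            "p": p,
            "adj_p": adj,
            "zero_variance": zero_var,
        },
        index=expr.index,
    )
    out["significant"] = (out["adj_p"] < spec.alpha) & (np.abs(out["fold_change"]) >= spec.fc_threshold)
    return out


def _tukey_pairwise_p(
    means: np.ndarray, counts: np.ndarray, mse: np.ndarray, df: int, i: int, j: int
) -> np.ndarray:
    """Vectorised Tukey HSD p-values for the (i, j) group contrast."""
    k = len(counts)
    se = np.sqrt(mse / 2.0 * (1.0 / counts[i] + 1.0 / counts[j]))
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.abs(means[:, i] - means[:, j]) / se
    p = np.ones_like(q)
    finite = np.isfinite(q)
    p[finite] = stats.studentized_range.sf(q[finite], k, df)
    # zero MSE with distinct means: infinitely strong evidence
    p[~finite & (np.abs(means[:, i] - means[:, j]) > 0)] = 0.0
    return np.clip(p, 0.0, 1.0)


def multi_group_test(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    groups: list[str],
    study: str | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> dict[tuple[str, str], pd.DataFrame]:
    """One-way ANOVA per gene followed by Tukey HSD pairwise contrasts.

    The ANOVA p-value is BH-adjusted across genes; a pair (a, b) flags a
    gene when the adjusted ANOVA p and the Tukey p are both below ``alpha``
    and the pairwise linear fold change reaches ``fc_threshold``.  Returns
    one result table per unordered group pair, fold change signed with
    positive = up in the second group of the pair.
    """
    if len(groups) < 2:
        raise ValueError("multi_group_test needs at least 2 groups")
    arrays = [expr[_group_columns(annot, g, study)].to_numpy() for g in groups]
    if any(arr.shape[1] < 2 for arr in arrays):
        raise ValueError("each group needs at least 2 samples")

    with np.errstate(invalid="ignore", divide="ignore"):
        f_res = stats.f_oneway(*arrays, axis=1)
    anova_p = np.asarray(f_res.pvalue, dtype=float)

    counts = np.array([arr.shape[1] for arr in arrays], dtype=float)
    n_total = int(counts.sum())
    k = len(groups)
    df = n_total - k
    means = np.column_stack([arr.mean(axis=1) for arr in arrays])
    ss_within = sum(((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for arr in arrays)
    mse = ss_within / df

    zero_var = mse == 0
    spread = means.max(axis=1) - means.min(axis=1)
    anova_p[zero_var & (spread == 0)] = 1.0
    anova_p[zero_var & (spread > 0)] = 0.0
    anova_adj = benjamini_hochberg(anova_p)

    results: dict[tuple[str, str], pd.DataFrame] = {}
    for i in range(k):
        for j in range(i + 1, k):
            tukey_p = _tukey_pairwise_p(means, counts, mse, df, i, j)
            diff = means[:, j] - means[:, i]
            fc = signed_fold_change(diff)
            tab = pd.DataFrame(
                {
                    "fold_change": fc,
                    "log2_fc": diff,
                    "anova_p": anova_p,
                    "anova_adj_p": anova_adj,
                    "p": tukey_p,
                    "zero_variance": zero_var & (spread == 0),
                },
                index=expr.index,
            )
            tab["adj_p"] = tab["anova_adj_p"]  # gene-level multiplicity handled at the ANOVA stage
            tab["significant"] = (
                (tab["anova_adj_p"] < alpha)
                & (tab["p"] < alpha)
                & (np.abs(tab["fold_change"]) >= fc_threshold)
            )
            results[(groups[i], groups[j])] = tab
    return results


def intersect_studies(results: list[pd.DataFrame], min_studies: int = 2) -> pd.DataFrame:
    """Intersect significant gene lists across studies, direction-consistent.

    A gene is reported when it is significant (``significant`` column) in at
    least ``min_studies`` of the input tables *with the same fold-change
    sign everywhere it is significant*.  The output carries the incidence
    count and the per-study signed fold changes, sorted by count descending
    then gene ID.
    """
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    if not results:
        return pd.DataFrame(columns=["gene", "n_studies", "direction"]).set_index("gene")

    rows = []
    all_genes = sorted(set().union(*(set(r.index) for r in results)))
    for gene in all_genes:
        signs, fcs = [], []
        for r in results:
            if gene in r.index and bool(r.loc[gene, "significant"]):
                fc = float(r.loc[gene, "fold_change"])
                signs.append(np.sign(fc))
                fcs.append(fc)
            else:
                fcs.append(np.nan)
        if len(signs) >= min_studies and len(set(signs)) == 1:
            row = {"gene": gene, "n_studies": len(signs), "direction": "up" if signs[0] > 0 else "down"}
            row.update({f"fc_study{i + 1}": fc for i, fc in enumerate(fcs)})
            rows.append(row)

    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["gene", "n_studies", "direction"]).set_index("gene")
    return out.sort_values(["n_studies", "gene"], ascending=[False, True], kind="stable").set_index("gene")
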