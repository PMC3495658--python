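"""Reference-gene style screen for expression similarity between two groups.

Identifies genes whose expression is high, low-variance and essentially
unchanged between two tumour groups — the screen used to find shared
expression programmes between entities after removing ubiquitous
housekeeping genes.  Three criteria, all evaluated on the linear intensity
scale:

i.   presence — the gene's intensity is above the per-sample 20th
     percentile of that sample's intensity distribution in at least 80% of
     the samples of *each* group;
ii.  stability — the coefficient of variation (sd/mean) across the pooled
     samples of both groups is below 0.3;
iii. invariance — the fold change between the two group means is below 1.2
     (assessed symmetrically: max(ratio, 1/ratio)).

A user-supplied list of known housekeeping genes is removed from the
result, leaving the genes whose similarity is specific to the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd


@dataclass
class StabilityCriteria:
    """Thresholds of the three-part similarity screen."""

    presence_percentile: float = 20.0  # per-sample intensity percentile
    min_presence_fraction: float = 0.8  # fraction of samples per group above it
    cv_max: float = 0.3  # linear-scale coefficient of variation
    fc_max: float = 1.2  # symmetric linear fold change between group means
    fc_statistic: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if not (0 < self.presence_percentile < 100):
            raise ValueError("presence_percentile must lie in (0, 100)")
        if not (0 < self.min_presence_fraction <= 1):
            raise ValueError("min_presence_fraction must lie in (0, 1]")
        if self.cv_max <= 0:
            raise ValueError("cv_max must be > 0")
        if self.fc_max <= 1:
            raise ValueError("fc_max must be > 1")
        if self.fc_statistic not in ("mean", "median"):
            raise ValueError("fc_statistic must be 'mean' or 'median'")


def presence_mask(linear: np.ndarray, percentile: float) -> np.ndarray:
    """Boolean genes x samples mask: above that sample's intensity percentile."""
    cutoffs = np.percentile(linear, percentile, axis=0)  # per sample, linear interpolation
    return linear > cutoffs[None, :]


def find_stable_genes(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    groups: tuple[str, str],
    criteria: StabilityCriteria | None = None,
    exclude: list[str] | None = None,
    study: str | None = None,
) -> pd.DataFrame:
    """Genes with highly similar expression between two groups.

    ``expr`` holds log2 intensities; all criteria are evaluated on the
    linear scale.  Returns a DataFrame (index gene) with columns ``cv`` and
    ``fc`` (symmetric, >= 1), sorted by fold change ascending, with any
    gene in ``exclude`` removed.
    """
    criteria = criteria or StabilityCriteria()
    exclude_set = set(exclude or [])
    ga, gb = groups

    def _cols(g: str) -> list[str]:
        mask = annot["group"] == g
        if study is not None:
            mask &= annot["study"] == study
        cols = list(annot.index[mask])
        if len(cols) < 3:
            raise ValueError(f"group {g!r} needs >= 3 samples (found {len(cols)})")
        return cols

    cols_a, cols_b = _cols(ga), _cols(gb)
    sub = expr[cols_a + cols_b]
    linear = np.exp2(sub.to_numpy(dtype=float))
    na = len(cols_a)

    present = presence_mask(linear, criteria.presence_percentile)
    frac_a = present[:, :na].mean(axis=1)
    frac_b = present[:, na:].mean(axis=1)
    pass_presence = (frac_a >= criteria.min_presence_fraction) & (frac_b >= criteria.min_presence_fraction)

    mean_all = linear.mean(axis=1)
    sd_all = linear.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean_all > 0, sd_all / mean_all, np.inf)

    stat = np.mean if criteria.fc_statistic == "mean" else np.median
    stat_a = stat(linear[:, :na], axis=1)
    stat_b = stat(linear[:, na:], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = stat_b / stat_a
    fc = np.maximum(ratio, 1.0 / ratio)

    keep = pass_presence & (cv < criteria.cv_max) & (fc < criteria.fc_max)
    out = pd.DataFrame({"cv": cv, "fc": fc}, index=expr.index)[keep]
    out = out[~out.index.isin(exclude_set)]
    return out.sort_values(["fc", "cv"], kind="stable")


def multi_platform_consensus(lists: list[list[str]], min_lists: int = 2) -> pd.DataFrame:
    """Genes present in at least ``min_lists`` input lists.

    Returns a table (index gene) with the incidence count ``n_lists``,
    ranked by count descending then gene ID — the cross-platform consensus
    rule ("common in at least two comparisons").
    """
    if min_lists < 1:
        raise ValueError("min_lists must be >= 1")
    counts = Counter()
    for lst in lists:
        counts.update(set(lst))
    rows = [(g, c) for g, c in counts.items() if c >= min_lists]
    out = pd.DataFrame(rows, columns=["gene", "n_lists"])
    if out.empty:
        return out.set_index("gene")
    return out.sort_values(["n_lists", "gene"], ascending=[False, True], kind="stable").set_index("gene")
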