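"""Cooperative-game-theory gene relevance: the microarray game.

Each two-group contrast defines a coalitional game in which genes are the
players and samples are the games.  A gene "supports" a sample when its
expression in that sample exceeds a fold-change threshold relative to the
reference group; a coalition of genes wins on a sample when it contains the
sample's whole support.  The Shapley value of this game — the unique
allocation satisfying efficiency, symmetry, null-player and additivity —
reduces to a closed form: average, over samples, each gene's share of the
sample's support (1/|support| for members, 0 otherwise).  Genes are then
max-normalised to [0, 1] and a gene is *selected* for a direction when its
normalised index exceeds a cutoff (default 0.6) in both framings of the
contrast: the direct run (samples of the altered group against the
reference mean) and the reciprocal run (reference samples against the
altered group's mean, with the reciprocal threshold criterion).

An exhaustive-coalition brute-force Shapley solver (``shapley_bruteforce``)
is provided for validation on small matrices; the closed form is used in
production.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd

BRUTE_FORCE_MAX_GENES = 15


@dataclass
class BooleanGameMatrix:
    """Genes x samples 0/1 support matrix for one directed comparison."""

    values: pd.DataFrame  # int8 {0,1}, genes in rows, samples in columns
    direction: str = ""  # free-text label of which group supplied the samples
    fc_threshold: float = 2.0

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size == 0:
            raise ValueError("BooleanGameMatrix needs at least one gene and one sample")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("BooleanGameMatrix entries must be 0 or 1")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def empty_columns(self) -> list[str]:
        colsum = self.values.sum(axis=0)
        return list(colsum.index[colsum == 0])


def build_boolean_matrix(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    fc_threshold: float = 2.0,
    criterion: str = "above",
    direction: str = "",
) -> BooleanGameMatrix:
    """Support matrix of group A samples against the group B reference.

    With ``criterion="above"`` an entry (g, j) is 1 when the linear
    expression of gene g in A-sample j exceeds ``fc_threshold`` times the
    geometric mean of g over all B samples (on log2 data: log2 value above
    the B mean plus log2 threshold).  ``criterion="below"`` applies the
    reciprocal rule (expression below reference / threshold), which frames
    the same biological direction from the opposite group's samples.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if criterion not in ("above", "below"):
        raise ValueError("criterion must be 'above' or 'below'")
    if not expr_a.index.equals(expr_b.index):
        only_a = sorted(set(expr_a.index) - set(expr_b.index))
        only_b = sorted(set(expr_b.index) - set(expr_a.index))
        raise ValueError(
            f"gene universes differ: {len(only_a)} genes only in A (e.g. {only_a[:5]}), "
            f"{len(only_b)} only in B (e.g. {only_b[:5]})"
        )
    log_thr = np.log2(fc_threshold)
    ref = expr_b.mean(axis=1).to_numpy()[:, None]  # log2 of B geometric mean
    a = expr_a.to_numpy()
    if criterion == "above":
        flags = a > ref + log_thr
    else:
        flags = a < ref - log_thr
    values = pd.DataFrame(flags.astype(np.int8), index=expr_a.index, columns=expr_a.columns)
    return BooleanGameMatrix(values=values, direction=direction, fc_threshold=fc_threshold)


def shapley_index(m: BooleanGameMatrix, empty_column_policy: str = "efficiency") -> pd.DataFrame:
    """Closed-form Shapley values of the microarray game, max-normalised.

    For gene g, ``raw(g)`` is the mean over non-empty columns j of
    ``m(g, j) / colsum(j)``, scaled by the fraction of non-empty columns, so
    the raw values sum exactly to (non-empty columns) / (total columns) —
    the game's total worth (efficiency).  ``empty_column_policy="renormalize"``
    instead averages over non-empty columns only (raw values then sum to 1
    whenever any column is non-empty).

    ``normalized = raw / max(raw)``; if every column is empty all values are
    0 and the result's ``attrs["all_empty"]`` flag is set.  The excluded
    empty columns are reported in ``attrs["empty_columns"]``.
    """
    if empty_column_policy not in ("efficiency", "renormalize"):
        raise ValueError("empty_column_policy must be 'efficiency' or 'renormalize'")
    x = m.values.to_numpy(dtype=float)
    colsum = x.sum(axis=0)
    nonempty = colsum > 0
    n_total = x.shape[1]
    n_nonempty = int(nonempty.sum())

    if n_nonempty == 0:
        raw = np.zeros(x.shape[0])
    else:
        shares = x[:, nonempty] / colsum[nonempty]
        denom = n_total if empty_column_policy == "efficiency" else n_nonempty
        raw = shares.sum(axis=1) / denom

    max_raw = raw.max() if raw.size else 0.0
    normalized = raw / max_raw if max_raw > 0 else np.zeros_like(raw)

    out = pd.DataFrame({"raw": raw, "normalized": normalized}, index=m.genes)
    out.attrs["empty_columns"] = list(m.values.columns[~nonempty])
    out.attrs["all_empty"] = n_nonempty == 0
    return out


def shapley_bruteforce(m: BooleanGameMatrix) -> pd.DataFrame:
    """Shapley values by exhaustive coalition enumeration (validation only).

    Evaluates the game ``v(S) = (1/m) * #{samples j: support_j non-empty and
    support_j subset of S}`` and averages each gene's marginal contribution
    with the standard coalition weights ``|S|! (n-|S|-1)! / n!``.  Refuses
    matrices with more than 15 genes.
    """
    n = m.values.shape[0]
    if n > BRUTE_FORCE_MAX_GENES:
        raise ValueError(f"brute force capped at {BRUTE_FORCE_MAX_GENES} genes (got {n})")
    x = m.values.to_numpy()
    n_samples = x.shape[1]
    supports = []
    for j in range(n_samples):
        mask = 0
        for i in range(n):
            if x[i, j]:
                mask |= 1 << i
        if mask:
            supports.append(mask)

    def v(coalition: int) -> float:
        return sum(1 for s in supports if s & ~coalition == 0) / n_samples

    fact = [factorial(i) for i in range(n + 1)]
    raw = np.zeros(n)
    full = (1 << n) - 1
    for i in range(n):
        bit = 1 << i
        others = full & ~bit
        # iterate over all subsets S of N \ {i}
        s = others
        while True:
            size = bin(s).count("1")
            w = fact[size] * fact[n - size - 1] / fact[n]
            raw[i] += w * (v(s | bit) - v(s))
            if s == 0:
                break
            s = (s - 1) & others

    max_raw = raw.max() if raw.size else 0.0
    normalized = raw / max_raw if max_raw > 0 else np.zeros_like(raw)
    out = pd.DataFrame({"raw": raw, "normalized": normalized}, index=m.genes)
    out.attrs["all_empty"] = not supports
    return out


def reciprocal_select(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    fc_threshold: float = 2.0,
    cutoff: float = 0.6,
    labels: tuple[str, str] = ("A", "B"),
    empty_column_policy: str = "efficiency",
) -> pd.DataFrame:
    """Two-direction reciprocal Shapley selection for one contrast.

    For the "up in A" direction the index is computed twice: from the A
    samples against the B reference (above-threshold criterion) and from
    the B samples against the A reference (below-threshold criterion, the
    reciprocal framing of the same direction).  A gene is selected up-in-A
    when its normalised index exceeds ``cutoff`` in *both* runs; up-in-B is
    handled symmetrically and the union is reported with direction labels.

    Returns a per-gene table with the four normalised indices, a
    ``selected`` flag and a ``direction`` column (``up_in_<label>`` or "").
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    la, lb = labels

    def _norm(ea: pd.DataFrame, eb: pd.DataFrame, criterion: str, tag: str) -> pd.Series:
        mat = build_boolean_matrix(ea, eb, fc_threshold, criterion=criterion, direction=tag)
        return shapley_index(mat, empty_column_policy=empty_column_policy)["normalized"]

    up_a = _norm(expr_a, expr_b, "above", f"up_in_{la}")
    up_a_rev = _norm(expr_b, expr_a, "below", f"up_in_{la}_reciprocal")
    up_b = _norm(expr_b, expr_a, "above", f"up_in_{lb}")
    up_b_rev = _norm(expr_a, expr_b, "below", f"up_in_{lb}_reciprocal")

    out = pd.DataFrame(
        {
            f"norm_up_{la}": up_a,
            f"norm_up_{la}_reciprocal": up_a_rev,
            f"norm_up_{lb}": up_b,
            f"norm_up_{lb}_reciprocal": up_b_rev,
        },
        index=expr_a.index,
    )
    # inclusive boundary: cutoff=1.0 keeps exactly the genes attaining the
    # maximum in both runs; at interior cutoffs ties are measure-zero
    sel_a = (up_a >= cutoff) & (up_a_rev >= cutoff)
    sel_b = (up_b >= cutoff) & (up_b_rev >= cutoff)
    score_a = np.minimum(up_a, up_a_rev)
    score_b = np.minimum(up_b, up_b_rev)
    direction = np.where(
        sel_a & (~sel_b | (score_a >= score_b)),
        f"up_in_{la}",
        np.where(sel_b, f"up_in_{lb}", ""),
    )
    out["selected"] = sel_a | sel_b
    out["direction"] = direction
    return out


def reciprocal_select_groups(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    cutoff: float = 0.6,
    study: str | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: split an annotated matrix into the two groups."""
    mask_a = annot["group"] == group_a
    mask_b = annot["group"] == group_b
    if study is not None:
        mask_a &= annot["study"] == study
        mask_b &= annot["study"] == study
    cols_a = list(annot.index[mask_a])
    cols_b = list(annot.index[mask_b])
    if not cols_a or not cols_b:
        raise ValueError(f"groups {group_a!r}/{group_b!r} not both present in annotation")
    return reciprocal_select(
        expr[cols_a], expr[cols_b], fc_threshold=fc_threshold, cutoff=cutoff, labels=(group_a, group_b)
    )
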