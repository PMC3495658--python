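"""Gene set enrichment analysis with a gene-set permutation null.

The engine follows the weighted Kolmogorov-Smirnov formulation: genes are
ranked by a differential statistic (signal-to-noise by default), a running
sum walks the ranked list incrementing at set members by their weighted
score share and decrementing at non-members by 1/(N - N_hits), and the
enrichment score (ES) is the signed maximum deviation from zero.  The null
distribution is obtained by *gene-set permutation*: random gene sets of the
same size drawn from the ranked universe (1000 draws by default).  The
normalised ES (NES) divides each ES by the mean magnitude of the same-sign
null ES of its set, nominal p-values are side-matched one-sided null
frequencies, and the FDR q-value is the canonical NES-ratio estimate over
the pooled null.  Significance defaults to nominal p < 0.05 and q < 0.25.

The leading edge of an enriched set — the members at or before the running
sum's peak (at or after it for negative ES) — is the core subset carrying
the enrichment signal and is attached to every result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from crestmeta.diffexp import benjamini_hochberg


@dataclass
class EnrichmentScore:
    """ES of one set on one ranked list, with its running-sum profile."""

    es: float
    running: np.ndarray
    peak_index: int


def rank_by_signal_to_noise(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    groups: tuple[str, str],
    metric: str = "s2n",
    study: str | None = None,
) -> pd.Series:
    """Rank genes by a two-group differential metric, descending.

    Positive scores mark genes higher in the *second* group of ``groups``
    (so swapping the pair negates every score).  Metrics:

    * ``s2n`` — signal-to-noise (difference of group means over the sum of
      group s.d.s, each s.d. floored at 0.2 x |group mean|, or 0.2 when the
      mean is 0); needs >= 3 samples per group.
    * ``tstat`` — equal-variance t statistic.
    * ``log2_ratio`` — difference of log2 group means.

    Ties are broken by gene ID so the ranking is deterministic.
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

    a = expr[_cols(ga)].to_numpy(dtype=float)
    b = expr[_cols(gb)].to_numpy(dtype=float)

    if metric == "s2n":
        if a.shape[1] < 3 or b.shape[1] < 3:
            raise ValueError(
                "signal-to-noise needs >= 3 samples per group; use metric='tstat' for smaller groups"
            )
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        sa, sb = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
        floor_a = np.where(np.abs(ma) > 0, 0.2 * np.abs(ma), 0.2)
        floor_b = np.where(np.abs(mb) > 0, 0.2 * np.abs(mb), 0.2)
        scores = (mb - ma) / (np.maximum(sa, floor_a) + np.maximum(sb, floor_b))
    elif metric == "tstat":
        res = stats.ttest_ind(b, a, axis=1)
        scores = np.nan_to_num(np.asarray(res.statistic, dtype=float))
    elif metric == "log2_ratio":
        scores = b.mean(axis=1) - a.mean(axis=1)
    else:
        raise ValueError("metric must be 's2n', 'tstat' or 'log2_ratio'")

    s = pd.Series(scores, index=expr.index, name=metric)
    order = np.lexsort((s.index.to_numpy(), -s.to_numpy()))  # descending score, gene ID on ties
    return s.iloc[order]


def _hit_positions(ranked: pd.Series, gene_set: list[str] | set[str]) -> np.ndarray:
    pos_of = {g: i for i, g in enumerate(ranked.index)}
    return np.array(sorted(pos_of[g] for g in set(gene_set) if g in pos_of), dtype=int)


def _es_from_positions(abs_w: np.ndarray, positions: np.ndarray, n: int) -> float:
    """ES evaluated only at hit positions (used for permutation nulls)."""
    k = positions.size
    w = abs_w[positions]
    total = w.sum()
    if total <= 0:
        w = np.full(k, 1.0 / k)
        total = 1.0
    cum = np.cumsum(w) / total
    miss = (positions - np.arange(k)) / (n - k)
    after = cum - miss
    before = np.concatenate(([0.0], cum[:-1])) - miss
    hi = after.max()
    lo = before.min()
    return float(hi if hi >= -lo else lo)


def enrichment_score(
    ranked: pd.Series, gene_set: list[str] | set[str], weight: float = 1.0
) -> EnrichmentScore:
    """Weighted KS running-sum enrichment score of one set.

    Hits increment the running sum by ``|score|**weight`` normalised over
    the hits; misses decrement by ``1/(N - N_hits)``.  The ES is the signed
    maximum deviation from zero and the peak index is where it is attained
    (the first such position on exact ties).  The set must intersect the
    ranked list and must not cover it entirely.
    """
    n = len(ranked)
    positions = _hit_positions(ranked, gene_set)
    if positions.size == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if positions.size == n:
        raise ValueError("gene set covers the entire ranked list (miss step undefined)")

    hit = np.zeros(n, dtype=bool)
    hit[positions] = True
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    w = np.where(hit, abs_w, 0.0)
    total = w.sum()
    if total <= 0:
        w = hit / hit.sum()
        total = 1.0
    running = np.cumsum(w) / total - np.cumsum(~hit) / (n - positions.size)
    peak = int(np.argmax(np.abs(running)))
    return EnrichmentScore(es=float(running[peak]), running=running, peak_index=peak)


def leading_edge(ranked: pd.Series, gene_set: list[str] | set[str], es_result: EnrichmentScore) -> list[str]:
    """Core members of a set: at/before the ES peak (at/after for ES < 0).

    Returned in ranked-list order, always a subset of the set.
    """
    positions = _hit_positions(ranked, gene_set)
    if es_result.es >= 0:
        keep = positions[positions <= es_result.peak_index]
    else:
        keep = positions[positions >= es_result.peak_index]
    return [ranked.index[i] for i in keep]


def gene_set_permutation_test(
    ranked: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    alpha: float = 0.05,
    q_threshold: float = 0.25,
    min_size: int = 3,
) -> pd.DataFrame:
    """GSEA over a collection of sets with a gene-set permutation null.

    For each set the null ES distribution comes from ``n_perm`` random gene
    sets of the same size drawn from the ranked universe (nulls are shared
    between sets of equal size).  Nominal p is the side-matched one-sided
    null frequency (never reported as 0: floored at 1/n_perm); NES divides
    the ES by the mean |null ES| of the same sign; q is the canonical
    NES-ratio FDR estimate; ``significant`` requires nominal p < ``alpha``
    and q < ``q_threshold``.  Sets smaller than ``min_size`` after
    restriction to measured genes are skipped with a warning.  Fully
    deterministic for a given seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    n = len(ranked)
    abs_w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng(seed)

    usable: list[tuple[str, np.ndarray]] = []
    for name, members in sets.items():
        positions = _hit_positions(ranked, members)
        if positions.size < min_size:
            warnings.warn(f"set {name!r}: only {positions.size} members measured (< {min_size}); skipped")
            continue
        if positions.size == n:
            warnings.warn(f"set {name!r} covers the whole ranked list; skipped")
            continue
        usable.append((name, positions))

    null_by_size: dict[int, np.ndarray] = {}
    for _name, positions in usable:
        k = positions.size
        if k not in null_by_size:
            null = np.empty(n_perm)
            for r in range(n_perm):
                draw = np.sort(rng.choice(n, size=k, replace=False))
                null[r] = _es_from_positions(abs_w, draw, n)
            null_by_size[k] = null

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, positions in usable:
        es_res = enrichment_score(ranked, [ranked.index[i] for i in positions], weight=weight)
        es = es_res.es
        null = null_by_size[positions.size]
        same_side = null[null >= 0] if es >= 0 else null[null < 0]
        if same_side.size == 0:
            p = 1.0 / n_perm
            nes = np.nan
        else:
            count = int((same_side >= es).sum()) if es >= 0 else int((same_side <= es).sum())
            p = max(count / same_side.size, 1.0 / n_perm)
            nes = es / np.abs(same_side).mean()
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes_pool.append(nn[np.isfinite(nn)])
        le = leading_edge(ranked, [ranked.index[i] for i in positions], es_res)
        rows.append(
            {
                "set": name,
                "size": positions.size,
                "es": es,
                "nes": nes,
                "p": p,
                "peak_index": es_res.peak_index,
                "leading_edge": le,
            }
        )

    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out

    pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs = out["nes"].to_numpy(dtype=float)
    q = np.full(len(out), np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac_denom = (pooled >= 0).sum()
            null_frac = (pooled >= nes).sum() / null_frac_denom if null_frac_denom else 1.0
            obs_denom = (obs >= 0).sum()
            obs_frac = (obs >= nes).sum() / obs_denom if obs_denom else 1.0
        else:
            null_frac_denom = (pooled < 0).sum()
            null_frac = (pooled <= nes).sum() / null_frac_denom if null_frac_denom else 1.0
            obs_denom = (obs < 0).sum()
            obs_frac = (obs <= nes).sum() / obs_denom if obs_denom else 1.0
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    out["q"] = q
    out["significant"] = (out["p"] < alpha) & (out["q"] < q_threshold)
    return out.set_index("set")


def cytogenetic_overlap(results: pd.DataFrame, aberrations: pd.DataFrame) -> pd.DataFrame:
    """Match enriched positional sets against known chromosomal aberrations.

    ``aberrations`` needs columns ``region`` (labels in the positional GMT
    naming scheme) and ``direction`` (``gain`` or ``loss``).  A region is
    reported when its set is significant and direction-concordant: gains
    must show positive ES (genes of the band up), losses negative ES.
    """
    cols = ["region", "direction", "es", "nes", "p", "q", "leading_edge"]
    if aberrations.empty:
        return pd.DataFrame(columns=cols)
    if not {"region", "direction"}.issubset(aberrations.columns):
        raise ValueError("aberration list needs 'region' and 'direction' columns")
    bad = set(aberrations["direction"]) - {"gain", "loss"}
    if bad:
        raise ValueError(f"aberration direction must be 'gain' or 'loss', got {sorted(bad)}")

    overlap = set(aberrations["region"]) & set(results.index)
    if not overlap:
        warnings.warn("no aberration label matches any enriched set name")
        return pd.DataFrame(columns=cols)

    rows = []
    for _, ab in aberrations.iterrows():
        region = ab["region"]
        if region not in results.index:
            continue
        r = results.loc[region]
        if not bool(r["significant"]):
            continue
        concordant = (ab["direction"] == "gain" and r["es"] > 0) or (
            ab["direction"] == "loss" and r["es"] < 0
        )
        if not concordant:
            continue
        rows.append(
            {
                "region": region,
                "direction": ab["direction"],
                "es": r["es"],
                "nes": r["nes"],
                "p": r["p"],
                "q": r["q"],
                "leading_edge": list(r["leading_edge"]),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def fisher_ora(
    gene_list: list[str] | set[str],
    universe: list[str] | set[str],
    sets: dict[str, list[str]],
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of a gene list in each set.

    A generic pathway over-representation step (the open counterpart of
    commercial pathway tools): for every set, tests whether the list hits
    it more often than expected under hypergeometric sampling from the
    universe, with BH correction across sets.
    """
    universe = set(universe)
    gene_list = set(gene_list) & universe
    if not set(gene_list) <= universe:
        raise ValueError("gene list must be a subset of the universe")

    rows = []
    for name, members in sets.items():
        members = set(members) & universe
        a = len(gene_list & members)
        b = len(gene_list - members)
        c = len(members - gene_list)
        d = len(universe) - a - b - c
        if len(gene_list) == 0:
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"set": name, "n_overlap": a, "set_size": len(members), "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
    return out
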