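"""Synthetic multi-study expression data with planted ground truth.

The generator emulates the statistical structure of a multi-platform tumour
microarray compendium: log2-scale intensities with gene-specific baselines,
group-specific fold changes for planted differentially expressed (DE) genes,
low-variance planted "stable" (reference-like) genes, additive per-platform
intensity shifts, optional floor-intensity (unexpressed) genes, and miRNA
profiles whose planted target genes are inversely coupled to them.  Every
planted feature is reported in a :class:`GroundTruth` object so downstream
stages (differential expression, Shapley selection, reference-gene screen,
GSEA, miRNA integration) can be scored against a known answer.

Scales
------
Expression values are Gaussian on the log2 scale (lognormal linear
intensities), the usual working scale for single-channel microarray data
after normalisation.  A planted effect of ``de_log2fc`` log2 units is a
``2**de_log2fc``-fold change on the linear scale, so any ``de_log2fc >= 1``
clears a 2-fold filter in expectation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from crestmeta import io


class ConfigError(ValueError):
    """Raised when a simulation configuration violates a field constraint."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic compendium.

    Parameters
    ----------
    n_genes:
        Total number of genes.  Planted genes (DE, stable, floor, miRNA
        targets) are carved out of this total; the remainder are background
        noise genes.
    n_groups:
        Number of sample groups (tumour subtypes); at least 2.
    samples_per_group:
        Samples per group in every study.
    n_de_genes:
        Planted DE genes *per unordered group pair*.
    de_log2fc:
        Planted effect size in log2 units (>= 1, i.e. >= 2-fold).
    n_stable_genes:
        Planted reference-like genes: high baseline, low variance, no group
        effect.
    stable_cv_max:
        Upper bound on the linear-scale coefficient of variation the stable
        genes are generated to respect (their noise s.d. is set to half the
        log-scale equivalent of this bound).
    baseline_mean, baseline_sd:
        Mean log2 intensity of the gene population and the within-gene
        residual s.d. of a background gene.  The default of 0.5 log2 units
        matches the residual within-subtype variability of normalized
        single-channel arrays for the bulk of genes; with it, a null
        sample exceeds 2-fold of the opposite group's mean only ~2-3% of
        the time, as on real null data.
    between_gene_sd:
        Spread of gene-specific baselines around ``baseline_mean`` (log2).
        Microarray intensity distributions span several log2 units; 2.0
        reproduces that spread and makes the 20th-percentile presence
        criterion of the reference-gene screen meaningful.
    platform_shift_sd:
        S.d. of the additive per-platform, per-gene shift (drawn once per
        platform), emulating systematic cross-platform offsets.
    n_studies:
        Number of independent studies; each study gets its own platform
        label and its own samples, while the planted biology (which genes
        are DE, in which direction) is shared.
    n_floor_genes:
        Genes planted at floor intensity (far below the 20th percentile) to
        exercise the unexpressed-mRNA filter.
    n_mirnas, targets_per_mirna, mirna_coupling:
        miRNA layer: number of profiled miRNAs, planted targets per miRNA,
        and the fraction of each target's variance explained (with inverted
        sign) by its regulating miRNA.
    mirna_de_log2fc:
        Group effect planted on each miRNA (applied in the last group,
        alternating up/down across miRNAs) so that miRNA differential
        expression and inverse-target selection are exercisable end to end.
    seed:
        Master seed; identical configs reproduce outputs bit for bit.
    """

    n_genes: int = 1000
    n_groups: int = 2
    samples_per_group: int = 20
    n_de_genes: int = 50
    de_log2fc: float = 3.0
    n_stable_genes: int = 50
    stable_cv_max: float = 0.2
    baseline_mean: float = 8.0
    baseline_sd: float = 0.5
    platform_shift_sd: float = 0.5
    n_mirnas: int = 0
    targets_per_mirna: int = 0
    mirna_coupling: float = 0.9
    mirna_de_log2fc: float = 2.0
    n_studies: int = 1
    n_floor_genes: int = 0
    between_gene_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be a positive integer")
        if self.n_groups < 2:
            raise ConfigError("n_groups must be >= 2")
        if self.samples_per_group < 1:
            raise ConfigError("samples_per_group must be a positive integer")
        if self.n_de_genes < 0:
            raise ConfigError("n_de_genes must be >= 0")
        if self.n_de_genes > 0 and self.de_log2fc < 1:
            raise ConfigError("de_log2fc must be >= 1 (at least 2-fold) so planted genes clear the fold filter")
        if self.n_stable_genes < 0:
            raise ConfigError("n_stable_genes must be >= 0")
        if not (0 < self.stable_cv_max < 0.3):
            raise ConfigError("stable_cv_max must lie in (0, 0.3)")
        if self.baseline_sd <= 0:
            raise ConfigError("baseline_sd must be > 0")
        if self.platform_shift_sd < 0:
            raise ConfigError("platform_shift_sd must be >= 0")
        if self.n_mirnas < 0 or self.targets_per_mirna < 0:
            raise ConfigError("n_mirnas and targets_per_mirna must be >= 0")
        if not (0 <= self.mirna_coupling <= 1):
            raise ConfigError("mirna_coupling must lie in [0, 1]")
        if self.n_studies < 1:
            raise ConfigError("n_studies must be a positive integer")
        if self.n_floor_genes < 0:
            raise ConfigError("n_floor_genes must be >= 0")
        n_pairs = self.n_groups * (self.n_groups - 1) // 2
        planted = (
            self.n_de_genes * n_pairs
            + self.n_stable_genes
            + self.n_floor_genes
            + self.n_mirnas * self.targets_per_mirna
        )
        if planted > self.n_genes:
            raise ConfigError(
                f"n_genes too small: {planted} planted genes "
                f"(n_de_genes x {n_pairs} pairs + n_stable_genes + n_floor_genes + miRNA targets) "
                f"exceed n_genes={self.n_genes}"
            )

    @property
    def group_labels(self) -> list[str]:
        return [f"grp{i + 1}" for i in range(self.n_groups)]

    @property
    def group_pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.group_labels, 2))


@dataclass
class GroundTruth:
    """Planted features of one simulated compendium.

    ``de_genes`` maps each unordered group pair (a, b) to its planted genes
    with direction relative to the *second* group: ``up`` means higher in b.
    """

    de_genes: dict[tuple[str, str], list[tuple[str, str]]] = field(default_factory=dict)
    stable_genes: list[str] = field(default_factory=list)
    floor_genes: list[str] = field(default_factory=list)
    mirna_targets: dict[str, list[str]] = field(default_factory=dict)
    mirna_directions: dict[str, str] = field(default_factory=dict)
    platform_of_sample: dict[str, str] = field(default_factory=dict)

    def all_de_gene_ids(self) -> set[str]:
        return {g for genes in self.de_genes.values() for g, _ in genes}


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _stable_log2_sd(cv_max: float) -> float:
    # linear CV of a lognormal: sqrt(exp(s_ln^2) - 1) with s_ln = s_log2 * ln 2;
    # target half the admissible CV so sampling noise stays inside the bound
    target_cv = cv_max / 2.0
    s_ln = np.sqrt(np.log1p(target_cv**2))
    return float(s_ln / np.log(2.0))


def simulate_expression(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a gene-by-sample log2 expression matrix with planted truth.

    Returns ``(expr, annot, truth)`` where ``expr`` has one row per gene and
    ``n_studies * n_groups * samples_per_group`` columns, ``annot`` maps each
    sample to its group/study/platform, and ``truth`` records every planted
    feature.  Identical configs (including the seed) reproduce the output
    bit for bit.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    genes = _gene_ids(config.n_genes)
    groups = config.group_labels
    pairs = config.group_pairs

    # gene-specific baselines; planted stable genes re-anchored high so the
    # presence criterion of the reference screen is about variance, not level
    mu = config.baseline_mean + config.between_gene_sd * rng.standard_normal(config.n_genes)

    truth = GroundTruth()
    cursor = 0
    de_effect = np.zeros((config.n_genes, config.n_groups))  # log2 shift per group
    for a, b in pairs:
        planted: list[tuple[str, str]] = []
        n_up = (config.n_de_genes + 1) // 2
        for k in range(config.n_de_genes):
            g = cursor
            cursor += 1
            # contiguous direction blocks, so a positional band can coincide
            # with a planted gain (all up) or loss (all down)
            direction = "up" if k < n_up else "down"
            sign = 1.0 if direction == "up" else -1.0
            # symmetric half-effects: the full de_log2fc separates exactly
            # the designated pair; any third group sits halfway
            de_effect[g, groups.index(a)] -= sign * config.de_log2fc / 2.0
            de_effect[g, groups.index(b)] += sign * config.de_log2fc / 2.0
            planted.append((genes[g], direction))
        truth.de_genes[(a, b)] = planted

    stable_idx = list(range(cursor, cursor + config.n_stable_genes))
    cursor += config.n_stable_genes
    truth.stable_genes = [genes[i] for i in stable_idx]
    mu[stable_idx] = config.baseline_mean + config.between_gene_sd + 0.25 * rng.standard_normal(len(stable_idx))

    floor_idx = list(range(cursor, cursor + config.n_floor_genes))
    cursor += config.n_floor_genes
    truth.floor_genes = [genes[i] for i in floor_idx]
    mu[floor_idx] = config.baseline_mean - 3.0 * config.between_gene_sd + 0.25 * rng.standard_normal(len(floor_idx))

    # reserve target genes now so their IDs are stable; coupling itself is
    # installed by simulate_mirna
    target_idx = list(range(cursor, cursor + config.n_mirnas * config.targets_per_mirna))

    noise_sd = np.full(config.n_genes, config.baseline_sd)
    if stable_idx:
        noise_sd[stable_idx] = _stable_log2_sd(config.stable_cv_max)
    if floor_idx:
        noise_sd[floor_idx] = 0.5 * config.baseline_sd

    columns: list[str] = []
    annot_rows: list[dict[str, str]] = []
    blocks: list[np.ndarray] = []
    for s in range(config.n_studies):
        study = f"study{s + 1}"
        platform = f"platform{s + 1}"
        shift = config.platform_shift_sd * rng.standard_normal(config.n_genes)
        for gi, group in enumerate(groups):
            n = config.samples_per_group
            base = mu + de_effect[:, gi] + shift
            block = base[:, None] + noise_sd[:, None] * rng.standard_normal((config.n_genes, n))
            blocks.append(block)
            for r in range(n):
                sample = f"{study}_{group}_s{r + 1:02d}"
                columns.append(sample)
                annot_rows.append({"sample": sample, "group": group, "study": study, "platform": platform})
                truth.platform_of_sample[sample] = platform

    expr = pd.DataFrame(np.hstack(blocks), index=pd.Index(genes, name="gene"), columns=columns)
    annot = pd.DataFrame(annot_rows).set_index("sample", drop=False)

    # stash reserved target slots for simulate_mirna
    truth._reserved_target_genes = [genes[i] for i in target_idx]  # type: ignore[attr-defined]
    return expr, annot, truth


def simulate_mirna(
    config: SimulationConfig, expr: pd.DataFrame, truth: GroundTruth
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate miRNA profiles and install the inverse coupling on targets.

    Each miRNA receives a planted group effect (``mirna_de_log2fc`` in the
    last group, alternating up/down across miRNAs) and a reserved block of
    target genes.  Each target row of ``expr`` is rewritten in place as

        target = baseline - sqrt(coupling) * standardized(miRNA) * sd + residual

    so the miRNA explains a ``mirna_coupling`` fraction of the target's
    variance with inverted sign, the mechanism a leading-edge inverse
    screen is designed to detect.  With ``n_mirnas == 0`` an empty matrix is
    returned and ``expr`` is untouched.
    """
    config.validate()
    if config.n_mirnas == 0:
        empty = pd.DataFrame(index=pd.Index([], name="mirna"), columns=expr.columns, dtype=float)
        return empty, truth

    rng = np.random.default_rng([config.seed, 1])
    samples = list(expr.columns)
    n_samples = len(samples)
    last_group = config.group_labels[-1]
    in_last = np.array([s.split("_")[1] == last_group for s in samples])

    mirna_ids = [f"miR-{i + 1:03d}" for i in range(config.n_mirnas)]
    reserved: list[str] = getattr(truth, "_reserved_target_genes", [])
    mat = np.empty((config.n_mirnas, n_samples))
    for i, mid in enumerate(mirna_ids):
        direction = "up" if i % 2 == 0 else "down"
        sign = 1.0 if direction == "up" else -1.0
        base = config.baseline_mean + config.between_gene_sd * rng.standard_normal()
        row = base + config.baseline_sd * rng.standard_normal(n_samples)
        row = row + sign * config.mirna_de_log2fc * in_last
        mat[i] = row
        truth.mirna_directions[mid] = direction

        lo = i * config.targets_per_mirna
        targets = reserved[lo : lo + config.targets_per_mirna]
        truth.mirna_targets[mid] = list(targets)
        if targets and config.mirna_coupling >= 0:
            z = (row - row.mean()) / max(row.std(), 1e-12)
            c = config.mirna_coupling
            for t in targets:
                baseline = float(expr.loc[t].mean())
                resid = rng.standard_normal(n_samples)
                expr.loc[t] = baseline + config.baseline_sd * (
                    -np.sqrt(c) * z + np.sqrt(1.0 - c) * resid
                )

    mirna_expr = pd.DataFrame(mat, index=pd.Index(mirna_ids, name="mirna"), columns=samples)
    return mirna_expr, truth


def positional_sets(genes: list[str], band_size: int = 50) -> dict[str, list[str]]:
    """Partition genes into contiguous pseudo-cytoband sets (chr1p, chr1q, ...)."""
    sets: dict[str, list[str]] = {}
    chrom, arm = 1, "p"
    for start in range(0, len(genes), band_size):
        sets[f"chr{chrom}{arm}"] = genes[start : start + band_size]
        if arm == "p":
            arm = "q"
        else:
            arm, chrom = "p", chrom + 1
    return sets


def ground_truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Flatten a GroundTruth into a (entity, role, partner, direction) table."""
    rows = []
    for (a, b), genes in truth.de_genes.items():
        for g, d in genes:
            rows.append({"entity": g, "role": "de_gene", "partner": f"{a}|{b}", "direction": d})
    for g in truth.stable_genes:
        rows.append({"entity": g, "role": "stable_gene", "partner": "", "direction": ""})
    for g in truth.floor_genes:
        rows.append({"entity": g, "role": "floor_gene", "partner": "", "direction": ""})
    for m, targets in truth.mirna_targets.items():
        for t in targets:
            rows.append({"entity": m, "role": "mirna_target", "partner": t,
                         "direction": truth.mirna_directions.get(m, "")})
    for s, p in truth.platform_of_sample.items():
        rows.append({"entity": s, "role": "sample_platform", "partner": p, "direction": ""})
    return pd.DataFrame(rows, columns=["entity", "role", "partner", "direction"])


def write_fixture_bundle(outdir: str | Path, config: SimulationConfig, band_size: int = 50) -> dict:
    """Simulate one compendium and write every artefact to ``outdir``.

    Writes the expression TSV, annotation TSV, miRNA TSV, positional GMT
    (a partition of all genes into pseudo-cytobands), per-miRNA target GMT
    when miRNAs are simulated, a flat ground-truth TSV, and a JSON manifest
    with a sha256 checksum per file.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, annot, truth = simulate_expression(config)
    mirna_expr, truth = simulate_mirna(config, expr, truth)

    files: dict[str, str] = {}

    def _register(name: str) -> None:
        files[name] = io.sha256_of(outdir / name)

    io.write_expression(expr, outdir / "expression.tsv")
    _register("expression.tsv")
    io.write_annotation(annot, outdir / "annotation.tsv")
    _register("annotation.tsv")
    mirna_expr.to_csv(outdir / "mirna.tsv", sep="\t", index_label="mirna", float_format="%.6f")
    _register("mirna.tsv")
    io.write_gmt(positional_sets(list(expr.index), band_size), outdir / "positional.gmt", description="pseudo-cytoband")
    _register("positional.gmt")
    if truth.mirna_targets:
        io.write_gmt(
            {f"targets_{m}": t for m, t in truth.mirna_targets.items() if t},
            outdir / "mirna_targets.gmt",
            description="planted targets",
        )
        _register("mirna_targets.gmt")
    ground_truth_table(truth).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    _register("ground_truth.tsv")

    manifest = {"config": asdict(config), "files": files}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
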