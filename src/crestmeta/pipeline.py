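"""End-to-end pipeline orchestration from a single YAML configuration.

A run executes the analysis stages in dependency order — simulate (or load)
-> differential expression -> Shapley selection -> reference genes -> GSEA
-> miRNA integration -> clustering — writing every stage's outputs as
tab-separated text plus a JSON manifest with per-file sha256 checksums and
row counts.  All randomness flows from the single top-level seed through
per-stage derived seeds, so re-running an identical configuration
reproduces byte-identical outputs.

Configuration schema (YAML, all thresholds default to the analysis'
standard settings: 2-fold filter, BH alpha 0.05, Shapley cutoff 0.6, GSEA
p 0.05 / q 0.25, 1000 permutations)::

    seed: 7
    out: runs/demo
    simulation:            # either this block or explicit input paths
      n_genes: 600
      n_groups: 2
      samples_per_group: 20
      ...                  # any SimulationConfig field
    inputs:                # alternative to simulation
      expression: expr.tsv
      annotation: annot.tsv
      mirna: mirna.tsv          # optional
      gene_sets: sets.gmt       # optional; simulated runs use positional sets
      exclude: housekeeping.txt # optional
    comparison:
      group_a: grp1
      group_b: grp2
    thresholds:
      fc: 2.0
      alpha: 0.05
      shapley_cutoff: 0.6
      gsea_p: 0.05
      gsea_q: 0.25
    n_perm: 1000
    stages: [simulate, de, shapley, refgenes, gsea, mirna, cluster]
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from crestmeta import clustering, diffexp, game_theory, gsea, io, mirna, reference_genes, simulate

log = logging.getLogger("crestmeta")

ALL_STAGES = ["simulate", "de", "shapley", "refgenes", "gsea", "mirna", "cluster"]
DEFAULT_THRESHOLDS = {
    "fc": 2.0,
    "alpha": 0.05,
    "shapley_cutoff": 0.6,
    "gsea_p": 0.05,
    "gsea_q": 0.25,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    seed: int = 0
    out: str = "crestmeta_run"
    simulation: dict | None = None
    inputs: dict | None = None
    comparison: dict = field(default_factory=lambda: {"group_a": "grp1", "group_b": "grp2"})
    thresholds: dict = field(default_factory=dict)
    n_perm: int = 1000
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulation is None and not (self.inputs and self.inputs.get("expression")):
            raise ValueError("config needs either a 'simulation' block or inputs.expression")
        if self.simulation is not None and self.inputs is not None:
            raise ValueError("give either 'simulation' or 'inputs', not both")
        thr = {**DEFAULT_THRESHOLDS, **self.thresholds}
        if thr["fc"] <= 1:
            raise ValueError("thresholds.fc must be > 1")
        if not (0 < thr["alpha"] < 1):
            raise ValueError("thresholds.alpha must lie in (0, 1)")
        if not (0 < thr["shapley_cutoff"] <= 1):
            raise ValueError("thresholds.shapley_cutoff must lie in (0, 1]")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        if self.inputs:
            for key, path in self.inputs.items():
                if key in ("expression", "annotation", "mirna", "gene_sets", "exclude") and path:
                    if not Path(path).exists():
                        raise ValueError(f"inputs.{key}: path does not exist: {path}")


def _stage_seed(seed: int, index: int) -> int:
    return (seed * 1000003 + 7919 * (index + 1)) % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    config.validate()
    thr = {**DEFAULT_THRESHOLDS, **config.thresholds}
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "thresholds": thr, "stages": {}}

    def record(stage: str, name: str, rows: int | None = None) -> None:
        entry = manifest["stages"].setdefault(stage, {"files": {}})
        entry["files"][name] = {"sha256": io.sha256_of(outdir / name)}
        if rows is not None:
            entry["files"][name]["rows"] = rows

    # ---- acquire inputs -------------------------------------------------
    truth = None
    mirna_expr = None
    gene_sets = None
    exclude: list[str] = []
    try:
        if config.simulation is not None:
            sim_cfg = simulate.SimulationConfig(**{**config.simulation, "seed": _stage_seed(config.seed, 0)})
            if "simulate" in config.stages:
                log.info("stage simulate: writing fixture bundle")
                datadir = outdir / "data"
                simulate.write_fixture_bundle(datadir, sim_cfg)
                for f in sorted(p.name for p in datadir.iterdir()):
                    record("simulate", f"data/{f}")
            expr, annot, truth = simulate.simulate_expression(sim_cfg)
            mirna_expr, truth = simulate.simulate_mirna(sim_cfg, expr, truth)
            if mirna_expr.empty:
                mirna_expr = None
            gene_sets = simulate.positional_sets(list(expr.index))
        else:
            inp = config.inputs or {}
            expr = io.read_expression(inp["expression"])
            annot = io.read_annotation(inp["annotation"])
            if inp.get("mirna"):
                mirna_expr = io.read_expression(inp["mirna"])
            if inp.get("gene_sets"):
                gene_sets = io.read_gmt(inp["gene_sets"])
            if inp.get("exclude"):
                exclude = io.read_gene_list(inp["exclude"])
    except Exception as exc:  # noqa: BLE001 - fail with stage context
        raise PipelineError(f"stage input acquisition failed: {exc}") from exc

    ga = config.comparison.get("group_a", "grp1")
    gb = config.comparison.get("group_b", "grp2")
    spec = diffexp.ComparisonSpec(group_a=ga, group_b=gb, fc_threshold=thr["fc"], alpha=thr["alpha"])

    ranked = None
    for stage in [s for s in config.stages if s != "simulate"]:
        log.info("stage %s", stage)
        try:
            if stage == "de":
                studies = sorted(set(annot["study"]))
                per_study = []
                for study in studies:
                    res = diffexp.two_group_test(
                        expr[annot.index[annot["study"] == study]],
                        annot[annot["study"] == study],
                        spec,
                    )
                    name = f"de_{study}_{ga}_vs_{gb}.tsv"
                    res.to_csv(outdir / name, sep="\t", float_format="%.6g")
                    record("de", name, len(res))
                    per_study.append(res)
                if len(per_study) > 1:
                    inter = diffexp.intersect_studies(per_study, min_studies=2)
                    inter.to_csv(outdir / "intersection.tsv", sep="\t", float_format="%.6g")
                    record("de", "intersection.tsv", len(inter))
            elif stage == "shapley":
                sel = game_theory.reciprocal_select_groups(
                    expr, annot, ga, gb, fc_threshold=thr["fc"], cutoff=thr["shapley_cutoff"]
                )
                sel.to_csv(outdir / "shapley.tsv", sep="\t", float_format="%.6g")
                record("shapley", "shapley.tsv", len(sel))
            elif stage == "refgenes":
                ref = reference_genes.find_stable_genes(expr, annot, (ga, gb), exclude=exclude)
                ref.to_csv(outdir / "refgenes.tsv", sep="\t", float_format="%.6g")
                record("refgenes", "refgenes.tsv", len(ref))
            elif stage == "gsea":
                if gene_sets is None:
                    log.warning("no gene sets supplied; skipping gsea stage")
                    continue
                ranked = gsea.rank_by_signal_to_noise(expr, annot, (ga, gb))
                enr = gsea.gene_set_permutation_test(
                    ranked,
                    gene_sets,
                    n_perm=config.n_perm,
                    seed=_stage_seed(config.seed, 4),
                    alpha=thr["gsea_p"],
                    q_threshold=thr["gsea_q"],
                )
                flat = enr.copy()
                flat["leading_edge"] = flat["leading_edge"].map(",".join)
                flat.to_csv(outdir / "gsea.tsv", sep="\t", float_format="%.6g")
                record("gsea", "gsea.tsv", len(flat))
                le_sets = {
                    name: list(enr.loc[name, "leading_edge"])
                    for name in enr.index[enr["significant"]]
                    if enr.loc[name, "leading_edge"]
                }
                if le_sets:
                    io.write_gmt(le_sets, outdir / "leading_edge.gmt", description="leading edge")
                    record("gsea", "leading_edge.gmt", len(le_sets))
            elif stage == "mirna":
                if mirna_expr is None:
                    log.warning("no miRNA matrix supplied; skipping mirna stage")
                    continue
                if ranked is None:
                    ranked = gsea.rank_by_signal_to_noise(expr, annot, (ga, gb))
                de_m = mirna.mirna_de(mirna_expr, annot, [ga, gb], alpha=thr["alpha"])[(ga, gb)]
                if truth is not None:
                    targets: dict[str, list[str]] = {m: t for m, t in truth.mirna_targets.items() if t}
                else:
                    targets = {}
                targets = mirna.filter_unexpressed(targets, expr, annot, (ga, gb)) if targets else {}
                pairs = mirna.inverse_target_selection(
                    ranked,
                    de_m,
                    targets,
                    n_perm=config.n_perm,
                    seed=_stage_seed(config.seed, 5),
                    alpha=thr["gsea_p"],
                    q_threshold=thr["gsea_q"],
                )
                pairs.to_csv(outdir / "mirna_pairs.tsv", sep="\t", index=False, float_format="%.6g")
                record("mirna", "mirna_pairs.tsv", len(pairs))
            elif stage == "cluster":
                profiles = clustering.group_average(expr, annot)
                tree = clustering.hcluster(profiles, metric="euclidean")
                (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
                record("cluster", "tree.nwk")
                tree.merge_table().to_csv(outdir / "merges.tsv", sep="\t", index=False, float_format="%.6g")
                record("cluster", "merges.tsv", len(tree.merge_table()))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
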