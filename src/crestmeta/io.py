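"""Readers and writers for the plain-text formats used throughout the package.

Conventions
-----------
* Expression matrices are tab-separated text, one row per gene (or miRNA),
  one column per sample, a single header row of sample IDs and the feature
  ID in the first column.  Values are log2-scale intensities.
* Sample annotations are tab-separated with columns ``sample``, ``group``,
  ``study``, ``platform``.
* Gene sets use the GMT convention: set name, description, then the member
  IDs, all tab-separated on one line.
* miRNA target-prediction exports are two-column TSV (miRNA ID, target gene
  ID), one file per source database.

All loaders return plain pandas objects; there is deliberately no wrapper
class around the expression matrix — a DataFrame with genes in the index is
the package's working container.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

ANNOTATION_COLUMNS = ["sample", "group", "study", "platform"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample log2 expression matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label=expr.index.name or "gene", float_format="%.6f")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (sample, group, study, platform)."""
    annot = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample", "group") if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation file {path} lacks required column(s): {missing}")
    for col in ("study", "platform"):
        if col not in annot.columns:
            annot[col] = "study1" if col == "study" else "platform1"
    return annot.set_index("sample", drop=False)


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.reset_index(drop=True)[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into an ordered mapping name -> member list."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 member): {line[:80]!r}")
            name, _desc, *members = fields
            sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_target_table(path: str | Path, source: str) -> pd.DataFrame:
    """Read a two-column (miRNA, target gene) prediction export.

    Returns a DataFrame with columns mirna/target/source, duplicate
    (miRNA, gene) rows within the file collapsed to one.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna", "target"], dtype=str, comment="#")
    df = df.drop_duplicates()
    df["source"] = source
    return df.reset_index(drop=True)


def read_rnk(path: str | Path) -> pd.Series:
    """Read a two-column ranked-list file (gene, score) sorted descending."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], comment="#", dtype={0: str})
    s = pd.Series(df["score"].astype(float).values, index=df["gene"].astype(str))
    return s.sort_values(ascending=False, kind="stable")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
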