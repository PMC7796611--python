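"""Readers and writers for on-disk pipeline artifacts.

Formats are deliberately plain: counts and lengths as TSV, metadata as
CSV, gene sets as GMT.  Readers validate strictly and never drop rows
silently; every malformed record raises with enough context to locate it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .containers import CountMatrix, ValidationError, validate_metadata


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column TSV ``gene_id\\tlength_bp`` into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValidationError(
            f"{path}: gene-length file must have exactly 2 columns, got {df.shape[1]}"
        )
    df.columns = ["gene_id", "length_bp"]
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene ID {dup!r} in lengths file")
    return pd.Series(
        df["length_bp"].to_numpy(dtype=float),
        index=pd.Index(df["gene_id"].astype(str), name="gene_id"),
        name="length_bp",
    )


def read_count_matrix(path, lengths_path=None) -> CountMatrix:
    """Read a gene x sample TSV count matrix (header row of sample IDs,
    first column gene IDs), optionally with a gene-lengths TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene ID {dup!r}")
    lengths: Optional[pd.Series] = None
    if lengths_path is not None:
        lengths = read_gene_lengths(lengths_path)
        missing = df.index.difference(lengths.index)
        if len(missing):
            raise ValidationError(
                f"{lengths_path}: lengths missing for genes {missing[:5].tolist()}"
            )
        lengths = lengths.reindex(df.index)
    return CountMatrix(df, lengths)


def write_count_matrix(cm: CountMatrix, path, lengths_path=None) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    if lengths_path is not None:
        if cm.gene_lengths is None:
            raise ValidationError("count matrix carries no gene lengths to write")
        cm.gene_lengths.astype(int).to_csv(
            lengths_path, sep="\t", index_label="gene_id", header=["length_bp"]
        )


def read_sample_metadata(path) -> pd.DataFrame:
    """Read and validate the sample-metadata CSV.

    Required columns: sample_id, tissue, treatment ('untreated'/'ifng',
    case-insensitive).  Optional: pair_id, group.
    """
    meta = pd.read_csv(path, dtype=str)
    return validate_metadata(meta)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_gene_sets(path) -> dict[str, list[str]]:
    """Parse a GMT file: one gene set per line, ``name\\tdescription\\tgene...``.

    Duplicate members within a line are dropped (first occurrence kept);
    empty sets are rejected.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name = fields[0]
            members = [g for g in fields[2:] if g != ""]
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen = set()
            unique = []
            for g in members:
                if g not in seen:
                    seen.add(g)
                    unique.append(g)
            sets[name] = unique
    return sets


def write_gene_sets(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
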