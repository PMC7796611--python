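"""Core in-memory containers for the MSC variability pipeline.

Count and expression matrices are stored gene-by-sample (rows are genes,
columns are samples), the orientation of featureCounts-style output that
bulk RNA-seq pipelines consume.  All containers validate on construction
and are immutable by convention (methods return new objects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

TREATMENTS = ("untreated", "ifng")


class ValidationError(ValueError):
    """Raised when an input artifact violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dup = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup[:5]}")


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample count matrix with optional gene lengths (bp)."""

    counts: pd.DataFrame  # genes x samples, integer
    gene_lengths: Optional[pd.Series] = None  # bp, indexed like counts

    def __post_init__(self):
        df = self.counts
        _check_unique(df.index, "gene IDs")
        _check_unique(df.columns, "sample IDs")
        vals = df.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("counts contain non-finite values")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            g, s = np.argwhere(vals != np.round(vals))[0]
            raise ValidationError(
                f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if self.gene_lengths is not None:
            gl = self.gene_lengths
            missing = df.index.difference(gl.index)
            if len(missing):
                raise ValidationError(
                    f"gene lengths missing for: {missing[:5].tolist()}"
                )
            gl = gl.reindex(df.index)
            if (gl.to_numpy() <= 0).any() or not np.isfinite(gl.to_numpy()).all():
                raise ValidationError("gene lengths must be positive and finite")
            object.__setattr__(self, "gene_lengths", gl.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes) -> "CountMatrix":
        gl = None if self.gene_lengths is None else self.gene_lengths.loc[genes]
        return CountMatrix(self.counts.loc[genes], gl)

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, samples], self.gene_lengths)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued gene x sample matrix tagged with its unit."""

    values: pd.DataFrame  # genes x samples
    unit: str  # "cpm" | "tpm" | "logcpm"

    _UNITS = ("cpm", "tpm", "logcpm")

    def __post_init__(self):
        if self.unit not in self._UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected {self._UNITS}")
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "sample IDs")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("expression values contain non-finite entries")
        if (vals < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def require_unit(self, unit: str) -> "ExpressionMatrix":
        if self.unit != unit:
            raise ValidationError(f"expected a {unit} matrix, got {self.unit}")
        return self


@dataclass(frozen=True)
class NormFactors:
    """Per-sample library sizes and TMM scale factors (geometric mean 1)."""

    table: pd.DataFrame  # index sample_id; columns library_size, tmm_factor

    def __post_init__(self):
        t = self.table
        for col in ("library_size", "tmm_factor"):
            if col not in t.columns:
                raise ValidationError(f"NormFactors table missing column {col!r}")
        if (t["library_size"].to_numpy() <= 0).any():
            raise ValidationError("library sizes must be positive")
        f = t["tmm_factor"].to_numpy(dtype=float)
        if (f <= 0).any():
            raise ValidationError("TMM factors must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    def effective_sizes(self) -> pd.Series:
        return self.table["library_size"] * self.table["tmm_factor"]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a sample-metadata table.

    Required columns: sample_id, tissue, treatment.  Optional: pair_id,
    group.  Treatment labels are case-insensitive on input and stored
    lowercase; only 'untreated' and 'ifng' are accepted.
    """
    required = {"sample_id", "tissue", "treatment"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.copy()
    _check_unique(meta["sample_id"], "sample IDs")
    meta["treatment"] = meta["treatment"].astype(str).str.lower()
    bad = sorted(set(meta["treatment"]) - set(TREATMENTS))
    if bad:
        raise ValidationError(
            f"unknown treatment values {bad}; expected one of {TREATMENTS}"
        )
    if "pair_id" in meta.columns:
        paired = meta[meta["pair_id"].notna() & (meta["pair_id"].astype(str) != "")]
        for pid, sub in paired.groupby("pair_id"):
            tr = sorted(sub["treatment"])
            if tr != ["ifng", "untreated"]:
                raise ValidationError(
                    f"pair_id {pid!r} must link exactly one untreated and one "
                    f"ifng sample; got treatments {tr}"
                )
    meta.index = pd.Index(meta["sample_id"], name="sample_id")
    return meta


def complete_pairs(meta: pd.DataFrame) -> pd.DataFrame:
    """Return rows belonging to complete untreated/ifng pairs."""
    if "pair_id" not in meta.columns:
        return meta.iloc[0:0]
    paired = meta[meta["pair_id"].notna() & (meta["pair_id"].astype(str) != "")]
    sizes = paired.groupby("pair_id")["sample_id"].count()
    keep = sizes[sizes == 2].index
    return paired[paired["pair_id"].isin(keep)]
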