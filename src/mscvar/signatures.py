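"""Potency signature logic.

From the licensing contrasts, genes partition into three sets: set1
(unique to the common response genes), set2 (shared between common and
different response genes), set3 (unique to the different response
genes).  The potency panel is the top-100 set2 genes by DM.  Two
read-outs follow:

* an immunosuppressive score for IFNγ-treated samples — the sum of
  log-normalized expression of seven licensing-associated genes (VEGF,
  IFNa, CXCL10, GCSF, CXCL9, IL-7, CCL2 in their common literature
  labels; mapped to canonical symbols via a configurable map);
* a PCA-quadrant classification of untreated samples on panel-gene
  expression, with the known low-potency reference group anchoring the
  third quadrant (PCA signs are arbitrary, so the orientation is fixed
  by requiring the reference centroid to have negative PC1 and PC2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import pca
from .containers import ExpressionMatrix, ValidationError

#: Literature labels of the seven score genes mapped to gene symbols.
DEFAULT_SCORE_GENE_MAP = {
    "VEGF": "VEGFA",
    "IFNa": "IFNA1",
    "CXCL10": "CXCL10",
    "GCSF": "CSF3",
    "CXCL9": "CXCL9",
    "IL-7": "IL7",
    "CCL2": "CCL2",
}


@dataclass(frozen=True)
class GeneSetPartition:
    set1: list[str]  # unique to CRGs
    set2: list[str]  # shared between CRGs and DRGs
    set3: list[str]  # unique to DRGs

    def __post_init__(self):
        s1, s2, s3 = map(set, (self.set1, self.set2, self.set3))
        if s1 & s2 or s1 & s3 or s2 & s3:
            raise ValidationError("partition sets must be pairwise disjoint")


@dataclass(frozen=True)
class PotencyResult:
    panel: list[str]
    coords: pd.DataFrame      # samples x (pc1, pc2)
    quadrant: pd.Series       # samples -> {1, 2, 3, 4}
    potency_call: pd.Series   # samples -> {"low", "other"}
    score: pd.Series | None = None
    parameters: dict = field(default_factory=dict)


def partition_gene_sets(
    crgs: list[str], drgs: list[str], dm_table: pd.DataFrame | None = None
) -> GeneSetPartition:
    """Split CRGs and DRGs into unique/shared sets.

    Ordering is by descending DM when a DM table is supplied, else
    lexicographic.
    """
    crg_set, drg_set = set(crgs), set(drgs)

    def _ordered(genes: set[str]) -> list[str]:
        if dm_table is not None:
            present = [g for g in genes if g in dm_table.index]
            absent = sorted(genes - set(present))
            ranked = sorted(
                present, key=lambda g: (-float(dm_table.loc[g, "dm"]), g)
            )
            return ranked + absent
        return sorted(genes)

    return GeneSetPartition(
        set1=_ordered(crg_set - drg_set),
        set2=_ordered(crg_set & drg_set),
        set3=_ordered(drg_set - crg_set),
    )


def derive_panel(
    partition: GeneSetPartition, dm_table: pd.DataFrame, n_panel: int = 100
) -> list[str]:
    """Top ``n_panel`` set2 genes by descending DM (ties by gene_id)."""
    if not partition.set2:
        raise ValidationError("set2 (CRGs ∩ DRGs) is empty; no panel derivable")
    missing = set(partition.set2) - set(dm_table.index)
    if missing:
        raise ValidationError(
            f"set2 genes absent from DM table: {sorted(missing)[:5]}"
        )
    ranked = sorted(
        partition.set2, key=lambda g: (-float(dm_table.loc[g, "dm"]), g)
    )
    if len(ranked) <= n_panel:
        if len(ranked) < n_panel:
            warnings.warn(
                f"set2 has only {len(ranked)} genes (< {n_panel}); using all"
            )
        return ranked
    return ranked[:n_panel]


def immunosuppressive_score(
    em: ExpressionMatrix,
    samples: list[str],
    score_genes: list[str] | None = None,
    gene_map: dict[str, str] | None = None,
) -> pd.Series:
    """Sum of log-normalized expression of the score genes per treated
    sample.  Missing genes contribute zero and are reported via warning."""
    em.require_unit("logcpm")
    if score_genes is None:
        gene_map = DEFAULT_SCORE_GENE_MAP if gene_map is None else gene_map
        score_genes = list(gene_map.values())
    present = [g for g in score_genes if g in em.values.index]
    missing = [g for g in score_genes if g not in em.values.index]
    if not present:
        raise ValidationError(f"none of the score genes found: {score_genes}")
    if missing:
        warnings.warn(f"score genes missing from matrix (contribute 0): {missing}")
    bad = set(samples) - set(em.sample_ids)
    if bad:
        raise ValidationError(f"samples absent from matrix: {sorted(bad)[:5]}")
    score = em.values.loc[present, samples].sum(axis=0)
    score.name = "immunosuppressive_score"
    return score


def _quadrant(pc1: np.ndarray, pc2: np.ndarray) -> np.ndarray:
    """Quadrant from signs: 1:+/+, 2:-/+, 3:-/-, 4:+/-.

    Coordinates exactly on an axis go to the lower quadrant index.
    """
    q = np.empty(len(pc1), dtype=int)
    pos1, pos2 = pc1 > 0, pc2 > 0
    q[pos1 & pos2] = 1
    q[~pos1 & pos2] = 2
    q[~pos1 & ~pos2] = 3
    q[pos1 & ~pos2] = 4
    # ties: pc==0 counts as non-positive, handled by the masks above;
    # 2 < 1 and 3 < 4, so an axis point lands on the lower index side
    return q


def quadrant_classify(
    em: ExpressionMatrix,
    panel: list[str],
    samples: list[str],
    reference: list[str],
) -> PotencyResult:
    """Classify untreated samples by oriented PCA quadrant of panel genes.

    PC1/PC2 signs are flipped so the reference-group centroid lies in the
    third quadrant (both coordinates negative); samples sharing that
    quadrant are called low-potency.
    """
    em.require_unit("logcpm")
    if not reference:
        raise ValidationError("reference sample set must be non-empty")
    if not set(reference) <= set(samples):
        raise ValidationError("reference must be a subset of samples")
    sub = ExpressionMatrix(em.values.loc[:, samples], "logcpm")
    n_pcs = min(2, len(samples), len(panel))
    if n_pcs < 2:
        raise ValidationError("need at least 2 samples and 2 panel genes")
    emb = pca(sub, genes=panel, n_pcs=2)
    coords = emb.coords.copy()
    centroid = coords.loc[reference].mean(axis=0)
    signs = []
    for pc in ("PC1", "PC2"):
        c = centroid[pc]
        if c == 0:
            raise ValidationError(
                "reference centroid lies exactly on a PCA axis; "
                "enlarge the reference set"
            )
        signs.append(-1.0 if c > 0 else 1.0)
    coords = coords * np.array(signs)
    q = _quadrant(coords["PC1"].to_numpy(), coords["PC2"].to_numpy())
    quadrant = pd.Series(q, index=coords.index, name="quadrant")
    call = pd.Series(
        np.where(q == 3, "low", "other"), index=coords.index, name="potency_call"
    )
    return PotencyResult(
        panel=list(panel),
        coords=coords.rename(columns={"PC1": "pc1", "PC2": "pc2"}),
        quadrant=quadrant,
        potency_call=call,
        parameters={"reference": list(reference), "orientation_signs": signs},
    )


def suppression_percentage(
    prolif_with_msc: float, prolif_positive_control: float
) -> float:
    """Co-culture suppression: 100 * (1 - proliferation with MSCs /
    positive-control proliferation).  May be negative if proliferation
    exceeds the control."""
    if prolif_positive_control == 0:
        raise ValidationError("positive-control proliferation must be non-zero")
    return 100.0 * (1.0 - prolif_with_msc / prolif_positive_control)
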