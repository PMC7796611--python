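"""Gene ranking and pre-ranked gene set enrichment analysis (GSEA).

Genes are ranked either by a significance-weighted effect size,
-log10(FDR) * log2 fold-change, or directly by DM.  Enrichment of a gene
set in a ranked list is the weighted Kolmogorov-Smirnov running-sum
statistic (weight exponent 1 on |score|); significance comes from
gene-label permutations with sign-matched normalization (NES) and a
add-one-corrected empirical p-value, BH-adjusted across sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ValidationError
from .diffexp import bh_adjust

FDR_FLOOR = 1e-300


def ranking_score(de_table: pd.DataFrame) -> pd.Series:
    """Rank genes by -log10(FDR) * log2 fold-change, descending."""
    for col in ("fdr", "log2fc"):
        if col not in de_table.columns:
            raise ValidationError(f"DE table missing column {col!r}")
    score = -np.log10(np.maximum(de_table["fdr"], FDR_FLOOR)) * de_table["log2fc"]
    return _sorted_ranks(score)


def ranked_by_dm(dm_table: pd.DataFrame) -> pd.Series:
    """Rank genes by DM, descending."""
    if "dm" not in dm_table.columns:
        raise ValidationError("DM table missing column 'dm'")
    return _sorted_ranks(dm_table["dm"])


def _sorted_ranks(score: pd.Series) -> pd.Series:
    if not np.isfinite(score.to_numpy(dtype=float)).all():
        raise ValidationError("ranking scores must be finite")
    order = np.lexsort((score.index, -score.to_numpy(dtype=float)))
    return score.iloc[order]


def enrichment_score(ranked: pd.Series, members: set[str]) -> float:
    """Weighted KS running-sum enrichment score of one gene set."""
    scores = np.abs(ranked.to_numpy(dtype=float))
    in_set = np.fromiter((g in members for g in ranked.index), bool, len(ranked))
    return _es_from_arrays(scores, in_set)


def _es_from_arrays(abs_scores: np.ndarray, in_set: np.ndarray) -> float:
    n_hit = int(in_set.sum())
    n = len(abs_scores)
    if n_hit == 0 or n_hit == n:
        raise ValidationError("gene set must be a proper, non-empty subset")
    hit_sum = abs_scores[in_set].sum()
    if hit_sum == 0:
        # all member scores zero: hits contribute uniform steps
        p_hit = np.cumsum(in_set) / n_hit
    else:
        p_hit = np.cumsum(np.where(in_set, abs_scores, 0.0)) / hit_sum
    p_miss = np.cumsum(~in_set) / (n - n_hit)
    running = p_hit - p_miss
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranked: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 300,
    seed: int = 1,
) -> pd.DataFrame:
    """Pre-ranked GSEA over named gene sets.

    Sets are restricted to genes present in the ranking; those outside
    [min_size, max_size] after restriction are dropped.  The null is
    gene-label permutation (random member draws of the same size); NES
    divides ES by the mean |null ES| of matching sign; p-values are
    sign-matched empirical with add-one correction, FDR-adjusted by BH.
    """
    universe = set(ranked.index)
    abs_scores = np.abs(ranked.to_numpy(dtype=float))
    n = len(ranked)
    gene_pos = {g: i for i, g in enumerate(ranked.index)}
    retained: list[tuple[str, np.ndarray]] = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in universe]
        if min_size <= len(present) <= max_size and len(present) < n:
            mask = np.zeros(n, dtype=bool)
            mask[[gene_pos[g] for g in present]] = True
            retained.append((name, mask))
    if not retained:
        warnings.warn("no gene sets survive the size filter")
        return pd.DataFrame(
            columns=["es", "nes", "pvalue", "fdr", "size"]
        ).rename_axis("set")
    rng = np.random.default_rng(seed)
    # group sets by size so permutation nulls are shared per size
    nulls_by_size: dict[int, np.ndarray] = {}
    for _, mask in retained:
        size = int(mask.sum())
        if size in nulls_by_size:
            continue
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            m = np.zeros(n, dtype=bool)
            m[idx] = True
            null_es[b] = _es_from_arrays(abs_scores, m)
        nulls_by_size[size] = null_es
    rows = []
    for name, mask in retained:
        size = int(mask.sum())
        es = _es_from_arrays(abs_scores, mask)
        null_es = nulls_by_size[size]
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        denom = np.abs(null_es[same_sign]).mean() if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        pvalue = (extreme + 1.0) / (n_same + 1.0)
        rows.append((name, es, nes, pvalue, size))
    out = pd.DataFrame(
        rows, columns=["set", "es", "nes", "pvalue", "size"]
    ).set_index("set")
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out[["es", "nes", "pvalue", "fdr", "size"]]
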