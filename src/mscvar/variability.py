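"""Distance-to-median (DM) expression-variability statistic.

The squared coefficient of variation of a gene's CPM across samples
depends strongly on its mean expression and, for count data, on gene
length.  DM removes both dependencies by taking residuals against rolling
window medians: genes are sorted by log10 mean CPM, partitioned into
overlapping windows, and each gene's log10 CV^2 is compared to the median
of its window(s); the same windowing against log10 gene length removes
the residual length trend.  Genes with DM > 1 (a tenfold excess of CV^2
over the typical gene of the same mean) are called highly variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError

DEFAULT_N_WINDOWS = 50
DEFAULT_OVERLAP = 25


def squared_cv(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean CPM and squared coefficient of variation (unbiased
    variance / mean^2) across samples.  Genes with zero mean are excluded
    with a warning (they cannot occur after expression filtering)."""
    em.require_unit("cpm")
    if len(em.sample_ids) < 2:
        raise ValidationError("CV^2 needs at least 2 samples")
    vals = em.values
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    zero = mean == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} gene(s) with zero mean CPM from CV^2"
        )
    out = pd.DataFrame({"mean_cpm": mean, "cv2": var / mean.pow(2)})
    return out[~zero]


def _window_bounds(n_items: int, n_windows: int, overlap: int):
    """Equal-width overlapping windows over ``n_items`` sorted items.

    Width w = round((G + overlap*(k-1))/k), step w - overlap; the last
    window absorbs the remainder.  Returns a list of (start, stop) pairs.
    """
    if n_windows < 1:
        raise ValidationError("n_windows must be >= 1")
    if n_items < n_windows:
        reduced = max(1, n_items // 2)
        warnings.warn(
            f"only {n_items} items for {n_windows} windows; reducing to {reduced}"
        )
        n_windows = reduced
        # the configured overlap may exceed what the reduced windows
        # allow; clamp it below the nominal window width
        overlap = min(overlap, max(0, -(-n_items // n_windows) - 1))
    w = int(round((n_items + overlap * (n_windows - 1)) / n_windows))
    w = max(w, 1)
    if n_windows > 1 and overlap >= w:
        raise ValidationError(f"overlap {overlap} must be smaller than window width {w}")
    step = w - overlap
    bounds = []
    for i in range(n_windows):
        start = i * step
        stop = start + w
        if i == n_windows - 1:
            stop = n_items
        bounds.append((start, min(stop, n_items)))
    return bounds


def rolling_median_residual(
    y: pd.Series,
    x: pd.Series,
    n_windows: int = DEFAULT_N_WINDOWS,
    overlap: int = DEFAULT_OVERLAP,
) -> pd.Series:
    """Residual of y against its rolling-window median along x.

    Items are sorted ascending by x (ties broken by index), split into
    ``n_windows`` overlapping windows; each item's expected value is the
    median of y over every window containing it (averaged when the item
    lies in an overlap), and the residual is y minus that expectation.
    """
    if not y.index.equals(x.index):
        raise ValidationError("y and x must be aligned on the same index")
    # stable sort on x with the index as secondary key for reproducibility
    order = (
        pd.DataFrame({"x": x, "y": y})
        .rename_axis("item")
        .reset_index()
        .sort_values(["x", "item"], kind="mergesort")
    )
    n = len(order)
    bounds = _window_bounds(n, n_windows, overlap)
    yv = order["y"].to_numpy(dtype=float)
    expected_sum = np.zeros(n)
    expected_cnt = np.zeros(n, dtype=int)
    for start, stop in bounds:
        med = np.median(yv[start:stop])
        expected_sum[start:stop] += med
        expected_cnt[start:stop] += 1
    expected = expected_sum / expected_cnt
    resid = pd.Series(yv - expected, index=order["item"])
    return resid.reindex(y.index)


@dataclass(frozen=True)
class DMResult:
    """DM table plus the flag recording whether lengths were available."""

    table: pd.DataFrame  # gene_id index; mean_cpm, cv2, resid_mean, dm, zero_cv2
    length_corrected: bool


def dm_statistic(
    em: ExpressionMatrix,
    gene_lengths: pd.Series | None = None,
    n_windows: int = DEFAULT_N_WINDOWS,
    overlap: int = DEFAULT_OVERLAP,
) -> DMResult:
    """Compute the DM statistic for every gene of a filtered CPM matrix.

    Steps: (1) CV^2 per gene; (2) mean-corrected residual of log10 CV^2
    vs log10 mean CPM via rolling medians; (3) if lengths are available,
    subtract the expected residual from log10 gene length using the same
    windowing.  Zero-CV^2 genes are excluded from the median fits and
    assigned a sentinel DM one unit below the dataset minimum.
    """
    stats = squared_cv(em)
    zero_cv2 = stats["cv2"] == 0
    work = stats[~zero_cv2]
    if len(work) == 0:
        raise ValidationError("no genes with positive CV^2")
    log_cv2 = np.log10(work["cv2"])
    log_mean = np.log10(work["mean_cpm"])
    resid_mean = rolling_median_residual(log_cv2, log_mean, n_windows, overlap)
    length_corrected = gene_lengths is not None
    if length_corrected:
        missing = work.index.difference(gene_lengths.index)
        if len(missing):
            raise ValidationError(
                f"gene lengths missing for {missing[:5].tolist()}"
            )
        log_len = np.log10(gene_lengths.reindex(work.index).astype(float))
        dm = rolling_median_residual(resid_mean, log_len, n_windows, overlap)
    else:
        warnings.warn("gene lengths absent; DM is the mean-corrected residual only")
        dm = resid_mean
    table = stats.copy()
    table["resid_mean"] = resid_mean.reindex(table.index)
    table["dm"] = dm.reindex(table.index)
    table["zero_cv2"] = zero_cv2
    if zero_cv2.any():
        sentinel = float(table.loc[~zero_cv2, "dm"].min()) - 1.0
        table.loc[zero_cv2, "dm"] = sentinel
        table.loc[zero_cv2, "resid_mean"] = sentinel
    table.index.name = "gene_id"
    return DMResult(table, length_corrected)


def select_hvgs(dm: DMResult | pd.DataFrame, dm_min: float = 1.0) -> list[str]:
    """Genes with DM > dm_min, ordered by descending DM (ties by gene_id)."""
    table = dm.table if isinstance(dm, DMResult) else dm
    sel = table[table["dm"] > dm_min]
    if len(sel) == 0:
        warnings.warn(f"no genes exceed DM > {dm_min}")
        return []
    sel = sel.iloc[np.lexsort((sel.index, -sel["dm"].to_numpy()))]
    return sel.index.tolist()
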