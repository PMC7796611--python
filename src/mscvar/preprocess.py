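"""Filtering, normalization, and cohort-level quality control.

The normalization chain mirrors standard bulk RNA-seq practice: genes are
kept if CPM > 1 in at least 10% of samples, between-sample composition is
normalized by trimmed mean of M-values (TMM), and downstream analyses use
log2(CPM + 1) on TMM-scaled library sizes.

The TMM implementation follows the published algorithm: gene-wise
log-ratios (M) against a reference sample are doubly trimmed — 30% on M
and 5% on average log-expression (A) — and averaged with inverse
asymptotic-variance weights; factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, ExpressionMatrix, NormFactors, ValidationError

ISCT_POSITIVE_MARKERS = ["ENG", "NT5E", "THY1"]
ISCT_NEGATIVE_MARKERS = [
    "PTPRC", "CD34", "CD14", "ITGAM", "CD79A", "CD19", "HLA-DRA", "HLA-DRB1",
]


def _libsizes(cm: CountMatrix) -> pd.Series:
    lib = cm.library_sizes()
    zero = lib[lib == 0]
    if len(zero):
        raise ValidationError(f"zero library size for sample(s) {zero.index.tolist()}")
    return lib


def compute_cpm(cm: CountMatrix) -> ExpressionMatrix:
    """Counts per million: counts scaled so each sample sums to 1e6."""
    lib = _libsizes(cm)
    cpm = cm.counts.div(lib, axis=1) * 1e6
    return ExpressionMatrix(cpm, "cpm")


def compute_tpm(cm: CountMatrix) -> ExpressionMatrix:
    """Transcripts per kilobase million (length- then depth-normalized)."""
    if cm.gene_lengths is None:
        raise ValidationError("TPM requires gene lengths")
    rate = cm.counts.div(cm.gene_lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValidationError(
            f"zero length-normalized total for sample(s) {zero.index.tolist()}"
        )
    tpm = rate.div(denom, axis=1) * 1e6
    return ExpressionMatrix(tpm, "tpm")


def filter_expressed(
    cm: CountMatrix, cpm_min: float = 1.0, frac_min: float = 0.10
) -> CountMatrix:
    """Keep genes with CPM > cpm_min in at least ceil(frac_min * n) samples."""
    cpm = compute_cpm(cm).values.to_numpy()
    n_min = math.ceil(frac_min * cm.n_samples)
    keep = (cpm > cpm_min).sum(axis=1) >= n_min
    return cm.subset_genes(cm.counts.index[keep])


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference sample."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        log_r = np.log2(p_obs / p_ref)
        abs_e = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0:
        raise ValidationError("no genes usable for TMM (all zero in one sample)")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        raise ValidationError("no genes survive TMM trimming")
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors for all samples.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the cohort mean of that fraction.
    """
    if cm.n_samples < 2:
        raise ValidationError("TMM needs at least 2 samples")
    lib = _libsizes(cm)
    counts = cm.counts.to_numpy(dtype=float)
    libv = lib.to_numpy(dtype=float)
    f75 = np.quantile(counts, 0.75, axis=0) / libv
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(
                counts[:, j], counts[:, ref_idx], libv[j], libv[ref_idx],
                trim_m, trim_a,
            )
            for j in range(cm.n_samples)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    table = pd.DataFrame(
        {"library_size": lib.astype(int), "tmm_factor": factors},
        index=pd.Index(cm.sample_ids, name="sample_id"),
    )
    return NormFactors(table)


def log_normalize(cm: CountMatrix, nf: NormFactors) -> ExpressionMatrix:
    """log2(CPM + 1) on TMM-scaled effective library sizes."""
    missing = set(cm.sample_ids) - set(nf.sample_ids)
    if missing:
        raise ValidationError(f"norm factors missing for samples {sorted(missing)}")
    eff = nf.effective_sizes().reindex(cm.sample_ids)
    logcpm = np.log2(cm.counts.div(eff, axis=1) * 1e6 + 1.0)
    return ExpressionMatrix(logcpm, "logcpm")


def correlation_qc(em: ExpressionMatrix, r_min: float = 0.9) -> pd.DataFrame:
    """Median pairwise Pearson correlation per sample on log-normalized
    expression; samples with median r below r_min are flagged as outliers."""
    em.require_unit("logcpm")
    if len(em.sample_ids) < 3:
        raise ValidationError("correlation QC needs at least 3 samples")
    vals = em.values.to_numpy()
    sds = vals.std(axis=0)
    constant = sds == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(vals.T)
    rows = []
    for i, sid in enumerate(em.sample_ids):
        if constant[i]:
            rows.append((sid, np.nan, False, "constant expression"))
            continue
        others = np.delete(corr[i], i)
        med = float(np.nanmedian(others))
        rows.append((sid, med, med >= r_min, ""))
    return pd.DataFrame(
        rows, columns=["sample_id", "median_r", "pass", "reason"]
    ).set_index("sample_id")


def marker_qc(
    tpm: ExpressionMatrix,
    positive: list[str] | None = None,
    negative: list[str] | None = None,
) -> pd.DataFrame:
    """Report ISCT marker expression: per-marker cohort median TPM and
    median within-sample rank percentile.  Reporting only — samples are
    never filtered on markers (IFNγ exposure and some culture conditions
    legitimately induce HLA-DR)."""
    tpm.require_unit("tpm")
    positive = ISCT_POSITIVE_MARKERS if positive is None else positive
    negative = ISCT_NEGATIVE_MARKERS if negative is None else negative
    vals = tpm.values
    # percentile of each gene within each sample (fraction of genes <= it)
    pct = vals.rank(axis=0, pct=True)
    rows = []
    for role, markers in (("positive", positive), ("negative", negative)):
        for m in markers:
            if m not in vals.index:
                rows.append((m, role, True, np.nan, np.nan))
                continue
            rows.append(
                (
                    m,
                    role,
                    False,
                    float(vals.loc[m].median()),
                    float(pct.loc[m].median()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["marker", "role", "missing", "median_tpm", "median_rank_percentile"],
    ).set_index("marker")
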