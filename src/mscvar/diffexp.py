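"""Negative-binomial differential expression for IFNγ-licensing contrasts.

Counts are modeled per gene as NB(mu, phi) with variance mu + phi*mu^2 and
a log link, log mu = offset + X beta, where the offset is the log of the
TMM-scaled library size.  Gene-wise dispersions are estimated by
maximizing the Cox-Reid adjusted profile likelihood on a dispersion grid
(with quadratic refinement) and shrunk toward a lowess trend on mean
expression.  Contrasts are tested by likelihood-ratio chi-square.

Two analyses are built on this machinery:

* common response genes (CRGs): a paired design (pair blocks + treatment)
  testing the shared IFNγ response; CRGs are the genes called up at
  |fold| >= 2 and BH FDR < 0.1;
* different response genes (DRGs): one response coefficient per sample
  group, tested against the shared-response model (interaction LRT with
  n_groups - 1 df), gated on the largest pairwise difference of group
  response fold-changes.

The IRLS fits are vectorized across genes (one batched linear solve per
iteration), which keeps cohort-scale analyses in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import (
    CountMatrix,
    NormFactors,
    ValidationError,
    complete_pairs,
)

LN2 = np.log(2.0)
_PHI_GRID = np.logspace(-4, 1, 12)
_TREND_WEIGHT = 0.25  # weight of the lowess trend in dispersion shrinkage


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# vectorized NB GLM


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood; phi broadcast as (G, 1)."""
    r = 1.0 / np.maximum(phi, 1e-10)
    mu = np.maximum(mu, 1e-10)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    eta0: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-8,
):
    """Batched IRLS for the NB GLM with log link.

    y is genes x samples, X is samples x coefficients, offset is (samples,)
    or genes x samples, phi is (G, 1).  Returns (beta, mu, eta, XtWX).
    """
    G, n = y.shape
    p = X.shape[1]
    eta = np.log(np.maximum(y, 0.5)) if eta0 is None else eta0.copy()
    eta = np.clip(eta, -50.0, 50.0)
    eye = np.eye(p)
    beta = np.zeros((G, p))
    # design cross-products: XtWX for all genes is one GEMM, W @ P
    P = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    active = np.arange(G)  # genes not yet converged
    for _ in range(max_iter):
        ya, ea, pa = y[active], eta[active], phi[active]
        mu = np.maximum(np.exp(ea), 1e-10)
        W = mu / (1.0 + pa * mu)
        z = (ea - offset) + (ya - mu) / mu
        XtWX = (W @ P).reshape(len(active), p, p)
        XtWz = (W * z) @ X
        diag_mean = np.einsum("gpp->g", XtWX) / p
        ridge = (1e-10 * diag_mean + 1e-12)[:, None, None] * eye
        beta[active] = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        new_eta = np.clip(offset + beta[active] @ X.T, -50.0, 50.0)
        delta = np.max(np.abs(new_eta - ea), axis=1)
        eta[active] = new_eta
        active = active[delta >= tol]
        if active.size == 0:
            break
    mu = np.maximum(np.exp(eta), 1e-10)
    W = mu / (1.0 + phi * mu)
    XtWX = (W @ P).reshape(G, p, p)
    return beta, mu, eta, XtWX


def _cox_reid_apl(y, X, offset, phi_scalar, eta0=None):
    """Cox-Reid adjusted profile log-likelihood at one dispersion value."""
    G = y.shape[0]
    phi = np.full((G, 1), phi_scalar)
    beta, mu, eta, XtWX = _irls(y, X, offset, phi, eta0=eta0, tol=1e-6, max_iter=30)
    sign, logdet = np.linalg.slogdet(XtWX)
    apl = _nb_loglik(y, mu, phi) - 0.5 * logdet
    return apl, eta


def estimate_dispersions(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> np.ndarray:
    """Gene-wise Cox-Reid APL dispersion estimates, shrunk toward a lowess
    trend on average log expression.  Returns phi per gene."""
    G = y.shape[0]
    apls = np.empty((len(_PHI_GRID), G))
    eta0 = None
    for i, phi in enumerate(_PHI_GRID):
        apls[i], eta0 = _cox_reid_apl(y, X, offset, phi, eta0=eta0)
    best = np.argmax(apls, axis=0)
    log_grid = np.log(_PHI_GRID)
    # quadratic refinement around the grid maximum (interior points only)
    log_phi = log_grid[best].copy()
    interior = (best > 0) & (best < len(_PHI_GRID) - 1)
    idx = np.where(interior)[0]
    if idx.size:
        b = best[idx]
        y0, y1, y2 = apls[b - 1, idx], apls[b, idx], apls[b + 1, idx]
        h = log_grid[1] - log_grid[0]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        log_phi[idx] = log_grid[b] + np.clip(shift, -1.0, 1.0) * h
    # trend on average log CPM-scale expression
    avg_log = np.log(y.mean(axis=1) + 0.5)
    if G >= 10:
        trend = lowess(
            log_phi, avg_log, frac=0.5, it=1, return_sorted=False
        )
        trend = np.where(np.isfinite(trend), trend, np.median(log_phi))
    else:
        trend = np.full(G, np.median(log_phi))
    shrunk = (1.0 - _TREND_WEIGHT) * log_phi + _TREND_WEIGHT * trend
    return np.exp(shrunk)


def nb_lrt(
    y: np.ndarray,
    offset: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    phi: np.ndarray | None = None,
):
    """Likelihood-ratio test of nested NB GLMs, vectorized over genes.

    Returns (pvalues, beta_full, phi); df = rank difference of the designs.
    """
    for name, X in (("full", X_full), ("reduced", X_reduced)):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValidationError(f"{name} design matrix is not full rank")
    df = X_full.shape[1] - X_reduced.shape[1]
    if df < 1:
        raise ValidationError("full design must have more coefficients than reduced")
    if phi is None:
        phi = estimate_dispersions(y, X_full, offset)
    phi_col = phi[:, None]
    beta_full, mu_full, _, _ = _irls(y, X_full, offset, phi_col)
    beta_red, mu_red, _, _ = _irls(y, X_reduced, offset, phi_col)
    stat = 2.0 * (_nb_loglik(y, mu_full, phi_col) - _nb_loglik(y, mu_red, phi_col))
    stat = np.maximum(stat, 0.0)
    pvalues = chi2.sf(stat, df)
    return pvalues, beta_full, phi


# ---------------------------------------------------------------------------
# designs over sample metadata


@dataclass(frozen=True)
class DesignSpec:
    """Model terms for the licensing contrasts.

    ``pairing`` adds fixed pair-block effects; ``group_interaction``
    replaces the single treatment coefficient with one response
    coefficient per group (tested jointly against the shared response).
    """

    treatment: bool = True
    pairing: bool = True
    group_interaction: bool = False


def _design_matrices(meta: pd.DataFrame, design: DesignSpec):
    """Build (X_full, X_reduced, coef_names, df) from sample metadata.

    Rows follow meta order.  Baseline columns: intercept plus pair blocks
    (first pair as reference) when pairing is on.
    """
    n = len(meta)
    cols = [np.ones(n)]
    names = ["intercept"]
    if design.pairing:
        pair_ids = sorted(meta["pair_id"].unique())
        for pid in pair_ids[1:]:
            cols.append((meta["pair_id"] == pid).to_numpy(dtype=float))
            names.append(f"pair[{pid}]")
    treated = (meta["treatment"] == "ifng").to_numpy(dtype=float)
    X_base = np.column_stack(cols)
    base_names = list(names)
    if design.group_interaction:
        if "group" not in meta.columns or meta["group"].isna().any():
            raise ValidationError("group labels required for interaction design")
        groups = sorted(meta["group"].astype(str).unique())
        if len(groups) < 2:
            raise ValidationError("interaction design needs >= 2 groups")
        full_cols, full_names = list(cols), list(names)
        for gname in groups:
            ind = (meta["group"].astype(str) == gname).to_numpy(dtype=float)
            full_cols.append(treated * ind)
            full_names.append(f"response[{gname}]")
        X_full = np.column_stack(full_cols)
        red_cols = list(cols) + [treated]
        red_names = base_names + ["treatment"]
        X_reduced = np.column_stack(red_cols)
        return X_full, X_reduced, full_names, red_names, groups
    if design.treatment:
        X_full = np.column_stack(cols + [treated])
        full_names = names + ["treatment"]
        return X_full, X_base, full_names, base_names, None
    raise ValidationError("design specifies no tested term")


def _offsets(cm: CountMatrix, nf: NormFactors) -> np.ndarray:
    missing = set(cm.sample_ids) - set(nf.sample_ids)
    if missing:
        raise ValidationError(f"norm factors missing for samples {sorted(missing)}")
    eff = nf.effective_sizes().reindex(cm.sample_ids).to_numpy(dtype=float)
    return np.log(eff)


def _calls(log2fc: np.ndarray, fdr: np.ndarray, fc_min: float, fdr_max: float):
    thr = np.log2(fc_min)
    call = np.full(log2fc.shape, "ns", dtype=object)
    call[(log2fc >= thr) & (fdr < fdr_max)] = "up"
    call[(log2fc <= -thr) & (fdr < fdr_max)] = "down"
    return call


def nb_fit_test(
    cm: CountMatrix,
    nf: NormFactors,
    meta: pd.DataFrame,
    design: DesignSpec = DesignSpec(),
    contrast: str = "treatment",
    fc_min: float = 2.0,
    fdr_max: float = 0.1,
) -> pd.DataFrame:
    """Fit the NB GLM and test one coefficient by LRT.

    Returns a DE table indexed by gene with log2fc, pvalue, fdr, call.
    """
    meta = meta.loc[cm.sample_ids]
    X_full, X_reduced, full_names, red_names, _ = _design_matrices(meta, design)
    if contrast not in full_names or contrast in red_names:
        raise ValidationError(
            f"contrast {contrast!r} is not a tested coefficient of this design"
        )
    if design.group_interaction:
        raise ValidationError("use call_drgs for the interaction design")
    y = cm.counts.to_numpy(dtype=float)
    offset = _offsets(cm, nf)
    pvalues, beta_full, _ = nb_lrt(y, offset, X_full, X_reduced)
    log2fc = beta_full[:, full_names.index(contrast)] / LN2
    fdr = bh_adjust(pvalues)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalues,
            "fdr": fdr,
            "call": _calls(log2fc, fdr, fc_min, fdr_max),
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )


def _paired_subset(cm: CountMatrix, meta: pd.DataFrame):
    meta = meta.loc[[s for s in cm.sample_ids if s in meta.index]]
    paired = complete_pairs(meta)
    if len(paired) == 0:
        raise ValidationError("no complete untreated/ifng pairs in metadata")
    order = paired.sort_values(["pair_id", "treatment"], kind="mergesort")
    return cm.subset_samples(order["sample_id"].tolist()), order


def call_crgs(
    cm: CountMatrix,
    nf: NormFactors,
    meta: pd.DataFrame,
    fc_min: float = 2.0,
    fdr_max: float = 0.1,
) -> dict:
    """Paired IFNγ-vs-untreated test; CRGs are the significantly
    up-regulated genes (|fold| >= fc_min, FDR < fdr_max)."""
    cm_p, meta_p = _paired_subset(cm, meta)
    table = nb_fit_test(
        cm_p, nf, meta_p, DesignSpec(pairing=True), "treatment", fc_min, fdr_max
    )
    return {
        "up": table.index[table["call"] == "up"].tolist(),
        "down": table.index[table["call"] == "down"].tolist(),
        "table": table,
    }


def call_drgs(
    cm: CountMatrix,
    nf: NormFactors,
    meta: pd.DataFrame,
    fc_min: float = 2.0,
    fdr_max: float = 0.1,
) -> dict:
    """Group-dependent IFNγ response: interaction LRT plus an effect gate.

    A gene is a DRG when the per-group response model beats the shared
    response model at FDR < fdr_max and the largest pairwise difference
    between group response log2 fold-changes is >= log2(fc_min).
    """
    cm_p, meta_p = _paired_subset(cm, meta)
    if "group" not in meta_p.columns or meta_p["group"].isna().any():
        raise ValidationError("group labels required to call DRGs")
    by_group = meta_p.groupby(meta_p["group"].astype(str))["pair_id"].nunique()
    empty = by_group[by_group == 0]
    if len(empty):
        raise ValidationError(f"group(s) without pairs: {empty.index.tolist()}")
    design = DesignSpec(pairing=True, group_interaction=True)
    X_full, X_reduced, full_names, _, groups = _design_matrices(meta_p, design)
    y = cm_p.counts.to_numpy(dtype=float)
    offset = _offsets(cm_p, nf)
    pvalues, beta_full, _ = nb_lrt(y, offset, X_full, X_reduced)
    fdr = bh_adjust(pvalues)
    resp_cols = [full_names.index(f"response[{g}]") for g in groups]
    resp_log2fc = beta_full[:, resp_cols] / LN2
    spread = resp_log2fc.max(axis=1) - resp_log2fc.min(axis=1)
    is_drg = (fdr < fdr_max) & (spread >= np.log2(fc_min))
    table = pd.DataFrame(
        {"pvalue": pvalues, "fdr": fdr, "response_spread_log2": spread,
         "is_drg": is_drg},
        index=pd.Index(cm_p.gene_ids, name="gene_id"),
    )
    for j, g in enumerate(groups):
        table[f"log2fc[{g}]"] = resp_log2fc[:, j]
    return {"drgs": table.index[is_drg].tolist(), "table": table, "groups": groups}
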