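"""Synthetic MSC-like paired bulk RNA-seq cohorts with planted truth.

The generator emulates the structure of a multi-tissue MSC cohort with
paired IFNγ licensing: negative-binomial counts with a mean-dispersion
trend, log-normal library sizes and gene lengths, planted sample groups
with group-specific baseline shifts on highly variable genes (HVGs), a
shared treatment response on common response genes (CRGs), group-specific
responses on different response genes (DRGs), and ISCT marker genes
(three constitutively high, several near zero).

A subset of the DRGs — the "licensing signature" genes, by default also
planted as HVGs — carries a coherent baseline axis across groups: the
non-responder group expresses these genes lowest at baseline, the
strongest responders highest, plus per-group residual heterogeneity.
This encodes the biological premise under study: genes that respond
differently to licensing are also baseline-variable, and their baseline
expression tracks immunosuppressive potency.  Seven of the signature
genes are named as the immunosuppressive score genes, and the ISCT
markers are always planted.

Every draw is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError, validate_metadata

SCORE_GENE_SYMBOLS = ["VEGFA", "IFNA1", "CXCL10", "CSF3", "CXCL9", "IL7", "CCL2"]
POSITIVE_MARKER_SYMBOLS = ["ENG", "NT5E", "THY1"]
NEGATIVE_MARKER_SYMBOLS = [
    "PTPRC", "CD34", "CD14", "ITGAM", "CD79A", "CD19", "HLA-DRA", "HLA-DRB1",
]
_TISSUES = ["UC", "BM", "AD", "PL", "DP", "ED"]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a synthetic cohort.  Log-scale gene parameters are
    log2 relative abundances; library sizes and lengths are log-normal."""

    n_genes: int = 2000
    n_groups: int = 4
    samples_per_group: int = 8
    paired: bool = True
    libsize_log_mean: float = float(np.log(2e6))
    libsize_log_sd: float = 0.35
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 2.0
    planted_baseline_log_mean: float = 4.0
    planted_baseline_log_sd: float = 1.5
    dispersion_a0: float = 0.02
    dispersion_a1: float = 4.0
    n_hvg: int = 150
    hvg_log2_shift_sd: float = 2.0
    n_crg: int = 80
    crg_log2fc: float = 2.0
    n_drg: int = 60
    drg_log2fc_by_group: tuple = (0.0, 2.0, 2.0, 2.0)
    n_signature: int = 40  # DRGs that are also HVGs (licensing signature)
    signature_baseline_by_group: tuple = (-2.5, 0.3, 0.8, 1.4)
    signature_axis2_by_group: tuple = (-1.5, -2.0, 1.0, 2.5)
    signature_residual_sd: float = 1.0
    pair_effect_sd: float = 0.1
    gene_length_log_mean: float = float(np.log(2000.0))
    gene_length_log_sd: float = 0.6
    positive_marker_log2: float = 9.0
    negative_marker_log2: float = -6.0
    seed: int = 1

    def validate(self) -> "SimSpec":
        if self.n_genes <= 0 or self.n_groups < 1 or self.samples_per_group < 1:
            raise ValidationError("cohort dimensions must be positive")
        if len(self.drg_log2fc_by_group) != self.n_groups:
            raise ValidationError(
                "drg_log2fc_by_group must have one entry per group"
            )
        for name in ("signature_baseline_by_group", "signature_axis2_by_group"):
            if len(getattr(self, name)) != self.n_groups:
                raise ValidationError(f"{name} must have one entry per group")
        if self.n_signature > min(self.n_hvg, self.n_drg):
            raise ValidationError("n_signature cannot exceed n_hvg or n_drg")
        n_marker = len(POSITIVE_MARKER_SYMBOLS) + len(NEGATIVE_MARKER_SYMBOLS)
        n_planted = self.n_hvg + self.n_crg + (self.n_drg - self.n_signature)
        if n_planted + n_marker > self.n_genes:
            raise ValidationError("planted gene sets exceed n_genes")
        for name in ("libsize_log_sd", "baseline_log_sd", "dispersion_a0",
                     "dispersion_a1", "gene_length_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        return self


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cohort."""

    genes: pd.DataFrame       # per gene: hvg, crg, drg, signature flags
    response: pd.DataFrame    # per gene x group true response log2fc
    samples: pd.DataFrame     # sample_id, group, treatment, pair_id
    group_potency: pd.Series  # planted mean response over CRG ∪ DRG genes


def default_paper_like_spec(seed: int = 1) -> SimSpec:
    """The scaled-down default cohort: 2000 genes, 4 groups x 8 paired
    samples, 150 HVGs, 80 CRGs, 60 DRGs with one non-responder group,
    a 40-gene licensing signature, score genes and ISCT markers planted."""
    return SimSpec(seed=seed).validate()


def _gene_layout(spec: SimSpec):
    """Deterministic planted-set index layout.

    [0, n_signature): signature genes (HVG ∩ DRG);
    [n_signature, n_hvg): remaining HVGs;
    [n_hvg, n_hvg + n_drg - n_signature): DRG-only genes;
    next n_crg: CRGs; last genes: ISCT markers.
    """
    sig = np.arange(spec.n_signature)
    hvg = np.arange(spec.n_hvg)
    drg_only = np.arange(spec.n_hvg, spec.n_hvg + spec.n_drg - spec.n_signature)
    drg = np.concatenate([sig, drg_only])
    crg_start = spec.n_hvg + spec.n_drg - spec.n_signature
    crg = np.arange(crg_start, crg_start + spec.n_crg)
    return hvg, crg, drg, sig


def _gene_names(spec: SimSpec) -> list[str]:
    width = max(4, len(str(spec.n_genes)))
    names = [f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    for j, sym in enumerate(SCORE_GENE_SYMBOLS):
        names[j] = sym
    markers = POSITIVE_MARKER_SYMBOLS + NEGATIVE_MARKER_SYMBOLS
    for j, sym in enumerate(markers):
        names[spec.n_genes - len(markers) + j] = sym
    return names


def simulate_cohort(spec: SimSpec):
    """Draw one cohort.  Returns (CountMatrix, metadata, SimTruth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    hvg_idx, crg_idx, drg_idx, sig_idx = _gene_layout(spec)
    names = _gene_names(spec)
    n_marker = len(POSITIVE_MARKER_SYMBOLS) + len(NEGATIVE_MARKER_SYMBOLS)
    marker_idx = np.arange(G - n_marker, G)

    # baseline log2 relative abundance; planted genes drawn well expressed
    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, G)
    planted = np.unique(np.concatenate([hvg_idx, crg_idx, drg_idx]))
    baseline[planted] = rng.normal(
        spec.planted_baseline_log_mean, spec.planted_baseline_log_sd, planted.size
    )
    baseline[marker_idx[: len(POSITIVE_MARKER_SYMBOLS)]] = spec.positive_marker_log2
    baseline[marker_idx[len(POSITIVE_MARKER_SYMBOLS):]] = spec.negative_marker_log2

    lengths = rng.lognormal(spec.gene_length_log_mean, spec.gene_length_log_sd, G)
    lengths = np.maximum(np.round(lengths), 200.0)

    K = spec.n_groups
    # group baseline shifts on HVGs: realized between-group sd is exactly
    # hvg_log2_shift_sd per gene (the planted effect size is the label)
    shifts = np.zeros((G, K))
    raw = rng.normal(0.0, 1.0, (spec.n_hvg, K))
    raw -= raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    shifts[hvg_idx] = raw / sd * spec.hvg_log2_shift_sd
    # signature genes: a coherent potency axis (all genes lower in the
    # weak-responder groups) plus a second coherent group axis with
    # random +/-1 gene loadings, plus residual heterogeneity — groups
    # occupy a genuinely two-dimensional region of signature space
    sig_base = np.asarray(spec.signature_baseline_by_group, dtype=float)
    axis2 = np.asarray(spec.signature_axis2_by_group, dtype=float)
    loadings2 = rng.choice([-1.0, 1.0], size=spec.n_signature)
    resid = rng.normal(0.0, 1.0, (spec.n_signature, K))
    resid -= resid.mean(axis=1, keepdims=True)
    rsd = resid.std(axis=1, ddof=0, keepdims=True)
    rsd[rsd == 0] = 1.0
    shifts[sig_idx] = (
        sig_base[None, :]
        + loadings2[:, None] * axis2[None, :]
        + resid / rsd * spec.signature_residual_sd
    )

    # treatment response log2fc per gene x group
    response = np.zeros((G, K))
    response[crg_idx] = spec.crg_log2fc
    response[drg_idx] = np.asarray(spec.drg_log2fc_by_group, dtype=float)[None, :]

    # samples
    rows = []
    bio = 0
    for k in range(K):
        for _ in range(spec.samples_per_group):
            bio += 1
            sid = f"S{bio:03d}"
            tissue = _TISSUES[(bio - 1) % len(_TISSUES)]
            if spec.paired:
                rows.append((f"{sid}U", tissue, "untreated", f"P{bio:03d}", f"G{k}"))
                rows.append((f"{sid}T", tissue, "ifng", f"P{bio:03d}", f"G{k}"))
            else:
                rows.append((f"{sid}U", tissue, "untreated", "", f"G{k}"))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "tissue", "treatment", "pair_id", "group"]
    )
    n_bio = bio
    groups_of_bio = np.repeat(np.arange(K), spec.samples_per_group)

    libsizes = rng.lognormal(spec.libsize_log_mean, spec.libsize_log_sd, len(meta))
    pair_noise = rng.normal(0.0, spec.pair_effect_sd, (G, n_bio))

    counts = np.empty((G, len(meta)), dtype=np.int64)
    col = 0
    for b in range(n_bio):
        k = groups_of_bio[b]
        log2q = baseline + shifts[:, k] + pair_noise[:, b]
        conditions = ("untreated", "ifng") if spec.paired else ("untreated",)
        for cond in conditions:
            lq = log2q + (response[:, k] if cond == "ifng" else 0.0)
            q = np.exp2(lq)
            q /= q.sum()
            mu = libsizes[col] * q
            phi = spec.dispersion_a0 + spec.dispersion_a1 / np.maximum(mu, 1e-8)
            r = 1.0 / phi
            p = r / (r + mu)
            counts[:, col] = rng.negative_binomial(r, p)
            col += 1

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(names, name="gene_id"),
                     columns=meta["sample_id"].tolist()),
        pd.Series(lengths, index=pd.Index(names, name="gene_id"), name="length_bp"),
    )
    meta = validate_metadata(meta)

    flags = pd.DataFrame(
        False, index=pd.Index(names, name="gene_id"),
        columns=["hvg", "crg", "drg", "signature"],
    )
    flags.iloc[hvg_idx, 0] = True
    flags.iloc[crg_idx, 1] = True
    flags.iloc[drg_idx, 2] = True
    flags.iloc[sig_idx, 3] = True
    flags["baseline_log2"] = baseline
    resp_df = pd.DataFrame(
        response, index=flags.index, columns=[f"G{k}" for k in range(K)]
    )
    de_idx = np.unique(np.concatenate([crg_idx, drg_idx]))
    potency_vals = response[de_idx].mean(axis=0) if de_idx.size else np.zeros(K)
    potency = pd.Series(
        potency_vals, index=[f"G{k}" for k in range(K)], name="planted_potency"
    )
    truth = SimTruth(
        genes=flags, response=resp_df,
        samples=meta[["sample_id", "group", "treatment", "pair_id"]].copy(),
        group_potency=potency,
    )
    return cm, meta, truth


def null_spec(
    n_genes: int = 2000,
    n_groups: int = 1,
    samples_per_group: int = 12,
    paired: bool = True,
    seed: int = 1,
) -> SimSpec:
    """A cohort with no planted effects (for calibration studies)."""
    return SimSpec(
        n_genes=n_genes,
        n_groups=n_groups,
        samples_per_group=samples_per_group,
        paired=paired,
        n_hvg=0,
        n_crg=0,
        crg_log2fc=0.0,
        n_drg=0,
        drg_log2fc_by_group=tuple([0.0] * n_groups),
        n_signature=0,
        signature_baseline_by_group=tuple([0.0] * n_groups),
        signature_axis2_by_group=tuple([0.0] * n_groups),
        seed=seed,
    ).validate()
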