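"""scikit-learn-style estimators over the pipeline steps.

These wrap the fit/transform-shaped stages — expressed-gene filtering,
TMM log-normalization, DM-based HVG selection, SNN-Louvain clustering,
and the quadrant potency classifier — so they compose with sklearn
pipelines and model selection.  The estimator convention here is samples
as rows: X is an (n_samples, n_genes) DataFrame of raw counts (or
log-normalized expression for the clusterer/classifier), gene IDs as
columns.  The functional API in the sibling modules shares the same core
implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import preprocess as _pp
from . import variability as _var
from .cluster import cluster_samples
from .containers import CountMatrix, ExpressionMatrix, ValidationError
from .signatures import quadrant_classify


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(
        X,
        index=[f"sample{i}" for i in range(X.shape[0])],
        columns=[f"gene{j}" for j in range(X.shape[1])],
    )


def _count_matrix(X, gene_lengths=None) -> CountMatrix:
    df = _as_frame(X)
    gl = None
    if gene_lengths is not None:
        gl = pd.Series(np.asarray(gene_lengths, dtype=float), index=df.columns)
    return CountMatrix(df.T, gl)


class ExpressedGeneFilter(TransformerMixin, BaseEstimator):
    """Keep genes with CPM > cpm_min in at least ceil(frac_min * n) samples."""

    def __init__(self, cpm_min: float = 1.0, frac_min: float = 0.10):
        self.cpm_min = cpm_min
        self.frac_min = frac_min

    def fit(self, X, y=None):
        cm = _count_matrix(X)
        kept = _pp.filter_expressed(cm, self.cpm_min, self.frac_min)
        self.n_features_in_ = cm.n_genes
        self.gene_ids_ = kept.gene_ids
        self.support_ = np.isin(np.asarray(cm.gene_ids), self.gene_ids_)
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return _as_frame(X).loc[:, self.gene_ids_]


class TMMLogNormalizer(TransformerMixin, BaseEstimator):
    """TMM scale factors plus log2(CPM + 1) normalization.

    fit() learns per-sample factors on the fitted cohort; transform()
    recomputes factors for the given samples (normalization is a
    per-cohort, not per-gene, operation) and returns log-normalized
    expression.
    """

    def __init__(self, trim_m: float = 0.30, trim_a: float = 0.05):
        self.trim_m = trim_m
        self.trim_a = trim_a

    def fit(self, X, y=None):
        cm = _count_matrix(X)
        nf = _pp.tmm_factors(cm, self.trim_m, self.trim_a)
        self.n_features_in_ = cm.n_genes
        self.library_sizes_ = nf.table["library_size"].to_numpy()
        self.tmm_factors_ = nf.table["tmm_factor"].to_numpy()
        self._norm_factors = nf
        return self

    def transform(self, X):
        check_is_fitted(self, "tmm_factors_")
        cm = _count_matrix(X)
        nf = _pp.tmm_factors(cm, self.trim_m, self.trim_a)
        return _pp.log_normalize(cm, nf).values.T

    def fit_transform(self, X, y=None):
        cm = _count_matrix(X)
        self.fit(X)
        return _pp.log_normalize(cm, self._norm_factors).values.T


class DistanceToMedianHVG(TransformerMixin, BaseEstimator):
    """Select highly variable genes by the DM statistic (DM > dm_min).

    X is a raw count frame; gene lengths (aligned to columns) enable the
    length-correction step.  Fitted attributes expose the full DM table.
    """

    def __init__(
        self,
        dm_min: float = 1.0,
        n_windows: int = 50,
        overlap: int = 25,
        gene_lengths=None,
    ):
        self.dm_min = dm_min
        self.n_windows = n_windows
        self.overlap = overlap
        self.gene_lengths = gene_lengths

    def fit(self, X, y=None):
        cm = _count_matrix(X, self.gene_lengths)
        cpm = _pp.compute_cpm(cm)
        res = _var.dm_statistic(
            cpm, cm.gene_lengths, self.n_windows, self.overlap
        )
        self.n_features_in_ = cm.n_genes
        self.dm_table_ = res.table
        self.length_corrected_ = res.length_corrected
        self.hvgs_ = _var.select_hvgs(res, self.dm_min)
        return self

    def transform(self, X):
        check_is_fitted(self, "hvgs_")
        return _as_frame(X).loc[:, self.hvgs_]


class SNNLouvain(ClusterMixin, BaseEstimator):
    """PCA -> shared-nearest-neighbor graph -> Louvain sample clustering.

    X is log-normalized expression (samples x genes, HVG-restricted by
    the caller or via a preceding DistanceToMedianHVG step).
    """

    def __init__(
        self,
        k: int = 10,
        n_pcs: int = 10,
        resolution: float = 2.0,
        prune: float = 1.0 / 15.0,
        random_state: int = 1,
    ):
        self.k = k
        self.n_pcs = n_pcs
        self.resolution = resolution
        self.prune = prune
        self.random_state = random_state

    def fit(self, X, y=None):
        df = _as_frame(X)
        em = ExpressionMatrix(df.T, "logcpm")
        emb, result = cluster_samples(
            em,
            hvgs=df.columns.tolist(),
            k=self.k,
            n_pcs=self.n_pcs,
            resolution=self.resolution,
            seed=self.random_state,
            prune=self.prune,
        )
        self.n_features_in_ = df.shape[1]
        self.embedding_ = emb.coords
        self.labels_ = result.labels.loc[df.index].to_numpy()
        self.modularity_ = result.modularity
        return self


class QuadrantPotencyClassifier(ClassifierMixin, BaseEstimator):
    """Low-potency call from the oriented PCA quadrant of panel genes.

    fit(X, y) takes untreated-sample log-normalized expression over the
    panel genes and binary y marking the low-potency reference samples;
    predict() labels samples 'low' (third quadrant) or 'other'.
    """

    def __init__(self, panel: list[str] | None = None):
        self.panel = panel

    def fit(self, X, y):
        df = _as_frame(X)
        y = np.asarray(y)
        if y.shape[0] != df.shape[0]:
            raise ValidationError("y must mark each sample")
        reference = df.index[y.astype(bool)].tolist()
        panel = self.panel if self.panel is not None else df.columns.tolist()
        em = ExpressionMatrix(df.T, "logcpm")
        result = quadrant_classify(em, panel, df.index.tolist(), reference)
        self.n_features_in_ = df.shape[1]
        self.classes_ = np.array(["low", "other"])
        self.result_ = result
        self.coords_ = result.coords
        self.orientation_signs_ = result.parameters["orientation_signs"]
        self._loadings = None
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        df = _as_frame(X)
        if df.index.equals(self.result_.potency_call.index):
            return self.result_.potency_call.to_numpy()
        # project new samples is out of scope; refit on the given cohort
        raise ValidationError(
            "QuadrantPotencyClassifier classifies the fitted cohort; "
            "call fit on the samples to classify"
        )
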