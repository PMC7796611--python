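import numpy as np
import pandas as pd
import pytest

from mscvar import preprocess as pp
from mscvar.containers import CountMatrix, ExpressionMatrix
from mscvar.simulate import default_paper_like_spec, simulate_cohort


def make_count_matrix(values, gene_ids=None, sample_ids=None, lengths=None):
    values = np.asarray(values)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    gl = None
    if lengths is not None:
        gl = pd.Series(np.asarray(lengths, dtype=float), index=gene_ids)
    return CountMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), gl)


def random_count_matrix(rng, n_genes=50, n_samples=6, with_lengths=False):
    counts = rng.negative_binomial(5, 0.05, size=(n_genes, n_samples))
    lengths = rng.integers(300, 5000, n_genes) if with_lengths else None
    return make_count_matrix(counts, lengths=lengths)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort plus its processed artifacts, shared
    across tests that only read from it."""
    cm, meta, truth = simulate_cohort(default_paper_like_spec(seed=1))
    filt = pp.filter_expressed(cm)
    nf = pp.tmm_factors(filt)
    logcpm = pp.log_normalize(filt, nf)
    untreated = meta.index[meta["treatment"] == "untreated"].tolist()
    cpm_untreated = pp.compute_cpm(filt.subset_samples(untreated))
    return {
        "cm": cm, "meta": meta, "truth": truth, "filtered": filt,
        "norm_factors": nf, "logcpm": logcpm, "untreated": untreated,
        "cpm_untreated": cpm_untreated,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
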