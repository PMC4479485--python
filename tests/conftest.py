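import pandas as pd
import pytest

from ucptx import (
    KalZDifferentialExpression,
    gen_annotations,
    gen_counts,
    gen_metabolites,
    gen_qpcr,
)


@pytest.fixture(scope="session")
def pinned_sim():
    """Pinned synthetic study: spiked DE genes, GO term and pathway (seed 7/8)."""
    counts, truth = gen_counts(
        n_genes=2000,
        library_size=500_000,
        de_fraction=0.05,
        de_log2fc=3.0,
        dispersion=0.05,
        seed=7,
    )
    annotation, pathways = gen_annotations(counts, truth, seed=8)
    return counts, truth, annotation, pathways


@pytest.fixture(scope="session")
def fitted_deg(pinned_sim):
    counts, _, _, _ = pinned_sim
    return KalZDifferentialExpression().fit(counts)


@pytest.fixture(scope="session")
def pinned_metabolites():
    """125 metabolites, 2 shifted by 0.6 log10 units, 6 samples per group."""
    matrix, truth = gen_metabolites(
        n_metabolites=125, n_per_group=6, n_shifted=2, shift=0.6, seed=3
    )
    return matrix, truth


@pytest.fixture()
def toy_counts_file(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "gene\tlength\tWT\tOE1\tOE2\n"
        "g1\t1000\t10\t20\t30\n"
        "g2\t2000\t5\t0\t1\n"
        "g3\t500\t0\t0\t0\n"
    )
    return path
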