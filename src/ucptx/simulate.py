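"""Synthetic inputs with known ground truth.

The generators emulate the study design the pipeline targets: a single
pooled wild-type library and two independent overexpressor libraries
(no biological replicates within genotype), gene annotations carrying GO
terms and EC numbers, a Gramene-style pathway map, a GC-MS style
metabolite intensity matrix, and a qPCR Ct panel.  Every planted effect
is recorded in a :class:`SimTruth` so downstream calls can be scored for
sensitivity and false-positive rate.

Counts are negative binomial rather than Poisson: the design has no
replicates, so overdispersion is the honest default when stress-testing
a proportion test that assumes pure counting noise.  Setting
``dispersion=0`` recovers Poisson sampling for calibration studies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotationTable, CountTable, MetaboliteMatrix, PathwayMap, QpcrTable

WT_SAMPLE = "WT"
OE_SAMPLES = ("OE1", "OE2")
REFERENCE_GENE = "NtEF"

# contig length range of the assembly the pipeline consumes (bp)
MIN_GENE_LENGTH = 200
MAX_GENE_LENGTH = 5386


@dataclass
class SimTruth:
    """Ground truth planted by the generators."""

    seed: int
    gene_ids: list[str] = field(default_factory=list)
    de_log2fc: dict[str, float] = field(default_factory=dict)
    enriched_go_terms: list[str] = field(default_factory=list)
    shifted_pathway: str | None = None
    pathway_ec_shift: dict[str, float] = field(default_factory=dict)
    shifted_metabolites: dict[str, float] = field(default_factory=dict)
    qpcr_log2fc: dict[str, float] = field(default_factory=dict)

    @property
    def de_gene_ids(self) -> set[str]:
        return set(self.de_log2fc)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mean + dispersion * mean^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_counts(
    n_genes: int = 2000,
    library_size: int = 500_000,
    de_fraction: float = 0.05,
    de_log2fc: float = 3.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[CountTable, SimTruth]:
    """Simulate one WT and two OE count libraries with spiked fold changes.

    Baseline relative abundances are log-normal (a long-tailed positive
    distribution, so the table contains both deeply and shallowly covered
    genes).  A ``de_fraction`` of genes gets its mean multiplied by
    ``2**(+/- de_log2fc)`` in *both* OE libraries, with the same sign in
    both — mirroring a design that treats two independent overexpressor
    lines as replicas of the same perturbation.
    """
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    if library_size < 10_000:
        raise ValueError("library_size must be >= 1e4")
    if not 0 <= de_fraction < 0.5:
        raise ValueError("de_fraction must be in [0, 0.5): universe must be mostly null")
    rng = np.random.default_rng(seed)

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    lengths = rng.integers(MIN_GENE_LENGTH, MAX_GENE_LENGTH + 1, size=n_genes)
    abundance = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    base_mean = abundance / abundance.sum() * library_size

    n_de = int(round(n_genes * de_fraction))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    log2fc = np.zeros(n_genes)
    log2fc[de_idx] = signs * de_log2fc

    means = np.column_stack([base_mean, base_mean * 2.0**log2fc, base_mean * 2.0**log2fc])
    counts = _nb_counts(rng, means, dispersion)
    samples = [WT_SAMPLE, *OE_SAMPLES]
    table = CountTable(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples, dtype=np.int64),
        lengths=pd.Series(lengths, index=gene_ids),
        conditions={WT_SAMPLE: "WT", OE_SAMPLES[0]: "OE1", OE_SAMPLES[1]: "OE2"},
    )
    truth = SimTruth(
        seed=seed,
        gene_ids=gene_ids,
        de_log2fc={gene_ids[i]: float(log2fc[i]) for i in sorted(de_idx)},
    )
    return table, truth


def gen_annotations(
    count_table: CountTable,
    truth: SimTruth,
    n_go_terms: int = 20,
    n_pathways: int = 6,
    ecs_per_pathway: int = 6,
    seed: int = 0,
    spiked_go_prob: float = 0.9,
    background_terms_per_gene: float = 2.0,
) -> tuple[AnnotationTable, PathwayMap]:
    """Assign GO terms and ECs; spike one GO term and one pathway.

    The first GO term is attached to every true DE gene with probability
    ``spiked_go_prob`` on top of a uniform background, making it the
    planted enrichment signal.  The first pathway's ECs map one-to-one
    onto up-regulated truth genes, so its member enzymes carry a
    coordinated positive fold change; all other pathways draw their
    coding genes from the null pool.  ``truth`` is updated in place.
    """
    rng = np.random.default_rng(seed)
    genes = count_table.gene_ids
    n_ec_total = n_pathways * ecs_per_pathway
    if ecs_per_pathway < 5:
        raise ValueError("ecs_per_pathway must be >= 5 so a pathway survives the filter")
    if n_ec_total > len(genes):
        raise ValueError("fewer genes than EC numbers demanded")

    go_terms = [f"GO:{i + 1:07d}" for i in range(n_go_terms)]
    spiked_term = go_terms[0]
    background = go_terms[1:] if n_go_terms > 1 else go_terms
    gene_to_go: dict[str, set[str]] = {}
    for g in genes:
        k = rng.poisson(background_terms_per_gene)
        k = min(k, len(background))
        gene_to_go[g] = set(rng.choice(background, size=k, replace=False)) if k else set()
    for g in sorted(truth.de_gene_ids):
        if rng.random() < spiked_go_prob:
            gene_to_go[g].add(spiked_term)

    up_genes = sorted(g for g, fc in truth.de_log2fc.items() if fc > 0)
    null_genes = [g for g in genes if g not in truth.de_gene_ids]
    if len(up_genes) < ecs_per_pathway:
        raise ValueError("not enough up-regulated truth genes to spike a pathway")
    if len(null_genes) < n_ec_total - ecs_per_pathway:
        raise ValueError("not enough null genes for the background pathways")

    pathway_ids = [f"PWY{i + 1:03d}" for i in range(n_pathways)]
    names = {pid: f"synthetic pathway {i + 1}" for i, pid in enumerate(pathway_ids)}
    ec_numbers = [f"{1 + i // 100}.{1 + (i // 10) % 10}.{1 + i % 10}.{i + 1}" for i in range(n_ec_total)]
    ecs = {
        pid: set(ec_numbers[i * ecs_per_pathway : (i + 1) * ecs_per_pathway])
        for i, pid in enumerate(pathway_ids)
    }

    gene_to_ec: dict[str, set[str]] = {g: set() for g in genes}
    spiked_hosts = list(rng.choice(up_genes, size=ecs_per_pathway, replace=False))
    other_hosts = list(
        rng.choice(null_genes, size=n_ec_total - ecs_per_pathway, replace=False)
    )
    hosts = spiked_hosts + other_hosts
    for ec, host in zip(ec_numbers, hosts):
        gene_to_ec[host].add(ec)

    truth.enriched_go_terms = [spiked_term]
    truth.shifted_pathway = pathway_ids[0]
    truth.pathway_ec_shift = {
        ec: truth.de_log2fc[host] for ec, host in zip(ec_numbers[:ecs_per_pathway], spiked_hosts)
    }
    return AnnotationTable(gene_to_go=gene_to_go, gene_to_ec=gene_to_ec), PathwayMap(
        names=names, ecs=ecs
    )


def gen_metabolites(
    n_metabolites: int = 125,
    n_per_group: int = 6,
    n_shifted: int = 2,
    shift: float = 0.6,
    seed: int = 0,
    truth: SimTruth | None = None,
) -> tuple[MetaboliteMatrix, SimTruth]:
    """Simulate log-normal metabolite intensities with planted group shifts.

    Shifted metabolites differ between WT and OE groups by ``shift`` on
    the log10 scale, with alternating sign (first up in OE, second down,
    ...) — emulating a profile in which one compound accumulates and
    another is depleted in the transgenics.
    """
    if n_shifted > n_metabolites:
        raise ValueError("n_shifted must be <= n_metabolites")
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group for a t-test")
    rng = np.random.default_rng(seed)
    names = [f"metab_{i + 1:03d}" for i in range(n_metabolites)]
    samples = [f"WT_{i + 1}" for i in range(n_per_group)] + [
        f"OE_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(["WT"] * n_per_group + ["OE"] * n_per_group, index=samples)

    base_log10 = rng.uniform(2.0, 5.0, size=n_metabolites)
    log10_vals = base_log10[None, :] + rng.normal(0.0, 0.15, size=(2 * n_per_group, n_metabolites))
    shifted_idx = rng.choice(n_metabolites, size=n_shifted, replace=False)
    shifts = {}
    for j, idx in enumerate(sorted(shifted_idx)):
        s = shift if j % 2 == 0 else -shift
        log10_vals[n_per_group:, idx] += s
        shifts[names[idx]] = float(s)

    matrix = MetaboliteMatrix(
        intensities=pd.DataFrame(10.0**log10_vals, index=samples, columns=names),
        groups=groups,
    )
    if truth is None:
        truth = SimTruth(seed=seed)
    truth.shifted_metabolites = shifts
    return matrix, truth


def gen_qpcr(
    sim_truth: SimTruth,
    n_genes_assayed: int = 17,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
) -> QpcrTable:
    """Simulate a Ct panel whose expected 2^-ddCt equals the true fold change.

    The reference gene Ct is constant across samples up to noise, and each
    target gene's OE Ct is its WT Ct minus the true log2 fold change, so
    with zero noise the comparative-Ct arithmetic recovers the planted
    fold change exactly.  Truth genes are assayed first; the panel is
    padded with null genes (fold change 1).
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    de_genes = sorted(sim_truth.de_log2fc)
    null_genes = [g for g in sim_truth.gene_ids if g not in sim_truth.de_log2fc]
    if n_genes_assayed > len(de_genes) + len(null_genes):
        raise ValueError("n_genes_assayed exceeds available genes")
    panel = de_genes[:n_genes_assayed]
    panel += null_genes[: n_genes_assayed - len(panel)]

    samples = [WT_SAMPLE, *OE_SAMPLES]
    rows = []
    for s in samples:
        rows.append((REFERENCE_GENE, s, 20.0 + rng.normal(0.0, ct_noise_sd)))
    qpcr_truth = {}
    for g in panel:
        fc = sim_truth.de_log2fc.get(g, 0.0)
        qpcr_truth[g] = fc
        wt_ct = rng.uniform(22.0, 30.0)
        rows.append((g, WT_SAMPLE, wt_ct + rng.normal(0.0, ct_noise_sd)))
        for s in OE_SAMPLES:
            rows.append((g, s, wt_ct - fc + rng.normal(0.0, ct_noise_sd)))
    sim_truth.qpcr_log2fc = qpcr_truth
    return QpcrTable(
        data=pd.DataFrame(rows, columns=["gene", "sample", "ct"]),
        reference_gene=REFERENCE_GENE,
        calibrator_sample=WT_SAMPLE,
    )
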