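"""Readers and writers for every table the pipeline touches.

All tables are UTF-8 and tab-separated, except metabolite intensity
matrices which are comma-separated.  Numbers are written plainly (no
thousands separators) so a written table re-reads to at least six
significant digits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ucptx")

#: dotted 4-field Enzyme Commission pattern; partial ECs use "-" and the
#: serial field may carry a preliminary "n" prefix (e.g. 1.1.1.n5).
EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")


class FormatError(ValueError):
    """A file violated the expected table format or an invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Gene-level read counts for one WT and two overexpressor libraries.

    Parameters
    ----------
    counts
        genes x samples integer read counts.
    lengths
        per-gene transcript length in bp, indexed like ``counts``.
    library_totals
        per-sample library size in reads.  Defaults to the column sums of
        ``counts``; an external override is allowed because a mapper's
        "total mapped reads" may exceed the per-gene column sum.
    conditions
        optional sample -> condition label mapping (``WT``/``OE1``/``OE2``).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_totals: pd.Series | None = None
    conditions: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if not np.issubdtype(counts.to_numpy().dtype, np.integer):
            raise FormatError("counts must be integers")
        if (counts.to_numpy() < 0).any():
            gene, sample = next(
                (g, s) for g, s in counts.stack().index[counts.stack() < 0]
            )
            raise FormatError(f"negative count at gene {gene!r}, sample {sample!r}")
        self.lengths = self.lengths.reindex(counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][0]
            raise FormatError(f"missing length for counted gene {missing!r}")
        if (self.lengths <= 0).any():
            raise FormatError("gene lengths must be positive")
        col_sums = counts.sum(axis=0)
        if self.library_totals is None:
            self.library_totals = col_sums
        else:
            self.library_totals = self.library_totals.reindex(counts.columns)
            if (self.library_totals < col_sums).any():
                raise FormatError("library totals below column sums")
        if (self.library_totals <= 0).any():
            raise FormatError("library totals must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class AnnotationTable:
    """Gene id -> GO term set and gene id -> EC number set."""

    gene_to_go: dict[str, set[str]]
    gene_to_ec: dict[str, set[str]]

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, terms in self.gene_to_go.items() if term in terms}

    def genes_for_ec(self, ec: str) -> set[str]:
        return {g for g, ecs in self.gene_to_ec.items() if ec in ecs}

    @property
    def go_terms(self) -> set[str]:
        return set().union(*self.gene_to_go.values()) if self.gene_to_go else set()


@dataclass
class PathwayMap:
    """Pathway id -> (name, set of member EC numbers)."""

    names: dict[str, str]
    ecs: dict[str, set[str]]

    def __post_init__(self) -> None:
        for pid, ec_set in self.ecs.items():
            if not ec_set:
                raise FormatError(f"pathway {pid!r} has no EC numbers")

    def __len__(self) -> int:
        return len(self.ecs)

    def __iter__(self):
        return iter(self.ecs)

    def __contains__(self, pid: str) -> bool:
        return pid in self.ecs


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites positive intensities with a group label per sample."""

    intensities: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() <= 0).any():
            raise FormatError("metabolite intensities must be positive")
        self.groups = self.groups.reindex(self.intensities.index)
        if self.groups.isna().any():
            raise FormatError("every sample needs a group label")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.intensities.columns)


@dataclass
class QpcrTable:
    """Long-format Ct table with a designated reference gene and calibrator."""

    data: pd.DataFrame  # columns: gene, sample, ct
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"gene", "sample", "ct"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"qPCR table needs columns {sorted(required)}")
        if not np.isfinite(self.data["ct"]).all():
            raise FormatError("non-finite Ct value")
        samples = set(self.data["sample"])
        ref_samples = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        if samples - ref_samples:
            raise FormatError(
                f"reference gene {self.reference_gene!r} missing for samples "
                f"{sorted(samples - ref_samples)}"
            )

    def ct(self, gene: str, sample: str) -> float:
        rows = self.data[(self.data["gene"] == gene) & (self.data["sample"] == sample)]
        if rows.empty:
            raise KeyError(f"no Ct for gene {gene!r} in sample {sample!r}")
        return float(rows["ct"].mean())

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.data["sample"]))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, totals: Mapping[str, int] | None = None) -> CountTable:
    """Read a tab-separated count table: gene id, length, then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError("count table needs gene id, length and >=1 sample column")
    gene_col, length_col = df.columns[:2]
    sample_cols = list(df.columns[2:])
    for col in sample_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            row = df.loc[bad, gene_col].iloc[0]
            raise FormatError(
                f"invalid count {df.loc[bad, col].iloc[0]!r} at gene {row!r}, column {col!r}"
            )
    counts = df.set_index(gene_col)[sample_cols].astype(np.int64)
    lengths = df.set_index(gene_col)[length_col].astype(np.int64)
    lib = pd.Series(totals).reindex(sample_cols) if totals is not None else None
    return CountTable(counts=counts, lengths=lengths, library_totals=lib)


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read gene annotations: gene id, ;-joined GO ids, ;-joined EC numbers.

    Malformed EC tokens are skipped with a logged warning rather than
    aborting the run: annotation exports routinely carry stray tokens.
    """
    gene_to_go: dict[str, set[str]] = {}
    gene_to_ec: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = parts + [""] * (3 - len(parts))
            gene, go_field, ec_field = parts[0], parts[1], parts[2]
            if gene in gene_to_go:
                raise FormatError(f"duplicate gene id {gene!r} at line {lineno}")
            gene_to_go[gene] = {t for t in go_field.split(";") if t.strip()}
            ecs = set()
            for tok in ec_field.split(";"):
                tok = tok.strip()
                if not tok:
                    continue
                if EC_PATTERN.match(tok):
                    ecs.add(tok)
                else:
                    logger.warning("skipping malformed EC token %r for gene %r", tok, gene)
            gene_to_ec[gene] = ecs
    return AnnotationTable(gene_to_go=gene_to_go, gene_to_ec=gene_to_ec)


def read_pathways(path: str | Path) -> PathwayMap:
    """Read a Gramene-style pathway map: pathway id, name, ;-joined ECs."""
    names: dict[str, str] = {}
    ecs: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            pid, name, ec_field = line.split("\t")[:3]
            if pid in names:
                raise FormatError(f"duplicate pathway id {pid!r} at line {lineno}")
            ec_set = {t.strip() for t in ec_field.split(";") if t.strip()}
            if not ec_set:
                raise FormatError(f"pathway {pid!r} has no EC numbers (line {lineno})")
            names[pid] = name
            ecs[pid] = ec_set
    return PathwayMap(names=names, ecs=ecs)


def read_metabolite_matrix(path: str | Path) -> MetaboliteMatrix:
    """Read a comma-separated intensity matrix: sample, group, then metabolites."""
    df = pd.read_csv(path, sep=",", dtype={0: str, 1: str})
    sample_col, group_col = df.columns[:2]
    df = df.set_index(sample_col)
    return MetaboliteMatrix(
        intensities=df.drop(columns=[group_col]).astype(float),
        groups=df[group_col],
    )


def read_qpcr(path: str | Path, reference_gene: str, calibrator_sample: str) -> QpcrTable:
    """Read a long-format qPCR Ct table (gene, sample, ct)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str})
    return QpcrTable(
        data=df, reference_gene=reference_gene, calibrator_sample=calibrator_sample
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write result tables as tab-separated files ``<name>.tsv``.

    Floats are written with 10 significant digits so a round trip through
    ``read_result`` reproduces values well within 1e-6 relative tolerance.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=True, float_format="%.10g")
        written.append(path)
        logger.info("wrote %s (%d rows)", path, len(table))
    return written


def read_result(path: str | Path) -> pd.DataFrame:
    """Re-read a table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", index_col=0)


def load_config(path: str | Path) -> dict:
    """Load a ``key: value`` configuration file (YAML subset)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
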