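"""Readers and writers for the text formats the tool touches.

Expression matrices are genes x samples tables (TSV or CSV, first column the
gene identifier).  Edge lists follow the DREAM-challenge gold-standard
dialect: whitespace-separated ``TF  target  [label]`` rows, where an optional
third column of 0/1 marks known negatives/positives.  Sequences are plain
FASTA.  Ranked predictions are written as a TSV sorted by descending score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "EdgeList",
    "SequenceSet",
    "read_expression_matrix",
    "read_edge_list",
    "read_fasta",
    "write_predictions",
    "read_predictions",
]

_VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """An input file violates the expected dialect."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with ordered gene identifiers."""

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != len(set(self.gene_ids)):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise FormatError(f"duplicate gene ids: {dupes}")
        if self.values.ndim != 2 or self.values.shape[0] != len(self.gene_ids):
            raise FormatError("row count does not match number of gene ids")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")
        if not self.sample_ids:
            self.sample_ids = [f"s{i+1}" for i in range(self.values.shape[1])]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class EdgeList:
    """Ordered directed edges ``(source, target, label)`` with 0/1 labels."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self):
        pairs = [(s, t) for s, t, _ in self.edges]
        if len(pairs) != len(set(pairs)):
            seen, dupes = set(), set()
            for p in pairs:
                (dupes if p in seen else seen).add(p)
            raise FormatError(f"duplicate edge pairs: {sorted(dupes)}")

    def positives(self) -> list[tuple[str, str]]:
        return [(s, t) for s, t, lab in self.edges if lab != 0]

    def negatives(self) -> list[tuple[str, str]]:
        return [(s, t) for s, t, lab in self.edges if lab == 0]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class SequenceSet:
    """Mapping gene id -> uppercase nucleotide sequence over {A,C,G,T,N}."""

    records: dict[str, str]

    def __post_init__(self):
        for gid, seq in self.records.items():
            if not seq:
                raise FormatError(f"empty sequence for {gid!r}")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(f"invalid bases {sorted(bad)} in {gid!r}")

    def __len__(self) -> int:
        return len(self.records)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x samples table; first column gene id, rest numeric."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"duplicate gene ids: {dupes}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            raise FormatError(
                f"non-numeric cell at gene {bad[0]!r}, column {col!r}")
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(gene_ids, values, [str(c) for c in df.columns])


def read_edge_list(path, directed: bool = True) -> EdgeList:
    """Read a DREAM-dialect edge list (``TF target [0/1]`` per line)."""
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 2:
                src, tgt = fields
                lab = 1.0
            elif len(fields) == 3:
                src, tgt = fields[:2]
                try:
                    lab = float(fields[2])
                except ValueError as exc:
                    raise FormatError(
                        f"line {lineno}: non-numeric label {fields[2]!r}") from exc
                if not math.isfinite(lab):
                    raise FormatError(f"line {lineno}: non-finite label")
            else:
                raise FormatError(
                    f"line {lineno}: expected 2 or 3 fields, got {len(fields)}")
            edges.append((src, tgt, lab))
    return EdgeList(edges)


def read_fasta(path) -> SequenceSet:
    """Read FASTA; the header token up to the first whitespace is the id."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id
        if gid in records:
            raise FormatError(f"duplicate record id {gid!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {gid!r}")
        records[gid] = seq
    return SequenceSet(records)


def write_predictions(scored_edges, path) -> None:
    """Write ranked edge predictions: TSV, descending score, lexicographic ties."""
    for s, t, score in scored_edges:
        if not math.isfinite(score):
            raise FormatError(f"non-finite score for edge ({s}, {t})")
    ordered = sorted(scored_edges, key=lambda e: (-e[2], e[0], e[1]))
    with open(path, "w") as fh:
        fh.write("source\ttarget\tscore\n")
        for s, t, score in ordered:
            fh.write(f"{s}\t{t}\t{score:.9g}\n")


def read_predictions(path) -> list[tuple[str, str, float]]:
    """Read back a predictions file written by :func:`write_predictions`."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source"):
            raise FormatError("missing predictions header")
        for line in fh:
            s, t, score = line.split("\t")
            out.append((s, t, float(score)))
    return out
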