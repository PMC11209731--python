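"""Synthetic benchmark instances: regulatory graph, expression, sequences.

The generator emulates the structure of a DREAM-style in-silico benchmark at
its published scale (100 genes, 210 expression samples, ~176 known
regulations by default):

* a directed scale-free graph from a transcription-factor subset toward
  targets (preferential attachment), with a configurable fraction of nodes
  forced to total degree 1 — the low-degree regime that motivates local
  augmentation;
* expression by a sigmoidal regulation model: regulators are drawn from a
  standard normal, every target is a logistic function of a signed weighted
  sum of its regulators plus Gaussian noise;
* nucleotide sequences whose GC content carries a weak class signal (TFs are
  drawn from a higher-GC distribution), so sequence descriptors have
  something recoverable;
* an independent per-site substitution process for mutation-robustness
  simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_formats import EdgeList, ExpressionMatrix, SequenceSet
from .proximity import DirectedGRN

__all__ = ["SyntheticConfig", "generate_digraph", "simulate_expression",
           "generate_sequences", "mutate_sequences", "write_fixture"]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark (defaults = DREAM scale)."""

    n_genes: int = 100
    n_tf_fraction: float = 0.25
    n_samples: int = 210
    edge_density: float = 176 / (100 * 99)   # ~176 edges at n=100
    noise_sd: float = 0.1
    lowdegree_fraction: float = 0.3
    seq_length: tuple[int, int] = (150, 250)
    tf_gc: float = 0.55          # mean GC of transcription-factor sequences
    bg_gc: float = 0.45          # mean GC of non-TF sequences
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 3 or self.n_samples < 2:
            raise ValueError("n_genes >= 3 and n_samples >= 2 required")
        if not (0 < self.n_tf_fraction < 1):
            raise ValueError("n_tf_fraction must be in (0, 1)")
        if not (0 <= self.lowdegree_fraction <= 1):
            raise ValueError("lowdegree_fraction must be in [0, 1]")
        lo, hi = self.seq_length
        if lo < 10 or hi < lo:
            raise ValueError("seq_length range must satisfy 10 <= lo <= hi")

    @property
    def n_tfs(self) -> int:
        return max(1, int(round(self.n_tf_fraction * self.n_genes)))

    @property
    def n_edges(self) -> int:
        return int(round(self.edge_density * self.n_genes * (self.n_genes - 1)))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i+1}" for i in range(n)]


def generate_digraph(cfg: SyntheticConfig) -> tuple[DirectedGRN, EdgeList]:
    """Directed scale-free regulatory graph with forced low-degree nodes.

    Nodes are ordered so every edge runs from a lower to a higher index
    (TFs occupy the lowest indices), which keeps the graph acyclic for the
    expression simulator.  Edges attach preferentially to TFs that already
    regulate many targets.  The first ``lowdegree_fraction`` of non-TF nodes
    receive exactly one incident edge.
    """
    rng = np.random.default_rng(cfg.seed)
    n, n_tfs, n_edges = cfg.n_genes, cfg.n_tfs, cfg.n_edges
    ids = _gene_ids(n)
    n_low = int(round(cfg.lowdegree_fraction * n))
    if n_low > n - n_tfs:
        raise ValueError("lowdegree_fraction leaves too few free targets")
    if n_edges < n_low or n_edges > n_tfs * (n - 1) - n_tfs:
        raise ValueError("edge_density infeasible for this node count")
    # low-degree nodes: the last n_low indices, one in-edge each
    low_nodes = list(range(n - n_low, n))
    free_targets = [v for v in range(n_tfs, n) if v not in set(low_nodes)]
    edges: set[tuple[int, int]] = set()
    out_deg = np.ones(n_tfs)  # +1 smoothing for preferential attachment
    for v in low_nodes:
        u = rng.choice(n_tfs, p=out_deg / out_deg.sum())
        edges.add((int(u), v))
        out_deg[u] += 1
    attempts = 0
    while len(edges) < n_edges:
        attempts += 1
        if attempts > 100 * n_edges:
            raise ValueError("edge_density infeasible: sampling stalled")
        u = int(rng.choice(n_tfs, p=out_deg / out_deg.sum()))
        # targets: any higher-index node that is not low-degree
        candidates = [v for v in range(u + 1, n - n_low)]
        if not candidates:
            continue
        v = int(rng.choice(candidates))
        if (u, v) in edges:
            continue
        edges.add((u, v))
        out_deg[u] += 1
    ordered = sorted(edges)
    g = DirectedGRN.from_edges(ids, [(ids[u], ids[v]) for u, v in ordered])
    el = EdgeList([(ids[u], ids[v], 1.0) for u, v in ordered])
    return g, el


def simulate_expression(g: DirectedGRN, cfg: SyntheticConfig
                        ) -> ExpressionMatrix:
    """Sigmoidal regulation with additive Gaussian noise.

    Regulator-free genes draw from N(0, 1); a regulated gene g_j is
    ``logistic(sum_i w_ij x_i)`` (weights signed, |w| in [1, 2.5], centred
    then scaled to roughly unit range) plus N(0, noise_sd) noise.  The graph
    must be acyclic in index order (as produced by :func:`generate_digraph`).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n, m = g.n, cfg.n_samples
    A = g.A
    src, tgt = np.nonzero(A)
    if np.any(src >= tgt):
        raise ValueError("expression simulator requires index-ordered edges")
    W = np.zeros_like(A)
    signs = rng.choice([-1.0, 1.0], size=len(src))
    W[src, tgt] = signs * rng.uniform(1.0, 2.5, size=len(src))
    X = np.zeros((n, m))
    for j in range(n):
        parents = np.nonzero(W[:, j])[0]
        if len(parents) == 0:
            X[j] = rng.standard_normal(m)
        else:
            drive = W[parents, j] @ X[parents]
            X[j] = 4.0 * (1.0 / (1.0 + np.exp(-drive)) - 0.5)
            if cfg.noise_sd > 0:
                X[j] += rng.normal(0.0, cfg.noise_sd, size=m)
    return ExpressionMatrix(list(g.node_ids), X)


def generate_sequences(g: DirectedGRN, cfg: SyntheticConfig) -> SequenceSet:
    """Random sequences with GC bias tied to regulatory role.

    TFs (nodes with at least one out-edge) draw bases with GC probability
    ``tf_gc``; all other genes with ``bg_gc``.  Lengths are uniform over
    ``seq_length``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    is_tf = g.A.sum(axis=1) > 0
    lo, hi = cfg.seq_length
    records: dict[str, str] = {}
    for i, gid in enumerate(g.node_ids):
        gc = cfg.tf_gc if is_tf[i] else cfg.bg_gc
        length = int(rng.integers(lo, hi + 1))
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A,C,G,T
        records[gid] = "".join(rng.choice(_BASES, size=length, p=p))
    return SequenceSet(records)


def mutate_sequences(s: SequenceSet, rate: float, seed: int = 0) -> SequenceSet:
    """Independent per-site substitution to a uniformly different base."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("mutation rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for gid in s.records:  # dict order is insertion order -> deterministic
        arr = np.array(list(s.records[gid]))
        hit = rng.random(len(arr)) < rate
        if hit.any():
            for pos in np.nonzero(hit)[0]:
                current = arr[pos]
                choices = [b for b in "ACGT" if b != current]
                arr[pos] = choices[int(rng.integers(3))]
        out[gid] = "".join(arr)
    return SequenceSet(out)


def write_fixture(outdir, cfg: SyntheticConfig) -> dict[str, Path]:
    """Generate and write a complete benchmark instance.

    Files: ``expression.tsv``, ``goldstandard.tsv``, ``sequences.fasta`` and
    ``synthetic_config.yaml`` — exactly the dialects the readers accept.
    Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, el = generate_digraph(cfg)
    expr = simulate_expression(g, cfg)
    seqs = generate_sequences(g, cfg)
    paths = {
        "expression": outdir / "expression.tsv",
        "edges": outdir / "goldstandard.tsv",
        "fasta": outdir / "sequences.fasta",
        "config": outdir / "synthetic_config.yaml",
    }
    with open(paths["expression"], "w") as fh:
        fh.write("gene\t" + "\t".join(expr.sample_ids) + "\n")
        for gid, row in zip(expr.gene_ids, expr.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    with open(paths["edges"], "w") as fh:
        for s, t, lab in el.edges:
            fh.write(f"{s}\t{t}\t{int(lab)}\n")
    with open(paths["fasta"], "w") as fh:
        for gid, seq in seqs.records.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(paths["config"], "w") as fh:
        d = dict(cfg.__dict__)
        d["seq_length"] = list(cfg.seq_length)
        yaml.safe_dump(d, fh, sort_keys=True)
    return paths
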