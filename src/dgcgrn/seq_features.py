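"""Gene-sequence feature extraction.

Two complementary representations of a nucleotide sequence:

1. Physicochemical descriptors — a fixed 25-dimensional vector:
   Z-curve endpoint (3, scaled by 1/n), GC content (1), AT/GC ratio (1),
   mononucleotide composition NAC (4) and adjacent-dinucleotide composition
   CKSNAP with spacing k=0 (16).
2. Hidden features — overlapping k-mer tokens (default k=5) embedded and run
   through a bidirectional GRU whose final states are projected to a fixed
   width (default 60).  The encoder is trained jointly with the
   edge-prediction loss.

``N`` bases are excluded from all descriptor counts; any k-mer containing an
``N`` maps to a dedicated unknown token.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Linear, Tensor, col_slice, concat, embedding, glorot

__all__ = [
    "kmerize",
    "z_curve",
    "gc_content",
    "atgc_ratio",
    "nac",
    "cksnap0",
    "physchem_vector",
    "physchem_matrix",
    "KmerEncoding",
    "BiGRUEncoder",
]

_BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}


def _counts(seq: str) -> dict[str, int]:
    return {b: seq.count(b) for b in _BASE_ORDER}


def kmerize(seq: str, k: int) -> list[str]:
    """Overlapping k-mers (stride 1).  Sequences shorter than k give []."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [seq[i:i + k] for i in range(len(seq) - k + 1)]


def z_curve(seq: str) -> np.ndarray:
    """Normalised Z-curve endpoint (X_n, Y_n, Z_n) / n.

    X_n = (A+G)-(C+T), Y_n = (A+C)-(T+G), Z_n = (A+T)-(C+G), with n the
    number of non-N bases; each coordinate lies in [-1, 1] after scaling.
    """
    c = _counts(seq)
    n = sum(c.values())
    if n == 0:
        raise ValueError("sequence has no A/C/G/T bases")
    x = (c["A"] + c["G"]) - (c["C"] + c["T"])
    y = (c["A"] + c["C"]) - (c["T"] + c["G"])
    z = (c["A"] + c["T"]) - (c["C"] + c["G"])
    return np.array([x, y, z], dtype=float) / n


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T)."""
    c = _counts(seq)
    n = sum(c.values())
    if n == 0:
        raise ValueError("sequence has no A/C/G/T bases")
    return (c["G"] + c["C"]) / n


def atgc_ratio(seq: str) -> float:
    """(A + T) / (G + C); a +1 pseudocount in the denominator when GC = 0."""
    c = _counts(seq)
    denom = c["G"] + c["C"]
    if denom == 0:
        denom = 1
    return (c["A"] + c["T"]) / denom


def nac(seq: str) -> np.ndarray:
    """Mononucleotide frequencies (A, C, G, T); sums to 1."""
    c = _counts(seq)
    n = sum(c.values())
    if n == 0:
        raise ValueError("sequence has no A/C/G/T bases")
    return np.array([c[b] for b in _BASE_ORDER], dtype=float) / n


def cksnap0(seq: str) -> np.ndarray:
    """Adjacent (0-spaced) dinucleotide frequencies, 16 values summing to 1.

    Pairs containing an N are excluded from both numerator and denominator.
    """
    counts = np.zeros(16)
    total = 0
    for i in range(len(seq) - 1):
        a, b = seq[i], seq[i + 1]
        if a in _BASE_INDEX and b in _BASE_INDEX:
            counts[_BASE_INDEX[a] * 4 + _BASE_INDEX[b]] += 1
            total += 1
    if total == 0:
        raise ValueError("sequence has no valid adjacent base pair")
    return counts / total


def physchem_vector(seq: str) -> np.ndarray:
    """Concatenated 25-dim descriptor: z-curve(3), gc, at/gc, nac(4), cksnap(16)."""
    return np.concatenate([
        z_curve(seq),
        [gc_content(seq)],
        [atgc_ratio(seq)],
        nac(seq),
        cksnap0(seq),
    ])


def physchem_matrix(gene_ids: list[str], sequences: dict[str, str]) -> np.ndarray:
    """Stack descriptor vectors for ``gene_ids``; genes without a sequence get zeros."""
    X = np.zeros((len(gene_ids), 25))
    for i, g in enumerate(gene_ids):
        seq = sequences.get(g)
        if seq:
            X[i] = physchem_vector(seq)
    return X


@dataclass
class KmerEncoding:
    """Padded integer k-mer token batch for a fixed gene order.

    Token ids: 0..4^k-1 for pure-ACGT k-mers (base-4 code), 4^k for any k-mer
    containing N, and 4^k + 1 for padding.  ``max_len`` defaults to the 95th
    percentile of token counts (sequences longer than that are truncated).
    """

    gene_ids: list[str]
    k: int
    tokens: np.ndarray      # (n_genes, max_len) int
    lengths: np.ndarray     # (n_genes,) valid token counts after truncation
    vocab_size: int         # 4^k + 2 including unknown and pad

    @property
    def unknown_id(self) -> int:
        return self.vocab_size - 2

    @property
    def pad_id(self) -> int:
        return self.vocab_size - 1

    @classmethod
    def build(cls, gene_ids: list[str], sequences: dict[str, str],
              k: int = 5, max_len: int | None = None) -> "KmerEncoding":
        if k < 1:
            raise ValueError("k must be >= 1")
        unknown = 4 ** k
        pad = 4 ** k + 1
        token_lists: list[np.ndarray] = []
        for g in gene_ids:
            seq = sequences.get(g, "")
            ids = []
            for mer in kmerize(seq, k):
                code = 0
                ok = True
                for ch in mer:
                    if ch not in _BASE_INDEX:
                        ok = False
                        break
                    code = code * 4 + _BASE_INDEX[ch]
                ids.append(code if ok else unknown)
            token_lists.append(np.asarray(ids, dtype=np.int64))
        raw_lens = np.array([len(t) for t in token_lists])
        if max_len is None:
            positive = raw_lens[raw_lens > 0]
            max_len = int(np.percentile(positive, 95)) if len(positive) else 1
            max_len = max(max_len, 1)
        tokens = np.full((len(gene_ids), max_len), pad, dtype=np.int64)
        lengths = np.minimum(raw_lens, max_len)
        for i, t in enumerate(token_lists):
            tokens[i, :lengths[i]] = t[:max_len]
        return cls(list(gene_ids), k, tokens, lengths, pad + 1)


class BiGRUEncoder:
    """Bidirectional GRU over k-mer tokens, projected to ``out_dim`` features.

    The forward and backward final hidden states are concatenated and mapped
    linearly to ``out_dim`` (default 60).  Genes with no tokens produce a
    zero vector (with a warning at construction of the batch).
    """

    def __init__(self, vocab_size: int, emb_dim: int = 16, hidden: int = 32,
                 out_dim: int = 60, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.emb_dim, self.hidden, self.out_dim = emb_dim, hidden, out_dim
        self.embed = Tensor(rng.normal(0, 0.1, size=(vocab_size, emb_dim)),
                            requires_grad=True)
        self._gru = {}
        for direction in ("fwd", "bwd"):
            self._gru[direction] = {
                "W": Tensor(glorot(rng, emb_dim, 3 * hidden), requires_grad=True),
                "U": Tensor(glorot(rng, hidden, 3 * hidden), requires_grad=True),
                "b": Tensor(np.zeros(3 * hidden), requires_grad=True),
            }
        self.proj = Linear(2 * hidden, out_dim, rng)

    def params(self) -> list[Tensor]:
        out = [self.embed]
        for d in ("fwd", "bwd"):
            out += [self._gru[d]["W"], self._gru[d]["U"], self._gru[d]["b"]]
        out += self.proj.params()
        return out

    def _run_direction(self, tokens: np.ndarray, lengths: np.ndarray,
                       direction: str) -> Tensor:
        n, L = tokens.shape
        h = self.hidden
        p = self._gru[direction]
        state = Tensor(np.zeros((n, h)))
        for t in range(L):
            ids = tokens[:, t]
            mask = (t < lengths).astype(float)[:, None]
            if not mask.any():
                break
            x = embedding(self.embed, ids)
            gates_x = x @ p["W"] + p["b"]
            gates_h = state @ p["U"]
            zr_x = col_slice(gates_x, 0, 2 * h)
            zr_h = col_slice(gates_h, 0, 2 * h)
            zr = (zr_x + zr_h).sigmoid()
            z = col_slice(zr, 0, h)
            r = col_slice(zr, h, 2 * h)
            cand = (col_slice(gates_x, 2 * h, 3 * h)
                    + r * col_slice(gates_h, 2 * h, 3 * h)).tanh()
            new_state = (1.0 - z) * state + z * cand
            m = Tensor(mask)
            state = m * new_state + (1.0 - m) * state
        return state

    def encode(self, enc: KmerEncoding) -> Tensor:
        """Encode a token batch to an (n_genes, out_dim) feature tensor."""
        if np.any(enc.lengths == 0):
            empty = [enc.gene_ids[i] for i in np.nonzero(enc.lengths == 0)[0]]
            warnings.warn(f"genes with no k-mer tokens get zero features: {empty}")
        # reverse valid tokens for the backward pass, padding stays at the end
        rev = np.full_like(enc.tokens, enc.pad_id)
        for i, ln in enumerate(enc.lengths):
            rev[i, :ln] = enc.tokens[i, :ln][::-1]
        h_fwd = self._run_direction(enc.tokens, enc.lengths, "fwd")
        h_bwd = self._run_direction(rev, enc.lengths, "bwd")
        out = self.proj(concat([h_fwd, h_bwd], axis=1))
        nonempty = (enc.lengths > 0).astype(float)[:, None]
        return Tensor(nonempty) * out
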