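"""The directed graph convolutional network and its edge-scoring head.

Each layer runs three spectral-convolution branches over the normalised
first-order, second-order-in and second-order-out proximity matrices,

    Z_b = norm(A_b) @ X @ Theta_b,        b in {F, S_in, S_out},

fuses them by column concatenation [Z_F || alpha Z_S_in || beta Z_S_out]
followed by a rectifier, and stacks two such blocks.  A directed edge
(i, j) is scored by pushing the ordered concatenation (h_i || h_j) of final
embeddings through a two-layer feed-forward head with a logistic output, so
score(i, j) and score(j, i) are free to differ — direction is preserved.

With alpha = beta = 0 and a symmetrised adjacency the model reduces to an
ordinary undirected GCN, which is the first rung of the ablation ladder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Linear, Tensor, concat, glorot, rows
from .proximity import ProximityMatrices

__all__ = ["NodeFeatureMatrix", "DGCNLayerParams", "BranchEmbeddings",
           "dgcn_layer", "fuse_branches", "score_edge", "DGCNModel"]


@dataclass
class NodeFeatureMatrix:
    """Node features with a named block layout (expression / physchem / ...)."""

    X: np.ndarray
    blocks: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] == 0:
            raise ValueError("feature matrix must have at least one column")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix must be finite")
        if not self.blocks:
            self.blocks = [("features", self.X.shape[1])]
        if sum(w for _, w in self.blocks) != self.X.shape[1]:
            raise ValueError("block widths must sum to the feature dimension")

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class DGCNLayerParams:
    """Per-branch convolution weights plus scalar fusion mixing weights."""

    theta_F: Tensor
    theta_S_in: Tensor
    theta_S_out: Tensor
    alpha: float = 1.0
    beta: float = 1.0

    def params(self) -> list[Tensor]:
        uniq, out = set(), []
        for t in (self.theta_F, self.theta_S_in, self.theta_S_out):
            if id(t) not in uniq:
                uniq.add(id(t))
                out.append(t)
        return out


@dataclass
class BranchEmbeddings:
    Z_F: Tensor
    Z_S_in: Tensor
    Z_S_out: Tensor


def dgcn_layer(X, P: ProximityMatrices, params: DGCNLayerParams
               ) -> BranchEmbeddings:
    """One spectral convolution per branch: norm(A_b) @ X @ Theta_b."""
    Xt = X if isinstance(X, Tensor) else Tensor(X)
    for name in ("norm_F", "norm_S_in", "norm_S_out"):
        if getattr(P, name) is None:
            raise ValueError(f"proximity matrices missing {name}")
    if P.norm_F.shape[1] != Xt.shape[0]:
        raise ValueError("node count of proximity matrices != rows of X")
    if Xt.shape[1] != params.theta_F.shape[0]:
        raise ValueError("feature width != Theta input dimension")
    return BranchEmbeddings(
        Z_F=Tensor(P.norm_F) @ Xt @ params.theta_F,
        Z_S_in=Tensor(P.norm_S_in) @ Xt @ params.theta_S_in,
        Z_S_out=Tensor(P.norm_S_out) @ Xt @ params.theta_S_out,
    )


def fuse_branches(Z: BranchEmbeddings, params: DGCNLayerParams) -> Tensor:
    """[Z_F || alpha Z_S_in || beta Z_S_out], rectified; width 3 x d_out."""
    return concat([Z.Z_F, params.alpha * Z.Z_S_in, params.beta * Z.Z_S_out],
                  axis=1).relu()


def score_edge(h_source, h_target, head: "EdgeHead") -> float:
    """Directed probability for one (source, target) embedding pair."""
    hs = np.atleast_2d(np.asarray(h_source, dtype=float))
    ht = np.atleast_2d(np.asarray(h_target, dtype=float))
    logit = head.logits(Tensor(hs), Tensor(ht))
    return float(1.0 / (1.0 + np.exp(-logit.data[0, 0])))


class EdgeHead:
    """Two-layer feed-forward scorer on ordered concatenated embeddings."""

    def __init__(self, d_embed: int, hidden: int, rng: np.random.Generator):
        self.l1 = Linear(2 * d_embed, hidden, rng)
        self.l2 = Linear(hidden, 1, rng)

    def logits(self, h_s: Tensor, h_t: Tensor) -> Tensor:
        return self.l2(self.l1(concat([h_s, h_t], axis=1)).relu())

    def params(self) -> list[Tensor]:
        return self.l1.params() + self.l2.params()


class DGCNModel:
    """Two stacked convolution+fusion blocks and a directed edge head."""

    def __init__(self, d_in: int, hidden_dims: tuple[int, ...] = (64, 32),
                 head_hidden: int = 64, alpha: float = 1.0, beta: float = 1.0,
                 share_theta: bool = False, dropout: float = 0.5,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d_in = d_in
        self.hidden_dims = tuple(hidden_dims)
        self.alpha, self.beta = alpha, beta
        self.share_theta = share_theta
        self.dropout = dropout
        self.seed = seed
        self.layers: list[DGCNLayerParams] = []
        d_prev = d_in
        for d_out in self.hidden_dims:
            theta_F = Tensor(glorot(rng, d_prev, d_out), requires_grad=True)
            if share_theta:
                t_in = t_out = theta_F
            else:
                t_in = Tensor(glorot(rng, d_prev, d_out), requires_grad=True)
                t_out = Tensor(glorot(rng, d_prev, d_out), requires_grad=True)
            self.layers.append(DGCNLayerParams(theta_F, t_in, t_out,
                                               alpha=alpha, beta=beta))
            d_prev = 3 * d_out
        self.head = EdgeHead(d_prev, head_hidden, rng)

    def params(self) -> list[Tensor]:
        out = []
        for layer in self.layers:
            out += layer.params()
        return out + self.head.params()

    def node_embeddings(self, X, P: ProximityMatrices, *,
                        training: bool = False,
                        rng: np.random.Generator | None = None) -> Tensor:
        """Run the stacked convolution blocks; dropout only when training."""
        H = X if isinstance(X, Tensor) else Tensor(np.atleast_2d(X))
        for li, layer in enumerate(self.layers):
            H = fuse_branches(dgcn_layer(H, P, layer), layer)
            if training and self.dropout > 0 and li < len(self.layers) - 1:
                if rng is None:
                    raise ValueError("dropout during training needs an rng")
                keep = (rng.random(H.shape) >= self.dropout) / (1 - self.dropout)
                H = H * Tensor(keep)
        return H

    def pair_logits(self, H: Tensor, pairs: np.ndarray) -> Tensor:
        pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
        return self.head.logits(rows(H, pairs[:, 0]), rows(H, pairs[:, 1]))

    def forward(self, X, P: ProximityMatrices, pairs: np.ndarray) -> np.ndarray:
        """Deterministic directed scores in (0, 1) for queried (i, j) pairs."""
        H = self.node_embeddings(X, P, training=False)
        logits = self.pair_logits(H, pairs).data[:, 0]
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite logits in forward pass")
        return 1.0 / (1.0 + np.exp(-logits))

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        meta = dict(d_in=self.d_in, hidden_dims=list(self.hidden_dims),
                    alpha=self.alpha, beta=self.beta,
                    share_theta=self.share_theta, dropout=self.dropout,
                    seed=self.seed,
                    head_hidden=self.head.l1.W.shape[1])
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "DGCNModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            model = cls(meta["d_in"], tuple(meta["hidden_dims"]),
                        head_hidden=meta["head_hidden"], alpha=meta["alpha"],
                        beta=meta["beta"], share_theta=meta["share_theta"],
                        dropout=meta["dropout"], seed=meta["seed"])
            for i, p in enumerate(model.params()):
                saved = z[f"p{i}"]
                if saved.shape != p.data.shape:
                    raise ValueError("checkpoint shape mismatch")
                p.data = saved
        return model
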