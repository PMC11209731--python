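"""Local feature augmentation with a conditional variational autoencoder.

Low-degree genes give a graph convolution little to aggregate.  The CVAE
learns the distribution of neighbour features X_u conditioned on the central
node's features X_v over all (neighbour, centre) incidences of the training
graph (direction ignored), and then generates one feature vector per node by
decoding a latent draw z ~ N(0, I) together with X_v.  The generated block
(default width 50) is concatenated to — never replaces — the original
features.

When the generated width differs from the raw feature width, the
reconstruction target is X_u mapped through a fixed, seeded orthonormal
random projection into the generated space (identity when the widths match),
so the evidence bound stays a well-defined squared-error + KL objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Linear, Tensor, col_slice, concat
from .proximity import DirectedGRN

__all__ = ["CVAEParams", "collect_pairs", "cvae_loss", "train_cvae",
           "generate_augmented", "kl_standard_normal", "reparameterize"]


@dataclass
class CVAEParams:
    """Encoder/decoder weights plus the fixed target projection."""

    enc1: Linear
    enc2: Linear          # -> (mu || logvar), width 2 L
    dec1: Linear
    dec2: Linear          # -> d_gen
    latent_dim: int
    d_raw: int
    d_gen: int
    target_proj: np.ndarray | None   # (d_raw, d_gen) orthonormal columns, or None

    def params(self) -> list[Tensor]:
        out = []
        for layer in (self.enc1, self.enc2, self.dec1, self.dec2):
            out += layer.params()
        return out

    def project_target(self, X_u: np.ndarray) -> np.ndarray:
        """Map raw neighbour features into the generated (target) space."""
        if self.target_proj is None:
            if self.d_gen == self.d_raw:
                return X_u
            out = np.zeros((X_u.shape[0], self.d_gen))
            out[:, :self.d_raw] = X_u
            return out
        return X_u @ self.target_proj


def _make_target_proj(d_raw: int, d_gen: int, rng: np.random.Generator):
    if d_gen == d_raw or d_gen > d_raw:
        return None  # identity / zero-padding
    G = rng.normal(size=(d_raw, d_gen))
    Q, _ = np.linalg.qr(G)
    return Q


def collect_pairs(g: DirectedGRN, X: np.ndarray):
    """All (neighbour, centre) feature pairs of the graph, direction ignored.

    Returns ``(X_u, X_v, idx)`` where row p of ``X_u`` is the neighbour's
    features, row p of ``X_v`` the centre's, and ``idx`` the (u, v) index
    pairs.  Each undirected adjacency contributes both orientations; isolated
    nodes contribute nothing.
    """
    und = np.maximum(g.A, g.A.T) > 0
    u_idx, v_idx = np.nonzero(und)
    idx = np.column_stack([u_idx, v_idx])
    return X[u_idx], X[v_idx], idx


def kl_standard_normal(mu: Tensor, logvar: Tensor) -> Tensor:
    """KL( N(mu, diag exp(logvar)) || N(0, I) ), summed over latent dims."""
    return ((mu ** 2 + logvar.exp() - 1.0 - logvar) * 0.5).sum(axis=1)


def reparameterize(mu: Tensor, logvar: Tensor, rng: np.random.Generator
                   ) -> Tensor:
    """Differentiable latent draw z = mu + eps * exp(logvar / 2), eps ~ N(0, I)."""
    eps = rng.standard_normal(mu.shape)
    return mu + Tensor(eps) * (logvar * 0.5).exp()


def cvae_loss(x_u: np.ndarray, x_v: np.ndarray, params: CVAEParams,
              rng: np.random.Generator) -> Tensor:
    """Mean per-pair evidence-bound loss: squared reconstruction error + KL."""
    Xu = Tensor(np.atleast_2d(x_u))
    Xv = Tensor(np.atleast_2d(x_v))
    L = params.latent_dim
    hidden = params.enc1(concat([Xu, Xv], axis=1)).relu()
    stats = params.enc2(hidden)
    mu = col_slice(stats, 0, L)
    logvar = col_slice(stats, L, 2 * L)
    z = reparameterize(mu, logvar, rng)
    dh = params.dec1(concat([z, Xv], axis=1)).relu()
    recon = params.dec2(dh)
    target = params.project_target(np.atleast_2d(x_u))
    rec_err = ((recon - Tensor(target)) ** 2).sum(axis=1)
    return (rec_err + kl_standard_normal(mu, logvar)).mean()


def train_cvae(X_u: np.ndarray, X_v: np.ndarray, *, d_gen: int = 50,
               latent_dim: int = 16, hidden: int = 64, epochs: int = 200,
               lr: float = 1e-3, seed: int = 0) -> tuple[CVAEParams, list[float]]:
    """Fit the CVAE on collected pairs by full-batch Adam.

    Returns the trained parameters and the per-epoch loss trace.
    Deterministic given ``seed``.
    """
    X_u = np.atleast_2d(np.asarray(X_u, dtype=float))
    X_v = np.atleast_2d(np.asarray(X_v, dtype=float))
    if X_u.shape[0] == 0:
        raise ValueError("cannot train the CVAE with zero neighbour pairs")
    d_raw = X_u.shape[1]
    rng = np.random.default_rng(seed)
    params = CVAEParams(
        enc1=Linear(2 * d_raw, hidden, rng),
        enc2=Linear(hidden, 2 * latent_dim, rng),
        dec1=Linear(latent_dim + d_raw, hidden, rng),
        dec2=Linear(hidden, d_gen, rng),
        latent_dim=latent_dim, d_raw=d_raw, d_gen=d_gen,
        target_proj=_make_target_proj(d_raw, d_gen, rng),
    )
    opt = Adam(params.params(), lr=lr)
    trace = []
    for _ in range(epochs):
        opt.zero_grad()
        loss = cvae_loss(X_u, X_v, params, rng)
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
        if not np.isfinite(trace[-1]):
            raise FloatingPointError("CVAE loss diverged to NaN/inf")
    return params, trace


def generate_augmented(X: np.ndarray, params: CVAEParams, seed: int = 0
                       ) -> np.ndarray:
    """One generated feature vector per node: decode (z ~ N(0,I), X_v).

    A single draw per node per run; isolated nodes are handled like any
    other, since the decoder only needs the node's own features.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((X.shape[0], params.latent_dim))
    dh = params.dec1(concat([Tensor(z), Tensor(X)], axis=1)).relu()
    return params.dec2(dh).data
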