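"""Run configuration: every pipeline flag in one validated dataclass.

Defaults follow the method's published operating point: generated-feature
width 50, Bi-GRU sequence-feature width 60, 5-mers, 10 repeats of 5-fold
cross-validation, binary cross-entropy with Adam at learning rate 1e-3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # -- paths ------------------------------------------------------------
    expression: str | None = None
    edges: str | None = None
    fasta: str | None = None
    outdir: str = "out"

    # -- model flags ------------------------------------------------------
    use_dgcn: bool = True       # second-order branches + directed adjacency
    use_cvae: bool = True       # CVAE-generated feature block
    use_seq: bool = False       # Bi-GRU + physicochemical sequence blocks
    use_dynamic: bool = True    # dynamic edge-weight update during training
    share_theta: bool = False   # tie Theta across the three branches
    sym_mode: str = "max"       # symmetrisation rule for first-order proximity
    hidden_dims: tuple[int, ...] = (64, 32)
    head_hidden: int = 64
    dropout: float = 0.5
    alpha: float = 1.0          # second-order-in mixing weight
    beta: float = 1.0           # second-order-out mixing weight

    # -- feature dimensions -----------------------------------------------
    d_gen: int = 50             # CVAE generated feature width
    latent_dim: int = 16
    cvae_hidden: int = 64
    cvae_epochs: int = 200
    cvae_lr: float = 1e-3
    seq_dim: int = 60           # Bi-GRU output width
    k: int = 5                  # k-mer length
    emb_dim: int = 16
    gru_hidden: int = 32
    max_tokens: int | None = None   # None -> 95th percentile of token counts

    # -- training ---------------------------------------------------------
    epochs: int = 200
    lr: float = 1e-3
    warmup: int = 10            # epochs before the first dynamic update
    neg_ratio: float = 1.0
    allow_reverse: bool = True  # reversed positives eligible as negatives
    keep_known_negatives: bool = False  # use gold-standard 0-label rows
    folds: int = 5
    repeats: int = 10
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.hidden_dims = tuple(int(h) for h in self.hidden_dims)
        if not self.hidden_dims:
            raise ValueError("hidden_dims must be non-empty")
        for name in ("d_gen", "latent_dim", "seq_dim", "k", "epochs",
                     "folds", "repeats", "head_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.neg_ratio <= 0:
            raise ValueError("neg_ratio must be positive")
        if self.sym_mode not in ("max", "sum", "mean"):
            raise ValueError(f"unknown sym_mode {self.sym_mode!r}")

    @property
    def depth(self) -> int:
        return len(self.hidden_dims)

    # -- (de)serialisation -------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
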