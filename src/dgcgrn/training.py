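"""Edge-set assembly, training loop, dynamic update, cross-validation, metrics.

Link-prediction protocol: known regulations are positives; an equal number
of uniformly sampled ordered non-edges (reversed positives eligible, since
direction matters) are negatives.  Positives are split into folds; the
message-passing graph of each fold is built from its training positives
only, so test edges never shape the proximity matrices, the CVAE pairs, or
the dynamic edge-weight updates.

The dynamic update strategy: after a warm-up, the model's current directed
edge probabilities replace the training-graph edge weights each epoch and
the three proximity matrices are rebuilt before the next epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .autodiff import Adam, Tensor, concat
from .config import RunConfig
from .dgcn import DGCNModel, NodeFeatureMatrix
from .io_formats import EdgeList, ExpressionMatrix
from .local_augment import collect_pairs, generate_augmented, train_cvae
from .proximity import DirectedGRN, ProximityMatrices, build_proximity
from .seq_features import BiGRUEncoder, KmerEncoding, physchem_matrix

__all__ = ["EdgeSplit", "EvalResult", "FeatureAssembly", "TrainResult",
           "sample_negatives", "draw_negatives", "dynamic_update",
           "auroc_rank", "evaluate", "train", "cross_validate",
           "run_ablation", "ABLATION_VARIANTS"]


@dataclass
class EdgeSplit:
    """Train/test positive and negative directed pairs for one fold."""

    train_pos: np.ndarray
    train_neg: np.ndarray
    test_pos: np.ndarray
    test_neg: np.ndarray
    fold_id: int = 0
    repeat_id: int = 0


@dataclass
class EvalResult:
    """Confusion counts at a threshold plus threshold-free AUROC / AUPR."""

    TP: int
    FP: int
    TN: int
    FN: int
    TPR: float
    FPR: float
    ACC: float
    AUROC: float
    AUPR: float
    fold_id: int = 0
    repeat_id: int = 0


@dataclass
class FeatureAssembly:
    """Static node-feature blocks plus an optional k-mer token batch."""

    static: NodeFeatureMatrix
    kmer: KmerEncoding | None = None


@dataclass
class TrainResult:
    model: DGCNModel
    encoder: BiGRUEncoder | None
    graph: DirectedGRN          # final (possibly re-weighted) training graph
    proximity: ProximityMatrices
    X_final: np.ndarray         # static + sequence-hidden features at the end
    log: list[dict] = field(default_factory=list)

    def predict(self, pairs: np.ndarray) -> np.ndarray:
        return self.model.forward(self.X_final, self.proximity, pairs)


# ---------------------------------------------------------------------------
# negative sampling and the dynamic update
# ---------------------------------------------------------------------------

def sample_negatives(n_nodes: int, positives: np.ndarray, ratio: float = 1.0,
                     seed: int = 0, allow_reverse: bool = True,
                     exclude: np.ndarray | None = None) -> np.ndarray:
    """Uniformly sample ordered non-positive pairs as negatives.

    ``ratio`` scales the sample size relative to ``len(positives)``.  With
    ``allow_reverse`` (default) the reversal (j, i) of a positive (i, j) is an
    eligible negative — direction is part of the prediction task.
    """
    positives = np.atleast_2d(np.asarray(positives, dtype=np.int64))
    n_wanted = int(round(ratio * len(positives)))
    forbidden = np.zeros((n_nodes, n_nodes), dtype=bool)
    np.fill_diagonal(forbidden, True)
    forbidden[positives[:, 0], positives[:, 1]] = True
    if not allow_reverse:
        forbidden[positives[:, 1], positives[:, 0]] = True
    if exclude is not None and len(exclude):
        exclude = np.atleast_2d(np.asarray(exclude, dtype=np.int64))
        forbidden[exclude[:, 0], exclude[:, 1]] = True
    src, tgt = np.nonzero(~forbidden)
    if len(src) < n_wanted:
        raise ValueError(
            f"only {len(src)} non-edges available, {n_wanted} requested")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(src), size=n_wanted, replace=False)
    return np.column_stack([src[pick], tgt[pick]])


def dynamic_update(g: DirectedGRN, scores: dict[tuple[int, int], float]
                   ) -> DirectedGRN:
    """Replace every training-edge weight by its current model probability.

    The edge set is preserved; only weights change, and the proximity
    matrices must be rebuilt from the returned graph before the next epoch.
    """
    edges = g.edge_index()
    new_weights = {}
    for i, j in map(tuple, edges):
        if (i, j) not in scores:
            raise ValueError(f"missing score for training edge ({i}, {j})")
        s = float(scores[(i, j)])
        if not (0.0 < s < 1.0):
            raise ValueError(f"score for edge ({i}, {j}) outside (0, 1): {s}")
        new_weights[(i, j)] = s
    return g.with_weights(new_weights)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auroc_rank(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-statistic AUROC (Mann-Whitney with tie averaging)."""
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    if len(pos_scores) == 0 or len(neg_scores) == 0:
        raise ValueError("AUROC undefined for a one-class test set")
    r = rankdata(np.concatenate([pos_scores, neg_scores]))
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    return (r[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def evaluate(scores: dict[tuple[int, int], float], test_pos, test_neg,
             threshold: float = 0.5, fold_id: int = 0, repeat_id: int = 0
             ) -> EvalResult:
    """Confusion counts at ``threshold`` plus rank AUROC and AUPR."""
    test_pos = [tuple(p) for p in np.asarray(test_pos, dtype=np.int64).reshape(-1, 2)]
    test_neg = [tuple(p) for p in np.asarray(test_neg, dtype=np.int64).reshape(-1, 2)]
    if not test_pos or not test_neg:
        raise ValueError("evaluation needs both positive and negative pairs")
    pos = np.array([scores[p] for p in test_pos], dtype=float)
    neg = np.array([scores[p] for p in test_neg], dtype=float)
    tp = int(np.sum(pos >= threshold))
    fn = len(pos) - tp
    fp = int(np.sum(neg >= threshold))
    tn = len(neg) - fp
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    s = np.concatenate([pos, neg])
    return EvalResult(
        TP=tp, FP=fp, TN=tn, FN=fn,
        TPR=tp / (tp + fn), FPR=fp / (fp + tn),
        ACC=(tp + tn) / (tp + fp + tn + fn),
        AUROC=auroc_rank(pos, neg),
        AUPR=float(average_precision_score(y, s)),
        fold_id=fold_id, repeat_id=repeat_id,
    )


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """mean( softplus(logit) - y * logit ) — stable binary cross-entropy."""
    yt = Tensor(np.asarray(y, dtype=float).reshape(-1, 1))
    return (logits.softplus() - yt * logits).mean()


def train(g: DirectedGRN, assembly: FeatureAssembly, split: EdgeSplit,
          cfg: RunConfig, seed: int = 0) -> TrainResult:
    """Fit the model on one fold's training edges.

    Per epoch: forward (with dropout), binary cross-entropy on training
    positives + negatives, Adam step; after ``cfg.warmup`` epochs the dynamic
    update rewrites edge weights from the current (dropout-free) scores and
    the proximity matrices are rebuilt.  Deterministic given ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_model, s_gru, s_drop = (int(c.generate_state(1)[0] % (2 ** 31))
                              for c in ss.spawn(3))
    use_seq = assembly.kmer is not None
    d_in = assembly.static.d + (cfg.seq_dim if use_seq else 0)
    alpha = cfg.alpha if cfg.use_dgcn else 0.0
    beta = cfg.beta if cfg.use_dgcn else 0.0
    model = DGCNModel(d_in, cfg.hidden_dims, head_hidden=cfg.head_hidden,
                      alpha=alpha, beta=beta, share_theta=cfg.share_theta,
                      dropout=cfg.dropout, seed=s_model)
    encoder = None
    params = model.params()
    if use_seq:
        encoder = BiGRUEncoder(assembly.kmer.vocab_size, emb_dim=cfg.emb_dim,
                               hidden=cfg.gru_hidden, out_dim=cfg.seq_dim,
                               seed=s_gru)
        params = params + encoder.params()
    opt = Adam(params, lr=cfg.lr)
    drop_rng = np.random.default_rng(s_drop)

    pairs = np.vstack([split.train_pos, split.train_neg])
    y = np.concatenate([np.ones(len(split.train_pos)),
                        np.zeros(len(split.train_neg))])
    P = build_proximity(g, sym_mode=cfg.sym_mode)
    X_static = Tensor(assembly.static.X)
    seq_data = np.zeros((assembly.static.X.shape[0], 0))
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        if use_seq:
            seq_t = encoder.encode(assembly.kmer)
            Xt = concat([X_static, seq_t], axis=1)
            seq_data = seq_t.data
        else:
            Xt = X_static
        H = model.node_embeddings(Xt, P, training=True, rng=drop_rng)
        logits = model.pair_logits(H, pairs)
        loss = _bce_with_logits(logits, y)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"loss diverged at epoch {epoch}")
        loss.backward()
        opt.step()
        entry = {"epoch": epoch, "loss": float(loss.data)}
        if cfg.use_dynamic and epoch + 1 >= cfg.warmup:
            X_now = np.concatenate([assembly.static.X, seq_data], axis=1)
            edges = g.edge_index()
            probs = model.forward(X_now, P, edges)
            probs = np.clip(probs, 1e-9, 1 - 1e-9)
            g = dynamic_update(g, {tuple(e): p for e, p in zip(edges, probs)})
            P = build_proximity(g, sym_mode=cfg.sym_mode)
            entry["dynamic"] = True
        log.append(entry)
    X_final = np.concatenate([assembly.static.X, seq_data], axis=1)
    return TrainResult(model=model, encoder=encoder, graph=g, proximity=P,
                       X_final=X_final, log=log)


# ---------------------------------------------------------------------------
# feature assembly and cross-validation
# ---------------------------------------------------------------------------

def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _zscore_cols(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def assemble_features(g_train: DirectedGRN, expr_z: np.ndarray,
                      physchem: np.ndarray | None,
                      kmer: KmerEncoding | None, cfg: RunConfig,
                      seed: int = 0) -> FeatureAssembly:
    """Build the per-fold node-feature matrix.

    Blocks: z-scored expression; column-standardised physicochemical
    descriptors (sequence runs only); CVAE-generated features trained on the
    fold's training graph.  The Bi-GRU block is attached lazily at training
    time because it is learned jointly.
    """
    blocks = [("expression", expr_z.shape[1])]
    parts = [expr_z]
    if physchem is not None:
        parts.append(physchem)
        blocks.append(("physchem", physchem.shape[1]))
    base = np.concatenate(parts, axis=1)
    if cfg.use_cvae:
        U, V, _ = collect_pairs(g_train, base)
        if len(U) == 0:
            raise ValueError("training graph has no edges; cannot augment")
        ss = np.random.SeedSequence(seed)
        s_fit, s_gen = (int(c.generate_state(1)[0] % (2 ** 31))
                        for c in ss.spawn(2))
        params, _ = train_cvae(U, V, d_gen=cfg.d_gen, latent_dim=cfg.latent_dim,
                               hidden=cfg.cvae_hidden, epochs=cfg.cvae_epochs,
                               lr=cfg.cvae_lr, seed=s_fit)
        aug = generate_augmented(base, params, seed=s_gen)
        parts.append(aug)
        blocks.append(("augmented", aug.shape[1]))
    X = np.concatenate(parts, axis=1)
    return FeatureAssembly(static=NodeFeatureMatrix(X, blocks), kmer=kmer)


def _fold_slices(n: int, folds: int) -> list[slice]:
    bounds = np.linspace(0, n, folds + 1).astype(int)
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def draw_negatives(n_nodes: int, pos: np.ndarray, known_neg: np.ndarray,
                   cfg: RunConfig, seed: int) -> np.ndarray:
    """Assemble the negative set for one repeat.

    With ``cfg.keep_known_negatives``, gold-standard rows labelled 0 are
    used first (shuffled); any remainder up to ``neg_ratio * |pos|`` is
    sampled uniformly from the non-positive ordered pairs.
    """
    n_wanted = int(round(cfg.neg_ratio * len(pos)))
    rng = np.random.default_rng(seed)
    picked = np.empty((0, 2), dtype=np.int64)
    if cfg.keep_known_negatives and len(known_neg):
        order = rng.permutation(len(known_neg))
        picked = known_neg[order][:n_wanted]
    if len(picked) < n_wanted:
        sampled = sample_negatives(
            n_nodes, pos, ratio=(n_wanted - len(picked)) / len(pos),
            seed=seed, allow_reverse=cfg.allow_reverse, exclude=picked)
        picked = np.vstack([picked, sampled])
    return picked


def cross_validate(expr: ExpressionMatrix, edges: EdgeList, cfg: RunConfig,
                   sequences: dict[str, str] | None = None,
                   seed: int | None = None) -> list[EvalResult]:
    """Repeated k-fold link-prediction cross-validation.

    Returns ``cfg.repeats * cfg.folds`` fold results.  Fold assignments and
    negative samples are redrawn each repeat; everything derives from
    ``seed`` (default ``cfg.seed``).
    """
    seed = cfg.seed if seed is None else seed
    gene_index = {gid: i for i, gid in enumerate(expr.gene_ids)}
    pos_pairs = [(gene_index[s], gene_index[t]) for s, t in edges.positives()
                 if s in gene_index and t in gene_index and s != t]
    pos = np.array(sorted(set(pos_pairs)), dtype=np.int64)
    known_neg = np.array(sorted({(gene_index[s], gene_index[t])
                                 for s, t in edges.negatives()
                                 if s in gene_index and t in gene_index
                                 and s != t}),
                         dtype=np.int64).reshape(-1, 2)
    n = expr.n_genes
    if len(pos) < cfg.folds:
        raise ValueError(f"{len(pos)} positives cannot fill {cfg.folds} folds")
    use_seq = cfg.use_seq and sequences is not None
    expr_z = _zscore_rows(expr.values)
    physchem = None
    kmer = None
    if use_seq:
        physchem = _zscore_cols(physchem_matrix(expr.gene_ids, sequences))
        kmer = KmerEncoding.build(expr.gene_ids, sequences, k=cfg.k,
                                  max_len=cfg.max_tokens)

    results: list[EvalResult] = []
    root = np.random.SeedSequence(seed)
    for repeat, rep_ss in enumerate(root.spawn(cfg.repeats)):
        states = [int(c.generate_state(1)[0] % (2 ** 31))
                  for c in rep_ss.spawn(3)]
        s_perm, s_neg, s_fold = states
        order = np.random.default_rng(s_perm).permutation(len(pos))
        shuffled = pos[order]
        negs = draw_negatives(n, pos, known_neg, cfg, seed=s_neg)
        slices = _fold_slices(len(pos), cfg.folds)
        neg_slices = _fold_slices(len(negs), cfg.folds)
        for fold, (sl, nsl) in enumerate(zip(slices, neg_slices)):
            test_pos = shuffled[sl]
            train_pos = np.vstack([shuffled[:sl.start], shuffled[sl.stop:]])
            test_neg = negs[nsl]
            train_neg = np.vstack([negs[:nsl.start], negs[nsl.stop:]])
            split = EdgeSplit(train_pos, train_neg, test_pos, test_neg,
                              fold_id=fold, repeat_id=repeat)
            g_train = DirectedGRN.from_edges(
                expr.gene_ids,
                [(expr.gene_ids[i], expr.gene_ids[j]) for i, j in train_pos])
            if not cfg.use_dgcn:
                g_train = DirectedGRN(list(g_train.node_ids),
                                      np.maximum(g_train.A, g_train.A.T))
            fold_seed = s_fold + fold
            assembly = assemble_features(g_train, expr_z, physchem, kmer,
                                         cfg, seed=fold_seed)
            fit = train(g_train, assembly, split, cfg, seed=fold_seed)
            all_pairs = np.vstack([test_pos, test_neg])
            scores = fit.predict(all_pairs)
            smap = {tuple(p): sc for p, sc in zip(all_pairs, scores)}
            results.append(evaluate(smap, test_pos, test_neg,
                                    threshold=cfg.threshold,
                                    fold_id=fold, repeat_id=repeat))
    return results


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

ABLATION_VARIANTS: dict[str, dict] = {
    "E.1": dict(use_dgcn=False, use_cvae=False, use_seq=False, use_dynamic=False),
    "E.2": dict(use_dgcn=True, use_cvae=False, use_seq=False, use_dynamic=False),
    "E.3": dict(use_dgcn=True, use_cvae=True, use_seq=False, use_dynamic=False),
    "E.4": dict(use_dgcn=True, use_cvae=True, use_seq=True, use_dynamic=False),
    "E.5": dict(use_dgcn=True, use_cvae=True, use_seq=False, use_dynamic=True),
    "E.6": dict(use_dgcn=True, use_cvae=True, use_seq=True, use_dynamic=True),
}


def run_ablation(expr: ExpressionMatrix, edges: EdgeList, cfg: RunConfig,
                 sequences: dict[str, str] | None = None,
                 variants: list[str] | None = None,
                 seed: int | None = None):
    """Cross-validate each ablation variant; returns a summary DataFrame.

    Variant ladder: undirected GCN (E.1), directed convolution (E.2), + CVAE
    augmentation (E.3), + sequence features (E.4), E.3 + dynamic update
    (E.5), everything (E.6).  Sequence variants are skipped when no
    sequences are supplied.
    """
    import pandas as pd

    names = variants or list(ABLATION_VARIANTS)
    rows = []
    for name in names:
        flags = ABLATION_VARIANTS[name]
        if flags["use_seq"] and sequences is None:
            continue
        vcfg = cfg.replace(**flags)
        res = cross_validate(expr, edges, vcfg, sequences=sequences, seed=seed)
        aucs = np.array([r.AUROC for r in res])
        auprs = np.array([r.AUPR for r in res])
        rows.append({"variant": name, "mean_auroc": aucs.mean(),
                     "sd_auroc": aucs.std(ddof=1) if len(aucs) > 1 else 0.0,
                     "mean_aupr": auprs.mean(), "n_folds": len(res)})
    return pd.DataFrame(rows)
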