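"""Shared fixtures: tiny graphs, a synthetic fixture directory, and the
scaled-down ablation/robustness runs reused by several test modules."""

from __future__ import annotations

import numpy as np
import pytest

from dgcgrn.config import RunConfig
from dgcgrn.proximity import DirectedGRN
from dgcgrn.synthetic import (SyntheticConfig, generate_digraph,
                              generate_sequences, mutate_sequences,
                              simulate_expression)
from dgcgrn.training import cross_validate


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.3,
                   weighted: bool = True) -> DirectedGRN:
    """A random weighted digraph without self-loops."""
    A = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(A, 0.0)
    if weighted:
        A *= rng.uniform(0.1, 2.0, size=(n, n))
    return DirectedGRN([f"g{i}" for i in range(n)], A)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small written synthetic benchmark (30 genes) for I/O and CLI tests."""
    from dgcgrn.synthetic import write_fixture

    out = tmp_path_factory.mktemp("fixture")
    cfg = SyntheticConfig(n_genes=30, n_samples=40, edge_density=50 / (30 * 29),
                          lowdegree_fraction=0.2, seed=7)
    paths = write_fixture(out, cfg)
    return paths


def _cv_mean_auroc(scfg: SyntheticConfig, cfg: RunConfig, seed: int,
                   sequences=None) -> float:
    g, el = generate_digraph(scfg)
    expr = simulate_expression(g, scfg)
    res = cross_validate(expr, el, cfg, sequences=sequences, seed=seed)
    return float(np.mean([r.AUROC for r in res]))


@pytest.fixture(scope="session")
def ablation_results():
    """Scaled-down study runs shared across test modules.

    Five generator seeds at the default benchmark scale (100 genes, ~176
    edges, 210 samples); one repeat of 5-fold CV per seed; 60 training
    epochs (40 with the jointly trained Bi-GRU, token length capped at 150)
    — sizes chosen so the planted structure is clearly recoverable while the
    suite stays fast.  The augmentation comparison additionally runs at 30
    expression samples, the low-information regime local augmentation is
    meant for.
    """
    seeds = [1, 2, 3, 4, 5]
    base = RunConfig(epochs=60, repeats=1, folds=5, cvae_epochs=150)
    seq_cfg = dict(epochs=40, max_tokens=150)
    out = {k: [] for k in ["E.1", "E.2", "E.6", "E.6_mut",
                           "E.2_lowinfo", "E.3_lowinfo"]}
    for seed in seeds:
        scfg = SyntheticConfig(seed=seed)
        g, el = generate_digraph(scfg)
        expr = simulate_expression(g, scfg)
        seqs = generate_sequences(g, scfg)
        mut = mutate_sequences(seqs, rate=1e-3, seed=seed + 100)
        out["E.1"].append(_cv_mean_auroc(scfg, base.replace(
            use_dgcn=False, use_cvae=False, use_dynamic=False), seed))
        out["E.2"].append(_cv_mean_auroc(scfg, base.replace(
            use_cvae=False, use_dynamic=False), seed))
        full = base.replace(use_seq=True, **seq_cfg)
        res = cross_validate(expr, el, full, sequences=seqs.records, seed=seed)
        out["E.6"].append(float(np.mean([r.AUROC for r in res])))
        res_m = cross_validate(expr, el, full, sequences=mut.records, seed=seed)
        out["E.6_mut"].append(float(np.mean([r.AUROC for r in res_m])))
        lo = SyntheticConfig(seed=seed, n_samples=30)
        out["E.2_lowinfo"].append(_cv_mean_auroc(lo, base.replace(
            use_cvae=False, use_dynamic=False), seed))
        out["E.3_lowinfo"].append(_cv_mean_auroc(lo, base.replace(
            use_dynamic=False), seed))
    return {k: np.array(v) for k, v in out.items()}
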