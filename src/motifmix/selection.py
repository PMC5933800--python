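"""Bayesian selection of the number of binding modes.

For each candidate mode count *m*, several independently seeded chains are
run and the one with the highest MAP collapsed log posterior is kept.  The
models are then compared by

    selection_score(m) = map_log_post(m) - lambda * |M_m|

where |M_m| = sum_k 3*w_k + (m - 1) is the number of free parameters
(3 free entries per PWM column, m-1 free mode proportions) and the
exponential prior exp(-lambda*|M_m|) penalises richer models.  The default
penalty weight is lambda = 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .background import BackgroundModel
from .model_core import ModeModel, ModelState, mode_models
from .sampler import ChainConfig, ChainResult, run_chain
from .sequence_io import SequenceSet


@dataclass
class SearchConfig:
    """Settings of a full model search over the mode-count range."""

    m_min: int = 1
    m_max: int = 20
    n_starts: int = 5
    lam: float = 5.0
    base_seed: int = 0
    workers: int = 1
    chain: ChainConfig = field(default_factory=lambda: ChainConfig(m=1))

    def __post_init__(self) -> None:
        if not (1 <= self.m_min <= self.m_max):
            raise ValueError("need 1 <= m_min <= m_max")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class PerModeCount:
    """Best chain for one value of m and its selection score."""

    m: int
    result: ChainResult
    n_params: int
    selection_score: float
    best_start: int


@dataclass
class SearchResult:
    """Outcome of the search: per-m best chains and the selected model."""

    per_m: Dict[int, PerModeCount]
    best_m: int

    @property
    def best(self) -> PerModeCount:
        return self.per_m[self.best_m]

    @property
    def best_state(self) -> ModelState:
        return self.best.result.best_state

    def best_mode_models(self) -> List[ModeModel]:
        return mode_models(self.best_state)


def count_free_parameters(state: ModelState) -> int:
    """|M_m| = sum_k 3*w_k + (m - 1)."""
    return int(3 * state.widths.sum() + (state.m - 1))


def selection_score(result: ChainResult, lam: float) -> float:
    """MAP collapsed log posterior penalised by the parameter count."""
    return float(result.map_log_post - lam * count_free_parameters(result.best_state))


def derive_seed(base_seed: int, m: int, start: int) -> int:
    """Stable per-chain seed from (base_seed, m, start); independent of the
    number of starts or the m range, so extending the search never perturbs
    existing chains."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(m, start))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _run_one(seqs: SequenceSet, bg: BackgroundModel, config: SearchConfig,
             m: int, start: int) -> ChainResult:
    cfg = replace(config.chain, m=m, seed=derive_seed(config.base_seed, m, start))
    try:
        return run_chain(seqs, bg, cfg)
    except Exception as exc:  # re-raise with chain identity
        raise RuntimeError(f"chain failed for m={m}, start={start}: {exc}") from exc


def search_models(seqs: SequenceSet, bg: BackgroundModel,
                  config: SearchConfig) -> SearchResult:
    """Run n_starts chains for every m in [m_min, m_max] and pick the best
    model.  The result is a pure function of the inputs: chain seeds are
    derived from (base_seed, m, start) alone, so the worker count only
    affects wall-clock time."""
    jobs = [
        (m, s)
        for m in range(config.m_min, config.m_max + 1)
        for s in range(1, config.n_starts + 1)
    ]
    if config.workers and config.workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=config.workers)(
            delayed(_run_one)(seqs, bg, config, m, s) for m, s in jobs
        )
    else:
        results = [_run_one(seqs, bg, config, m, s) for m, s in jobs]

    per_m: Dict[int, PerModeCount] = {}
    for (m, s), res in zip(jobs, results):
        cur = per_m.get(m)
        if cur is None or res.map_log_post > cur.result.map_log_post:
            per_m[m] = PerModeCount(
                m=m, result=res,
                n_params=count_free_parameters(res.best_state),
                selection_score=selection_score(res, config.lam),
                best_start=s,
            )
    best_m = min(per_m)
    for m in sorted(per_m):
        if per_m[m].selection_score > per_m[best_m].selection_score:
            best_m = m
    return SearchResult(per_m=per_m, best_m=best_m)


def summary_table(result: SearchResult) -> "pandas.DataFrame":  # noqa: F821
    """Per-m table: MAP log posterior, parameter count, selection score,
    convergence flag and sweeps run."""
    import pandas as pd

    rows = []
    for m in sorted(result.per_m):
        pm = result.per_m[m]
        rows.append({
            "m": m,
            "map_log_post": pm.result.map_log_post,
            "n_params": pm.n_params,
            "selection_score": pm.selection_score,
            "converged": pm.result.converged,
            "sweeps": pm.result.sweeps_run,
            "best_start": pm.best_start,
        })
    return pd.DataFrame(rows)
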