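"""Collapsed Gibbs sampler for one chain: assignment and width moves,
convergence detection, the iteration cap, and terminal hill climbing.

One *sweep* resamples every sequence's (mode, position, strand) in fixed
index order from its collapsed conditional, then proposes the five width
moves (no change; grow/shrink one column on the motif's left or right) for
each mode in turn.  The per-sweep collapsed log posterior is traced;
sampling stops when the ordinary-least-squares slope over the trailing
window is near zero, or when the budget of per-sequence updates (default
2*n^2, i.e. 2n sweeps) is exhausted.  A deterministic hill climb from the
highest-posterior sample then yields the MAP estimate.

Every chain is a pure function of (sequence set, background, config): all
randomness flows from the config seed through one PCG64 generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .background import BackgroundModel
from .model_core import (
    Hyperparameters,
    ModeCounts,
    ModelState,
    STRAND_MINUS,
    _column_dirmult,
    log_predictive_matrix,
    model_log_posterior,
    new_version,
    update_counts,
)
from .sequence_io import BASE_N, COMPLEMENT, SequenceSet


@dataclass
class ChainConfig:
    """Settings of a single sampling chain."""

    m: int
    seed: int = 0
    w_init: int = 12
    w_min: int = 6
    w_max: int = 40
    slope_tol: float = 1e-3
    trace_window: Optional[int] = None       # default: n sweeps (one per sequence)
    max_updates: Optional[int] = None        # default: 2 * n**2 assignment updates
    hill_climb_max_rounds: int = 50
    double_strand: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.w_min <= self.w_init <= self.w_max):
            raise ValueError("need w_min <= w_init <= w_max")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    def resolved_window(self, n: int) -> int:
        """Trailing-window length for the stop rule.  The default — the
        last n sweeps — doubles as a patience horizon: the sampler often
        sits on a flat metastable plateau for tens of sweeps before a motif
        nucleates, and a short window mistakes that plateau for
        convergence."""
        return self.trace_window if self.trace_window is not None else max(n, 2)

    def resolved_max_updates(self, n: int) -> int:
        return self.max_updates if self.max_updates is not None else 2 * n * n


@dataclass
class ChainResult:
    """Outcome of one chain: the hill-climbed MAP state and its trace."""

    best_state: ModelState
    map_log_post: float
    trace: np.ndarray
    sweeps_run: int
    converged: bool


@dataclass
class SamplerContext:
    """Precomputed per-run quantities: encoded sequences as int64 arrays
    and the background cumulative log-probability of every sequence."""

    seqs: SequenceSet
    bg: BackgroundModel
    enc: List[np.ndarray]
    bg_prefix: List[np.ndarray]
    double_strand: bool = True
    _win_cache: dict = field(default_factory=dict, repr=False)
    _lp_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def build(cls, seqs: SequenceSet, bg: BackgroundModel,
              double_strand: bool = True) -> "SamplerContext":
        enc = [s.bases.astype(np.int64) for s in seqs]
        pref = [bg.prefix_log_prob(s) for s in seqs]
        return cls(seqs=seqs, bg=bg, enc=enc, bg_prefix=pref,
                   double_strand=double_strand)

    def padded(self):
        """(enc2d, lengths, pref2d) padded matrices for the compiled sweep."""
        cached = self._win_cache.get("_padded")
        if cached is None:
            n = self.seqs.n
            lengths = np.array([e.size for e in self.enc], dtype=np.int64)
            Lmax = int(lengths.max())
            enc2d = np.full((n, Lmax), 4, dtype=np.int64)
            pref2d = np.zeros((n, Lmax + 1), dtype=np.float64)
            for i, (e, p) in enumerate(zip(self.enc, self.bg_prefix)):
                enc2d[i, : e.size] = e
                pref2d[i, : p.size] = p
            cached = (enc2d, lengths, pref2d)
            self._win_cache["_padded"] = cached
        return cached

    def windows(self, i: int, w: int) -> np.ndarray:
        """Cached (L-w+1, w) sliding view of sequence i's encoded bases."""
        key = (i, w)
        win = self._win_cache.get(key)
        if win is None:
            win = sliding_window_view(self.enc[i], w)
            self._win_cache[key] = win
        return win

    def log_predictive(self, k: int, mc: ModeCounts, hyper: Hyperparameters):
        """Per-mode cached (log-predictive, reverse-complement log-predictive,
        row-index) triple, keyed by the count-matrix version."""
        key = (mc.version, mc.width)
        cached = self._lp_cache.get(k)
        if cached is not None and cached[0] == key:
            return cached[1]
        lp = log_predictive_matrix(mc, hyper)
        lp_rc = np.ascontiguousarray(lp[::-1][:, COMPLEMENT])
        entry = (lp, lp_rc, np.arange(mc.width))
        self._lp_cache[k] = (key, entry)
        return entry


@dataclass
class CandidateTable:
    """All (mode, position, strand) candidates for one sequence, in the
    fixed ordering mode-major, then position, then '+' before '-'."""

    mode: np.ndarray
    position: np.ndarray
    strand: np.ndarray
    log_score: np.ndarray
    prob: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.prob is None:
            s = self.log_score - self.log_score.max()
            p = np.exp(s)
            self.prob = p / p.sum()

    def __len__(self) -> int:
        return int(self.mode.size)


def default_hyper(bg: BackgroundModel) -> Hyperparameters:
    """Composition-weighted PWM pseudocounts (beta_0 = 1), alpha_gamma = 1."""
    return Hyperparameters.from_background(bg.mono_freqs, total=1.0, alpha_gamma=1.0)


# ---------------------------------------------------------------------------
# initialisation

def init_state(seqs: SequenceSet, bg: BackgroundModel, config: ChainConfig,
               rng: Optional[np.random.Generator] = None) -> ModelState:
    """Uniform-random starting state: positions uniform over valid starts,
    modes uniform over 1..m, strand uniform (or '+' only)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = seqs.n
    w = config.w_init
    for s in seqs:
        if s.length < w:
            raise ValueError(
                f"sequence {s.id!r} (length {s.length}) is shorter than the "
                f"initial motif width {w}"
            )
    position = np.array(
        [rng.integers(0, s.length - w + 1) for s in seqs], dtype=np.int64
    )
    mode = rng.integers(0, config.m, size=n).astype(np.int64)
    if config.double_strand:
        strand = rng.integers(0, 2, size=n).astype(np.int8)
    else:
        strand = np.zeros(n, dtype=np.int8)
    widths = np.full(config.m, w, dtype=np.int64)
    state = ModelState(
        m=config.m, mode=mode, position=position, strand=strand,
        widths=widths, mode_counts=[ModeCounts.empty(w) for _ in range(config.m)],
        hyper=default_hyper(bg), included=np.zeros(n, dtype=bool),
    )
    for i in range(n):
        update_counts(state, seqs, i, add=True)
    return state


# ---------------------------------------------------------------------------
# assignment moves

def _mode_position_scores(state: ModelState, ctx: SamplerContext, i: int,
                          k: int) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Collapsed site scores of sequence i at every valid start of mode k,
    for '+' and (when double-stranded) '-'.  Sequence i must be excluded."""
    enc = ctx.enc[i]
    pref = ctx.bg_prefix[i]
    mc = state.mode_counts[k]
    w = mc.width
    L = enc.size
    npos = L - w + 1
    if npos <= 0:
        return np.empty(0), (np.empty(0) if ctx.double_strand else None)
    a = state.hyper.alpha_gamma
    membership = math.log(mc.members + a) - math.log(state.n - 1 + state.m * a)
    bg_win = pref[w:] - pref[:-w]  # (npos,)
    lp, lp_rc, rows = ctx.log_predictive(k, mc, state.hyper)
    win = ctx.windows(i, w)  # (npos, w) view
    plus = lp[rows, win].sum(axis=1) + (membership - bg_win)
    if not ctx.double_strand:
        return plus, None
    minus = lp_rc[rows, win].sum(axis=1) + (membership - bg_win)
    return plus, minus


def conditional_distribution(state: ModelState, ctx: SamplerContext,
                             i: int) -> CandidateTable:
    """Full conditional over (mode, position, strand) for sequence i, whose
    counts must already be removed from the state."""
    if state.included[i]:
        raise ValueError(f"sequence {i} must be removed before scoring")
    modes, positions, strands, scores = [], [], [], []
    for k in range(state.m):
        plus, minus = _mode_position_scores(state, ctx, i, k)
        npos = plus.size
        if npos == 0:
            continue
        pos = np.arange(npos, dtype=np.int64)
        if minus is None:
            modes.append(np.full(npos, k, dtype=np.int64))
            positions.append(pos)
            strands.append(np.zeros(npos, dtype=np.int8))
            scores.append(plus)
        else:
            # interleave '+' then '-' at each position
            modes.append(np.full(2 * npos, k, dtype=np.int64))
            p2 = np.empty(2 * npos, dtype=np.int64)
            p2[0::2] = pos
            p2[1::2] = pos
            positions.append(p2)
            s2 = np.empty(2 * npos, dtype=np.int8)
            s2[0::2] = 0
            s2[1::2] = 1
            strands.append(s2)
            sc = np.empty(2 * npos, dtype=np.float64)
            sc[0::2] = plus
            sc[1::2] = minus
            scores.append(sc)
    if not modes:
        raise ValueError(
            f"sequence {i} admits no candidate site for any mode "
            "(all mode widths exceed its length)"
        )
    return CandidateTable(
        mode=np.concatenate(modes),
        position=np.concatenate(positions),
        strand=np.concatenate(strands),
        log_score=np.concatenate(scores),
    )


def sample_assignment(state: ModelState, ctx: SamplerContext, i: int,
                      rng: np.random.Generator) -> ModelState:
    """One collapsed Gibbs update of sequence i: remove it, draw a new
    (mode, position, strand) by inverse CDF over the fixed candidate
    ordering using a single uniform variate, and add it back."""
    update_counts(state, ctx.seqs, i, add=False)
    tbl = conditional_distribution(state, ctx, i)
    u = rng.random()
    cum = np.cumsum(tbl.prob)
    idx = int(np.searchsorted(cum, u, side="right"))
    idx = min(idx, len(tbl) - 1)
    state.mode[i] = tbl.mode[idx]
    state.position[i] = tbl.position[idx]
    state.strand[i] = tbl.strand[idx]
    update_counts(state, ctx.seqs, i, add=True)
    return state


# ---------------------------------------------------------------------------
# width moves

#: width move candidates as (motif-left delta, motif-right delta), in the
#: fixed order used for sampling and tie-breaking
_WIDTH_MOVES = (
    ("none", 0, 0),
    ("grow_left", 1, 0),
    ("shrink_left", -1, 0),
    ("grow_right", 0, 1),
    ("shrink_right", 0, -1),
)


@dataclass
class _WidthCandidate:
    name: str
    dl: int
    dr: int
    new_width: int
    score: float
    new_counts: np.ndarray


def _width_candidates(state: ModelState, ctx: SamplerContext, k: int,
                      w_min: int, w_max: int) -> List[_WidthCandidate]:
    """Feasible width moves for mode k with their collapsed scores.

    Each score is the Dirichlet-multinomial marginal of the mode's count
    matrix under the new window minus the background log-probability of all
    member bases the new window covers — exactly the terms of the collapsed
    log posterior that the move changes.
    """
    mc = state.mode_counts[k]
    w = mc.width
    members = np.flatnonzero((state.mode == k) & state.included)
    # aggregate per-member quantities in one pass
    bg_cur = 0.0
    d_gl = d_sl = d_gr = d_sr = 0.0
    col_gl = np.zeros(4)
    col_gr = np.zeros(4)
    gl_ok = gr_ok = True
    for i in members:
        z = int(state.position[i])
        enc = ctx.enc[i]
        pref = ctx.bg_prefix[i]
        L = enc.size
        minus = state.strand[i] == STRAND_MINUS
        bg_cur += pref[z + w] - pref[z]
        # forward coordinates of the motif's left/right flanking columns
        if not minus:
            lflank, lcol, rcol, rflank = z - 1, z, z + w - 1, z + w
        else:
            lflank, lcol, rcol, rflank = z + w, z + w - 1, z, z - 1
        # grow on the motif's left: needs the flanking base to exist
        if 0 <= lflank < L:
            d_gl += pref[lflank + 1] - pref[lflank]
            b = enc[lflank]
            if minus:
                b = COMPLEMENT[b]
            if b != BASE_N:
                col_gl[b] += 1
        else:
            gl_ok = False
        d_sl += pref[lcol + 1] - pref[lcol]
        if 0 <= rflank < L:
            d_gr += pref[rflank + 1] - pref[rflank]
            b = enc[rflank]
            if minus:
                b = COMPLEMENT[b]
            if b != BASE_N:
                col_gr[b] += 1
        else:
            gr_ok = False
        d_sr += pref[rcol + 1] - pref[rcol]

    beta = state.hyper.beta
    dm_cur = _column_dirmult(mc.counts, beta)
    counts = mc.counts.astype(np.float64)
    out = []
    for name, dl, dr in _WIDTH_MOVES:
        nw = w + dl + dr
        if name != "none" and not (w_min <= nw <= w_max):
            continue
        if name == "grow_left" and not gl_ok:
            continue
        if name == "grow_right" and not gr_ok:
            continue
        if name == "none":
            score = dm_cur - bg_cur
            newc = mc.counts
        elif name == "grow_left":
            score = dm_cur + _column_dirmult(col_gl[None, :], beta) - (bg_cur + d_gl)
            newc = np.vstack([col_gl, counts]).astype(np.int64)
        elif name == "shrink_left":
            score = dm_cur - _column_dirmult(counts[:1], beta) - (bg_cur - d_sl)
            newc = mc.counts[1:]
        elif name == "grow_right":
            score = dm_cur + _column_dirmult(col_gr[None, :], beta) - (bg_cur + d_gr)
            newc = np.vstack([counts, col_gr]).astype(np.int64)
        else:  # shrink_right
            score = dm_cur - _column_dirmult(counts[-1:], beta) - (bg_cur - d_sr)
            newc = mc.counts[:-1]
        out.append(_WidthCandidate(name, dl, dr, nw, float(score), newc))
    return out


def _apply_width_move(state: ModelState, k: int, cand: _WidthCandidate) -> None:
    if cand.name == "none":
        return
    members = np.flatnonzero((state.mode == k) & state.included)
    for i in members:
        if state.strand[i] == STRAND_MINUS:
            state.position[i] -= cand.dr
        else:
            state.position[i] -= cand.dl
    state.widths[k] = cand.new_width
    state.mode_counts[k] = ModeCounts(
        width=cand.new_width,
        counts=np.ascontiguousarray(cand.new_counts, dtype=np.int64),
        members=state.mode_counts[k].members,
        version=new_version(),
    )


def sample_widths(state: ModelState, ctx: SamplerContext,
                  rng: np.random.Generator, w_min: int,
                  w_max: int) -> ModelState:
    """Sample one width move per mode, in mode order, each proportional to
    exp(score).  Empty modes keep their width and consume no randomness."""
    for k in range(state.m):
        if state.mode_counts[k].members == 0:
            continue
        cands = _width_candidates(state, ctx, k, w_min, w_max)
        scores = np.array([c.score for c in cands])
        p = np.exp(scores - scores.max())
        p /= p.sum()
        u = rng.random()
        idx = int(np.searchsorted(np.cumsum(p), u, side="right"))
        idx = min(idx, len(cands) - 1)
        _apply_width_move(state, k, cands[idx])
    return state


# ---------------------------------------------------------------------------
# sweeps, convergence, hill climbing

def gibbs_sweep(state: ModelState, ctx: SamplerContext,
                rng: np.random.Generator, config: ChainConfig,
                trace: Optional[list] = None) -> ModelState:
    """One full sweep: resample every assignment in index order (one
    uniform variate per sequence), then the widths; append the collapsed
    log posterior to ``trace``."""
    _sweep_assignments_fast(state, ctx, rng)
    sample_widths(state, ctx, rng, config.w_min, config.w_max)
    state.log_post = model_log_posterior(state, ctx.bg_prefix)
    if trace is not None:
        trace.append(state.log_post)
    return state


def _sweep_assignments_fast(state: ModelState, ctx: SamplerContext,
                            rng: np.random.Generator) -> None:
    """Assignment phase of a sweep through the compiled kernel: pack the
    count matrices into a padded tensor, run the in-place pass, unpack."""
    from ._kernels import _sweep_assignments

    enc2d, lengths, pref2d = ctx.padded()
    m = state.m
    widths = state.widths
    wmax = int(widths.max())
    counts = np.zeros((m, wmax, 4), dtype=np.float64)
    members = np.empty(m, dtype=np.int64)
    for k, mc in enumerate(state.mode_counts):
        counts[k, : mc.width] = mc.counts
        members[k] = mc.members
    uniforms = rng.random(state.n)
    _sweep_assignments(
        enc2d, lengths, pref2d, counts, widths.astype(np.int64), members,
        state.mode, state.position, state.strand,
        state.hyper.beta, state.hyper.beta0, state.hyper.alpha_gamma,
        ctx.double_strand, uniforms,
    )
    for k, mc in enumerate(state.mode_counts):
        mc.counts[:] = counts[k, : mc.width].astype(np.int64)
        mc.members = int(members[k])
        mc.version = new_version()


def check_convergence(trace: Sequence[float], window: int,
                      slope_tol: float, t_crit: float = 2.0) -> bool:
    """Flat-trace stop rule on the trailing ``window`` log posteriors.

    Fits an ordinary-least-squares line through (sweep index, log
    posterior) and declares convergence when the slope is close to zero:
    either its magnitude is below ``slope_tol``, or it is not significantly
    positive given the trace noise (slope <= t_crit standard errors).  The
    noise-aware clause matters because a stationary but fluctuating trace
    produces slope estimates whose sampling error far exceeds any fixed
    small tolerance.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(trace) < window:
        return False
    y = np.asarray(trace[-window:], dtype=np.float64)
    x = np.arange(window, dtype=np.float64)
    x -= x.mean()
    sxx = float((x * x).sum())
    slope = float((x * (y - y.mean())).sum() / sxx)
    if abs(slope) < slope_tol:
        return True
    resid = y - y.mean() - slope * x
    dof = max(window - 2, 1)
    se = float(np.sqrt((resid * resid).sum() / dof / sxx))
    return slope <= t_crit * se


def hill_climb(state: ModelState, ctx: SamplerContext, config: ChainConfig,
               max_rounds: Optional[int] = None) -> ModelState:
    """Deterministic coordinate ascent from the best sample: set every
    assignment to the argmax of its conditional, then every width to its
    argmax move, until a full round changes nothing.  Ties break toward the
    first candidate in the fixed ordering, so each move is non-decreasing
    in the collapsed log posterior."""
    if max_rounds is None:
        max_rounds = config.hill_climb_max_rounds
    for _ in range(max_rounds):
        changed = False
        for i in range(state.n):
            update_counts(state, ctx.seqs, i, add=False)
            tbl = conditional_distribution(state, ctx, i)
            idx = int(np.argmax(tbl.log_score))
            new = (tbl.mode[idx], tbl.position[idx], tbl.strand[idx])
            if (state.mode[i], state.position[i], state.strand[i]) != new:
                changed = True
            state.mode[i], state.position[i], state.strand[i] = new
            update_counts(state, ctx.seqs, i, add=True)
        for k in range(state.m):
            if state.mode_counts[k].members == 0:
                continue
            cands = _width_candidates(state, ctx, k, config.w_min, config.w_max)
            idx = int(np.argmax([c.score for c in cands]))
            if cands[idx].name != "none":
                changed = True
                _apply_width_move(state, k, cands[idx])
        if not changed:
            break
    state.log_post = model_log_posterior(state, ctx.bg_prefix)
    return state


def run_chain(seqs: SequenceSet, bg: BackgroundModel,
              config: ChainConfig) -> ChainResult:
    """Run one chain to convergence (or the update cap), then hill-climb
    from the highest-posterior sample seen."""
    ctx = SamplerContext.build(seqs, bg, double_strand=config.double_strand)
    rng = np.random.default_rng(config.seed)
    state = init_state(seqs, bg, config, rng)
    n = seqs.n
    window = config.resolved_window(n)
    max_updates = config.resolved_max_updates(n)
    trace: List[float] = []
    best_lp = -np.inf
    best_state = None
    converged = False
    updates = 0
    while True:
        gibbs_sweep(state, ctx, rng, config, trace)
        updates += n
        if trace[-1] > best_lp:
            best_lp = trace[-1]
            best_state = state.copy()
        if check_convergence(trace, window, config.slope_tol):
            converged = True
            break
        if updates >= max_updates:
            break
    final = hill_climb(best_state, ctx, config)
    return ChainResult(
        best_state=final,
        map_log_post=float(final.log_post),
        trace=np.asarray(trace),
        sweeps_run=len(trace),
        converged=converged,
    )
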