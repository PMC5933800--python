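"""Model state, collapsed sufficient statistics, and posterior arithmetic.

A model with *m* modes assigns every sequence exactly one site: a mode
label, a 0-based start position and a strand.  PWM entries and mode
proportions are integrated out under Dirichlet priors, so the state carries
only the aligned base-count matrix of each mode (motif-strand oriented) and
the member counts.  The collapsed log posterior — the quantity the sampler
traces and maximises — is, up to an additive constant,

    sum_k [Dirichlet-multinomial marginal of mode k's count matrix]
    + [Dirichlet-multinomial marginal of the member-count vector]
    + sum_i [background log-probability of sequence i outside its site].

Uniform priors over positions, strands and widths are dropped as constants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .sequence_io import BASE_N, COMPLEMENT, EncodedSequence, SequenceSet

STRAND_PLUS, STRAND_MINUS = 0, 1
STRAND_CHARS = "+-"

_VERSION_COUNTER = itertools.count(1)


def new_version() -> int:
    """Globally unique, monotonically increasing count-matrix version.
    Uniqueness across copied states keeps cached derived matrices safe."""
    return next(_VERSION_COUNTER)


@dataclass(frozen=True)
class Hyperparameters:
    """Dirichlet pseudocounts of the collapsed model.

    beta: per-base pseudocount of every PWM column (default: the background
    mononucleotide composition, summing to 1 — weak, composition-weighted
    smoothing).  alpha_gamma: symmetric pseudocount on mode proportions.
    """

    beta: np.ndarray
    alpha_gamma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=np.float64))
        if self.beta.shape != (4,) or np.any(self.beta <= 0):
            raise ValueError("beta must be 4 positive pseudocounts")
        if self.alpha_gamma <= 0:
            raise ValueError("alpha_gamma must be positive")
        object.__setattr__(self, "_beta0", float(self.beta.sum()))

    @property
    def beta0(self) -> float:
        return self._beta0

    @classmethod
    def from_background(cls, mono_freqs: np.ndarray, total: float = 1.0,
                        alpha_gamma: float = 1.0) -> "Hyperparameters":
        return cls(beta=np.asarray(mono_freqs) * total, alpha_gamma=alpha_gamma)

    @classmethod
    def uniform(cls, total: float = 1.0, alpha_gamma: float = 1.0) -> "Hyperparameters":
        return cls(beta=np.full(4, total / 4.0), alpha_gamma=alpha_gamma)


@dataclass
class Assignment:
    """One sequence's site: mode label, 0-based start, strand ('+'/'-')."""

    mode: int
    position: int
    strand: str = "+"


@dataclass
class ModeCounts:
    """Aligned base counts of one mode's member sites (motif-strand
    oriented).  ``counts[a, b]`` = number of members with base ``b`` at
    motif position ``a``; N bases contribute to no cell, so each column sum
    equals the number of members with a non-N base there."""

    width: int
    counts: np.ndarray
    members: int = 0
    version: int = 0  # bumped on every mutation; lets scorers cache safely

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.width, 4):
            raise ValueError("counts must be width x 4")

    @classmethod
    def empty(cls, width: int) -> "ModeCounts":
        return cls(width=width, counts=np.zeros((width, 4), dtype=np.int64))

    def copy(self) -> "ModeCounts":
        return ModeCounts(self.width, self.counts.copy(), self.members,
                          self.version)


@dataclass
class ModeModel:
    """Reporting form of one mode: posterior-mean PWM and proportion."""

    pwm: np.ndarray
    members: int
    gamma_hat: float

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[b] for b in np.argmax(self.pwm, axis=1))


@dataclass
class ModelState:
    """Mutable sampler state for a fixed number of modes *m*.

    Per-sequence assignment vectors plus per-mode cached count matrices.
    ``included[i]`` is False while sequence i is temporarily removed during
    a Gibbs update.  Rebuilding the count matrices from the assignment
    vectors must reproduce the cache exactly at all times when every
    sequence is included.
    """

    m: int
    mode: np.ndarray       # (n,) int64, 0-based mode labels
    position: np.ndarray   # (n,) int64, 0-based starts
    strand: np.ndarray     # (n,) int8, 0='+' 1='-'
    widths: np.ndarray     # (m,) int64
    mode_counts: List[ModeCounts]
    hyper: Hyperparameters
    included: np.ndarray = field(default=None)  # (n,) bool
    log_post: Optional[float] = None

    def __post_init__(self) -> None:
        if self.included is None:
            self.included = np.ones(self.n, dtype=bool)

    @property
    def n(self) -> int:
        return int(self.mode.size)

    @property
    def members(self) -> np.ndarray:
        return np.array([mc.members for mc in self.mode_counts], dtype=np.int64)

    def copy(self) -> "ModelState":
        return ModelState(
            m=self.m,
            mode=self.mode.copy(),
            position=self.position.copy(),
            strand=self.strand.copy(),
            widths=self.widths.copy(),
            mode_counts=[mc.copy() for mc in self.mode_counts],
            hyper=self.hyper,
            included=self.included.copy(),
            log_post=self.log_post,
        )

    def assignments(self) -> List[Assignment]:
        return [
            Assignment(int(self.mode[i]), int(self.position[i]),
                       STRAND_CHARS[self.strand[i]])
            for i in range(self.n)
        ]


# ---------------------------------------------------------------------------
# site extraction and count bookkeeping

def revcomp(bases: np.ndarray) -> np.ndarray:
    """Reverse complement of encoded bases (N maps to N)."""
    return COMPLEMENT[bases][::-1]


def site_bases(seq: EncodedSequence, position: int, width: int,
               strand: str = "+") -> np.ndarray:
    """The site's bases in motif orientation: the slice for '+', its
    reverse complement for '-'.  N passes through unchanged."""
    if position < 0 or position + width > seq.length:
        raise ValueError(
            f"site [{position}, {position + width}) out of range "
            f"for sequence {seq.id!r} of length {seq.length}"
        )
    window = seq.bases[position : position + width]
    if strand in ("-", STRAND_MINUS, 1):
        return revcomp(window)
    return window.copy()


def _oriented_site(state: ModelState, seqs: SequenceSet, i: int) -> np.ndarray:
    strand = "-" if state.strand[i] == STRAND_MINUS else "+"
    k = int(state.mode[i])
    return site_bases(seqs[i], int(state.position[i]), int(state.widths[k]), strand)


def update_counts(state: ModelState, seqs: SequenceSet, i: int,
                  add: bool) -> ModelState:
    """Add or remove sequence i's oriented site bases to/from its mode's
    count matrix (in place).  N bases touch no cell."""
    if add and state.included[i]:
        raise ValueError(f"sequence {i} is already included")
    if not add and not state.included[i]:
        raise ValueError(f"sequence {i} is already excluded")
    k = int(state.mode[i])
    mc = state.mode_counts[k]
    site = _oriented_site(state, seqs, i)
    delta = 1 if add else -1
    for a in range(site.size):
        b = site[a]
        if b != BASE_N:
            mc.counts[a, b] += delta
    mc.members += delta
    mc.version = new_version()
    state.included[i] = add
    if not add and (mc.members < 0 or np.any(mc.counts < 0)):
        raise RuntimeError(f"negative count in mode {k}: bookkeeping error")
    return state


def rebuild_counts(state: ModelState, seqs: SequenceSet) -> List[ModeCounts]:
    """Count matrices recomputed from scratch from the assignments of all
    included sequences (consistency oracle for the cached ones)."""
    fresh = [ModeCounts.empty(int(w)) for w in state.widths]
    for i in range(state.n):
        if not state.included[i]:
            continue
        k = int(state.mode[i])
        site = _oriented_site(state, seqs, i)
        for a, b in enumerate(site):
            if b != BASE_N:
                fresh[k].counts[a, b] += 1
        fresh[k].members += 1
    return fresh


# ---------------------------------------------------------------------------
# collapsed scores

def log_predictive_matrix(mc: ModeCounts, hyper: Hyperparameters) -> np.ndarray:
    """(width, 5) matrix of log posterior-predictive base probabilities,
    column 4 (N) fixed at 0.  Row ``a`` is log[(counts[a,b] + beta_b) /
    (column_total_a + beta_0)]; column totals count only non-N members, so
    the predictive stays an exact Dirichlet-multinomial ratio."""
    col_tot = mc.counts.sum(axis=1, keepdims=True)
    lp = np.zeros((mc.width, 5), dtype=np.float64)
    lp[:, :4] = np.log(mc.counts + hyper.beta) - np.log(col_tot + hyper.beta0)
    return lp


def collapsed_site_score(mc: ModeCounts, site: np.ndarray,
                         hyper: Hyperparameters, bg_log_prob: float,
                         n_total: int, m: int) -> float:
    """Collapsed log odds of placing a site with the given bases into this
    mode, relative to the background.

    Equals log[(members + alpha) / (n_total - 1 + m*alpha)]
    + sum_a log predictive(site_a) - bg_log_prob, where the predictive is
    the Dirichlet-multinomial posterior ratio excluding the scored
    sequence.  N positions contribute to neither term.
    """
    if site.size != mc.width:
        raise ValueError("site length must equal the mode width")
    a = hyper.alpha_gamma
    score = np.log(mc.members + a) - np.log(n_total - 1 + m * a)
    lp = log_predictive_matrix(mc, hyper)
    score += lp[np.arange(site.size), site].sum()
    return float(score - bg_log_prob)


def _column_dirmult(counts: np.ndarray, beta: np.ndarray) -> float:
    """Sum over columns of the Dirichlet-multinomial log marginal of the
    count matrix (each motif column integrated against Dirichlet(beta))."""
    if counts.size == 0:
        return 0.0
    counts = np.asarray(counts, dtype=np.float64)
    beta0 = beta.sum()
    col_tot = counts.sum(axis=1)
    val = gammaln(counts + beta).sum() - gammaln(beta).sum() * counts.shape[0]
    val += counts.shape[0] * gammaln(beta0) - gammaln(col_tot + beta0).sum()
    return float(val)


def _membership_dirmult(members: np.ndarray, alpha: float, n: int) -> float:
    m = members.size
    return float(
        gammaln(m * alpha) - m * gammaln(alpha)
        + gammaln(members + alpha).sum() - gammaln(n + m * alpha)
    )


def model_log_posterior(state: ModelState, bg_prefix: Sequence[np.ndarray]) -> float:
    """Collapsed log posterior of the state (up to an additive constant).

    ``bg_prefix[i]`` is the background cumulative log-probability array of
    sequence i (:meth:`BackgroundModel.prefix_log_prob`).  All sequences
    must be included.
    """
    if not np.all(state.included):
        raise ValueError("log posterior requires every sequence included")
    if int(state.members.sum()) != state.n:
        raise ValueError("member counts inconsistent with n")
    total = _membership_dirmult(state.members, state.hyper.alpha_gamma, state.n)
    for mc in state.mode_counts:
        total += _column_dirmult(mc.counts, state.hyper.beta)
    for i in range(state.n):
        pref = bg_prefix[i]
        z = int(state.position[i])
        w = int(state.widths[state.mode[i]])
        # background over the whole sequence minus the site window
        total += float(pref[-1] - (pref[z + w] - pref[z]))
    return float(total)


def mode_models(state: ModelState) -> List[ModeModel]:
    """Posterior-mean PWMs and mode proportions from the current counts."""
    a = state.hyper.alpha_gamma
    members = state.members
    gammas = (members + a) / (members.sum() + state.m * a)
    out = []
    for k, mc in enumerate(state.mode_counts):
        col_tot = mc.counts.sum(axis=1, keepdims=True)
        pwm = (mc.counts + state.hyper.beta) / (col_tot + state.hyper.beta0)
        out.append(ModeModel(pwm=pwm, members=int(mc.members),
                             gamma_hat=float(gammas[k])))
    return out


def sequence_log_likelihood(state: ModelState, bg, seqs: SequenceSet, i: int,
                            params: Optional[List[ModeModel]] = None) -> float:
    """Point-estimate log likelihood of sequence i: background prefix +
    PWM window (oriented by strand) + background suffix."""
    if params is None:
        params = mode_models(state)
    seq = seqs[i]
    k = int(state.mode[i])
    z = int(state.position[i])
    w = int(state.widths[k])
    pwm = params[k].pwm
    strand = "-" if state.strand[i] == STRAND_MINUS else "+"
    site = site_bases(seq, z, w, strand)
    total = 0.0
    for a, b in enumerate(site):
        if b != BASE_N:
            total += float(np.log(pwm[a, b]))
    pref = bg.prefix_log_prob(seq)
    total += float(pref[z] - pref[0]) + float(pref[-1] - pref[z + w])
    return total
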