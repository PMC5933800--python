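"""Synthetic sequence sets with planted binding modes.

The generator mirrors the model's own likelihood read generatively: each
sequence draws a mode from the mixing proportions, a start uniform over the
valid positions, and a strand uniform over both (or '+' only); background
bases come from a Markov chain and the site's bases column-wise from the
mode's PWM, reverse-complemented into place on '-'.  Planting replaces
background bases, keeping the sequence length fixed.

The recovery scorer compares an inference result against the planted truth
after optimal one-to-one label matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment

from .background import BackgroundModel
from .model_core import STRAND_MINUS, mode_models
from .sequence_io import COMPLEMENT, EncodedSequence, SequenceSet


def consensus_pwm(consensus: str, p: float = 0.94) -> np.ndarray:
    """PWM putting probability ``p`` on each consensus base and the rest
    spread evenly.  ``p = 0.94`` gives about 1.6 bits of information per
    column."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(consensus)
    pwm = np.full((w, 4), (1.0 - p) / 3.0)
    for a, ch in enumerate(consensus.upper()):
        pwm[a, code[ch]] = p
    return pwm


def random_consensus_pwm(width: int, rng: np.random.Generator,
                         p: float = 0.94) -> np.ndarray:
    cons = "".join("ACGT"[b] for b in rng.integers(0, 4, size=width))
    return consensus_pwm(cons, p)


def pwm_information(pwm: np.ndarray) -> np.ndarray:
    """Per-column information content in bits."""
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(pwm > 0, pwm * np.log2(pwm), 0.0).sum(axis=1)
    return 2.0 - h


@dataclass
class PlantSpec:
    """Recipe for one synthetic dataset."""

    n: int
    length: int
    gamma: np.ndarray                 # (K,) mode proportions, sums to 1
    pwms: List[np.ndarray]            # K PWMs, possibly different widths
    background: Union[BackgroundModel, np.ndarray, None] = None
    double_strand: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if not np.isclose(self.gamma.sum(), 1.0):
            raise ValueError("gamma must sum to 1")
        if self.gamma.size != len(self.pwms):
            raise ValueError("one PWM per mode required")
        for pwm in self.pwms:
            if not np.allclose(pwm.sum(axis=1), 1.0):
                raise ValueError("PWM rows must sum to 1")
            if pwm.shape[0] > self.length:
                raise ValueError("sequence length must be >= every PWM width")
        if self.n < 1 or self.length < 1:
            raise ValueError("n and length must be positive")

    @property
    def k(self) -> int:
        return len(self.pwms)


@dataclass
class TruthTable:
    """Planted ground truth: per sequence, the mode (0-based), the 0-based
    forward-coordinate start of the planted window, and the strand."""

    mode: np.ndarray
    start: np.ndarray
    strand: np.ndarray  # int8: 0='+', 1='-'

    @property
    def n(self) -> int:
        return int(self.mode.size)

    def to_tsv(self, path: Union[str, Path], ids: Sequence[str]) -> None:
        with open(path, "w") as fh:
            fh.write("id\tmode\tstart_1based\tstrand\n")
            for i in range(self.n):
                fh.write(
                    f"{ids[i]}\t{int(self.mode[i]) + 1}\t"
                    f"{int(self.start[i]) + 1}\t"
                    f"{'-' if self.strand[i] else '+'}\n"
                )


def _background_sampler(background, length: int, rng: np.random.Generator):
    """Draw one background sequence of the given length."""
    if background is None:
        freqs = np.full(4, 0.25)
    elif isinstance(background, BackgroundModel):
        bases = np.empty(length, dtype=np.uint8)
        for j in range(length):
            c = min(background.order, j)
            idx = 0
            for t in range(j - c, j):
                idx = idx * 4 + int(bases[t])
            probs = background.cond_prob[c][idx]
            bases[j] = rng.choice(4, p=probs)
        return bases
    else:
        freqs = np.asarray(background, dtype=np.float64)
        freqs = freqs / freqs.sum()
    cum = np.cumsum(freqs)
    return np.searchsorted(cum, rng.random(length), side="right").astype(np.uint8)


def _sample_site(pwm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(pwm, axis=1)
    u = rng.random(pwm.shape[0])
    return np.array(
        [np.searchsorted(cum[a], u[a], side="right") for a in range(pwm.shape[0])],
        dtype=np.uint8,
    )


def generate_dataset(spec: PlantSpec):
    """Generate (SequenceSet, TruthTable) with exactly one planted site per
    sequence.  Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    widths = [pwm.shape[0] for pwm in spec.pwms]
    modes = np.empty(spec.n, dtype=np.int64)
    starts = np.empty(spec.n, dtype=np.int64)
    strands = np.zeros(spec.n, dtype=np.int8)
    records = []
    ndigits = len(str(spec.n))
    for i in range(spec.n):
        k = int(rng.choice(spec.k, p=spec.gamma))
        w = widths[k]
        z = int(rng.integers(0, spec.length - w + 1))
        s = int(rng.integers(0, 2)) if spec.double_strand else 0
        bases = _background_sampler(spec.background, spec.length, rng)
        site = _sample_site(spec.pwms[k], rng)
        if s == STRAND_MINUS:
            site = COMPLEMENT[site][::-1]
        bases[z : z + w] = site
        modes[i], starts[i], strands[i] = k, z, s
        records.append(EncodedSequence(id=f"seq{i + 1:0{ndigits}d}", bases=bases))
    return SequenceSet(records), TruthTable(mode=modes, start=starts, strand=strands)


# ---------------------------------------------------------------------------
# recovery scoring

@dataclass
class RecoveryReport:
    """Agreement between inferred and planted structure after optimal
    one-to-one label matching."""

    label_accuracy: float
    site_accuracy: float
    pwm_mad: float
    mode_map: dict          # inferred mode -> true mode
    n_matched_modes: int


def _best_offset_mad(inferred: np.ndarray, truth: np.ndarray) -> float:
    """Minimum mean absolute difference between two PWMs over overlapping
    columns, over all offsets and both orientations of the inferred PWM."""
    best = np.inf
    for cand in (inferred, inferred[::-1, ::-1]):
        wi, wt = cand.shape[0], truth.shape[0]
        for off in range(-(wi - 1), wt):
            lo_t, hi_t = max(0, off), min(wt, off + wi)
            if hi_t - lo_t < min(wi, wt) // 2 + 1:
                continue
            sl_t = truth[lo_t:hi_t]
            sl_i = cand[lo_t - off : hi_t - off]
            best = min(best, float(np.abs(sl_i - sl_t).mean()))
    return best


def score_recovery(truth: TruthTable, result, slack: int = 1,
                   true_pwms: Optional[List[np.ndarray]] = None) -> RecoveryReport:
    """Score an inference result (a SearchResult or a bare ModelState)
    against the planted truth.

    Labels are matched one-to-one by maximising agreement
    (linear assignment on the contingency table); site accuracy counts a
    sequence when, among label-matched sequences, the inferred window's
    left or right edge lies within ``slack`` of the planted window's
    corresponding edge (edge matching absorbs small width mismatches and
    opposite-strand discoveries of the same physical site).
    """
    state = result.best_state if hasattr(result, "best_state") else result
    if state.n != truth.n:
        raise ValueError("truth and result cover different numbers of sequences")
    k_true = int(truth.mode.max()) + 1
    m = state.m
    contingency = np.zeros((m, k_true), dtype=np.int64)
    for i in range(state.n):
        contingency[state.mode[i], truth.mode[i]] += 1
    rows, cols = linear_sum_assignment(-contingency)
    mode_map = {int(r): int(c) for r, c in zip(rows, cols)}

    agree = sum(int(contingency[r, c]) for r, c in mode_map.items())
    label_accuracy = agree / truth.n

    true_widths = None
    if true_pwms is not None:
        true_widths = [p.shape[0] for p in true_pwms]

    hits = 0
    matched_total = 0
    for i in range(state.n):
        r = int(state.mode[i])
        if mode_map.get(r) != int(truth.mode[i]):
            continue
        matched_total += 1
        z = int(state.position[i])
        w = int(state.widths[r])
        t = int(truth.start[i])
        if true_widths is not None:
            v = true_widths[int(truth.mode[i])]
        else:
            v = w
        if abs(z - t) <= slack or abs((z + w) - (t + v)) <= slack:
            hits += 1
    site_accuracy = hits / truth.n

    pwm_mad = np.nan
    if true_pwms is not None and mode_map:
        inferred = mode_models(state)
        mads = [
            _best_offset_mad(inferred[r].pwm, true_pwms[c])
            for r, c in mode_map.items()
            if inferred[r].members > 0
        ]
        if mads:
            pwm_mad = float(np.mean(mads))

    return RecoveryReport(
        label_accuracy=float(label_accuracy),
        site_accuracy=float(site_accuracy),
        pwm_mad=pwm_mad,
        mode_map=mode_map,
        n_matched_modes=len(mode_map),
    )
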