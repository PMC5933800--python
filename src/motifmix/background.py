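"""Order-k Markov background model of the input sequence set.

The background distribution is fitted once from the whole dataset (default
order 2) and frozen; it is never resampled.  Lower-order tables are fitted
from the same data and used near sequence starts where fewer preceding
bases exist.

N handling: windows containing an N are skipped while counting; when
scoring, an N base contributes probability 1 (log 0) and an N inside a
context truncates the context to the bases after the N.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Union

import numpy as np

from .sequence_io import BASE_N, ALPHABET, EncodedSequence, SequenceSet


@dataclass
class BackgroundModel:
    """Markov chain over {A,C,G,T} with per-context conditional tables.

    ``cond_prob[c]`` has shape ``(4**c, 4)``: row ``r`` is the distribution
    of the next base given the length-``c`` context whose big-endian base-4
    encoding is ``r``.  All probabilities are strictly positive whenever the
    fitting pseudocount is positive.
    """

    order: int
    pseudocount: float
    cond_prob: List[np.ndarray] = field(repr=False)
    log_cond: List[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.cond_prob) != self.order + 1:
            raise ValueError("need one conditional table per context length 0..order")
        for c, tab in enumerate(self.cond_prob):
            if tab.shape != (4**c, 4):
                raise ValueError(f"table for context length {c} has shape {tab.shape}")
            sums = tab.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("conditional probability rows must sum to 1")
        with np.errstate(divide="ignore"):
            self.log_cond = [np.log(tab) for tab in self.cond_prob]

    @property
    def mono_freqs(self) -> np.ndarray:
        """Order-0 mononucleotide frequencies (A,C,G,T)."""
        return self.cond_prob[0][0]

    # -- scoring -----------------------------------------------------------

    def position_log_prob(self, seq: EncodedSequence, j: int) -> float:
        """log P(base at j | preceding context), truncating at N and at the
        sequence start; an N base itself contributes 0."""
        bases = seq.bases
        b = bases[j]
        if b == BASE_N:
            return 0.0
        c = min(self.order, j)
        # truncate the context after the most recent N
        start = j - c
        for t in range(j - 1, start - 1, -1):
            if bases[t] == BASE_N:
                start = t + 1
                break
        c = j - start
        idx = 0
        for t in range(start, j):
            idx = idx * 4 + int(bases[t])
        return float(self.log_cond[c][idx, int(b)])

    def per_position_log_prob(self, seq: EncodedSequence) -> np.ndarray:
        """Vector of per-position conditional log-probabilities."""
        bases = seq.bases.astype(np.int64)
        L = bases.size
        out = np.empty(L, dtype=np.float64)
        k = self.order
        has_n = bool(np.any(bases == BASE_N))
        if not has_n and L > k:
            # fast path: full-order contexts for j >= k
            idx = np.zeros(L - k, dtype=np.int64)
            for off in range(k):
                idx = idx * 4 + bases[off : off + L - k]
            out[k:] = self.log_cond[k][idx, bases[k:]]
            for j in range(min(k, L)):
                out[j] = self.position_log_prob(seq, j)
            return out
        for j in range(L):
            out[j] = self.position_log_prob(seq, j)
        return out

    def prefix_log_prob(self, seq: EncodedSequence) -> np.ndarray:
        """Cumulative array ``P`` with ``P[e] - P[s]`` = log-probability of
        the segment [s, e).  Length ``L + 1``."""
        out = np.zeros(seq.length + 1, dtype=np.float64)
        np.cumsum(self.per_position_log_prob(seq), out=out[1:])
        return out

    # -- serialization -----------------------------------------------------

    def to_text(self, path: Union[str, Path]) -> None:
        """Write the model as a plain-text table, one context per line."""
        with open(path, "w") as fh:
            fh.write(f"# markov background  order={self.order}  "
                     f"pseudocount={self.pseudocount:g}\n")
            fh.write("# context\tP(A)\tP(C)\tP(G)\tP(T)\n")
            for c, tab in enumerate(self.cond_prob):
                for r, ctx in enumerate(itertools.product(ALPHABET[:4], repeat=c)):
                    label = "".join(ctx) if c else "."
                    probs = "\t".join(f"{p:.10g}" for p in tab[r])
                    fh.write(f"{label}\t{probs}\n")

    @classmethod
    def from_text(cls, path: Union[str, Path]) -> "BackgroundModel":
        order = None
        pseudocount = 1.0
        rows = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for tok in line.split():
                        if tok.startswith("order="):
                            order = int(tok.split("=")[1])
                        elif tok.startswith("pseudocount="):
                            pseudocount = float(tok.split("=")[1])
                    continue
                if not line:
                    continue
                label, *probs = line.split("\t")
                rows[label if label != "." else ""] = np.array(
                    [float(p) for p in probs]
                )
        if order is None:
            raise ValueError("missing order header")
        tables = []
        code = {ch: i for i, ch in enumerate(ALPHABET[:4])}
        for c in range(order + 1):
            tab = np.zeros((4**c, 4))
            for ctx in itertools.product(ALPHABET[:4], repeat=c):
                label = "".join(ctx)
                idx = 0
                for ch in label:
                    idx = idx * 4 + code[ch]
                tab[idx] = rows[label]
            tables.append(tab)
        return cls(order=order, pseudocount=pseudocount, cond_prob=tables)


def fit_background(
    sset: SequenceSet, order: int = 2, pseudocount: float = 1.0
) -> BackgroundModel:
    """Fit the background Markov model from the whole dataset.

    For each context length ``c`` in 0..order, counts of each base following
    each c-mer are accumulated over all sequences on the given strand only
    (no reverse-complement pooling); windows containing an N are skipped.
    Probabilities are ``(count + pseudocount) / (context_total +
    4*pseudocount)``.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if sset.n == 0:
        raise ValueError("cannot fit background on an empty sequence set")

    tables = []
    for c in range(order + 1):
        counts = np.zeros((4**c, 4), dtype=np.float64)
        for seq in sset:
            bases = seq.bases.astype(np.int64)
            L = bases.size
            if L < c + 1:
                continue
            nwin = L - c
            ok = np.ones(nwin, dtype=bool)
            idx = np.zeros(nwin, dtype=np.int64)
            for off in range(c):
                part = bases[off : off + nwin]
                ok &= part != BASE_N
                idx = idx * 4 + part
            nxt = bases[c:]
            ok &= nxt != BASE_N
            np.add.at(counts, (idx[ok], nxt[ok]), 1.0)
        counts += pseudocount
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError(
                f"context length {c}: some contexts have no counts and "
                "pseudocount is 0; use a positive pseudocount"
            )
        tables.append(counts / totals)
    return BackgroundModel(order=order, pseudocount=pseudocount, cond_prob=tables)


def segment_log_prob(
    model: BackgroundModel, seq: EncodedSequence, start: int, end: int
) -> float:
    """Background log-probability of bases in [start, end).

    Each base is conditioned on the actual preceding bases in the full
    sequence (the context may extend left of ``start``), so segment scores
    are additive over any split point.
    """
    if not (0 <= start <= end <= seq.length):
        raise ValueError(
            f"segment [{start}, {end}) out of range for length {seq.length}"
        )
    return float(sum(model.position_log_prob(seq, j) for j in range(start, end)))
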