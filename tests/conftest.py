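"""Shared fixtures and oracle helpers for the test suite."""

import numpy as np
import pytest

from motifmix.background import BackgroundModel, fit_background
from motifmix.model_core import (
    Hyperparameters,
    ModeCounts,
    ModelState,
    model_log_posterior,
    update_counts,
)
from motifmix.sampler import SamplerContext
from motifmix.sequence_io import EncodedSequence, SequenceSet


def seqset(*texts, prefix="s"):
    """Build a SequenceSet from plain strings."""
    return SequenceSet(
        [EncodedSequence.from_text(f"{prefix}{i}", t) for i, t in enumerate(texts)]
    )


def random_seqset(rng, n, length):
    """Uniform-random A/C/G/T sequences."""
    return SequenceSet(
        [
            EncodedSequence(id=f"r{i}", bases=rng.integers(0, 4, size=length).astype(np.uint8))
            for i in range(n)
        ]
    )


def uniform_bg(order=0):
    """Uniform background of the given order (all conditionals = 1/4)."""
    tables = [np.full((4**c, 4), 0.25) for c in range(order + 1)]
    return BackgroundModel(order=order, pseudocount=1.0, cond_prob=tables)


def build_state(seqs, bg, m, widths, mode, pos, strand, hyper=None):
    """Construct a consistent ModelState from explicit assignments."""
    if hyper is None:
        hyper = Hyperparameters.uniform()
    n = seqs.n
    state = ModelState(
        m=m,
        mode=np.asarray(mode, dtype=np.int64),
        position=np.asarray(pos, dtype=np.int64),
        strand=np.asarray(strand, dtype=np.int8),
        widths=np.asarray(widths, dtype=np.int64),
        mode_counts=[ModeCounts.empty(int(w)) for w in widths],
        hyper=hyper,
        included=np.zeros(n, dtype=bool),
    )
    for i in range(n):
        update_counts(state, seqs, i, add=True)
    return state


def random_state(rng, seqs, bg, m, widths, double_strand=True, hyper=None):
    """Random valid assignments for the given widths."""
    n = seqs.n
    mode = rng.integers(0, m, size=n)
    pos = np.array(
        [rng.integers(0, seqs[i].length - widths[mode[i]] + 1) for i in range(n)]
    )
    strand = rng.integers(0, 2, size=n) if double_strand else np.zeros(n, dtype=int)
    return build_state(seqs, bg, m, widths, mode, pos, strand, hyper=hyper)


def brute_force_conditional(state, ctx, i):
    """Independent oracle for the collapsed conditional of sequence i.

    For every (mode, position, strand) candidate in the fixed ordering,
    re-insert the sequence, recompute the full collapsed log posterior from
    scratch, and softmax over candidates.  Sequence i must be excluded.
    """
    assert not state.included[i]
    cand, lps = [], []
    L = ctx.seqs[i].length
    strands = (0, 1) if ctx.double_strand else (0,)
    for k in range(state.m):
        w = int(state.widths[k])
        if w > L:
            continue
        for z in range(L - w + 1):
            for s in strands:
                state.mode[i], state.position[i], state.strand[i] = k, z, s
                update_counts(state, ctx.seqs, i, add=True)
                lps.append(model_log_posterior(state, ctx.bg_prefix))
                update_counts(state, ctx.seqs, i, add=False)
                cand.append((k, z, s))
    lps = np.array(lps)
    p = np.exp(lps - lps.max())
    return cand, p / p.sum()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_set():
    """Six length-20 sequences with recognisable planted 6-mers."""
    return seqset(
        "ACGTACGTACGTACGTACGT",
        "TTTTGGGGCCCCAAAATTTT",
        "GATCGATCGATCGATCGATC",
        "CCCCCCGGGGGGAAAAAATT",
        "ACGGCGTTAACCGGTTAACC",
        "TGCATGCATGCATGCATGCA",
    )


@pytest.fixture
def toy_bg(toy_set):
    return fit_background(toy_set, order=2, pseudocount=1.0)
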