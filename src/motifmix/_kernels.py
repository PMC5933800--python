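"""Compiled inner loop of the Gibbs sweep.

The assignment phase of a sweep — remove each sequence, score every
(mode, position, strand) candidate with the collapsed predictive, draw one
candidate by inverse CDF, re-insert — is a tight per-base loop that
dominates run time.  This module holds a numba translation of exactly the
arithmetic in :mod:`motifmix.model_core`; the pure-numpy
``conditional_distribution`` remains the reference implementation and the
two are held together by an equivalence test.

Sequences are passed as a padded (n, Lmax) matrix with per-sequence
lengths; count matrices as a padded (m, wmax, 4) tensor.  All randomness
enters through a caller-supplied vector of uniforms, one per sequence.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def _sweep_assignments(enc, lengths, pref, counts, widths, members,
                       mode, position, strand, beta, beta0, alpha,
                       double_strand, uniforms):
    """One assignment pass over all sequences, in index order, in place.

    ``enc``: (n, Lmax) int64 base codes (4 = N, padding arbitrary);
    ``pref``: (n, Lmax+1) background cumulative log-probabilities;
    ``counts``: (m, wmax, 4) float64 aligned base counts;
    ``uniforms``: (n,) one uniform variate per sequence update.
    """
    n = lengths.shape[0]
    m = widths.shape[0]
    wmax = counts.shape[1]
    Lmax = enc.shape[1]
    nstr = 2 if double_strand else 1
    # scratch buffers
    max_cands = m * (Lmax + 1) * 2
    scores = np.empty(max_cands, dtype=np.float64)
    cmode = np.empty(max_cands, dtype=np.int64)
    cpos = np.empty(max_cands, dtype=np.int64)
    cstr = np.empty(max_cands, dtype=np.int8)
    lp = np.empty((wmax, 5), dtype=np.float64)

    for i in range(n):
        L = lengths[i]
        # ---- remove sequence i from its mode ----
        k0 = mode[i]
        w0 = widths[k0]
        z0 = position[i]
        if strand[i] == 0:
            for a in range(w0):
                b = enc[i, z0 + a]
                if b != 4:
                    counts[k0, a, b] -= 1.0
        else:
            for a in range(w0):
                b = enc[i, z0 + w0 - 1 - a]
                if b != 4:
                    counts[k0, a, 3 - b] -= 1.0
        members[k0] -= 1

        # ---- score all candidates in fixed order ----
        nc = 0
        for k in range(m):
            w = widths[k]
            npos = L - w + 1
            if npos <= 0:
                continue
            membership = (np.log(members[k] + alpha)
                          - np.log(n - 1 + m * alpha))
            for a in range(w):
                tot = (counts[k, a, 0] + counts[k, a, 1]
                       + counts[k, a, 2] + counts[k, a, 3])
                denom = np.log(tot + beta0)
                for b in range(4):
                    lp[a, b] = np.log(counts[k, a, b] + beta[b]) - denom
                lp[a, 4] = 0.0
            for z in range(npos):
                bg = pref[i, z + w] - pref[i, z]
                s_plus = membership - bg
                for a in range(w):
                    s_plus += lp[a, enc[i, z + a]]
                cmode[nc] = k
                cpos[nc] = z
                cstr[nc] = 0
                scores[nc] = s_plus
                nc += 1
                if nstr == 2:
                    s_minus = membership - bg
                    for a in range(w):
                        b = enc[i, z + a]
                        if b != 4:
                            s_minus += lp[w - 1 - a, 3 - b]
                    cmode[nc] = k
                    cpos[nc] = z
                    cstr[nc] = 1
                    scores[nc] = s_minus
                    nc += 1

        # ---- inverse-CDF draw ----
        smax = scores[0]
        for c in range(1, nc):
            if scores[c] > smax:
                smax = scores[c]
        total = 0.0
        for c in range(nc):
            scores[c] = np.exp(scores[c] - smax)
            total += scores[c]
        target = uniforms[i] * total
        acc = 0.0
        pick = nc - 1
        for c in range(nc):
            acc += scores[c]
            if acc > target:
                pick = c
                break

        # ---- re-insert with the drawn assignment ----
        k1 = cmode[pick]
        z1 = cpos[pick]
        w1 = widths[k1]
        mode[i] = k1
        position[i] = z1
        strand[i] = cstr[pick]
        if cstr[pick] == 0:
            for a in range(w1):
                b = enc[i, z1 + a]
                if b != 4:
                    counts[k1, a, b] += 1.0
        else:
            for a in range(w1):
                b = enc[i, z1 + w1 - 1 - a]
                if b != 4:
                    counts[k1, a, 3 - b] += 1.0
        members[k1] += 1
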