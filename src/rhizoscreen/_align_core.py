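"""Numba kernel for exhaustive single-diagonal (ungapped) local alignment.

The kernel scans every diagonal of the query x subject comparison matrix
and, per diagonal, finds the best-scoring contiguous segment with a
prefix-minimum variant of Kadane's algorithm.  Tie-breaking is total and
matches the brute-force enumeration order used by the test oracle:
higher score, then longer segment, then more matches, then smaller
subject start, then smaller query start.  Strand preference is resolved
by the caller, between the two per-strand optima.

Characters are compared through a 256-entry code table where only
A, C, G, T map to distinct codes; every other byte (N and the IUPAC
ambiguity codes) maps to a sentinel that never matches, so ambiguity
always scores as a mismatch.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
del _i, _b


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T -> 0..3, other -> 255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def best_segment(q: np.ndarray, s: np.ndarray, reward: int,
                 penalty: int) -> tuple[int, int, int, int, int]:
    """Best ungapped local segment of ``q`` vs ``s``.

    Returns ``(score, length, matches, q_start, s_start)``; a non-positive
    score means no positive-scoring segment exists (caller reports no-hit).
    """
    nq, ns = q.shape[0], s.shape[0]
    best_sc = -1 << 60
    best_len = 0
    best_mat = 0
    best_qs = 0
    best_ss = 0
    for d in range(-(nq - 1), ns):
        i0 = 0 if d >= 0 else -d
        j0 = i0 + d
        n = min(nq - i0, ns - j0)
        psum = 0
        pmat = 0
        min_p = 0
        min_idx = 0
        mat_at_min = 0
        for t in range(n):
            eq = q[i0 + t] == s[j0 + t] and q[i0 + t] != 255
            if eq:
                psum += reward
                pmat += 1
            else:
                psum += penalty
            sc = psum - min_p
            ln = t + 1 - min_idx
            mat = pmat - mat_at_min
            ss = j0 + min_idx
            qs = i0 + min_idx
            better = False
            if sc > best_sc:
                better = True
            elif sc == best_sc:
                if ln > best_len:
                    better = True
                elif ln == best_len:
                    if mat > best_mat:
                        better = True
                    elif mat == best_mat:
                        if ss < best_ss or (ss == best_ss and qs < best_qs):
                            better = True
            if better:
                best_sc, best_len, best_mat = sc, ln, mat
                best_qs, best_ss = qs, ss
            if psum < min_p:
                min_p = psum
                min_idx = t + 1
                mat_at_min = pmat
    return best_sc, best_len, best_mat, best_qs, best_ss
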