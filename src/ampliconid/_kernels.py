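"""Numba kernels for glocal (read-global / reference-local) affine-gap DP.

The recurrence is the standard three-state affine model:

    H[i,j] = max(H[i-1,j-1] + s(q_i, r_j), E[i,j], F[i,j])
    E[i,j] = max(H[i-1,j] - (open+ext), E[i-1,j] - ext)   # read base vs gap
    F[i,j] = max(H[i,j-1] - (open+ext), F[i,j-1] - ext)   # ref  base vs gap

with free reference end gaps (H[0,j] = 0; the final score is max_j H[m,j]),
so the read aligns end-to-end against any contiguous reference stretch.
A gap of length k costs open + k*ext.

Bases are encoded A=0 C=1 G=2 T=3; any other code is 4 and never matches.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**8))

# traceback op codes
OP_MATCH = 0
OP_MISMATCH = 1
OP_INS = 2  # read base not in reference (gap in reference)
OP_DEL = 3  # reference base not in read (gap in read)


@njit(cache=True)
def score_one(q, r, match, mispen, gapopen, gapext):
    """Glocal score of query q against reference r (rolling rows)."""
    m = q.shape[0]
    L = r.shape[0]
    go = gapopen + gapext
    prev_h = np.zeros(L + 1, dtype=np.int32)
    prev_e = np.full(L + 1, NEG, dtype=np.int32)
    cur_h = np.empty(L + 1, dtype=np.int32)
    cur_e = np.empty(L + 1, dtype=np.int32)
    for i in range(1, m + 1):
        e0 = max(prev_h[0] - go, prev_e[0] - gapext)
        cur_e[0] = e0
        cur_h[0] = e0
        f = NEG
        qi = q[i - 1]
        for j in range(1, L + 1):
            e = max(prev_h[j] - go, prev_e[j] - gapext)
            f = max(cur_h[j - 1] - go, f - gapext)
            if qi == r[j - 1] and qi < 4:
                diag = prev_h[j - 1] + match
            else:
                diag = prev_h[j - 1] - mispen
            h = diag
            if e > h:
                h = e
            if f > h:
                h = f
            cur_e[j] = e
            cur_h[j] = h
        prev_h, cur_h = cur_h, prev_h
        prev_e, cur_e = cur_e, prev_e
    best = prev_h[0]
    for j in range(1, L + 1):
        if prev_h[j] > best:
            best = prev_h[j]
    return best


@njit(cache=True)
def score_many(q, refs, ref_lens, match, mispen, gapopen, gapext):
    """Scores of one query against every row of a padded reference matrix."""
    n = refs.shape[0]
    out = np.empty(n, dtype=np.int32)
    for k in range(n):
        out[k] = score_one(q, refs[k, : ref_lens[k]], match, mispen, gapopen, gapext)
    return out


@njit(cache=True)
def align_traceback(q, r, match, mispen, gapopen, gapext):
    """Full-matrix glocal alignment with deterministic traceback.

    Returns (score, ref_start, ref_end, ops) where ops is an int8 array of
    OP_* codes from alignment start to end.  Ties resolve diagonal > up
    (read gap-in-reference) > left (reference gap-in-read); among equal
    final scores the leftmost reference end is chosen.
    """
    m = q.shape[0]
    L = r.shape[0]
    go = gapopen + gapext
    H = np.empty((m + 1, L + 1), dtype=np.int32)
    E = np.empty((m + 1, L + 1), dtype=np.int32)
    F = np.empty((m + 1, L + 1), dtype=np.int32)
    for j in range(L + 1):
        H[0, j] = 0
        E[0, j] = NEG
        F[0, j] = NEG
    for i in range(1, m + 1):
        e0 = max(H[i - 1, 0] - go, E[i - 1, 0] - gapext)
        E[i, 0] = e0
        H[i, 0] = e0
        F[i, 0] = NEG
        qi = q[i - 1]
        for j in range(1, L + 1):
            e = max(H[i - 1, j] - go, E[i - 1, j] - gapext)
            f = max(H[i, j - 1] - go, F[i, j - 1] - gapext)
            if qi == r[j - 1] and qi < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] - mispen
            h = diag
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    # leftmost maximal end in the last row
    j_end = 0
    best = H[m, 0]
    for j in range(1, L + 1):
        if H[m, j] > best:
            best = H[m, j]
            j_end = j

    ops = np.empty(m + L, dtype=np.int8)
    n_ops = 0
    i = m
    j = j_end
    state = 0  # 0=H, 1=E, 2=F
    while i > 0:
        if state == 0:
            qi = q[i - 1]
            if j > 0:
                if qi == r[j - 1] and qi < 4:
                    diag = H[i - 1, j - 1] + match
                    dcode = OP_MATCH
                else:
                    diag = H[i - 1, j - 1] - mispen
                    dcode = OP_MISMATCH
                if H[i, j] == diag:
                    ops[n_ops] = dcode
                    n_ops += 1
                    i -= 1
                    j -= 1
                    continue
            if H[i, j] == E[i, j]:
                state = 1
                continue
            state = 2
            continue
        if state == 1:
            ops[n_ops] = OP_INS
            n_ops += 1
            if E[i, j] == H[i - 1, j] - go:
                state = 0
            i -= 1
            continue
        # state == 2
        ops[n_ops] = OP_DEL
        n_ops += 1
        if F[i, j] == H[i, j - 1] - go:
            state = 0
        j -= 1
    ref_start = j
    out = ops[:n_ops][::-1].copy()
    return best, ref_start, j_end, out


def warmup() -> None:
    """Trigger JIT compilation on tiny inputs (a few seconds, once)."""
    q = np.array([0, 1, 2, 3], dtype=np.int8)
    r = np.array([0, 1, 2, 3, 0], dtype=np.int8)
    score_one(q, r, np.int32(1), np.int32(4), np.int32(6), np.int32(1))
    refs = np.zeros((1, 5), dtype=np.int8)
    refs[0] = r
    score_many(q, refs, np.array([5], dtype=np.int64), np.int32(1), np.int32(4), np.int32(6), np.int32(1))
    align_traceback(q, r, np.int32(1), np.int32(4), np.int32(6), np.int32(1))
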