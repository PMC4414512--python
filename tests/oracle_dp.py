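"""Independent brute-force glocal DP oracle (pure Python, full matrices).

Deliberately written without reference to the package's kernel code: three
dense score matrices, no rolling rows, no traceback shortcuts.  Used to
verify optimality of the production aligner on random instances.
"""

NEG = -(10**9)


def oracle_glocal_score(query, ref, match=1, mismatch=4, gap_open=6, gap_extend=1):
    """Best score aligning the whole query against any substring of ref.

    A gap of length k costs gap_open + k*gap_extend.
    """
    m, L = len(query), len(ref)
    H = [[NEG] * (L + 1) for _ in range(m + 1)]
    E = [[NEG] * (L + 1) for _ in range(m + 1)]  # gap in ref (consumes query)
    F = [[NEG] * (L + 1) for _ in range(m + 1)]  # gap in query (consumes ref)
    for j in range(L + 1):
        H[0][j] = 0
    for i in range(1, m + 1):
        for j in range(L + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            if j > 0:
                F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            best = max(E[i][j], F[i][j])
            if j > 0:
                s = match if query[i - 1] == ref[j - 1] else -mismatch
                best = max(best, H[i - 1][j - 1] + s)
            H[i][j] = best
    return max(H[m])


def oracle_p_distance(a, b):
    """Symmetric p-distance matching the package's definition, recomputed
    from the oracle DP with an explicit traceback-free edit count.

    distance(q, r) = (edits + uncovered ref) / total columns, averaged over
    both directions; edits are recovered from the optimal score via
    score = matches - 4*mismatches - sum(6 + k) over gaps, by re-running a
    small exhaustive alignment enumeration.
    """
    return 0.5 * (_directed(a, b) + _directed(b, a))


def _directed(q, r):
    # enumerate alignments via DP over (matches, mismatches, ins, del, ref span)
    # using the same scoring, then derive the column-normalized distance
    best = _best_alignment_stats(q, r)
    n_match, n_mm, n_ins, n_del, ref_span = best
    overhang = len(r) - ref_span
    cols = n_match + n_mm + n_ins + n_del + overhang
    return (n_mm + n_ins + n_del + overhang) / cols


def _best_alignment_stats(q, r, match=1, mismatch=4, gap_open=6, gap_extend=1):
    """Optimal glocal alignment statistics via DP with stats carried along."""
    m, L = len(q), len(r)
    # cell: (score, (n_match, n_mm, n_ins, n_del, ref_start)) per state
    def better(a, b):
        if a is None:
            return b
        if b is None:
            return a
        return a if a[0] >= b[0] else b

    H = [[None] * (L + 1) for _ in range(m + 1)]
    E = [[None] * (L + 1) for _ in range(m + 1)]
    F = [[None] * (L + 1) for _ in range(m + 1)]
    for j in range(L + 1):
        H[0][j] = (0, (0, 0, 0, 0, j))
    for i in range(1, m + 1):
        for j in range(L + 1):
            cands_e = []
            if H[i - 1][j] is not None:
                s, st = H[i - 1][j]
                cands_e.append((s - gap_open - gap_extend, _add(st, ins=1)))
            if E[i - 1][j] is not None:
                s, st = E[i - 1][j]
                cands_e.append((s - gap_extend, _add(st, ins=1)))
            E[i][j] = _argmax(cands_e)
            cands_f = []
            if j > 0 and H[i][j - 1] is not None:
                s, st = H[i][j - 1]
                cands_f.append((s - gap_open - gap_extend, _add(st, dele=1)))
            if j > 0 and F[i][j - 1] is not None:
                s, st = F[i][j - 1]
                cands_f.append((s - gap_extend, _add(st, dele=1)))
            F[i][j] = _argmax(cands_f)
            # candidate order encodes the declared tie-break: diagonal > up > left
            cands_h = []
            if j > 0 and H[i - 1][j - 1] is not None:
                s, st = H[i - 1][j - 1]
                if q[i - 1] == r[j - 1]:
                    cands_h.append((s + match, _add(st, mat=1)))
                else:
                    cands_h.append((s - mismatch, _add(st, mm=1)))
            cands_h += [E[i][j], F[i][j]]
            H[i][j] = _argmax([c for c in cands_h if c is not None])
    best = None
    for j in range(L + 1):
        cell = H[m][j]
        if cell is None:
            continue
        if best is None or cell[0] > best[0][0]:
            best = (cell, j)
    (score, (n_match, n_mm, n_ins, n_del, ref_start)), j_end = best
    return n_match, n_mm, n_ins, n_del, j_end - ref_start


def _add(st, mat=0, mm=0, ins=0, dele=0):
    a, b, c, d, rs = st
    return (a + mat, b + mm, c + ins, d + dele, rs)


def _argmax(cands):
    best = None
    for c in cands:
        if c is None:
            continue
        if best is None or c[0] > best[0]:
            best = c
    return best
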