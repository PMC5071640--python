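"""Numba kernels: banded affine-gap global alignment and pair merging.

These are hot loops shared by the spectrum pipeline. Sequences are handled
as uint8 code arrays (A,C,G,T = 0..3; N = 4). The aligner is a standard
three-state (match / gap-in-reference / gap-in-read) Needleman–Wunsch with
affine gap costs, evaluated inside a diagonal band; ties are broken so that
gaps land at their leftmost equivalent placement.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18

# traceback op codes
OP_MATCH = 0  # consumes one read and one reference base
OP_INS = 1    # consumes one read base (gap in reference)
OP_DEL = 2    # consumes one reference base (gap in read)


@njit(cache=True)
def banded_affine_align(read, ref, match, mismatch, gap_open, gap_ext, band):
    """Global affine-gap alignment within a diagonal band.

    Returns (score, ops, n_ops) where ops[:n_ops] lists OP_* codes from the
    start of the alignment. ``band`` must be >= |len(read) - len(ref)|.
    The first base of a gap costs ``gap_open``; each additional base
    ``gap_ext`` (both negative).
    """
    m = read.shape[0]
    n = ref.shape[0]
    M = np.empty((m + 1, n + 1), dtype=np.float64)
    X = np.empty((m + 1, n + 1), dtype=np.float64)  # gap in ref (insertion)
    Y = np.empty((m + 1, n + 1), dtype=np.float64)  # gap in read (deletion)
    PM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    PX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    PY = np.zeros((m + 1, n + 1), dtype=np.uint8)

    M[0, 0] = 0.0
    X[0, 0] = NEG
    Y[0, 0] = NEG
    jmax0 = min(n, band)
    for j in range(1, jmax0 + 1):
        Y[0, j] = gap_open + (j - 1) * gap_ext
        M[0, j] = NEG
        X[0, j] = NEG
        PY[0, j] = 2
    if jmax0 + 1 <= n:
        M[0, jmax0 + 1] = NEG
        X[0, jmax0 + 1] = NEG
        Y[0, jmax0 + 1] = NEG

    for i in range(1, m + 1):
        j0 = i - band
        if j0 < 1:
            j0 = 1
        j1 = i + band
        if j1 > n:
            j1 = n
        # left border of the band in this row
        if j0 == 1 and i <= band:
            X[i, 0] = gap_open + (i - 1) * gap_ext
            M[i, 0] = NEG
            Y[i, 0] = NEG
            PX[i, 0] = 1
        else:
            M[i, j0 - 1] = NEG
            X[i, j0 - 1] = NEG
            Y[i, j0 - 1] = NEG
        for j in range(j0, j1 + 1):
            rb = read[i - 1]
            fb = ref[j - 1]
            s = match if rb == fb else mismatch
            # M: diagonal predecessor; prefer M, then X, then Y on ties
            bm = M[i - 1, j - 1]
            bs = 0
            if X[i - 1, j - 1] > bm:
                bm = X[i - 1, j - 1]
                bs = 1
            if Y[i - 1, j - 1] > bm:
                bm = Y[i - 1, j - 1]
                bs = 2
            M[i, j] = bm + s
            PM[i, j] = bs
            # X: vertical predecessor (i-1, j); out of band when j == i+band
            if j - (i - 1) > band:
                X[i, j] = NEG
                PX[i, j] = 0
            else:
                vm = M[i - 1, j] + gap_open
                vs = 0
                if X[i - 1, j] + gap_ext > vm:
                    vm = X[i - 1, j] + gap_ext
                    vs = 1
                if Y[i - 1, j] + gap_open > vm:
                    vm = Y[i - 1, j] + gap_open
                    vs = 2
                X[i, j] = vm
                PX[i, j] = vs
            # Y: horizontal predecessor (i, j-1); always inside or border
            hm = M[i, j - 1] + gap_open
            hs = 0
            if X[i, j - 1] + gap_open > hm:
                hm = X[i, j - 1] + gap_open
                hs = 1
            if Y[i, j - 1] + gap_ext > hm:
                hm = Y[i, j - 1] + gap_ext
                hs = 2
            Y[i, j] = hm
            PY[i, j] = hs
        if j1 + 1 <= n:
            M[i, j1 + 1] = NEG
            X[i, j1 + 1] = NEG
            Y[i, j1 + 1] = NEG

    # final state: prefer M, then X, then Y on ties
    score = M[m, n]
    state = 0
    if X[m, n] > score:
        score = X[m, n]
        state = 1
    if Y[m, n] > score:
        score = Y[m, n]
        state = 2

    ops = np.empty(m + n, dtype=np.uint8)
    k = 0
    i, j = m, n
    while i > 0 or j > 0:
        if state == 0:
            prev = PM[i, j]
            ops[k] = OP_MATCH
            i -= 1
            j -= 1
        elif state == 1:
            prev = PX[i, j]
            ops[k] = OP_INS
            i -= 1
        else:
            prev = PY[i, j]
            ops[k] = OP_DEL
            j -= 1
        k += 1
        state = prev
    # reverse in place
    for t in range(k // 2):
        tmp = ops[t]
        ops[t] = ops[k - 1 - t]
        ops[k - 1 - t] = tmp
    return score, ops, k


@njit(cache=True)
def merge_batch(
    r1, q1, r2rc, q2rc, len1, len2,
    min_overlap, threshold, early_accept,
    out_seq, out_qual, out_len, out_score, out_k,
):
    """Merge read pairs by best ungapped overlap.

    ``r1``/``r2rc`` are code matrices (R2 already reverse-complemented),
    ``q1``/``q2rc`` the per-base Phred qualities. The overlap of length k
    aligns the last k bases of R1 with the first k of R2rc; its score is
    the quality-weighted agreement sum(w * agree) / sum(w) with
    w = min(q1, q2), so a single disagreement among equally trusted bases
    costs 1/k. Candidate overlaps are scanned from short to long, stopping
    early at ``early_accept`` (a perfect overlap scores exactly 1). Pairs
    whose best score falls below ``threshold`` get out_len = 0.

    Merged base/quality: outside the overlap, the covering mate; inside,
    the higher-quality base; merged quality is the max of the two.
    """
    nreads = r1.shape[0]
    for idx in range(nreads):
        l1 = len1[idx]
        l2 = len2[idx]
        best_score = -1.0
        best_k = -1
        maxk = l1 if l1 < l2 else l2
        for k in range(min_overlap, maxk + 1):
            s = 0.0
            wsum = 0.0
            off = l1 - k
            for t in range(k):
                qa = q1[idx, off + t]
                qb = q2rc[idx, t]
                w = qa if qa < qb else qb
                wsum += w
                if r1[idx, off + t] == r2rc[idx, t]:
                    s += w
            score = s / wsum if wsum > 0 else 0.0
            if score > best_score:
                best_score = score
                best_k = k
            if score >= early_accept:
                break
        out_score[idx] = best_score
        out_k[idx] = best_k
        if best_k < 0 or best_score < threshold:
            out_len[idx] = 0
            continue
        k = best_k
        off = l1 - k
        mlen = l1 + l2 - k
        out_len[idx] = mlen
        for t in range(off):
            out_seq[idx, t] = r1[idx, t]
            out_qual[idx, t] = q1[idx, t]
        for t in range(k):
            a = r1[idx, off + t]
            b = r2rc[idx, t]
            qa = q1[idx, off + t]
            qb = q2rc[idx, t]
            if a == b or qa >= qb:  # higher-quality base; ties go to R1
                out_seq[idx, off + t] = a
            else:
                out_seq[idx, off + t] = b
            out_qual[idx, off + t] = qa if qa > qb else qb
        for t in range(k, l2):
            out_seq[idx, l1 + t - k] = r2rc[idx, t]
            out_qual[idx, l1 + t - k] = q2rc[idx, t]
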