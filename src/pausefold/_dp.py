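"""Banded minimum-free-energy dynamic program (numba kernels).

The recursion works on a band of spans ``j - i < band`` so that a 1-nt-step
sliding-window scan shares all interior work between overlapping windows:
matrices are filled once over the whole sequence, then each window only runs
its own O(w^2) external loop.

Matrices (integer energies, 0.01 kcal/mol; ``INF`` = inadmissible), stored
as ``A[i, j - i]``:

``CL``  pair (i, j) closes a hairpin, interior/bulge loop, or multibranch
        loop (it is the innermost pair of its helix).
``D``   pair (i, j) exists and the helix extends inward until some pair
        closes a loop: ``D = min(CL, stack + D(i+1, j-1))``.
``CH``  pair (i, j) starts an admissible branch.  Without lonely pairs this
        requires the helix to be at least two pairs long:
        ``CH = stack + D(i+1, j-1)``; with lonely pairs allowed, ``CH = D``.
``M``   at least one branch in [i, j] inside a multibranch loop, with affine
        per-branch / per-unpaired costs.
``M1``  exactly one branch, starting at i, trailing unpaired allowed.

External (per window): ``W[t] = min(W[t-1], min_k W[k] + CH(k, t))``; the
MFE is ``min(W, 0)`` — the all-unpaired state has energy zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF32 = 1 << 28


@njit(cache=True)
def can_pair(a, b):
    # A=0 C=1 G=2 T=3: Watson-Crick A:T and C:G only
    return a + b == 3


@njit(cache=True)
def fill_banded(codes, band, minloop, maxint, stack, hairpin, bulge, internal,
                asym, asym_max, ml_close, ml_branch, ml_unpaired,
                allow_lonely):
    n = codes.shape[0]
    CL = np.full((n, band), INF32, dtype=np.int32)
    D = np.full((n, band), INF32, dtype=np.int32)
    CH = np.full((n, band), INF32, dtype=np.int32)
    M = np.full((n, band), INF32, dtype=np.int32)
    M1 = np.full((n, band), INF32, dtype=np.int32)

    for s in range(1, band):
        for i in range(0, n - s):
            j = i + s
            pairable = can_pair(codes[i], codes[j]) and (s - 1 >= minloop)
            if pairable:
                # --- CL: closes a loop ---
                best = INF32
                # hairpin
                hp = hairpin[s - 1] if s - 1 < hairpin.shape[0] else INF32
                if hp < best:
                    best = hp
                # interior / bulge: inner branch (k, l), n1 + n2 >= 1
                for n1 in range(0, maxint + 1):
                    k = i + 1 + n1
                    if k >= j:
                        break
                    for n2 in range(0, maxint + 1 - n1):
                        if n1 == 0 and n2 == 0:
                            continue
                        l = j - 1 - n2
                        if l <= k:
                            break
                        inner = CH[k, l - k]
                        if inner >= INF32:
                            continue
                        if n1 == 0 or n2 == 0:
                            pen = bulge[n1 + n2]
                        else:
                            a = asym * (n1 - n2 if n1 > n2 else n2 - n1)
                            if a > asym_max:
                                a = asym_max
                            pen = internal[n1 + n2] + a
                        cand = pen + inner
                        if cand < best:
                            best = cand
                # multibranch: >= 2 branches inside
                for k in range(i + 2, j - 1):
                    a1 = M[i + 1, k - (i + 1)]
                    if a1 >= INF32:
                        continue
                    a2 = M1[k + 1, j - 1 - (k + 1)] if j - 1 > k + 1 else INF32
                    if a2 >= INF32:
                        continue
                    cand = ml_close + ml_branch + a1 + a2
                    if cand < best:
                        best = cand
                CL[i, s] = best

                # --- D: helix extends inward ---
                d = best
                if s >= 2 and can_pair(codes[i + 1], codes[j - 1]):
                    dn = D[i + 1, s - 2]
                    if dn < INF32:
                        cand = stack[codes[i], codes[i + 1]] + dn
                        if cand < d:
                            d = cand
                        CH[i, s] = stack[codes[i], codes[i + 1]] + dn
                D[i, s] = d
                if allow_lonely:
                    CH[i, s] = d

            # --- M1 ---
            best1 = INF32
            if s >= 1:
                prev = M1[i, s - 1]
                if prev < INF32:
                    best1 = prev + ml_unpaired
            ch = CH[i, s]
            if ch < INF32 and ch + ml_branch < best1:
                best1 = ch + ml_branch
            M1[i, s] = best1

            # --- M ---
            bm = best1
            if s >= 1:
                lead = M[i + 1, s - 1]
                if lead < INF32 and lead + ml_unpaired < bm:
                    bm = lead + ml_unpaired
                for k in range(i + 1, j + 1):
                    a1 = M[i, k - 1 - i]
                    if a1 >= INF32:
                        continue
                    a2 = M1[k, j - k]
                    if a2 >= INF32:
                        continue
                    if a1 + a2 < bm:
                        bm = a1 + a2
            M[i, s] = bm

    return CL, D, CH, M, M1


@njit(cache=True)
def window_mfe(CH, n, band, window, step):
    """MFE (integer) of each complete window, via the external recursion."""
    n_win = (n - window) // step + 1 if n >= window else 0
    out = np.zeros(n_win, dtype=np.int32)
    W = np.zeros(window + 1, dtype=np.int32)
    for w in range(n_win):
        ws = w * step
        W[0] = 0
        for t in range(1, window + 1):
            p = ws + t - 1  # absolute position of last base considered
            best = W[t - 1]
            kmin = p - band + 1
            if kmin < ws:
                kmin = ws
            for k in range(kmin, p):
                ch = CH[k, p - k]
                if ch >= INF32:
                    continue
                cand = W[k - ws] + ch
                if cand < best:
                    best = cand
            W[t] = best
        e = W[window]
        out[w] = e if e < 0 else 0
    return out


def external_trace_arrays(CH, ws, we):
    """Python-side external DP for one window, returning W for traceback."""
    band = CH.shape[1]
    w = we - ws
    W = np.zeros(w + 1, dtype=np.int64)
    for t in range(1, w + 1):
        p = ws + t - 1
        best = W[t - 1]
        kmin = max(p - band + 1, ws)
        for k in range(kmin, p):
            ch = CH[k, p - k]
            if ch >= INF32:
                continue
            cand = W[k - ws] + ch
            if cand < best:
                best = cand
        W[t] = best
    return W
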