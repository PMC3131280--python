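"""Numba kernel for the constrained minimum-free-energy dynamic program.

Energies are integers in units of 0.01 kcal/mol. ``pcode[i, j]`` holds the
pair-type code (0..5) of the ordered pair (i, j) if that pair is admissible
under the model *and* the active constraint set, else -1. ``can_unpair[p]``
is False only for endpoints of forced pairs. All loop-initiation tables are
pre-extrapolated to the sequence length before the kernel runs.

Recurrences (Zuker-style, hard constraints):

  V[i,j]  = best energy of a structure on i..j closed by pair (i,j):
            hairpin | stack/bulge/internal to inner pair (k,l) | multiloop.
  WM[i,j] = best energy of a multiloop segment i..j holding >= 1 branch
            (per-branch and per-unpaired affine terms included).
  W[j]    = best energy of the exterior loop over 1..j.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.int64(1) << 40


@njit(cache=True)
def fill_tables(
    n,
    pcode,          # int8 (n+2, n+2)
    can_unpair,     # bool (n+2,)
    stack,          # int64 (6, 6)
    hp_tab,         # int64 (n+2,) hairpin initiation by loop size
    bg_tab,         # int64 (n+2,) bulge initiation by loop size
    il_tab,         # int64 (n+2,) internal initiation by total loop size
    ninio_m,        # int64
    ninio_max,      # int64
    ml_a,           # int64 multiloop closing
    ml_b,           # int64 multiloop per-branch
    ml_c,           # int64 multiloop per-unpaired
    term,           # int64 (6,) terminal non-GC penalty per pair code
    min_hp,         # int64
    max_loop,       # int64
):
    V = np.full((n + 2, n + 2), INF, np.int64)
    WM = np.full((n + 2, n + 2), INF, np.int64)
    W = np.full(n + 1, INF, np.int64)

    for span in range(1, n):
        for i in range(1, n - span + 1):
            j = i + span
            c = pcode[i, j]
            if c >= 0 and span > min_hp:
                best = INF
                # hairpin loop
                ok = True
                for p in range(i + 1, j):
                    if not can_unpair[p]:
                        ok = False
                        break
                if ok:
                    e = hp_tab[span - 1] + term[c]
                    if e < best:
                        best = e
                # stack / bulge / internal loop to inner pair (k, l)
                kmax = j - min_hp - 2
                k_hi = i + max_loop + 1
                if k_hi > kmax:
                    k_hi = kmax
                for k in range(i + 1, k_hi + 1):
                    s1 = k - i - 1
                    okk = True
                    for p in range(i + 1, k):
                        if not can_unpair[p]:
                            okk = False
                            break
                    if not okk:
                        break  # larger k only widens the 5' gap
                    for l in range(j - 1, k + min_hp, -1):
                        s2 = j - l - 1
                        if s1 + s2 > max_loop:
                            break  # smaller l only widens the 3' gap
                        c2 = pcode[k, l]
                        if c2 < 0 or V[k, l] >= INF:
                            continue
                        okl = True
                        for p in range(l + 1, j):
                            if not can_unpair[p]:
                                okl = False
                                break
                        if not okl:
                            continue
                        if s1 == 0 and s2 == 0:
                            le = stack[c, c2]
                        elif s1 == 0 or s2 == 0:
                            s = s1 + s2
                            if s == 1:
                                le = bg_tab[1] + stack[c, c2]
                            else:
                                le = bg_tab[s] + term[c] + term[c2]
                        else:
                            asym = s1 - s2
                            if asym < 0:
                                asym = -asym
                            pen = ninio_m * asym
                            if pen > ninio_max:
                                pen = ninio_max
                            le = il_tab[s1 + s2] + pen + term[c] + term[c2]
                        e = V[k, l] + le
                        if e < best:
                            best = e
                # multiloop closure: >= 2 branches inside
                for k in range(i + 1, j - 1):
                    a = WM[i + 1, k]
                    b = WM[k + 1, j - 1]
                    if a < INF and b < INF:
                        e = a + b + ml_a + term[c]
                        if e < best:
                            best = e
                V[i, j] = best

            # WM: multiloop segment with >= 1 branch
            best = INF
            if can_unpair[i] and WM[i + 1, j] < INF:
                e = WM[i + 1, j] + ml_c
                if e < best:
                    best = e
            if can_unpair[j] and WM[i, j - 1] < INF:
                e = WM[i, j - 1] + ml_c
                if e < best:
                    best = e
            if c >= 0 and V[i, j] < INF:
                e = V[i, j] + ml_b + term[c]
                if e < best:
                    best = e
            for k in range(i, j):
                a = WM[i, k]
                b = WM[k + 1, j]
                if a < INF and b < INF:
                    e = a + b
                    if e < best:
                        best = e
            WM[i, j] = best

    W[0] = 0
    for j in range(1, n + 1):
        best = INF
        if can_unpair[j] and W[j - 1] < INF:
            best = W[j - 1]
        for i in range(1, j - min_hp):
            c = pcode[i, j]
            if c >= 0 and V[i, j] < INF and W[i - 1] < INF:
                e = W[i - 1] + V[i, j] + term[c]
                if e < best:
                    best = e
        W[j] = best

    return V, WM, W
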