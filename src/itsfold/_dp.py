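"""Numba kernels for the Zuker-style minimum-free-energy recursions.

Matrices (all energies integer centi-kcal/mol):

* ``V[i, j]``  — minimum energy of the segment ``i..j`` given that ``(i, j)``
  is a base pair (INF when the pair is disallowed).
* ``WM[i, j]`` — minimum energy of ``i..j`` placed inside a multibranch
  loop, containing at least one branch (per-branch ``b`` and per-unpaired
  ``c`` terms included).
* ``E[k]``     — minimum energy of the prefix covering positions ``0..k-1``
  as an exterior (external-loop) segment; ``E[0] = 0``.
* ``F[k]``     — minimum energy of the suffix ``k..n-1``; ``F[n] = 0``.

Tracebacks use a fixed deterministic case priority (hairpin, stack/internal
in fill order, then multibranch split) and, at the exterior level, prefer
the outermost pairing (smallest i, then largest j).
"""
from __future__ import annotations

import numpy as np
from numba import njit

INF = 2**40


@njit(cache=False)
def fill_matrices(codes, pair_idx, stack, hairpin, bulge, internal,
                  ml_a, ml_b, ml_c, min_loop, max_int):
    n = codes.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            p = pair_idx[codes[i], codes[j]]
            if p >= 0 and span - 1 >= min_loop:
                best = hairpin[span - 1]
                # stacked pair / bulge / internal loop
                for k in range(i + 1, j):
                    n1 = k - i - 1
                    if n1 > max_int:
                        break
                    for l in range(j - 1, k, -1):
                        n2 = j - l - 1
                        if n1 + n2 > max_int:
                            break
                        if V[k, l] >= INF:
                            continue
                        if n1 == 0 and n2 == 0:
                            e = stack[p, pair_idx[codes[k], codes[l]]] + V[k, l]
                        elif n1 == 0 or n2 == 0:
                            e = bulge[n1 + n2] + V[k, l]
                        else:
                            e = internal[n1 + n2] + V[k, l]
                        if e < best:
                            best = e
                # multibranch loop (>= 2 branches via WM + WM split)
                for h in range(i + 2, j - 1):
                    if WM[i + 1, h] < INF and WM[h + 1, j - 1] < INF:
                        e = ml_a + WM[i + 1, h] + WM[h + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM
            wm = INF
            if V[i, j] < INF:
                wm = V[i, j] + ml_b
            if WM[i + 1, j] < INF and WM[i + 1, j] + ml_c < wm:
                wm = WM[i + 1, j] + ml_c
            if WM[i, j - 1] < INF and WM[i, j - 1] + ml_c < wm:
                wm = WM[i, j - 1] + ml_c
            for h in range(i + 1, j):
                if WM[i, h] < INF and WM[h + 1, j] < INF:
                    e = WM[i, h] + WM[h + 1, j]
                    if e < wm:
                        wm = e
            WM[i, j] = wm

    E = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        best = E[j]
        for i in range(j):
            if V[i, j] < INF:
                e = E[i] + V[i, j]
                if e < best:
                    best = e
        E[j + 1] = best
    F = np.zeros(n + 2, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        best = F[i + 1]
        for j in range(i + min_loop + 1, n):
            if V[i, j] < INF:
                e = V[i, j] + F[j + 1]
                if e < best:
                    best = e
        F[i] = best
    return V, WM, E, F


@njit(cache=False)
def _push(st_i, st_j, st_k, top, i, j, kind):
    st_i[top] = i
    st_j[top] = j
    st_k[top] = kind
    return top + 1


@njit(cache=False)
def trace_v(i0, j0, codes, pair_idx, stack, hairpin, bulge, internal,
            ml_a, ml_b, ml_c, min_loop, max_int, V, WM, out_i, out_j, nout):
    """Traceback of V(i0, j0); appends pairs to out arrays, returns new count."""
    n = codes.shape[0]
    st_i = np.empty(n + 2, dtype=np.int64)
    st_j = np.empty(n + 2, dtype=np.int64)
    st_k = np.empty(n + 2, dtype=np.int64)  # 0 = V, 1 = WM
    top = _push(st_i, st_j, st_k, 0, i0, j0, 0)
    while top > 0:
        top -= 1
        i, j, kind = st_i[top], st_j[top], st_k[top]
        if kind == 0:
            target = V[i, j]
            out_i[nout] = i
            out_j[nout] = j
            nout += 1
            p = pair_idx[codes[i], codes[j]]
            if hairpin[j - i - 1] == target:
                continue
            found = False
            for k in range(i + 1, j):
                n1 = k - i - 1
                if n1 > max_int or found:
                    break
                for l in range(j - 1, k, -1):
                    n2 = j - l - 1
                    if n1 + n2 > max_int:
                        break
                    if V[k, l] >= INF:
                        continue
                    if n1 == 0 and n2 == 0:
                        e = stack[p, pair_idx[codes[k], codes[l]]] + V[k, l]
                    elif n1 == 0 or n2 == 0:
                        e = bulge[n1 + n2] + V[k, l]
                    else:
                        e = internal[n1 + n2] + V[k, l]
                    if e == target:
                        top = _push(st_i, st_j, st_k, top, k, l, 0)
                        found = True
                        break
            if found:
                continue
            for h in range(i + 2, j - 1):
                if WM[i + 1, h] < INF and WM[h + 1, j - 1] < INF:
                    if ml_a + WM[i + 1, h] + WM[h + 1, j - 1] == target:
                        top = _push(st_i, st_j, st_k, top, i + 1, h, 1)
                        top = _push(st_i, st_j, st_k, top, h + 1, j - 1, 1)
                        found = True
                        break
        else:
            target = WM[i, j]
            if V[i, j] < INF and V[i, j] + ml_b == target:
                top = _push(st_i, st_j, st_k, top, i, j, 0)
                continue
            if WM[i + 1, j] < INF and WM[i + 1, j] + ml_c == target:
                top = _push(st_i, st_j, st_k, top, i + 1, j, 1)
                continue
            if WM[i, j - 1] < INF and WM[i, j - 1] + ml_c == target:
                top = _push(st_i, st_j, st_k, top, i, j - 1, 1)
                continue
            for h in range(i + 1, j):
                if WM[i, h] < INF and WM[h + 1, j] < INF:
                    if WM[i, h] + WM[h + 1, j] == target:
                        top = _push(st_i, st_j, st_k, top, i, h, 1)
                        top = _push(st_i, st_j, st_k, top, h + 1, j, 1)
                        break
    return nout


@njit(cache=False)
def trace_suffix(s, codes, pair_idx, stack, hairpin, bulge, internal,
                 ml_a, ml_b, ml_c, min_loop, max_int, V, WM, F,
                 out_i, out_j, nout):
    """Best exterior structure on suffix [s, n); outermost-first tie-break."""
    n = codes.shape[0]
    i = s
    while i < n:
        if F[i] == F[i + 1]:
            i += 1
            continue
        hit = -1
        for j in range(n - 1, i + min_loop, -1):  # largest j first
            if V[i, j] < INF and V[i, j] + F[j + 1] == F[i]:
                hit = j
                break
        if hit < 0:  # numerically impossible; defensive
            i += 1
            continue
        nout = trace_v(i, hit, codes, pair_idx, stack, hairpin, bulge, internal,
                       ml_a, ml_b, ml_c, min_loop, max_int, V, WM, out_i, out_j, nout)
        i = hit + 1
    return nout


@njit(cache=False)
def trace_prefix(p, codes, pair_idx, stack, hairpin, bulge, internal,
                 ml_a, ml_b, ml_c, min_loop, max_int, V, WM, E,
                 out_i, out_j, nout):
    """Best exterior structure on prefix [0, p)."""
    j = p - 1
    while j >= 0:
        if E[j + 1] == E[j]:
            j -= 1
            continue
        hit = -1
        for i in range(j - min_loop):  # smallest i first
            if V[i, j] < INF and E[i] + V[i, j] == E[j + 1]:
                hit = i
                break
        if hit < 0:
            j -= 1
            continue
        nout = trace_v(hit, j, codes, pair_idx, stack, hairpin, bulge, internal,
                       ml_a, ml_b, ml_c, min_loop, max_int, V, WM, out_i, out_j, nout)
        j = hit - 1
    return nout
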