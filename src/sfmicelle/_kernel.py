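"""Numba-accelerated tree propagation kernel.

Falls back to the pure-numpy implementation in :mod:`engine` when numba
is unavailable (set ``SFMICELLE_NO_NUMBA=1`` to force the fallback).
"""

from __future__ import annotations

import os

import numpy as np

HAVE_NUMBA = False
if not os.environ.get("SFMICELLE_NO_NUMBA"):
    try:
        from numba import njit

        HAVE_NUMBA = True
    except Exception:  # pragma: no cover
        HAVE_NUMBA = False

if HAVE_NUMBA:

    @njit(cache=True, fastmath=False)
    def propagate_tree(Grows, child_ptr, child_idx, lamm, lam0, lamp, L, bulk):
        """Message passing over a rooted tree (children after parents).

        Returns per-node densities normalized per molecule and the
        per-node log partition function values.
        """
        n, M = Grows.shape
        up = np.empty((n, M))
        up_ln = np.zeros(n)
        pre = np.empty((n, M))
        pre_ln = np.zeros(n)
        avg = np.empty(M)

        for v in range(n - 1, -1, -1):
            prod = Grows[v].copy()
            ln = 0.0
            for ci in range(child_ptr[v], child_ptr[v + 1]):
                c = child_idx[ci]
                for r in range(M):
                    prod[r] *= up[c, r]
                ln += up_ln[c]
            for r in range(M):
                pre[v, r] = prod[r]
            pre_ln[v] = ln
            # local average; mirror inner, bulk or mirror outer
            for r in range(M):
                val = lam0[r] * prod[r]
                if r > 0:
                    val += lamm[r] * prod[r - 1]
                else:
                    val += lamm[0] * prod[0]
                if r < M - 1:
                    val += lamp[r] * prod[r + 1]
                else:
                    if bulk:
                        ev = -ln
                        if ev < -700.0:
                            ev = -700.0
                        val += lamp[M - 1] * np.exp(ev)
                    else:
                        val += lamp[M - 1] * prod[M - 1]
                avg[r] = val
            s = avg[0]
            for r in range(1, M):
                if avg[r] > s:
                    s = avg[r]
            if not np.isfinite(s) or s <= 0.0:
                return np.empty((0, 0)), np.empty(0)
            for r in range(M):
                up[v, r] = avg[r] / s
            up_ln[v] = ln + np.log(s)

        down = np.empty((n, M))
        down_ln = np.zeros(n)
        for r in range(M):
            down[0, r] = 1.0
        raw_c = np.empty(M)
        for v in range(n):
            k0, k1 = child_ptr[v], child_ptr[v + 1]
            nc = k1 - k0
            if nc == 0:
                continue
            for i in range(nc):
                c = child_idx[k0 + i]
                ln_c = down_ln[v] + pre_ln[v] - up_ln[c]
                for r in range(M):
                    raw_c[r] = Grows[v, r] * down[v, r]
                for j in range(nc):
                    if j == i:
                        continue
                    c2 = child_idx[k0 + j]
                    for r in range(M):
                        raw_c[r] *= up[c2, r]
                # average
                for r in range(M):
                    val = lam0[r] * raw_c[r]
                    if r > 0:
                        val += lamm[r] * raw_c[r - 1]
                    else:
                        val += lamm[0] * raw_c[0]
                    if r < M - 1:
                        val += lamp[r] * raw_c[r + 1]
                    else:
                        lnn = down_ln[v]
                        for j in range(nc):
                            if j != i:
                                lnn += up_ln[child_idx[k0 + j]]
                        if bulk:
                            ev = -lnn
                            if ev < -700.0:
                                ev = -700.0
                            val += lamp[M - 1] * np.exp(ev)
                        else:
                            val += lamp[M - 1] * raw_c[M - 1]
                    avg[r] = val
                s = avg[0]
                for r in range(1, M):
                    if avg[r] > s:
                        s = avg[r]
                if not np.isfinite(s) or s <= 0.0:
                    return np.empty((0, 0)), np.empty(0)
                lnn = down_ln[v]
                for j in range(nc):
                    if j != i:
                        lnn += up_ln[child_idx[k0 + j]]
                for r in range(M):
                    down[c, r] = avg[r] / s
                down_ln[c] = lnn + np.log(s)

        node_phi = np.empty((n, M))
        logq_v = np.empty(n)
        for v in range(n):
            w = 0.0
            for r in range(M):
                node_phi[v, r] = pre[v, r] * down[v, r]
                w += node_phi[v, r] * L[r]
            if w <= 0.0 or not np.isfinite(w):
                return np.empty((0, 0)), np.empty(0)
            for r in range(M):
                node_phi[v, r] /= w
            logq_v[v] = np.log(w) + pre_ln[v] + down_ln[v]
        return node_phi, logq_v
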