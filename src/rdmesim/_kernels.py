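"""Numba-compiled NSM event loop for mass-action models.

The kernel operates on flat arrays only: per-species CSR diffusion
generators, per-reaction per-voxel rate prefactors (two sets, switching
at ``tswitch`` to support mid-run parameter changes), a dense
stoichiometry matrix and a sink mask.  Reaction propensities are
``kloc * 1``, ``kloc * x``, ``kloc * x1 * x2`` or ``kloc * x * (x - 1)``
depending on the reactant index pair — every volume / area / subdomain
factor is folded into ``kloc`` by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["nsm_mass_action", "first_passage_times"]


@njit(cache=True)
def first_passage_times(indptr, indices, rates, qtot, sink, starts, seed):
    """Sample the absorption time of independent molecules on a CTMC.

    ``indptr/indices/rates`` are the off-diagonal CSR of the generator,
    ``qtot`` the per-voxel total outflow rate, ``sink`` a uint8 mask of
    absorbing voxels and ``starts`` the initial voxel of each molecule.
    """
    np.random.seed(seed)
    n = starts.shape[0]
    out = np.empty(n)
    for k in range(n):
        i = starts[k]
        t = 0.0
        while sink[i] == 0:
            rate = qtot[i]
            if rate <= 0.0:
                t = np.inf
                break
            t += -np.log(1.0 - np.random.random()) / rate
            y = np.random.random() * rate
            acc = 0.0
            j = indices[indptr[i + 1] - 1]
            for p in range(indptr[i], indptr[i + 1]):
                acc += rates[p]
                if acc > y:
                    j = indices[p]
                    break
            i = j
        out[k] = t
    return out


@njit(cache=True, inline="always")
def _heap_swap(heap_t, heap_ix, pos, a, b):
    heap_t[a], heap_t[b] = heap_t[b], heap_t[a]
    heap_ix[a], heap_ix[b] = heap_ix[b], heap_ix[a]
    pos[heap_ix[a]] = a
    pos[heap_ix[b]] = b


@njit(cache=True, inline="always")
def _heap_less(heap_t, heap_ix, a, b):
    # ties broken by voxel index for reproducibility
    if heap_t[a] != heap_t[b]:
        return heap_t[a] < heap_t[b]
    return heap_ix[a] < heap_ix[b]


@njit(cache=True)
def _sift_up(heap_t, heap_ix, pos, k):
    while k > 0:
        parent = (k - 1) // 2
        if _heap_less(heap_t, heap_ix, k, parent):
            _heap_swap(heap_t, heap_ix, pos, k, parent)
            k = parent
        else:
            break


@njit(cache=True)
def _sift_down(heap_t, heap_ix, pos, k, n):
    while True:
        left = 2 * k + 1
        if left >= n:
            break
        child = left
        right = left + 1
        if right < n and _heap_less(heap_t, heap_ix, right, left):
            child = right
        if _heap_less(heap_t, heap_ix, child, k):
            _heap_swap(heap_t, heap_ix, pos, k, child)
            k = child
        else:
            break


@njit(cache=True)
def _heap_update(heap_t, heap_ix, pos, voxel, new_t):
    k = pos[voxel]
    old = heap_t[k]
    heap_t[k] = new_t
    if new_t < old:
        _sift_up(heap_t, heap_ix, pos, k)
    else:
        _sift_down(heap_t, heap_ix, pos, k, len(heap_t))


@njit(cache=True, inline="always")
def _exp_draw(rate):
    if rate <= 0.0:
        return np.inf
    return -np.log(1.0 - np.random.random()) / rate


@njit(cache=True, inline="always")
def _reaction_total(u, kloc, i, rs1, rs2, R):
    tot = 0.0
    for r in range(R):
        kl = kloc[r, i]
        if kl == 0.0:
            continue
        s1 = rs1[r]
        if s1 < 0:
            tot += kl
        else:
            x1 = u[s1, i]
            s2 = rs2[r]
            if s2 < 0:
                tot += kl * x1
            elif s2 == s1:
                tot += kl * x1 * (x1 - 1)
            else:
                tot += kl * x1 * u[s2, i]
    return tot


@njit(cache=True, inline="always")
def _diffusion_total(u, qtot, i, M):
    tot = 0.0
    for m in range(M):
        tot += u[m, i] * qtot[m, i]
    return tot


@njit(cache=True)
def nsm_mass_action(
    u,            # (M, N) int64, modified in place
    tspan,        # (T,) output times
    states,       # (T, M, N) int64 output
    dptr,         # (M, N+1) int64: per-species CSR row pointers
    dcol,         # int64 concatenated column indices
    drate,        # float64 concatenated jump rates
    qtot,         # (M, N) per-species total outflow rate per molecule
    kloc1,        # (R, N) rate prefactor before tswitch
    kloc2,        # (R, N) rate prefactor from tswitch on
    tswitch,      # (R,) switch times (inf = never)
    rs1,          # (R,) first reactant species (-1: none)
    rs2,          # (R,) second reactant species (-1: none)
    S,            # (R, M) stoichiometry
    sink,         # (N,) uint8: absorbing voxels delete arrivals
    seed,
):
    np.random.seed(seed)
    M, N = u.shape
    R = kloc1.shape[0]
    T = tspan.shape[0]
    t_end = tspan[T - 1]

    # a global switch re-evaluates every voxel; gather distinct finite times
    t = tspan[0]

    a = np.empty(N)
    b = np.empty(N)
    kloc = kloc1
    for i in range(N):
        a[i] = _reaction_total(u, kloc, i, rs1, rs2, R)
        b[i] = _diffusion_total(u, qtot, i, M)

    heap_t = np.empty(N)
    heap_ix = np.empty(N, dtype=np.int64)
    pos = np.empty(N, dtype=np.int64)
    for i in range(N):
        heap_t[i] = t + _exp_draw(a[i] + b[i])
        heap_ix[i] = i
        pos[i] = i
    # heapify
    for k in range(N // 2 - 1, -1, -1):
        _sift_down(heap_t, heap_ix, pos, k, N)

    # single global switch time (minimum of per-reaction switches)
    t_sw = np.inf
    for r in range(R):
        if tswitch[r] < t_sw:
            t_sw = tswitch[r]
    switched = False

    out_ptr = 0
    states[0] = u
    out_ptr = 1
    n_reac = 0
    n_diff = 0

    while True:
        i = heap_ix[0]
        tev = heap_t[0]

        if (not switched) and tev >= t_sw and t_sw <= t_end:
            # activate the post-switch rates at exactly t_sw and rebuild
            kloc = kloc2
            switched = True
            for v in range(N):
                old = a[v] + b[v]
                a[v] = _reaction_total(u, kloc, v, rs1, rs2, R)
                new = a[v] + b[v]
                if old <= 0.0 or heap_t[pos[v]] == np.inf:
                    _heap_update(heap_t, heap_ix, pos, v, t_sw + _exp_draw(new))
                elif new != old:
                    _heap_update(
                        heap_t, heap_ix, pos, v, t_sw + (heap_t[pos[v]] - t_sw) * old / new
                    )
            continue

        while out_ptr < T and tspan[out_ptr] <= tev:
            states[out_ptr] = u
            out_ptr += 1
        if out_ptr >= T or tev > t_end or tev == np.inf:
            break
        t = tev

        atot = a[i]
        btot = b[i]
        x = np.random.random() * (atot + btot)
        j_affected = -1
        if x < atot:
            # reaction event: linear search over channels
            acc = 0.0
            rsel = -1
            for r in range(R):
                kl = kloc[r, i]
                if kl == 0.0:
                    continue
                s1 = rs1[r]
                if s1 < 0:
                    acc += kl
                else:
                    x1 = u[s1, i]
                    s2 = rs2[r]
                    if s2 < 0:
                        acc += kl * x1
                    elif s2 == s1:
                        acc += kl * x1 * (x1 - 1)
                    else:
                        acc += kl * x1 * u[s2, i]
                if acc > x:
                    rsel = r
                    break
            if rsel < 0:
                rsel = R - 1  # numerical slack: last active channel
                for r in range(R - 1, -1, -1):
                    if kloc[r, i] != 0.0:
                        rsel = r
                        break
            for m in range(M):
                u[m, i] += S[rsel, m]
            n_reac += 1
        else:
            # diffusion event: choose species, then target voxel
            x -= atot
            msel = -1
            acc = 0.0
            for m in range(M):
                acc += u[m, i] * qtot[m, i]
                if acc > x:
                    msel = m
                    break
            if msel < 0:
                for m in range(M - 1, -1, -1):
                    if u[m, i] > 0 and qtot[m, i] > 0:
                        msel = m
                        break
            # target ~ per-molecule rates
            y = np.random.random() * qtot[msel, i]
            jsel = -1
            acc = 0.0
            for p in range(dptr[msel, i], dptr[msel, i + 1]):
                acc += drate[p]
                if acc > y:
                    jsel = dcol[p]
                    break
            if jsel < 0:
                jsel = dcol[dptr[msel, i + 1] - 1]
            u[msel, i] -= 1
            if sink[jsel] == 0:
                u[msel, jsel] += 1
                j_affected = jsel
            n_diff += 1

        # update propensities and heap for affected voxels
        a[i] = _reaction_total(u, kloc, i, rs1, rs2, R)
        b[i] = _diffusion_total(u, qtot, i, M)
        _heap_update(heap_t, heap_ix, pos, i, t + _exp_draw(a[i] + b[i]))
        if j_affected >= 0:
            j = j_affected
            old = a[j] + b[j]
            a[j] = _reaction_total(u, kloc, j, rs1, rs2, R)
            b[j] = _diffusion_total(u, qtot, j, M)
            new = a[j] + b[j]
            tj = heap_t[pos[j]]
            if old <= 0.0 or tj == np.inf:
                _heap_update(heap_t, heap_ix, pos, j, t + _exp_draw(new))
            elif new != old:
                _heap_update(heap_t, heap_ix, pos, j, t + (tj - t) * old / new)

    while out_ptr < T:
        states[out_ptr] = u
        out_ptr += 1
    return n_reac, n_diff
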