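"""Numba heat-bath sweep kernels.

The kernels mutate ``labels`` (0-based) and the per-layer per-label degree
sums in place and return the number of label flips in the sweep.  They use
numba's global NumPy RNG; :func:`seed_kernel_rng` must be called before a
deterministic run.  The pure-NumPy mirror of the per-node energy lives in
:mod:`orthoclust._compiled` and is held to agree with this kernel (and with
full cost recomputation) in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def sweep(
    labels,
    q,
    T,
    order,
    layer_of,
    indptr0,
    indices0,
    k0,
    norm0,
    inv2m0,
    indptr1,
    indices1,
    k1,
    norm1,
    inv2m1,
    o_indptr,
    o_indices,
    o_weights,
    t_indptr,
    t_p1,
    t_p2,
    kappa,
    kappa_t,
    lam,
    K0,
    K1,
):
    flips = 0
    e = np.empty(q)
    for idx in range(order.shape[0]):
        i = order[idx]
        l = layer_of[i]
        old = labels[i]
        for s in range(q):
            e[s] = 0.0
        # sign class 0: positive (or all) edges
        if norm0[l] > 0.0:
            ki = k0[i]
            coef = norm0[l] * 2.0 * lam * ki * inv2m0[l]
            for s in range(q):
                kexc = K0[l, s]
                if s == old:
                    kexc -= ki
                e[s] += coef * kexc
            for p in range(indptr0[i], indptr0[i + 1]):
                e[labels[indices0[p]]] -= 2.0 * norm0[l]
        # sign class 1: negative edges, opposite sign
        if norm1[l] > 0.0:
            ki = k1[i]
            coef = norm1[l] * 2.0 * lam * ki * inv2m1[l]
            for s in range(q):
                kexc = K1[l, s]
                if s == old:
                    kexc -= ki
                e[s] -= coef * kexc
            for p in range(indptr1[i], indptr1[i + 1]):
                e[labels[indices1[p]]] += 2.0 * norm1[l]
        # orthology coupling
        for p in range(o_indptr[i], o_indptr[i + 1]):
            e[labels[o_indices[p]]] -= kappa * o_weights[p]
        # 1-1-1 triplet coupling
        for p in range(t_indptr[i], t_indptr[i + 1]):
            s1 = labels[t_p1[p]]
            if s1 == labels[t_p2[p]]:
                e[s1] -= kappa_t
        # Gibbs sampling over labels, max-subtracted for overflow safety
        emin = e[0]
        for s in range(1, q):
            if e[s] < emin:
                emin = e[s]
        z = 0.0
        for s in range(q):
            e[s] = np.exp(-(e[s] - emin) / T)
            z += e[s]
        r = np.random.random() * z
        new = q - 1
        acc = 0.0
        for s in range(q):
            acc += e[s]
            if r < acc:
                new = s
                break
        if new != old:
            flips += 1
            labels[i] = new
            K0[l, old] -= k0[i]
            K0[l, new] += k0[i]
            K1[l, old] -= k1[i]
            K1[l, new] += k1[i]
    return flips


def run_sweep(cn, labels, q, T, order, K0, K1):
    """Python-side convenience wrapper unpacking a CompiledNetwork."""
    return sweep(
        labels,
        q,
        T,
        order,
        cn.layer_of,
        cn.indptr0,
        cn.indices0,
        cn.k0,
        cn.norm0,
        cn.inv2m0,
        cn.indptr1,
        cn.indices1,
        cn.k1,
        cn.norm1,
        cn.inv2m1,
        cn.o_indptr,
        cn.o_indices,
        cn.o_weights,
        cn.t_indptr,
        cn.t_p1,
        cn.t_p2,
        cn.kappa,
        cn.kappa_t,
        cn.lam,
        K0,
        K1,
    )
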