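"""Flat-array view of a multi-layer network for the annealing inner loop.

The heat-bath sweep touches every node many thousands of times, so the
network is compiled once into CSR-style integer/float arrays that a numba
kernel (and a pure-NumPy mirror used in tests) can walk without touching
Python objects.  Two edge-sign classes are kept: class 0 holds positive (or
all, in unsigned mode) edges, class 1 the negative edges (empty in unsigned
mode).  Per-layer per-class prefactors encode the layer normalization and
the configuration-model null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix

from .cost import CostParams
from .graph_core import MultiLayerNetwork


@dataclass
class CompiledNetwork:
    M: int
    n_layers: int
    layer_of: np.ndarray  # int64[M]
    # sign class 0 (positive / all) and 1 (negative)
    indptr0: np.ndarray
    indices0: np.ndarray
    k0: np.ndarray  # float64[M], within-layer degree of the class
    norm0: np.ndarray  # float64[n_layers], modularity prefactor (0 when m = 0)
    inv2m0: np.ndarray  # float64[n_layers], 1/(2m) of the class (0 when m = 0)
    indptr1: np.ndarray
    indices1: np.ndarray
    k1: np.ndarray
    norm1: np.ndarray
    inv2m1: np.ndarray
    # symmetric orthology CSR
    o_indptr: np.ndarray
    o_indices: np.ndarray
    o_weights: np.ndarray
    # triplet incidence: node i participates with partners (p1, p2)
    t_indptr: np.ndarray
    t_p1: np.ndarray
    t_p2: np.ndarray
    kappa: float
    kappa_t: float
    lam: float


def _class_csr(mln: MultiLayerNetwork, sign: int | None):
    """Symmetric adjacency CSR plus per-layer degree/m arrays for one class."""
    M = mln.M
    n_layers = len(mln.layers)
    rows, cols = [], []
    m_layer = np.zeros(n_layers, dtype=float)
    k = np.zeros(M, dtype=float)
    for li, layer in enumerate(mln.layers):
        off = mln.layer_offset(layer.species_id)
        u, v = layer.edge_arrays(sign)
        rows.extend((off + u).tolist())
        cols.extend((off + v).tolist())
        m_layer[li] = u.size
        kl = layer.degrees(sign).astype(float)
        k[off : off + layer.n_nodes] = kl
    if rows:
        r = np.array(rows + cols, dtype=np.int64)
        c = np.array(cols + rows, dtype=np.int64)
        adj = coo_matrix((np.ones(r.size), (r, c)), shape=(M, M)).tocsr()
    else:
        adj = coo_matrix((M, M)).tocsr()
    return (
        adj.indptr.astype(np.int64),
        adj.indices.astype(np.int64),
        k,
        m_layer,
    )


def compile_network(mln: MultiLayerNetwork, params: CostParams) -> CompiledNetwork:
    M = mln.M
    n_layers = len(mln.layers)
    layer_of = np.empty(M, dtype=np.int64)
    for li, layer in enumerate(mln.layers):
        layer_of[mln.layer_slice(layer.species_id)] = li

    if params.signed_mode:
        ip0, ix0, k0, m0 = _class_csr(mln, sign=1)
        ip1, ix1, k1, m1 = _class_csr(mln, sign=-1)
        if np.any((m0 == 0) & (m1 == 0)):
            bad = mln.layers[int(np.argmax((m0 == 0) & (m1 == 0)))].species_id
            raise ValueError(f"layer {bad!r} has no edges in either sign class")
    else:
        ip0, ix0, k0, m0 = _class_csr(mln, sign=None)
        ip1 = np.zeros(M + 1, dtype=np.int64)
        ix1 = np.empty(0, dtype=np.int64)
        k1 = np.zeros(M, dtype=float)
        m1 = np.zeros(n_layers, dtype=float)
        if np.any(m0 == 0):
            bad = mln.layers[int(np.argmax(m0 == 0))].species_id
            raise ValueError(f"layer {bad!r} has no edges (m = 0)")

    def prefactors(m):
        norm = np.zeros(n_layers)
        inv2m = np.zeros(n_layers)
        nz = m > 0
        inv2m[nz] = 1.0 / (2.0 * m[nz])
        norm[nz] = inv2m[nz] if params.normalize_layers else 1.0
        return norm, inv2m

    norm0, inv2m0 = prefactors(m0)
    norm1, inv2m1 = prefactors(m1)

    ii, jj, ww = mln.ortholog_edges_global()
    if ii.size:
        o = coo_matrix(
            (np.concatenate([ww, ww]), (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
            shape=(M, M),
        ).tocsr()
        o_indptr = o.indptr.astype(np.int64)
        o_indices = o.indices.astype(np.int64)
        o_weights = o.data.astype(float)
    else:
        o_indptr = np.zeros(M + 1, dtype=np.int64)
        o_indices = np.empty(0, dtype=np.int64)
        o_weights = np.empty(0, dtype=float)

    trip = mln.triplet_indices()
    per_node: list[list[tuple[int, int]]] = [[] for _ in range(M)]
    for a, b, c in trip:
        per_node[a].append((b, c))
        per_node[b].append((a, c))
        per_node[c].append((a, b))
    t_indptr = np.zeros(M + 1, dtype=np.int64)
    t_p1, t_p2 = [], []
    for i in range(M):
        t_indptr[i + 1] = t_indptr[i] + len(per_node[i])
        for p1, p2 in per_node[i]:
            t_p1.append(p1)
            t_p2.append(p2)

    return CompiledNetwork(
        M=M,
        n_layers=n_layers,
        layer_of=layer_of,
        indptr0=ip0,
        indices0=ix0,
        k0=k0,
        norm0=norm0,
        inv2m0=inv2m0,
        indptr1=ip1,
        indices1=ix1,
        k1=k1,
        norm1=norm1,
        inv2m1=inv2m1,
        o_indptr=o_indptr,
        o_indices=o_indices,
        o_weights=o_weights,
        t_indptr=t_indptr,
        t_p1=np.array(t_p1, dtype=np.int64),
        t_p2=np.array(t_p2, dtype=np.int64),
        kappa=float(params.kappa),
        kappa_t=float(params.kappa_triplet),
        lam=float(params.lambda_res),
    )


def degree_sums(cn: CompiledNetwork, labels0: np.ndarray, q: int):
    """Per-layer per-label degree sums K[c][layer, label] for 0-based labels."""
    K0 = np.zeros((cn.n_layers, q))
    K1 = np.zeros((cn.n_layers, q))
    np.add.at(K0, (cn.layer_of, labels0), cn.k0)
    np.add.at(K1, (cn.layer_of, labels0), cn.k1)
    return K0, K1


def local_energies(cn: CompiledNetwork, labels0: np.ndarray, node: int, q: int) -> np.ndarray:
    """NumPy mirror of the kernel's per-label local energy for one node.

    Returns e[s] such that moving ``node`` to 0-based label s changes the
    total cost H by e[s] - e[current]; label-independent constants are
    dropped.  This is the contract the incremental kernel must satisfy
    against full :func:`orthoclust.cost.total_cost` recomputation.
    """
    e = np.zeros(q)
    l = int(cn.layer_of[node])
    old = int(labels0[node])
    K0, K1 = degree_sums(cn, labels0, q)
    for sgn, indptr, indices, k, norm, inv2m, K in (
        (+1.0, cn.indptr0, cn.indices0, cn.k0, cn.norm0, cn.inv2m0, K0),
        (-1.0, cn.indptr1, cn.indices1, cn.k1, cn.norm1, cn.inv2m1, K1),
    ):
        if norm[l] == 0.0:
            continue
        ki = k[node]
        Kexc = K[l].copy()
        Kexc[old] -= ki
        e += sgn * norm[l] * 2.0 * cn.lam * ki * inv2m[l] * Kexc
        nbr = indices[indptr[node] : indptr[node + 1]]
        np.add.at(e, labels0[nbr], -2.0 * sgn * norm[l])
    o = slice(cn.o_indptr[node], cn.o_indptr[node + 1])
    np.add.at(e, labels0[cn.o_indices[o]], -cn.kappa * cn.o_weights[o])
    for p in range(cn.t_indptr[node], cn.t_indptr[node + 1]):
        s1 = labels0[cn.t_p1[p]]
        if s1 == labels0[cn.t_p2[p]]:
            e[s1] -= cn.kappa_t
    return e
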