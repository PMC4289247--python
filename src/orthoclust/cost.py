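"""The multi-layer Potts cost function.

Every node takes a label sigma in {1..q}; nodes sharing a label form a
module.  The cost of a configuration is

    H = -( sum_layers Q_layer + kappa * sum_pairs O_pair + kappa_t * T )

where ``Q_layer`` is the (signed) modularity of the layer under the labeling,
``O_pair`` sums ortholog-link weights over co-labeled cross-species pairs,
and ``T`` counts 1-1-1 triplets whose three members share a label.  Lower H
is better: dense within-module wiring and co-labeled orthologs both lower
the cost.  The coupling constant ``kappa`` sets the relative importance of
orthology links against intra-species co-association; the resolution
parameter ``lambda`` rescales the configuration-model null term
Lambda_ij = A_ij - lambda * k_i k_j / (2m) and thereby the typical module
size (lambda = 1 is the conventional choice).

The optimal assignment is the ground state of a q-state Potts model; the
annealing module searches for it, and :func:`ground_state_bruteforce` finds
it exactly on tiny instances for validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

from .graph_core import Labeling, MultiLayerNetwork, OrthologyMap, SpeciesNetwork


@dataclass
class CostParams:
    """Parameters of the cost function.

    kappa
        Coupling constant on pairwise orthology agreement (>= 0).
    lambda_res
        Resolution parameter multiplying the degree-product null (> 0).
    signed_mode
        Score positive and negative edge classes separately (Q+ - Q-).
    kappa_triplet
        Coupling on 1-1-1 triplet agreement; defaults to ``kappa``.
    normalize_layers
        Divide each layer's modularity by its own 2m.  Off by default: on
        the raw scale one co-labeled edge and one co-labeled ortholog pair
        contribute comparably (kappa of order 1 balances them), which is the
        scale on which the coupling constant is meant to be tuned.  The
        normalized option makes unequal layers contribute comparably but
        puts the two cost terms on temperature scales ~2m apart, which
        single-spin annealing resolves poorly.
    """

    kappa: float = 1.0
    lambda_res: float = 1.0
    signed_mode: bool = False
    kappa_triplet: float | None = None
    normalize_layers: bool = False

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.lambda_res <= 0:
            raise ValueError("lambda_res must be > 0")
        if self.kappa_triplet is None:
            self.kappa_triplet = self.kappa
        if self.kappa_triplet < 0:
            raise ValueError("kappa_triplet must be >= 0")


def modularity_term(
    net: SpeciesNetwork,
    labels: np.ndarray,
    lambda_res: float = 1.0,
    normalize: bool = True,
    sign: int | None = None,
) -> float:
    """Modularity of one layer under a labeling.

    Q = (1/2m) * sum_{i,j} [A_ij - lambda * k_i k_j / (2m)] delta(s_i, s_j),
    the sum running over ordered pairs including i = j.  With lambda = 1 the
    all-one-module labeling scores exactly 0.  ``sign`` restricts the layer
    to one edge-sign class (degrees and m of that class).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != net.n_nodes:
        raise ValueError("labeling does not cover the layer")
    m = net.edge_count(sign)
    if m == 0:
        raise ValueError(f"layer {net.species_id!r} has no edges (sign={sign})")
    u, v = net.edge_arrays(sign)
    k = net.degrees(sign).astype(float)
    edge_term = 2.0 * np.count_nonzero(labels[u] == labels[v])
    # sum_s (sum_{i: s_i=s} k_i)^2 realizes the ordered-pair degree product
    _, inv = np.unique(labels, return_inverse=True)
    ks = np.bincount(inv, weights=k)
    null_term = lambda_res * float(np.sum(ks**2)) / (2.0 * m)
    raw = edge_term - null_term
    return raw / (2.0 * m) if normalize else raw


def signed_modularity_term(
    net_pos: SpeciesNetwork,
    net_neg: SpeciesNetwork,
    labels: np.ndarray,
    lambda_res: float = 1.0,
    normalize: bool = True,
) -> float:
    """Q+ - Q-: each sign class scored with its own degrees and m.

    Negative links act oppositely: co-labeling anti-correlated genes is
    penalized.  An empty sign class contributes 0.
    """
    if net_pos.nodes != net_neg.nodes:
        raise ValueError("sign classes must share one node set")
    total = 0.0
    if net_pos.edge_count() > 0:
        total += modularity_term(net_pos, labels, lambda_res, normalize)
    if net_neg.edge_count() > 0:
        total -= modularity_term(net_neg, labels, lambda_res, normalize)
    if net_pos.edge_count() == 0 and net_neg.edge_count() == 0:
        raise ValueError("both sign classes are empty")
    return total


def split_signs(net: SpeciesNetwork) -> tuple[SpeciesNetwork, SpeciesNetwork]:
    """Split a layer into its positive-edge and negative-edge subgraphs."""
    pos = SpeciesNetwork(net.species_id, list(net.nodes))
    neg = SpeciesNetwork(net.species_id, list(net.nodes))
    for a, b, s in net.edges():
        (pos if s > 0 else neg).add_edge(a, b, 1)
    return pos, neg


def orthology_term(
    om: OrthologyMap,
    labels_first: Mapping[str, int],
    labels_second: Mapping[str, int],
) -> float:
    """Sum of ortholog-pair weights whose endpoints share a label."""
    total = 0.0
    for (a, b), w in zip(om.pairs, om.weights):
        if labels_first[a] == labels_second[b]:
            total += float(w)
    return total


def _layer_modularity(net: SpeciesNetwork, labels: np.ndarray, params: CostParams) -> float:
    if params.signed_mode:
        pos, neg = split_signs(net)
        return signed_modularity_term(
            pos, neg, labels, params.lambda_res, params.normalize_layers
        )
    return modularity_term(net, labels, params.lambda_res, params.normalize_layers)


def total_cost(mln: MultiLayerNetwork, labeling: Labeling, params: CostParams) -> float:
    """Full cost H of a labeling; lower is better."""
    sigma = labeling.sigma
    if sigma.shape[0] != mln.M:
        raise ValueError(f"labeling covers {sigma.shape[0]} nodes, network has {mln.M}")
    score = 0.0
    for layer in mln.layers:
        score += _layer_modularity(layer, sigma[mln.layer_slice(layer.species_id)], params)
    ii, jj, ww = mln.ortholog_edges_global()
    if ii.size:
        score += params.kappa * float(ww[sigma[ii] == sigma[jj]].sum())
    trip = mln.triplet_indices()
    if trip.shape[0]:
        same = (sigma[trip[:, 0]] == sigma[trip[:, 1]]) & (
            sigma[trip[:, 1]] == sigma[trip[:, 2]]
        )
        score += params.kappa_triplet * float(np.count_nonzero(same))
    return -score


def _canonical_labelings(M: int, q: int) -> Iterator[np.ndarray]:
    """Restricted-growth strings: one representative per label permutation."""
    sigma = np.ones(M, dtype=np.int64)

    def rec(i: int, used: int) -> Iterator[np.ndarray]:
        if i == M:
            yield sigma.copy()
            return
        for s in range(1, min(used + 1, q) + 1):
            sigma[i] = s
            yield from rec(i + 1, max(used, s))

    yield from rec(0, 0)


def ground_state_bruteforce(
    mln: MultiLayerNetwork, params: CostParams, q: int
) -> Labeling:
    """Exhaustive minimizer of :func:`total_cost`, up to label permutation.

    Guard: refuses instances with q**M > 1e7 configurations.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if q**mln.M > 10**7:
        raise ValueError(
            f"instance too large for brute force: q^M = {q}^{mln.M} > 1e7"
        )
    best: np.ndarray | None = None
    best_cost = np.inf
    for sigma in _canonical_labelings(mln.M, q):
        c = total_cost(mln, Labeling(sigma, q), params)
        if c < best_cost - 1e-12:
            best_cost = c
            best = sigma.copy()
    assert best is not None
    return Labeling(best, q)
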