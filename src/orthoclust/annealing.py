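"""Heat-bath simulated annealing over Potts labelings.

The annealer starts from a random labeling at a calibrated temperature hot
enough that nearly every node changes label each sweep (flipping rate above
1 - 1/q, the rate of uniform resampling), then cools geometrically by a
factor of 0.9, running a fixed number of full heat-bath sweeps at each
temperature, and stops once fewer than 1% of nodes flip in a sweep.  The
returned labeling is the minimum-cost configuration encountered anywhere in
the run, not necessarily the final one.  Multiple independent runs
(:func:`run_ensemble`) feed the consensus co-appearance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._compiled import CompiledNetwork, compile_network, degree_sums, local_energies
from .cost import CostParams
from .graph_core import Labeling, MultiLayerNetwork


@dataclass
class AnnealSchedule:
    """Cooling schedule parameters.

    ``target_initial_fliprate`` defaults to 1 - 1/q at calibration time.
    """

    cooling_factor: float = 0.9
    target_initial_fliprate: float | None = None
    stop_fliprate: float = 0.01
    sweeps_per_temperature: int = 20
    max_temperatures: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_factor < 1.0:
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.sweeps_per_temperature < 1:
            raise ValueError("sweeps_per_temperature must be >= 1")
        if self.max_temperatures < 1:
            raise ValueError("max_temperatures must be >= 1")

    def resolved_target(self, q: int) -> float:
        t = self.target_initial_fliprate if self.target_initial_fliprate is not None else 1.0 - 1.0 / q
        if not 0.0 < self.stop_fliprate < t < 1.0:
            raise ValueError("need 0 < stop_fliprate < target_initial_fliprate < 1")
        return t


@dataclass
class AnnealResult:
    labeling: Labeling
    final_cost: float
    temperature_trace: list[tuple[float, float, float]] = field(default_factory=list)
    seed: int = 0
    converged: bool = True


class _FastCost:
    """Total cost from compiled arrays; agrees with cost.total_cost."""

    def __init__(self, cn: CompiledNetwork):
        self.cn = cn
        self.rows0 = np.repeat(np.arange(cn.M), np.diff(cn.indptr0))
        self.rows1 = np.repeat(np.arange(cn.M), np.diff(cn.indptr1))
        self.lay0 = cn.layer_of[self.rows0] if self.rows0.size else self.rows0
        self.lay1 = cn.layer_of[self.rows1] if self.rows1.size else self.rows1
        self.orows = np.repeat(np.arange(cn.M), np.diff(cn.o_indptr))

    def __call__(self, labels0: np.ndarray) -> float:
        cn = self.cn
        score = 0.0
        for rows, lay, indices, k, norm, inv2m, sgn in (
            (self.rows0, self.lay0, cn.indices0, cn.k0, cn.norm0, cn.inv2m0, +1.0),
            (self.rows1, self.lay1, cn.indices1, cn.k1, cn.norm1, cn.inv2m1, -1.0),
        ):
            if not np.any(norm > 0.0):
                continue
            eq = (labels0[rows] == labels0[indices]).astype(float)
            e_l = np.bincount(lay, weights=eq, minlength=cn.n_layers)
            # per-layer per-label degree sums give the ordered-pair null
            ks = np.zeros((cn.n_layers, int(labels0.max()) + 1))
            np.add.at(ks, (cn.layer_of, labels0), k)
            null_l = np.sum(ks**2, axis=1)
            score += sgn * float(np.sum(norm * (e_l - cn.lam * inv2m * null_l)))
        if cn.o_weights.size:
            eq = labels0[self.orows] == labels0[cn.o_indices]
            score += cn.kappa * float(cn.o_weights[eq].sum()) / 2.0  # symmetric CSR
        if cn.t_p1.size:
            i = np.repeat(np.arange(cn.M), np.diff(cn.t_indptr))
            same = (labels0[i] == labels0[cn.t_p1]) & (labels0[cn.t_p1] == labels0[cn.t_p2])
            score += cn.kappa_t * float(np.count_nonzero(same)) / 3.0  # 3 incidences/triplet
        return -score


def coalesce_labels(cn: CompiledNetwork, labels: np.ndarray, q: int) -> int:
    """Greedily merge whole labels while a merge strictly lowers the cost.

    Single-spin heat-bath moves cannot relabel a whole module at once, so
    two well-formed modules that ought to share a label (conserved
    counterparts in different layers, or fragments of one module) can stay
    apart behind an energy barrier.  Merging two labels is exactly the
    collective move that crosses it: the cost change of merging labels a, b
    is computed exactly from the between-label edge counts, degree sums,
    orthology weight and triplet completions, and the best strictly
    negative merge is applied until none remains.  At high temperature the
    next sweeps re-randomize, so the pass only matters once the system has
    begun to order.  Returns the number of merges; mutates ``labels``.
    """
    active = np.unique(labels)
    if active.size < 2:
        return 0
    nl = cn.n_layers
    # between-label co-labeled-edge counts per layer per class, degree sums,
    # and pairwise orthology weight
    E = [np.zeros((nl, q, q)), np.zeros((nl, q, q))]
    K = [np.zeros((nl, q)), np.zeros((nl, q))]
    for c, (indptr, indices, k) in enumerate(
        ((cn.indptr0, cn.indices0, cn.k0), (cn.indptr1, cn.indices1, cn.k1))
    ):
        rows = np.repeat(np.arange(cn.M), np.diff(indptr))
        if rows.size:
            # symmetric accumulation: E[l, a, b] = #edges between groups a, b
            np.add.at(E[c], (cn.layer_of[rows], labels[rows], labels[indices]), 1.0)
        np.add.at(K[c], (cn.layer_of, labels), k)
    W = np.zeros((q, q))
    orows = np.repeat(np.arange(cn.M), np.diff(cn.o_indptr))
    if orows.size:
        np.add.at(W, (labels[orows], labels[cn.o_indices]), cn.o_weights / 2.0)
        W = W + W.T  # undirected pair weight between label groups

    def pair_gain() -> np.ndarray:
        """Score gain (= -dH) of merging each label pair; -inf off-support."""
        g = np.zeros((q, q))
        for c, sgn in ((0, 1.0), (1, -1.0)):
            coef = (cn.norm0, cn.norm1)[c]
            inv2m = (cn.inv2m0, cn.inv2m1)[c]
            for l in range(nl):
                if coef[l] == 0.0:
                    continue
                kk = np.outer(K[c][l], K[c][l])
                g += sgn * coef[l] * (2.0 * E[c][l] - 2.0 * cn.lam * inv2m[l] * kk)
        g += cn.kappa * W
        return g

    def triplet_gain(a: int, b: int) -> float:
        if cn.t_p1.size == 0:
            return 0.0
        i = np.repeat(np.arange(cn.M), np.diff(cn.t_indptr))
        la, lb, lc_ = labels[i], labels[cn.t_p1], labels[cn.t_p2]
        before = (la == lb) & (lb == lc_)
        la2 = np.where(la == b, a, la)
        lb2 = np.where(lb == b, a, lb)
        lc2 = np.where(lc_ == b, a, lc_)
        after = (la2 == lb2) & (lb2 == lc2)
        return cn.kappa_t * float(after.sum() - before.sum()) / 3.0

    G = pair_gain()
    mask = np.zeros(q, dtype=bool)
    mask[active] = True
    G[~mask, :] = -np.inf
    G[:, ~mask] = -np.inf
    np.fill_diagonal(G, -np.inf)
    n_merges = 0
    tol = 1e-10
    while True:
        flat = int(np.argmax(G))
        a, b = flat // q, flat % q
        gain = G[a, b] + (triplet_gain(a, b) if cn.t_p1.size else 0.0)
        if not np.isfinite(gain) or gain <= tol:
            break
        labels[labels == b] = a
        n_merges += 1
        for c in range(2):
            E[c][:, a, :] += E[c][:, b, :]
            E[c][:, :, a] += E[c][:, :, b]
            E[c][:, b, :] = 0.0
            E[c][:, :, b] = 0.0
            K[c][:, a] += K[c][:, b]
            K[c][:, b] = 0.0
        W[a, :] += W[b, :]
        W[:, a] += W[:, b]
        W[a, a] = 0.0
        W[b, :] = 0.0
        W[:, b] = 0.0
        mask[b] = False
        # refresh gains involving the merged label only
        Gnew = np.full(q, -np.inf)
        idx = np.where(mask)[0]
        for x in idx:
            if x == a:
                continue
            g = 0.0
            for c, sgn in ((0, 1.0), (1, -1.0)):
                coef = (cn.norm0, cn.norm1)[c]
                inv2m = (cn.inv2m0, cn.inv2m1)[c]
                for l in range(nl):
                    if coef[l] == 0.0:
                        continue
                    g += sgn * coef[l] * (
                        2.0 * E[c][l, a, x]
                        - 2.0 * cn.lam * inv2m[l] * K[c][l, a] * K[c][l, x]
                    )
            Gnew[x] = g + cn.kappa * W[a, x]
        G[a, :] = Gnew
        G[:, a] = Gnew
        G[b, :] = -np.inf
        G[:, b] = -np.inf
    return n_merges


def decollide_labels(cn: CompiledNetwork, labels: np.ndarray, q: int) -> int:
    """Move label-squatting groups to fresh labels (cost-neutral, exact).

    When groups in different layers share a label without any orthology
    between them, the collision is invisible to the cost function but fakes
    cross-layer co-appearance and blocks the label merges that align
    conserved counterparts.  For every label occupied in more than one
    layer, each layer group with zero ortholog weight to the other
    same-label nodes (keeping the lowest-layer group in place) is moved to
    an unused label; the move changes neither modularity (target empty) nor
    the orthology term (weight zero).  Returns the number of moves.
    """
    n_moves = 0
    occ = np.zeros((cn.n_layers, q), dtype=np.int64)
    np.add.at(occ, (cn.layer_of, labels), 1)
    free = [int(t) for t in range(q) if occ[:, t].sum() == 0]
    orows = np.repeat(np.arange(cn.M), np.diff(cn.o_indptr))
    OX = np.zeros((cn.n_layers, q, q))
    if orows.size:
        np.add.at(OX, (cn.layer_of[orows], labels[orows], labels[cn.o_indices]), cn.o_weights)
    for a in range(q):
        layers_here = np.where(occ[:, a] > 0)[0]
        if layers_here.size < 2:
            continue
        for l in layers_here[1:]:
            if not free:
                return n_moves
            if cn.kappa * OX[l, a, a] == 0.0:
                t = free.pop()
                labels[(cn.layer_of == l) & (labels == a)] = t
                n_moves += 1
    return n_moves


def regroup_pass(cn: CompiledNetwork, labels: np.ndarray, q: int, cost_of) -> int:
    """Steepest-descent moves of whole (layer, label) groups to better labels.

    Complements :func:`coalesce_labels`: a group move can re-align one
    layer's module onto its cross-layer counterpart's label or re-attach a
    fragment, resolving accidental label collisions between unrelated
    modules in different layers (cost-neutral for single-spin dynamics but
    poison for the consensus).  Each candidate move's gain is computed from
    group-level accumulators and verified against the exact cost before it
    is applied.  Returns the number of moves; mutates ``labels``.
    """
    n_moves = 0
    current_cost = cost_of(labels)
    while True:
        nl = cn.n_layers
        E = [np.zeros((nl, q, q)), np.zeros((nl, q, q))]
        K = [np.zeros((nl, q)), np.zeros((nl, q))]
        for c, (indptr, indices, k) in enumerate(
            ((cn.indptr0, cn.indices0, cn.k0), (cn.indptr1, cn.indices1, cn.k1))
        ):
            rows = np.repeat(np.arange(cn.M), np.diff(indptr))
            if rows.size:
                np.add.at(E[c], (cn.layer_of[rows], labels[rows], labels[indices]), 1.0)
            np.add.at(K[c], (cn.layer_of, labels), k)
        OX = np.zeros((nl, q, q))  # ortholog weight from (layer, label) to label
        orows = np.repeat(np.arange(cn.M), np.diff(cn.o_indptr))
        if orows.size:
            np.add.at(
                OX, (cn.layer_of[orows], labels[orows], labels[cn.o_indices]), cn.o_weights
            )
        best_gain = 0.0
        best_move = None
        tol = 1e-10
        for l in range(nl):
            occupied = np.where((K[0][l] > 0) | (K[1][l] > 0))[0]
            for a in occupied:
                gain = np.zeros(q)
                for c, sgn in ((0, 1.0), (1, -1.0)):
                    coef = (cn.norm0, cn.norm1)[c]
                    inv2m = (cn.inv2m0, cn.inv2m1)[c]
                    if coef[l] == 0.0:
                        continue
                    gain += sgn * coef[l] * (
                        2.0 * E[c][l, a] - 2.0 * cn.lam * inv2m[l] * K[c][l, a] * K[c][l]
                    )
                gain += cn.kappa * (OX[l, a] - OX[l, a, a])
                gain[a] = 0.0
                t = int(np.argmax(gain))
                if gain[t] > best_gain + tol:
                    best_gain = float(gain[t])
                    best_move = (l, int(a), t)
        if best_move is None:
            return n_moves
        l, a, t = best_move
        trial = labels.copy()
        trial[(cn.layer_of == l) & (labels == a)] = t
        trial_cost = cost_of(trial)
        if trial_cost >= current_cost - 1e-10:  # triplet terms may disagree
            return n_moves
        labels[:] = trial
        current_cost = trial_cost
        n_moves += 1


def heat_bath_update(
    mln: MultiLayerNetwork,
    labeling: Labeling,
    node: int,
    T: float,
    params: CostParams,
    rng: np.random.Generator,
    compiled: CompiledNetwork | None = None,
) -> int:
    """Resample one node's label from the Gibbs distribution at temperature T.

    Samples label s with probability proportional to exp(-H(s)/T), where
    H(s) is the total cost with only ``node``'s label varied; the shared
    constant cancels, so only the node's local terms enter.  Returns the new
    1-based label (the labeling object is not mutated).
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    cn = compiled if compiled is not None else compile_network(mln, params)
    labels0 = labeling.sigma - 1
    e = local_energies(cn, labels0, node, labeling.q)
    w = np.exp(-(e - e.min()) / T)
    p = w / w.sum()
    return int(rng.choice(labeling.q, p=p)) + 1


def _measure_fliprate(
    cn: CompiledNetwork, q: int, T: float, rng: np.random.Generator, n_sweeps: int = 3
) -> float:
    labels = rng.integers(0, q, cn.M).astype(np.int64)
    K0, K1 = degree_sums(cn, labels, q)
    flips = 0
    for _ in range(n_sweeps):
        order = rng.permutation(cn.M).astype(np.int64)
        flips += _kernels.run_sweep(cn, labels, q, T, order, K0, K1)
    return flips / (n_sweeps * cn.M)


def calibrate_initial_temperature(
    mln: MultiLayerNetwork,
    params: CostParams,
    q: int,
    schedule: AnnealSchedule,
    rng: np.random.Generator,
    compiled: CompiledNetwork | None = None,
    max_doublings: int = 60,
) -> float:
    """Doubling search for the coolest temperature that still melts the system.

    Returns the smallest T on the grid {T0 * 2^k} whose measured per-sweep
    flipping rate (3 sweeps from a random labeling) exceeds 1 - 1/q.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    cn = compiled if compiled is not None else compile_network(mln, params)
    target = schedule.resolved_target(q)
    T = 1.0
    if _measure_fliprate(cn, q, T, rng) > target:
        for _ in range(max_doublings):
            if _measure_fliprate(cn, q, T / 2.0, rng) <= target:
                return T
            T /= 2.0
        raise RuntimeError("temperature calibration failed to bracket the target rate")
    for _ in range(max_doublings):
        T *= 2.0
        if _measure_fliprate(cn, q, T, rng) > target:
            return T
    raise RuntimeError("temperature calibration failed within 60 doublings")


def anneal(
    mln: MultiLayerNetwork,
    params: CostParams,
    q: int,
    schedule: AnnealSchedule,
    compiled: CompiledNetwork | None = None,
) -> AnnealResult:
    """One full annealing run; deterministic given ``schedule.seed``."""
    if q < 2:
        raise ValueError("q must be >= 2")
    cn = compiled if compiled is not None else compile_network(mln, params)
    rng = np.random.default_rng(schedule.seed)
    _kernels.seed_kernel_rng(int(schedule.seed) % (2**31 - 1))
    T = calibrate_initial_temperature(mln, params, q, schedule, rng, compiled=cn)
    cost_of = _FastCost(cn)
    labels = rng.integers(0, q, cn.M).astype(np.int64)
    K0, K1 = degree_sums(cn, labels, q)
    best = labels.copy()
    best_cost = cost_of(labels)
    trace: list[tuple[float, float, float]] = []
    converged = False
    for _ in range(schedule.max_temperatures):
        flips = 0
        for _s in range(schedule.sweeps_per_temperature):
            order = rng.permutation(cn.M).astype(np.int64)
            flips = _kernels.run_sweep(cn, labels, q, T, order, K0, K1)
            c = cost_of(labels)
            if c < best_cost:
                best_cost = c
                best = labels.copy()
        moved = decollide_labels(cn, labels, q)
        moved += coalesce_labels(cn, labels, q)
        moved += regroup_pass(cn, labels, q, cost_of)
        if moved:
            K0, K1 = degree_sums(cn, labels, q)
        # ties included: the decollided/coalesced configuration is preferred
        c = cost_of(labels)
        if c <= best_cost + 1e-12:
            best_cost = min(c, best_cost)
            best = labels.copy()
        rate = flips / cn.M  # last sweep at this temperature
        trace.append((T, rate, cost_of(labels)))
        if rate < schedule.stop_fliprate:
            converged = True
            break
        T *= schedule.cooling_factor
    return AnnealResult(
        labeling=Labeling(best + 1, q),
        final_cost=float(best_cost),
        temperature_trace=trace,
        seed=schedule.seed,
        converged=converged,
    )


def run_ensemble(
    mln: MultiLayerNetwork,
    params: CostParams,
    q: int,
    schedule: AnnealSchedule,
    R: int,
    n_jobs: int = 1,
) -> list[AnnealResult]:
    """R independent annealing runs with seeds seed+0 .. seed+R-1.

    Every run seeds its own RNG streams at start, so parallel execution
    (``n_jobs`` != 1, via joblib processes) returns results identical to the
    serial loop.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    cn = compile_network(mln, params)
    schedules = [
        AnnealSchedule(
            cooling_factor=schedule.cooling_factor,
            target_initial_fliprate=schedule.target_initial_fliprate,
            stop_fliprate=schedule.stop_fliprate,
            sweeps_per_temperature=schedule.sweeps_per_temperature,
            max_temperatures=schedule.max_temperatures,
            seed=schedule.seed + r,
        )
        for r in range(R)
    ]
    if n_jobs == 1:
        return [anneal(mln, params, q, s, compiled=cn) for s in schedules]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=n_jobs, backend="loky")(
        delayed(anneal)(mln, params, q, s) for s in schedules
    )
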