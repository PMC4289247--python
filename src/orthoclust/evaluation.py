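"""Benchmarking machinery for cross-species modules.

Genes are keyed as ``(species_id, gene)`` tuples throughout so that the same
machinery serves intra- and cross-species comparisons.  Provided here:

* GO semantic similarity between genes (term vectors weighted by inverse
  document frequency, compared by cosine) and the weighted-network
  modularity of a module assignment against that GO similarity network --
  the benchmark used to pick the coupling constant kappa;
* metagene recovery (fraction of cross-species gold-standard groups whose
  members land in a single module);
* hypergeometric enrichment of ortholog pairs between a module pair;
* the pairwise-overlap statistic I/(I+II+III) for comparing clusterings;
* a permutation test for regulator sharing within vs between modules;
* expression-based mapping of ncRNAs onto modules with an empirical-FDR
  neighbor threshold, plus per-class enrichment of the mapped ncRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annealing import AnnealSchedule, run_ensemble
from .consensus import ModuleSet, coappearance, extract_modules
from .cost import CostParams, modularity_term
from .graph_core import MultiLayerNetwork, OrthologyMap

logger = logging.getLogger(__name__)

GeneKey = tuple[str, str]


# ---------------------------------------------------------------------------
# GO similarity
# ---------------------------------------------------------------------------

@dataclass
class GOAnnotationMatrix:
    """Binary gene-by-term incidence matrix."""

    genes: list[GeneKey]
    terms: list[str]
    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B)
        if self.B.shape != (len(self.genes), len(self.terms)):
            raise ValueError("B shape does not match genes x terms")
        if not np.isin(self.B, (0, 1)).all():
            raise ValueError("B must be binary")

    @classmethod
    def from_annotations(cls, annotations: Mapping[GeneKey, Iterable[str]]) -> "GOAnnotationMatrix":
        genes = list(annotations)
        terms = sorted({t for ts in annotations.values() for t in ts})
        tindex = {t: j for j, t in enumerate(terms)}
        B = np.zeros((len(genes), len(terms)), dtype=np.int8)
        for i, g in enumerate(genes):
            for t in annotations[g]:
                B[i, tindex[t]] = 1
        return cls(genes, terms, B)


@dataclass
class GOSimilarityNetwork:
    """Weighted gene-gene similarity network (cosine of idf-weighted vectors)."""

    genes: list[GeneKey]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.genes), len(self.genes)):
            raise ValueError("W must be genes x genes")


def go_similarity(ann: GOAnnotationMatrix) -> GOSimilarityNetwork:
    """IDF-weighted cosine similarity between annotation vectors.

    Term j is weighted idf_j = ln(n / n_j) with n_j the number of genes
    carrying the term; a term annotating every gene gets weight 0, so
    uninformative high-level terms drop out.  Genes annotated with no term
    are excluded (logged); genes whose weighted vector is all-zero get
    similarity 0 to everything.  The diagonal of the returned W is 0 (the
    network view used for modularity).
    """
    has_term = ann.B.sum(axis=1) > 0
    n_excl = int((~has_term).sum())
    if n_excl:
        logger.warning("excluding %d gene(s) with no GO terms from similarity", n_excl)
    B = ann.B[has_term].astype(float)
    genes = [g for g, k in zip(ann.genes, has_term) if k]
    n = B.shape[0]
    n_j = B.sum(axis=0)
    with np.errstate(divide="ignore"):
        idf = np.where(n_j > 0, np.log(n / np.maximum(n_j, 1)), 0.0)
    G = B * idf
    norms = np.linalg.norm(G, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d gene(s) have all-zero weighted GO vectors; similarity 0", int(zero.sum()))
    norms[zero] = 1.0
    U = G / norms[:, None]
    W = np.clip(U @ U.T, 0.0, 1.0)
    W[zero, :] = 0.0
    W[:, zero] = 0.0
    np.fill_diagonal(W, 0.0)
    return GOSimilarityNetwork(genes, W)


def weighted_modularity(
    net: GOSimilarityNetwork, modules: ModuleSet | Mapping[GeneKey, int]
) -> float:
    """Modularity of a module assignment on the weighted similarity network.

    Q_w = (1/2m) sum_modules [ W_within - (sum k_in_module)^2 / (2m) ] with
    k_i = sum_j W_ij and m = sum_i k_i / 2; genes not assigned to any module
    are ignored by the delta but keep their degrees.
    """
    member = modules.membership_keys() if isinstance(modules, ModuleSet) else dict(modules)
    k = net.W.sum(axis=1)
    two_m = float(k.sum())
    if two_m == 0:
        raise ValueError("similarity network has zero total weight")
    by_module: dict[int, list[int]] = {}
    for i, g in enumerate(net.genes):
        if g in member:
            by_module.setdefault(member[g], []).append(i)
    q = 0.0
    for idx in by_module.values():
        ix = np.asarray(idx)
        q += float(net.W[np.ix_(ix, ix)].sum()) - float(k[ix].sum()) ** 2 / two_m
    return q / two_m


# ---------------------------------------------------------------------------
# metagenes
# ---------------------------------------------------------------------------

@dataclass
class MetageneSet:
    """Named cross-species gene groups expected to co-cluster."""

    groups: dict[str, list[GeneKey]]

    def __len__(self) -> int:
        return len(self.groups)


def metagene_recovery(
    modules: ModuleSet | Mapping[GeneKey, int],
    metagenes: MetageneSet,
    universe: set[GeneKey] | None = None,
) -> float:
    """Fraction of metagenes whose resolvable members share one module.

    Members outside ``universe`` (when given) are dropped as unresolvable;
    members in the universe but unassigned to any module count against
    recovery.  Metagenes with no resolvable member are skipped.
    """
    if not metagenes.groups:
        raise ValueError("empty metagene set")
    member = modules.membership_keys() if isinstance(modules, ModuleSet) else dict(modules)
    total = 0
    recovered = 0
    for name, genes in metagenes.groups.items():
        resolvable = [g for g in genes if universe is None or g in universe]
        if not resolvable:
            logger.debug("metagene %s has no resolvable members; skipped", name)
            continue
        total += 1
        mids = {member.get(g) for g in resolvable}
        if None not in mids and len(mids) == 1:
            recovered += 1
    if total == 0:
        raise ValueError("no metagene has resolvable members")
    return recovered / total


# ---------------------------------------------------------------------------
# ortholog enrichment between a module pair
# ---------------------------------------------------------------------------

def ortholog_enrichment(
    module_a: Iterable[str],
    module_b: Iterable[str],
    orthology: OrthologyMap,
    totals: tuple[int, int, int],
) -> tuple[float | None, float]:
    """Fold enrichment and hypergeometric p for ortholog pairs across modules.

    ``totals`` = (N_a, N_b, O): genome sizes of the two species and the
    total number of ortholog pairs between them.  Expected count is
    O * (n_a/N_a) * (n_b/N_b).  The null draws the observed pairs as
    successes among the n_a*n_b candidate cross pairs out of the N_a*N_b
    total pairs containing O successes.
    """
    set_a, set_b = set(module_a), set(module_b)
    N_a, N_b, O = totals
    n_a, n_b = len(set_a), len(set_b)
    observed = sum(1 for a, b in orthology.pairs if a in set_a and b in set_b)
    expected = O * (n_a / N_a) * (n_b / N_b)
    fold = observed / expected if expected > 0 else None
    if fold is None:
        logger.warning("expected ortholog count is 0; fold undefined (observed=%d)", observed)
    p = float(hypergeom.sf(observed - 1, N_a * N_b, O, n_a * n_b))
    return fold, p


# ---------------------------------------------------------------------------
# clustering overlap I/(I+II+III)
# ---------------------------------------------------------------------------

def _pair_counts(member_a: Mapping, member_b: Mapping) -> tuple[int, int, int]:
    """(I, II, III): pairs co-assigned by both / A only / B only."""

    def n_pairs(member: Mapping) -> int:
        from collections import Counter

        c = Counter(member.values())
        return sum(n * (n - 1) // 2 for n in c.values())

    from collections import Counter

    joint = Counter(
        (member_a[g], member_b[g]) for g in member_a.keys() & member_b.keys()
    )
    I = sum(n * (n - 1) // 2 for n in joint.values())
    return I, n_pairs(member_a) - I, n_pairs(member_b) - I


def clustering_overlap(
    a: ModuleSet | Mapping, b: ModuleSet | Mapping
) -> float:
    """Pairwise overlap I/(I+II+III) between two clusterings.

    Node pairs are classified by whether each side co-assigns them; pairs
    co-assigned by neither (the dominant, uninformative category) are
    excluded.  Identical clusterings score 1; a clustering with no shared
    pair against one with all pairs shared scores 0.  When neither side
    co-assigns any pair (both all-singletons) the overlap is defined as 1.
    """
    ma = a.membership() if isinstance(a, ModuleSet) else dict(a)
    mb = b.membership() if isinstance(b, ModuleSet) else dict(b)
    I, II, III = _pair_counts(ma, mb)
    denom = I + II + III
    if denom == 0:
        return 1.0
    return I / denom


# ---------------------------------------------------------------------------
# regulator-sharing coherence
# ---------------------------------------------------------------------------

def regulatory_coherence(
    reg_edges: Sequence[tuple[str, GeneKey]],
    modules: ModuleSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Shared-regulator enrichment of within-module vs between-module pairs.

    Statistic: mean number of common regulators over within-module gene
    pairs divided by the mean over between-module pairs.  The null shuffles
    the gene-to-module assignment preserving module sizes; p is the
    (add-one) fraction of null statistics >= the observed one.
    """
    member = modules.membership_keys()
    genes = sorted(member)
    if len({member[g] for g in genes}) < 2:
        raise ValueError("need >=2 modules for a within/between comparison")
    gindex = {g: i for i, g in enumerate(genes)}
    regs = sorted({r for r, _ in reg_edges})
    rindex = {r: j for j, r in enumerate(regs)}
    B = np.zeros((len(genes), len(regs)))
    for r, g in reg_edges:
        if g in gindex:
            B[gindex[g], rindex[r]] = 1.0
    S = B @ B.T  # shared-regulator counts per gene pair
    labels = np.array([member[g] for g in genes])
    total_sum = float(S.sum() - np.trace(S))
    n = len(genes)
    total_pairs = n * (n - 1)

    def stat(lab: np.ndarray) -> float:
        sw = 0.0
        cw = 0
        for mid in np.unique(lab):
            ix = np.where(lab == mid)[0]
            sw += float(S[np.ix_(ix, ix)].sum()) - float(np.trace(S[np.ix_(ix, ix)]))
            cw += ix.size * (ix.size - 1)
        sb = total_sum - sw
        cb = total_pairs - cw
        if cw == 0:
            raise ValueError("no within-module pairs")
        mw = sw / cw
        mb = sb / cb if cb > 0 else np.nan
        if mb == 0:
            return np.inf if mw > 0 else 1.0
        return mw / mb

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return float(observed), float(p)


# ---------------------------------------------------------------------------
# ncRNA mapping
# ---------------------------------------------------------------------------

def _row_standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (x - mu) / sd


def map_ncrna(
    ncrna_expr: pd.DataFrame,
    coding_expr: pd.DataFrame,
    modules: ModuleSet,
    species: str,
    n_shuffles: int = 10,
    fdr: float = 0.05,
    p_map: float = 0.01,
    seed: int = 0,
) -> dict[str, list[tuple[int, float]]]:
    """Map ncRNAs onto modules by guilt-by-association co-expression.

    Each ncRNA is correlated with every protein-coding gene over the shared
    conditions.  A pooled null is built by shuffling every ncRNA profile
    across conditions ``n_shuffles`` times and correlating the shuffles with
    all coding genes.  The neighbor threshold c is the smallest correlation
    at which the empirical FDR (null tail fraction over observed tail
    fraction) drops below ``fdr``.  Each ncRNA's neighbors are then tested
    per module with an upper-tail hypergeometric test; the ncRNA maps to
    every module with p < ``p_map`` (possibly several, possibly none).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    shared = [c for c in coding_expr.columns if c in set(ncrna_expr.columns)]
    if len(shared) < 3:
        raise ValueError("need >=3 shared conditions between ncRNA and coding matrices")
    rng = np.random.default_rng(seed)
    Xn = _row_standardize(ncrna_expr[shared].to_numpy(dtype=float))
    Xc = _row_standardize(coding_expr[shared].to_numpy(dtype=float))
    T = len(shared)
    r_obs = np.nan_to_num(Xn @ Xc.T / T)
    null_parts = []
    for _ in range(n_shuffles):
        perm = np.argsort(rng.random(Xn.shape), axis=1)
        Xs = np.take_along_axis(Xn, perm, axis=1)
        null_parts.append(np.nan_to_num(Xs @ Xc.T / T).ravel())
    null_all = np.sort(np.concatenate(null_parts))
    obs_all = np.sort(r_obs.ravel())

    # smallest threshold with empirical FDR below the target
    cand = np.unique(obs_all)
    n_obs, n_null = obs_all.size, null_all.size
    frac_obs = (n_obs - np.searchsorted(obs_all, cand, side="left")) / n_obs
    frac_null = (n_null - np.searchsorted(null_all, cand, side="left")) / n_null
    ok = np.flatnonzero((frac_obs > 0) & (frac_null / np.maximum(frac_obs, 1e-300) < fdr))
    if ok.size == 0:
        logger.warning("no correlation threshold achieves FDR < %g; nothing mapped", fdr)
        return {name: [] for name in ncrna_expr.index}
    c = float(cand[ok[0]])

    member = modules.membership_keys()
    coding_genes = list(coding_expr.index)
    in_module = np.array([member.get((species, g)) is not None for g in coding_genes])
    module_ids = sorted({mid for (sp, _), mid in member.items() if sp == species})
    module_mask = {
        mid: np.array([member.get((species, g)) == mid for g in coding_genes])
        for mid in module_ids
    }
    N = int(in_module.sum())
    out: dict[str, list[tuple[int, float]]] = {}
    for row, name in enumerate(ncrna_expr.index):
        nbr = r_obs[row] >= c
        draws = int((nbr & in_module).sum())
        hits: list[tuple[int, float]] = []
        if draws > 0:
            for mid in module_ids:
                K = int(module_mask[mid].sum())
                x = int((nbr & module_mask[mid]).sum())
                p = float(hypergeom.sf(x - 1, N, K, draws))
                if p < p_map:
                    hits.append((mid, p))
        out[name] = hits
    return out


def ncrna_class_enrichment(
    assignments: Mapping[str, Sequence[tuple[int, float]] | Sequence[int]],
    classes: Mapping[str, str],
) -> list[dict]:
    """Per-(module, class) hypergeometric enrichment of mapped ncRNAs.

    The pool is the set of ncRNAs mapped to at least one module; for each
    module, drawing its mapped ncRNAs from the pool, the upper-tail
    probability of its count of each class is reported.
    """
    mapped: dict[str, set[int]] = {}
    for name, hits in assignments.items():
        mids = {h[0] if isinstance(h, (tuple, list)) else h for h in hits}
        if mids:
            mapped[name] = mids
    pool = sorted(mapped)
    if not pool:
        return []
    pool_class = {}
    for name in pool:
        if name not in classes:
            logger.warning("ncRNA %s has no class annotation; skipped", name)
            continue
        pool_class[name] = classes[name]
    N = len(pool_class)
    class_totals: dict[str, int] = {}
    for cl in pool_class.values():
        class_totals[cl] = class_totals.get(cl, 0) + 1
    all_mids = sorted({m for mids in mapped.values() for m in mids})
    rows = []
    for mid in all_mids:
        members = [n for n in pool_class if mid in mapped[n]]
        draws = len(members)
        if draws == 0:
            continue
        for cl, K in sorted(class_totals.items()):
            x = sum(1 for n in members if pool_class[n] == cl)
            p = float(hypergeom.sf(x - 1, N, K, draws))
            rows.append({"module": mid, "class": cl, "count": x, "mapped": draws, "p": p})
    return rows


# ---------------------------------------------------------------------------
# kappa scan
# ---------------------------------------------------------------------------

def consensus_partition_labels(modules: ModuleSet, M: int) -> np.ndarray:
    """Module labels per node with unassigned nodes as singleton modules."""
    lab = modules.labels_array(M)
    next_id = (lab.max() + 1) if lab.size else 0
    for i in np.where(lab < 0)[0]:
        lab[i] = next_id
        next_id += 1
    return lab


def kappa_scan(
    mln: MultiLayerNetwork,
    q: int,
    schedule: AnnealSchedule,
    R: int,
    kappa_grid: Sequence[float],
    benchmarks: Mapping[str, object] | None = None,
    base_params: CostParams | None = None,
    threshold: float = 0.95,
    min_size: int = 5,
) -> dict:
    """Run the full pipeline at each kappa and report the tradeoff.

    For every kappa: anneal R times, build the consensus partition, and
    report each layer's modularity at that partition, the metagene recovery
    fraction (if ``benchmarks['metagenes']`` given) and the GO-network
    weighted modularity (if ``benchmarks['go_network']`` given).  The
    recommended kappa maximizes GO-network modularity when available;
    otherwise it maximizes the sum of min-max-scaled recovery and mean layer
    modularity (the knee of the tradeoff between the two).
    """
    if not len(kappa_grid):
        raise ValueError("kappa_grid must be non-empty")
    benchmarks = benchmarks or {}
    base = base_params or CostParams()
    report: dict = {
        "kappas": list(map(float, kappa_grid)),
        "layer_modularity": {l.species_id: [] for l in mln.layers},
        "n_modules": [],
        "metagene_recovery": [],
        "go_modularity": [],
    }
    node_table = mln.node_table()
    for kappa in kappa_grid:
        params = replace(base, kappa=float(kappa), kappa_triplet=None)
        results = run_ensemble(mln, params, q, schedule, R)
        coap = coappearance(results, node_table=node_table)
        modules = extract_modules(coap, threshold=threshold, min_size=min_size)
        labels = consensus_partition_labels(modules, mln.M)
        for layer in mln.layers:
            ql = modularity_term(layer, labels[mln.layer_slice(layer.species_id)])
            report["layer_modularity"][layer.species_id].append(float(ql))
        report["n_modules"].append(len(modules.modules))
        if "metagenes" in benchmarks:
            rec = metagene_recovery(
                modules, benchmarks["metagenes"], universe=set(node_table)
            )
            report["metagene_recovery"].append(float(rec))
        if "go_network" in benchmarks:
            report["go_modularity"].append(
                float(weighted_modularity(benchmarks["go_network"], modules))
            )
    if report["go_modularity"]:
        best = int(np.argmax(report["go_modularity"]))
    elif report["metagene_recovery"]:
        mod_mean = np.mean(
            [report["layer_modularity"][l.species_id] for l in mln.layers], axis=0
        )
        rec = np.asarray(report["metagene_recovery"])

        def scaled(x):
            x = np.asarray(x, dtype=float)
            rng_ = x.max() - x.min()
            return np.zeros_like(x) if rng_ == 0 else (x - x.min()) / rng_

        best = int(np.argmax(scaled(rec) + scaled(mod_mean)))
    else:
        best = 0
    report["recommended_kappa"] = report["kappas"][best]
    return report


# ---------------------------------------------------------------------------
# cross-layer co-appearance enrichment (null control for kappa = 0)
# ---------------------------------------------------------------------------

def cross_layer_enrichment(
    coap_values: np.ndarray,
    matched_groups: Sequence[tuple[np.ndarray, np.ndarray]],
    pool_b: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for cross-layer co-appearance of matched module pairs.

    Statistic: mean co-appearance over all (a, b) node pairs of the matched
    groups.  The null redraws each group's layer-B members uniformly from
    ``pool_b`` (sizes preserved).  Returns (observed statistic, p-value).
    """
    rng = np.random.default_rng(seed)

    def stat(groups_b: Sequence[np.ndarray]) -> float:
        vals = [
            coap_values[np.ix_(np.asarray(a), np.asarray(b))].mean()
            for (a, _), b in zip(matched_groups, groups_b)
        ]
        return float(np.mean(vals))

    observed = stat([b for _, b in matched_groups])
    pool_b = np.asarray(pool_b)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool_b)
        offset = 0
        fake = []
        for _, b in matched_groups:
            fake.append(perm[offset : offset + len(b)])
            offset += len(b)
        if stat(fake) >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return observed, float(p)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_gaf(path, species: str, use_symbol: bool = False) -> GOAnnotationMatrix:
    """Read GO annotations from a GAF 2.x file for one species.

    Gene id comes from column 2 (DB Object ID) or column 3 (symbol) when
    ``use_symbol``; the term from column 5.  NOT-qualified rows and ``!``
    comment lines are skipped.
    """
    gene_col = 2 if use_symbol else 1
    ann: dict[GeneKey, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            if "NOT" in parts[3]:
                continue
            ann.setdefault((species, parts[gene_col]), set()).add(parts[4])
    return GOAnnotationMatrix.from_annotations({g: sorted(t) for g, t in ann.items()})


def read_gmt(path) -> dict[str, list[GeneKey]]:
    """Read a GMT gene-set file; members ``species|gene`` become key tuples."""
    groups: dict[str, list[GeneKey]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            members = []
            for m in parts[2:]:
                if "|" in m:
                    sp, g = m.split("|", 1)
                    members.append((sp, g))
                else:
                    members.append(("", m))
            groups[parts[0]] = members
    return groups


def write_gmt(groups: Mapping[str, Sequence[GeneKey]], path) -> None:
    with open(path, "w") as fh:
        for name, members in groups.items():
            body = "\t".join(f"{sp}|{g}" for sp, g in members)
            fh.write(f"{name}\tna\t{body}\n")


def read_regulator_tsv(path, species: str) -> list[tuple[str, GeneKey]]:
    """Read ``regulator\ttarget`` rows for one species."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            reg, target = line.rstrip("\n").split("\t")[:2]
            rows.append((reg, (species, target)))
    return rows
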