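"""Consensus modules from repeated annealing runs.

Single annealing runs are stochastic, so modules are read off a
co-appearance matrix: entry (i, j) is the fraction of the R runs in which
nodes i and j shared a label.  Nodes joined at co-appearance >= 0.95 (by
connected components of the thresholded graph) form a module; components
smaller than ``min_size`` are left unassigned.  Module sizes typically
follow a power law, whose exponent is estimated by discrete maximum
likelihood.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import zeta

from .annealing import AnnealResult
from .graph_core import MultiLayerNetwork

logger = logging.getLogger(__name__)


@dataclass
class CoappearanceMatrix:
    """Symmetric M x M matrix of co-labeling fractions over R runs."""

    values: np.ndarray
    R: int
    node_table: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("co-appearance matrix must be square")
        self.values = v

    @property
    def M(self) -> int:
        return self.values.shape[0]


@dataclass
class ModuleSet:
    """Disjoint node modules (global indices) plus the unassigned remainder."""

    modules: dict[int, list[int]]
    unassigned: list[int] = field(default_factory=list)
    node_table: list[tuple[str, str]] | None = None

    def sizes(self) -> list[int]:
        return [len(v) for v in self.modules.values()]

    def labels_array(self, M: int) -> np.ndarray:
        """Module id per node; -1 for unassigned."""
        lab = np.full(M, -1, dtype=np.int64)
        for mid, nodes in self.modules.items():
            lab[np.asarray(nodes, dtype=np.int64)] = mid
        return lab

    def membership(self) -> dict[int, int]:
        return {n: mid for mid, nodes in self.modules.items() for n in nodes}

    def membership_keys(self) -> dict[tuple[str, str], int]:
        """(species, gene) -> module id; requires a node table."""
        if self.node_table is None:
            raise ValueError("module set has no node table")
        return {
            self.node_table[n]: mid
            for mid, nodes in self.modules.items()
            for n in nodes
        }

    def species_composition(self, mid: int) -> Counter:
        if self.node_table is None:
            raise ValueError("module set has no node table")
        return Counter(self.node_table[n][0] for n in self.modules[mid])


def coappearance(results: list[AnnealResult], node_table=None) -> CoappearanceMatrix:
    """Fraction-of-runs-co-labeled matrix from an annealing ensemble."""
    if not results:
        raise ValueError("need at least one annealing result")
    M = len(results[0].labeling)
    acc = np.zeros((M, M))
    for res in results:
        s = res.labeling.sigma
        if s.shape[0] != M:
            raise ValueError("annealing results cover different node sets")
        acc += s[:, None] == s[None, :]
    return CoappearanceMatrix(acc / len(results), R=len(results), node_table=node_table)


def extract_modules(
    coap: CoappearanceMatrix, threshold: float = 0.95, min_size: int = 5
) -> ModuleSet:
    """Connected components of the graph {(i,j): coap >= threshold}.

    Components of size >= ``min_size`` become modules (ids in order of each
    component's smallest node index); smaller components are unassigned.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    M = coap.M
    iu, ju = np.where(np.triu(coap.values, k=1) >= threshold)
    g = coo_matrix((np.ones(iu.size), (iu, ju)), shape=(M, M))
    _, comp = connected_components(g, directed=False)
    modules: dict[int, list[int]] = {}
    unassigned: list[int] = []
    next_id = 0
    for c in sorted(set(comp), key=lambda c: int(np.argmax(comp == c))):
        nodes = np.where(comp == c)[0].tolist()
        if len(nodes) >= min_size:
            modules[next_id] = nodes
            next_id += 1
        else:
            unassigned.extend(nodes)
    return ModuleSet(modules, sorted(unassigned), node_table=coap.node_table)


def classify_modules(
    modules: ModuleSet, mln: MultiLayerNetwork, min_cross: int = 3
) -> dict[int, str]:
    """Tag each module ``conserved`` or ``specific:<species>``.

    Conserved requires at least ``min_cross`` genes from each of two or more
    species and at least one ortholog pair internal to the module.
    """
    node_species = np.empty(mln.M, dtype=object)
    for layer in mln.layers:
        node_species[mln.layer_slice(layer.species_id)] = layer.species_id
    ii, jj, _ = mln.ortholog_edges_global()
    tags: dict[int, str] = {}
    for mid, nodes in modules.modules.items():
        nodeset = set(nodes)
        counts = Counter(node_species[n] for n in nodes)
        multi = sum(1 for c in counts.values() if c >= min_cross) >= 2
        internal = any(i in nodeset and j in nodeset for i, j in zip(ii, jj))
        if multi and internal:
            tags[mid] = "conserved"
        else:
            tags[mid] = f"specific:{counts.most_common(1)[0][0]}"
    return tags


def fit_size_distribution(modules: ModuleSet | list[int]) -> tuple[float, int]:
    """Discrete power-law ML fit of module sizes; returns (exponent, xmin).

    The exponent is reported negative (a distribution p(s) ~ s^exponent)
    with xmin fixed at the smallest module size; the likelihood uses the
    Hurwitz zeta normalization of the discrete power law.
    """
    sizes = np.asarray(modules if isinstance(modules, (list, np.ndarray)) else modules.sizes())
    if sizes.size < 10:
        raise ValueError(f"need >=10 modules to fit a size distribution, got {sizes.size}")
    if np.unique(sizes).size == 1:
        raise ValueError("no spread: all module sizes are equal")
    if np.unique(sizes).size == 2:
        logger.warning("only two distinct module sizes; power-law fit is low-confidence")
    xmin = int(sizes.min())
    slog = float(np.log(sizes).sum())
    n = sizes.size

    def nll(alpha: float) -> float:
        return n * np.log(zeta(alpha, xmin)) + alpha * slog

    res = minimize_scalar(nll, bounds=(1.0 + 1e-6, 10.0), method="bounded")
    return -float(res.x), xmin


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------

def write_coappearance_mtx(coap: CoappearanceMatrix, path, index_path=None) -> None:
    """Sparse upper triangle in Matrix Market format plus a node-index TSV."""
    from scipy.io import mmwrite

    upper = np.triu(coap.values)
    mmwrite(str(path), coo_matrix(upper))
    if index_path is not None and coap.node_table is not None:
        with open(index_path, "w") as fh:
            fh.write("index\tspecies\tgene\n")
            for i, (sp, g) in enumerate(coap.node_table):
                fh.write(f"{i}\t{sp}\t{g}\n")


def write_modules_tsv(modules: ModuleSet, tags: dict[int, str] | None, path) -> None:
    if modules.node_table is None:
        raise ValueError("module set has no node table")
    with open(path, "w") as fh:
        fh.write("gene\tspecies\tmodule_id\ttag\n")
        for mid, nodes in modules.modules.items():
            tag = (tags or {}).get(mid, "")
            for n in nodes:
                sp, g = modules.node_table[n]
                fh.write(f"{g}\t{sp}\t{mid}\t{tag}\n")


def write_modules_gmt(modules: ModuleSet, path: str | Path, prefix: str = "module") -> None:
    if modules.node_table is None:
        raise ValueError("module set has no node table")
    with open(path, "w") as fh:
        for mid, nodes in modules.modules.items():
            genes = "\t".join(modules.node_table[n][1] for n in nodes)
            fh.write(f"{prefix}_{mid}\tna\t{genes}\n")
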