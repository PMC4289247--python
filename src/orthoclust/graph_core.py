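"""Data model for species layers, orthology maps and the multi-layer network.

A multi-layer network stacks one undirected co-association graph per species
(edges carry a sign, +1 for positive association, -1 for negative) and joins
the layers with weighted orthology links.  Because eukaryotic orthology is
frequently many-to-many, each cross-species pair (i, j) is down-weighted by
the number of orthologs of its endpoints:

    w_ij = (1/a + 1/b) / 2

where ``a`` is the number of orthologs of *i* in *j*'s species and ``b`` the
number of orthologs of *j* in *i*'s species.  One-to-one pairs keep weight 1;
large bipartite ortholog cliques are damped so they cannot dominate the
clustering cost.  Alternative normalizations (``product`` = 1/(a*b),
``geometric`` = 1/sqrt(a*b), ``uniform`` = 1) are available for sensitivity
analysis.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

WEIGHT_SCHEMES = ("reciprocal_mean", "product", "geometric", "uniform")


@dataclass
class SpeciesNetwork:
    """One species' undirected co-association graph with signed edges.

    Edges are stored canonically as ``(min_idx, max_idx)`` local-index pairs
    with a sign in {+1, -1}.  Self-loops are rejected; duplicate edges keep
    the first sign seen.
    """

    species_id: str
    nodes: list[str]
    _index: dict[str, int] = field(init=False, repr=False)
    _edges: dict[tuple[int, int], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"duplicate gene ids in layer {self.species_id!r}")
        self._index = {g: i for i, g in enumerate(self.nodes)}

    # -- construction -----------------------------------------------------
    def add_edge(self, a: str, b: str, sign: int = 1) -> None:
        if sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {sign}")
        ia, ib = self._index[a], self._index[b]
        if ia == ib:
            raise ValueError(f"self-loop on {a!r} in layer {self.species_id!r}")
        key = (ia, ib) if ia < ib else (ib, ia)
        self._edges.setdefault(key, sign)

    @classmethod
    def from_edges(
        cls,
        species_id: str,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str] | tuple[str, str, int]],
    ) -> "SpeciesNetwork":
        net = cls(species_id, list(nodes))
        for e in edges:
            if len(e) == 2:
                net.add_edge(e[0], e[1])
            else:
                net.add_edge(e[0], e[1], int(e[2]))
        return net

    # -- views ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def edges(self, sign: int | None = None) -> list[tuple[str, str, int]]:
        return [
            (self.nodes[i], self.nodes[j], s)
            for (i, j), s in sorted(self._edges.items())
            if sign is None or s == sign
        ]

    def edge_arrays(self, sign: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Local-index endpoint arrays ``(u, v)`` for edges of the given sign."""
        pairs = [k for k, s in self._edges.items() if sign is None or s == sign]
        if not pairs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        arr = np.array(sorted(pairs), dtype=np.int64)
        return arr[:, 0], arr[:, 1]

    def degrees(self, sign: int | None = None) -> np.ndarray:
        k = np.zeros(self.n_nodes, dtype=np.int64)
        u, v = self.edge_arrays(sign)
        np.add.at(k, u, 1)
        np.add.at(k, v, 1)
        return k

    def edge_count(self, sign: int | None = None) -> int:
        """m: number of edges (of the given sign class); equals sum(k)/2."""
        return sum(1 for s in self._edges.values() if sign is None or s == sign)


@dataclass
class OrthologyMap:
    """Weighted orthologous gene pairs between one species pair."""

    species_pair: tuple[str, str]
    pairs: list[tuple[str, str]]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.pairs) != len(self.weights):
            raise ValueError("pairs/weights length mismatch")
        if np.any(self.weights <= 0):
            raise ValueError("orthology weights must be positive")

    def __len__(self) -> int:
        return len(self.pairs)

    def partner_counts(self) -> tuple[dict[str, int], dict[str, int]]:
        """Number of orthologs of each gene (first-species dict, second-species dict)."""
        ca: dict[str, int] = {}
        cb: dict[str, int] = {}
        for a, b in self.pairs:
            ca[a] = ca.get(a, 0) + 1
            cb[b] = cb.get(b, 0) + 1
        return ca, cb


@dataclass(frozen=True)
class OrthologTriplet:
    """One gene per species for three species, mutually one-to-one orthologous."""

    species: tuple[str, str, str]
    genes: tuple[str, str, str]


def compute_ortholog_weights(
    species_pair: tuple[str, str],
    pairs: Iterable[tuple[str, str]],
    scheme: str = "reciprocal_mean",
) -> OrthologyMap:
    """Build an :class:`OrthologyMap` with weights normalized per endpoint.

    For pair (i, j) let ``a`` = number of orthologs of i and ``b`` = number of
    orthologs of j (within this species pair).  Weights:

    ========== =====================
    scheme     w_ij
    ========== =====================
    reciprocal_mean  (1/a + 1/b)/2   (default)
    product          1/(a*b)
    geometric        1/sqrt(a*b)
    uniform          1
    ========== =====================

    Duplicate pairs are deduplicated with a warning.  One-to-one pairs have
    weight exactly 1 under every non-uniform scheme.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}; choose from {WEIGHT_SCHEMES}")
    seen: dict[tuple[str, str], None] = {}
    n_dup = 0
    for p in pairs:
        p = (p[0], p[1])
        if p in seen:
            n_dup += 1
        else:
            seen[p] = None
    if n_dup:
        logger.warning(
            "%d duplicate ortholog pair(s) for %s dropped", n_dup, species_pair
        )
    uniq = list(seen)
    if not uniq:
        raise ValueError(f"empty ortholog pair set for {species_pair}")
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for a, b in uniq:
        count_a[a] = count_a.get(a, 0) + 1
        count_b[b] = count_b.get(b, 0) + 1
    w = np.empty(len(uniq))
    for idx, (a, b) in enumerate(uniq):
        na, nb = count_a[a], count_b[b]
        if scheme == "reciprocal_mean":
            w[idx] = 0.5 * (1.0 / na + 1.0 / nb)
        elif scheme == "product":
            w[idx] = 1.0 / (na * nb)
        elif scheme == "geometric":
            w[idx] = 1.0 / np.sqrt(na * nb)
        else:
            w[idx] = 1.0
    return OrthologyMap(species_pair, uniq, w)


@dataclass
class Labeling:
    """Assignment of every global node to a label in {1..q}."""

    sigma: np.ndarray
    q: int

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.int64)
        if self.sigma.ndim != 1:
            raise ValueError("sigma must be one-dimensional")
        if self.q < 1:
            raise ValueError("q must be positive")
        if self.sigma.size and (self.sigma.min() < 1 or self.sigma.max() > self.q):
            raise ValueError("labels must lie in {1..q}")

    def __len__(self) -> int:
        return self.sigma.size


@dataclass
class MultiLayerNetwork:
    """Ordered species layers joined by per-pair orthology maps.

    The global node index concatenates layers in declared order, nodes in
    input order; it is recorded so independent runs are comparable.
    """

    layers: list[SpeciesNetwork]
    orthologies: dict[tuple[str, str], OrthologyMap] = field(default_factory=dict)
    triplets: list[OrthologTriplet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [l.species_id for l in self.layers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species_id among layers")
        for l in self.layers:
            if l.n_nodes == 0:
                raise ValueError(f"layer {l.species_id!r} is empty")
        self._layer_by_id = {l.species_id: l for l in self.layers}
        offsets = np.cumsum([0] + [l.n_nodes for l in self.layers])
        self._offsets = {l.species_id: int(o) for l, o in zip(self.layers, offsets)}
        self.M = int(offsets[-1])
        for (sa, sb), om in self.orthologies.items():
            if sa not in self._layer_by_id or sb not in self._layer_by_id:
                raise ValueError(f"orthology references unknown species ({sa}, {sb})")
            la, lb = self._layer_by_id[sa], self._layer_by_id[sb]
            for a, b in om.pairs:
                if a not in la or b not in lb:
                    raise ValueError(f"orthology pair ({a!r}, {b!r}) not in layers")

    # -- node index -------------------------------------------------------
    def layer(self, species_id: str) -> SpeciesNetwork:
        return self._layer_by_id[species_id]

    def layer_offset(self, species_id: str) -> int:
        return self._offsets[species_id]

    def global_index(self, species_id: str, gene: str) -> int:
        return self._offsets[species_id] + self._layer_by_id[species_id].index_of(gene)

    def layer_slice(self, species_id: str) -> slice:
        off = self._offsets[species_id]
        return slice(off, off + self._layer_by_id[species_id].n_nodes)

    def node_table(self) -> list[tuple[str, str]]:
        """Global-index-ordered list of (species_id, gene)."""
        out = []
        for l in self.layers:
            out.extend((l.species_id, g) for g in l.nodes)
        return out

    def ortholog_edges_global(
        self, species_pair: tuple[str, str] | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All ortholog links as global-index arrays ``(i, j, w)``."""
        ii, jj, ww = [], [], []
        for (sa, sb), om in self.orthologies.items():
            if species_pair is not None and (sa, sb) != tuple(species_pair):
                continue
            offa, offb = self._offsets[sa], self._offsets[sb]
            la, lb = self._layer_by_id[sa], self._layer_by_id[sb]
            for (a, b), w in zip(om.pairs, om.weights):
                ii.append(offa + la.index_of(a))
                jj.append(offb + lb.index_of(b))
                ww.append(w)
        return (
            np.array(ii, dtype=np.int64),
            np.array(jj, dtype=np.int64),
            np.array(ww, dtype=float),
        )

    def triplet_indices(self) -> np.ndarray:
        """Global-index array of shape (n_triplets, 3)."""
        if not self.triplets:
            return np.empty((0, 3), dtype=np.int64)
        rows = [
            [self.global_index(s, g) for s, g in zip(t.species, t.genes)]
            for t in self.triplets
        ]
        return np.array(rows, dtype=np.int64)


def find_triplets(
    layers: Sequence[SpeciesNetwork],
    orthologies: Mapping[tuple[str, str], OrthologyMap],
) -> list[OrthologTriplet]:
    """Enumerate 1-1-1 ortholog triplets across every triple of species.

    A triplet (g1, g2, g3) qualifies when each of its three pairwise relations
    exists and each member has exactly one ortholog in each of the other two
    species (no competing partner anywhere in the triple).
    """
    ids = [l.species_id for l in layers]
    out: list[OrthologTriplet] = []

    def pair_map(sa: str, sb: str):
        """(pairs oriented sa->sb, partner counts keyed by gene)."""
        if (sa, sb) in orthologies:
            om = orthologies[(sa, sb)]
            pairs = set(om.pairs)
        elif (sb, sa) in orthologies:
            om = orthologies[(sb, sa)]
            pairs = {(b, a) for a, b in om.pairs}
        else:
            return set(), {}, {}
        ca: dict[str, int] = {}
        cb: dict[str, int] = {}
        for a, b in pairs:
            ca[a] = ca.get(a, 0) + 1
            cb[b] = cb.get(b, 0) + 1
        return pairs, ca, cb

    for s1, s2, s3 in itertools.combinations(ids, 3):
        p12, c12a, c12b = pair_map(s1, s2)
        p13, c13a, c13b = pair_map(s1, s3)
        p23, c23a, c23b = pair_map(s2, s3)
        for g1, g2 in p12:
            if c12a.get(g1, 0) != 1 or c12b.get(g2, 0) != 1:
                continue
            if c13a.get(g1, 0) != 1:
                continue
            g3 = next(b for a, b in p13 if a == g1)
            if c13b.get(g3, 0) != 1:
                continue
            if (g2, g3) in p23 and c23a.get(g2, 0) == 1 and c23b.get(g3, 0) == 1:
                out.append(OrthologTriplet((s1, s2, s3), (g1, g2, g3)))
    return out


def build_multilayer(
    layers: Sequence[SpeciesNetwork],
    ortholog_tables: Iterable[tuple[str, str, str, str]] = (),
    triplet_detection: bool = False,
    weight_scheme: str = "reciprocal_mean",
) -> MultiLayerNetwork:
    """Assemble a :class:`MultiLayerNetwork` from layers and raw ortholog rows.

    ``ortholog_tables`` rows are ``(species_a, gene_a, species_b, gene_b)``.
    Pairs referencing genes absent from their declared layer are dropped with
    a logged count.  Weights are computed per species pair with
    :func:`compute_ortholog_weights`.
    """
    by_id = {l.species_id: l for l in layers}
    if len(by_id) != len(list(layers)):
        raise ValueError("duplicate species_id among layers")
    raw: dict[tuple[str, str], list[tuple[str, str]]] = {}
    n_dropped = 0
    for sa, ga, sb, gb in ortholog_tables:
        if sa not in by_id or sb not in by_id:
            raise ValueError(f"ortholog row references unknown species ({sa}, {sb})")
        if sa == sb:
            raise ValueError(f"ortholog row within a single species {sa!r}")
        # canonical orientation: declared layer order
        order = {l.species_id: i for i, l in enumerate(layers)}
        if order[sa] > order[sb]:
            sa, ga, sb, gb = sb, gb, sa, ga
        if ga not in by_id[sa] or gb not in by_id[sb]:
            n_dropped += 1
            continue
        raw.setdefault((sa, sb), []).append((ga, gb))
    if n_dropped:
        logger.warning("dropped %d ortholog pair(s) referencing unknown genes", n_dropped)
    orthologies = {
        pair: compute_ortholog_weights(pair, rows, scheme=weight_scheme)
        for pair, rows in raw.items()
    }
    triplets: list[OrthologTriplet] = []
    if triplet_detection and len(list(layers)) >= 3:
        triplets = find_triplets(layers, orthologies)
    return MultiLayerNetwork(list(layers), orthologies, triplets)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_edge_tsv(path: str | Path, species_id: str, nodes: Sequence[str] | None = None) -> SpeciesNetwork:
    """Read a ``gene_a\tgene_b\tsign`` edge list (sign optional, default +1).

    Comment lines start with ``#``.  When ``nodes`` is None the node list is
    the genes seen in edge order.
    """
    edges: list[tuple[str, str, int]] = []
    seen: list[str] = []
    seen_set: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            a, b = parts[0], parts[1]
            sign = int(parts[2]) if len(parts) > 2 and parts[2] else 1
            edges.append((a, b, sign))
            for g in (a, b):
                if g not in seen_set:
                    seen_set.add(g)
                    seen.append(g)
    return SpeciesNetwork.from_edges(species_id, list(nodes) if nodes is not None else seen, edges)


def write_edge_tsv(net: SpeciesNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tsign\n")
        for a, b, s in net.edges():
            fh.write(f"{a}\t{b}\t{s}\n")


def read_ortholog_tsv(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Read ``species_a\tgene_a\tspecies_b\tgene_b`` rows; ``#`` comments allowed."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            rows.append((parts[0], parts[1], parts[2], parts[3]))
    return rows


def write_ortholog_tsv(mln: MultiLayerNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# species_a\tgene_a\tspecies_b\tgene_b\tweight\n")
        for (sa, sb), om in sorted(mln.orthologies.items()):
            for (a, b), w in zip(om.pairs, om.weights):
                fh.write(f"{sa}\t{a}\t{sb}\t{b}\t{w:.10g}\n")


def dump_network(mln: MultiLayerNetwork, outdir: str | Path, weight_scheme: str = "reciprocal_mean") -> None:
    """Write a JSON manifest plus per-layer edge TSVs and the ortholog table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "weight_scheme": weight_scheme,
        "M": mln.M,
        "layers": [
            {
                "species_id": l.species_id,
                "n_nodes": l.n_nodes,
                "n_edges": l.edge_count(),
                "edge_file": f"edges_{l.species_id}.tsv",
                "node_file": f"nodes_{l.species_id}.txt",
            }
            for l in mln.layers
        ],
        "orthology_pairs": {f"{sa}|{sb}": len(om) for (sa, sb), om in mln.orthologies.items()},
        "n_triplets": len(mln.triplets),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for l in mln.layers:
        write_edge_tsv(l, outdir / f"edges_{l.species_id}.tsv")
        (outdir / f"nodes_{l.species_id}.txt").write_text("\n".join(l.nodes) + "\n")
    if mln.orthologies:
        write_ortholog_tsv(mln, outdir / "orthologs.tsv")


def load_network(outdir: str | Path) -> MultiLayerNetwork:
    """Round-trip counterpart of :func:`dump_network`."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    layers = []
    for entry in manifest["layers"]:
        nodes = (outdir / entry["node_file"]).read_text().splitlines()
        layers.append(read_edge_tsv(outdir / entry["edge_file"], entry["species_id"], nodes))
    rows: list[tuple[str, str, str, str]] = []
    ortho_path = outdir / "orthologs.tsv"
    if ortho_path.exists():
        with open(ortho_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                sa, a, sb, b, _w = line.rstrip("\n").split("\t")
                rows.append((sa, a, sb, b))
    return build_multilayer(
        layers,
        rows,
        triplet_detection=manifest.get("n_triplets", 0) > 0,
        weight_scheme=manifest.get("weight_scheme", "reciprocal_mean"),
    )
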