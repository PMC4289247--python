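"""Synthetic multi-species data with planted ground truth.

Everything the pipeline consumes can be generated here with known structure:
planted multi-layer networks (stochastic block layers joined by orthologs
that follow the planted conserved-module correspondence), expression
matrices whose within-module correlation is controlled, and benchmark
annotations (GO terms, metagenes, regulator tables, ncRNA profiles) wired to
the same truth.  The default scenario -- two species of 200 genes, four
modules each, two of them conserved, within-module correlation 0.7 over 30
conditions, ortholog fidelity 0.9 -- is the package's desk-scale stand-in
for a two-transcriptome study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import build_coexpression_layer
from .evaluation import GeneKey, GOAnnotationMatrix, MetageneSet
from .graph_core import MultiLayerNetwork, SpeciesNetwork, build_multilayer


@dataclass
class PlantedTruth:
    """Ground truth of a planted scenario.

    ``module_of[sp][i]`` is the planted module index of the i-th gene of
    species ``sp``; conserved pairs list which module of one species
    corresponds to which module of another.  ``group_of`` merges conserved
    counterparts into shared cross-species group ids.
    """

    species: list[str]
    genes: dict[str, list[str]]
    module_of: dict[str, np.ndarray]
    conserved_pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    ortholog_rows: list[tuple[str, str, str, str]]
    params: dict = field(default_factory=dict)

    @property
    def group_of(self) -> dict[tuple[str, int], int]:
        """(species, module) -> cross-species group id (conserved merged)."""
        parent: dict[tuple[str, int], tuple[str, int]] = {}

        def find(x):
            while parent.get(x, x) != x:
                x = parent[x]
            return x

        for sp in self.species:
            for m in np.unique(self.module_of[sp]):
                parent.setdefault((sp, int(m)), (sp, int(m)))
        for a, b in self.conserved_pairs:
            parent[find(a)] = find(b)
        roots = {}
        out = {}
        for key in list(parent):
            r = find(key)
            out[key] = roots.setdefault(r, len(roots))
        return out

    def truth_labels(self, sp: str) -> np.ndarray:
        return self.module_of[sp]

    def group_labels(self) -> dict[GeneKey, int]:
        g = self.group_of
        return {
            (sp, gene): g[(sp, int(m))]
            for sp in self.species
            for gene, m in zip(self.genes[sp], self.module_of[sp])
        }

    def module_genes(self, sp: str, m: int) -> list[str]:
        return [g for g, mm in zip(self.genes[sp], self.module_of[sp]) if mm == m]


def generate_truth(
    n_species: int = 2,
    genes_per_species: int = 200,
    modules_per_species: int = 4,
    n_conserved: int = 2,
    ortholog_fidelity: float = 0.9,
    many_to_many_spec: list[dict] | None = None,
    n_noise_orthologs: int = 0,
    seed: int = 0,
) -> PlantedTruth:
    """Planted module assignments plus an ortholog table following them.

    Modules 0..n_conserved-1 are conserved across every species pair:
    their genes are matched by within-module position and each matched pair
    becomes an ortholog with probability ``ortholog_fidelity``.
    ``many_to_many_spec`` adds complete bipartite ortholog cliques; each
    entry is ``{"pair": (ia, ib), "picks_a": [(module, count), ...],
    "picks_b": [...]}`` taking the first ``count`` genes of each module.
    ``n_noise_orthologs`` adds that many uniformly random cross-species
    pairs per species pair, emulating orthologs whose co-expression is not
    conserved (the bulk of a real ortholog table).
    """
    if not 0.0 <= ortholog_fidelity <= 1.0:
        raise ValueError("ortholog_fidelity must be in [0, 1]")
    if n_conserved > modules_per_species:
        raise ValueError("n_conserved cannot exceed modules_per_species")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1}" for i in range(n_species)]
    genes = {
        sp: [f"{sp}_g{i:04d}" for i in range(genes_per_species)] for sp in species
    }
    base = np.repeat(
        np.arange(modules_per_species),
        -(-genes_per_species // modules_per_species),
    )[:genes_per_species]
    module_of = {sp: base.copy() for sp in species}
    conserved = [
        ((species[a], m), (species[b], m))
        for a in range(n_species)
        for b in range(a + 1, n_species)
        for m in range(n_conserved)
    ]
    rows: list[tuple[str, str, str, str]] = []
    for a in range(n_species):
        for b in range(a + 1, n_species):
            spa, spb = species[a], species[b]
            for m in range(n_conserved):
                ga = [g for g, mm in zip(genes[spa], module_of[spa]) if mm == m]
                gb = [g for g, mm in zip(genes[spb], module_of[spb]) if mm == m]
                for x, y in zip(ga, gb):
                    if rng.random() < ortholog_fidelity:
                        rows.append((spa, x, spb, y))
    if n_noise_orthologs:
        for a in range(n_species):
            for b in range(a + 1, n_species):
                spa, spb = species[a], species[b]
                seen = set(rows)
                added = 0
                while added < n_noise_orthologs:
                    x = genes[spa][int(rng.integers(genes_per_species))]
                    y = genes[spb][int(rng.integers(genes_per_species))]
                    row = (spa, x, spb, y)
                    if row not in seen:
                        seen.add(row)
                        rows.append(row)
                        added += 1
    for entry in many_to_many_spec or []:
        ia, ib = entry["pair"]
        spa, spb = species[ia], species[ib]
        pick_a = [
            g
            for m, cnt in entry["picks_a"]
            for g in [x for x, mm in zip(genes[spa], module_of[spa]) if mm == m][:cnt]
        ]
        pick_b = [
            g
            for m, cnt in entry["picks_b"]
            for g in [x for x, mm in zip(genes[spb], module_of[spb]) if mm == m][:cnt]
        ]
        for x in pick_a:
            for y in pick_b:
                rows.append((spa, x, spb, y))
    return PlantedTruth(
        species=species,
        genes=genes,
        module_of=module_of,
        conserved_pairs=conserved,
        ortholog_rows=rows,
        params=dict(
            n_species=n_species,
            genes_per_species=genes_per_species,
            modules_per_species=modules_per_species,
            n_conserved=n_conserved,
            ortholog_fidelity=ortholog_fidelity,
            many_to_many_spec=many_to_many_spec,
            seed=seed,
        ),
    )


def generate_planted_multilayer(
    n_species: int = 2,
    genes_per_species: int = 200,
    modules_per_species: int = 4,
    n_conserved: int = 2,
    p_in: float = 0.3,
    p_out: float = 0.02,
    ortholog_fidelity: float = 0.9,
    many_to_many_spec: list[dict] | None = None,
    n_noise_orthologs: int = 0,
    weight_scheme: str = "reciprocal_mean",
    seed: int = 0,
) -> tuple[MultiLayerNetwork, PlantedTruth]:
    """Stochastic-block layers joined by truth-following orthologs.

    Intra-layer edges are Bernoulli(p_in) within planted modules and
    Bernoulli(p_out) between; all edges are positive.  Triplet detection is
    switched on automatically for three or more species.
    """
    if not p_in > p_out:
        raise ValueError("need p_in > p_out")
    truth = generate_truth(
        n_species,
        genes_per_species,
        modules_per_species,
        n_conserved,
        ortholog_fidelity,
        many_to_many_spec,
        n_noise_orthologs,
        seed=seed,
    )
    truth.params.update(p_in=p_in, p_out=p_out, weight_scheme=weight_scheme)
    rng = np.random.default_rng(seed + 1)
    size = genes_per_species / modules_per_species
    if size * p_in < 1:
        import logging

        logging.getLogger(__name__).warning(
            "expected within-module degree < 1; layers may disconnect"
        )
    layers = []
    for sp in truth.species:
        net = SpeciesNetwork(sp, truth.genes[sp])
        mod = truth.module_of[sp]
        n = len(truth.genes[sp])
        iu, ju = np.triu_indices(n, k=1)
        p = np.where(mod[iu] == mod[ju], p_in, p_out)
        draw = rng.random(iu.size) < p
        for i, j in zip(iu[draw], ju[draw]):
            net.add_edge(truth.genes[sp][i], truth.genes[sp][j], 1)
        layers.append(net)
    mln = build_multilayer(
        layers,
        truth.ortholog_rows,
        triplet_detection=n_species >= 3,
        weight_scheme=weight_scheme,
    )
    return mln, truth


def generate_expression_from_truth(
    truth: PlantedTruth,
    n_conditions: int = 30,
    within_corr: float = 0.7,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-species expression with controlled within-module correlation.

    Each cross-species module group draws one latent condition profile
    (conserved counterparts share it); a member gene's profile is
    sqrt(rho) * latent + sqrt(1 - rho) * noise.  With unit noise the
    expected within-module Pearson correlation is rho.
    """
    if not 0.0 <= within_corr < 1.0:
        raise ValueError("within_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    group = truth.group_of
    latents = {
        gid: rng.normal(size=n_conditions) for gid in sorted(set(group.values()))
    }
    conditions = [f"cond{t:02d}" for t in range(n_conditions)]
    out = {}
    for sp in truth.species:
        n = len(truth.genes[sp])
        X = np.empty((n, n_conditions))
        for i, m in enumerate(truth.module_of[sp]):
            lat = latents[group[(sp, int(m))]]
            eps = rng.normal(size=n_conditions) * noise_sd
            X[i] = np.sqrt(within_corr) * lat + np.sqrt(1.0 - within_corr) * eps
        out[sp] = pd.DataFrame(X, index=truth.genes[sp], columns=conditions)
    return out


@dataclass
class Benchmarks:
    """Benchmark inputs generated from a planted truth."""

    go: GOAnnotationMatrix
    metagenes: MetageneSet
    regulators: list[tuple[str, GeneKey]]
    ncrna_expr: dict[str, pd.DataFrame] | None = None
    ncrna_truth: dict[str, tuple[str, int]] | None = None
    ncrna_classes: dict[str, str] | None = None


def generate_benchmarks_from_truth(
    truth: PlantedTruth,
    expr: dict[str, pd.DataFrame] | None = None,
    go_terms_per_module: int = 5,
    annotation_prob: float = 0.8,
    n_background_terms: int = 2,
    n_noise_terms: int = 30,
    metagenes_per_pair: int = 15,
    regulators_per_module: int = 3,
    regulator_coverage: float = 0.8,
    ncrna_per_module: int = 2,
    ncrna_noise: float = 0.5,
    seed: int = 0,
) -> Benchmarks:
    """GO annotations, metagenes, regulator targets and ncRNA profiles.

    Conserved module groups share module-specific GO terms across species;
    ubiquitous background terms (idf 0) and random rare terms exercise the
    idf weighting.  Metagenes sample matched ortholog pairs inside conserved
    groups.  Regulators target one planted module each.  When ``expr`` is
    given, ncRNAs copy the module mean profile plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    group = truth.group_of
    # GO annotations
    ann: dict[GeneKey, set[str]] = {}
    for sp in truth.species:
        for gene, m in zip(truth.genes[sp], truth.module_of[sp]):
            gid = group[(sp, int(m))]
            terms = {
                f"GO:grp{gid}_{t}"
                for t in range(go_terms_per_module)
                if rng.random() < annotation_prob
            }
            terms |= {f"GO:bg{t}" for t in range(n_background_terms)}
            terms |= {
                f"GO:noise{rng.integers(n_noise_terms)}"
                for _ in range(2)
            }
            ann[(sp, gene)] = terms
    go = GOAnnotationMatrix.from_annotations({k: sorted(v) for k, v in ann.items()})
    # metagenes from matched ortholog pairs within conserved groups
    groups: dict[str, list[GeneKey]] = {}
    pair_rows: dict[tuple, list] = {}
    module_key = {
        (sp, g): int(m)
        for sp in truth.species
        for g, m in zip(truth.genes[sp], truth.module_of[sp])
    }
    for spa, ga, spb, gb in truth.ortholog_rows:
        key = (spa, module_key[(spa, ga)], spb, module_key[(spb, gb)])
        pair_rows.setdefault(key, []).append((spa, ga, spb, gb))
    for (spa, ma), (spb, mb) in truth.conserved_pairs:
        rows = pair_rows.get((spa, ma, spb, mb), [])
        take = min(metagenes_per_pair, len(rows))
        chosen = rng.choice(len(rows), size=take, replace=False) if rows else []
        for i in chosen:
            sa, a, sb, b = rows[int(i)]
            groups[f"mg_{sa}m{ma}_{sb}m{mb}_{i}"] = [(sa, a), (sb, b)]
    metagenes = MetageneSet(groups)
    # regulators per planted (species, module)
    regulators: list[tuple[str, GeneKey]] = []
    for sp in truth.species:
        for m in np.unique(truth.module_of[sp]):
            members = truth.module_genes(sp, int(m))
            for r in range(regulators_per_module):
                for g in members:
                    if rng.random() < regulator_coverage:
                        regulators.append((f"TF_{sp}_m{int(m)}_{r}", (sp, g)))
    # ncRNAs copying module mean profiles
    ncrna_expr = None
    ncrna_truth = None
    ncrna_classes = None
    if expr is not None:
        ncrna_expr = {}
        ncrna_truth = {}
        ncrna_classes = {}
        class_names = ["lncRNA", "miRNA", "snoRNA", "tRNA"]
        for sp in truth.species:
            profiles = []
            names = []
            for m in np.unique(truth.module_of[sp]):
                members = truth.module_genes(sp, int(m))
                mean_prof = expr[sp].loc[members].mean(axis=0).to_numpy()
                for r in range(ncrna_per_module):
                    name = f"nc_{sp}_m{int(m)}_{r}"
                    profiles.append(
                        mean_prof + ncrna_noise * rng.normal(size=mean_prof.size)
                    )
                    names.append(name)
                    ncrna_truth[name] = (sp, int(m))
                    ncrna_classes[name] = class_names[int(rng.integers(len(class_names)))]
            ncrna_expr[sp] = pd.DataFrame(
                np.array(profiles), index=names, columns=expr[sp].columns
            )
    return Benchmarks(go, metagenes, regulators, ncrna_expr, ncrna_truth, ncrna_classes)


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

@dataclass
class ExpressionScenario:
    mln: MultiLayerNetwork
    truth: PlantedTruth
    expr: dict[str, pd.DataFrame]
    d_per_species: dict[str, int]


def default_expression_scenario(
    seed: int = 0,
    genes_per_species: int = 200,
    n_conditions: int = 30,
    within_corr: float = 0.7,
    ortholog_fidelity: float = 0.9,
    d_max: int = 10,
    weight_scheme: str = "reciprocal_mean",
) -> ExpressionScenario:
    """The default two-species expression study: 4 modules each, 2 conserved.

    Expression is generated from the truth, co-expression layers are built
    with the automatic choice of d, and the multi-layer network is assembled
    with truth-following orthologs.
    """
    truth = generate_truth(
        n_species=2,
        genes_per_species=genes_per_species,
        modules_per_species=4,
        n_conserved=2,
        ortholog_fidelity=ortholog_fidelity,
        seed=seed,
    )
    expr = generate_expression_from_truth(
        truth, n_conditions=n_conditions, within_corr=within_corr, seed=seed + 1
    )
    layers = []
    d_per = {}
    for sp in truth.species:
        net, d = build_coexpression_layer(expr[sp], sp, d=None, d_max=d_max)
        layers.append(net)
        d_per[sp] = d
    mln = build_multilayer(layers, truth.ortholog_rows, weight_scheme=weight_scheme)
    return ExpressionScenario(mln, truth, expr, d_per)


def kappa_scan_scenario(seed: int = 0) -> tuple[MultiLayerNetwork, PlantedTruth]:
    """Desk-scale scenario for sweeping the coupling constant.

    Two species of 60 genes (4 modules of 15, 2 conserved) with a realistic
    twist: besides the matched orthologs of the conserved modules, 40
    uniformly random cross-species pairs per species pair emulate orthologs
    whose co-expression is not conserved.  Those conflicting links are what
    make a too-large kappa degrade the layers' own modular structure, so
    the recovery-vs-modularity tradeoff is visible on the scan.
    """
    return generate_planted_multilayer(
        n_species=2,
        genes_per_species=60,
        modules_per_species=4,
        n_conserved=2,
        p_in=0.5,
        p_out=0.04,
        ortholog_fidelity=0.9,
        n_noise_orthologs=40,
        seed=seed,
    )


def clique_scenario(
    weight_scheme: str = "reciprocal_mean", seed: int = 0
) -> tuple[MultiLayerNetwork, PlantedTruth]:
    """Two conserved clique structures spanned by one 8x8 ortholog clique.

    Each species has two 8-gene modules (built as cliques: p_in = 1,
    p_out = 0); matched one-to-one orthologs define two conserved
    structures.  On top, a complete bipartite ortholog clique joins 8 genes
    per species, half drawn from each module, so the many-to-many block
    straddles both structures.  Under per-endpoint weight normalization the
    clique links are damped to ~1/9 each and the two structures stay
    resolved; under uniform weights the clique dominates the coupling and
    collapses everything into one module.
    """
    spec = [
        {"pair": (0, 1), "picks_a": [(0, 4), (1, 4)], "picks_b": [(0, 4), (1, 4)]}
    ]
    return generate_planted_multilayer(
        n_species=2,
        genes_per_species=16,
        modules_per_species=2,
        n_conserved=2,
        p_in=1.0,
        p_out=0.0,
        ortholog_fidelity=1.0,
        many_to_many_spec=spec,
        weight_scheme=weight_scheme,
        seed=seed,
    )
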