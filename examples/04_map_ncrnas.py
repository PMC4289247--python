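"""Map non-coding RNAs onto modules by guilt-by-association co-expression.

ncRNAs rarely have recognizable orthologs, so they are attached to modules
through their expression profiles instead: each ncRNA's correlations to all
protein-coding genes are thresholded against a shuffled-profile null at 5%
empirical FDR, and the surviving neighbors are tested per module with a
hypergeometric test (mapped where p < 0.01; multiple modules allowed).
Here the ncRNAs are planted copies of module mean profiles plus noise, so
each should map back to its own module; pure-noise profiles stay unmapped.
"""

import numpy as np
import pandas as pd

from orthoclust.consensus import ModuleSet
from orthoclust.evaluation import map_ncrna, ncrna_class_enrichment
from orthoclust.synthetic import default_expression_scenario, generate_benchmarks_from_truth

scen = default_expression_scenario(seed=5, genes_per_species=80)
bm = generate_benchmarks_from_truth(scen.truth, expr=scen.expr, seed=6)

# use the planted truth as the module set (the pipeline's output in practice)
table = scen.mln.node_table()
groups = scen.truth.group_labels()
mods: dict[int, list[int]] = {}
for idx, key in enumerate(table):
    mods.setdefault(groups[key], []).append(idx)
modules = ModuleSet(mods, node_table=table)

assignments = map_ncrna(bm.ncrna_expr["sp1"], scen.expr["sp1"], modules,
                        species="sp1", n_shuffles=10, fdr=0.05, p_map=0.01, seed=0)
group_of = scen.truth.group_of
print("ncRNA        planted module   mapped to (p)")
for name, hits in assignments.items():
    sp, m = bm.ncrna_truth[name]
    want = group_of[(sp, m)]
    shown = ", ".join(f"{mid} (p={p:.1e})" for mid, p in hits) or "unmapped"
    print(f"{name:12s}  {want:14d}   {shown}")

rng = np.random.default_rng(7)
noise = pd.DataFrame(rng.normal(size=(20, scen.expr['sp1'].shape[1])),
                     index=[f"noise{i}" for i in range(20)],
                     columns=scen.expr["sp1"].columns)
noise_hits = map_ncrna(noise, scen.expr["sp1"], modules, species="sp1", seed=1)
unmapped = sum(1 for h in noise_hits.values() if not h)
print(f"pure-noise profiles unmapped: {unmapped}/20")

rows = ncrna_class_enrichment(assignments, bm.ncrna_classes)
sig = [r for r in rows if r["p"] < 0.05]
print(f"ncRNA class enrichments tested: {len(rows)}, significant at 0.05: {len(sig)}")
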