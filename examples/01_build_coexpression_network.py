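"""Build a signed rank-based co-expression network from an expression matrix.

Generates a small planted expression matrix (4 modules of 15 genes over 30
conditions), computes the gene-gene Pearson correlation, picks the smallest
neighbor count d that connects all genes into one component, and builds the
top-d nomination network.  The printed mean degree always lies in [d, 2d]
because every gene nominates exactly d partners and edges are the union of
nominations.
"""

from orthoclust.coexpression import choose_d, correlation_matrix, rank_network
from orthoclust.synthetic import generate_expression_from_truth, generate_truth

truth = generate_truth(n_species=1, genes_per_species=60, modules_per_species=4,
                       n_conserved=0, seed=0)
expr = generate_expression_from_truth(truth, n_conditions=30, within_corr=0.7,
                                      seed=1)["sp1"]
corr = correlation_matrix(expr)
d = choose_d(corr, d_max=20)
net = rank_network(corr, d, species_id="sp1")

print(f"genes: {net.n_nodes}, conditions: {expr.shape[1]}")
print(f"chosen d (smallest connecting the network): {d}")
print(f"edges: {net.edge_count()}  "
      f"(positive {net.edge_count(sign=1)}, negative {net.edge_count(sign=-1)})")
print(f"mean degree: {net.degrees().mean():.2f}  (bounds [{d}, {2 * d}])")
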