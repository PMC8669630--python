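"""Build a typed multilayer network from an edge table and summarize it.

Writes a small edge table in the tab-separated format (gene_a, relation,
gene_b[, weight[, provenance]]), reads it back, prints the census (gene
count, edges per relation layer) and the degree summary of the aggregate.
"""

import io

import deathnet as dn

EDGE_TABLE = """\
# a hand-curated apoptosis fragment
TP53\tTS\tBAX\t1\tcuration
TP53\tA\tBAX
BAX\tPP\tBCL2
BAX\tA\tCASP9
CASP9\tMC\tCASP3
CASP3\tMC\tPARP1
BCL2\tI\tBAX
TP53\tPP\tBCL2
"""

net = dn.read_edge_table(io.StringIO(EDGE_TABLE))
n_genes, per_layer = dn.census(net)
print(f"genes: {n_genes}")
print(f"edges per relation layer: {per_layer}")

summary = dn.degree_summary(net)  # aggregate: distinct neighbours per gene
print(f"aggregate degrees: {dict(sorted(summary.degrees.items()))}")
print(f"median {summary.median:g}, quartiles [{summary.q1:g}, {summary.q3:g}], "
      f"outliers {summary.outliers}")

# The census counts one undirected edge per distinct (gene pair, relation);
# BCL2-I-BAX and BAX-PP-BCL2 are different layers, so both are kept, while
# the degree summary counts each neighbour once however many layers link it.
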