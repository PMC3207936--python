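"""Connectivity is not feasibility: the five-gene worked example.

Genes A, B, C, D form a connected chain in the enzyme graph (each gene's
product is the next gene's substrate for *some* pair of reactions), yet no
unbroken chain of metabolite conversion runs A -> D: B consumes A's product
C2 in a reaction that makes C7, which C cannot use.  Starting from Z instead,
B's other reaction converts C3 to C4 and the chain closes.
"""

import feasipath as fp

recon = fp.make_fig1_reconstruction()
graph = fp.build_enzyme_graph(recon)

print("enzyme graph:", fp.graph_summary(graph))
print("edges:", sorted(graph.graph.edges))

for genes in [("A", "B", "C", "D"), ("Z", "B", "C", "D")]:
    res = fp.check_feasibility(genes, recon, enzyme_graph=graph)
    if res.feasible:
        chain = " -> ".join(res.feasible_path.linking_chain)
        print(f"{'->'.join(genes)}: FEASIBLE via metabolites {chain}")
    else:
        prefix = "->".join(res.max_feasible_prefix)
        print(f"{'->'.join(genes)}: infeasible (conversion stops after {prefix})")

# The connected-but-infeasible path is exactly why a feasibility check is
# needed on top of shortest-path search: graph adjacency alone overstates
# which metabolic routes a cell can actually realize.
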