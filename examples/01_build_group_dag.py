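"""Build and query the DAG linking experimental groups.

Eight groups form three layers below a baseline: three one-factor groups,
three two-factor groups, and one three-factor group.  The model's recursions
need the layer structure, ancestor generations, and Markov blankets that
this example prints.
"""

import graphdp as gdp

dag = gdp.eight_group_dag()

print("layers:", [list(layer) for layer in dag.layers])
print("K (non-root layers):", dag.K, " p (non-root nodes):", dag.p)
# generation-g ancestors of the deepest group: parents, grandparents, root
for g in (1, 2, 3):
    print(f"generation-{g} ancestors of group 8:", sorted(gdp.ancestors(dag, 8, g)))
print("Markov blanket of group 6:", sorted(gdp.markov_blanket(dag, 6)))

# two disconnected roots are joined under one hidden parent automatically
two_studies = gdp.build_dag([], observed={1: True, 2: True})
print("hidden root added:", two_studies.root, "observed:", two_studies.observed)
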