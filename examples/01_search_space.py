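"""How large is the space of candidate ConvNets?

Counts layer-kind sequences of bounded length exactly, plus the per-layer
parameter-permutation calculus and the training budgets of both searches.
"""

from swarmnas import (
    count_models_aco,
    count_models_pso,
    count_parameterized_space,
    count_search_space,
)

# Four layer kinds (conv, max pool, average pool, dense), 3 to 20 layers:
total = count_search_space(4, 3, 20)
print(f"unconstrained architectures, 4 kinds, length 3-20: {total:,}")
# -> 1,466,015,503,680 distinct layer-kind sequences before any
#    structural rule or parameter choice is applied.

# Per-layer parameter permutations (conv 9, max-pool 2, batch-norm 1,
# dense 4) for a fixed 31-layer template with 12 convs, 1 pool, 15 batch
# norms and 3 dense layers:
as_sum = count_parameterized_space([9, 2, 1, 4], [12, 1, 15, 3], "as_printed")
as_product = count_parameterized_space([9, 2, 1, 4], [12, 1, 15, 3], "combinatorial")
print(f"sum-of-powers parameter count:     {as_sum:,}")
print(f"product (distinct assignments):    {as_product:,}")
# The sum form mirrors the published closed form; the product is the true
# number of distinct parameterizations of that fixed layer sequence.

# Search budgets: how many candidate models each swarm actually trains.
print(f"ant search, 16 ants x depth 32:    {count_models_aco(16, 32)} models")
print(f"particle search, 5 x 12 x 20:      {count_models_pso(5, 12, 20)} models")
# Both are vanishingly small fractions of the full space - the point of
# heuristic search.
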