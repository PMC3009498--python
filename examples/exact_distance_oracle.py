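"""Exact minimum-weight distances on toy genomes by exhaustive search.

Only tiny alphabets are feasible; the oracle is the reference that
sandwiches the heuristic: lb <= exact <= found weight.
"""

from dupsort import Genome, exact_distance, lower_bound, sort

cases = [
    (Genome([(1, 2, 3)]), Genome([(1, 2, 3)], n=3)),     # identical
    (Genome([(1, 2)]), Genome([(1, -2)], n=2)),          # one reversal
    (Genome([(1, 2, 3)]), Genome([(1, 3)], n=3)),        # one deletion
    (Genome([(1, 2, 3)]), Genome([(2, 1, 3)], n=3)),     # one transposition (weight 2)
    (Genome([(1, 2), (3, 4)]), Genome([(1, 4), (3, 2)], n=4)),  # one translocation
]

for rho, pi in cases:
    d = exact_distance(rho, pi, max_weight=4)
    w = sort(rho, pi).total_weight
    print(f"{[list(c) for c in rho.chromosomes]} -> "
          f"{[list(c) for c in pi.chromosomes]}: "
          f"lb={lower_bound(rho, pi)} exact={d} sorter={w}")
    assert lower_bound(rho, pi) <= d <= w

# on these toys the greedy sorter is optimal: sorter weight equals the
# exhaustive minimum in every row
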