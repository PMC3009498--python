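"""Sort a descendant genome back into its ancestor and inspect the scenario.

Builds a small diploid-style ancestor, scrambles it by hand with a few
known operations, and lets the greedy sorter recover a scenario.
"""

from dupsort import Genome, OpKind, Operation, apply, genome_metrics, lower_bound, sort

# ancestor: two chromosome types, the second present in two copies
rho = Genome([(1, 2, 3, 4), (5, 6, 7, 8), (5, 6, 7, 8)])

# evolve a descendant: a reversal, a tandem duplication, a translocation
history = [
    Operation(OpKind.REVERSAL, chrom=(1, 2, 3, 4), start=1, end=3),
    Operation(OpKind.TANDEM_DUPLICATION, chrom=(5, 6, 7, 8), start=1, end=3),
    Operation(OpKind.TRANSLOCATION, chrom=(1, -3, -2, 4), chrom_b=(5, 6, 7, 8),
              pos=2, pos_b=2),
]
pi = rho
for op in history:
    pi = apply(op, pi)
print("descendant:", [list(ch) for ch in pi.chromosomes])

m = genome_metrics(rho, pi)
print(f"lower bound lb = {m.lb}, tie-breaker tau = {m.tau} "
      f"(T = {m.T} incorrect telomeres, {m.C} graph components)")

scenario = sort(rho, pi)
print(f"found scenario of weight {scenario.total_weight} "
      f"(true history weighed {sum(op.weight for op in history)}):")
for op in scenario.operations:
    print("  ", op.kind.value, op.params())

assert scenario.replay(Genome(rho.chromosomes, n=pi.n)) == pi
print("replaying the scenario on the ancestor reproduces the descendant exactly")
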