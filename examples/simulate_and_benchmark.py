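"""Benchmark the sorter on simulated data with a known true weight.

Generates replicates of the 36-element, 12-chromosome diploid preset at
two divergence levels, sorts each pair, and compares the found weight
with the lower bound and the generating weight.
"""

import statistics

from dupsort import Genome, lower_bound, preset, simulate, sort

for alpha in (0.2, 0.5):
    lbs, calcs, trues = [], [], []
    for seed in range(5):
        inst = simulate(preset("dataset2", alpha=alpha, seed=seed))
        scenario = sort(inst.rho, inst.pi)
        assert scenario.replay(Genome(inst.rho.chromosomes, n=inst.pi.n)) == inst.pi
        lbs.append(lower_bound(inst.rho, inst.pi))
        calcs.append(scenario.total_weight)
        trues.append(inst.true_weight)
    print(f"alpha={alpha}: mean lower bound {statistics.mean(lbs):.1f} <= "
          f"mean found weight {statistics.mean(calcs):.1f} ~ "
          f"mean true weight {statistics.mean(trues):.1f}")

# the found weight sits between the bound and (near) the generating
# weight; at higher divergence the heuristic often finds scenarios
# shorter than the true history, since random histories waste weight
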