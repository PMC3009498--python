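"""Build a breakpoint graph and read off its components, loops and bridges.

The graph lives on the 2n block extremities; gray edges come from the
ancestor's adjacencies, black edges from the descendant's.  Bridges mark
where a component-increasing inverse DCJ can act.
"""

from dupsort import Genome, build_breakpoint_graph, classify_breakpoints

rho = Genome([(1, 2), (3, 4)])
pi = Genome([(1,), (4,), (-2, -3)], n=4)

bg = build_breakpoint_graph(rho, pi)
print("components:", bg.count_components())
print("loop vertices:", bg.count_loops())
print("1-bridges:", [(str(a), str(b)) for a, b in bg.find_1_bridges()])
print("2-bridges:", bg.find_2_bridges())

cls = classify_breakpoints(rho, pi)
print("inner breakpoints:", [(str(a), str(b)) for a, b in cls.inner_breakpoints])
print("telomere breakpoints:", [str(e) for e in cls.telomere_breakpoints])

# the single black edge (2t, 3h) is the only link between the two gray
# paths, so it is a 1-bridge: cutting it with an inverse operation would
# split the component and lower the distance bound
print()
print(bg.to_dot())
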