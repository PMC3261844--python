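"""Why geography matters: the early-adopter giant component.

Compares spatially embedded and non-spatial homophilous networks at the
same homophily preference, printing measured homophily and the share of
early adopters in the giant component of their induced subgraph.  In the
formation regime (low preference) only the spatial construction keeps
early adopters connected; far above it both constructions connect nearly
everyone.
"""

from adoptnet import (
    KernelParams,
    allocate_agents,
    build_nonspatial_homophilous_network,
    build_spatial_network,
    early_adopter_giant_component,
    generate_synthetic_cities,
    measure_homophily,
)

table = generate_synthetic_cities(408, seed=3)
pop = allocate_agents(table, 30_000)

print("pref | spatial: homophily  GC | non-spatial: homophily  GC")
for h in (0.2, 0.3, 0.5, 0.8):
    params = KernelParams(homophily_pref=h)
    sp = build_spatial_network(pop, table, 10.0, params, seed=10)
    ns = build_nonspatial_homophilous_network(pop, table, 10.0, params, seed=11)
    print(
        f"{h:4.1f} |          {measure_homophily(sp, pop):.3f} {early_adopter_giant_component(sp, pop):6.1%}"
        f" |              {measure_homophily(ns, pop):.3f} {early_adopter_giant_component(ns, pop):6.1%}"
    )
# At preference 0.2-0.3 the non-spatial giant component collapses while the
# spatial one persists: type preference alone cannot connect a 20% minority,
# but geographically concentrated early adopters find each other locally.
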