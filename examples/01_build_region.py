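"""Build a county region and inspect its two networks.

Generates a small synthetic region (a county grid with one interstate
route), writes it in the package's CSV input dialect, reloads it, and
prints the network sizes.  The same loader reads real county tables.
"""

from pathlib import Path

from slfspread import (
    SyntheticSpec,
    build_region,
    generate_region,
    load_adjacency_pairs,
    load_county_table,
    write_adjacency_pairs,
    write_county_table,
)

out = Path("scratch") / "example_region"
spec = SyntheticSpec(grid_shape=(4, 5), n_highways=1, highway_length=4, rng_seed=7)
region = generate_region(spec)

import networkx as nx

g = nx.from_numpy_array(region.A)
fips = region.fips_codes
write_county_table(region.counties, out / "region.csv")
write_adjacency_pairs([(fips[i], fips[j]) for i, j in g.edges()], out / "adjacency.csv")

reloaded = build_region(
    load_county_table(out / "region.csv"), load_adjacency_pairs(out / "adjacency.csv")
)
print(f"counties:      {reloaded.n_counties}")
print(f"border edges:  {int(reloaded.A.sum()) // 2}")
print(f"highway edges: {int(reloaded.H.sum()) // 2}")
# Border edges form the short-distance spread channel; highway edges link
# every pair of counties sharing an interstate (a clique per route) and
# carry the long-distance channel.
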