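"""Mapper sanity geometries: separated blobs and a circle.

Feeds raw 2-D point clouds straight into the cover/graph stage (no
expression matrix; clustering falls back to Euclidean distance in lens
space). Two well-separated Gaussian blobs must give two connected
components; a circle must close into a graph cycle.
"""

import networkx as nx

from neuromapper import MapperParams, build_graph
from neuromapper.synthetic import SyntheticSpec, gen_lens_cloud

blobs, labels = gen_lens_cloud(
    SyntheticSpec(kind="lens_cloud", shape="two_blobs", n_points=200,
                  separation=10.0, seed=0)
)
g = build_graph(None, blobs, MapperParams(window_pct=30, overlap_pct=50))
comps = [c for c in nx.connected_components(g.to_networkx()) if len(c) > 1]
print(f"two blobs -> {len(comps)} non-singleton components (expect 2)")

circle, _ = gen_lens_cloud(
    SyntheticSpec(kind="lens_cloud", shape="circle", n_points=500, seed=0)
)
g = build_graph(None, circle, MapperParams(window_pct=20, overlap_pct=40))
gx = g.to_networkx()
big = gx.subgraph(max(nx.connected_components(gx), key=len))
print(f"circle -> largest component has {big.number_of_nodes()} nodes, "
      f"{big.number_of_edges()} edges; cycle present: "
      f"{big.number_of_edges() >= big.number_of_nodes()}")
print("Edges >= nodes in a connected component implies at least one cycle: "
      "the nerve remembers the circle's topology.")
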