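"""Relatedness network over diagnosis groups from pairwise DMP counts.

Edges are binned by DMP count ({0}, 1-999, 1,000-4,999, 5,000-9,999,
10,000-14,999); fewer differential probes means stronger similarity.  Pairs
with 15,000+ DMPs get no edge; a group left isolated is annotated with its
closest possible connection and the exact count.
"""

import pandas as pd

import methylscape as ms
from methylscape.dmp import PairwiseDMPCounts
from methylscape.network import edge_list

labels = ["MCN-P", "MCN-L", "mBOT", "PDAC", "HCC"]
counts = pd.DataFrame([
    #  MCN-P  MCN-L   mBOT   PDAC    HCC
    [     0,     0,   820,  4200, 26000],   # MCN-P
    [     0,     0,   910,  5100, 27000],   # MCN-L
    [   820,   910,     0,  8800, 30000],   # mBOT
    [  4200,  5100,  8800,     0, 21000],   # PDAC
    [ 26000, 27000, 30000, 21000,     0],   # HCC
], index=labels, columns=labels)
pairwise = PairwiseDMPCounts(counts=counts, dmp_sets={})

graph = ms.build_network(pairwise)
graph = ms.annotate_closest(graph, pairwise)

print("edges (group_a, group_b, DMP count, bin):")
print(edge_list(graph).to_string(index=False))
print()
nearest, n = ms.nearest_entity(pairwise, "MCN-P")
print(f"nearest entity to MCN-P: {nearest} ({n} DMPs — the zero-count bin is")
print("the strongest possible connection)")
print(f"isolated groups annotated with closest connection: "
      f"{graph.closest_connections}")
# HCC has no pair under 15,000 DMPs, so it is disconnected and carries a
# closest-connection annotation to PDAC with the exact count (21,000).
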