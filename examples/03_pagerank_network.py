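"""Personalized PageRank on a small hand-built regulatory network.

Two TFs regulate overlapping gene sets; gene node weights (e^z of the
expression z-score) steer the walk, so the TF whose targets are more
up-regulated gets the higher global-influence score.
"""

import pandas as pd

from regnetrank.network import RegulatoryNetwork, node_weight
from regnetrank.pagerank import SolverConfig, personalized_pagerank, to_walk_matrix

# TF_A regulates g1, g2; TF_B regulates g2, g3.  g1 is strongly up (z=2),
# g3 is down (z=-1).
z = {"TF_A": 0.0, "TF_B": 0.0, "g1": 2.0, "g2": 0.0, "g3": -1.0}
nodes = pd.DataFrame(
    {
        "is_tf": [True, True, False, False, False],
        "node_weight": [node_weight(z[g]) for g in ["TF_A", "TF_B", "g1", "g2", "g3"]],
    },
    index=pd.Index(["TF_A", "TF_B", "g1", "g2", "g3"], name="gene"),
)
edges = pd.DataFrame(
    [
        ("TF_A", "g1", 1.0, 1),
        ("TF_A", "g2", 1.0, 1),
        ("TF_B", "g2", 1.0, 1),
        ("TF_B", "g3", 1.0, 1),
    ],
    columns=["tf", "target", "weight", "n_sites"],
)
net = RegulatoryNetwork("demo", nodes, edges)

walk = to_walk_matrix(net)
res = personalized_pagerank(walk, net.nodes["node_weight"], SolverConfig(damping=0.85))
print(f"converged in {res.iterations} iterations (L1 residual {res.residual:.1e})")
for gene, score in res.scores.sort_values(ascending=False).items():
    print(f"{gene:6s} {score:.4f}")

# Scores sum to 1.  TF_A outranks TF_B because its exclusive target g1
# carries node weight e^2 ~ 7.4 while TF_B's exclusive target g3 carries
# e^-1 ~ 0.37: the walk allocates more influence to the TF regulating the
# more differentially expressed genes.
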