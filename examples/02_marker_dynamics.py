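"""Quantify marker dynamics along a differentiation trajectory.

For each marker, computes the mutual information (in nats) between
pseudotime and expression on the erythroid branch, and the log2 fold
change between the start and the end of the trajectory — the two numbers
behind dot-plot summaries of trajectory-associated surface markers.
"""

import numpy as np

import cytoref as cr

config = cr.default_config()
atlas, _ = cr.generate_reference(config, seed=1)

pt = atlas.pseudotime["erythroid"].to_numpy(dtype=float)
on_branch = np.isfinite(pt)
print(f"{on_branch.sum()} cells on the erythroid trajectory\n")
print(f"{'marker':<8} {'MI (nats)':>10} {'log2 FC':>9}")
for marker in ("CD71", "CD326", "CD38", "CD3", "M12"):
    expr = atlas.expr.column(marker)[on_branch]
    mi = cr.pseudotime_mutual_information(pt[on_branch], expr, n_bins=8)
    lfc = cr.trajectory_logfc(pt[on_branch], expr, edge_fraction=0.1)
    print(f"{marker:<8} {mi:>10.3f} {lfc:>9.2f}")

# Markers configured to rise along the branch (CD71, CD326, M12) show high
# mutual information and positive fold change; markers tied to unrelated
# populations (CD3) carry essentially no information about this trajectory.
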