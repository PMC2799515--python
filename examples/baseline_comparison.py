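"""Compare model co-membership with the shared-neighbor baseline.

The hypergeometric baseline ranks vertex pairs by the surprise of their
shared neighbor count — a purely local signal.  The block model ranks the
same pairs from a global fit of the whole network.
"""

from dyhm import (
    co_membership,
    f1_max,
    fit_static,
    generate_static,
    pair_scores_and_labels,
    pr_curve,
    pvalue_score_matrix,
    rank_all_pairs,
)

snapshot, truth = generate_static(preset="contrast", seed=11)
print(f"network: {snapshot.n_vertices} vertices, {snapshot.n_edges} edges")

state = fit_static(snapshot, depth=3, seed=11)
for name, matrix in [
    ("hierarchical model", co_membership(state.membership)),
    ("hypergeometric baseline", pvalue_score_matrix(snapshot)),
]:
    scores, labels = pair_scores_and_labels(matrix, truth.labels)
    p, r = pr_curve(scores, labels)
    print(f"{name:<25} max-F1 = {f1_max(p, r):.3f}")

top = rank_all_pairs(snapshot).head(5)
print("\nbaseline's five most significant pairs:")
print(top.to_string(index=False))
# Higher max-F1 for the model reflects its global view: two vertices can
# be confidently co-clustered even when they share few direct neighbors.
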