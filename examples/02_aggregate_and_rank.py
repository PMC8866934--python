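"""Aggregate single cells into per-patient statistics and rank features.

Each patient's eCTC population is summarized by 34 features x 5 statistics
(mean, SD, quartiles) plus cell counts; features are then discretized into
four equal-frequency bins and ranked by information gain against the
dichotomized outcome (overall survival >30 months).
"""

import ctcstrat as cs

cohort = cs.generate_cohort(cs.SimConfig(seed=1))
matrix = cs.build_matrix(cohort, cls="eCTC", target="OS")
print(f"design matrix: {matrix.X.shape[0]} patients x {matrix.X.shape[1]} features")
print(f"(patients without eCTC or censored before 30 months are excluded)\n")

ranking = cs.rank_features(matrix, k_bins=4)
print(f"target entropy: {ranking.target_entropy:.3f} bits")
print("top 10 features by information gain:")
for i, (name, gain) in enumerate(ranking.ranking[:10], 1):
    print(f"  {i:2d}. {name:45s} {gain:.3f} bits")

# The planted survival effect lives in brightfield circularity, so its
# aggregate statistics should head the list; the gain is the reduction in
# outcome entropy achieved by knowing the feature's quartile bin.
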