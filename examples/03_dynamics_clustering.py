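"""Classify genes as dynamic vs stable per layer and cluster protein
trajectories into the standard developmental groups.

A gene is "dynamic" if the CV of its log2 values across the seven stages
exceeds 0.2.  Protein trajectories are z-scored and clustered by
Euclidean K-means; clusters undetected before ZGA that rise afterwards
are merged into one "embryonic" group.
"""

from oetomics import GeneratorConfig, generate_bundle
from oetomics import dynamics as dyn
from oetomics import preprocess as pp

bundle = generate_bundle(GeneratorConfig(n_genes=300, noise_sd=0.1, seed=1))
corrected = pp.apply_batch_correction(
    bundle.protein, pp.compute_batch_factors(bundle.protein)
)
protein = pp.merge_replicates(corrected)
rpf = pp.merge_replicates(bundle.rpf)
mrna = pp.merge_replicates(bundle.mrna)

for name, matrix in (("protein", protein), ("RPF", rpf), ("mRNA", mrna)):
    _, fraction = dyn.classify_dynamics(matrix)
    print(f"dynamic {name:8s}: {100 * fraction:5.1f}% of eligible genes")
# The proteome is buffered by the maternal stockpile, so its dynamic
# fraction is lower than translation and transcription.

assignments, sse = dyn.cluster_trajectories(protein, k=8, restarts=20, seed=1)
mapping = dyn.embryonic_merge_mapping(
    assignments, protein, detection_floor=bundle.config.detection_floor
)
groups = dyn.merge_to_groups(assignments, mapping)
print("\nK-means groups (k=8, embryonic clusters merged):")
print(groups["group_label"].value_counts().to_string())

corr = dyn.stage_correlation_matrix(protein, protein)
print("\nprotein stage-correlation (Spearman), FGO row:")
print(corr.loc["FGO"].astype(float).round(2).to_string())
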