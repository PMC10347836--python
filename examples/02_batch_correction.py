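"""Batch-correct the proteome anchored on FGO samples and build the
analysis gene universe.

FGOs were measured in every batch, so the median intensity of proteins
detected in all batches estimates each batch's additive log2 offset.
"""

from oetomics import GeneratorConfig, generate_bundle
from oetomics import preprocess as pp

bundle = generate_bundle(GeneratorConfig(n_genes=200, noise_sd=0.1, seed=1))

factors = pp.compute_batch_factors(bundle.protein, anchor_stage="FGO")
print("estimated batch offsets (log2):")
for batch, offset in sorted(factors.offsets.items()):
    true = bundle.config.batch_offsets[batch]
    print(f"  batch {batch}: {offset:+.3f}  (generator truth {true:+.1f})")

corrected = pp.apply_batch_correction(bundle.protein, factors)
universe = pp.filter_gene_universe(corrected, bundle.rpf, bundle.mrna)
print(f"\nanalysis universe: {len(universe)} of {bundle.config.n_genes} genes")
print("(excluded: proteins never detected, FGO-inconsistent detections,")
print(" and genes with no translatome/transcriptome signal at any stage)")

averaged = pp.merge_replicates(corrected)
print("\nstage-averaged protein matrix:", averaged.values.shape)
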