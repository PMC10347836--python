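"""Call DEPs between consecutive stages and attribute protein changes to
mRNA or translation, including the lagged window.
"""

from oetomics import GeneratorConfig, generate_bundle
from oetomics import concordance as conc
from oetomics import differential as diff
from oetomics import preprocess as pp

bundle = generate_bundle(GeneratorConfig(n_genes=300, noise_sd=0.1, seed=1))
corrected = pp.apply_batch_correction(
    bundle.protein, pp.compute_batch_factors(bundle.protein)
)
replicate = pp.replicate_matrix_with_derived_fgo(corrected)

deps = diff.deps_all_transitions(replicate)  # two-fold + t-test p < 0.05
called = deps[deps["direction"] != "none"]
print("DEPs per transition (|fold change| >= 2, p < 0.05):")
print(called.groupby("transition", sort=False)["direction"].value_counts().to_string())
print(f"\n{called.index.unique().size} genes differential in >= 1 transition")

rpf_changes = conc.change_matrix(pp.merge_replicates(bundle.rpf))
mrna_changes = conc.change_matrix(pp.merge_replicates(bundle.mrna))
attribution, fractions = diff.attribute_changes(deps, rpf_changes, mrna_changes, lag=2)
print("\nattribution of protein changes (current + 2 preceding transitions):")
print((100 * fractions).round(1).to_string())
# mrna_contributed: same-direction mRNA change > two-fold in the window;
# rpf_only: translation change without mRNA change; unexplained: neither
# (candidate post-translational regulation).

fgo_genes, persistence = diff.fgo_originated(
    pp.merge_replicates(corrected), pp.merge_replicates(bundle.rpf)
)
print(f"\nFGO-originated proteins (RPF FPKM < 5 from 1C on): {len(fgo_genes)}")
print(f"still detected in blastocyst: {100 * persistence:.1f}%")

dormant = diff.dormant_mrna_set(
    pp.merge_replicates(bundle.rpf), pp.merge_replicates(bundle.mrna)
)
print(f"dormant mRNAs (RPF MII/FGO > 2, mRNA MII/FGO < 2): {len(dormant)}")
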