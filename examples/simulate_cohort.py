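"""Generate a synthetic multi-population cohort and inspect its structure.

Builds a small cohort (one focal population plus three reference panels of
16 diploid samples each) under the Balding-Nichols frequency model and
prints what was planted: population-confined variants, GWAS-style frequency
outliers, and deletion loci.
"""

import popvar as pv

cfg = pv.SimConfig(
    n_populations=4,
    n_snps=4000,
    n_gwas_snps=500,
    n_rare=80,
    n_low_count_private=10,
    n_private=5,
    n_deletion_sites=100,
    seed=42,
)
sim = pv.simulate_all(cfg)
matrix, truth = sim["matrix"], sim["genotype_truth"]

print(f"cohort: {matrix.n_samples} samples x {matrix.n_variants} SNPs")
print(f"populations: {', '.join(cfg.populations)}")
print("realized sharing classes (focal population =", cfg.focal_population,
      "):")
for cls, n in truth.sharing_class.value_counts().items():
    print(f"  {cls:>18}: {n}")
print(f"planted GWAS outliers: {len(truth.planted_outlier_index)} of "
      f"{len(truth.gwas_index)} GWAS SNPs at |delta f| {cfg.planted_diff}")
n_false = round(cfg.false_deletion_frac * cfg.n_deletion_sites)
print(f"deletion loci: {cfg.n_deletion_sites} ({n_false} planted to violate "
      "het-SNP validation)")
# 'rare' = one focal chromosome and absent from every reference panel;
# 'private' = >3 focal chromosomes, absent elsewhere. These planted counts
# are the ground truth the downstream classifiers are tested against.
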