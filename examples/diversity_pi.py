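"""Per-population nucleotide diversity (pi).

Per-site pi is the unbiased heterozygosity (n/(n-1)) 2p(1-p); genome-wide
pi sums it over variable sites and divides by the ungapped genome length.
Populations simulated at the same Fst around the same ancestral frequencies
should show comparable diversity.
"""

import popvar as pv

cfg = pv.SimConfig(n_populations=4, n_snps=6000, n_gwas_snps=0,
                   n_planted_outliers=0, n_rare=0, n_low_count_private=0,
                   n_private=0, n_deletion_sites=1, seed=7)
matrix, table, panel, _ = pv.simulate_genotypes(cfg)
lengths = {str(c + 1): cfg.chrom_length for c in range(cfg.n_chroms)}

summary = pv.pi_by_population(matrix, panel, lengths)
print(summary.to_string(index=False, float_format=lambda x: f"{x:.3e}"))
print()
print("pi is the expected per-bp difference between two random chromosomes;")
print("here every population shares one ancestral pool, so the column is "
      "flat.")
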