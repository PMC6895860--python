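"""Plant a two-locus LD pair and estimate r² by both routes.

Draws 2,000 haplotypes from the exact four-gamete distribution with a target
r² of 0.36, then estimates r² (a) by direct gamete counting on the phased
haplotypes and (b) by the two-locus EM algorithm after collapsing the
haplotypes to unphased diploid genotypes.  Both estimates should sit near
the planted target; the EM route only differs through the phase ambiguity
of double heterozygotes.
"""

from finemap_array import em_haplotype_freqs, haplotype_freqs_phased, plant_ld_pair, r_squared
from finemap_array.ld import genotype_counts

hap_a, hap_b = plant_ld_pair(p_a=0.5, p_b=0.5, target_r2=0.36, n_haplotypes=2000, seed=4)

h_phased = haplotype_freqs_phased(hap_a, hap_b)
print(f"planted target r2      : 0.360")
print(f"phased counting r2     : {r_squared(h_phased):.4f}")

geno_a = hap_a[0::2] + hap_a[1::2]
geno_b = hap_b[0::2] + hap_b[1::2]
h_em = em_haplotype_freqs(genotype_counts(geno_a, geno_b))
print(f"unphased EM r2         : {r_squared(h_em):.4f}")
print(f"gamete freqs (phased)  : AB={h_phased.pAB:.3f} Ab={h_phased.pAb:.3f} "
      f"aB={h_phased.paB:.3f} ab={h_phased.pab:.3f}")
# The two estimates agree closely at this n because 1,000 individuals give
# the EM plenty of unambiguous cells to anchor the haplotype frequencies.
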