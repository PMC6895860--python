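# finemap-array

Content selection for custom fine-mapping genotyping arrays in multi-ethnic
studies.

Genome-wide association studies identify *index* variants that tag risk
loci, but the causal variants behind them usually remain unknown. One
cost-efficient route to localizing them is a custom genotyping array: take a
standard multi-ethnic base array and add a few thousand carefully chosen
bead types covering the variation most likely to be causal at each locus.
`finemap-array` implements that selection workflow as a reusable pipeline
for anyone designing such content: given index association signals with
Hispanic (AMR) and African American (AA) replication statistics, phased or
unphased reference genotype panels, a variant annotation table and the base
array's manifest, it produces the prioritized custom variant list with full
per-stage accounting.

## The selection model

Each autosomal index signal defines a 2-Mb window (±1 Mb around the index
variant, GRCh37, 1-based inclusive); overlapping windows merge into loci.
Two arms then nominate candidates:

**Coding/regulatory arm** (all loci plus the MHC, chr6:27–34 Mb). A variant
is selected if it exceeds at least one population's minor-allele-frequency
bound (AFR > 0.01, AMR > 0.01, NFE > 0.05, or EAS > 0.05 — a disjunction)
and satisfies at least one of: protein-altering or splice-site consequence,
CADD phred ≥ 30, or RegulomeDB category 1a–1e.

**Replication-conditional LD arm** (autosomal non-MHC loci). Pairwise LD is
the squared allelic correlation

r² = D² / (p_A(1−p_A) · p_B(1−p_B)),  D = p_AB − p_A p_B,

with gamete frequencies counted directly from phased haplotypes or
estimated from unphased genotypes by the classic two-locus EM algorithm
(only the double-heterozygote cell has latent phase; initialization at
linkage equilibrium, deterministic). Each signal's replication status picks
the rule a candidate must meet:

| replication outcome (AMR/AA) | rule |
|---|---|
| one-sided p ≤ 0.05 in both | r² ≥ 0.1 in **all** of NFE, AMR, AA |
| one-sided p ≤ 0.05 in one | r² ≥ 0.1 in **all** of NFE + that pool |
| opposite direction, two-sided p ≤ 0.10 | r² ≥ 0.1 in NFE **or** that pool |
| neither | r² ≥ 0.1 in NFE |

Undefined r² (the pool is monomorphic at either site) fails the rule — a
variant cannot be in LD where it does not vary.

Both arms exclude base-array overlap (position + unordered allele set) and
tri-allelic sites. The union is filtered for assay designability, then
partitioned: coding/regulatory content and LD content of replicated signals
are kept unconditionally; the remainder is pruned by imputation INFO score —
variants with INFO **above** a threshold are dropped because the base array
already imputes them well, and the threshold is the largest observed score
whose retained set still fits the bead-type budget (strand-ambiguous SNPs
and indels need two bead types, other SNPs one).

## Worked example

`examples/` holds one short script per capability. A full run on a
generated synthetic study (20 signals in a 2/8/1/9 BOTH/ONE/OPPOSITE/NONE
replication mix, pools of 403 NFE / 338 AMR / 149 AA individuals):

```bash
$ python examples/03_full_design_run.py
[union_dedup]
  n_coding      28
  n_fine_mapping        112
  n_overlap     16
  n_union       124
[info_pruning]
  info_threshold        0.6606
  n_retained    33
  n_excluded    25
...
final custom content: 88 variants, 120 bead types (budget 120)
```

Reading: the two arms nominated 124 unique variants (16 selected by both);
after designability filtering, 55 were priority content and 58 prunable;
the INFO threshold 0.6606 retained the 33 hardest-to-impute prunable
variants, exactly exhausting the 120-bead budget. And

```bash
$ python examples/01_plant_ld_and_estimate_r2.py
planted target r2      : 0.360
phased counting r2     : 0.3579
unphased EM r2         : 0.3607
```

shows the two r² routes agreeing on a planted-LD pair of 2,000 haplotypes.

The same workflow is scriptable from a shell:

```bash
finemap-array simulate --out study/ --seed 1
finemap-array design --config study/config.yaml --out results/
finemap-array ld --vcf study/panels/panel_NFE.vcf -a 1:20000000:A:G -b 1:19520000:A:G
```

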