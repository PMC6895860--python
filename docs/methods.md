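# Methods

## Scope and model

`finemap_array` selects custom genotyping-array content for fine-mapping
established risk loci in multi-ethnic samples. The working assumption is
two-sided: if the same causal variant drives association in every
population, it must lie in LD with the index variant in every population
(so demanding r² ≥ 0.1 in all relevant reference pools concentrates the
candidate set); if allelic or locus heterogeneity breaks that picture, the
dense coding/regulatory catalogue within each locus provides coverage that
does not depend on LD with the index at all. The pipeline implements both
arms and the subsequent budget-constrained pruning.

Coordinates are GRCh37, 1-based, inclusive on both interval ends throughout;
BED exports convert to 0-based half-open. Variant identity is the tuple
(chrom, pos, ref, alt); base-array overlap is matched on position plus the
unordered allele set, with no strand/TOP-BOT normalization attempted (real
manifests differ in strand convention; callers must pre-normalize — a known
limitation).

## LD engine

For two loci with alt-allele frequencies p_A, p_B and gamete frequency
p_AB, the disequilibrium coefficient is D = p_AB − p_A p_B and
r² = D²/(p_A q_A p_B q_B). On phased haplotypes, gamete frequencies are
relative counts over pairwise-complete haplotypes. On unphased diploid
genotypes they are maximum-likelihood estimates from the standard two-locus
EM: all cells of the 3×3 genotype table except the double heterozygote have
deterministic gamete composition; the E-step splits that cell between the
coupling (AB/ab) and repulsion (Ab/aB) phases in proportion to their
current expected frequencies, and the M-step re-tallies. Numerical choices:

* initialization at linkage equilibrium (p_AB = p_A p_B) — deterministic,
  no seed; non-identifiable tables resolve to the equilibrium-basin
  optimum, and an exactly balanced split (coupling odds undefined) falls
  back to 0.5;
* convergence when the largest frequency change is below 1e-8, cap 1000
  iterations; the per-iteration log-likelihood trace is available and is
  non-decreasing;
* a monomorphic locus makes r² *undefined* (`None`), which downstream
  selection treats as failing the LD requirement rather than as an error:
  this materially affects the smallest pool (AA), where sites monomorphic
  in that pool can never satisfy an ALL-combinator that includes it;
* r² comparisons against the 0.1 bound are inclusive (≥).

Population pools are taken as given panels (NFE / AMR / AA); samples within
a pool are treated as exchangeable, with no correction for internal
structure or admixture — a caveat inherited from pooling reference
subpopulations.

### Phase-information limit

The EM estimate is exact maximum likelihood (verified in the tests against
a 1-D grid search over p_AB at 1e-4 resolution), so on the same data the
only difference from phased counting is the realized vs. expected phase of
double heterozygotes. That difference is binomial: with n_dh double
heterozygotes and coupling probability p, the induced r² deviation has
standard deviation ≈ 2D·√(n_dh·p(1−p)) / (2N·p_A q_A p_B q_B). At 2N = 400
haplotypes this is ~0.02–0.03 for moderate LD (r² 0.1–0.5), shrinking to
near zero for r² ≥ 0.8 (phase nearly identifiable) and scaling as 1/√N.
Consequently, tight (±0.02) phased/unphased agreement at panel sizes of a
few hundred is only guaranteed in the strong-LD regime; the test suite
asserts tight agreement there, and convergence with growing N for moderate
LD. This is an information-theoretic property of the estimator, not an
implementation tolerance.

## Replication classification

Inputs are per-population (AMR, AA) summary statistics: effect sign
relative to the discovery direction and a two-sided p. The one-sided p is
p/2 for a direction-consistent effect and 1 − p/2 otherwise, so published
two-sided values can be used directly; replication means one-sided
p ≤ 0.05, and "significant-opposite" means sign −1 with two-sided p ≤ 0.10
(sign alone never suffices). Missing fields never satisfy a test. The four
classes are mutually exclusive with precedence BOTH > OPPOSITE > ONE >
NONE; OPPOSITE is ranked above ONE so that evidence of diverging LD
structure triggers the more permissive ANY-combinator. The precedence is
configurable, and the emitted status audit table records the p-values used,
so a signal that both replicates in one sample and flips in the other is
visible. If both samples are significant-opposite, the smaller p picks the
relevant population (logged).

## Pruning and bead accounting

Designability scores are consumed as a table (assay scoring itself is out
of scope); records at or above the cutoff (default 0.5 — a conventional
mid-scale cut, the vendor's true threshold being unpublished) survive, and
records without a score are dropped with a warning since they cannot be
ordered.

Imputation INFO is the ratio-of-variances measure: with per-sample expected
dose e_i = p_i1 + 2p_i2 and second moment f_i = p_i1 + 4p_i2,
INFO = 1 − Σ(f_i − e_i²) / (2N·θ(1−θ)), θ = Σe_i/2N, clamped to [0, 1],
defined as 1 when θ ∈ {0, 1} and exactly 1 on hard calls. Implementations
of "INFO" differ slightly across imputation tools; this variant was chosen
for its closed form and its hard-call identity, and scores can equally be
supplied precomputed.

Pruning is deliberately inverted relative to a quality filter: content that
imputes *well* from the base array is excluded (the array recovers it for
free) and the hard-to-impute tail is retained. The threshold is searched on
the grid of observed INFO values plus a sentinel 0.0: retained(t) =
{INFO ≤ t}, and the chosen t is the largest grid value whose retained set,
plus the priority content, fits the bead budget. Records with missing INFO
are treated as 0 — never excludable — so the search fails loudly (budget
infeasibility) rather than silently dropping unassessed content. Bead
accounting follows Infinium chemistry: strand-ambiguous SNPs (A/T, C/G)
and indels need two bead types, other SNPs one; the rule is a plain
function and can be swapped where a design uses different chemistry.

## Synthetic studies

The generator emulates the study conditions end to end: 20 index signals
(a 2/8/1/9 BOTH/ONE/OPPOSITE/NONE mix, i.e. a 16/85/5/94-style split of
200 signals at one-tenth scale), reference pools of 403 NFE / 338 AMR / 149 AA
individuals, and 12 candidates per signal whose per-pool target r² values
cycle through profiles covering every selection regime (LD everywhere, in
NFE plus one minority pool, NFE only, a minority pool only, both sides of
the 0.1 boundary, and none). Haplotypes are drawn per individual from the
exact four-gamete distribution given (p_A, p_B, r²) — by multinomial
sampling by default, or by largest-remainder exact counts where a fixture
must realize its target to O(1/n) (used for boundary-sensitive recovery
tests, where multinomial noise at the smallest pool would otherwise
dominate the 0.05 margin around the 0.1 bound). Annotation, manifest,
designability and INFO tables are allocated with exact criterion fractions,
and ground-truth sidecars are always written so tests compare against
stated intent, not generator internals.

What the generator does *not* emulate: recombination maps (candidates are
conditionally independent given the index), admixture LD, allele-frequency
spectra, genotyping error, or correlated annotation structure. Passing
tests therefore demonstrate that the selection logic is correct under
controlled LD, not that real-data candidate counts would match any
particular study.

The default bead budget (120) was sized from the fixture's own demand so
that every pruning regime is exercised: the priority set always fits and
the prunable set always exceeds the remainder, forcing a non-trivial
threshold search.

## Problem sizes

The bundled studies and checks run at deliberately modest scale — 20
signals, ~260 panel variants, pools of a few hundred individuals, 50-seed
replicate loops — chosen so the full suite and the acceptance script
each complete in seconds while still exercising every code path at the
reference pool sizes.

## Known limitations

* No liftover, no X chromosome (index signals are autosomal by design).
* Window clipping at position 1 only; chromosome-end clipping is not
  attempted (end coordinates are not known to the tool).
* The frequency gate is applied only in the coding/regulatory arm; a
  config flag (`apply_frequency_filter_fine_mapping`) can extend it to the
  LD arm, off by default.
* Manifest matching ignores strand; INFO definitions vary across tools;
  the designability cutoff is a convention, not a vendor constant.
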