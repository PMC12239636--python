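# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Cross model and genotype coding

The simulated pedigree is UT♀ × AZ♂ (P0) → 15 F1 intercross pairs → F2.
Because both P0 individuals are homozygous representatives of their
populations, all F1s are genetically identical (AZ/UT heterozygous on the
autosomes; F1 females X^AZ/X^UT, F1 males X^UT/neo-Y^AZ), and F1 family
structure affects only bookkeeping. The analysis treats F2s as
exchangeable, which the generator's family labels allow one to revisit.

Genotypes are coded as AZ-allele dosage after polarization (AA = 2 AZ
alleles, BB = 2 UT alleles). Hemizygous male X calls are emitted as the
homozygous-appearing code of the single inherited haplotype, which is what
a diploid genotype caller produces.

## Meiosis

Per meiosis and chromosome, the crossover count is Poisson with mean equal
to the map length in Morgans (no interference; consistent with the Haldane
map function used in estimation), positions are uniform in genetic
coordinates, and bp positions follow by inverting the chromosome's
piecewise-linear Marey curve. Recombination suppression therefore emerges
from the curve shape rather than from a separate mechanism. The X does not
recombine in males — a male has only one X — so the F1 father transmits his
X verbatim to daughters.

## The default genome

Twelve chromosomes: 11 acro/telocentric autosomes (20–40 Mb; distal 30% of
bp carries 10% of the map, a pericentromeric end) of 90.2 cM each, plus a
metacentric 64.7 Mb X of 77.0 cM whose 26–48 Mb interior is strongly
suppressed (~0.25 cM/Mb) — total 1,069.2 cM. The X's first 26 Mb is the
neo-Y-similar region where male calls can appear heterozygous through
neo-Y read contamination. Reference-discordant inversions are placed on
chromosome 2 (3.7 Mb), chromosome 3 (5.5 Mb) and the X (18 Mb, 40.5–58.5
Mb): marker coordinates are reported in reference space while inheritance
follows the true (reflected) arrangement. The default marker panel is 822
sites spread proportionally to physical length with ≥100 kb spacing,
emulating a thinned ddRAD panel. Default phenotype model: X-linked
generation time with class means 149 d (AZ-hemizygous males), 76 d
(UT-hemizygous males and UT/UT females), 90 d (heterozygous females;
partial dominance of the short-generation haplotype), residual SD 10 d;
body size is 20 equal-effect autosomal loci summing to a 0.09 mm AZ–UT
difference plus 0.05 mm noise — deliberately below what the default sample
size can detect, providing a negative-control regime.

Observation noise defaults: mis-genotyping 0.001 per call (uniform over
wrong codes), missingness 0.05, neo-Y contamination 0.10 for male X calls
in the similar region, DP/GQ drawn around 40/60. Noise order: error, then
contamination (overrides to heterozygous), then missingness.

## Viability selection

The default viability model removes F2 males whose maternal X recombined
in 26.9–49.0 Mb (survival 0), matching the observed crossover-free male
interior; rejection re-draws the male's gametes, so cohort size and sex
ratio are unchanged — the generator reproduces the observable genotype
pattern, not the demographic cost of lethality. When an inversion straddles
the region, the veto applies to the closure of the region plus the image of
their overlap, because reference-adjacent markers inside the region span
the inverted segment in true coordinates; without this, crossovers vetoed
"in the region" could still surface between region markers. Null analyses
pass `viability=None` explicitly.

The region carries only ~7.4 cM under the default X curve (consistent with
a ~7–8% female recombinant fraction there), so the whole-X male/female map
comparison needs large cohorts to be well powered: the acceptance test uses
3,000 F2s per replicate (~99% per-replicate power) rather than study-scale
cohorts, for which power is only ~70%.

## Linkage maps

Two-point recombination fractions are maximum-likelihood via EM on
phase-known F2 transmission tables: 3×3 genotype-pair tables for
autosome–autosome pairs (two independent meioses), direct discordance of
maternal origins for X–X pairs, and the shared maternal meiosis only for
mixed pairs. Multipoint maps use the forward–backward EM described in the
README, iterated to |Δ log-likelihood| < 1e-6 (max 1,000 iterations; the
likelihood is asserted non-decreasing each step). Initial fractions come
from adjacent-marker discordance. Calls whose posterior error odds exceed
10^4 (error-LOD > 4, configurable) can be masked, after which the map is
re-estimated once; the same masking (`clean_genotypes`) is applied before
obligate crossover counting, which is otherwise inflated by single bad
calls (one flipped homozygote mimics a double crossover).

Marker-order validation starts from physical order and hill-climbs with
single-marker relocation, accepting only strict reductions of the chained
two-point map length (deterministic left-to-right scan; ties keep the
current position). Relocation alone cannot unwind a long reversed block —
a segregating inversion is a deep local optimum for it — so segment
reversal (2-opt) moves follow, and each chromosome is finally oriented so
physical position ascends on balance. Markers whose strongest linkage LOD
lies on another chromosome are removed before ordering.

Sex-specific maps re-run the final map step on each F2 sex separately; no
normalization is needed because both sexes inherit exactly one maternally
recombined copy of every chromosome.

## QTL scan

Genotype probabilities at markers and pseudomarkers (1 cM grid by default)
come from one forward–backward pass with pseudomarkers as all-missing
emissions. At each position a normal mixture with known mixing weights is
fitted by EM (common variance; means per class, or per sex × class on the
X) to tolerance 1e-6. Permutation thresholds use within-sex shuffles for
the X and unrestricted shuffles for autosomes, with the α budget split by
map length. The Bayes credible interval normalizes 10^LOD over the
chromosome grid and grows greedily from the peak. At very large effect
sizes (the default QTL is ~7 residual SD) the posterior is nearly
degenerate and the interval spans one or two grid cells; the grid must then
resolve the posterior width for the interval to have meaningful coverage —
the coverage analyses scan the X at 0.1 cM for this reason.

## Marey maps and the landscape

Inversion calls are maximal runs of ≥11 consecutive markers with strictly
decreasing bp in map order (equal-bp neighbours break runs); endpoints are
the run's min/max bp and calls are labelled putative — a call cannot
distinguish a real segregating inversion from a reference mis-scaffold.
Local rates come from a tricube-weighted local quadratic fit of cM on Mb
(span 0.7), differentiated at each marker; negative rates are retained.
Gene density counts protein-coding genes by start coordinate in half-open
500 kb windows (window membership by start keeps window sums equal to the
total gene count). Before the rate–density OLS, markers with a negative
rate whose residual from the chromosome's local rate trend exceeds 3×MAD
are excluded and reported — a deterministic operationalization of removing
isolated negative-rate outliers.

On estimated maps, inversion recovery is partial when part of the inverted
block lies in a recombination plateau: marker order is statistically
unidentifiable at ~0 cM spacing, so the decreasing-bp run fragments. The
exact-endpoint acceptance check therefore runs on the ground-truth Marey
table (true genetic positions vs reference coordinates), which is the
infinite-sample limit of the estimated map.

## Crossovers, sex comparisons, coverage

Obligate crossover counts are the minimal number of exchanges consistent
with the non-missing codes: on the X, transitions between consecutive
resolved maternal origins; on autosomes the summed absolute dosage change,
which equals the exhaustive minimum over phase assignments (verified by
enumeration). Sex comparisons use the two-sided Mann–Whitney test in its
tie-corrected normal approximation, reporting W as the female sample's
U statistic (conventions differ across software; this one is fixed here),
Bonferroni-corrected over 12 linkage groups. Haplotype frequencies among
non-recombinant males get a two-sided exact binomial test against equal
transmission.

Coverage windows are half-open 50 kb bins of mean depth, normalized by the
sample's autosomal mean (so the male/female ratio is interpretable and
invariant to library size). Strata thresholds — hemizygous ≤ 0.6,
similar ≥ 0.85, runs shorter than 5 windows absorbed into the longer
neighbour — are an explicit operationalization of a visual classification
and are configuration-exposed.

## Problem sizes used in tests

Unit tests run on 60–250-individual crosses with 100–400 markers; the
statistical acceptance checks use 181–180 F2 × 822 markers for map/QTL
recovery, 50 replicates for interval coverage and the viability signature
(3,000 F2 each for the latter), and 200 replicates for both null
calibrations (reduced 5-chromosome genome, n = 120–180, 100 permutations
per replicate).

## What passing tests do and do not show

The generator reproduces the cross's inheritance constraints, the
contamination artifact class, pericentromeric suppression, and
reference-discordant inversions. It does not model linked-read artifacts,
allele-specific depth, segregation-distorting loci, crossover
interference, F1 family-level genotype correlation, neo-Y gene content, or
any demographic consequence of male lethality. Passing tests show the
estimators recover the parameters of this generative model at the stated
sizes — not that any particular biological mechanism holds in real data.

## Known limitations

* Marker ordering is a local search; pathological rf matrices can leave it
  in a suboptimal order, and order within zero-recombination stretches is
  arbitrary by construction.
* The error HMM assumes a symmetric, call-independent error process;
  systematic allele-biased errors would violate it.
* The X analysis assumes the paternal X is constitutively UT (forced by
  the cross design); other designs need a different phase resolution.
* Two-point estimates for mixed autosome–X pairs use only the maternal
  meiosis and are correspondingly noisier.
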