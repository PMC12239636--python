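# neoxqtl

Linkage mapping, QTL scanning and recombination-landscape analysis for F2
intercrosses in species with **neo-sex chromosomes** — built around the
design of a mountain pine beetle (*Dendroctonus ponderosae*) cross between
a long-generation-time southern (AZ) population and a short-generation-time
northern (UT) population.

## Who this is for

Geneticists analysing reduced-representation genotypes (e.g. ddRAD) from an
F2 intercross where the X is a neo-X: males are hemizygous, the neo-Y still
cross-maps onto part of the neo-X, and the cross design makes certain X
genotypes impossible. The package covers the full desk-side chain from a
genotyped VCF to maps, QTL scans and crossover statistics — plus a
simulator that reproduces the cross's inheritance structure so every stage
is testable without any sequencing data.

## The model

**Cross design.** P0 is a UT female × AZ male. Every F1 is heterozygous
AZ/UT along all autosomes; F1 females carry X<sup>AZ</sup>/X<sup>UT</sup>,
F1 males a single maternal X<sup>UT</sup> beside an AZ neo-Y. Hence each F2
inherits exactly one maternally recombined X; the F1 father contributes one
intact X<sup>UT</sup> to daughters and the neo-Y to sons. Two X genotype
classes are therefore impossible: heterozygous F2 males and AZ/AZ F2
females — their presence flags neo-Y read contamination or bad markers, and
the QC stage removes them exactly as a cross-design validation should.

**Maps.** Multipoint genetic maps come from an EM-fitted hidden Markov
model. On autosomes the hidden state is the ordered pair of gamete origins
(4 states, transition probability `r` per gamete per interval); on the X it
is the single maternal-gamete origin (2 states, emissions depend on sex).
Genotyping error enters as a symmetric emission error `ε` (default 0.001);
recombination fractions convert to cM through the Haldane map function,
`d = −50 ln(1 − 2r)`.

**QTL scan.** Standard single-QTL interval mapping: at each grid position
the phenotype is a normal mixture over putative QTL genotypes with weights
from the flanking-marker HMM, and

```
LOD(c) = log10 [ L(mixture at c) / L(single normal) ].
```

On the X the classes are the maternal origins {UT, AZ}, sex is a covariate
in the null, and permutations are stratified by sex. Significance
thresholds split the genome-wide α between autosomes and X by map length:
α_X = 1 − (1−α)^(L_X/L_T). QTL location uses a 0.95 Bayes credible
interval on the normalized 10^LOD posterior.

**Recombination landscape.** Marey maps (bp vs cM per marker) detect
putative inversions as runs of >10 consecutive markers with decreasing
physical position in map order; local recombination rate is the derivative
of a tricube-weighted local quadratic regression (span 0.7) and is
regressed on protein-coding gene density in 500 kb windows.

**Crossovers and coverage.** Obligate (minimal) crossover counts per F2
per chromosome feed Wilcoxon rank-sum sex comparisons with Bonferroni
correction over the 12 linkage groups; male/female normalized read depth in
50 kb windows stratifies the X into neo-Y-similar, intermediate and
hemizygous segments.

## Worked example

```python
from neoxqtl.config import RunConfig, SimStage, ScanStage
from neoxqtl.pipeline import run_pipeline

cfg = RunConfig(seed=1,
                simulate=SimStage(n_f2=120, n_markers=400),
                scan=ScanStage(n_perm=200, phenotypes=["generation_time"]))
summary = run_pipeline(cfg, "out/")
```

This simulates a 120-individual F2 cross at 400 markers under the study
conditions (X-linked generation-time QTL with hemizygous-male means 149 vs
76 days, neo-Y contamination over the first 26 Mb of the X, lethality of
male recombinants in 26.9–49.0 Mb), then runs QC → map → scan → Marey →
crossovers → coverage. Selected `summary.json` values from that exact run:

```
linkmap.total_cm                 1028.9      # vs 1,069.2 cM simulated truth
linkmap.male_x_cm / female_x_cm  15.0 / 46.8 # male X map shorter, as designed
scan.generation_time.peak_chrom  "X"
scan.generation_time.peak_lod    49.4        # thresholds: auto 3.74, X 4.75
scan.generation_time.significant true
xo.focal_region                  0/56 males vs 8/64 females with a
                                 crossover in 26.9–49.0 Mb
coverage.strata                  similar 0–26 Mb, intermediate 26–48 Mb,
                                 hemizygous 48–64.7 Mb
marey.rate_density.r_squared     0.62        # rate ~ gene density
```

Reading it: the scan finds the X-linked QTL far above the X-specific
permutation threshold; the male X map is much shorter than the female map
because contaminated markers over the neo-Y-similar region are filtered
out and surviving males carry no crossover in the focal region; the
coverage stratification recovers the three designed neo-X/neo-Y
differentiation strata. The male/female X map lengths mirror the kind of
sex asymmetry the design produces, not universal biology — see
`docs/methods.md` for what the simulator does and does not emulate.

A CLI mirrors the stages: `neoxqtl simulate|qc|map|scan|marey|coverage|run-all`.

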