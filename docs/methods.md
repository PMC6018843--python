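# Methods

This note documents the models, parameter choices and numerical conventions
behind fuzzmap, and what the synthetic-data generator does and does not
emulate.

## Phenotype and genotype conventions

The quantitative trait is the fuzz percentage,
`100·(ginned − delinted)/ginned`, in percent of ginned seed weight.
Visual fuzz classes have no published quantitative boundary, so the class
cut-offs are configuration: fuzzless below 1.5 %, intermediate below 6.0 %,
normal otherwise. The defaults sit between the ~2.7 % mean of fuzzless-type
accessions (range 0.29–9.2 %) and the 10–12 % of normal-fuzz cultivars;
both are exposed in `FuzzClassCutoffs` / the run config.

Genotypes are parental-origin codes: donor homozygote 1, heterozygote 0.5,
recurrent homozygote 0, missing NaN. Missing codes are excluded from every
downstream mean, never imputed; each operation reports the count used. The
mean code of a pool equals its donor-allele frequency, which makes array
pools (mean of genotype codes) and sequencing pools (donor reads / total
reads) directly comparable.

Coordinates are 1-based for marker and VCF positions on input, and 0-based
half-open for all window and region intervals (BED convention). Conversion
happens only in the I/O layer.

## Segregation tests

A trait requiring donor homozygosity at k unlinked loci appears in (1/4)^k
of a selfed F1's progeny. Observed {mutant, non-mutant} counts are tested
with the uncorrected two-class Pearson χ² (df = 1, upper-tail p). No Yates
correction is applied — the uncorrected statistic is the one used in the
classical segregation literature and is what the package's worked examples
reproduce. Model selection over a k-range simply maximizes the p-value,
breaking ties toward smaller k; this formalizes "which ratio fits best" and
is not a calibrated model-selection procedure (no penalty for k, no
likelihood).

## Sliding-window scan and region calling

Windows are anchored at position 0 of each chromosome and advance by the
step (defaults 1 Mbp / 500 kb); the trailing partial window is emitted. A
window's value is the unweighted mean of per-marker frequencies whose
(0-based) position falls in [start, start + window); windows with fewer
than `min_snps_per_window` markers are undefined and can never qualify.
Variant filtering precedes the scan: coverage ≥ 10, variant reads ≥ 3,
variant frequency ≥ 35 % (all boundaries inclusive); indels are flagged on
input and dropped by default.

Dual-bulk calling quantifies two qualitative expectations: over a causal
locus, a recessive (fixed-mutant) pool sits at donor frequency "1 or close
to 1" and a segregating pool at "~0.5". Defaults: high threshold 0.9,
segregating band [0.35, 0.65], normal-pool maximum 0.5 (array mode),
minimum run of 2 consecutive qualifying windows. Undefined windows break
runs. The segregating-band clause is what rejects regions fixed for donor
alleles by inbreeding drift (such regions show ~0 or ~1 in the segregating
pool). Raising the high threshold can only shrink or remove regions —
a monotonicity that is property-tested.

The intersection of sequencing-bulk (MBS) and array-pool candidate sets
keeps interval intersections with evidence `both` and retains
single-source regions unchanged, so no evidence is silently discarded.

## Association and effect classification

F2 plants are grouped at each marker by genotype code; pairwise group
contrasts use a two-sided Student's t-test with pooled variance (the
equal-variance form; Welch behind a flag), no multiple-testing correction
by default (per-marker reporting; Bonferroni optional), minimum testable
group size 3. Whether the original analysis assumed equal variances or
corrected for multiplicity is not documented; these are this package's
stated assumptions. Effect calls from the contrast pattern at level α:
suppressor (donor homozygote mean significantly lower than recurrent),
enhancer (significantly higher), additive_major (additionally the
heterozygote mean strictly between both homozygote means and significantly
separated from each — strict betweenness, not a midpoint test), otherwise
none.

## Expression dosage model

Relative expression is unit-free; a ΔCt converter (2^(Ct_ref − Ct_target),
perfect doubling, no per-primer efficiency correction) is provided for
convenience. When only total and Dt-homoeolog levels are assayable, the At
level is total − Dt; Dt may exceed total by at most 5 % of total
(measurement noise), which clamps At to 0 with a warning — larger excess is
an inconsistent-measurement error.

The classifier has two gates with user-supplied thresholds (the thresholds
are biological unknowns): total expression at ~0 dpa below threshold 2 →
fibreless; otherwise Dt at ~3 dpa below threshold 1 → fuzzless but linted;
otherwise fuzzy. The decision order makes the lintless-but-fuzzy cell
unreachable, encoding the empirical epistasis of fuzz over lint (no such
mutant has been reported); a unit test asserts unreachability over a grid
of inputs. The classifier is monotone along both expression axes.

## Synthetic populations

The generator exists so every stage is testable without restricted data;
its defaults are the study conditions the pipeline assumes.

**Genome and meiosis.** 26 chromosomes (A01–A13, D01–D13) × 60 Mb, one
marker per 250 kb (~6 240 markers, the same order as the ~5 400 informative
array SNPs of the motivating study), plus a marker at every causal
position. The genetic map is uniform 1 cM/Mb under Haldane (no
interference): per chromosome the crossover count is Poisson(length in
Morgans) with uniform positions — the simplest model consistent with the
absence of a published map for this material. Meiosis is validated against
the Haldane closed form (1 − e^(−2d))/2 and independent assortment.

**Trait architecture.** The default model plants five loci on five
chromosomes: three required-recessive loci (mutant phenotype requires donor
homozygosity at all three), one additive major locus (−2.5 fuzz points per
donor copy) and one enhancer (+3 points when donor-homozygous). Each
required locus also subtracts 2 points when donor-homozygous in non-mutant
individuals, mirroring the observed per-locus group contrasts. Effect sizes
were chosen once so that genotype-group contrasts are detectable in an F2
of ~170 plants at noise σ = 1.5 fuzz points.

**Phenotype.** A mutant (all required loci donor-homozygous, passing a
penetrance draw; default penetrance 1.0, sub-unity available to emulate
incompletely fuzzless families) draws residual fuzz |N(0.7, 0.4)| percent —
anchored to the low end of the fuzzless-accession range, a configuration
value, not a measured fact. Everyone else draws baseline 11 % plus locus
effects plus N(0, 1.5), truncated to [0, 100]. Note P(|N(0.7, 0.4)| < 1.5)
= Φ(2) ≈ 0.977, so ~2 % of true mutants are scored intermediate; and
plants stacking several donor-homozygous suppressor/additive alleles can
drop below the fuzzless cut-off without being mutants. Both behaviours are
faithful to a polygenic trait scored by threshold — they make observed
mutant counts a slightly noisy readout of the underlying k, exactly the
ambiguity (two- vs three-gene fits in different backgrounds) the original
segregation data show.

**Pedigrees.** The F2 design selfs the donor × recurrent F1. The NIL
design backcrosses an F1 four times to the recurrent parent with
marker-assisted retention of ≥ 1 donor allele at every causal locus, then
selfs four generations (BC4F5 parents, BC4F6 progeny) while driving the
causal loci to a target state: homozygous-donor ("fuzzless" NILs),
heterozygous ("segregating" NILs) or homozygous-recurrent ("normal" NILs).
The real programme selected on phenotype during backcrossing; marker
retention is a reproducible stand-in with the same genetic consequence
(donor alleles preserved at causal loci on a recurrent background).
Selection uses bounded retry/batch search (4 096 progeny cap per
generation, up to 6 extra selfing generations) and errors out rather than
silently relaxing the target.

Each cohort pools progeny of **four independently backcrossed lineages**
(progeny split evenly across lineages). This matters: a single lineage
fixes unlinked donor segments by drift, and when the same founder feeds
both bulks those segments reproduce the fixation-driven false-positive
regions the dual-bulk criterion is meant to reject. Independent lineages
fix different segments, so pooling suppresses them — the multi-NIL bulk
composition of the original design, not an extra assumption.

**Bulks and sequencing.** Recessive bulks sample only fuzzless-class
individuals (default 15), segregating bulks sample progeny of heterozygous
NILs regardless of phenotype (default 24); sampling is without replacement
and errors when too few individuals are eligible. Pooled sequencing is
emulated per marker as coverage ~ Poisson(depth, default 30×) and donor
reads ~ Binomial(coverage, p(1−e) + (1−p)e) with per-read error e (default
0). All generators are bit-reproducible under a fixed seed.

**What is not emulated.** No sequence-level artifacts (mapping bias,
duplicated/homoeologous read misassignment, base errors beyond the
symmetric e), no environmental effect on fuzz, no segregation distortion,
no marker misplacement (the study manually removed three misassigned array
markers; users must curate marker maps). Passing tests therefore show the
statistical machinery behaves correctly under the stated sampling models,
not that it is robust to those real-data artifacts.

## Problem sizes used in validation

The study-scale recovery check runs the full default conditions — 26 × 60
Mb genome, ~6 245 markers, F2 of 169, bulks of 24/15 at 30× depth, error
0 — for three fixed seeds (~2 s per replicate); the two-class χ²
enumeration covers every outcome at n ≤ 12; window oracles run 200
randomized small chromosomes; the segregating-bulk expectation averages
200–500 seeded replicates of 24-progeny bulks. Sizes were chosen to make
the checked expectations sharp (binomial standard errors well inside the
asserted tolerances).

## Known limitations

- The window scan reports no confidence measure per window or region; the
  dual-pool thresholds are the only evidence filter.
- Model selection over k has no complexity penalty; with phenocopies the
  best-fitting k can sit below the number of planted required loci in a
  given draw.
- The additive/enhancer classification depends on per-marker t-tests at a
  user α; it is a labelling of contrast patterns, not an effect-size
  estimator.
- `n_selfs` below ~3 leaves enough residual heterozygosity in NIL
  backgrounds that occasional drift-fixed false-positive regions appear
  even with multiple lineages.
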