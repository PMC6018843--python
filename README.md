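# fuzzmap

Genetic dissection of a recessive, multilocus seed-fibre trait by
bulk-segregant analysis, for geneticists and breeders mapping traits in
biparental populations of an allotetraploid crop (the motivating system is
the fuzzless-seed trait of Pima cotton introgressed into an upland cotton
background).

Cotton seeds bear two fibre types: long lint (initiating at ~0 days
post-anthesis) and short fuzz (~3–4 dpa). The quantitative phenotype is the
**fuzz percentage**

> FP = 100 · (W_ginned − W_delinted) / W_ginned,

~10–12 % in normal-fuzz cultivars and near zero in fuzzless material. The
trait is recessive and multilocus: in a selfed F1, a phenotype requiring
donor homozygosity at *k* unlinked loci appears in (1/4)^k of F2 plants —
a (4^k − 1):1 ratio tested with an uncorrected two-class Pearson χ² on 1 df.

The mapping engine codes every genotype by parental origin (donor
homozygote 1, heterozygote 0.5, recurrent homozygote 0) so that the mean
code of a pool is its **donor-allele frequency**. Two pools are scanned in
1-Mbp sliding windows (500 kb step): a *recessive* bulk of fixed
mutant-phenotype progeny, expected at frequency ≈ 1 over a causal locus,
and a *segregating* bulk from progeny of a heterozygous parent, expected at
≈ 0.5. Windows with recessive frequency ≥ 0.9 and segregating frequency in
[0.35, 0.65] merge into candidate regions; the ~0.5 requirement discards
loci merely fixed by inbreeding drift. An analogous caller handles
array-genotyped pools (reduced-phenotype pool ≥ 0.9, normal pool < 0.5),
and the two evidence sets can be intersected.

Around the scan the package provides: pooled-variant filtering (coverage
≥ 10, variant reads ≥ 3, frequency ≥ 35 %), segregation-model selection
over *k*, per-marker association of genotype class with fuzz percentage
(pooled-variance Student's t) with enhancer / suppressor / additive-major
effect classification, a two-threshold homoeolog expression dosage
classifier (total expression at ~0 dpa gates lint; Dt-homoeolog expression
at ~3 dpa gates fuzz), and a fully seeded synthetic-population generator
(Haldane map, 1 cM/Mb) that emulates the F2 and backcross-derived NIL
designs end to end.

## Worked example

Run the whole simulated workflow — F2 segregation and association plus
NIL bulking, pooled sequencing, window scan and region calling — with the
default five-locus architecture (three required-recessive loci, one
additive major locus, one enhancer, on 5 of 26 chromosomes):

```sh
fuzzmap run --seed 1 --out demo/
# done: 4/5 planted loci recovered, summary at demo/summary.json
```

The segregation table (`demo/segregation.tsv`) for this seed counts 4
fuzzless plants among 169 F2 and prefers the three-gene model:

```
k  ratio   chi2     df  p
1  3:1     46.1716  1   0.0000
2  15:1    4.3491   1   0.0370
3  63:1    0.7109   1   0.3991
4  255:1   16.9631  1   0.0000
```

i.e. only the 63:1 expectation is not rejected (χ² = 0.711, p = 0.399).
The association stage classifies every planted locus from its genotype-group
contrasts — the enhancer locus shows donor homozygotes with *more* fuzz,
the additive locus shows the heterozygote mean strictly between both
homozygote means and separated from each:

```
A08_20000000  enhancer
A10_30000000  suppressor
D05_35000000  suppressor
D07_25000000  suppressor
D12_50000000  additive_major
```

and the dual-bulk scan (`demo/regions_mbs.bed`) calls 8 regions, all on
planted chromosomes, covering 4 of the 5 planted loci, e.g.
`D12  46000000  50500000  MBS  9` over the additive major locus.

Individual stages are available as subcommands (`simulate`, `filter`,
`scan`, `call-regions`, `intersect`, `segregate`, `associate`, `dosage`)
and as library functions; e.g. the printed-value check

```python
>>> from fuzzmap import ratio_chisq
>>> r = ratio_chisq(3, 169, k=3)
>>> round(r.chi_square, 4), round(r.p_value, 4)
(0.0497, 0.8236)
```

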