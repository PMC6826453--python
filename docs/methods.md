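# Methods

## Scope and data model

`diagpanel` operates downstream of variant calling: the inputs are a
genotype matrix (individuals × biallelic SNPs, codes HOM_REF/HET/HOM_ALT/
MISSING) with two-species population labels, and a RAD-tag catalog
grouping SNPs into short tags (36 bp by default, the AlfI 2b-RAD fragment
length) with genome-alignment hit counts. Read demultiplexing, locus
assembly and SNP calling are out of scope; so are external-primer design
and thermodynamic multiplex checks.

Coordinate dialects are fixed: internal tag offsets are 0-based, VCF POS
is 1-based, BED intervals are half-open 0-based. Population labels travel
in a two-column sidecar sample map because VCF has no standard population
field. Tags without a unique placement are written under the synthetic
contig `tag:<tag_id>` so multi-mapping tags stay representable — the
cascade must be able to count them before discarding them. Missing is a
first-class genotype code everywhere; nothing is imputed. The CSV matrix
dialect carries no allele columns, so loci read from CSV receive
placeholder alleles (A/C); all downstream statistics use call codes only.

## SNP categories and the filter cascade

Per locus and species we compute, from non-missing calls only: the number
of called individuals n, the reference-allele frequency p, the observed
heterozygosity Ho, the expected heterozygosity He = 2p(1−p), and
MAF = min(p, 1−p). Categories:

* **DIAGNOSTIC** — observed fixed for alternative alleles (p = 1 in one
  species, p = 0 in the other) with both per-species call-count minima
  met;
* **PRIVATE_A / PRIVATE_B** — polymorphic in one species, monomorphic in
  the other (the MAF spectrum of private SNPs is evaluated in the
  polymorphic species; in the other it is identically 0);
* **SHARED_POLY**, **MONOMORPHIC**, **UNCLASSIFIED_LOW_CALLS** as named.

Fixation is defined on observed calls (sample-fixed), not via a frequency
threshold; the per-species minimum call counts (defaults 30 species-A /
15 species-B, i.e. a quarter and a half of the default sample sizes)
carry the sampling-depth burden. Category percentages are kept at full
precision internally and rounded to one decimal only for display.

The cascade applies, in order, recording (n_in, n_out) per stage:

1. **diagnostic** — observed fixation, evaluated with a relaxed one-call
   minimum so that the call-count filter below is the only stage that
   enforces depth (each provenance row thereby isolates one filter; final
   markers still satisfy the full DIAGNOSTIC definition);
2. **single_snp_tag** — the diagnostic SNP must be its tag's only
   diagnostic SNP and the tag must carry no other observed polymorphism
   (within-tag variation would compromise primer sites);
3. **call_count** — the per-species minima;
4. **unique_alignment** — tag hit count must be 1;
5. **random_subset** — optional uniform draw without replacement, seeded,
   for the final assay-sized panel.

Counts are monotone non-increasing by construction and the final panel
records the allele fixed in each species plus the genome placement.

## F_IS and the permutation test

F_IS = 1 − Ho/He per locus; the global estimate uses ratio-of-sums
weighting, 1 − ΣHo/ΣHe over loci with He > 0 (monomorphic loci are
excluded, with the count reported). This estimator is deliberately simple
and is not Weir–Cockerham; it is documented, testable, and exactly what
the permutation test recomputes. The one-sided test shuffles the 2n
alleles of the called individuals within each locus and re-pairs them at
random, which preserves allele frequencies (and hence He) while
destroying the within-individual correlation that creates heterozygote
deficit; p = (1 + #{null ≥ observed}) / (1 + n_perm) is never exactly
zero and is reported as "< 1/(1+n_perm)" at the floor.

## Hybrid classification and power

Diagnostic loci are assumed unlinked (motivated by the unique-alignment
filter) and exchangeable, so each class needs one genotype triple over
(AA, AB, BB): pures (1,0,0)/(0,0,1), F1 (0,1,0), F2 (¼,½,¼), backcrosses
(½,½,0)/(0,½,½). Only first-generation classes are modelled; repeated
backcross generations converge on the pure classes and are statistically
indistinguishable from them at a handful of loci. A symmetric genotyping
error ε (default 0.001) moves each triple to g(1−ε) + (1−g)·ε/2 per
genotype, so one miscall cannot produce a −∞ log-likelihood cliff.
Classification is MAP under a configurable prior (uniform by default,
since wild hybrid frequencies are unknown), normalised in log space; ties
are broken by the fixed class order PURE_A, PURE_B, F1, F2, BC_A, BC_B
and flagged. Missing loci are dropped per specimen and the effective
locus count is reported so power can be re-read at that L.

Analytic power: the probability that a class yields a multilocus genotype
identical to some pure species is (½)^L for backcrosses, 2·(¼)^L for F2,
0 for F1, 1 for pures; detection power is the complement, and
`min_loci_for_confidence` inverts it. At L = 7 the worst hybrid class
(backcross) reaches power 0.9922; the package reports per-class values
and takes the worst case when a single bound is wanted.

## Multiplex tail design

Extension products of a single-base-extension multiplex are separated by
length, so internal primers receive 5′ tails built from a repeated 4-nt
unit (default "gact", configurable) and possibly truncated. The greedy
scheme sorts cores by length, gives the shortest a zero tail and each
next primer the smallest tail placing it at least `min_spacing` (default
4 nt) above the previous total; the output is deterministic and
independent of input order. `validate_set` checks pairwise spacing and
tail pattern of any set, including hand-designed ones such as the bundled
published nine-primer cockle set (totals 22–74 nt). Cross-dimer
thermodynamics are intentionally not modelled.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with exact (largest-remainder) allocation of SNPs to categories so truth
counts match the requested fractions deterministically. Defaults describe
a screen of 120 species-A and 30 species-B individuals over 200 tags
carrying 1–3 SNPs (probabilities 0.50/0.46/0.04); SNP fractions 0.15
fixed differences, 0.12 private-A, 0.73 private-B mirror a pool dominated
by the more diverse species. Within-species genotypes follow the
inbreeding model P(hom ref) = p² + Fpq, P(het) = 2pq(1−F), with default
F = 0.129 (A) and 0.252 (B). Minor allele frequencies are drawn as
0.5·Beta(1, shape); the shapes (3.5 for A, 28 for B) were calibrated so
the *observed* private-SNP spectra at the default sample sizes — after
loci that realise monomorphic drop out — show roughly 28% (A) and 70% (B)
rare alleles (MAF < 0.05), reproducing a strong interspecific contrast in
rare-allele load. Missingness is i.i.d. per call (default 5%), and 23% of
tags are flagged multi-mapping with two genome placements. Hybrid
specimens are drawn i.i.d. per locus from the class triples with ε
applied.

What the generator does **not** emulate: linkage and LD between tags,
locus-specific call-rate structure (dropout correlated with divergence,
null alleles — a likely real cause of heterozygote deficit), sequencing
or PCR error beyond the symmetric ε, demography/coalescent correlation
among loci, and later-generation introgression. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to those real-data effects.

## Numerical and testing choices

Frequencies are computed in double precision with NaN marking undefined
values (zero called individuals, He = 0). Posteriors are normalised via
log-sum-exp; posterior ties use an exact-equality tolerance of 1e−12
relative. All randomness flows through `numpy.random.default_rng` seeds
carried in configs, so every simulation, subset draw and permutation test
is reproducible; identical seeds give byte-identical outputs.

Test problem sizes are chosen to make the statistical assertions sharp at
desk scale: truth-set recovery on 200 single-SNP tags; F recovery at 500
loci × 200 individuals (±0.05); classifier confusion on 2000 specimens
per class at 7 loci against analytic rates within 3 binomial s.e.;
permutation-null calibration over 200 replicates of 30 loci × 40
individuals with 199 permutations, checked by a Kolmogorov–Smirnov test
at α = 0.01 (the add-one discretisation of p on a 199-permutation grid
biases the KS statistic by at most 1/200, well inside the criterion).

## Known limitations

* The classifier cannot separate later-generation backcrosses from pures;
  a specimen called pure may still carry introgressed material.
* Diagnostic status is sample-relative: markers fixed in the screening
  sample can be polymorphic in unsampled parts of a species' range, so
  validation on wider geographic samples remains necessary.
* The F_IS permutation test targets heterozygote deficit specifically and
  is one-sided; it is not a general HWE test.
* `assign_tails` guarantees spacing, not primer chemistry; designed sets
  should still be screened for cross-dimers before ordering oligos.
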