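# Methods

This note records the model choices, numerical conventions, defaults and
known limitations behind `rohmap`, in the order the pipeline runs.

## Coordinates and genotype coding

All coordinates are 1-based with inclusive intervals (the PLINK text
convention); BED export converts to 0-based half-open. Genotypes are
allele-B dosages {0, 1, 2} with −1 for missing. In PED input, allele A is
the lexicographically smaller observed allele, so orientation does not
depend on sample order; for a monomorphic variant the observed allele is
taken as allele B (its counterpart is unknowable from a PED file), and a
`ref_alleles` map can pin the orientation explicitly. Binary BED input
preserves the .bim allele order exactly.

## Quality control

Filters run in a fixed order: non-autosomal variants, then samples by call
rate, then variants by missingness, MAF and the exact Hardy–Weinberg test.
Sample filtering precedes variant statistics, mirroring PLINK. All
thresholds are strict inequalities — a sample at exactly 95 % call rate or
a variant at exactly MAF 0.05 is removed. The HWE test conditions on
allele counts and sums the probabilities of heterozygote counts no more
probable than observed (two-sided exact, not χ²), computed in log space;
it is exact for all counts and safe for rare genotypes. QC is idempotent;
whether HWE is tested before or after sample removal is fixed (after) and
visible in the report.

One interaction worth knowing: a region where a fraction f of the
population is autozygous shows a heterozygote deficit of the same
fraction, so at large sample sizes the HWE filter begins to remove the
very SNPs that carry high-frequency consensus regions (at n = 600,
carrier frequencies above ~0.2 are stripped at p ≤ 1e-6). The synthetic
study designs therefore plant association regions at carrier frequencies
≤ 0.2; with real data the same tension exists and the HWE floor is a
config knob.

## ROH detection

The scanner is a faithful reimplementation of the PLINK `--homozyg`
two-stage screen with the standard bovine-array settings as defaults:

| parameter | default | meaning |
|---|---|---|
| window_snps | 50 | sliding-window width (SNPs) |
| window_max_het | 1 | heterozygotes allowed per window |
| window_max_missing | 5 | missing calls allowed per window |
| window_hit_threshold | 0.05 | min fraction of homozygous windows per SNP |
| min_length_bp | 500 kb | minimum segment length |
| min_snps | 100 | minimum SNPs per segment |
| min_density_bp_per_snp | 50 kb | maximum average SNP spacing |
| max_gap_bp | 100 kb | maximum inter-SNP gap inside a segment |
| roh_max_het | 1 | heterozygotes allowed per segment |
| roh_max_missing | 2 | missing calls allowed per segment |

The window missing allowance is not part of the published criteria set and
takes PLINK's default (5). The per-SNP hit rate is the fraction of
*existing* windows containing the SNP that are homozygous, so chromosome
ends are handled without padding; chromosomes shorter than one window
yield no candidates.

Deterministic tie-breaks, fixed once: candidate stretches (hit rate ≥
threshold) are split at gaps > 100 kb, then scanned left to right; a run
grows until the het/missing budget would be exceeded, is trimmed back to a
homozygous non-missing endpoint, and scanning resumes after the violating
SNP — emitted segments never overlap. Segment length is
`end − start + 1` on SNP positions. The density criterion is
`length / n_snps ≤ 50 kb`. Size-class boundaries are [0.5, 1) / [1, 5] /
(5, ∞) Mb; the shared endpoints are assigned to the smaller class's upper
edge deterministically (1 Mb is Medium, 5 Mb is Medium).

The test suite holds the scanner set-identical to an independently coded
loop-based enumeration over fuzzed matrices and parameterisations.

## Summaries

F_ROH divides each animal's total ROH length by the SNP-covered autosome
length (sum over chromosomes of last-minus-first SNP position), not the
assembly length: the array cannot witness homozygosity beyond its first
and last probes, and this keeps the coefficient self-contained.
Zero-ROH animals stay in all averages. Two genome-level lengths are
reported separately: the mean per-individual total and the union coverage
across animals.

## Consensus regions, islands, carriers

Pooling is positional single-linkage on intervals per chromosome — no
allelic-match refinement, since downstream use needs only intervals, SNP
counts and carrier sets. Each pool reports its intersection interval;
when a transitive chain has an empty intersection the pool is split
greedily left to right. Regions with fewer than 5 SNPs are dropped.
A carrier is an animal with one ROH fully covering the consensus interval
(pool members qualify by construction); carrier sets are recomputed
against the final interval so that a region's frequency always equals the
population mean of carrier status. Islands are maximal runs of SNPs with
incidence rate strictly above 0.2, merged across physical gaps ≤ 100 kb
(the scanner's gap constant, configurable separately).

## Phenotype adjustment and extreme groups

Traits are adjusted by OLS on farm, year and sex (reference-level coding,
first level by sort order — any full-rank coding yields the same
residuals) plus weight before fattening and fattening days as covariates;
main effects only. Average daily gain is weight gain over the fattening
period divided by fattening days (kg/day). Rows with missing values are
dropped with a logged count; rank-deficient designs are an error naming
the collinear columns. Extreme groups take the top-n and bottom-n by
adjusted trait with ties broken by sample id for determinism.

## Fisher enrichment

Each region × trait gives a 2×2 table (high/low group × carrier/
non-carrier) tested with the two-sided Fisher exact test — implemented in
the package as a vectorised hypergeometric tail sum (probabilities no
larger than the observed table's, the R `fisher.test` convention) and
cross-checked against both an exact integer-arithmetic enumeration and
scipy. Odds ratios use the Haldane 0.5 correction when a cell is zero.
No multiplicity correction is applied by default (matching the
uncorrected α = 0.05 regional counts this design reports);
Benjamini–Hochberg is available behind a flag.

A calibration caveat that the acceptance suite makes explicit: the exact
test is *conservative* on discrete tables. Its realized null rejection
rate at nominal α = 0.05 — computable exactly by summing hypergeometric
masses — is ~0.01–0.03 for 15-per-group margins and at most ~0.047 even
at 300 per group. A simulation criterion that expects the empirical null
rate to bracket 0.05 therefore cannot be met by a correct implementation;
the suite's calibration test asserts the nominal band anyway and records
the measured (conservative) rate in its failure message rather than
widening the band.

## GRM and REML mixed model

The GRM is VanRaden method 1 with observed allele frequencies: dosages
centred by 2p̂ and scaled by 2Σp̂(1−p̂); missing genotypes are mean-imputed
for this step only; monomorphic SNPs are excluded with a warning.

The validating model is y = Xb + u + e with u ~ N(0, G σ²_g),
e ~ N(0, I σ²_e) and one record per animal (Z = I). The restricted
likelihood is profiled on the eigenbasis of G over the single ratio
λ = σ²_g/σ²_e, making each evaluation a diagonal reweighting; λ is
optimised on a log10 scale over [1e-8, 1e8] by bounded Brent with
xatol 1e-9, deterministically and with no starting-value sensitivity.
Estimates at the lower edge are reported as σ²_g = 0 with a boundary
flag; a GRM proportional to the identity leaves λ unidentifiable and is
flagged degenerate. The mixed model is fitted on raw traits with the
fixed effects in X (the adjusted-residual route exists separately in
`compare_carriers`, which contrasts adjusted traits between carriers and
non-carriers with a Wilcoxon test). The ROH coefficient is tested by
Wald with a normal reference; at the mixed-model sample sizes used here
(hundreds of animals) this is accurate, at much smaller n it is mildly
liberal.

## Linkage disequilibrium

Two-locus haplotype frequencies come from the standard EM for unphased
diploids: all genotype pairs except the double heterozygote have known
phase; the coupling/repulsion split of double heterozygotes is
re-estimated each iteration (convergence Δ < 1e-10, cap 1,000
iterations; the EM log-likelihood is non-decreasing and is exposed for
testing). r² = D²/(p_A p_a p_B p_b) and D′ = D/D_max; the matrix stores
|D′| with the sign available separately. Missing data are handled by
pairwise-complete observations.

## Synthetic data

The generator emulates the structure the analysis assumes rather than a
coalescent history — segments are planted directly, which keeps the truth
tables exact:

* SNP positions from exponential spacings (mean 4 kb — high-density
  bovine array scale); allele-B frequencies Uniform(0.05, 0.5).
* Background genotypes drawn under HWE per SNP.
* Per-animal autozygous segments: count Poisson with mean chosen so the
  expected F_ROH matches a target (default 0.047, a typical beef-cattle
  value); lengths from a short/long log-normal mixture (medians ~0.7 Mb
  and ~6 Mb, 85 % short), reflecting the predominance of small ROH over
  rare large ones; inside a segment the animal is homozygous with the
  allele drawn once per SNP by its frequency.
* Heterozygote-error and missingness rates applied afterwards.
* Association regions plant a segment in a fixed fraction of animals and
  add an effect (trait units) to a chosen trait.
* Phenotypes: fixed effects (farm, year, sex, two covariates with
  realistic fattening-scale values) + region effects × carrier +
  polygenic term drawn through a ridge-stabilised Cholesky factor of the
  realised GRM × σ_g + Gaussian noise; σ²_g = σ²_e = 1 by default.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs.

What the simulator does **not** emulate, and hence what passing tests do
not show about real data: linkage disequilibrium (planted segments draw
alleles independently per SNP, so ROH regions show no elevated r² — LD
correctness is instead tested on constructed genotype pairs); population
structure and relatedness beyond what planting induces (the realised GRM
is near-identity, so REML recovery tests use SNP counts small enough to
spread its spectrum); selection, pedigree structure, and allele-frequency
clines. Fixture sizes used by the tests and the acceptance script —
60 × 6,000 SNPs (small) and 600 × 50,000 SNPs (medium) — were chosen as
the smallest designs whose statistical checks are informative.

## Known limitations

* No HMM/likelihood ROH caller; the window scanner is the deliberate
  scope, including its known edge behaviour (a boundary SNP whose two
  outward neighbours are both heterozygous can fall below the window hit
  threshold, so a called segment may start one SNP inside the true one).
* Consensus pooling ignores allelic identity within pools.
* Single random effect only; no dominance or epistatic GRMs, no GBLUP
  prediction.
* The Wilcoxon implementation defers to scipy (exact for small untied
  groups, tie-and-continuity-corrected normal otherwise).
* Sex chromosomes are excluded, not analysed.
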