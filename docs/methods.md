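# Methods

This note documents the models behind each stage, the defaults and why
they are set where they are, what the synthetic generator does and does
not emulate, and the numerical choices that matter. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Study design being emulated

A recessive nuclear male-sterility locus segregates in an F2 of 252
plants from a sterile × fertile cross of inbred melon lines. Sterile
plants are homozygous for the sterile-parent (P) allele; fertile plants
are resolved into homozygous (b) and heterozygous (h) classes by growing
F3 families of 15 selfed offspring. Two 30-plant bulks — sterile, and
*homozygous* fertile — are sequenced at roughly 30 reads per marker, and
the causal region is located where the bulks' allele frequencies
diverge. Using the homozygous-fertile class (rather than all fertile
plants) as the second bulk drives Δ(SNP-index) to −1 instead of −2/3 at
the causal locus, which is what makes the 0.6 threshold comfortable.

## Segregation tests

Pearson's X² = Σ(obs − exp)²/exp with expected counts from the integer
ratio, df = k − 1, upper-tail p. **No Yates continuity correction**: the
uncorrected statistic reproduces the F2 values a worked example of this
design prints (2.13 for 48:112 vs 1:3; 1.7251 for 148:502), whereas the
corrected one does not. `classify_inheritance` screens a candidate set
(1:3, 1:1, 7:9, 1:15 in sterile:fertile order) and calls the fit
ambiguous when two passing ratios differ in X² by less than 0.5 — an
arbitrary but fixed tie margin. Type-I error at α = 0.05 under a true
1:3 ratio is checked by simulation (10⁴ replicates, n = 160) and sits
within 0.05 ± 0.01.

## Reduced-representation (SLAF-style) loci

The wet protocol — MseI digestion and adapter ligation, a second
digestion with HaeIII + BfaI that destroys a subset of fragments, then
gel selection of 260–420 bp — is modeled by its selective effect: keep
every MseI–MseI fragment whose length is in the window and whose
sequence contains no internal HaeIII/BfaI site. Digest scanning is exact
overlapping motif search; built-in motifs (TTAA, GGCC, CTAG) are
palindromic so one strand suffices, and user enzymes with
non-palindromic motifs are scanned on both strands with the mirrored cut
offset. Fragment lengths always sum to the chromosome length (a
property test), and locus selection is verified against an exhaustive
brute-force enumerator on a 1-Mb random genome.

Allele "tags" per locus are the distinct parental haplotype sequences
across the SNPs it overlaps — with two inbred parents, a locus
overlapping any SNP has exactly two tags. The 2–4-tag polymorphism rule
and the repetitive (>4) class are implemented as stated in the field's
convention for tag-clustered loci; read-level clustering of raw
sequences into loci is out of scope (it needs reads, not genomes).

## SNP-index association

Per bulk and SNP, the index is M/(P+M) over reads attributable to each
parent. Records below `min_depth` (default 4 reads in that bulk) are
**undefined, not zero** — imputing 0 would fabricate extreme indices at
shallow sites. Δ = index(aa) − index(ab).

Smoothing is a centered sliding-window mean of the defined |Δ| within
±`smoothing_window_bp`/2 (default window 100 kb, i.e. ~20 markers at the
generator's density); windows with fewer than `min_markers` defined
markers are undefined. A loess-style alternative (tri-cube-weighted
local mean over a span fraction of markers) is available behind
`method="loess"`; the windowed mean is the default because it is exactly
reproducible by a naive O(n·w) recomputation, which the tests use as an
oracle. Thresholding uses the **magnitude** of the smoothed track: the
sign of Δ only encodes which parent was labeled P (the causal
configuration here is Δ = −1), so calling on |Δ| > 0.6 is the
label-invariant reading of the published rule. Regions are maximal
above-threshold marker runs, merged across gaps shorter than
`merge_gap_bp` (50 kb), bounded by marker positions (no midpoint
extension, matching how such regions are tabulated), and reported with
size in Mb to two decimals.

## CAPS markers

An enzyme is a candidate for a SNP when substituting the two alleles
into the flanking sequence changes the number of recognition sites in
the window of all placements touching the SNP (length 2·|site| − 1).
Fragment patterns come from the same digest engine. Scoring compares
observed gel bands to the two allele patterns and their union
(heterozygotes run both amplicon copies) within a ±3 bp tolerance —
roughly polyacrylamide resolution — after dropping bands below a 20-bp
detectability floor. The floor is what makes the classic 502 / 495+7 bp
assay scoreable as printed: the 7-bp fragment runs off the gel, so a
lone 495-bp band identifies the fertile homozygote. Ambiguous matches
(more than one pattern within tolerance) score as missing rather than
guessing. Primer design and amplicon placement are user inputs; primer
thermodynamics is out of scope.

## Two-point linkage

The two-locus F2 likelihood assumes a coupling-phase F1 producing
independent gametes with no crossover interference (consistent with the
simulator). The EM estimator attributes expected recombinant gametes to
each of the nine genotype classes — only the double heterozygote is
phase-ambiguous, contributing 2r²/(r² + (1−r)²) expected recombinants —
and iterates r ← E[recombinants]/2n to |Δr| < 10⁻⁶ from r = 0.25. It is
checked against a 10⁻⁴-resolution likelihood grid on 100 simulated
instances. A floor of 20 doubly-genotyped individuals guards against
meaningless estimates.

Distances use the Kosambi function d = 25·ln((1+2r)/(1−2r)) cM (inverse
r = tanh(d/50)/2, round-tripping to 10⁻¹⁰). Markers are grouped at
LOD ≥ 3 (conventional default) and each group is ordered by greedy
seriation: the mutually most distant pair seeds the order and each
remaining marker is inserted where it minimizes total adjacent distance.
This replaces full multipoint regression mapping deliberately: the
downstream quantities of interest (nearest flanking markers and their cM
to the trait) depend only on two-point estimates. For ≤ 8 well-spaced
markers the seriation reaches the exhaustive-permutation optimum (an
acceptance check); it is a heuristic and can be suboptimal on noisy or
clustered r matrices. The trait locus is placed by coding it as one more
codominant marker (sterile = a; fertile b/h from F3 resolution,
unresolved plants excluded with a logged count).

## Expression

ΔCt = Ct(target) − Ct(reference) per paired replicate; ΔΔCt against the
fertile 2-mm calibrator; fold = 2^(−ΔΔCt) with dispersion propagated as
fold·ln2·SE(ΔΔCt). Group comparisons are Welch two-sided t-tests on the
ΔCt scale (where qPCR noise is near-Gaussian), α = 0.01. At 3
replicates per group the Welch test is conservative (simulated type-I
rate ≈ 0.005 at nominal 0.01) because the Satterthwaite df estimate is
noisy at tiny n; its calibration is therefore verified at 8 replicates
per group, where the approximation holds. Replicates are treated as
biological. Amplification-efficiency correction is not implemented;
Benjamini–Hochberg across genes is available as an off-by-default flag.

## The synthetic generator

Defaults are the study conditions: 12 chromosomes, 252 F2, 30-plant
bulks, mean depth 30, causal locus on chr9, per-read miscall 0.01.
Physical scale is compressed — 1 Mb per chromosome at SNP density
2×10⁻⁴ bp⁻¹ (≈200 SNPs ≥50 bp apart per chromosome) with recombination
rate 10⁻⁶ Morgan/bp, i.e. ~100 cM per chromosome. Genetic lengths, the
1:2:1 dosage process, bulk allele-frequency signal and per-marker depth
are therefore realistic while whole runs stay at desk scale; only
physical bp spans (region sizes in Mb) are smaller than in a real
genome, and no acceptance check depends on absolute physical span of
simulated regions.

Meiosis: per gamete and chromosome, Poisson crossover count with mean =
rate × length, uniform breakpoints, no interference (Haldane model) —
the simplest process sufficient for two-point recovery. Bulk read
depths: total Poisson(mean_depth) per SNP and bulk; each read samples
the M allele with probability equal to the bulk's M-allele frequency and
is flipped with the error rate (symmetric miscall). The depth
distribution across bulk members is an assumption, not an inferred
protocol detail. F3 resolution uses simulated truth: a real 15-plant
progeny test misclassifies a heterozygous family with probability
(3/4)¹⁵ ≈ 0.013, a refinement not modeled. An optional promoter
insertion (e.g. 8 bp) can be planted in the sterile parent's sequence
near the causal position; it is recorded in ground truth and never
enters the depth statistics. Ct tables: reference gene at constant Ct
plus N(0, 0.15²) cycles of noise; target at reference + baseline ΔCt −
log2(fold) plus noise; three replicates per condition.

The generator does **not** emulate: read-level errors correlated along
fragments, PCR duplicates, GC or reference bias, segregation distortion,
crossover interference, partial penetrance, or phenotyping error.
Passing recovery tests therefore show the statistics behave correctly
under a clean, fully penetrant single-locus model — not that they are
robust to those real-data artifacts.

The expression preset plants fold changes (vs fertile 2-mm buds) of
0.15/0.3 for the AMS-like gene in sterile plants at the two stages and
4.0/3.0 for the five other candidate genes. The pattern the tests
require of it mirrors the qualitative claim such a study makes: the
down-regulated gene significantly down at P < 0.01, the other five
directionally up. With 3 replicates and 0.15-cycle noise the per-gene
power at fold 4 is about 95%, so demanding *joint* significance of all
five up-genes in ≥95% of replicates would be mathematically
unattainable at these conditions; directionality is the claim tested
for them.

## Determinism and problem sizes

Every stochastic path takes a single integer seed; independent child
streams are derived per stage via seed sequences, so regenerating any
one artifact does not perturb the others. Pipeline reports are JSON
with sorted keys: same seed and inputs give byte-identical files.
Replicated study-level checks use 50 seeded crosses for region
recovery/null control, 10⁴ replicates for test-calibration rates, 200
for qPCR fold recovery, and 100 instances for EM-vs-grid agreement —
sizes at which the binomial uncertainty of each pass criterion is
several times smaller than its margin.

## Known limitations

- Region calling reports marker-bounded intervals only; no confidence
  intervals on Δ (QTL-seq style simulation bands) or G′ statistics.
- The seriation orderer is exact only in the small-marker regime typical
  of a single association region.
- The VCF converter accepts biallelic SNPs with per-sample AD only.
- Smoothing near chromosome ends averages over one-sided windows, which
  inflates variance at the margins of sparse chromosomes.
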