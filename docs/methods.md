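# Methods

This note documents the models, conventions, numerical choices and
limitations of the `cicerchip` pipeline. Coordinates are 1-based inclusive
(VCF/GFF3 convention) throughout.

## Probe design

A candidate probe is the 71-mer reference window `[pos−35, pos+35]` around a
SNP. The isolation rule removes **both** members of any SNP pair within
35 bp on the same chromosome. The seven quality filters then run in a fixed
sequence (SSR, indel, biallelic, MAF, GC, ambiguity, quality); attrition is
reported per filter in that order, and the survivor **set** is
order-invariant because every filter is a pure per-variant predicate (a
property the tests assert). Records too close to a chromosome end for a
full window are reported under an `edge` reason instead of failing.

Threshold comparisons are inclusive on the passing side: MAF ≥ 0.05,
0.40 ≤ GC ≤ 0.70, QUAL ≥ 30, conversion score ≥ 0.3. "Ambiguity" means any
character outside {A, C, G, T}, i.e. all IUPAC ambiguity codes including N.
Triallelic sites fail the biallelic filter regardless of how rare the
second alternate is, and any indel overlapping the window disqualifies the
SNP.

**SSR definition.** Perfect tandem repeats of a primitive motif (length
1–6) with minimum complete copy numbers 10 / 6 / 5 / 5 / 5 / 5 for mono-
through hexanucleotides — MISA-convention defaults, configurable. Tracts
are maximal (they cannot be extended by one period in either direction) and
non-ACGT characters terminate them. The detector is checked against an
exhaustive enumeration over every start, motif length and phase.

**Annotation.** Gene models carry CDS exons only. A position is `coding`
inside a CDS exon, `intronic` inside a gene but outside all exons, else
`intergenic`; annotated-UTR positions (when present in external GFF3) fall
into `intergenic` unless they are in CDS, because the three-way
classification used downstream has no UTR class. Coding effects come from
strand-aware codon reconstruction under the standard genetic code; the 2-bp
intronic dinucleotides take splice-donor/acceptor precedence over codon
logic; a start-codon change to CTG/TTG (alternative starts) is
`synonymous_start`, any other start change is `start_lost`.

The probe-conversion score is a pluggable hook (default: constant 1, i.e. a
no-op) with an inclusive 0.3 retention threshold; the vendor's conversion
model itself is out of scope.

## Genotype QC

Cluster geometry is summarised per genotype cluster as mean/SD of contrast
(x) and size (y). The vendor does not publish its metric formulas, so this
package states its own explicitly and tests them:

* `FLD = min_hom |x̄_het − x̄_hom| / σ_pooled`, with σ_pooled the root mean
  within-cluster contrast variance over the present clusters. For SNPs with
  two homozygote clusters and no het cluster the analogous `hom_fld` uses
  `|x̄_AA − x̄_BB|`.
* `HetSO` = size-axis offset of the het cluster mean from the chord joining
  the two homozygote cluster means.
* `HomRO` = signed minimum over homozygote clusters of contrast distance
  from zero, positive on the expected side (AA positive, BB negative).

Classification order: call rate (< 0.97 fails first), OTV (flag plus
HetSO < −0.3), then the cluster-count gate — one cluster passes to
MonoHighResolution at HomRO ≥ 0.6; het + one hom passes to NoMinorHom at
FLD ≥ 3.6 and HomRO ≥ 0.3; two homozygote clusters pass to HomHomResolution
at hom_fld ≥ 6.5; three clusters pass to PolyHighResolution at FLD ≥ 3.6,
HetSO ≥ −0.1, HomRO ≥ 0.3 and ≥ 2 minor homozygotes — then the AA/BB
x/y-variance classes, else Other. The hom_fld cutoff (6.5), the variance
cutoffs (0.25 on the synthetic signal scale) and the minor-homozygote
minimum (2) are not published anywhere and are package defaults, all
config-exposed. The "inbred penalty" (12) belongs to the upstream allele
caller and is carried as metadata only. The tree is exhaustive and
exclusive, and improving any single metric never demotes a passing SNP
(asserted as a property test).

The OTV flag is raised when an extra low-size cluster holds ≥ 5% of the
samples; assignment to the OTV category additionally requires the sunken
het-like cluster (HetSO < −0.3), mirroring the mismatch-hybridisation
signature.

## Linkage mapping

Selfed F∞ RILs are assumed: two homozygous genotype classes segregating
1:1, so the segregation test is χ² = (n_A−n_B)²/(n_A+n_B) on 1 df with
removal at p < 0.01. Heterozygous and missing calls are excluded from
pairwise counts rather than treated as half-recombinants. Duplicate markers
are those identical on jointly non-missing entries with ≥ 50% joint
coverage; bins are connected components of that relation and the
representative is the first marker in genome order.

The observed recombinant fraction between RIL markers overestimates the
meiotic rate; the selfed-RIL mapping R = 2r/(1+2r) is inverted to
r = R/(2(1−R)), capped at 0.4999. The grouping thresholds (r ≤ 0.35,
LOD ≥ 6) apply to the corrected r. Pairwise LOD is set to 0 for R ≥ 0.5:
the likelihood-ratio formula is symmetric about one half and would
otherwise report spurious support in repulsion.

Ordering minimises the sum of adjacent recombination fractions (SARF):
greedy nearest-neighbour paths from every start, keeping the best, then a
ripple pass permuting every sliding window of four markers to convergence —
exact for groups of up to four, and recovering the true order of simulated
10-marker groups in ≥ 95% of seeds at n = 500. Orientation is
canonicalised so the marker with the smallest genome coordinate sits
nearest position 0. Inter-marker distances are Kosambi transforms of the
adjacent-pair r (not multipoint likelihood): tractable, testable, and
consistent with the estimator; the cost is a small downward bias when an
interior marker is missing, since adjacent observed fractions do not
compose exactly.

## ICIM-ADD

Markers are coded +1 (parent-1 homozygote), −1 (parent-2 homozygote), 0
(het or missing). Stepwise selection uses partial F-tests with entry
p = 0.001 and exit p = 2 × entry — the conventional defaults of the
reference ICIM implementation; collinear candidates (no residual variance
after projection, tolerance 1e−8·n) never enter, so duplicated markers
contribute one cofactor. For each scanned position the phenotype is
adjusted by all cofactors except the two markers flanking the interval.
The expected QTL genotype off-marker is the linear interpolation of the
flanking-marker codings (the no-double-crossover convention); LOD uses the
regression approximation (n/2) log₁₀(RSS₀/RSS₁) rather than an EM mixture
likelihood — deterministic, and the standard choice for near-fully
homozygous RILs — and PVE = 100(1 − RSS₁/RSS₀) at each position.

The permutation threshold reruns the full procedure (stepwise plus
adjusted scan) on each permuted phenotype; permutations where nothing is
selected reduce to plain interval mapping and are evaluated on a vectorised
fast path. The threshold is the 100(1−α) percentile of per-permutation
genome-wide maxima; it is invariant to location/scale changes of the
phenotype because permutation indices and LOD both are. QTLs are local
maxima above threshold with a 1-LOD support interval; peaks within 5 cM
merge into the higher one, and the stable/consistent co-location window is
10 cM — the walking step (1 cM), merge radius, support drop and co-location
window are package defaults, config-exposed, since no published values
exist for them.

## Synthetic data: what it emulates, and what it does not

The generator stands in for unpublished resequencing, array-intensity and
phenotype data, so every stage has a parameter-recovery test:

* **Genome**: i.i.d. bases at a target GC (0.5 default), with planted
  three-exon protein-coding genes (ATG…stop, canonical GT/AG introns,
  random strand) and SSR tracts whose flanks are set to break periodicity,
  making each tract exactly recoverable.
* **Panel**: SNP positions are per-base Bernoulli draws; alternate-allele
  frequencies follow Beta(0.8, 0.8) for a U-shaped MAF spectrum; site
  qualities follow Gamma(4, 15) so a realistic minority falls below the
  QUAL 30 cutoff. One planted "filter-killer" violates each design filter.
  Planting the ambiguity killer edits a single flanking base of that site
  to N in the genome object passed in — the one place a generated genome
  departs from pure A/C/G/T — and the edit is recorded in the returned
  truth table.
* **RILs**: F∞ selfed lines (fully homozygous by default;
  `residual_het_rate` is an optional knob) recombining marker-to-marker at
  the RIL-observed rate R = 2r/(1+2r) with independent intervals and no
  interference — exactly the model the rf estimator inverts, which makes
  recovery tests sharp but means crossover interference in real data is
  not emulated.
* **Phenotypes**: y = Σ aₖxₖ + environment shift + N(0, σ²), with the QTL
  genotype at off-marker positions interpolated from the flanking markers.
  Defaults a = 1, σ = 1 put single-QTL heritability at 0.5.
* **Cluster signals**: contrast centres at ±separation·σₓ (default
  separation 10, σₓ = 0.1, i.e. strongly resolved clusters), size 1.0;
  OTV contamination moves ~10% of samples into a low-size cluster and sinks
  the het-like cluster below the chord. DQC is **generated** (Beta mixture
  with a configurable below-0.82 fraction), never computed: raw-intensity
  dish QC is out of scope and enters the pipeline only as a threshold.

Consequently, passing tests demonstrate correctness of the pipeline's
*computations* under its own model assumptions — not robustness to
crossover interference, segregation distortion, linkage disequilibrium
beyond the biparental cross, batch effects in cluster signals, or
non-Gaussian phenotypes, none of which the generator produces.

The default pipeline configuration simulates RILs with a 2% residual
heterozygosity so the QC stage sees realistic three-cluster polymorphic
SNPs; the linkage stage excludes hets from pairwise counts, so the map is
unaffected.

## Problem sizes and numerics

The shipped tests and the acceptance script run at desk scale chosen as
representative populations for this class of analysis: genomes of a few
hundred kb, panels of a few hundred variants, populations of 150–300 RILs,
8-group maps of ~100 markers, 100–200 permutations for threshold
calibration and 100–200 replicates for level checks. Group-length recovery
at n = 300 carries ~5% sampling error per 55-cM group from the binomial
noise of per-interval R̂ alone, so recovery assertions use a ≥ 95%-within-
15% criterion across seeds × groups rather than a hard per-group cap.
Degenerate cases are explicit errors, not silent values: zero pooled SD
(FLD), equal homozygote contrasts (HetSO chord), zero informative pairs
(rf), zero residual variance (scan), r ≥ 0.5 (Kosambi). Percentages in
reports are rendered to two decimals with half-up rounding. A
single-marker group has length 0 and its density is reported as
not-available.

## Known limitations

* Map distances are two-point, not multipoint; dense maps with heavy
  missingness would benefit from multipoint likelihood.
* The QC category tree fixes one precedence among variance classes and
  Other; the vendor tool's exact internal precedence is unpublished.
* ICIM here is the additive model only (RILs carry no dominance);
  epistatic scans and multi-environment joint models are out of scope.
* The probe-conversion score is a hook; no conversion model is bundled.
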