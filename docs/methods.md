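# Methods

This note describes the models and procedures implemented in txatlas, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinates and tracks

All in-memory coordinates are 1-based and inclusive on both ends
(GFF3-native); BED and bedGraph are converted at the I/O boundary, the single
place where off-by-one errors could enter. Coverage is kept as two dense
integer vectors per (replicon, strand, library): 5'-read-start counts and
full read coverage. TSS calling consumes start counts; terminator and
transcript calling consume full coverage. Libraries are the exonuclease
treated (TEX+) and untreated (TEX-) halves of a dRNA-seq experiment; reads
are assigned to the strand of transcription (the protocol is stranded).

## TSS detection and classification

A position is a TSS candidate when its TEX+ start count is at least
`min_height` (default 10 reads) and the enrichment ratio
TEX+/max(TEX-, pseudocount) is at least `min_enrichment` (default 2.0,
pseudocount 1). Candidates within `cluster_window` (default 3 bp) on one
strand are merged keeping the highest TEX+ peak, ties resolved toward the
transcriptionally upstream position. These thresholds are conventional
dRNA-seq practice; they are declared defaults, not hidden constants, and all
are configurable.

Classification relative to a gene uses the 300-bp region upstream of the
annotated gene start, implemented as the inclusive window
[start-300, start-1] on the plus strand and [end+1, end+300] on the minus
strand (300 positions; an offset of exactly -300 is inside the window,
-301 is outside). Among same-strand candidates in a gene's window, the one
with the highest enrichment is that gene's primary TSS (enrichment ties go
to the candidate closer to the start, for determinism); the rest are
secondary. Sense candidates inside the gene body are internal; antisense
candidates overlapping the gene or its 100-bp flanks are antisense; anything
acquiring no class is orphan. One physical TSS may hold several classes with
respect to different genes and is emitted as a single record with the full
assignment list — including the (rare, flagged-by-inspection) case of being
primary for two divergent genes, which the classifier deliberately allows.

## Terminators and operons

Two independent terminator heuristics are reported with method labels and
never merged, since there is no principled way to reconcile their scores:

* **Hairpin scanner** — a stem of `stem_range` = 5-12 pairs (G·U wobble
  counted as a match, standard for RNA stems; this is a documented divergence
  from DNA-alphabet scanners), at most 1 non-complementary pair, a loop of
  3-8 nt, and a run of >= 4 T within 8 nt downstream. Score =
  (matched pairs - mismatches) + U-tail length; overlapping hits reduce to
  the maximum score.
* **Coverage-drop detector** — for each same-strand adjacent gene pair, the
  intergenic position maximizing 1 - (mean coverage in the 50-bp window
  downstream)/(mean upstream), restricted to positions whose upstream mean is
  at least 10 reads (without that restriction the argmax lands on
  zero-coverage background where a 0.1-vs-0 ratio is formally a perfect
  drop), reported when the drop is >= 0.5. One position is reported per gene
  pair; when an independently transcribed unit (for example an intergenic
  sRNA) lies in the same intergenic span, its transcript end can out-compete
  the genuine terminator for that single report — a known limitation of the
  per-pair semantics.

Operon assembly joins consecutive same-strand genes when the intergenic gap
is <= 300 bp (mirroring the TSS window), the minimum intergenic coverage is
>= 5 reads, and no terminator lies between them. Only coverage-drop
terminators feed the assembly: hairpin hits are sequence-only evidence and,
on random sequence, frequent enough at the permissive default stem range to
split genuine operons. The operon's lead TSS is the primary TSS of its first
gene (in transcription order) when present; every primary/secondary TSS at a
non-first member opens a sub-operon running from that member to the operon
end.

## Small RNAs

Transcripts are maximal runs of coverage >= 10 reads, merged across gaps of
<= 10 bp, discarded under 30 nt. Because a stable fragment of a longer
transcript appears as a boundary change rather than a separate coverage
island, sRNA candidates are the transcripts plus their segmentation at
internal anchors (TSSs and processing sites). Processing sites are defined
operationally — the source methods invoke them without a detection rule — as
5'-start pileups present in the untreated library (>= 10 reads, >= 3x the
local start-count background in a ±25-bp window) but not TSS-enriched after
exonuclease treatment (TEX+/TEX- ratio < 2): a processed monophosphorylated
end is degraded by the treatment.

Each candidate receives exactly one class, testing in the precedence order
intergenic → antisense → 5'-UTR-derived → 3'-UTR-derived → intra-operonic
(first satisfied wins; intergenic first keeps the class feeding the fitness
reanalysis maximally conservative):

* **intergenic** — TSS at the 5' end (±5 bp) and a parent transcript
  overlapping no gene on either strand;
* **antisense** — 5' anchor plus overlap with a gene on the opposing strand;
* **5'-UTR-derived** — the 5' TSS is a primary or secondary TSS of a
  same-strand gene and the candidate ends before that gene's start (the
  processing site or coverage drop "in front of the CDS" is what created the
  segment boundary);
* **3'-UTR-derived** — the 5' anchor (TSS or processing site) lies within
  300 bp downstream of a same-strand gene end, and the 3' end is supported by
  a terminator, a processing site, or the parent transcript's own 3' end
  (±20 bp) — the last option covers termination shared with the mRNA when the
  terminator heuristic reported a different position in the same span;
* **intra-operonic** — contained in an assembled operon span with a 5'
  anchor and 3' support as above.

Curation then applies the exclusion rules automatically: (1) no TSS or
processing site within 50 bp upstream of the 5' end; (2) complete overlap
with a same-strand annotated mRNA; (3) complete overlap with an annotated
terminator; (4) overlap with cis-regulatory elements, applied only when an
interval file of riboswitches/thermometers is supplied; (5) no evident
coverage change versus the flanking 50-bp regions — the source gives no
threshold here, so it is exposed as a fold parameter (default 2x the mean of
the flank means). Accepted records additionally satisfy a 30-500 nt length
range and the folding-stability criterion.

**Folding score.** A Nussinov-style minimum-score dynamic program over
nested pairings with per-pair weights GC = -3, AU = -2, GU = -1 and hairpin
loops >= 3 nt replaces a full nearest-neighbour thermodynamic model. It is a
stability *proxy*: the normalized threshold (score/length < -0.05) applies on
this scale and is configurable. "Normalized folding energy" is taken to mean
energy per nucleotide — an assumption, flagged here. Two consequences are
documented rather than hidden: scores are not calibrated to kcal/mol, and
because G·U pairs are scored, the value is not exactly invariant under
reverse complement (wobble pairs are not closed under complementation); the
invariance holds for Watson-Crick-only optima and is tested there. The DP is
O(n³) and is only evaluated for candidates that already pass the length
filter.

## Invertons

The scanner is exhaustive, not seeded: every base pairing (x, y) of an
inverted repeat satisfies x + y = constant, so all (arm, spacer) geometries
are windows along anti-diagonals of the self-comparison, swept with
cumulative sums vectorized across diagonals. Mismatch budgets are 0 for arms
<= 11 bp, 1 for 12-19 bp and 2 for > 19 bp; the source rule is silent for
14-19 bp and the budget of 1 is the monotone interpolation between its 13-bp
and >19-bp anchors. Arm range defaults to 5-25 bp and spacer to 30-1,000 bp
(common scanner practice; no bounds are stated upstream). A hit is suppressed
as non-maximal when both arms lie inside another hit's arms with at most the
same mismatch count. Filters: homopolymeric arms (each arm a single repeated
nucleotide) removed; GC fraction over both arms restricted to [0.15, 0.85].
A hit is promoter-associated when its arms-plus-spacer span intersects the
50-bp window upstream of any mapped TSS; the window is strand-aware by
default with a switch to ignore strand, since the upstream source does not
state which was used.

An independent brute-force enumerator (sliding fixed (arm, spacer) window
pairs against the reverse complement — a different decomposition of the same
search) ships with the package and is used as the equivalence oracle in
tests; the two agree exactly on random sequences. With the budget rule
active, chance hits at 15-bp arms on i.i.d. random 5-kb sequence occur at a
calculable rate of ~0.2 per scan (5e3 positions x ~970 spacers x 46/4^15),
so false-positive control claims are made at 18-bp arms, where the expected
rate is ~0.004.

## Expression

CPM(g, s) = counts / library size x 1e6, library sizes defaulting to column
sums; no compositional (TMM-style) normalization is applied by default, with
a hook for user-supplied factors. A gene is "expressed" when its CPM exceeds
0.6635 in all replicates of at least one condition (the threshold is kept as
a literal default — it corresponds to roughly ten reads at a ~15-million-read
library, and 10/15,072,000 x 1e6 = 0.6635 to four decimals).

The differential-expression engine is a deliberately simple stand-in for a
tagwise-dispersion GLM framework: counts are rescaled to the mean library
size, a single common NB dispersion is estimated by method of moments from
within-condition replicate scatter (pooled regression through the origin of
s² - m on an unbiased estimate of µ², across gene x condition cells), and a
two-group exact-style conditional test is applied per gene — given the total
count, the group-A sum follows a ratio of NB pmfs with sizes n_A/φ and
n_B/φ, and the two-sided p-value sums all outcomes no more likely than the
observed one (the Poisson limit φ→0 reduces to a conditional binomial).
Fold changes are log2 ratios of mean CPM with pseudocount 0.5; FDR is
Benjamini-Hochberg. Downstream thresholding (up: log2FC > 2 and FDR < 0.05;
down symmetric), the ranking metric -log10(p) x sign(FC) (zero p-values
floored at the smallest positive double, flagged), and enrichment all also
accept externally computed DE tables, so thresholds can be applied verbatim
to output of a full GLM fit. At 3-vs-3 replicates and dispersion 0.05 the
stand-in's null type-I error at nominal 0.05 measures ~0.04 (slightly
conservative from count discreteness) with essentially full power at
|log2FC| = 4.

Preranked enrichment uses the weighted Kolmogorov-Smirnov-style running sum
(hit increments weighted by |score|), so ES lies in [-1, 1] and flips sign
when the ranking is negated. The null permutes gene labels (equivalently,
draws random member sets) — a preranked list has no sample labels to
permute — with two-sided p = (1 + #{|ES_perm| >= |ES|})/(n_perm + 1),
n_perm >= 100 enforced and 10,000 by default. Sets with fewer than 10
members present in the ranking are dropped unless explicitly exempted
(mirroring the "retain PULs regardless of size" convention).

## Integration

Co-expression profiles are z-scores of CPM, computed by default over
condition means (replicates averaged), with a per-sample switch; both modes
exist because the upstream description ("across all profiled conditions")
does not fix the replicate handling. For a query gene, each gene set's
summary is the median Pearson correlation between the query profile and the
member profiles, the query excluded from its own sets, sets with fewer than
ten usable members dropped, and |median r| > 0.5 labelled. The ten-member
floor counts operons when an operon collapse map is supplied and gene
members otherwise.

Fitness categorization applies the thresholds as independent predicates —
significant: |t| > 4; strong: |fit| > 2 and |t| > 5; combined: both —
restricted to successful experiments; note |t| in (4, 5] with |fit| > 2 is
significant but not strong. sRNAs are ranked by (number of significant
experiments, max |fit|, id) with expression context (max condition-mean CPM
and its condition) attached where available. The binding fit is plain least
squares on Y = Bmax·X/(Kd + X) (scipy `curve_fit`, positivity bounds),
starting from Bmax = max(y) and Kd = the x at half-max by interpolation;
noise-free model data is recovered exactly and the residual sum of squares is
reported.

## Synthetic data: what it emulates, and what it does not

The generator plants, with recorded truth: TEX+-enriched start pileups at
TSSs (TEX+ mean = `tss_height`, TEX- mean = height/enrichment factor, both
Poisson); the inverse pattern at processing sites; transcript coverage as
per-position Poisson around a unit height, reading through terminators at
(1 - drop) of the height for 100 bp; background Poisson noise (default rate
0.1/position) on both strands; inverted repeats with exact arm coordinates
and mismatch counts (homopolymeric decoys are A-padded at arms and spacer
edges so that chance arm extensions stay GC-free and are caught by the GC
filter rather than surviving as mixed-base arms); negative-binomial counts
(gamma-Poisson; dispersion 0 is the Poisson limit) around condition means
with planted log2 fold changes; correlated regulon blocks; and fitness
tables whose background |t| stays below 3 with planted hits outside that
band and a 5% unsuccessful-experiment rate.

Regulon blocks deserve one note: the target correlation is defined on the
linear CPM scale where the co-expression method measures it. Members share a
latent condition profile (standardized, private noise orthogonalized and
standardized so the *realized* sample correlation matches the target rather
than merely its expectation), and the latent-scale correlation planted is
back-computed by inverting two analytic shrinkages — lognormal correlation
shrinkage from exponentiating a log-scale profile, and counting-noise
attenuation (dispersion/replicates relative to e^{σ²} - 1). The default
amplitude is 1.0 (log2 sd): large enough to dominate count noise, small
enough that the shrinkage corrections stay mild.

The demo dataset (`make-demo`) is a 50-kb genome with 20 genes in 14
transcription units (two 3-gene and two 2-gene operons, ten singletons),
40 TSSs (unit leads, sRNA 5' ends, 4 secondary, 4 internal, 3 antisense-only,
5 orphan), 10 terminators, 12 sRNAs (5 intergenic, 3 antisense, 2
5'-UTR-derived, 2 3'-UTR-derived), 8 detectable inverted repeats spanning the
budget regimes plus 2 homopolymeric decoys, a 600-gene x 15-sample count
matrix (5 conditions x 3 replicates, library size 2e6, dispersion 0.05, 40
planted DE genes at ±4 log2, one 15-gene regulon), five gene sets including a
small exempt one, and an 80-sRNA x 100-experiment fitness table with 5
planted hits. Unit transcript heights are 40-70 reads and the terminator
read-through fraction is 0.05, so that read-through coverage stays below the
transcript-calling floor while intra-operon coverage stays far above the
operon-joining floor. Intra-operonic sRNAs are not planted in the demo:
recovering one requires segment boundaries inside an expressed operon to
survive coverage noise, which makes the planted truth ill-defined at this
scale; the class logic is exercised on constructed geometries in the unit
tests instead.

Not emulated: read-level FASTQ, mapping artefacts, rRNA contamination,
batch effects, biological promoter motifs, or sequence composition bias —
the genome is i.i.d. uniform. Passing the recovery tests therefore shows the
*logic* of the pipeline is correct under its stated signal model, not that
the default thresholds are optimal for real libraries, where coverage is
burstier and enrichment ratios vary by orders of magnitude.

## Problem sizes

The test suite and the acceptance script keep simulations at desk scale:
scanner/oracle equivalence on 20-40 random sequences of 0.9-1.2 kb (spacers
to 150-180 bp), the 36-geometry TSS truth table, one 50-kb demo genome,
10,000 null genes and 2,000 genes with 100 planted effects for DE
calibration, 1,000-gene rankings with 100 random sets (400 permutations) and
one extreme set (2,000 permutations) for enrichment, and an 80 x 100 fitness
table. The full suite runs in about a minute; the acceptance script in well
under one.

## Known limitations

* The DE stand-in uses one common dispersion; genes with atypical dispersion
  are mis-calibrated relative to a tagwise model.
* The coverage-drop terminator reports one position per gene pair (see
  above); terminators of the last gene on a strand (no following same-strand
  gene) are not scanned.
* Processing-site detection is an operational definition, not a validated
  model of RNase processing.
* The folding proxy ranks stability sensibly on clear positives/negatives
  but its normalized threshold is not transferable to thermodynamic-model
  outputs.
* `compare_tss_sets` uses greedy nearest matching, which is not globally
  optimal for pathological clusters of near-coincident sites.
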