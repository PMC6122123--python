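# Methods

## The question and the model system

`recinv` implements the analysis needed to ask whether two hybridizing
butterfly species are kept apart by chromosomal inversions or by a general
reduction of recombination in their hybrids.  The model system is a
Lepidopteran one: 21 chromosomes, achiasmatic female meiosis (all observed
crossovers are paternal), and roughly one crossover per chromosome per male
meiosis, so each chromosome maps to ~50 cM and a genome of 21 chromosomes to
~1050 cM.  The pipeline has five analytical stages — linkage-map estimation
from crosses, windowed rate comparison between groups, a detection-power
simulation for inversions, a multi-filter sieve for split-read inversion
candidates, and introgression statistics around surviving candidates — plus a
synthetic-data stage that generates every input with known ground truth.

## Synthetic crosses

`simulate_cross` draws, per offspring and chromosome, either zero or one
paternal crossover with probability 1/2 each (`obligate_single`; one obligate
chiasma whose recombinant chromatid is inherited half the time), or a
Poisson(0.5) count (`poisson`).  Crossover position is uniform on physical
length: the simplest null, consistent with per-chromosome rates clustering
around length-determined values; a non-uniform intensity can be emulated by
composing datasets.  Inversions are modelled as intervals that suppress
crossovers in heterozygous fathers only — the hybrid-backcross design makes
the F1 father heterozygous for every species-specific inversion, while a
within-species father is homozygous and recombines freely.  Suppression is
implemented by rejection sampling of the crossover position, which preserves
the obligate per-chromosome count; this is an approximation to
heterokaryotype crossover suppression (it redistributes, rather than
removes, the obligate chiasma).

Markers are placed with exponential inter-marker gaps (default mean 115 kb,
matching the observed mean marker spacing; the observed median of 87 kb
indicates the real gap distribution is more concentrated than exponential —
see Limitations).  Genotyping noise is independent per call: symmetric
phase flips at `genotype_error_rate` and missingness at `missing_rate`.
These exist to exercise the detector's noise filter, not to reconstruct any
particular genotyping platform.  Maternal haplotypes are transmitted whole
(no recombination); the dataset carries the maternal call matrix so the
achiasmy guarantee is testable rather than assumed.

All randomness in a generator call flows from its single integer seed
through one `numpy.random.Generator`.

## Crossover detection and map estimation

A crossover is called at each paternal phase switch corroborated by at least
`min_support` consecutive informative markers of the new phase (default 2:
single-marker flips are the dominant error mode of the noise model).  The
initial phase is that of the first informative marker; missing calls widen
the localization interval, which runs half-open from the last informative
marker of the old phase to the first of the new.  Two consequences worth
knowing: crossovers outside the marker span are undetectable in principle,
and with `min_support` = 2 a crossover localized in the terminal marker
interval is discarded as a possible error — so estimated map lengths sit
slightly below the simulated truth.

Map distances use the recombination fraction alone (cM increment =
100 × crossovers / offspring per marker interval; no mapping function), which
is adequate at ~100 kb marker spacing where double crossovers between
adjacent markers are negligible.  A crossover whose localization interval
spans several marker intervals is pro-rated by physical overlap, making the
total map length conserve the crossover count exactly: total cM / 100 equals
mean crossovers per offspring by construction.

## Windowed rates, bootstrap, and tests

Chromosomes are tiled with 1 Mb windows at 100 kb steps; the trailing
truncated window is kept (this convention reproduces the expected 2,549
windows on the 21 reference chromosome lengths) and truncated windows use
their actual span when converting cM to cM/Mb.  Crossovers contribute
fractional mass to windows by interval overlap, again conservation-exact, in
preference to assigning each crossover to every window it touches (which
double-counts) or to its interval midpoint (which is brittle when marker
gaps are asymmetric).

Confidence intervals resample offspring — the exchangeable unit — with
replacement, 10,000 times by default, taking empirical 2.5/97.5% quantiles.

Chromosome-scale comparisons use per-offspring crossover counts, which are
discrete with heavy ties, so the one-sided KS statistic
D⁺ = max ₓ [ECDF_b(x) − ECDF_a(x)] (testing that group b recombines less) is
calibrated by bootstrap: both samples are redrawn at their original sizes
from the pooled sample, and p = (1 + #{D* ≥ D_obs}) / (n_boot + 1).  The
pooled-bootstrap null is the standard construction for a ties-robust KS; the
+1 correction keeps p > 0.

Window-scale comparisons permute offspring group labels globally, each
offspring carrying all its crossovers, and compare window cM between groups;
the default is two-sided with `less` available for the directional
hybrid-reduction question.  Benjamini–Hochberg controls the FDR across
windows (q-values via `statsmodels`).  Note that permutation p-values are
only near-uniform under the null when the window statistic is
near-continuous; with point-localized crossovers the statistic is
integer-valued and the two-sided p-values are conservative.  Realistic
marker-gap-sized localization intervals (~115 kb) restore near-continuity.

Desk-scale defaults in the tests and acceptance script use 500–3,000
resamples; the full 10,000 bootstrap / 270,000 permutation settings remain
available through the function arguments and CLI flags.

## Detection power of a linkage map

A map orders markers only where their cM positions differ, so the default
detectability criterion (`two_informative`) requires an inversion to contain
at least two markers at distinct cM — flipping the segment would then
visibly reorder the map.  The laxer `two_markers` criterion (any two
markers) is provided for comparison and is an upper envelope.  Random
inversions of each size are placed uniformly on the genome: chromosome
chosen proportional to length with placements crossing chromosome ends
rejected, implemented as the equivalent direct draw (chromosome weighted by
its number of valid starts).  Power is monotone non-decreasing in inversion
size by containment of marker sets.  Under Poisson marker spacing with mean
115 kb the chance that a 100 kb segment holds two markers is only ~0.2, so
absolute power at small sizes is sensitive to the criterion and to the real
gap distribution; only the qualitative shape of the curve is asserted in
tests.

## The candidate sieve

Filters are pure per-candidate predicates, hence order-independent and
idempotent:

* **recombination** — reject if a same-species crossover interval is wholly
  contained in the candidate (containment, not mere overlap: a partially
  overlapping crossover may have occurred outside the candidate);
* **trio span** — reject if a single same-species forward alignment covers
  the candidate and extends more than half its length beyond *both*
  breakpoints (`--span-mode either` relaxes this to one side; a collinear
  scaffold across both breakpoints is what refutes an inversion, so "both"
  is the default). Reverse-orientation alignments never reject;
* **length** — strictly shorter than 1 kb rejected (linkage disequilibrium
  at that scale is above background regardless of inversions);
* **tentative rescue** — relaxed-support candidates from low-coverage
  samples are kept only where they overlap a default-tier candidate from a
  different sample.

Survivors merge into groups as connected components of the ≥1 bp
interval-overlap graph on each chromosome (no reciprocal-overlap fraction).
Groups are classified by evidence pattern, checking the most specific
pattern first: split reads in one species but inverted trio scaffolds in
both (`split_one_trio_both`), then split-read plus same-species inverted
trio scaffold (`split_and_trio`), else `split_only`.  Trio inversion
evidence for a species means a single scaffold with a reverse-orientation
alignment overlapping the group and a forward alignment extending outside it
— forward and reverse hits flanking a breakpoint.  Chained multi-scaffold
evidence is deliberately not accepted for the spanning filter (single
alignment only).  Breakpoints within 5 kb (configurable) of a contig
boundary are flagged, since misassembly at contig ends mimics inversions.

## Introgression statistics

For each candidate, up to 11 contiguous windows of the candidate's own
length (five per flank) are laid out; windows extending off the chromosome
are dropped rather than truncated so all windows stay equal-sized.  Per
window, from derived-allele frequencies of P1, P2 (recipient), P3 (donor)
and outgroup O:

* **FST** — Hudson-type ratio of averages with the (n−1) sampling
  correction: per-site numerator (p_a−p_b)² − p_a(1−p_a)/(n_a−1) −
  p_b(1−p_b)/(n_b−1), denominator p_a(1−p_b) + p_b(1−p_a); undefined when
  the window has no variation.
* **dXY** — mean per-site p_a(1−p_b) + p_b(1−p_a); scaled over all
  accessible sites when that count is supplied, otherwise over variant sites
  only (a "variant-scaled" value).
* **D and fd** — ABBA = (1−p1)p2p3(1−pO), BABA = p1(1−p2)p3(1−pO),
  D = (ΣABBA−ΣBABA)/(ΣABBA+ΣBABA) (0 when there is no ABBA/BABA mass at
  all); fd shares D's numerator, with its denominator recomputed using
  pD = max(p2,p3) in place of both p2 and p3.  fd is reported as missing —
  never clamped — when D < 0 or the denominator vanishes, because the
  admixture-proportion interpretation only holds for a positive excess.

The site-frequency generator drifts an ancestral Beta(0.5, 0.5) frequency
independently into the (P1,P2) and P3 lineages (truncated-normal steps,
sd 0.2, then 0.1 within the pair), keeps the outgroup fixed ancestral at 95%
of sites, and redraws P2's value from the P3 lineage at a fraction γ of
sites; observed frequencies are binomial samples over `n_hap` haplotypes.
fd rises monotonically with γ but underestimates it in absolute terms
(shared ancestral polymorphism inflates both ABBA and BABA), which is the
expected behaviour of fd on single windows.

## What the synthetic data does and does not show

The generators reproduce the design of the study — sample sizes (~300
offspring per group), the obligate crossover model, achiasmatic females,
marker spacing, species-specific suppressing inversions, a false-positive
process for split-read calls, haplotype scaffolds with reversed segments
inside carrier inversions — with known truth and fixed seeds.  They do not
model: interference beyond the obligate count, non-uniform crossover
intensity, segregation distortion, linked-marker error correlation, the
sequence-level behaviour of a real SV caller (candidate endpoints are exact,
real ones are repeat-blurred), or linkage disequilibrium structure in the
site-frequency tables (sites are independent).  Passing tests therefore
validate the pipeline's logic and calibration, not the error profile of any
particular sequencing platform.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 200–300 offspring per
group, 3 × 10 Mb genomes for planted-effect checks and the full 21-chromosome
genome for tiling/power checks, 500–3,000 resamples, 1,000 KS-calibration
replicates, 2,000 power placements and 10,000-site frequency tables.  These
sizes keep every Monte-Carlo check comfortably inside its tolerance band.
Coordinates are 0-based half-open throughout (1-based positions only in the
site-frequency table, as in VCF); marker positions must be strictly
increasing and are rejected otherwise; rates are reported to 2 decimals as
in the reference tables; resampling p-values carry the +1 continuity
correction; and all seeds are explicit function arguments.
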