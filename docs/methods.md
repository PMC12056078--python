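# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Synthetic data (`megatx.simdata`)

**Genome.** Chromosomes are i.i.d. random DNA at a target GC content
(default 0.35, typical for a thermophilic *Firmicute*). Random sequence is
adequate here because every downstream stage keys on exact or
near-exact sequence identity, not on genome structure; the one structural
property that matters — that a junction 2k-mer is absent from the
chromosome — holds with overwhelming probability for random 50-mers and is
asserted, not assumed, by `junctions.check_specificity`.

**Scenario geometry.** The default scenario scales the real discovery
(two duplications of 60.1 and 25.7 kb, 8.3 kb apart, on a 2.4 Mb
chromosome) to desk size: a 150 kb chromosome with 17.2 kb and 11.8 kb
forward duplications 6.1 kb apart, forming a 29.0 kb circle. The
duplicated fraction (~19%) deliberately exceeds the real ~3.6% so the
tests also exercise the median-normalization's robustness; boundaries are
placed off the 1 kb bin grid so recovery exercises refinement. Circle
copy number enters as a per-condition source weight (high under "CO",
zero under "glucose"); the true per-cell copy number is not known for the
real element, so the weight is a free parameter and the depth simulation
uses the observed 2.2 copy ratio directly.

**Depth.** Per-base depth is Poisson(mean_depth × copy_ratio), simulated
directly rather than via read alignment so the segmentation is testable
without an external aligner. This omits GC bias, mappability structure
and overdispersion of real short-read coverage — passing tests show the
caller recovers clean copy-number steps, not that it is robust to those
artifacts (it has no GC correction; see Non-goals below). A minimal
short-read emitter exists for users who want to run a real aligner; no
pipeline stage uses it.

**Long reads.** Lengths are lognormal (median 5,697 — the raw-read N50
scale of a PromethION bacterial run — σ_log 0.6) truncated to
[200, 50,000]; starts are uniform with wrap-around on circular sources;
a source is chosen proportionally to weight × molecule length. Errors
are i.i.d. per base — deletion, then substitution, then single-base
insertion (defaults 2% / 2% / 1.5%, ~94–95% identity) — with no
homopolymer awareness, no chimeras and no quality modeling (FASTQ
qualities are a constant 'I' and are never read downstream). That is
sufficient to make exact 50-mer matching insensitive (a clean 50-mer
survives with probability (1−e)^50) and therefore to exercise the
approximate matcher; it does not reproduce ONT's error locality.

All randomness flows through one `numpy` generator per operation call
with a required seed; identical inputs give byte-identical outputs.

## Depth segmentation (`megatx.depthseg`)

Per-bin means (default 1 kb bins) are divided by the genome-wide *median*
of bin means; the median keeps the single-copy baseline at 1.0 even when
duplications span a sizeable genome fraction, which a mean would not.
Bins at ratio ≥ 1.75 (duplication) or ≤ 0.25 (deletion) are thresholded
into maximal runs; runs separated by at most 5 neutral bins are merged
(never across a bin qualifying for the opposite kind); duplications
shorter than 10 kb and deletions shorter than 1 kb are discarded. The
thresholds sit between single copy (1.0) and the ~2.2 signal of a
one-extra-copy population, and 0.25 catches a homozygous deletion whose
expected ratio is 0.

**Boundary refinement.** Bin-level boundaries carry up to one bin of
error. Each boundary is moved to the base maximizing the *signed* step
between the flanking w = refine_window/2 means — depth rises at a
duplication start and falls at a deletion start. The sign matters: with
the default 2 kb search range both boundaries of a short event (like a
2.4 kb deletion) lie in one range, and an unsigned step statistic can
lock onto the opposite edge, whose step is equally strong. Ties break
toward the unrefined boundary, then toward the smaller coordinate;
windows that do not fit the contig leave the boundary unrefined with a
warning.

Copy ratios are the median of in-segment bin ratios, reported to two
decimals. Reports carry both the inclusive length (end − start + 1) and
the span (end − start), labelled, plus all three conventions for the
distance between two calls, because published figures mix these
conventions and off-by-one length bookkeeping is the dominant failure
mode in this kind of accounting.

## Junctions (`megatx.junctions`)

A junction is the last k bases contributed by one oriented segment end
followed by the first k bases of the next (default k = 25, so a 50-mer).
Specificity requires that neither the junction nor its reverse complement
occurs exactly in the reference (including the wrap window for circular
references).

Scanning is semi-global: the junction must align end-to-end within a
read, read ends free. The default is exact matching (`max_edits = 0`,
matching the raw-read selection procedure the element was quantified
with); `max_edits = 3` is the noisy-read preset because i.i.d. errors at
e = 2% leave only ~36% of true junction occurrences exactly intact.
Approximate matching delegates to edlib's infix mode, which is
exactly the semi-global DP; the test suite checks agreement with an
independent full-DP oracle on 1,000 random pairs. The counting unit is
reads (a read counts once per junction no matter how many times it
matches), the normalization denominator is the read file as given (no
trimming), and an empty input yields a flagged "undefined" rate rather
than a NaN.

## Circle reconstruction (`megatx.circlerec`)

Reconstruction is reference-guided: the duplicated segments are known
from coverage, so only the adjacency structure and exact breakpoints are
inferred. De novo assembly is deliberately out of scope.

**Candidates.** All oriented end-to-start adjacencies between segments
are enumerated, self-joins and fold-backs included. An adjacency
traversed backwards is the reverse complement of the same junction, so
one representative per mirror pair is kept — 10 distinct candidates for
two segments, 3 for one segment (the fold-backs are their own mirrors,
so the count is not simply half of the 16 ordered oriented pairs).
Candidates whose 2k-mer occurs in the reference are flagged as reference
adjacencies and excluded from resolution.

**Flank refinement.** Depth-called boundaries can be off by hundreds of
bases, which would make every candidate 2k-mer miss every read. Junction-
spanning reads are therefore located first, by requiring an interior
50-base anchor on each side of the nominal boundary at a plausible
spacing (anchors sit 60 bases inside each segment, clear of the ±50 base
search window). Probe 2k-mers sliding across each boundary then trace a
support step: a probe extending past the true breakpoint leaves the
circle's sequence and stops matching junction reads, so each flank's
offset is read off the step edge (at half-maximal support). Probes are
matched exactly even when reads are scanned approximately, because an
edit allowance would let a probe overhang the breakpoint by up to
max_edits bases at one edit each, biasing the edge. Finally, because
micro-homology between the donor's continuation and the acceptor's start
makes the one-sided steps overshoot (the breakpoint of a junction is
only defined up to that homology), the two offsets are chosen jointly by
maximizing support of the assembled junction 2k-mer itself over a small
grid, with ties broken toward the depth-called boundary. Within the
homology the junction sequence — and hence the assembled circle as a
circular molecule — is invariant; only the reported breakpoint
coordinate moves, which is why circle comparisons in the tests are
rotation-invariant (equal length and occurrence in the doubled partner).

**Resolution.** Candidates are accepted greedily by support (default
min_support 3) while their segment ends are unused; a conflicting
candidate within a factor 2 of an accepted one raises an explicit
ambiguous-layout error, and anything short of a single Hamiltonian cycle
over all segments raises incomplete-circle; both errors carry the full
evidence table. The cycle check is exact — segment counts here are tiny.
Assembly concatenates the refined, orientation-adjusted segment
sequences; the length always equals the sum of inclusive segment
lengths. Rotation to an anchor position is provided (rotations compose
modulo the length); the default origin is the start of the first
segment, since anchoring on an annotated feature (such as the insertion-
sequence transposase the real element was rotated to) would require
annotation, which is out of scope.

## Physiology (`megatx.physio`)

Gas rates are computed from inlet/outlet GC mole fractions with N2 as
the internal standard: outlet flow = inlet flow × y_N2,in / y_N2,out, and
q_i = (in − out)/(V·X) in mmol g⁻¹ h⁻¹, uptake positive and production
negative (so on CO the water-gas shift shows up as negative q_H2 and
q_CO2). Rates are invariant to any consistent rescaling of the outlet
stream by construction.

Steady-state arithmetic: q_Ace = 1000·D·c_Ace/(M_acetate·X) with feed
acetate assumed zero (defined mineral medium); Y_Ace/X = c_Ace/(M·X);
Y_X/S = 1000·D/q_S (chemostat identity µ = D); substrate-per-acetate
ratios are reported to one decimal. The carbon balance counts produced
carbon (negative gas rates, acetate, biomass at 1000·D/(g per Cmol))
against consumed carbon. Biomass carbon content is configurable and
defaults to 25.0 g per Cmol (the standard CH₁.₈O₀.₅N₀.₂-type
assumption) because elemental composition is rarely reported; carbon
balances are therefore compared as tolerance bands, never as exact
equalities. Growth rates are the least-squares slope of ln(OD) versus
time inside an explicit exponential-phase window, with T_d = ln 2/µ
reported to one decimal.

One caveat is inherent to published chemostat tables: tabulated yields
are usually means of per-replicate ratios, while this package recomputes
ratios of tabulated means — the two differ by up to roughly one standard
deviation (e.g. recomputed q_Ace 15.1 versus a printed 14.6 ± 0.5), and
more when a column's rates were derived from a subset of the replicates
behind the concentration means. Derived quantities are therefore always
checked against printed values within the printed standard deviation.

## Problem sizes

The default test scenario uses a 150 kb chromosome, ~150x coverage and
1.5 Mb of simulated long reads per condition; the segmentation recovery
sweeps use 50 seeds and the end-to-end recovery 20 seeds at 2%
substitution error. These sizes were chosen so each property is measured
with comfortable statistical margin (tens of junction-spanning reads per
adjacency, boundary steps far above Poisson noise) while the whole suite
stays desk-scale; all of them scale up linearly through the same
parameters.

## Known limitations

- No GC-bias or mappability correction in depth calling; no diploid CNV
  genotyping.
- Junction scanning has no split-read alignment or per-position pileup;
  a read is a hit or not.
- Reconstruction assumes the segments come from one circular product; it
  does not deconvolve mixtures of distinct circles sharing a segment
  (these surface as ambiguous-layout errors rather than answers).
- The read error model is i.i.d.; homopolymer-dominated ONT error
  locality, chimeric reads and basecaller artifacts are not emulated, so
  recovery rates on real noisy data may differ from the simulated ones.
- The simulator treats circle copy number as a sampling weight; it does
  not model replication dynamics or per-cell heterogeneity.
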