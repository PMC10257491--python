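# Methods

`rdnascope` analyses the architecture of major (45S) ribosomal DNA clusters
from long and short sequencing reads: which repeats live in the intergenic
spacers (IGS), how long the satellite arrays are, how homogeneous the gene
copies remain, and what fraction of units carry retrotransposon insertions.
This note describes the models and procedures, the choices that were
genuinely open, and what the synthetic data can and cannot show.

## The rDNA unit model

A major rDNA cluster is modelled as a tandem array of units, each the
transcription unit 18S–ITS1–5.8S–ITS2–28S followed by an IGS. The IGS may
carry, in a fixed per-species order: truncated mobile-element (ME)
fragments, a satellite array of head-to-tail monomer copies, and
microsatellite runs, interleaved with anonymous spacer DNA. A configurable
fraction *f* of units carries an R2-type non-LTR retrotransposon inserted at
a fixed site inside the 28S gene (R1/R2 elements are site-specific 28S
parasites that pseudogenise their host copy). Unit copies diverge from the
template by an independent per-base substitution rate *d* (concerted
evolution keeps real copies similar; *d* is the knob for how similar).

All coordinates are 0-based half-open throughout; BED output is native,
GFF3 output converts to 1-based inclusive. Minus-strand hits are reported in
plus-strand read coordinates with the strand recorded, and compositions are
emitted in the canonical unit orientation (18S→28S). `N` never counts as a
match in any identity computation.

## Synthetic landscapes

`simulate.build_landscape` assembles the locus with planted truth: exactly
`round(f·n_units)` units carry the insertion and exactly
`round(irregular_fraction·n_units)` units have a shuffled IGS element order;
both sets are drawn uniformly. ME fragments in the genome are 5′- or
3′-truncated copies of a full-length consensus (alternating per element);
the annotation library holds the full consensus, so partial-homology
detection is exercised by construction — mirroring the nonautonomous,
protein-domain-free IGS copies seen in real spacers. Satellite copy number
per unit is uniform over a configured range (real arrays vary strongly in
length; no distribution is established, so uniform is the least-assumptive
testable choice). IGS spacer segments are template-based and diverge like
the rest of the unit, since real spacer DNA is homologous between copies.

`simulate.simulate_reads` draws read start positions uniformly (no
chimeras). Long-read lengths are log-normal (median, log-sigma, optional
hard cap); errors are split into substitution/insertion/deletion parts of a
total per-base rate *e* (ONT-like preset: median 8 kb, e = 0.07; HiFi-like:
median 15 kb, e = 0.003). Per-base qualities are the target mean ±1, so the
probability-space read quality lands within one Phred unit of the target.
Paired mode emits mates of fixed read length from fixed-size inserts
(defaults 150 bp / 450 bp).

What the generator does **not** emulate: homopolymer-biased or signal-level
ONT errors, chimeric reads, coverage biases (GC, mappability), higher-order
repeat structure inside satellites, and chromosome-scale context beyond a
random (optionally telomeric-capped) flank. Passing tests therefore
demonstrate correctness of the *computations* under idealised sequencing,
not robustness to every real-data artefact.

A regime choice worth stating: in the study species the rDNA unit (≈25–47 kb)
exceeds the filtered read lengths (N50 6–22 kb), so an element occurs at
most about once per read. The default benchmark landscapes reproduce that
geometry (unit length above the read cap). When a read does contain two
near-identical copies of a region, the uniqueness filter removes both — the
correct behaviour of a mapping-quality threshold over a tandem array, but a
regime the benchmarks deliberately avoid because the real data sit outside
it.

## Read mining

Long reads are kept when length ≥ 15,000 bp and mean quality is strictly
above Q10, with read quality defined in error-probability space,
Q = −10·log₁₀(mean(10^(−qᵢ/10))) — the convention of the standard long-read
filtering tools (an arithmetic mean of Phred scores overstates quality).

rDNA detection replaces an external local aligner with an in-package
seed–chain–align mapper: exact k-mer anchors (k = 15) between a reference
and the read are chained along near-constant diagonals (drift ≤ 50,
skip ≤ 600 bp), chains need ≥ 2 anchors and a span ≥ 2k (suppressing chance
micro-matches), and each chain is scored by edlib global alignment over the
spanned segments. A read is rDNA-bearing when the union of gene-hit
intervals (18S, ITS1, 5.8S, ITS2, 28S; union gaps ≤ 25 bp bridged, the
footprint of an isolated substitution on exact anchors) reaches 1,000 bp of
the unit. ITS references count toward the rule because the rule concerns
the transcription unit, not only the genes; a flag can restrict it. The
identity floor defaults to 0.75 (tolerant of ~7% read error against ~0.2%
unit divergence); any mapper meeting the recall properties is conforming.

Short paired reads are preprocessed as the quantitative analyses expect:
pairs are dropped unless both mates have mean quality strictly above Q18,
survivors are 3′-trimmed to a uniform 120 bp.

## Repeat annotation and composition

Every library consensus (genes, ME fragments' full-length consensi,
satellite monomer) is located on both strands of each read. Adjacent
same-label placements within 100 bp (smaller than any simulated element,
larger than alignment jitter) are collapsed *before* uniqueness is
assessed, so a contiguous satellite array is one placement. Mapping quality
is a uniqueness proxy: `mapq = min(60, round(40·(1 − s2/s1)))` over best and
second-best scores of placements sharing ≥ 50% of the consensus interval,
with 60 for a unique placement and 0 when an equal-or-better home exists.
Only the limit cases (unique exact → 60, perfect ambiguity → 0) and
monotonicity are contractual; the numbers in between are not calibrated to
any external aligner. Hits below mapq 20 are discarded.

Per read, the surviving hits give an ordered composition in canonical
orientation (orientation voted by gene-hit basepairs). The R2-in-28S flag
tests whether an insertion-labelled hit, grown by 50 bp of slop, touches a
28S hit — with exact boundaries an insertion *abuts* the two flanking 28S
pieces rather than overlapping either. A read "spans a full IGS" when a 28S
hit is followed canonically by an 18S hit; only such reads are classified
against the cohort's modal IGS composition as canonical, ME-free, or
irregular (differs from modal and is not ME-free). Truncated reads are
ineligible — otherwise truncation would masquerade as irregularity. The
irregularity rule is a declared operationalisation: the field reports
"irregular patterns" without a formal criterion.

The insertion fraction by read counting is per fully-observed 28S copy, not
per read. A copy counts only when the read covers the whole
insertion-capable window (host gene length + insertion length downstream of
the copy's canonical 5′ edge): an inserted copy needs a longer window to be
seen complete, so without this equal-opportunity window empty copies are
oversampled and the estimate is biased low (we measured ≈ 0.25 for a
planted 1/3 without the correction).

"Adjacent to the rRNA genes" is operationalised as same-read co-occurrence
of an element hit and a gene hit; no distance is established in the field's
usage.

## Consensus polishing

In place of de novo assembly, `polish_consensus` builds a reference-guided
majority-vote consensus: each read's overlap with a seed region is located
by anchoring, globally aligned, and tallied per seed column over
{A, C, G, T, deletion}. Ties between bases break in fixed order A<C<G<T; a
deletion needs a strict majority over all bases; an insertion between
columns is emitted when more than half of covering reads agree (modal
sequence, lexicographic tie-break). Polishing refuses to run when more than
10% of columns have depth < 3 and reports the gaps.

## Satellite arrays and microsatellites

Tandem arrays are detected by self-comparison periodicity, the in-silico
counterpart of reading a self-dotplot: every repeated k-mer (k = 12) votes
with the spacing between consecutive occurrences (window 10–2000 bp); runs
of ≥ 5 supporting votes define candidate arrays; the period is the modal
spacing refined by the median of spacings within 20% of the mode; adjacent
monomers must align at ≥ 70% identity; arrays need ≥ ~2 copies; arrays
overlapping > 50% deduplicate to the higher copy number. Monomer length is
recovered within 2% for 157–400 bp monomers at ≤ 5% divergence, and random
10 kb sequences produce no arrays (measured false-positive rate 0/100).

Satellite *presence* in a read is a base-pair rule (≥ 200 bp of monomer
homology) and deliberately separate from array *geometry*: single partial
monomers count toward presence but not as arrays. A satellite-only read has
≥ 200 bp of satellite, no rDNA call and no IGS-element hit. Array-length
statistics (median, max, quartiles) are computed per array; a per-read
alternative would merge the two IGS copies a long read can hold, and is not
the default.

Microsatellite runs (motifs 2–10 bp, e.g. TTAGG, TTATG) are chained from
exact motif occurrences on either strand, require ≥ 3 copies and ≥ 90%
cyclic-motif agreement, and merge across gaps of one motif length.

## Variability: clustering and identity statistics

Gene regions are cut from rDNA reads that carry no R1/R2 hit (insertion-
bearing units are pseudogenised and would inflate variability), keeping
hits covering ≥ 50% of the reference region, in canonical orientation.

Clustering is the greedy incremental scheme of the classic identity-
threshold clusterers: sequences longest-first (ties by id), each joining
the first cluster (in creation order) whose representative it matches at
identity ≥ t, else founding a new cluster. Identity is matching columns
over the *shorter* sequence of a global alignment (the cited tools'
default; an alignment-length denominator is available behind a flag).
Default thresholds: 0.80 and 0.95. Cluster counts are non-increasing as the
threshold drops, and each member matches its representative at ≥ t — both
property-tested against an all-pairs oracle.

Identity statistics use a reference-anchored alignment (each sequence
globally aligned to the consensus; insertions relative to the consensus
ignored — the flagged alternative counts them as differences). The
identical-site fraction is the fraction of consensus columns where every
sequence carries the same non-gap base; average pairwise identity is
matching columns over mutually non-gap columns, averaged over pairs. The
identical-site fraction is the stricter statistic and cannot exceed the
pairwise mean for ≥ 3 sequences.

## Coverage profiling

Preprocessed short reads are placed on a single-unit consensus by k-mer
seeding plus edlib scoring; the best placement wins, equal scores break by
a seeded RNG, and placements under 90% identity are discarded. The
consensus is circular by default (one period of a tandem array), removing
unit-boundary edge artefacts. Because the tandem copies are near-identical,
depth on the consensus is the per-unit collapse, so
`block_means[element] / block_means[host]` estimates the fraction of units
carrying the element — valid only when the element is locus-restricted; an
element also present elsewhere in the genome inflates the ratio, which the
estimator flags in its note.

Smoothing is locally weighted linear regression with tricube weights over a
window of `span · length` nearest positions (span default 0.05; no span is
established for the published figures — sensitivity is a one-line change).
Constants and straight lines are reproduced exactly; output clamps at zero
since depth cannot be negative. The implementation is in-package so the
window and weight conventions are pinned; the statsmodels LOWESS is used in
the tests as an independent cross-check, never as the implementation.

`genome_proportion` is a read-mapping analogue of graph-clustering
abundance estimates: aligned read bp over total read bp. On uniform reads
it recovers a planted 0.5% locus share within ±0.1 absolute percentage
points; agreement with cluster-size-based estimates on real data is
expected only approximately.

## Benchmark study conditions and problem sizes

The validation experiments (`experiments.py`, driven by `analysis/` and
`scripts/acceptance.py`) use these conditions:

- **Mining**: ghost-moth-like preset (12 units of ~23.7 kb, 8 IGS elements
  of 588 bp–4.3 kb), 500 reads at e = 0 and at e = 0.07. Expected: perfect
  classification at e = 0; recall ≥ 0.99 on reads with ≥ 2 kb of genes at
  ONT error.
- **Composition**: same preset, 150 error-free unit-scale reads; per-read
  element order must equal the truth order.
- **Irregular fraction**: compact-IGS variant of the 8-element architecture
  (50 units, ~10.8 kb each) so that ~60% of unit-length reads span a full
  IGS; 12% of units shuffled; 500-read cohorts. The per-cohort
  classification is exact against truth, leaving ~1.9-point binomial
  sampling noise, so the experiment averages three independent cohorts.
- **Insertion fraction**: 157 bp-satellite landscape, f = 1/3 planted.
  Read-count route: two 800-read cohorts (copies counted per
  equal-opportunity window). Coverage route: ~50× trimmed-read depth on an
  insertion-bearing unit consensus.
- **Satellite geometry**: monomers 157/252/258/400 bp at 5% divergence,
  15 copies; 30 planted satellite-only reads over a locus whose arrays stay
  below the read-length floor (so the planted count is the exact truth).
- **Clustering**: two 10-sequence subfamilies at 10% mutual divergence,
  ≤ 1% within; 2 clusters at 0.95, 1 at 0.80.
- **Coverage machinery**: exact depth conservation, LOESS exactness to
  1e−6 on lines, block means to 1e−12 against a brute-force oracle.
- **Determinism**: two identical pipeline runs hash-compare equal.

## Known limitations

- The anchored mapper needs exact k-mer seeds; above ~15% read error or for
  references shorter than ~2k it will start missing placements. The study
  regimes (≤ 7% error, references ≥ 150 bp) are comfortably inside.
- The uniqueness filter silences regions duplicated within one read; on
  data whose units are shorter than the reads, per-element counts will be
  conservative (as with any mapping-quality threshold over tandem repeats).
- The irregularity measure depends on the modal composition and is only
  defined for cohorts with IGS-spanning reads.
- Satellite period estimation assumes the monomer is not itself strongly
  periodic; higher-order repeat structure is out of scope.
- The coverage-based insertion fraction assumes the element is restricted
  to the locus and the consensus is representative; both assumptions are
  stated in the estimate's note field rather than checked.
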