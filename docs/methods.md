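# Methods

This note documents the models and procedures the toolkit implements, the
parameters that matter, what the simulator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Canonical k-mer counting

K-mers are produced by sliding a window of k bases one base at a time
over each read; consecutive windows overlap in k−1 bases. Counting is
strand-neutral: each window is folded onto its canonical form, the
lexicographic minimum (A<C<G<T) of the k-mer and its reverse complement.
Windows containing an N are skipped entirely — no masking or substitution
— which keeps counts deterministic and matches common k-mer-counter
behaviour.

Internally k-mers are packed 2 bits per base into uint64, which caps k at
31 (the largest default the toolkit uses) and makes integer order equal
lexicographic order, so canonicalization is a vectorized `min`. Reads are
joined on `N` separators before packing so the vectorized path works on
long buffers; the separator windows are discarded by the N rule, making
joined and per-read counting provably identical. The test suite holds the
engine to exact equality with a naive window-enumeration oracle for
k ∈ {3, 15, 21, 31}.

Subsampling (screening only; default fraction 0.10) is systematic by
default — every round(1/f)-th read — because it is exactly reproducible
with no seed; a seeded Bernoulli mode is available. Tables serialize as
sorted two-column TSV under a self-describing header
(`#knowyourdata kmer-table v1 k=21`), diffable and language-neutral.

## Contamination screening

A read "hits" when it contains at least one canonical k-mer of the
reference table (`min_hit_kmers` raises the bar if desired; its default
of 1 is the most sensitive reading). Two percentages are reported:

- reads_with_hit_pct = 100 · hits / reads screened,
- ref_covered_pct = 100 · distinct reference k-mers observed anywhere in
  the sampled reads / reference k-mers total.

"Percentage of the contaminant genome covered" is implemented as
distinct-k-mer coverage, not per-base coverage: the screen is k-mer-native
and base coverage would require alignment, which this tool deliberately
does not do. `interpret_screen` encodes the decision logic: both metrics
high ⇒ true contamination; read hits high but coverage low ⇒ shared
k-mers between related organisms; otherwise clean. The default thresholds
(read hit 5%, coverage 20%) are configurable operating points, not
measurements; any pair in [0,100] is accepted.

Filtering never subsamples (a filter must be total to be useful) and
removes whole pairs when either mate hits, preserving pairing downstream.

## K-mer spectra

The spectrum is the histogram of multiplicity m versus the number of
distinct k-mers seen m times, computed separately for read 1, read 2 and
their pooled counts (pooled = spectrum of summed per-k-mer counts, not
the sum of histograms). At k = 31 and depth D with read length L, the
expected k-mer coverage of the main peak is D·(L−k+1)/L (≈ 35 at D = 50,
L = 100).

- **Error threshold**: the smallest m with bins[m+1] > bins[m] — the
  first valley separating the error peak (each sequencing error creates
  up to k novel k-mers, piling mass at multiplicity ~1) from signal. A
  monotone-decreasing histogram has no valley; the threshold falls back
  to 1 and the analysis is marked undetermined.
- **Peaks**: local maxima of a centred moving average (window 5 bins,
  configurable) restricted to m > threshold. Flat-top plateaus resolve to
  their leftmost bin. Small simulations produce jagged histograms;
  without smoothing, single-bin noise would masquerade as peaks.
- **Zygosity**: a heterozygous sample shows two peaks an octave apart —
  haplotype-specific k-mers appear in one haplotype only, so at half the
  depth of shared k-mers. Either peak of the pair can be the taller
  (their heights cross near a SNP rate of ~1% at k = 31, where a fraction
  1−(1−r)^k ≈ 27% of positions sit within k of a SNP), so the rule
  accepts a companion peak at main/2 or 2·main, within a ±25% relative
  tolerance, and requires the companion to reach ≥ 10% of the main peak's
  height so that tail noise cannot trigger the flag.
- **Genome size**: Σ_{m>threshold} m·bins[m] / main-peak multiplicity, in
  distinct-k-mer units (a proxy for bases up to k−1 edge effects). This
  standard mass-over-depth estimator assumes a single dominant coverage
  peak; on heterozygous samples its meaning depends on which octave peak
  is main, and it should be read qualitatively there.

## Nextera LMP analysis

The junction adaptor defaults to the 38-mer
`CTGTCTCTTATACACATCTAGATGTGTATAAGAGACAG` — the 19-base transposon end
sequence's reverse complement followed by the sequence itself. The
concatenation is its own reverse complement, so detection is inherently
strand-neutral. Matching is two-tier: any full 38-base window may carry
up to ⌊0.11 · 38⌋ = 4 mismatches, and end overlaps (a junction prefix
running off the read's 3′ end, or a suffix at the 5′ start) qualify down
to 18 bases with the budget scaled as ⌊0.11 · overlap⌋. These thresholds
are configurable defaults chosen to make the false-positive probability
on random sequence negligible (~10⁻⁹ per position for an 18-base overlap
with 1 mismatch) while tolerating realistic error rates.

Pairs are categorized A (junction in both reads), B (read 2 only), C
(read 1 only), D (neither); reads are clipped at the junction start, and
pairs whose clipped mate falls below `min_length` (default 25) are
excluded from output files but still counted in their category, so
category counts always sum to the input.

PCR duplication is estimated from signatures built from the first 16
bases of each raw mate (clipping varies with adaptor position; raw
prefixes are stable): rate = 100·(1 − distinct/total). Spiking a
duplicate fraction d yields 100·d/(1+d) by construction, which the tests
assert exactly.

Orientation is geometric, from alignments the caller supplies (the
toolkit performs no alignment): with `left` the mate at the smaller
position, inward (+,−) is paired-end geometry, outward (−,+) is
mate-pair geometry, equal strands are tandem; insert size is the 1-based
inclusive span between outermost aligned coordinates. Whether genuine
Nextera LMP pairs surface inward or outward after circularization is a
library-chemistry fact left to the user's labelling; the toolkit reports
the geometry.

## Offset-barcode demultiplexing

Every (sample, offset) candidate is scored jointly — no first-match
shortcut, so results are order-independent. A candidate requires the
barcode at [offset, offset+len) with ≤ `max_barcode_mismatch` (default 1)
mismatches and the overhang immediately after with ≤
`max_overhang_mismatch` (default 0) mismatches. The overhang is what
anchors the offset, which is why it is exact by default — loosening it
inflates ambiguity. The unique minimum-mismatch candidate wins; ties are
ambiguous, no qualifying candidate is undetermined, and
assigned + undetermined + ambiguous always equals the input count.
Trimming removes filler and barcode from read 1 but keeps the overhang —
it is genomic sequence — and never touches read 2. With barcode sets of
pairwise Hamming distance > 2·max_barcode_mismatch at every offset
alignment, one error can never reach another sample's barcode, so
misassignment is structurally zero; the tests verify this on 10⁴
simulated reads.

## Read metrics

Per-cycle quality statistics (mean, median, quartiles by linear
interpolation) are computed only over reads reaching each cycle. The
ambiguous headline "average length of read with quality at 30 or above"
is reported both ways it can be read — the mean count of Q ≥ 30 bases
per read, and the percent of reads whose mean quality is ≥ 30 (boundary
inclusive) — clearly labelled. Red flags are breaches of user-configured
minimums; none are enabled by default, and flags never alter exit codes.

## Metric store

A single-file SQLite database holds every metric with its run identity
(run alias, instrument, chemistry/software versions, lane, sample,
barcode) and one of three scopes: run, base (one position) or range
(inclusive 1-based span, e.g. bases 10–14). Upserts are idempotent on
(key, name, scope, positions); because SQLite treats NULLs in a primary
key as pairwise distinct, optional key fields are stored as sentinels
(lane −1, barcode '', positions 0) and mapped back on read. Numeric
values live in a REAL column (exact for float64 round-trips) with a text
fallback; aggregation over text raises rather than yielding silent NaNs.
The FastQC parser maps Basic Statistics to run scope, per-base quality
rows to base or range scope ("10" vs "10-14"), GC-content rows to
run-scope histogram records, and keeps module pass/warn/fail statuses;
row conservation (one block row ⇒ its column records) is tested. The
toolkit-report parser flattens every scalar losslessly and turns
integer-keyed histograms into base-scope series (histogram keys below 1,
e.g. a 0% GC bin, have no valid base position and are not stored as
series entries).

## Simulator

The simulator generates the study conditions the analyses are verified
under: i.i.d. random genomes at a configurable GC fraction (default 0.5),
optional second haplotype at a Bernoulli het-SNP rate, uniform read start
positions, per-base substitution errors, constant Q40 qualities or a
per-cycle profile, contaminant spikes at an exact fraction with seeded
interleaving, LMP libraries (fragment sizes normal, truncated at twice
the read length; the junction lands uniformly inside a secondary
molecule, leaving arms whose lengths equal the junction positions in the
reads), and RAD reads (offset filler + barcode + overhang + locus
sequence). Defaults are desk-scale: 100 kb genomes, depth 50, 100-base
reads — large enough for clean spectra and tight binomial checks, small
enough that the full suite runs in well under a minute.

The LMP truth table defines "adaptor present in a read" as at least
`min_overlap` (18) junction bases falling inside the read; an arm leaving
fewer visible bases is undetectable by any overlap-based method, so the
definition matches the detector's own visibility limit rather than
rewarding it. RAD barcode errors are placed inside the barcode only; an
error in the exact-match overhang forces "undetermined" by design, which
is documented behaviour, not a detection failure.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: genomic repeat structure (random 100 kb
sequences have essentially no repeated 31-mers, so real repeat-induced
spectrum shoulders are absent), indels, platform-specific error profiles
and quality miscalibration, GC-coverage bias, chimeras beyond the modelled
LMP artefacts, and PCR bias beyond explicit duplicate spiking. Exact
truth-recovery results (100% LMP categorization, zero demux
misassignment) are properties of error-free or single-error constructions
and set the method's ceiling, not its field performance.

## Pipeline

`run_pipeline` chains read metrics → contamination screen (each
configured reference) → optional spectra → MD5 manifest, then loads every
report into the metric store. Output is a pure function of (inputs,
config, seed); rerunning on identical inputs produces byte-identical
reports, which the tests assert. A stage failure names the stage and
returns exit status 2; red flags are reported but never change the exit
status, because flagging is advice to a human, not an error.

## Known limitations

- k ≤ 31 (uint64 packing); larger k would need two-word k-mers.
- In-memory counting only; ~10⁸ distinct k-mers is a practical ceiling,
  far above the toolkit's QC-scale use.
- The genome-size estimator is single-peak; polyploid or highly
  heterozygous samples need model-based fitting outside this scope.
- The metric store is single-process embedded storage, not a server.
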