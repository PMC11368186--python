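# Methods

## The hit-counting model

A guide is a 20-nt sequence read 5′→3′; position 19 abuts the PAM. Hit
counting emulates heuristic short-read mapping of guide sequences with a
seed requirement: a genomic window (either strand) is a hit iff the 12
PAM-adjacent bases (*seed*) match exactly and the 8 PAM-distal bases
carry at most 2 mismatches. Near-miss hits (1–2 distal mismatches) are
counted and reported but disqualify the guide from selection;
multiplicity counts only perfect hits. `N` in the genome matches
nothing: a window containing `N` anywhere in the protospacer span is
never a hit, and `N` never satisfies a PAM symbol.

PAM checking at hit sites is on by default (`require_pam_at_hits`):
only PAM-adjacent sites are cleavable, so counting PAM-less matches
would overstate the DSB dose. A flag disables it to reproduce
aligner-style counting of bare 20-mers, which has no PAM concept; both
modes are tested. The PAM is any IUPAC motif (default NGG), matched on
the protospacer's strand (3′ of it), i.e. at `[start+20, start+23)` in
+ orientation and at `[start−3, start)` for − strand hits, with `start`
always the leftmost protospacer coordinate.

Hit enumeration is seed-indexed: each chromosome's seed-length windows
are encoded base-4 into a sorted integer table built once per genome, so
each guide lookup is two binary searches (seed and its reverse
complement) plus per-site distal/PAM verification. The package carries a
deliberately independent oracle, `synthesis.brute_force_hits`, a
position-by-position scan with direct per-block mismatch counting; the
test suite asserts exact equality (coordinates, strands, mismatch
counts) on 100 seeded random genomes with planted sites and decoys.

## Candidate sampling and selection

Draws are split across chromosomes by a seeded multinomial with
probabilities proportional to chromosome length, then placed uniformly
over valid protospacer starts inside the allowed regions (introns
derived as exon gaps from the GTF, plus RepeatMasker intervals, merged
and restricted to the configured chromosomes). A draw is accepted when
the protospacer lies fully inside an allowed interval, starts with G, is
N-free, has a PAM on its source strand, and passes the simple-repeat
filter; rejected draws are redrawn up to 50× the chromosome quota before
a shortfall warning. Duplicate sequences collapse to one candidate with
identifiers assigned in first-draw order, making runs byte-reproducible
per seed. The nominal production pool size is 500,000 draws
(`DEFAULT_POOL_SIZE`); tests and examples use far smaller pools since
the contracts are size-independent.

Selection rejects a guide for any of: a near-miss hit anywhere
(`mismatched_hit`), a hit not fully contained in the allowed regions
(`off_region_hit` — containment is strict because a protospacer
straddling a region boundary is not "within" it), a hit on an unlisted
chromosome, two hits on one chromosome closer than `min_site_spacing`
(`clustered_hits`), or no hits at all. All applicable reasons are
reported. The spacing default is 10 kb: clustered cuts risk
rearrangements or large deletions rather than independent repair events,
and no smaller biological scale recommends itself; it is configurable.

Simple repeats are ≥ `min_units` (default 4) exact tandem copies of a
primitive unit of length ≤ `max_unit_len` (default 2) — excluding AAAA
and ACACACAC while passing e.g. GATTAATAGCCTAAACTGTC. Units are
canonicalized to their shortest period so an AAAAAAAA run is attributed
to unit A, not AA. Published multi-target guide sets do include 4-base
homopolymers, so the thresholds are fully configurable rather than
hard-coded.

## Assembly-panel validation and edit classification

A guide's haploid count on each panel assembly is its perfect-hit count
under the same policy; near-misses are tallied separately as warnings.
The diploid target number is 2 × the mean haploid count; both the exact
value and a rounded integer (half away from zero) are reported, plus a
concordance flag (all assemblies equal). The package does not silently
require concordance — the flag leaves that decision to the user.

Amplicons are classified against the unedited reference region by
global alignment with free end gaps (match +1, mismatch −1, gap open −2,
extend −1). Scores only shape the alignment path: classification is
threshold-free — any substitution, insertion or deletion whose span
intersects the inspection window (cut site ± 20 bp by default) makes the
call `edited`; differences outside the window are reported as evidence
only. The cut site is placed 3 bp 5′ of the PAM (canonical blunt-cut
geometry). Amplicons shorter than twice the window are classified on the
available span with a warning.

## Quantitation formulas

* Coverage depth = mapped reads × read length per pair (default
  300 = 2 × 150 nt) / span, for whole genomes or fixed windows.
* TE-family copies = mapped reads × 300 / (consensus length × genomic
  coverage depth): read base pairs per consensus base pair, normalized
  by depth, so one copy at uniform coverage gives 1.0.
* qPCR copies = 2^(reference CT − target CT), replicates averaged per
  assay and reference-gene means averaged into one reference CT. The
  exponent direction is fixed by the doubling model — more template ⇒
  lower target CT ⇒ larger estimate; the reversed direction would give
  sub-unity estimates for multi-copy elements, which is not meaningful.
  All reference genes present in a record are averaged.
* Insertion calls with read support < 2 are dropped; survivors are
  labeled `homozygous_like` when coverage frequency ≥ 0.7 (inclusive
  boundary), else `segregating`. Values are passed through unchanged;
  the caller's insertion-discovery tool, not this package, estimates
  frequencies.
* TSS distances are signed in gene orientation: negative = upstream of
  the nearest TSS (gene start on +, last spanned base on −),
  respecting gene strand; the within-1-kb flag uses |d| ≤ 1000
  inclusive. Orientation is sense/antisense when the insertion strand is
  known.

## Synthetic fixtures

The generator emulates the features the search logic actually exercises:
multi-chromosome i.i.d. genomes at a requested GC, random multi-exon
gene models (so introns exist) and TE intervals written as GTF and
RepeatMasker `.out`, perfect protospacer+PAM sites planted at chosen
multiplicities and spacings (order-statistics placement, so dense
packings up to capacity succeed), and near-miss decoys with exact,
verifiable mismatch placement — either random within the seed/distal
block or at explicit guide positions for boundary probes. After writing,
the genome is rescanned with the brute-force oracle; stray background
matches (expected ≪ 1 for 20-mers on ≤ 2 Mb random sequence) are
scrubbed so the recorded truth is exact, not probabilistic. Derived
assembly panels add SNPs and small indels that never touch protected
site spans; `break_sites f` instead destroys `round(f × k)` of the k
sites, each via one seed substitution in one randomly chosen assembly.

What the fixtures do **not** emulate: real repeat landscapes and
homology structure (nested/fragmented TEs, segmental duplications),
sequencing errors, or assembly artifacts. Passing tests therefore
demonstrate correctness of the counting, selection and estimation logic
under the stated model, not the biological hit spectrum of any real
genome; runs against a real reference use the same code paths via
`multiguide count`/`scan` on user-supplied files.

Quantitation inputs are simulated at the model level: target CTs are
constructed as reference CT − log₂(copies) plus Gaussian replicate
noise, TE read counts are Poisson at chosen copies × consensus length ×
depth / read length, and insertion calls carry requested
support/frequency pairs. Reads themselves are never simulated — the
estimators consume counts, so count-level simulation is the appropriate
fidelity.

## Numerical and design choices

* All internal coordinates are 0-based half-open; GTF and RepeatMasker
  readers shift the start by exactly one at the boundary. Hits sort by
  (chromosome, start, + before −); candidate ids follow draw order.
* A palindromic or overlapping occurrence on the opposite strand is a
  distinct hit.
* Introns are exon gaps per transcript, unioned across transcripts, with
  no UTR subtraction; GTF `intron` features are ignored as derived data.
* Soft-masked bases are uppercased and scanned normally (TE regions are
  intentionally targeted); `respect_softmask` excludes candidates
  sourced from masked spans.
* Diploid rounding is half away from zero; ties cannot arise for
  concordant panels, whose exact value is an even integer.
* Test problem sizes — 100 oracle genomes of ~21 kb, planted
  multiplicities up to 53 on a ~0.6 Mb chromosome, χ² sampling at
  n = 100,000, 100-run Monte-Carlo qPCR recovery — were chosen so the
  whole suite runs in seconds while still exercising every boundary in
  the model at full fidelity.

## Known limitations

No off-target scoring (CFD/MIT), no RNA–DNA bulge alignment, no
cleavage-efficiency prediction, and no liftover between assemblies —
multiplicity is validated by re-counting on each assembly instead.
GFF3 input and compressed random access for larger-than-memory genomes
are out of scope; the seed index holds one sorted int64 per genome
position, comfortable for invertebrate-scale genomes on a laptop.
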