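# Methods

## The problem and the evidence model

A transposable element (TE) that is active in a sequenced individual leaves
insertion sites that the reference assembly does not contain.  Short reads
cannot be assembled through such sites, but they carry two complementary
signals:

* **Flankers** — reads that cross a junction between genomic sequence and a
  TE end.  After the TE portion is trimmed off, the remaining flank maps
  immediately left or right of the insertion point.  Because class 2
  elements and LTR retrotransposons duplicate their target site (TSD) on
  insertion, the left flank ends with the TSD and the right flank begins
  with it: at a true site the two trimmed flanks overlap by *exactly* the
  TSD-width window, and the reference sequence in that window satisfies the
  TSD specification.
* **Spanners** — reads that cover the same target site in the reference
  without any TE sequence.  They witness an allele (or a cell population)
  that lacks the insertion.

Discovery uses only flankers; genotyping compares the average flanker count
F = (left + right)/2 — averaged because one insertion produces flanking
evidence at both ends — with the spanner total S.

## TE matching and trimming

Reads are scanned against the TE in both orientations with an exact-seed
(default 7 nt), ungapped-extension matcher.  Windows shorter than
`min_aligned` (default 10 nt) are ignored; the mismatch fraction
(mismatches / aligned length) must be ≤ the allowance, default 0, boundary
inclusive.  `N` never matches.  Gapped read-vs-TE alignment is deliberately
unsupported: junction reads are short and the default demands perfection.
Seeds are taken at every read position, a superset of coarser tiling, so at
allowance 0 every retained match is an exact substring relation.

Only matches containing the first or last TE base can arise from a
junction; internal matches are dropped.  Trimming removes the TE-matching
interval and everything beyond it toward the TE-side read end.  Reads that
are TE from end to end carry no positional information and are discarded,
as are flanks of ≤ 10 bp ("longer than 10" read strictly).  A match that
covers the *entire* TE with genomic sequence on both sides — a read
spanning a short element — yields two flanks, one per junction; an internal
partial match is geometrically inconsistent with a junction read and yields
none.

## Flanker placement and calling

Trimmed flanks are placed on the reference by exact 8-mer seeding plus
full-length ungapped scoring, both strands.  A flank is kept only if it has
a single best-scoring location with ≤ 3 mismatches; everything
multi-mapping is discarded, which makes insertions inside repetitive
sequence undetectable — a deliberate stringency, not a bug to fix.  Side
assignment is a pure function of the trim tag and the alignment strand
(trimmed-at-end on `+`, or trimmed-at-start on `-`, is a left flanker; the
mirror cases are right flankers).

Overlap-sorted flankers are clustered by single linkage (≥ 1 bp overlap).
Within a cluster, only the TE-adjacent window of each flank is examined:
the terminal TSD-width window of each left flanker and the initial window
of each right flanker.  A call requires one left and one right window on
the *identical* reference interval whose sequence satisfies the TSD matcher
on either strand (an exact TSD and its reverse complement are both
accepted).  Several distinct satisfying windows in one cluster (tandem
events) produce several calls.  The TE strand is reported when the
flankers' TE-end votes agree, `.` otherwise.  Coordinates are 0-based
half-open internally and 1-based inclusive (`chrom:start..end`) in every
report; the last-base coordinate is exposed as well since some conventions
report only that base.

TSD specifications must be fixed-width (exact sequence, integer length, or
fixed-width IUPAC/regex pattern); variable-width patterns are rejected
rather than guessed because the overlap test needs a fixed width.

## Reference copies

With the reference scan enabled, full-length TE copies are located by
seeded ungapped matching on both strands, with ragged ends trimmed at the
first 10-bp exact run; a copy must be within ±10% of the TE length with
< 10% mismatches over the element.  A copy with at least one trimmed-read
flanker within a few bases of either end is *shared*; a copy with no such
support is *reference-only* (which may mean excision in the sequenced
strain, a reference-private insertion, or missing coverage).  One-ended
support counts as shared — support at one end is not "a lack of reads".

## Genotype classification

The cascade (first satisfied rule wins) is documented in
`tetrace.genotype`; three clauses deserve their rationale:

* Rule iii, "20% fewer spanners than flankers but no more than 10
  spanners", is implemented as S ≤ F/5 (spanners at most 20% *of*
  flankers).  The alternative reading S ≤ 0.8·F would classify a clearly
  heterozygous site like (13.5, 8) as homozygous-with-excision; the chosen
  reading reproduces all published example classifications.
* "The average number of reads" in rules v and vii is (F+S)/2.
* Rule vi requires each of F and S to exceed 10 (not their sum); under the
  sum reading rule vii would be unreachable.

F can be half-integral, so all comparisons use exact rational arithmetic
(`fractions.Fraction`); nothing is rounded.  Rules ii/iii can claim
low-coverage heterozygous sites (e.g. F=6, S=3 fires rule ii); this is
faithful to the cascade and intentionally not "fixed" with a coverage
floor.

**Spanner definition.**  A spanner must cover the whole TSD interval in one
gap-free aligned block, extended by one TSD width on each side (clipped at
contig ends), with no mismatch in that window when the alignment records
mismatches (=/X CIGARs).  The margin exists because a junction read whose
few residual TE bases were absorbed as mismatches would otherwise count as
a spanner; requiring clean sequence just past the target site excludes it
while costing genuine spanners only a slightly narrower placement window.
Plain-M alignments from external mappers are held to the coverage
requirement only.

**Footprints.**  Imprecise excisions leave a few bases at the site.  They
are detected from the indel pileup of the whole-read alignment: the
most-supported indel within ± one TSD width of the site, requiring ≥ 2
distinct reads by default (exposed as `--min-footprint-support`).  Two
evidence filters keep junction artifacts out: an indel counts only if it
sits ≥ 10 aligned bases from both read ends, and only alignments with a
single indel op contribute — a TE stub absorbed by the aligner shows up as
a terminal indel or an indel ladder, whereas a genuine footprint is one
contiguous indel seen mid-read.  Precise excisions leave no footprint; they
surface only through rules ii/iii at homozygous-classified loci, and are
fundamentally invisible at heterozygous loci because a perfect-excision
spanner is indistinguishable from the insertion-free allele's spanner.

## Read preparation and whole-read alignment

Quality handling follows FASTX-Toolkit semantics: 3' trimming below
Phred 20 stopping at the first good base, discard below 50 bp, then a
filter keeping reads with ≥ 80% of bases at ≥ Q20 (boundary inclusive).
Mate synchronisation emits proper pairs and keeps singletons (more spanner
evidence).  Partitioning chunks the stream without splitting pairs;
chunked and whole-input processing give byte-identical reports.

The whole-read aligner — needed for spanner counting and footprints —
places each read at its best location using exact 13-mer seeds to nominate
candidate windows and edlib infix alignment inside each window for the edit
distance and CIGAR.  The band (default 8 bp, ≥ TSD width + 3) bounds
representable indels so footprints survive; the edit budget defaults to 6%
of the read length (minimum 4), sized so a footprint indel plus a
sequencing error still aligns while junction reads with more than a
handful of TE bases fail to place.  Multi-best reads are written with
mapping quality 0 and excluded from spanner and footprint evidence.  Any
coordinate-sorted SAM/BAM from a standard mapper can be substituted.

## The simulator

`tetrace.simulate` generates what the pipeline assumes: a random reference
(default 100 kb, GC 0.5), a random TE (default 430 bp, `TSD=TAA`, the
geometry of *mPing*), and a diploid individual whose planted events
duplicate the target site.  Somatic events are realised as extra cell
lineages mixed at their cell fraction; excisions restore the reference
(precise) or leave `TSD + footprint + TSD` (imprecise).  Reads (default
100 bp, 30× — the middle of the coverage range this kind of study uses)
are sampled uniformly across lineages weighted by fraction, half from each
haplotype, with substitution errors at 0.002 and a quality drop on errored
bases; paired mode draws fragments from Normal(350 bp, 50 bp), typical of
TruSeq-style libraries.  The default somatic cell fraction is 0.1, the
rarity implied by the one-or-two flankers such events show at ~30×.

The simulator does **not** model indel sequencing errors, quality-profile
structure, PCR duplicates, or repetitive genomic context.  Passing tests on
this data therefore demonstrate the pipeline's logic — junction detection,
TSD-overlap calling, the count-ratio cascade, footprint pileups — not its
behaviour in repeats (where multi-mapping discards evidence by design) or
under real error profiles.

## Problem sizes, determinism, degenerate inputs

The test suite runs the full pipeline at 30× on 100 kb with 20 planted
germline events (all homozygous events must be recovered at their exact
spans, ≥ 90% of germline genotypes correct), and the somatic-attrition
property on twenty 20-kb replicates (halving reads must lose a strictly
larger fraction of somatic than homozygous calls).  These sizes are chosen
to exercise every stage at realistic coverage while keeping the suite
quick to run.  All randomness flows from explicit seeds (numpy
`default_rng`); same-seed runs are byte-identical.  Degenerate inputs have
defined behaviour: empty call lists give header-only reports, TE-free read
sets give empty call sets and exit 0, malformed TSD tokens and
out-of-reference coordinates raise errors naming the offender, and CLI
usage errors exit with status 2.

## Known limitations

* Insertions inside repetitive sequence are undetectable (unique-mapping
  requirement, inherited deliberately).
* Flanker placement is ungapped; a polymorphism with an indel inside the
  flank loses that read.
* Reference-copy scanning is ungapped, so diverged copies with indels may
  fall outside the ±10% length window.
* Genotype calls are rule-based counts, not likelihoods; no quality scores
  are attached, and polyploids are out of scope.
* Heterozygous-site precise excisions cannot be identified, by the nature
  of the evidence.
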