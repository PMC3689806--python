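"""Genotype non-reference insertions from flanker and spanner read counts.

At an insertion site the reads split into *flankers* — junction reads that
carry part of the TE and flank the target site — and *spanners* — reads
that cover the target site in the reference with no gap and no TE
sequence.  Flankers witness the allele carrying the insertion; spanners
witness the allele (or the cells) without it.  The average of the left and
right flanker counts, F (averaged because one insertion produces flanking
reads at both ends), is compared with the spanner total S through a fixed
rule cascade, evaluated in order, first match wins:

 i.    S == 0                        -> homozygous
 ii.   F >= 5 and S < 5              -> homozygous with somatic excision
 iii.  S <= 10 and S <= F/5          -> homozygous with somatic excision
 iv.   F <= 2 and S > 10             -> somatic insertion
 v.    |F - S| <= (F+S)/2 + 10       -> heterozygous
 vi.   F > 10 and S > 10             -> heterozygous
 vii.  F <= 10 and |S - F| > (F+S)/2 -> somatic insertion
 viii. anything else                 -> other

"the average number of reads" in rules v and vii is (F+S)/2.  F may be
half-integral, so comparisons use exact rational arithmetic.

Somatic excisions that leave a footprint are detected from the indel
pileup of the whole-read alignment within ± one TSD width of the target
site.  Precise excisions leave no footprint and are only inferable at
homozygous-classified loci: at a heterozygous locus a perfect-excision
spanner is indistinguishable from a spanner of the insertion-free allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import pysam

from .model import InsertionCall

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
SOMATIC_INSERTION = "somatic_insertion"
HOMOZYGOUS_SOMATIC_EXCISION = "homozygous_somatic_excision"
OTHER = "other"

# (rule name, predicate(F, S), genotype), evaluated in this order
RULES: tuple = (
    ("i", lambda F, S: S == 0, HOMOZYGOUS),
    ("ii", lambda F, S: F >= 5 and S < 5, HOMOZYGOUS_SOMATIC_EXCISION),
    ("iii", lambda F, S: S <= 10 and S <= F / 5, HOMOZYGOUS_SOMATIC_EXCISION),
    ("iv", lambda F, S: F <= 2 and S > 10, SOMATIC_INSERTION),
    ("v", lambda F, S: abs(F - S) <= (F + S) / 2 + 10, HETEROZYGOUS),
    ("vi", lambda F, S: F > 10 and S > 10, HETEROZYGOUS),
    ("vii", lambda F, S: F <= 10 and abs(S - F) > (F + S) / 2, SOMATIC_INSERTION),
    ("viii", lambda F, S: True, OTHER),
)


@dataclass(frozen=True)
class FootprintCall:
    """An indel left at an excision site."""

    indel_type: str  # insertion | deletion
    offset: int  # signed bp from the TSD interval (0 = inside it)
    supporting_reads: int


@dataclass(frozen=True)
class GenotypeCall:
    site: InsertionCall
    avg_flankers: Fraction
    spanners: int
    genotype: str
    rule_fired: str
    footprint: Optional[FootprintCall] = None


def classify_genotype(
    F, S, rules: Sequence = RULES
) -> tuple[str, str]:
    """Classify a site from average flankers F and spanner total S.

    Returns (genotype, rule name of the first satisfied rule).  F must be
    positive — a site only exists through flankers — and S non-negative.
    """
    F = Fraction(F)
    S = Fraction(S)
    if F <= 0:
        raise ValueError("average flanker count must be positive")
    if S < 0:
        raise ValueError("spanner count cannot be negative")
    for name, pred, genotype in rules:
        if pred(F, S):
            return genotype, name
    raise AssertionError("rule cascade is not total")  # pragma: no cover


def _gapless_blocks(
    aln: pysam.AlignedSegment,
) -> list[tuple[int, int, tuple[int, ...]]]:
    """Maximal gap-free reference intervals covered by this read.

    Each block is (start, end, mismatch reference positions).  Aligned
    (M/=/X) stretches merge; any insertion or deletion breaks the block, so
    a read whose alignment opens a gap across a window does not span that
    window contiguously.  Mismatch positions are known only for =/X CIGARs
    (as our internal aligner writes); plain-M alignments yield none.
    """
    blocks = []
    pos = aln.reference_start
    cur_start = None
    mismatches: list[int] = []
    for op, length in aln.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            if cur_start is None:
                cur_start = pos
                mismatches = []
            if op == 8:
                mismatches.extend(range(pos, pos + length))
            pos += length
        elif op in (2, 3):  # D, N consume reference and break the block
            if cur_start is not None:
                blocks.append((cur_start, pos, tuple(mismatches)))
                cur_start = None
            pos += length
        elif op == 1:  # I breaks the block without consuming reference
            if cur_start is not None:
                blocks.append((cur_start, pos, tuple(mismatches)))
                cur_start = None
        # S, H, P: no reference consumption, no block effect
    if cur_start is not None:
        blocks.append((cur_start, pos, tuple(mismatches)))
    return blocks


def _read_indels(
    aln: pysam.AlignedSegment, end_margin: int = 10
) -> list[tuple[str, int, int]]:
    """(type, reference position, length) for each interior I/D.

    Indels closer than ``end_margin`` aligned bases to either end of the
    read are ignored, and alignments containing more than one indel op
    contribute nothing: terminal indels and indel ladders are how a
    junction read's residual TE stub gets absorbed, whereas a genuine
    excision footprint is one contiguous indel seen mid-read by the reads
    that span it.
    """
    n_indel_ops = sum(1 for op, _ in (aln.cigartuples or ()) if op in (1, 2, 3))
    if n_indel_ops != 1:
        return []
    out = []
    pos = aln.reference_start
    qpos = 0
    qlen = aln.query_length or sum(
        l for op, l in (aln.cigartuples or ()) if op in (0, 1, 4, 7, 8)
    )
    for op, length in aln.cigartuples or ():
        if op in (0, 7, 8):
            pos += length
            qpos += length
        elif op == 1:
            if qpos >= end_margin and qlen - (qpos + length) >= end_margin:
                out.append(("insertion", pos, length))
            qpos += length
        elif op in (2, 3):
            if qpos >= end_margin and qlen - qpos >= end_margin:
                out.append(("deletion", pos, length))
            pos += length
        elif op == 4:
            qpos += length
    return out


class AlignmentStore:
    """Whole-read alignments (untrimmed reads vs the reference), loaded once.

    Reads flagged ambiguous by the aligner (mapping quality 0) are kept out
    of spanner counting and footprint evidence.
    """

    def __init__(self, sam_path):
        self.chrom_lengths: dict[str, int] = {}
        self.blocks: dict[str, list[tuple[int, int, tuple[int, ...]]]] = {}
        self.indels: dict[str, list[tuple[str, int, int, str]]] = {}
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
            for name, length in zip(sam.references, sam.lengths):
                self.chrom_lengths[name] = length
                self.blocks[name] = []
                self.indels[name] = []
            for aln in sam:
                if aln.is_unmapped or aln.mapping_quality == 0:
                    continue
                chrom = aln.reference_name
                self.blocks[chrom].extend(_gapless_blocks(aln))
                for kind, pos, length in _read_indels(aln):
                    self.indels[chrom].append((kind, pos, length, aln.query_name))
        for chrom in self.blocks:
            self.blocks[chrom].sort()


def count_spanners(
    site: InsertionCall, store: AlignmentStore, margin: Optional[int] = None
) -> int:
    """Reads whose alignment covers the whole TSD interval with no gap.

    A spanner must contain no TE sequence, so the covering block has to
    extend ``margin`` bases (default: one TSD width) past the target site
    on each side and carry no mismatch in that window — a junction read
    whose residual TE stub was absorbed as mismatches fails both.  The
    window is clipped at contig ends.  Alignments without =/X mismatch
    information are held only to the coverage requirement.
    """
    iv = site.tsd_interval
    if iv.chrom not in store.chrom_lengths:
        raise ValueError(f"site {site.span}: chromosome absent from alignments")
    m = len(iv) if margin is None else margin
    lo = max(0, iv.start - m)
    hi = min(store.chrom_lengths[iv.chrom], iv.end + m)
    return sum(
        1
        for (s, e, mism) in store.blocks[iv.chrom]
        if s <= lo and e >= hi and not any(lo <= p < hi for p in mism)
    )


def _indel_offset(pos: int, start: int, end: int) -> int:
    if pos < start:
        return pos - start
    if pos >= end:
        return pos - (end - 1)
    return 0


def detect_footprint(
    site: InsertionCall,
    store: AlignmentStore,
    tsd_width: Optional[int] = None,
    min_support: int = 2,
) -> Optional[FootprintCall]:
    """Most-supported indel within ± one TSD width of the target site.

    Returns None when no indel in the window reaches ``min_support``
    distinct reads.
    """
    iv = site.tsd_interval
    w = tsd_width if tsd_width is not None else len(iv)
    groups: dict[tuple[str, int, int], set[str]] = {}
    for kind, pos, length, read_id in store.indels.get(iv.chrom, ()):
        if abs(_indel_offset(pos, iv.start, iv.end)) <= w:
            groups.setdefault((kind, pos, length), set()).add(read_id)
    best = None
    for (kind, pos, length), readers in sorted(groups.items()):
        if len(readers) < min_support:
            continue
        if best is None or len(readers) > best[1]:
            best = ((kind, pos), len(readers))
    if best is None:
        return None
    (kind, pos), support = best
    return FootprintCall(kind, _indel_offset(pos, iv.start, iv.end), support)


def characterize_all(
    calls: Iterable[InsertionCall],
    sam_path,
    min_footprint_support: int = 2,
) -> list[GenotypeCall]:
    """Genotype every site in a non-reference insertion report.

    F comes from the report's left/right flanker counts, S from the
    whole-read alignment; the rule cascade and the footprint detector do
    the rest.  Sites whose coordinates do not exist in the alignment's
    reference are reported together in one error.
    """
    calls = list(calls)
    store = AlignmentStore(sam_path)
    bad = [
        c.span
        for c in calls
        if c.tsd_interval.chrom not in store.chrom_lengths
        or c.tsd_interval.end > store.chrom_lengths[c.tsd_interval.chrom]
    ]
    if bad:
        raise ValueError(
            "sites outside the alignment reference: " + ", ".join(bad)
        )
    out = []
    for call in calls:
        F = Fraction(call.left_count + call.right_count, 2)
        S = count_spanners(call, store)
        genotype, rule = classify_genotype(F, S)
        footprint = detect_footprint(call, store, min_support=min_footprint_support)
        out.append(GenotypeCall(call, F, S, genotype, rule, footprint))
    return out


GENOTYPE_COLUMNS = (
    "te_name",
    "coordinates",
    "avg_flankers",
    "spanners",
    "genotype",
    "rule",
    "footprint_type",
    "footprint_offset",
    "footprint_reads",
)


def write_genotype_table(genotypes: list[GenotypeCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENOTYPE_COLUMNS) + "\n")
        for g in genotypes:
            fp = g.footprint
            fh.write(
                "\t".join(
                    [
                        g.site.te_name,
                        g.site.span,
                        f"{float(g.avg_flankers):g}",
                        str(g.spanners),
                        g.genotype,
                        g.rule_fired,
                        fp.indel_type if fp else ".",
                        str(fp.offset) if fp else ".",
                        str(fp.supporting_reads) if fp else ".",
                    ]
                )
                + "\n"
            )
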