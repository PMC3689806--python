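"""Raw-read preparation and the whole-read reference alignment.

Quality handling follows FASTX-Toolkit semantics: ``quality_trim`` removes
the maximal 3' suffix of bases below the trim threshold (stopping at the
first base from the 3' end at or above it) and drops reads left shorter
than the minimum length; ``quality_filter`` keeps a read only if at least
``min_fraction`` percent of its bases reach the filter threshold.  The
defaults (-l 50 -t 20, -q 20 -p 80) match common Illumina practice.

The whole-read aligner places each surviving read at its best location on
the reference, allowing mismatches and short indels, and writes a
coordinate-sorted SAM.  Candidate windows come from exact seed hits; the
alignment within each window is computed with edlib, whose edit path gives
the CIGAR (so excision footprints — small indels near a target site — stay
representable).  Reads with more than one best-scoring location are written
with mapping quality 0 and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import edlib
import pysam

from .model import SequenceRead, revcomp


@dataclass(frozen=True)
class QualityParams:
    trim_threshold: int = 20
    min_len_after_trim: int = 50
    filter_threshold: int = 20
    min_fraction: float = 80.0

    def __post_init__(self):
        if self.trim_threshold < 0 or self.filter_threshold < 0:
            raise ValueError("quality thresholds must be >= 0")
        if not (0 < self.min_fraction <= 100):
            raise ValueError("min_fraction must be in (0, 100]")


def quality_trim(read: SequenceRead, params: QualityParams) -> Optional[SequenceRead]:
    """Trim low-quality 3' bases; None if the survivor is too short."""
    i = len(read)
    while i > 0 and read.quals[i - 1] < params.trim_threshold:
        i -= 1
    if i < params.min_len_after_trim:
        return None
    if i == len(read):
        return read
    return SequenceRead(read.id, read.bases[:i], read.quals[:i], read.mate)


def quality_filter(read: SequenceRead, params: QualityParams) -> bool:
    """Keep iff >= min_fraction % of bases are at or above the threshold."""
    if len(read) == 0:
        return False
    good = sum(1 for q in read.quals if q >= params.filter_threshold)
    return 100.0 * good / len(read) >= params.min_fraction


def apply_quality(
    reads: Iterable[SequenceRead], params: QualityParams
) -> Iterator[SequenceRead]:
    for read in reads:
        trimmed = quality_trim(read, params)
        if trimmed is not None and quality_filter(trimmed, params):
            yield trimmed


def sync_mates(
    reads: Iterable[SequenceRead],
) -> tuple[list[tuple[SequenceRead, SequenceRead]], list[SequenceRead]]:
    """Split surviving paired reads into proper pairs and singletons."""
    by_mate: dict[int, dict[str, SequenceRead]] = {1: {}, 2: {}}
    order: list[str] = []
    for r in reads:
        if r.mate not in (1, 2):
            raise ValueError(f"read {r.id!r} has no mate number; input is not paired")
        if r.id in by_mate[r.mate]:
            raise ValueError(f"duplicate read ID {r.id!r} in mate {r.mate} file")
        if r.id not in by_mate[3 - r.mate]:
            order.append(r.id)
        by_mate[r.mate][r.id] = r
    pairs, singletons = [], []
    for rid in order:
        r1, r2 = by_mate[1].get(rid), by_mate[2].get(rid)
        if r1 is not None and r2 is not None:
            pairs.append((r1, r2))
        else:
            singletons.append(r1 or r2)
    return pairs, singletons


def partition_reads(
    reads: Iterable[SequenceRead], chunk: int = 1_000_000, paired: bool = False
) -> list[list[SequenceRead]]:
    """Sequential chunking that preserves order and mate adjacency.

    With ``paired`` the input is interleaved mate pairs and a chunk
    boundary never splits a pair.  Concatenating the chunks reproduces
    the input exactly, so chunked and whole-input processing agree.
    """
    if chunk < 1:
        raise ValueError("chunk size must be >= 1")
    if paired and chunk % 2:
        chunk += 1
    out: list[list[SequenceRead]] = []
    cur: list[SequenceRead] = []
    for r in reads:
        cur.append(r)
        if len(cur) == chunk:
            out.append(cur)
            cur = []
    if cur:
        out.append(cur)
    return out


_EDLIB_TO_SAM = {"=": 7, "X": 8, "I": 1, "D": 2}


def _parse_edlib_cigar(cigar: str) -> list[tuple[int, int]]:
    out = []
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            out.append((_EDLIB_TO_SAM[c], int(num)))
            num = ""
    return out


def _clean_cigar(ops: list[tuple[int, int]]) -> tuple[int, list[tuple[int, int]]]:
    """Convert edge insertions to soft clips; return (ref shift, ops)."""
    shift = 0
    while ops and ops[0][0] == 2:  # leading deletion: advance ref start
        shift += ops[0][1]
        ops = ops[1:]
    while ops and ops[-1][0] == 2:
        ops = ops[:-1]
    if ops and ops[0][0] == 1:
        ops[0] = (4, ops[0][1])  # leading I -> S
    if ops and ops[-1][0] == 1:
        ops[-1] = (4, ops[-1][1])
    return shift, ops


@dataclass
class _Placement:
    chrom: str
    start: int
    strand: str
    edits: int
    cigar: list


def _candidate_windows(seq: str, index, band: int) -> dict[str, set[int]]:
    k = index.k
    n = len(seq)
    positions = list(range(0, n - k + 1, max(1, k))) or [0]
    if positions[-1] != n - k and n >= k:
        positions.append(n - k)
    cands: dict[str, set[int]] = {}
    for off in positions:
        for chrom, pos in index.seed_hits(seq[off : off + k]):
            start = pos - off
            cands.setdefault(chrom, set()).add(start - (start % band))
    return cands


def _align_one(
    seq: str, index, band: int, max_edits: int
) -> list[_Placement]:
    """Best gapped placements of one oriented sequence on the reference."""
    placements: dict[tuple[str, int, str], _Placement] = {}
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for chrom, starts in _candidate_windows(s, index, band).items():
            ref = index.reference[chrom]
            for w0 in starts:
                lo = max(0, w0 - band)
                hi = min(len(ref), w0 + n + 2 * band)
                if hi - lo < n // 2:
                    continue
                res = edlib.align(s, ref[lo:hi], mode="HW", task="path", k=max_edits)
                if res["editDistance"] < 0:
                    continue
                shift, ops = _clean_cigar(_parse_edlib_cigar(res["cigar"]))
                start = lo + res["locations"][0][0] + shift
                key = (chrom, start, strand)
                p = _Placement(chrom, start, strand, res["editDistance"], ops)
                if key not in placements or p.edits < placements[key].edits:
                    placements[key] = p
    if not placements:
        return []
    lo_e = min(p.edits for p in placements.values())
    return sorted(
        (p for p in placements.values() if p.edits == lo_e),
        key=lambda p: (p.chrom, p.start, p.strand),
    )


def align_whole_reads(
    reads: Iterable[SequenceRead],
    reference: dict[str, str],
    sam_path,
    seed_len: int = 13,
    band: int = 8,
    max_edits: Optional[int] = None,
) -> None:
    """Align untrimmed reads to the reference and write a sorted SAM.

    ``band`` bounds the representable indel size (kept >= TSD width + 3 by
    callers so footprints survive); ``max_edits`` defaults to 6% of the
    read length (min 4).  Ambiguous (multi-best) reads get mapping quality
    0; unplaceable reads are omitted.

    The default edit budget (6% of the read length, minimum 4) is sized so
    that an excision footprint — an indel of TSD width plus a few bases —
    plus a sequencing error still aligns, while junction reads carrying
    more than a handful of TE bases fail to place instead of being absorbed
    as long mismatch runs next to the target site.
    """
    from .caller import GenomeIndex  # local import to avoid a cycle

    index = GenomeIndex(reference, k=seed_len)
    chroms = sorted(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
    }
    records = []
    for read in reads:
        k = max_edits if max_edits is not None else max(4, len(read) * 6 // 100)
        best = _align_one(read.bases.upper(), index, band, k)
        if not best:
            continue
        mapq = 60 if len(best) == 1 else 0
        p = best[0]
        records.append((p.chrom, p.start, read, p, mapq))
    records.sort(key=lambda r: (r[0], r[1], r[2].id))
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(chroms)}
        for chrom, start, read, p, mapq in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.id if read.mate is None else f"{read.id}/{read.mate}"
            seq = read.bases if p.strand == "+" else revcomp(read.bases)
            quals = read.quals if p.strand == "+" else read.quals[::-1]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            a.flag = 16 if p.strand == "-" else 0
            a.reference_id = tid[chrom]
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigartuples = p.cigar
            a.set_tag("NM", p.edits)
            out.write(a)


def process_raw_reads(
    reads: Iterable[SequenceRead],
    reference: dict[str, str],
    sam_path,
    params: QualityParams = QualityParams(),
    paired: bool = False,
    band: int = 8,
) -> list[SequenceRead]:
    """Quality-trim/filter, mate-sync if paired, align, write sorted SAM.

    Returns the surviving reads (pairs flattened, singletons retained and
    flagged only by their missing mate).
    """
    survivors = list(apply_quality(reads, params))
    if paired:
        pairs, singletons = sync_mates(survivors)
        survivors = [r for pair in pairs for r in pair] + singletons
    align_whole_reads(survivors, reference, sam_path, band=band)
    return survivors
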