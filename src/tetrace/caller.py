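"""Map TE-trimmed flanks to the reference and call insertion sites.

A non-reference insertion is called when, after unique ungapped placement of
the trimmed flanks, at least one left flanker and one right flanker overlap
by exactly the target-site duplication: the terminal TSD-width window at the
left flanker's TE-adjacent (high-coordinate) end and the initial window at
the right flanker's TE-adjacent (low-coordinate) end must occupy the same
reference interval, whose sequence satisfies the TSD specification on either
strand.  Reads placeable at more than one best location are discarded, so
insertions inside repetitive sequence are undetectable — a deliberate
stringency of the method.

The module also scans the reference itself for full-length TE copies
(±10% of the query length, <10% mismatches over the element) and classifies
them as shared (flanker-supported in the reads) or reference-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import GenomicInterval, InsertionCall, TEModel, TsdMatcher, revcomp
from .tescan import TE_3PRIME, TE_5PRIME, TRIM_END, TRIM_START, TrimmedRead

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class FlankerAlignment:
    """A uniquely placed TE-trimmed read supporting one junction side."""

    read_id: str
    interval: GenomicInterval
    side: str  # left | right
    mismatches: int
    te_end_touched: str
    trimmed_read_end: str
    from_pair: bool = False


@dataclass(frozen=True)
class ReferenceTECopy:
    """A full-length TE copy found in the reference assembly."""

    interval: GenomicInterval
    identity_fraction: float
    length_fraction: float
    te_name: str
    copy_class: str = ""  # shared | reference-only, set by classify_reference_sites


class GenomeIndex:
    """Exact k-mer index over a reference for seed lookup."""

    def __init__(self, reference: dict[str, str], k: int = 8):
        self.reference = {c: s.upper() for c, s in reference.items()}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.reference.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _count_mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _place_sequence(
    bases: str, index: GenomeIndex, max_mismatch: int
) -> list[tuple[str, int, str, int]]:
    """Best ungapped placements (chrom, start, strand, mismatches) of a sequence.

    Candidates come from exact k-mer seeds taken at every position of the
    sequence (both strands); each candidate diagonal is scored over the full
    sequence length.  Only placements at the minimal mismatch count are
    returned, and only if that count is <= max_mismatch.
    """
    k = index.k
    best: dict[tuple[str, int, str], int] = {}
    for strand, seq in (("+", bases), ("-", revcomp(bases))):
        n = len(seq)
        if n < k:
            continue
        candidates = set()
        for off in range(n - k + 1):
            for chrom, pos in index.seed_hits(seq[off : off + k]):
                start = pos - off
                if start < 0 or start + n > len(index.reference[chrom]):
                    continue
                candidates.add((chrom, start))
        for chrom, start in candidates:
            window = index.reference[chrom][start : start + n]
            mm = _count_mismatches(seq, window, max_mismatch)
            if mm <= max_mismatch:
                best[(chrom, start, strand)] = mm
    if not best:
        return []
    lo = min(best.values())
    return [(c, s, st, mm) for (c, s, st), mm in best.items() if mm == lo]


def flanker_side(trimmed_read_end: str, strand: str) -> str:
    """Junction side supported by a flank, from its trim tag and strand.

    A read trimmed at its end aligning on + (or trimmed at its start
    aligning on -) sits upstream of the insertion: a LEFT flanker.  The
    mirror cases are RIGHT flankers.
    """
    if (trimmed_read_end == TRIM_END) == (strand == "+"):
        return LEFT
    return RIGHT


def align_trimmed_reads(
    trimmed: list[TrimmedRead],
    index: GenomeIndex,
    max_mismatch: int = 3,
    paired: bool = False,
    counts: Optional[dict] = None,
) -> list[FlankerAlignment]:
    """Uniquely place trimmed flanks on the reference.

    Placements with more than ``max_mismatch`` mismatches are dropped, as
    are reads with more than one best-scoring location.  Duplicate
    (read, placement) records are collapsed.  The result is sorted by
    chromosome then start coordinate.
    """
    out = []
    seen = set()
    stats = {"aligned": 0, "non_unique": 0, "unmapped": 0}
    for t in trimmed:
        placements = _place_sequence(t.bases, index, max_mismatch)
        if not placements:
            stats["unmapped"] += 1
            continue
        if len(placements) > 1:
            stats["non_unique"] += 1
            continue
        chrom, start, strand, mm = placements[0]
        key = (t.tagged_id, chrom, start, strand)
        if key in seen:
            continue  # duplicate placement (e.g. single and paired pass)
        seen.add(key)
        stats["aligned"] += 1
        out.append(
            FlankerAlignment(
                read_id=t.tagged_id,
                interval=GenomicInterval(chrom, start, start + len(t.bases), strand),
                side=flanker_side(t.trimmed_read_end, strand),
                mismatches=mm,
                te_end_touched=t.te_end_touched,
                trimmed_read_end=t.trimmed_read_end,
                from_pair=paired,
            )
        )
    if counts is not None:
        counts.update(stats)
    return sorted(out, key=lambda a: (a.interval.chrom, a.interval.start, a.read_id))


def cluster_flankers(alignments: list[FlankerAlignment]) -> list[list[FlankerAlignment]]:
    """Single-linkage clustering of flankers by interval overlap.

    Input must be sorted by chromosome then start (as align_trimmed_reads
    returns); overlapping alignments (>= 1 bp) join the same cluster.
    """
    clusters: list[list[FlankerAlignment]] = []
    cur: list[FlankerAlignment] = []
    cur_chrom, cur_end = None, -1
    for a in alignments:
        if a.interval.chrom != cur_chrom or a.interval.start >= cur_end:
            if cur:
                clusters.append(cur)
            cur = [a]
            cur_chrom, cur_end = a.interval.chrom, a.interval.end
        else:
            cur.append(a)
            cur_end = max(cur_end, a.interval.end)
    if cur:
        clusters.append(cur)
    return clusters


def _tsd_windows(
    cluster: list[FlankerAlignment], width: int
) -> dict[tuple[str, int, int], tuple[list, list]]:
    """Candidate TSD intervals -> (left flankers, right flankers) at them.

    Only the TE-trimmed end of each read is inspected: the terminal window
    of a left flanker, the initial window of a right flanker.
    """
    windows: dict[tuple[str, int, int], tuple[list, list]] = {}
    for a in cluster:
        iv = a.interval
        if len(iv) < width:
            continue
        if a.side == LEFT:
            key = (iv.chrom, iv.end - width, iv.end)
            windows.setdefault(key, ([], []))[0].append(a)
        else:
            key = (iv.chrom, iv.start, iv.start + width)
            windows.setdefault(key, ([], []))[1].append(a)
    return windows


def find_tsd_overlap(
    cluster: list[FlankerAlignment],
    tsd: TsdMatcher,
    reference: dict[str, str],
) -> Optional[GenomicInterval]:
    """First reference interval where left and right flankers overlap by the TSD."""
    for iv, _, _ in _satisfying_windows(cluster, tsd, reference):
        return iv
    return None


def _satisfying_windows(cluster, tsd, reference):
    out = []
    for (chrom, s, e), (lefts, rights) in sorted(_tsd_windows(cluster, tsd.width).items()):
        if not lefts or not rights:
            continue
        window_seq = reference[chrom][s:e]
        if len(window_seq) < tsd.width:
            continue
        if tsd.matches_either_strand(window_seq):
            out.append((GenomicInterval(chrom, s, e), lefts, rights))
    return out


def _strand_vote(lefts, rights) -> str:
    votes = set()
    for a in lefts:
        votes.add("+" if a.te_end_touched == TE_5PRIME else "-")
    for a in rights:
        votes.add("+" if a.te_end_touched == TE_3PRIME else "-")
    return votes.pop() if len(votes) == 1 else "."


def call_insertions(
    clusters: list[list[FlankerAlignment]],
    tsd: TsdMatcher,
    reference: dict[str, str],
    te_name: str,
) -> list[InsertionCall]:
    """Emit one call per TSD interval with >=1 left and >=1 right flanker.

    A cluster holding several distinct satisfying windows (tandem events)
    yields several calls.
    """
    calls = []
    for cluster in clusters:
        for iv, lefts, rights in _satisfying_windows(cluster, tsd, reference):
            tsd_seq = reference[iv.chrom][iv.start : iv.end]
            assert tsd.matches_either_strand(tsd_seq)
            supporting = tuple(sorted({a.read_id for a in lefts + rights}))
            calls.append(
                InsertionCall(
                    te_name=te_name,
                    tsd_interval=iv,
                    tsd_sequence=tsd_seq,
                    left_count=len(lefts),
                    right_count=len(rights),
                    te_strand=_strand_vote(lefts, rights),
                    supporting_read_ids=supporting,
                )
            )
    return sorted(calls, key=lambda c: (c.tsd_interval.chrom, c.tsd_interval.start))


def scan_reference_for_te(
    reference: dict[str, str],
    te: TEModel,
    seed_len: int = 12,
    min_length_fraction: float = 0.9,
    max_length_fraction: float = 1.1,
    max_mismatch_fraction: float = 0.10,
) -> list[ReferenceTECopy]:
    """Find full-length TE copies in the reference on both strands.

    Seeded, ungapped: candidate offsets come from exact seed hits; the TE is
    laid along the candidate diagonal and ragged ends (no 10-bp exact run)
    are trimmed.  A copy is kept if its aligned length is within ±10% of the
    TE length and its mismatches are <10% of the TE length.
    """
    L = te.length
    run_len = min(10, max(1, L // 4))
    hits: list[ReferenceTECopy] = []
    for strand, query in (("+", te.sequence), ("-", revcomp(te.sequence))):
        seeds: dict[str, list[int]] = {}
        step = max(1, seed_len // 2)
        for i in range(0, L - seed_len + 1, step):
            seeds.setdefault(query[i : i + seed_len], []).append(i)
        for chrom, seq in reference.items():
            offsets = set()
            for i in range(len(seq) - seed_len + 1):
                for qpos in seeds.get(seq[i : i + seed_len], ()):
                    offsets.add(i - qpos)
            for g0 in sorted(offsets):
                w_start = max(0, g0)
                w_end = min(len(seq), g0 + L)
                if w_end - w_start < min_length_fraction * L:
                    continue
                is_match = [
                    seq[g] == query[g - g0] and seq[g] != "N"
                    for g in range(w_start, w_end)
                ]
                f = _first_run(is_match, run_len)
                r = _first_run(is_match[::-1], run_len)
                if f is None or r is None:
                    continue
                a, b = f, len(is_match) - r
                aligned_len = b - a
                lf = aligned_len / L
                if not (min_length_fraction < lf < max_length_fraction):
                    continue
                mm = is_match[a:b].count(False)
                if mm / L >= max_mismatch_fraction:
                    continue
                hits.append(
                    ReferenceTECopy(
                        interval=GenomicInterval(
                            chrom, w_start + a, w_start + b, strand
                        ),
                        identity_fraction=1 - mm / aligned_len,
                        length_fraction=lf,
                        te_name=te.name,
                    )
                )
    # collapse overlapping hits (e.g. found on both strands), keep the best
    hits.sort(
        key=lambda h: (h.interval.chrom, h.interval.start, -h.identity_fraction)
    )
    kept: list[ReferenceTECopy] = []
    for h in hits:
        if kept and kept[-1].interval.overlaps(h.interval):
            if h.identity_fraction > kept[-1].identity_fraction:
                kept[-1] = h
            continue
        kept.append(h)
    return kept


def _first_run(is_match: list[bool], run_len: int) -> Optional[int]:
    streak = 0
    for i, m in enumerate(is_match):
        streak = streak + 1 if m else 0
        if streak == run_len:
            return i - run_len + 1
    return None


def classify_reference_sites(
    copies: list[ReferenceTECopy],
    alignments: list[FlankerAlignment],
    slop: int = 5,
) -> list[ReferenceTECopy]:
    """Label each reference copy shared or reference-only.

    A copy is shared if at least one TE-trimmed read aligns flanking either
    of its ends (within ``slop`` bp); a lack of such reads — which could
    reflect excision in the sequenced strain, a reference-specific
    insertion, or missing coverage — makes it reference-only.  One-ended
    support still counts as shared.
    """
    out = []
    for c in copies:
        iv = c.interval
        supported = any(
            a.interval.chrom == iv.chrom
            and (
                abs(a.interval.end - iv.start) <= slop
                or abs(a.interval.start - iv.end) <= slop
            )
            for a in alignments
        )
        out.append(
            ReferenceTECopy(
                interval=c.interval,
                identity_fraction=c.identity_fraction,
                length_fraction=c.length_fraction,
                te_name=c.te_name,
                copy_class="shared" if supported else "reference-only",
            )
        )
    return out
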