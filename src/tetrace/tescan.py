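"""Find TE sequence in short reads and trim it off, keeping the genomic flank.

A read that crosses a TE insertion junction contains TE sequence at one end
and unique genomic sequence (ending in the target-site duplication) at the
other.  The scanner finds every maximal ungapped match between a read and
the TE in both orientations, seeded by an exact k-mer (default 7, the BLAT
tile size the original protocol used) and extended while the mismatch
fraction stays within the caller's allowance.  Matches shorter than
``min_aligned`` (default 10) are ignored.

Only matches anchored at a TE extremity (first or last TE base) can come
from a junction; internal matches are filtered.  Retained reads are trimmed
of the TE-matching portion and everything beyond it toward the TE-side read
end; flanks of ``min_len`` bp or shorter are discarded, as are reads that
are TE from end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from .model import SequenceRead, TEModel, revcomp

FORWARD = "forward"
REVERSE = "reverse"

TE_5PRIME = "te_5prime"
TE_3PRIME = "te_3prime"

TRIM_START = "start"  # start of the read was trimmed of TE sequence
TRIM_END = "end"


@dataclass(frozen=True)
class TEMatch:
    """An ungapped alignment between a read segment and a TE segment."""

    read_id: str
    read_interval: tuple[int, int]  # [start, end) on the read
    te_interval: tuple[int, int]  # [start, end) on the TE (TE coordinates)
    orientation: str  # forward | reverse
    mismatches: int

    @property
    def aligned_len(self) -> int:
        return self.read_interval[1] - self.read_interval[0]

    def __post_init__(self):
        rl = self.read_interval[1] - self.read_interval[0]
        tl = self.te_interval[1] - self.te_interval[0]
        if rl != tl:
            raise ValueError("ungapped match must cover equal read and TE spans")
        if self.mismatches > rl:
            raise ValueError("more mismatches than aligned bases")


@dataclass(frozen=True)
class TrimmedRead:
    """The genomic flank left after removing TE sequence from a junction read.

    ``trimmed_read_end`` records which end of the read lost TE sequence
    (mirrored in the read name as a ``:start``/``:end`` tag);
    ``te_end_touched`` records which TE extremity the read crossed.
    """

    read_id: str
    bases: str
    quals: tuple[int, ...]
    trimmed_read_end: str  # start | end
    te_end_touched: str  # te_5prime | te_3prime
    orientation: str

    @property
    def tagged_id(self) -> str:
        return f"{self.read_id}:{self.trimmed_read_end}"


def mismatch_fraction(match: TEMatch) -> float:
    """Mismatches over aligned length (matches plus mismatches)."""
    return match.mismatches / match.aligned_len


@lru_cache(maxsize=8)
def _seed_index(sequence: str, seed_len: int) -> dict:
    index: dict[str, list[int]] = {}
    for i in range(len(sequence) - seed_len + 1):
        kmer = sequence[i : i + seed_len]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _base_match(a: str, b: str) -> bool:
    return a == b and a != "N"


def _diagonal_windows(
    read: str, target: str, diag: int, seed_len: int, min_aligned: int, allowance: float
) -> list[tuple[int, int, int]]:
    """Maximal windows (read_start, read_end, mismatches) on one diagonal.

    diag is target_pos - read_pos.  A window qualifies if it is at least
    min_aligned long, its mismatch fraction is <= allowance, and it
    contains at least one exact seed_len-mer (the seed requirement).
    """
    rs = max(0, -diag)
    re_ = min(len(read), len(target) - diag)
    if re_ - rs < min_aligned:
        return []
    is_match = [_base_match(read[i], target[i + diag]) for i in range(rs, re_)]
    n = len(is_match)

    if allowance <= 0:
        # runs of exact matches
        out = []
        i = 0
        while i < n:
            if is_match[i]:
                j = i
                while j < n and is_match[j]:
                    j += 1
                if j - i >= min_aligned:
                    out.append((rs + i, rs + j, 0))
                i = j
            else:
                i += 1
        return out

    # prefix sums of mismatches; enumerate maximal qualifying windows
    pref = [0]
    for m in is_match:
        pref.append(pref[-1] + (0 if m else 1))
    run = [0] * (n + 1)  # run[i]: exact-match run length ending at i
    for i in range(1, n + 1):
        run[i] = run[i - 1] + 1 if is_match[i - 1] else 0

    candidates = []
    for j in range(min_aligned, n + 1):
        # longest window ending at j satisfying the mismatch fraction
        best_i = None
        for i in range(0, j - min_aligned + 1):
            mm = pref[j] - pref[i]
            if mm <= allowance * (j - i):
                best_i = i
                break
        if best_i is None:
            continue
        # seed requirement: some exact run >= seed_len inside the window
        if max(run[best_i + 1 : j + 1], default=0) >= seed_len:
            candidates.append((best_i, j, pref[j] - pref[best_i]))
    # keep maximal windows only
    out = []
    for (i, j, mm) in candidates:
        if any(oi <= i and j <= oj and (oi, oj) != (i, j) for (oi, oj, _) in candidates):
            continue
        out.append((rs + i, rs + j, mm))
    return sorted(set(out))


def scan_read_for_te(
    read: SequenceRead,
    te: TEModel,
    seed_len: int = 7,
    min_aligned: int = 10,
    allowance: float = 0.0,
) -> list[TEMatch]:
    """Every maximal ungapped read/TE match in both orientations.

    ``allowance`` is the maximum mismatch fraction (mismatches over aligned
    length); the default 0 demands perfect alignment.  N bases never match.
    """
    bases = read.bases.upper()
    out = []
    for orientation, target in ((FORWARD, te.sequence), (REVERSE, revcomp(te.sequence))):
        index = _seed_index(target, seed_len)
        diagonals = set()
        for i in range(len(bases) - seed_len + 1):
            for tpos in index.get(bases[i : i + seed_len], ()):
                diagonals.add(tpos - i)
        for diag in sorted(diagonals):
            for (s, e, mm) in _diagonal_windows(
                bases, target, diag, seed_len, min_aligned, allowance
            ):
                ts, te_end = s + diag, e + diag
                if orientation == REVERSE:
                    ts, te_end = te.length - te_end, te.length - ts
                out.append(
                    TEMatch(read.id, (s, e), (ts, te_end), orientation, mm)
                )
    return sorted(set(out), key=lambda m: (m.read_interval, m.orientation))


def end_anchor_filter(matches: list[TEMatch], te: TEModel) -> list[TEMatch]:
    """Keep only matches that include the first or last base of the TE."""
    return [
        m
        for m in matches
        if m.te_interval[0] == 0 or m.te_interval[1] == te.length
    ]


def _flank_te_end(match: TEMatch, te: TEModel, flank_is_prefix: bool) -> Optional[str]:
    """Which TE extremity a read flank abuts, or None if it abuts internal TE.

    A prefix flank (genomic bases before the match in read orientation) abuts
    the TE base at te_interval.start in forward orientation and at
    te_interval.end in reverse orientation; mirrored for a suffix flank.
    Only flanks abutting TE position 0 (5') or length-1 (3') are junctions.
    """
    ts, te_end = match.te_interval
    if match.orientation == FORWARD:
        if flank_is_prefix:
            return TE_5PRIME if ts == 0 else None
        return TE_3PRIME if te_end == te.length else None
    if flank_is_prefix:
        return TE_3PRIME if te_end == te.length else None
    return TE_5PRIME if ts == 0 else None


def trim_te_sequence(
    read: SequenceRead, match: TEMatch, te: TEModel, min_len: int = 10
) -> list[TrimmedRead]:
    """Strip the TE-matching portion of a junction read, keeping the flank.

    Returns zero, one, or (when the match covers the whole TE with genomic
    sequence on both sides — a read spanning a short element) two trimmed
    reads.  All-TE reads, flanks of ``min_len`` bp or shorter, and matches
    inconsistent with junction geometry yield nothing.
    """
    a, b = match.read_interval
    n = len(read)
    covers_whole_te = match.te_interval == (0, te.length)
    internal = a > 0 and b < n
    if internal and not covers_whole_te:
        return []  # genomic sequence on both sides of a partial TE match
    out = []
    if a > 0:
        te_end = _flank_te_end(match, te, flank_is_prefix=True)
        if te_end is not None and a > min_len:
            out.append(
                TrimmedRead(
                    read_id=read.id,
                    bases=read.bases[:a],
                    quals=read.quals[:a],
                    trimmed_read_end=TRIM_END,
                    te_end_touched=te_end,
                    orientation=match.orientation,
                )
            )
    if b < n:
        te_end = _flank_te_end(match, te, flank_is_prefix=False)
        if te_end is not None and n - b > min_len:
            out.append(
                TrimmedRead(
                    read_id=read.id,
                    bases=read.bases[b:],
                    quals=read.quals[b:],
                    trimmed_read_end=TRIM_START,
                    te_end_touched=te_end,
                    orientation=match.orientation,
                )
            )
    return out


def scan_and_trim(
    reads,
    te: TEModel,
    seed_len: int = 7,
    min_aligned: int = 10,
    allowance: float = 0.0,
    min_len: int = 10,
    counts: Optional[dict] = None,
) -> list[TrimmedRead]:
    """Full read-level stage: scan, end-anchor filter, mismatch filter, trim."""
    trimmed = []
    stats = {"reads": 0, "matched": 0, "end_anchored": 0, "trimmed": 0}
    for read in reads:
        stats["reads"] += 1
        matches = scan_read_for_te(read, te, seed_len, min_aligned, allowance)
        if matches:
            stats["matched"] += 1
        matches = end_anchor_filter(matches, te)
        matches = [m for m in matches if mismatch_fraction(m) <= allowance]
        if matches:
            stats["end_anchored"] += 1
        got = []
        for m in matches:
            got.extend(trim_te_sequence(read, m, te, min_len))
        # one trim record per retained (read, junction side)
        seen = set()
        for t in got:
            key = (t.read_id, t.trimmed_read_end)
            if key not in seen:
                seen.add(key)
                trimmed.append(t)
        if got:
            stats["trimmed"] += 1
    if counts is not None:
        counts.update(stats)
    return trimmed
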