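"""Core domain types: TE models, reads, intervals, and TSD matchers.

A transposable element (TE) query is a sequence plus a description of the
target-site duplication (TSD) it creates on insertion.  The TSD may be an
exact sequence (``TSD=TAA`` for the rice MITE mPing), a fixed-width pattern
over the IUPAC/regex alphabet (``TSD=T[AT]A``), or just a length
(``TSD=9`` for elements where only the duplication width is conserved).

Coordinates are handled in two conventions:

* internally everything is 0-based, half-open (``GenomicInterval``);
* all user-facing output is 1-based, inclusive, rendered ``chrom:start..end``.

``to_one_based`` / ``from_one_based`` convert between the two and are
mutually inverse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC ambiguity codes, for TSD patterns like "TNA" or "RYN"
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class TsdSpecError(ValueError):
    """Raised for a malformed TSD specification token."""


@dataclass(frozen=True)
class TEModel:
    """A query transposable element: sequence plus TSD specification.

    ``tsd_spec`` is the raw token from the FASTA description line
    (e.g. ``TSD=TAA``); ``tsd`` is its parsed fixed-width matcher.
    """

    name: str
    sequence: str
    tsd_spec: str
    tsd: "TsdMatcher" = field(init=False, repr=False)

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"TE {self.name!r} has an empty sequence")
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"TE {self.name!r} contains non-DNA letters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "tsd", parse_tsd_spec(self.tsd_spec))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceRead:
    """A short read: id, optional mate number, bases and Phred qualities."""

    id: str
    bases: str
    quals: tuple[int, ...]
    mate: Optional[int] = None  # 1, 2 or None

    def __post_init__(self):
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} quality scores"
            )
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= 93):
            raise ValueError(f"read {self.id!r}: Phred scores outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def format_span(chrom: str, start: int, end: int) -> str:
    """Render an internal interval as the 1-based ``chrom:start..end`` form."""
    s1, e1 = to_one_based(start, end)
    return f"{chrom}:{s1}..{e1}"


_SPAN_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)\.\.(?P<end>\d+)$")


def parse_span(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start..end`` (1-based inclusive) to internal coordinates."""
    m = _SPAN_RE.match(text)
    if not m:
        raise ValueError(f"malformed coordinate span {text!r}")
    start, end = from_one_based(int(m.group("start")), int(m.group("end")))
    return m.group("chrom"), start, end


@dataclass(frozen=True)
class TsdMatcher:
    """Fixed-width matcher for a target-site duplication.

    kind is one of ``exact`` (a literal DNA word), ``pattern`` (fixed-width
    IUPAC/regex pattern) or ``length`` (any word of the given width).
    ``matches`` is defined for every string of length == width; N in the
    subject never matches an exact or pattern position (conservative).
    """

    kind: str
    value: str | int
    width: int
    _regex: Optional[re.Pattern] = field(default=None, repr=False, compare=False)

    def matches(self, s: str) -> bool:
        if len(s) != self.width:
            return False
        s = s.upper()
        if self.kind == "length":
            return True
        if "N" in s:
            return False
        if self.kind == "exact":
            return s == self.value
        return self._regex.fullmatch(s) is not None

    def matches_either_strand(self, s: str) -> bool:
        """True if the window or its reverse complement satisfies the TSD."""
        return self.matches(s) or self.matches(revcomp(s))


@dataclass(frozen=True)
class InsertionCall:
    """A non-reference TE insertion supported by TSD-overlapping flankers.

    ``tsd_interval`` is the target-site span in the reference (internal
    coordinates); ``tsd_sequence`` is the reference substring there.
    ``left_count``/``right_count`` are the numbers of left/right flanking
    reads whose TE-adjacent window coincides with that span.
    """

    te_name: str
    tsd_interval: GenomicInterval
    tsd_sequence: str
    left_count: int
    right_count: int
    te_strand: str = "."
    supporting_read_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.left_count < 1 or self.right_count < 1:
            raise ValueError(
                "an insertion call needs at least one left and one right flanker"
            )
        if len(self.tsd_sequence) != len(self.tsd_interval):
            raise ValueError("TSD sequence length does not match its interval")

    @property
    def span(self) -> str:
        iv = self.tsd_interval
        return format_span(iv.chrom, iv.start, iv.end)

    @property
    def last_base_position(self) -> int:
        """1-based coordinate of the last base of the target site."""
        return self.tsd_interval.end

    @property
    def avg_flankers(self) -> float:
        return (self.left_count + self.right_count) / 2


def _pattern_width(pat: str) -> int:
    """Width of a fixed-width regex/IUPAC pattern; -1 if variable or invalid."""
    width = 0
    i = 0
    while i < len(pat):
        c = pat[i]
        if c == "[":
            j = pat.find("]", i)
            if j < 0:
                return -1
            inner = pat[i + 1 : j]
            if not inner or not set(inner) <= set("ACGT"):
                return -1
            width += 1
            i = j + 1
        elif c in _IUPAC or c == ".":
            width += 1
            i += 1
        else:
            return -1
        # quantifiers make the width variable
        if i < len(pat) and pat[i] in "*+?{":
            return -1
    return width


def parse_tsd_spec(raw: str) -> TsdMatcher:
    """Parse a TSD token from a TE FASTA description line.

    Accepts ``TSD=<value>`` or a bare value: a literal DNA word, an
    integer length, or a fixed-width pattern (IUPAC codes, ``.``,
    ``[ACGT]`` classes).  Variable-width patterns are rejected: the
    TSD-overlap test needs a fixed overlap width.
    """
    token = raw.strip()
    if token.upper().startswith("TSD="):
        token = token[4:]
    if not token:
        raise TsdSpecError(f"empty TSD specification in {raw!r}")
    if token.isdigit():
        width = int(token)
        if width < 1:
            raise TsdSpecError(f"TSD length must be >= 1 in {raw!r}")
        return TsdMatcher("length", width, width)
    up = token.upper()
    if set(up) <= set("ACGT"):
        return TsdMatcher("exact", up, len(up))
    width = _pattern_width(up)
    if width < 1:
        raise TsdSpecError(
            f"TSD pattern {raw!r} is not a fixed-width DNA/IUPAC pattern"
        )
    expanded = []
    i = 0
    while i < len(up):
        c = up[i]
        if c == "[":
            j = up.find("]", i)
            expanded.append(up[i : j + 1])
            i = j + 1
        elif c == ".":
            expanded.append("[ACGT]")
            i += 1
        else:
            expanded.append(_IUPAC[c])
            i += 1
    return TsdMatcher("pattern", up, width, re.compile("".join(expanded)))
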