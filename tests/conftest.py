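"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pysam
import pytest

from tetrace.model import SequenceRead, TEModel


def mk_read(rid: str, bases: str, qual: int = 38, mate=None) -> SequenceRead:
    return SequenceRead(rid, bases, tuple([qual] * len(bases)), mate)


def mk_te(sequence: str, tsd: str = "TSD=TAA", name: str = "TE1") -> TEModel:
    return TEModel(name, sequence, tsd)


def write_sam(path, chrom_lengths: dict[str, int], records):
    """Write a minimal coordinate-sorted SAM.

    records: (name, chrom, start, cigar) or (name, chrom, start, cigar, mapq).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    rows = []
    for rec in records:
        name, chrom, start, cigar = rec[:4]
        mapq = rec[4] if len(rec) > 4 else 60
        rows.append((chrom, start, name, cigar, mapq))
    rows.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for chrom, start, name, cigar, mapq in rows:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.reference_id = tid[chrom]
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigarstring = cigar
            qlen = a.infer_query_length()
            a.query_sequence = "A" * qlen
            out.write(a)
    return path


@pytest.fixture
def small_genome():
    """A deterministic 4-kb single-chromosome reference."""
    from tetrace.simulate import generate_reference

    return generate_reference(seed=42, lengths=(4000,))
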