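"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ go through Biopython's SeqIO; the insertion report is the
fixed-column tab-delimited table described in :func:`write_insertion_table`;
annotated TE copies and calls are emitted as GFF3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .model import (
    GenomicInterval,
    InsertionCall,
    SequenceRead,
    TEModel,
    format_span,
    parse_span,
)

_MATE_SUFFIX = re.compile(r"[/_.]([12])$")


def _split_mate(read_id: str) -> tuple[str, Optional[int]]:
    m = _MATE_SUFFIX.search(read_id)
    if m:
        return read_id[: m.start()], int(m.group(1))
    return read_id, None


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a name -> uppercase sequence map."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_te_fasta(path) -> list[TEModel]:
    """Load TE queries; the TSD spec is a ``TSD=...`` token in the description."""
    tes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        token = None
        for word in rec.description.split():
            if word.upper().startswith("TSD="):
                token = word
                break
        if token is None:
            raise ValueError(
                f"TE {rec.id!r}: no TSD=... token in the FASTA description line"
            )
        tes.append(TEModel(rec.id, str(rec.seq).upper(), token))
    return tes


def _records_to_reads(path, mate: Optional[int]) -> Iterator[SequenceRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        base_id, id_mate = _split_mate(rec.id)
        quals = tuple(rec.letter_annotations["phred_quality"])
        yield SequenceRead(
            id=base_id if (mate or id_mate) else rec.id,
            bases=str(rec.seq).upper(),
            quals=quals,
            mate=mate or id_mate,
        )


def read_fastq(path, path2=None) -> Iterator[SequenceRead]:
    """Stream reads from FASTQ (Sanger Phred+33).

    With two files, mates are interleaved pairwise and must correspond in
    order; read IDs are normalised so both mates share an ID and carry
    mate numbers 1 and 2.
    """
    if path2 is None:
        yield from _records_to_reads(path, None)
        return
    it1 = _records_to_reads(path, 1)
    it2 = _records_to_reads(path2, 2)
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise ValueError("paired FASTQ files have different read counts")
        if r1.id != r2.id:
            raise ValueError(f"mismatched pair at {r1.id!r} / {r2.id!r}")
        yield r1
        yield r2


def write_fastq(reads: Iterable[SequenceRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            name = r.id if r.mate is None else f"{r.id}/{r.mate}"
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{name}\n{r.bases}\n+\n{qual}\n")


REPORT_COLUMNS = (
    "te_name",
    "chrom",
    "coordinates",
    "tsd_sequence",
    "left_flankers",
    "right_flankers",
    "supporting_reads",
    "upstream_flank",
    "downstream_flank",
)


def write_insertion_table(
    calls: list[InsertionCall],
    reference: dict[str, str],
    path,
    flank_len: int = 100,
) -> None:
    """Write the non-reference insertion report.

    One row per call: TE name, chromosome, the 1-based inclusive TSD span
    rendered ``chrom:start..end``, the TSD sequence, left/right flanker
    counts, the supporting read IDs, and ``flank_len`` bp of reference
    sequence upstream and downstream of the target site (clipped at
    contig ends) for primer design.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for call in calls:
            iv = call.tsd_interval
            if iv.chrom not in reference:
                raise ValueError(f"call {call.span}: chromosome not in reference")
            chrom_seq = reference[iv.chrom]
            if iv.end > len(chrom_seq):
                raise ValueError(f"call {call.span}: coordinates beyond contig end")
            up = chrom_seq[max(0, iv.start - flank_len) : iv.start]
            down = chrom_seq[iv.end : iv.end + flank_len]
            fh.write(
                "\t".join(
                    [
                        call.te_name,
                        iv.chrom,
                        call.span,
                        call.tsd_sequence,
                        str(call.left_count),
                        str(call.right_count),
                        ",".join(call.supporting_read_ids),
                        up,
                        down,
                    ]
                )
                + "\n"
            )


def read_insertion_table(path) -> list[InsertionCall]:
    """Parse a report written by :func:`write_insertion_table`."""
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != REPORT_COLUMNS:
            raise ValueError(f"unrecognised insertion report header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom, start, end = parse_span(f[2])
            calls.append(
                InsertionCall(
                    te_name=f[0],
                    tsd_interval=GenomicInterval(chrom, start, end),
                    tsd_sequence=f[3],
                    left_count=int(f[4]),
                    right_count=int(f[5]),
                    supporting_read_ids=tuple(x for x in f[6].split(",") if x),
                )
            )
    return calls


@dataclass(frozen=True)
class AnnotatedFeature:
    """A classified TE location for GFF3 output."""

    interval: GenomicInterval
    te_name: str
    feature_class: str  # reference-only | shared | non-reference
    feature_id: str
    feature_type: str = "transposable_element_insertion_site"


def write_gff3(features: Iterable[AnnotatedFeature], path) -> None:
    """Write classified TE features as GFF3 (1-based inclusive coordinates).

    Features are stably sorted by chromosome then start; the TE name is
    the source column and the class goes in the attributes.
    """
    feats = sorted(features, key=lambda f: (f.interval.chrom, f.interval.start))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            iv = f.interval
            s1, e1 = iv.start + 1, iv.end
            attrs = f"ID={f.feature_id};class={f.feature_class}"
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        f.te_name,
                        f.feature_type,
                        str(s1),
                        str(e1),
                        ".",
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[AnnotatedFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in c[8].split(";") if "=" in kv)
            feats.append(
                AnnotatedFeature(
                    interval=GenomicInterval(c[0], int(c[3]) - 1, int(c[4]), c[6]),
                    te_name=c[1],
                    feature_class=attrs.get("class", ""),
                    feature_id=attrs.get("ID", ""),
                    feature_type=c[2],
                )
            )
    return feats
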