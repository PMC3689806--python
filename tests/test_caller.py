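"""Flanker placement, clustering, TSD-overlap calling and the reference scan."""

import networkx as nx
import numpy as np
import pytest

from tetrace.caller import (
    LEFT,
    RIGHT,
    FlankerAlignment,
    GenomeIndex,
    align_trimmed_reads,
    call_insertions,
    classify_reference_sites,
    cluster_flankers,
    find_tsd_overlap,
    flanker_side,
    scan_reference_for_te,
)
from tetrace.model import GenomicInterval, parse_tsd_spec, revcomp
from tetrace.simulate import generate_reference, plant_insertion, random_te
from tetrace.tescan import TE_3PRIME, TE_5PRIME, TRIM_END, TRIM_START, TrimmedRead

from conftest import mk_te


def _trimmed(rid, bases, trim_end=TRIM_END, te_end=TE_5PRIME):
    return TrimmedRead(rid, bases, tuple([38] * len(bases)), trim_end, te_end, "forward")


class TestAlignment:
    def test_unique_exact_placement(self, small_genome):
        index = GenomeIndex(small_genome)
        seq = small_genome["chr1"][500:530]
        (a,) = align_trimmed_reads([_trimmed("r1", seq)], index)
        assert a.interval == GenomicInterval("chr1", 500, 530, "+")
        assert a.mismatches == 0 and a.side == LEFT

    def test_reverse_strand_placement_flips_side(self, small_genome):
        index = GenomeIndex(small_genome)
        seq = revcomp(small_genome["chr1"][500:530])
        (a,) = align_trimmed_reads([_trimmed("r1", seq)], index)
        assert a.interval.strand == "-"
        assert a.side == RIGHT

    def test_multi_mapping_read_dropped(self):
        chunk = "ACGTTGCACCGTAGGCTAAGTCCAGTAGCA"
        ref = {"chr1": chunk + "T" * 50 + chunk + "G" * 50}
        counts = {}
        got = align_trimmed_reads(
            [_trimmed("r1", chunk)], GenomeIndex(ref), counts=counts
        )
        assert got == [] and counts["non_unique"] == 1

    def test_mismatch_boundary_three_kept_four_dropped(self, small_genome):
        index = GenomeIndex(small_genome)
        base = small_genome["chr1"][1000:1040]

        def mutate(s, n):
            out = list(s)
            for i in range(n):
                pos = 3 + 9 * i  # spread out, leaving 8-mer seeds intact
                out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
            return "".join(out)

        (a,) = align_trimmed_reads([_trimmed("r3", mutate(base, 3))], index)
        assert a.mismatches == 3
        assert align_trimmed_reads([_trimmed("r4", mutate(base, 4))], index) == []

    @pytest.mark.parametrize(
        "trim_end, strand, side",
        [
            (TRIM_END, "+", LEFT),
            (TRIM_START, "-", LEFT),
            (TRIM_START, "+", RIGHT),
            (TRIM_END, "-", RIGHT),
        ],
    )
    def test_side_assignment_table(self, trim_end, strand, side):
        assert flanker_side(trim_end, strand) == side


def _fa(rid, chrom, start, end, side, te_end=TE_5PRIME):
    return FlankerAlignment(
        rid,
        GenomicInterval(chrom, start, end, "+"),
        side,
        0,
        te_end,
        TRIM_END if side == LEFT else TRIM_START,
    )


class TestClustering:
    def test_overlap_chains_merge_transitively(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            alignments = []
            for i in range(int(rng.integers(2, 15))):
                chrom = f"chr{rng.integers(1, 3)}"
                start = int(rng.integers(0, 200))
                alignments.append(
                    _fa(f"r{i}", chrom, start, start + int(rng.integers(5, 40)), LEFT)
                )
            alignments.sort(key=lambda a: (a.interval.chrom, a.interval.start))
            got = cluster_flankers(alignments)
            # oracle: connected components of the overlap graph
            g = nx.Graph()
            g.add_nodes_from(range(len(alignments)))
            for i, a in enumerate(alignments):
                for j, b in enumerate(alignments):
                    if i < j and a.interval.overlaps(b.interval):
                        g.add_edge(i, j)
            expected = {
                frozenset(alignments[i].read_id for i in comp)
                for comp in nx.connected_components(g)
            }
            assert {frozenset(a.read_id for a in c) for c in got} == expected

    def test_different_chromosomes_never_cluster(self):
        a = _fa("r1", "chr1", 10, 40, LEFT)
        b = _fa("r2", "chr2", 10, 40, LEFT)
        assert len(cluster_flankers([a, b])) == 2


class TestTsdOverlap:
    reference = {"chr1": "G" * 110 + "CCTAAGG" + "C" * 110}
    tsd = parse_tsd_spec("TSD=TAA")
    # reference TAA occupies internal coordinates 112..115

    def test_identical_window_found(self):
        lf = _fa("l", "chr1", 80, 115, LEFT)
        rf = _fa("r", "chr1", 112, 150, RIGHT, TE_3PRIME)
        iv = find_tsd_overlap([lf, rf], self.tsd, self.reference)
        assert iv == GenomicInterval("chr1", 112, 115)

    def test_adjacent_but_not_overlapping_is_none(self):
        lf = _fa("l", "chr1", 80, 115, LEFT)
        rf = _fa("r", "chr1", 115, 150, RIGHT, TE_3PRIME)
        assert find_tsd_overlap([lf, rf], self.tsd, self.reference) is None

    def test_reverse_complement_rendering_accepted(self):
        ref = {"chr1": "G" * 112 + "TTA" + "C" * 110}  # TTA = revcomp(TAA)
        lf = _fa("l", "chr1", 80, 115, LEFT)
        rf = _fa("r", "chr1", 112, 150, RIGHT, TE_3PRIME)
        assert find_tsd_overlap([lf, rf], self.tsd, ref) == GenomicInterval(
            "chr1", 112, 115
        )

    def test_call_counts_and_minimum_evidence(self):
        lf1 = _fa("l1", "chr1", 80, 115, LEFT)
        lf2 = _fa("l2", "chr1", 75, 115, LEFT)
        rf = _fa("r1", "chr1", 112, 150, RIGHT, TE_3PRIME)
        (call,) = call_insertions([[lf1, lf2, rf]], self.tsd, self.reference, "TE1")
        assert (call.left_count, call.right_count) == (2, 1)
        assert call.tsd_sequence == "TAA"
        assert call.span == "chr1:113..115"
        assert call.te_strand == "+"
        # three left flankers, no right: no call
        lf3 = _fa("l3", "chr1", 70, 115, LEFT)
        assert call_insertions([[lf1, lf2, lf3]], self.tsd, self.reference, "TE1") == []


class TestReferenceScan:
    rng = np.random.default_rng(21)
    te = random_te(5, length=430)

    def _genome_with(self, copy_seq, at=2000):
        base = generate_reference(seed=77, lengths=(6000,))["chr1"]
        return {"chr1": base[:at] + copy_seq + base[at:]}

    def test_exact_copy_detected_both_strands(self):
        for body in (self.te.sequence, revcomp(self.te.sequence)):
            ref = self._genome_with(body)
            (hit,) = scan_reference_for_te(ref, self.te)
            assert hit.interval.start == 2000 and hit.interval.end == 2430
            assert hit.identity_fraction == 1.0

    def test_truncated_copy_rejected(self):
        ref = self._genome_with(self.te.sequence[:350])  # 81% of the element
        assert scan_reference_for_te(ref, self.te) == []

    def test_five_mismatches_still_detected(self):
        body = list(self.te.sequence)
        for i in range(5):
            pos = 50 + 70 * i
            body[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[body[pos]]
        ref = self._genome_with("".join(body))
        (hit,) = scan_reference_for_te(ref, self.te)
        assert hit.identity_fraction == pytest.approx(1 - 5 / 430)

    def test_classification_shared_vs_reference_only(self):
        ref = self._genome_with(self.te.sequence)
        (copy,) = scan_reference_for_te(ref, self.te)
        near_left = _fa("a", "chr1", 1960, 2001, LEFT)
        near_right = _fa("b", "chr1", 2430, 2470, RIGHT, TE_3PRIME)
        far = _fa("c", "chr1", 3500, 3540, LEFT)

        (both,) = classify_reference_sites([copy], [near_left, near_right])
        assert both.copy_class == "shared"
        (none,) = classify_reference_sites([copy], [far])
        assert none.copy_class == "reference-only"
        (one_end,) = classify_reference_sites([copy], [near_left])
        assert one_end.copy_class == "shared"  # one-ended support is not a lack
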