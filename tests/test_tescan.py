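"""TE matcher, end-anchor filtering and junction-read trimming."""

import numpy as np
import pytest

from tetrace.model import revcomp
from tetrace.tescan import (
    FORWARD,
    REVERSE,
    TE_3PRIME,
    TE_5PRIME,
    TRIM_END,
    TRIM_START,
    TEMatch,
    end_anchor_filter,
    mismatch_fraction,
    scan_read_for_te,
    trim_te_sequence,
)

from conftest import mk_read, mk_te


def brute_force_matches(read: str, te: str, seed_len, min_aligned, allowance):
    """Oracle: enumerate every (orientation, diagonal, window) ungapped match.

    A window qualifies if its mismatch fraction is <= allowance and it
    contains an exact run of >= seed_len matching bases; only windows not
    contained in another qualifying window on the same diagonal are kept.
    """
    out = set()
    for orientation, target in ((FORWARD, te), (REVERSE, revcomp(te))):
        for diag in range(-len(read) + 1, len(target)):
            lo, hi = max(0, -diag), min(len(read), len(target) - diag)
            ok = []
            for s in range(lo, hi):
                for e in range(s + min_aligned, hi + 1):
                    seg = [
                        read[i] == target[i + diag] and read[i] != "N"
                        for i in range(s, e)
                    ]
                    mm = seg.count(False)
                    if mm > allowance * len(seg):
                        continue
                    run = best = 0
                    for m in seg:
                        run = run + 1 if m else 0
                        best = max(best, run)
                    if best >= seed_len:
                        ok.append((s, e, mm))
            for (s, e, mm) in ok:
                if any(os <= s and e <= oe and (os, oe) != (s, e) for (os, oe, _) in ok):
                    continue
                ts, te_end = s + diag, e + diag
                if orientation == REVERSE:
                    ts, te_end = len(te) - te_end, len(te) - ts
                out.add(((s, e), (ts, te_end), orientation, mm))
    return out


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.mark.parametrize("allowance", [0.0, 0.05])
def test_scanner_matches_brute_force_on_random_instances(allowance):
    """Seed-and-extend output equals exhaustive enumeration of ungapped matches."""
    rng = np.random.default_rng(7)
    for trial in range(30):
        te_seq = _random_dna(rng, int(rng.integers(30, 80)))
        read_seq = _random_dna(rng, int(rng.integers(20, 60)))
        if trial % 2:  # plant TE sequence so matches actually occur
            k = int(rng.integers(10, min(25, len(te_seq))))
            t0 = int(rng.integers(0, len(te_seq) - k + 1))
            piece = te_seq[t0 : t0 + k]
            if trial % 4 == 1:
                piece = revcomp(piece)
            p = int(rng.integers(0, len(read_seq) - k + 1))
            read_seq = read_seq[:p] + piece + read_seq[p + k :]
        te = mk_te(te_seq)
        got = {
            (m.read_interval, m.te_interval, m.orientation, m.mismatches)
            for m in scan_read_for_te(
                mk_read("r", read_seq), te, seed_len=7, min_aligned=10,
                allowance=allowance,
            )
        }
        expected = brute_force_matches(read_seq, te_seq, 7, 10, allowance)
        assert got == expected


def test_exact_suffix_match_geometry():
    rng = np.random.default_rng(1)
    te = mk_te(_random_dna(rng, 60))
    flank = _random_dna(rng, 60)
    read = mk_read("r", flank + te.sequence[:40])
    (m,) = scan_read_for_te(read, te)
    assert m.read_interval == (60, 100)
    assert m.te_interval == (0, 40)
    assert m.orientation == FORWARD and m.mismatches == 0


def test_reverse_complement_match_touches_te_3prime():
    rng = np.random.default_rng(2)
    te = mk_te(_random_dna(rng, 430))
    read = mk_read("r", revcomp(te.sequence[390:430]) + _random_dna(rng, 60))
    matches = end_anchor_filter(scan_read_for_te(read, te), te)
    assert len(matches) == 1
    m = matches[0]
    assert m.orientation == REVERSE
    assert m.te_interval == (390, 430)


def test_short_shared_kmer_below_min_aligned_is_no_match():
    rng = np.random.default_rng(3)
    te_seq = _random_dna(rng, 60)
    read_seq = _random_dna(rng, 40)
    # plant exactly a 9-mer of TE, then ensure no longer chance alignment
    read_seq = read_seq[:10] + te_seq[20:29] + read_seq[19:]
    expected = brute_force_matches(read_seq, te_seq, 7, 10, 0.0)
    got = scan_read_for_te(mk_read("r", read_seq), mk_te(te_seq))
    assert [
        (m.read_interval, m.te_interval, m.orientation, m.mismatches) for m in got
    ] == sorted(expected)  # oracle confirms nothing reaches 10 aligned bases


def test_end_anchor_filter_keeps_te_extremities_only():
    te = mk_te("A" * 430)
    mk = lambda ts, tend: TEMatch("r", (0, tend - ts), (ts, tend), FORWARD, 0)
    kept = end_anchor_filter([mk(0, 40), mk(100, 160), mk(0, 430)], te)
    assert [m.te_interval for m in kept] == [(0, 40), (0, 430)]


def test_mismatch_fraction_boundary_is_inclusive():
    m = TEMatch("r", (0, 50), (0, 50), FORWARD, 1)
    assert mismatch_fraction(m) == pytest.approx(0.02)
    assert mismatch_fraction(m) <= 0.02  # allowance equal to fraction retains
    assert mismatch_fraction(TEMatch("r", (0, 50), (0, 50), FORWARD, 0)) == 0.0


class TestTrimming:
    rng = np.random.default_rng(4)
    te = mk_te("".join(rng.choice(list("ACGT"), size=430)))

    def test_suffix_te_match_keeps_prefix_flank(self):
        flank = _random_dna(self.rng, 60)
        read = mk_read("r", flank + self.te.sequence[:40])
        (m,) = [
            x
            for x in scan_read_for_te(read, self.te)
            if x.te_interval == (0, 40)
        ]
        (t,) = trim_te_sequence(read, m, self.te)
        assert t.bases == flank
        assert t.trimmed_read_end == TRIM_END
        assert t.te_end_touched == TE_5PRIME
        assert t.tagged_id == "r:end"
        # conservation: flank + aligned TE == whole read
        assert len(t.bases) + m.aligned_len == len(read)

    def test_all_te_read_is_discarded(self):
        read = mk_read("r", self.te.sequence[100:200])
        (m,) = scan_read_for_te(read, self.te)
        assert m.read_interval == (0, 100)
        assert trim_te_sequence(read, m, self.te) == []

    def test_min_len_boundary_is_strict(self):
        for flank_len, expect in [(10, 0), (11, 1)]:
            flank = _random_dna(self.rng, flank_len)
            read = mk_read("r", flank + self.te.sequence[:40])
            matches = [
                m
                for m in scan_read_for_te(read, self.te)
                if m.te_interval[0] == 0 and m.read_interval[1] == len(read)
            ]
            got = trim_te_sequence(read, matches[0], self.te, min_len=10)
            assert len(got) == expect, flank_len

    def test_whole_te_inside_read_yields_both_junction_flanks(self):
        short_te = mk_te(_random_dna(self.rng, 40))
        left, right = _random_dna(self.rng, 30), _random_dna(self.rng, 30)
        read = mk_read("r", left + short_te.sequence + right)
        matches = [
            m
            for m in scan_read_for_te(read, short_te)
            if m.te_interval == (0, 40)
        ]
        got = trim_te_sequence(read, matches[0], short_te)
        assert {(t.bases, t.trimmed_read_end, t.te_end_touched) for t in got} == {
            (left, TRIM_END, TE_5PRIME),
            (right, TRIM_START, TE_3PRIME),
        }

    def test_internal_partial_match_rejected_as_non_junction(self):
        read = mk_read(
            "r",
            _random_dna(self.rng, 20)
            + self.te.sequence[390:430]
            + _random_dna(self.rng, 20),
        )
        matches = [
            m for m in scan_read_for_te(read, self.te) if m.te_interval == (390, 430)
        ]
        assert matches, "planted match must be found"
        assert trim_te_sequence(read, matches[0], self.te) == []
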