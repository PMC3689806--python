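"""Synthetic data: references, diploid individuals with planted TE events,
and short reads with a machine-readable truth manifest.

The generator emulates the biology the pipeline targets: a TE that
duplicates its target site on insertion, individuals that are diploid with
homozygous and heterozygous germline insertions, somatic insertions present
in only a fraction of cells, and somatic excisions that are either precise
(the reference sequence is restored) or leave a footprint (a few bases
remain between the duplicated target sites).  Somatic events are realised
as extra cell lineages mixed at their cell fraction; reads are sampled
uniformly across lineages weighted by fraction, half from each haplotype,
with substitution errors at a configurable rate.  Everything is
deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import TEModel, revcomp

GENOTYPES = ("homozygous", "heterozygous", "somatic")
EXCISIONS = ("none", "precise", "footprint")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class TruthEvent:
    """One planted TE event.

    ``tsd_start``/``tsd_end`` give the pre-insertion target-site span in
    reference coordinates (0-based half-open).  ``cell_fraction`` is 1 for
    pure germline events; for a somatic insertion it is the fraction of
    cells carrying it, and for a germline event with a somatic excision it
    is the fraction of cells in the excised lineage.
    """

    chrom: str
    tsd_start: int
    tsd_end: int
    genotype: str
    cell_fraction: float = 1.0
    excision: str = "none"
    footprint_seq: str = ""
    te_strand: str = "+"

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.excision not in EXCISIONS:
            raise ValueError(f"unknown excision kind {self.excision!r}")
        if not (0 < self.cell_fraction <= 1):
            raise ValueError("cell_fraction must be in (0, 1]")
        if self.genotype == "somatic" and self.cell_fraction >= 1:
            raise ValueError("a somatic insertion needs cell_fraction < 1")
        if self.excision != "none" and self.cell_fraction >= 1:
            raise ValueError("a somatic excision needs cell_fraction < 1")
        if self.excision == "footprint" and not self.footprint_seq:
            raise ValueError("footprint excision needs the footprint sequence")


@dataclass
class Individual:
    """Cell lineages (fraction, chrom -> (haplotype A, haplotype B))."""

    lineages: list[tuple[float, dict[str, tuple[str, str]]]]
    reference_length: int


def generate_reference(
    seed: int, n_chrom: int = 1, lengths=(100_000,), gc: float = 0.5
) -> dict[str, str]:
    """Random reference sequences with the given GC content."""
    rng = np.random.default_rng(seed)
    at, gcf = (1 - gc) / 2, gc / 2
    probs = [at, gcf, gcf, at]  # A C G T
    ref = {}
    for i in range(n_chrom):
        n = lengths[i % len(lengths)]
        ref[f"chr{i + 1}"] = (
            rng.choice(_BASES, size=n, p=probs).tobytes().decode()
        )
    return ref


def random_te(seed: int, length: int = 430, tsd: str = "TSD=TAA", name: str = "TE1") -> TEModel:
    """A random TE query of the given length with the given TSD spec."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode()
    return TEModel(name, seq, tsd)


def plant_insertion(
    haplotype: str, te: TEModel, tsd_start: int, tsd_end: int, strand: str = "+"
) -> str:
    """Insert the TE at a target site, duplicating the site.

    The pre-insertion site sequence must satisfy the TE's TSD matcher; the
    result reads ``...TSD + TE + TSD...``.
    """
    site = haplotype[tsd_start:tsd_end]
    if not te.tsd.matches_either_strand(site):
        raise ValueError(f"site sequence {site!r} does not satisfy the TSD spec")
    body = te.sequence if strand == "+" else revcomp(te.sequence)
    return haplotype[:tsd_end] + body + haplotype[tsd_start:]


def _apply_events(chrom_seq: str, events: list[tuple[TruthEvent, str]], te: TEModel) -> str:
    """Apply (event, mode) edits right-to-left so coordinates stay valid.

    mode: "insert" plants the TE; "footprint" plants the excision footprint
    (TSD + footprint + TSD); "skip" leaves the reference sequence.
    """
    seq = chrom_seq
    for ev, mode in sorted(events, key=lambda p: -p[0].tsd_start):
        if mode == "insert":
            seq = plant_insertion(seq, te, ev.tsd_start, ev.tsd_end, ev.te_strand)
        elif mode == "footprint":
            seq = seq[: ev.tsd_end] + ev.footprint_seq + seq[ev.tsd_start :]
        elif mode != "skip":
            raise ValueError(mode)
    return seq


def build_individual(
    reference: dict[str, str], te: TEModel, events: list[TruthEvent]
) -> Individual:
    """Realise planted events as a mixture of cell lineages.

    Germline events go into every lineage (heterozygous ones on haplotype A
    only).  Each somatic event — a somatic insertion, or the excised state
    of a germline insertion — gets its own lineage at its cell fraction,
    on haplotype A of that lineage.
    """
    _check_events(events, reference)
    somatic = [e for e in events if e.genotype == "somatic" or e.excision != "none"]
    base_fraction = 1.0 - sum(e.cell_fraction for e in somatic)
    if base_fraction <= 0:
        raise ValueError("somatic cell fractions sum to >= 1")

    def haplotypes(special: Optional[TruthEvent]) -> dict[str, tuple[str, str]]:
        haps = {}
        for chrom, seq in reference.items():
            edits_a, edits_b = [], []
            for ev in events:
                if ev.chrom != chrom:
                    continue
                if ev.genotype == "homozygous":
                    mode_a = "insert"
                    if ev is special and ev.excision != "none":
                        mode_a = "footprint" if ev.excision == "footprint" else "skip"
                    edits_a.append((ev, mode_a))
                    edits_b.append((ev, "insert"))
                elif ev.genotype == "heterozygous":
                    mode_a = "insert"
                    if ev is special and ev.excision != "none":
                        mode_a = "footprint" if ev.excision == "footprint" else "skip"
                    edits_a.append((ev, mode_a))
                elif ev.genotype == "somatic":
                    if ev is special:
                        edits_a.append((ev, "insert"))
            haps[chrom] = (
                _apply_events(seq, edits_a, te),
                _apply_events(seq, edits_b, te),
            )
        return haps

    lineages = [(base_fraction, haplotypes(None))]
    for ev in somatic:
        lineages.append((ev.cell_fraction, haplotypes(ev)))
    return Individual(lineages, sum(len(s) for s in reference.values()))


def _check_events(events: list[TruthEvent], reference: dict[str, str]) -> None:
    by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in events:
        if ev.chrom not in reference:
            raise ValueError(f"event chromosome {ev.chrom!r} not in reference")
        if ev.tsd_end > len(reference[ev.chrom]):
            raise ValueError("event beyond chromosome end")
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.tsd_start)
        for a, b in zip(evs, evs[1:]):
            if b.tsd_start < a.tsd_end:
                raise ValueError(f"overlapping events on {chrom}")


def simulate_reads(
    individual: Individual,
    coverage: float,
    read_len: int = 100,
    paired: bool = False,
    error_rate: float = 0.002,
    seed: int = 0,
    frag_mean: float = 350.0,
    frag_sd: float = 50.0,
) -> list:
    """Sample reads across lineages and haplotypes, with substitution errors.

    Coverage is defined over the reference length; lineages contribute in
    proportion to their cell fraction, the two haplotypes equally.  Paired
    mode draws fragments of Normal(frag_mean, frag_sd) length and reads
    both ends (mate 2 reverse-complemented).  Errored bases get a reduced
    quality score.
    """
    from .model import SequenceRead

    rng = np.random.default_rng(seed)
    pool = []  # (weight, sequence)
    for fraction, haps in individual.lineages:
        total = sum(len(a) + len(b) for a, b in haps.values())
        for chrom, (hap_a, hap_b) in haps.items():
            for hap in (hap_a, hap_b):
                pool.append((fraction * len(hap) / total, hap))
    weights = np.array([w for w, _ in pool])
    weights = weights / weights.sum()

    n_units = int(round(coverage * individual.reference_length / read_len))
    if paired:
        n_units //= 2
    counts = rng.multinomial(n_units, weights)

    reads = []
    serial = 0

    def _make_read(rid, template, mate=None):
        nonlocal reads
        bases = np.frombuffer(template.encode(), dtype="S1").copy()
        errs = np.nonzero(rng.random(len(bases)) < error_rate)[0]
        quals = np.full(len(bases), 38, dtype=int)
        for i in errs:
            alternatives = _BASES[_BASES != bases[i]]
            bases[i] = alternatives[rng.integers(len(alternatives))]
            quals[i] = 12
        reads.append(
            SequenceRead(rid, bases.tobytes().decode(), tuple(int(q) for q in quals), mate)
        )

    for (w, hap), n in zip(pool, counts):
        hl = len(hap)
        if paired:
            for _ in range(int(n)):
                frag = int(np.clip(rng.normal(frag_mean, frag_sd), 2 * read_len, hl))
                start = int(rng.integers(0, hl - frag + 1))
                serial += 1
                rid = f"sim{serial}"
                _make_read(rid, hap[start : start + read_len], mate=1)
                _make_read(
                    rid, revcomp(hap[start + frag - read_len : start + frag]), mate=2
                )
        else:
            if hl < read_len:
                continue
            starts = rng.integers(0, hl - read_len + 1, size=int(n))
            for start in starts:
                serial += 1
                strand_flip = rng.random() < 0.5
                template = hap[start : start + read_len]
                if strand_flip:
                    template = revcomp(template)
                _make_read(f"sim{serial}", template)
    return reads


TRUTH_COLUMNS = (
    "chrom",
    "tsd_start",
    "tsd_end",
    "genotype",
    "cell_fraction",
    "excision",
    "footprint_seq",
    "te_strand",
)


def emit_truth(events: list[TruthEvent], path) -> None:
    """Write the planted-event manifest (1-based inclusive spans)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for ev in events:
            fh.write(
                "\t".join(
                    [
                        ev.chrom,
                        str(ev.tsd_start + 1),
                        str(ev.tsd_end),
                        ev.genotype,
                        f"{ev.cell_fraction:g}",
                        ev.excision,
                        ev.footprint_seq or ".",
                        ev.te_strand,
                    ]
                )
                + "\n"
            )


def read_truth(path) -> list[TruthEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"unrecognised truth manifest header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            events.append(
                TruthEvent(
                    chrom=f[0],
                    tsd_start=int(f[1]) - 1,
                    tsd_end=int(f[2]),
                    genotype=f[3],
                    cell_fraction=float(f[4]),
                    excision=f[5],
                    footprint_seq="" if f[6] == "." else f[6],
                    te_strand=f[7],
                )
            )
    return events


def find_target_sites(
    reference: dict[str, str],
    te: TEModel,
    rng: np.random.Generator,
    n: int,
    min_gap: int = 800,
    edge_margin: int = 300,
) -> list[tuple[str, int, int]]:
    """Pick n non-overlapping TSD-satisfying sites, well separated."""
    width = te.tsd.width
    candidates = []
    for chrom, seq in reference.items():
        for p in range(edge_margin, len(seq) - edge_margin - width):
            if te.tsd.matches_either_strand(seq[p : p + width]):
                candidates.append((chrom, p))
    rng.shuffle(candidates)
    chosen: list[tuple[str, int, int]] = []
    for chrom, p in candidates:
        if all(c != chrom or abs(p - s) >= min_gap for c, s, _ in chosen):
            chosen.append((chrom, p, p + width))
            if len(chosen) == n:
                return sorted(chosen)
    raise ValueError(f"could not place {n} sites with gap {min_gap}")


def simulate_dataset(
    seed: int,
    genome_length: int = 100_000,
    coverage: float = 30.0,
    read_len: int = 100,
    error_rate: float = 0.002,
    paired: bool = False,
    n_homozygous: int = 8,
    n_heterozygous: int = 6,
    n_somatic: int = 6,
    somatic_fraction: float = 0.1,
    n_excision: int = 0,
    excision_fraction: float = 0.1,
    footprint_seq: str = "",
    te: Optional[TEModel] = None,
):
    """One synthetic individual end to end.

    Returns (reference, te, reads, truth events).  Defaults mirror the
    study conditions the pipeline was built for: a 430-bp TAA-duplicating
    element, 100-bp reads at ~30x coverage, a 0.002 substitution error
    rate, somatic insertions at a 0.1 cell fraction (the rarity implied by
    the flanker counts such events show at ~30x).
    """
    rng = np.random.default_rng(seed)
    reference = generate_reference(int(rng.integers(2**31)), lengths=(genome_length,))
    if te is None:
        te = random_te(int(rng.integers(2**31)))
    n_total = n_homozygous + n_heterozygous + n_somatic + n_excision
    sites = find_target_sites(reference, te, rng, n_total)
    rng.shuffle(sites)
    events = []
    for i, (chrom, s, e) in enumerate(sites):
        if i < n_homozygous:
            events.append(TruthEvent(chrom, s, e, "homozygous"))
        elif i < n_homozygous + n_heterozygous:
            events.append(TruthEvent(chrom, s, e, "heterozygous"))
        elif i < n_homozygous + n_heterozygous + n_somatic:
            events.append(
                TruthEvent(chrom, s, e, "somatic", cell_fraction=somatic_fraction)
            )
        else:
            events.append(
                TruthEvent(
                    chrom,
                    s,
                    e,
                    "homozygous",
                    cell_fraction=excision_fraction,
                    excision="footprint" if footprint_seq else "precise",
                    footprint_seq=footprint_seq,
                )
            )
    events.sort(key=lambda ev: (ev.chrom, ev.tsd_start))
    individual = build_individual(reference, te, events)
    reads = simulate_reads(
        individual,
        coverage,
        read_len=read_len,
        paired=paired,
        error_rate=error_rate,
        seed=int(rng.integers(2**31)),
    )
    return reference, te, reads, events
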