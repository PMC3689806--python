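# tetrace

Discover and genotype transposable-element (TE) insertions from unassembled
short reads.

Active TEs — the 430-bp rice MITE *mPing* is the motivating case — create
insertion-site polymorphism that an assembled genome cannot show: new copies
in a sequenced individual are absent from the reference, and in very active
families insertions and excisions occur even in somatic tissue. `tetrace`
finds such sites directly from FASTQ reads against a reference genome, and
uses the depth of coverage to call the genotype of every non-reference site.

## How it works

**Insertion discovery.** A read crossing an insertion junction carries TE
sequence at one end and unique genomic sequence at the other.  `tetrace`
scans every read for ungapped TE matches (exact 7-mer seeds, minimum 10
aligned bases, mismatch fraction ≤ a configurable allowance, default 0),
keeps only matches anchored at a TE extremity, trims the TE portion, and
places the remaining flank uniquely on the reference (ungapped, ≤ 3
mismatches; multi-mapping flanks are discarded).  Because a TE duplicates
its target site (TSD; `TAA` for *mPing*) on insertion, the flanks from the
two sides of a real junction must overlap by exactly the TSD: a site is
called when at least one **left flanker** and one **right flanker** share an
identical TSD-width reference window whose sequence satisfies the TSD
specification (given in the TE FASTA description as an exact sequence,
fixed-width pattern, or length — `TSD=TAA`, `TSD=T[AT]A`, `TSD=9`).  With
`--reference-scan`, full-length TE copies in the reference (±10% length,
<10% mismatches) are reported as *shared* or *reference-only* depending on
flanker support.

**Genotyping.** For each called site the average flanker count
F = (left + right)/2 is compared with the number of **spanners** S — reads
covering the target site gap-free with no TE sequence — through a fixed rule
cascade (first match wins):

| rule | condition            | genotype                     |
|------|----------------------|------------------------------|
| i    | S = 0                | homozygous                   |
| ii   | F ≥ 5 and S < 5      | homozygous, somatic excision |
| iii  | S ≤ 10 and S ≤ F/5   | homozygous, somatic excision |
| iv   | F ≤ 2 and S > 10     | somatic insertion            |
| v    | \|F−S\| ≤ (F+S)/2 + 10 | heterozygous               |
| vi   | F > 10 and S > 10    | heterozygous                 |
| vii  | F ≤ 10 and \|S−F\| > (F+S)/2 | somatic insertion    |
| viii | otherwise            | other                        |

Imprecise excisions are additionally detected as indels within ± one TSD
width of the site in the whole-read alignment.

A synthetic-data generator (`tetrace simulate`) produces references, diploid
individuals with planted homozygous/heterozygous/somatic events (including
precise and footprint-leaving excisions), reads with substitution errors,
and a truth manifest, so the whole pipeline is testable without downloads.

## Worked example

```sh
tetrace simulate --seed 5 --out-dir sim --genome-length 15000 --coverage 25 \
    --n-homozygous 3 --n-heterozygous 1 --n-somatic 0
tetrace find sim/te.fa sim/reference.fa sim/reads.fastq --out-dir out
tetrace preprocess sim/reference.fa sim/reads.fastq --out-sam out/whole.sam
tetrace genotype out/TE1.insertions.tsv out/whole.sam --out out/genotypes.tsv
```

which prints

```
3750 reads, 4 planted events -> sim
TE1: 4 non-reference insertions
3750 reads aligned -> out/whole.sam
4 sites genotyped -> out/genotypes.tsv
```

and `out/genotypes.tsv` contains

```
te_name	coordinates	avg_flankers	spanners	genotype	rule	footprint_type	footprint_offset	footprint_reads
TE1	chr1:4333..4335	11.5	9	heterozygous	v	.	.	.
TE1	chr1:8615..8617	17.5	0	homozygous	i	.	.	.
TE1	chr1:10080..10082	10	0	homozygous	i	.	.	.
TE1	chr1:13032..13034	16	0	homozygous	i	.	.	.
```

Each row is one called insertion: its 1-based target-site span, the average
flanker count F, the spanner count S, the genotype with the rule that fired,
and footprint evidence if any.  Here all four planted events are recovered
at their exact spans; the heterozygous site shows the expected roughly
balanced flanker/spanner counts (one allele each), while homozygous sites
have no spanners at all.

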