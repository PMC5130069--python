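# Methods

## Problem and model

A grafted sample (human tumour grown in a mouse host, or any analogous
two-species mixture) produces one read set containing both species.
`xenosplit` assumes the reads have been aligned **twice, independently**,
once to each species' reference, by the same aligner. It then treats
disambiguation as a per-template decision problem: for each read name,
compare the best alignment quality achieved in each species and assign
the template to the species with the better evidence, to an ambiguous
bin when the evidence is equal, or to an unaligned bin when neither
input contains a mapped record.

The unit of decision is the *template*: all records sharing one read
name after stripping a single trailing `/1` or `/2` mate suffix — both
mates plus any secondary (flag 0x100) and supplementary (flag 0x800)
records. Secondary and supplementary alignments participate in the
per-mate best because aligners may report the genuinely better placement
as a non-primary record; duplicate and QC-fail flags are ignored (those
records are still scored). Alignment geometry (position, CIGAR, bases)
is never consulted — only names, flags, and the AS/NM/NH/XO tags.

## Scoring schemes

Two schemes cover the tag vocabularies of the commonly used aligners:

| Scheme | Aliases | Metric | Tie-break |
|---|---|---|---|
| `as-nm` | bwa, star, bowtie2 | AS (higher better) | −NM on a full AS tie |
| `sum-nm-nh-xo` | tophat2, hisat2 | NM + NH + XO (lower better) | — |

Bowtie2 is mapped to `as-nm` because it emits AS and NM but not the
TopHat2-style tag set. The scheme is a per-run choice; both inputs must
come from the same aligner.

Each decision compares two per-species pairs (read 1 best, read 2
best). The comparison is: better best wins; on a tied best, better
worst wins; a full tie falls through (to −NM for `as-nm`, to ambiguous
otherwise). For the sum scheme, "identical scores for the highest
ranking reads" is implemented as best *and* worst identical — under the
weaker reading (best only) the worst-pair tie-break in the assignment
rule could never fire.

### Orientation convention

Internally every metric is put on a higher-is-better orientation at
extraction time: AS is used as-is, edit distance becomes −NM, the sum
becomes −(NM+NH+XO). The published sum-scheme rules are stated
lower-is-better; their `min(QS)` (best) corresponds to `max` here and
vice versa. One comparator, fewer sign bugs. The independent rule
transcription used as a test oracle (`synthfix.reference_assignment`)
deliberately keeps the original orientations instead.

### Missing evidence

The tag vocabulary is aligner-dependent, so absent evidence needs an
explicit policy; it is resolved in exactly one place (the scoring
module) by sentinel substitution:

| Absent quantity | Sentinel |
|---|---|
| AS tag on a mapped record | −32768 |
| NM, NH or XO tag on a mapped record | 32768 (each) |
| mate with no mapped record (AS metric) | −32768 |
| mate with no mapped record (−NM metric) | −32768 |
| mate with no mapped record (sum metric) | −98304 |

The design constraint: absent evidence must lose against any real
evidence and tie against equally absent evidence, so that two templates
orphaned in opposite species still resolve on their present mates.
`MISSING` is a distinct sentinel, never 0 — conflating a missing NM with
`NM:i:0` would make an unscored alignment beat a perfect one.

Single-end data is handled by copying the read-1 slot into the read-2
slot of every quality quad (a group is single-end when none of its
records carries the paired flag). This makes min == max per species and
reduces the paired rules to a single-value comparison, keeping one code
path.

A template present in only one input with at least one mapped record is
assigned to that species without building quads; a mapped record whose
required tags are all missing therefore still claims its template in
the single-species case, while in the two-species case it competes (and
ties) at sentinel level.

## Streaming design

Both inputs must be natural-name-sorted: embedded digit runs compare
numerically (`read2` < `read10`), text runs compare bytewise, a numeric
run sorts before a text run at the same position, a chunk-prefix sorts
first, and equal numeric values with different digit strings ("007" vs
"7") tie-break on the shorter digit string — the last rule is needed for
a total order. Under this order the two files are walked with a
merge join, holding at most one template group per stream in memory.

Sortedness is validated on the fly and a violation is a hard error
(exit code 4): a silently misordered input would mis-pair templates
between the species, which is strictly worse than failing. For unsorted
inputs, `--no-assume-sorted` enables an internal spill-to-disk merge
sort (chunks of 500,000 records sorted in memory, written as temporary
BAM runs, merged lazily).

## Outputs

Per sample: `<id>.speciesA.bam`, `<id>.speciesB.bam`,
`<id>.ambiguousSpeciesA.bam`, `<id>.ambiguousSpeciesB.bam`, and
`<id>_summary.txt` (one tab-separated header + data line: sample,
total, speciesA, speciesB, ambiguous, unaligned). Records are copied
verbatim with the originating input's header plus one appended `@PG`
line. Ambiguous records go to two files, one per species, because
records aligned to different references cannot share one header
meaningfully. Unaligned templates appear only in the summary. Output
filenames are this package's stable contract.

## Synthetic fixtures: what they do and do not show

The fixture generator (`xenosplit.synthfix`) writes natural-name-sorted
SAM pairs with fully controlled names, flags and tags over a tiny
synthetic reference (one 1,000 bp contig per species, dummy positions
and CIGARs). Because the decision logic reads only names, flags and
tags, this exercises every code path the tool has.

Two fixture families:

* **Canonical branch-coverage fixture** — 12 hand-labelled templates per
  scheme covering every decision branch: strict best dominance (both
  directions), best tie broken by the worst mate (both directions), full
  AS tie broken by −NM (both directions), full tie → ambiguous,
  single-species presence (both directions), nothing mapped → unaligned,
  a best score carried by a secondary record, and an unmapped-mate
  orphan; the sum-scheme variant adds missing-tag and single-end cases.
  The hand labels are double-entered: tests require them to agree with
  the independent rule transcription.
* **Random fixtures** — seeded, bit-reproducible templates with tags
  drawn from small integer ranges (AS ∈ [0, 60], NM ∈ [0, 10],
  NH ∈ [1, 5], XO ∈ [0, 3]), 10 % chance of a species being absent,
  10 % of a mate being absent and 10 % unmapped, 5 % missing-tag rate
  per tag, 5 % single-end templates, 30 % secondary records. The small
  ranges are chosen to make ties (and hence the tie-break branches)
  reachable at moderate sample sizes. Truth labels come from the
  transcription oracle, never from the production path.

What passing these tests does **not** show: performance on real data.
Real disambiguation accuracy depends on genome homology between the two
species, aligner scoring idiosyncrasies, and library quality — none of
which the generator emulates (no sequences are compared, no error model
exists). The fixtures verify that the decision rules, the streaming
join, and the I/O contract are implemented correctly, not that the
rules themselves separate any particular species pair well.

## Test and acceptance problem sizes

Property checks use 10,000 random template pairs per scheme for
oracle agreement, 300–1,000-template random fixtures for end-to-end
conservation/symmetry/determinism checks, an exhaustive [0, 5]⁴ grid
for monotonicity in the best AS, and 500 random names for the natural
order; the whole suite runs in seconds on one CPU. These sizes give
every assignment category a nonzero count at the seeds used while
keeping the suite fast.

## Known limitations

* Exactly two species; no multi-way joins.
* Coordinate-sorted input is rejected, not converted (use the internal
  re-sort or `samtools sort -n` first; note natural order and
  samtools' name order agree on common Illumina-style names but are not
  identical dialects in general).
* No relative weighting of tags — deliberately out of scope to avoid
  overfitting any particular aligner's score distribution.
* No CRAM, no FASTQ, no built-in alignment; outputs are always BAM.
* Assignment trusts the aligner's tags; it never re-scores alignments.
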