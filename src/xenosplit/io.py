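"""Read/write SAM/BAM, drive an end-to-end run, write the summary.

Inputs may be SAM or BAM (auto-detected by htslib); outputs are always
BAM.  Each output file reuses the corresponding input's header with one
appended program-group line recording the tool and command line.

Per sample the run produces, under the output directory:

``<sample_id>.speciesA.bam``
    All records of templates assigned to species A, copied verbatim
    from input A.
``<sample_id>.speciesB.bam``
    Likewise from input B.
``<sample_id>.ambiguousSpeciesA.bam`` / ``...SpeciesB.bam``
    Records of ambiguous templates from each respective input.
``<sample_id>_summary.txt``
    Tab-separated counts of templates per category.

Templates mapped in neither input are counted as unaligned and written
to no output file, so they never inflate the ambiguous bin.
"""

from __future__ import annotations

import heapq
import logging
import os
import sys
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

from . import __version__
from .core import AssignmentCategory, SummaryStats, strip_mate_suffix
from .pairsync import NameKey, iter_template_groups, synchronize
from .scoring import Scheme, disambiguate_template, resolve_scheme

logger = logging.getLogger("xenosplit")

SUMMARY_COLUMNS = ("sample", "total", "speciesA", "speciesB", "ambiguous", "unaligned")

#: Records per in-memory chunk for the optional internal re-sort.
RESORT_CHUNK_SIZE = 500_000

_PROGRESS_EVERY = 1_000_000


@dataclass
class RunConfig:
    """Everything one disambiguation run needs."""

    path_a: Path
    path_b: Path
    scheme: Scheme
    sample_id: str
    out_dir: Path
    assume_sorted: bool = True
    log_level: str = "INFO"
    command_line: Optional[str] = None

    def __post_init__(self) -> None:
        self.path_a = Path(self.path_a)
        self.path_b = Path(self.path_b)
        self.out_dir = Path(self.out_dir)
        self.scheme = resolve_scheme(self.scheme)
        if self.path_a == self.path_b:
            raise ValueError("the two input files must differ")
        if os.sep in self.sample_id or "/" in self.sample_id:
            raise ValueError("sample_id must not contain path separators")


def _augmented_header(af: pysam.AlignmentFile, command_line: str) -> pysam.AlignmentHeader:
    """Input header plus one @PG line for this tool."""
    header = af.header.to_dict()
    programs = header.get("PG", [])
    ids = {pg.get("ID") for pg in programs}
    pg_id = "xenosplit"
    n = 1
    while pg_id in ids:
        n += 1
        pg_id = f"xenosplit.{n}"
    entry = {
        "ID": pg_id,
        "PN": "xenosplit",
        "VN": __version__,
        "CL": command_line,
    }
    if programs:
        entry["PP"] = programs[-1].get("ID", programs[-1].get("PN", ""))
    header["PG"] = programs + [entry]
    return pysam.AlignmentHeader.from_dict(header)


def _record_sort_key(record) -> NameKey:
    return NameKey(strip_mate_suffix(record.query_name))


def _name_sorted_records(
    af: pysam.AlignmentFile, tmpdir: str, chunk_size: int = RESORT_CHUNK_SIZE
) -> Iterator:
    """Spill-to-disk merge sort of a record stream by natural name.

    Chunks of ``chunk_size`` records are sorted in memory and written to
    temporary BAM files; the sorted runs are then merged lazily.
    """
    runs = []
    chunk = []
    for record in af.fetch(until_eof=True):
        chunk.append(record)
        if len(chunk) >= chunk_size:
            chunk.sort(key=_record_sort_key)
            path = os.path.join(tmpdir, f"run{len(runs)}.bam")
            with pysam.AlignmentFile(path, "wb", template=af) as out:
                for r in chunk:
                    out.write(r)
            runs.append(path)
            chunk = []
    chunk.sort(key=_record_sort_key)

    def _read_run(path: str) -> Iterator:
        with pysam.AlignmentFile(path, "rb") as run_af:
            yield from run_af.fetch(until_eof=True)

    streams: list = [_read_run(p) for p in runs]
    streams.append(iter(chunk))
    yield from heapq.merge(*streams, key=_record_sort_key)


def run(config: RunConfig) -> SummaryStats:
    """Execute one disambiguation run and return the summary counts."""
    command_line = config.command_line or " ".join(sys.argv)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    counts = {cat: 0 for cat in AssignmentCategory}
    total = 0

    with tempfile.TemporaryDirectory(prefix="xenosplit-sort-") as tmpdir, \
            pysam.AlignmentFile(str(config.path_a)) as af_a, \
            pysam.AlignmentFile(str(config.path_b)) as af_b:
        if config.assume_sorted:
            stream_a: Iterable = af_a.fetch(until_eof=True)
            stream_b: Iterable = af_b.fetch(until_eof=True)
        else:
            os.makedirs(os.path.join(tmpdir, "a"))
            os.makedirs(os.path.join(tmpdir, "b"))
            stream_a = _name_sorted_records(af_a, os.path.join(tmpdir, "a"))
            stream_b = _name_sorted_records(af_b, os.path.join(tmpdir, "b"))

        prefix = config.out_dir / config.sample_id
        out_paths = {
            "a": f"{prefix}.speciesA.bam",
            "b": f"{prefix}.speciesB.bam",
            "amb_a": f"{prefix}.ambiguousSpeciesA.bam",
            "amb_b": f"{prefix}.ambiguousSpeciesB.bam",
        }
        header_a = _augmented_header(af_a, command_line)
        header_b = _augmented_header(af_b, command_line)
        writers = {
            "a": pysam.AlignmentFile(out_paths["a"], "wb", header=header_a),
            "b": pysam.AlignmentFile(out_paths["b"], "wb", header=header_b),
            "amb_a": pysam.AlignmentFile(out_paths["amb_a"], "wb", header=header_a),
            "amb_b": pysam.AlignmentFile(out_paths["amb_b"], "wb", header=header_b),
        }
        try:
            pairs = synchronize(
                iter_template_groups(stream_a), iter_template_groups(stream_b)
            )
            for group_a, group_b in pairs:
                category = disambiguate_template(group_a, group_b, config.scheme)
                counts[category] += 1
                total += 1
                if category is AssignmentCategory.SPECIES_A:
                    if group_a is not None:
                        for r in group_a.records:
                            writers["a"].write(r)
                elif category is AssignmentCategory.SPECIES_B:
                    if group_b is not None:
                        for r in group_b.records:
                            writers["b"].write(r)
                elif category is AssignmentCategory.AMBIGUOUS:
                    if group_a is not None:
                        for r in group_a.records:
                            writers["amb_a"].write(r)
                    if group_b is not None:
                        for r in group_b.records:
                            writers["amb_b"].write(r)
                if total % _PROGRESS_EVERY == 0:
                    logger.info("processed %d templates", total)
        finally:
            for w in writers.values():
                w.close()

    stats = SummaryStats(
        sample_id=config.sample_id,
        n_species_a=counts[AssignmentCategory.SPECIES_A],
        n_species_b=counts[AssignmentCategory.SPECIES_B],
        n_ambiguous=counts[AssignmentCategory.AMBIGUOUS],
        n_unaligned=counts[AssignmentCategory.UNALIGNED],
        n_total=total,
    )
    write_summary(stats, config.out_dir / f"{config.sample_id}_summary.txt")
    logger.info(
        "sample %s: %d templates (%d species A, %d species B, %d ambiguous, "
        "%d unaligned)",
        stats.sample_id,
        stats.n_total,
        stats.n_species_a,
        stats.n_species_b,
        stats.n_ambiguous,
        stats.n_unaligned,
    )
    return stats


def write_summary(stats: SummaryStats, path) -> None:
    """Serialize the per-category template counts, tab-separated.

    Refuses to write stats whose category counts do not sum to the
    total.
    """
    stats.validate()
    row = (
        stats.sample_id,
        stats.n_total,
        stats.n_species_a,
        stats.n_species_b,
        stats.n_ambiguous,
        stats.n_unaligned,
    )
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        fh.write("\t".join(str(v) for v in row) + "\n")
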