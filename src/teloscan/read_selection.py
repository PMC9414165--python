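"""Select candidate telomeric reads from alignments and manage read pools.

Telomeric reads anchor to the reference through their subtelomeric sequence,
so candidates are the primary alignments overlapping a terminal window
(default 10 kb) of each chromosome arm.  The module derives those windows
from a sequence-length index, extracts overlapping reads, tabulates arm
coverage at nested window sizes, and partitions a read pool into a triaged
telomeric subset (to be re-basecalled with a tuned model) and an untouched
remainder, with exact recombination afterwards.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .repeat_scan import ReadRepeatSummary

DEFAULT_WINDOW = 10_000
COVERAGE_WINDOWS = (10_000, 100_000, 1_000_000)

_AUTOSOME_X = re.compile(r"^(chr)?([0-9]+|X)$")


@dataclass(frozen=True)
class ArmRegion:
    """A terminal window of one chromosome arm (0-based, half-open).

    ``arm`` is "p" (chromosome start), "q" (chromosome end), or "whole" when
    the chromosome is no longer than the window and both arms collapse into a
    single region.
    """

    chromosome: str
    arm: str
    start: int
    end: int
    window: int

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q", "whole"):
            raise ValueError(f"arm must be p, q or whole, got {self.arm!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad region [{self.start}, {self.end})")

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.end and end > self.start


@dataclass
class ReadPoolPartition:
    """Disjoint split of a read pool into telomeric candidates and the rest."""

    telomeric: set[str]
    remainder: set[str]

    def __post_init__(self) -> None:
        if self.telomeric & self.remainder:
            raise ValueError("telomeric and remainder pools overlap")


def read_fai(path: str | Path) -> dict[str, int]:
    """Sequence lengths from an FAI-style index (name, length, ...)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            lengths[fields[0]] = int(fields[1])
    return lengths


def autosome_x_names(names: Iterable[str]) -> list[str]:
    """Subset of sequence names that look like autosomes or chrX."""
    return [n for n in names if _AUTOSOME_X.match(n)]


def terminal_regions(
    lengths: Mapping[str, int] | str | Path,
    window: int = DEFAULT_WINDOW,
    chromosomes: Sequence[str] | None = None,
    autosomes_x_only: bool = False,
) -> list[ArmRegion]:
    """Terminal windows at both ends of each chromosome.

    Per chromosome: p-arm [0, min(window, len)) and q-arm
    [max(0, len - window), len).  Chromosomes shorter than the window yield a
    single deduplicated region flagged "whole".  ``chromosomes`` restricts to
    an explicit include-list; ``autosomes_x_only`` restricts to names that
    look like autosomes or the X chromosome.
    """
    if not isinstance(lengths, Mapping):
        lengths = read_fai(lengths)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    names = list(lengths)
    if chromosomes is not None:
        missing = [c for c in chromosomes if c not in lengths]
        if missing:
            raise KeyError(f"chromosomes absent from index: {missing}")
        names = list(chromosomes)
    if autosomes_x_only:
        names = autosome_x_names(names)
    regions: list[ArmRegion] = []
    for name in names:
        length = lengths[name]
        if length <= 0:
            raise ValueError(f"non-positive length for {name}")
        if length <= window:
            regions.append(
                ArmRegion(chromosome=name, arm="whole", start=0, end=length, window=window)
            )
        else:
            regions.append(
                ArmRegion(chromosome=name, arm="p", start=0, end=window, window=window)
            )
            regions.append(
                ArmRegion(
                    chromosome=name, arm="q", start=length - window, end=length, window=window
                )
            )
    return regions


def _iter_alignments(alignments) -> Iterable[pysam.AlignedSegment]:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments)) as bam:
            yield from bam
    elif isinstance(alignments, pysam.AlignmentFile):
        yield from alignments
    else:
        yield from alignments


def _is_primary(aln: pysam.AlignedSegment) -> bool:
    return not (aln.is_unmapped or aln.is_secondary or aln.is_supplementary)


def extract_terminal_reads(
    alignments,
    regions: Sequence[ArmRegion],
    min_mapq: int = 0,
) -> dict[str, ArmRegion]:
    """Primary alignments overlapping a terminal window by at least one base.

    Returns a mapping read name -> assigned region (first overlapping region
    in the given order when a read touches several).  Unmapped, secondary and
    supplementary records and reads below ``min_mapq`` are excluded.  The
    result does not depend on record order.
    """
    header_refs: set[str] | None = None
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments)) as bam:
            header_refs = set(bam.references)
    elif isinstance(alignments, pysam.AlignmentFile):
        header_refs = set(alignments.references)
    if header_refs is not None:
        unknown = {r.chromosome for r in regions} - header_refs
        if unknown:
            raise ValueError(
                f"regions reference sequences absent from alignment header: {sorted(unknown)}"
            )
    by_chrom: dict[str, list[ArmRegion]] = {}
    for region in regions:
        by_chrom.setdefault(region.chromosome, []).append(region)
    selected: dict[str, ArmRegion] = {}
    for aln in _iter_alignments(alignments):
        if not _is_primary(aln) or aln.mapping_quality < min_mapq:
            continue
        for region in by_chrom.get(aln.reference_name, ()):
            if region.overlaps(aln.reference_start, aln.reference_end):
                selected.setdefault(aln.query_name, region)
                break
    return selected


def arm_coverage(
    alignments,
    lengths: Mapping[str, int] | str | Path,
    windows: Sequence[int] = COVERAGE_WINDOWS,
    min_mapq: int = 0,
) -> pd.DataFrame:
    """Distinct primary reads overlapping each arm at each window size.

    Returns a table with columns chromosome, arm, window, n_reads; counts are
    monotone non-decreasing in window size since the windows nest.
    """
    if not isinstance(lengths, Mapping):
        lengths = read_fai(lengths)
    region_sets = {w: terminal_regions(lengths, window=w) for w in windows}
    reads: dict[tuple[str, str, int], set[str]] = {}
    for w, regions in region_sets.items():
        for region in regions:
            reads[(region.chromosome, region.arm, w)] = set()
    alns = list(_iter_alignments(alignments))
    for w, regions in region_sets.items():
        by_chrom: dict[str, list[ArmRegion]] = {}
        for region in regions:
            by_chrom.setdefault(region.chromosome, []).append(region)
        for aln in alns:
            if not _is_primary(aln) or aln.mapping_quality < min_mapq:
                continue
            for region in by_chrom.get(aln.reference_name, ()):
                if region.overlaps(aln.reference_start, aln.reference_end):
                    reads[(region.chromosome, region.arm, w)].add(aln.query_name)
    rows = [
        {"chromosome": c, "arm": a, "window": w, "n_reads": len(ids)}
        for (c, a, w), ids in sorted(reads.items())
    ]
    return pd.DataFrame(rows)


def partition_for_rebasecall(
    read_ids: Iterable[str],
    summaries: Mapping[str, ReadRepeatSummary],
) -> ReadPoolPartition:
    """Split a read pool by the triage decision recorded in each summary."""
    telomeric: set[str] = set()
    remainder: set[str] = set()
    for read_id in read_ids:
        if read_id not in summaries:
            raise KeyError(f"no repeat summary for read {read_id!r}")
        if summaries[read_id].triage_selected:
            telomeric.add(read_id)
        else:
            remainder.add(read_id)
    return ReadPoolPartition(telomeric=telomeric, remainder=remainder)


def recombine(
    partition: ReadPoolPartition,
    original: Mapping[str, str],
    rebasecalled: Mapping[str, str],
) -> dict[str, str]:
    """Merge re-basecalled telomeric reads back into the full pool.

    Telomeric reads take their re-basecalled sequence; remainder reads keep
    their original sequence.  The identifier set is preserved exactly; a
    telomeric read missing from ``rebasecalled`` is an error.
    """
    missing = partition.telomeric - set(rebasecalled)
    if missing:
        raise KeyError(f"rebasecalled pool missing reads: {sorted(missing)[:5]}")
    pool: dict[str, str] = {}
    for read_id in partition.telomeric:
        pool[read_id] = rebasecalled[read_id]
    for read_id in partition.remainder:
        pool[read_id] = original[read_id]
    return pool
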