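"""Construct ground-truth reference sequences for telomeric reads.

A telomeric read anchors to the reference through its subtelomeric portion,
but its telomeric tract — miscalled as artefact repeats — does not align and
is left as a clip on the telomere-facing end.  Basecaller tuning needs, for
each such read, a reference sequence the same length as the read's true span:
the aligned reference interval extended toward the chromosome end by the
estimated tract length.  This module assigns reads to arms, estimates the
tract length (from the telomere-facing clip, or from the artefact/telomeric
repeat content of the clipped bases), and extracts the matched reference
sequence for each read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pysam

from .pore_model import revcomp
from .read_selection import ArmRegion, _is_primary, _iter_alignments
from .repeat_scan import MotifSet

logger = logging.getLogger(__name__)

_CLIP_OPS = (4, 5)  # BAM CIGAR soft, hard clip


class ArmAssignmentError(ValueError):
    """Alignment overlaps zero or several terminal regions."""


@dataclass
class TruthPair:
    """A read paired with its length-matched ground-truth reference sequence.

    ``sequence`` is the reference interval covered by the alignment, extended
    ``effective_extension`` bases toward the chromosome end (the estimated
    telomeric tract), reported on the reference forward strand;
    ``is_reverse`` records the read's alignment orientation.  ``truncated``
    is set when the chromosome end cut the requested extension short.
    """

    read_id: str
    chromosome: str
    arm: str
    start: int
    end: int
    clip: int
    effective_extension: int
    truncated: bool
    sequence: str
    is_reverse: bool

    def __post_init__(self) -> None:
        if len(self.sequence) != (self.end - self.start) + self.effective_extension:
            raise ValueError(
                "truth length must equal aligned span plus effective extension"
            )


def assign_arm(
    aln: pysam.AlignedSegment, regions: Sequence[ArmRegion]
) -> ArmRegion:
    """The unique terminal region this alignment overlaps.

    The region's arm fixes the telomere direction: leftward for p, rightward
    for q.  Zero or multiple overlaps, or a whole-chromosome region (no
    defined direction), raise :class:`ArmAssignmentError`.
    """
    hits = [
        r
        for r in regions
        if r.chromosome == aln.reference_name
        and r.overlaps(aln.reference_start, aln.reference_end)
    ]
    if len(hits) != 1:
        raise ArmAssignmentError(
            f"read {aln.query_name!r} overlaps {len(hits)} terminal regions"
        )
    region = hits[0]
    if region.arm == "whole":
        raise ArmAssignmentError(
            f"read {aln.query_name!r} maps to a whole-chromosome region; "
            "telomere direction undefined"
        )
    return region


def _clip_lengths(aln: pysam.AlignedSegment) -> tuple[int, int]:
    """(left, right) clip lengths in reference orientation (soft + hard)."""
    cigar = aln.cigartuples
    if cigar is None:
        raise ValueError(f"read {aln.query_name!r} has no CIGAR")
    left = 0
    for op, length in cigar:
        if op in _CLIP_OPS:
            left += length
        else:
            break
    right = 0
    for op, length in reversed(cigar):
        if op in _CLIP_OPS:
            right += length
        else:
            break
    return left, right


def _clipped_query_seq(aln: pysam.AlignedSegment, side: str) -> str:
    """Soft-clipped query bases on the given reference-orientation side."""
    seq = aln.query_sequence or ""
    cigar = aln.cigartuples or []
    if side == "left":
        if cigar and cigar[0][0] == 4:
            return seq[: cigar[0][1]]
        return ""
    if cigar and cigar[-1][0] == 4:
        return seq[len(seq) - cigar[-1][1] :]
    return ""


def _repeat_covered_length(seq: str, motifs: Sequence[str]) -> int:
    """Bases covered by a greedy left-to-right tiling of any motif in the set."""
    seq = seq.upper()
    n = len(seq)
    covered = 0
    i = 0
    while i < n:
        for m in motifs:
            if seq.startswith(m, i):
                covered += len(m)
                i += len(m)
                break
        else:
            i += 1
    return covered


def estimate_telomeric_extent(
    aln: pysam.AlignedSegment,
    arm: str,
    method: str = "clip",
    motifs: MotifSet | None = None,
) -> int:
    """Estimated telomeric tract length (bp) on the telomere-facing end.

    ``method="clip"`` (default) reads off the soft/hard-clip length on the
    telomere-facing end of the alignment — the unalignable portion is
    precisely the miscalled tract.  ``method="repeat_count"`` instead
    measures how much of the telomere-facing soft-clipped sequence is covered
    by telomeric or artefact motif copies; the two agree on clean tracts.
    """
    if arm not in ("p", "q"):
        raise ValueError(f"arm must be p or q, got {arm!r}")
    side = "left" if arm == "p" else "right"
    if method == "clip":
        left, right = _clip_lengths(aln)
        return left if side == "left" else right
    if method == "repeat_count":
        motifs = motifs or MotifSet()
        return _repeat_covered_length(_clipped_query_seq(aln, side), motifs.all)
    raise ValueError(f"unknown method {method!r}")


def _reference_lookup(reference) -> tuple:
    """Return (get_length, get_slice) accessors over dict or FASTA object."""
    if isinstance(reference, Mapping):
        return (
            lambda name: len(reference[name]),
            lambda name, s, e: str(reference[name])[s:e],
        )
    # pyfaidx.Fasta / pysam.FastaFile style
    if hasattr(reference, "get_reference_length"):
        return (
            reference.get_reference_length,
            lambda name, s, e: reference.fetch(name, s, e),
        )
    return (
        lambda name: len(reference[name]),
        lambda name, s, e: str(reference[name][s:e]),
    )


def build_truth_pair(
    aln: pysam.AlignedSegment,
    reference,
    regions: Sequence[ArmRegion],
    method: str = "clip",
    pad_motif: str | None = None,
) -> TruthPair:
    """Ground-truth reference sequence for one aligned telomeric read.

    The truth sequence is the aligned reference interval extended toward the
    chromosome end by the estimated tract length, truncated at the chromosome
    boundary (never fabricating reference bases).  With ``pad_motif`` set, a
    truncated extension is padded with motif copies instead — an explicit
    opt-in for synthetic experiments.
    """
    region = assign_arm(aln, regions)
    arm = region.arm
    clip = estimate_telomeric_extent(aln, arm, method=method)
    get_length, get_slice = _reference_lookup(reference)
    chrom_len = get_length(region.chromosome)
    start, end = aln.reference_start, aln.reference_end
    if arm == "p":
        effective = min(clip, start)
        seq = get_slice(region.chromosome, start - effective, end)
    else:
        effective = min(clip, chrom_len - end)
        seq = get_slice(region.chromosome, start, end + effective)
    truncated = effective < clip
    if truncated and pad_motif is not None:
        need = clip - effective
        tiling = pad_motif * (need // len(pad_motif) + 2)
        # p-arm pads leftward (keep phase against the existing sequence)
        seq = tiling[-need:] + seq if arm == "p" else seq + tiling[:need]
        effective = clip
        truncated = False
    return TruthPair(
        read_id=aln.query_name,
        chromosome=region.chromosome,
        arm=arm,
        start=start,
        end=end,
        clip=clip,
        effective_extension=effective,
        truncated=truncated,
        sequence=str(seq).upper(),
        is_reverse=aln.is_reverse,
    )


def build_truth_pairs(
    alignments,
    reference,
    regions: Sequence[ArmRegion],
    method: str = "clip",
    pad_motif: str | None = None,
) -> list[TruthPair]:
    """Truth pairs for every primary alignment; per-read failures are logged."""
    pairs: list[TruthPair] = []
    for aln in _iter_alignments(alignments):
        if not _is_primary(aln):
            continue
        try:
            pairs.append(
                build_truth_pair(
                    aln, reference, regions, method=method, pad_motif=pad_motif
                )
            )
        except (ArmAssignmentError, ValueError, KeyError) as exc:
            logger.warning("skipping read %s: %s", aln.query_name, exc)
    return pairs


def write_truth_fasta(pairs: Sequence[TruthPair], path: str | Path) -> None:
    """Truth sequences as FASTA; headers carry read id, arm, interval, flags."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f">{p.read_id} {p.chromosome}:{p.start}-{p.end} arm={p.arm} "
                f"extension={p.effective_extension} truncated={int(p.truncated)} "
                f"reverse={int(p.is_reverse)}\n"
            )
            for i in range(0, len(p.sequence), 80):
                fh.write(p.sequence[i : i + 80] + "\n")


def write_truth_manifest(pairs: Sequence[TruthPair], path: str | Path) -> None:
    """Tab-separated manifest of the truth pairs (one row per read)."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\tchromosome\tarm\tstart\tend\tclip\t"
            "effective_extension\ttruncated\treverse\ttruth_length\n"
        )
        for p in pairs:
            fh.write(
                f"{p.read_id}\t{p.chromosome}\t{p.arm}\t{p.start}\t{p.end}\t"
                f"{p.clip}\t{p.effective_extension}\t{int(p.truncated)}\t"
                f"{int(p.is_reverse)}\t{len(p.sequence)}\n"
            )
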