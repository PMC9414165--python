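"""Synthetic genomes, telomeric reads and alignment fixtures.

Emulates the read structure that strand-specific repeat miscalls produce: a
mappable subtelomeric anchor followed by a telomeric tract in which blocks of
motif units have been replaced by the strand's artefact motif.  Chromosome
ends carry (CCCTAA)-type tracts at the start and (TTAGGG)-type tracts at the
end, reads span one end, and every generator is deterministic per seed — so
scanning, triage, selection and truth construction are all testable with no
external data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .pore_model import ALPHABET, revcomp

FORWARD_ARTEFACT = "TTAAAA"
REVERSE_ARTEFACTS = ("CTTCTT", "CCCTGG")
# mean artefact/telomeric block size in motif units; blocks, not scattered
# single units, are what miscalled tracts look like on real reads
MEAN_BLOCK_UNITS = 30


@dataclass
class Genome:
    """Named sequences plus convenience length/index accessors."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_fai(self, path: str | Path, width: int = 80) -> None:
        """FAI index matching :meth:`write_fasta` output at the same width."""
        pos = 0
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                pos += len(name) + 2  # '>' + name + newline
                n_lines = -(-len(seq) // width) if seq else 0
                fh.write(f"{name}\t{len(seq)}\t{pos}\t{width}\t{width + 1}\n")
                pos += len(seq) + n_lines


@dataclass(frozen=True)
class SyntheticReadSpec:
    """Conditions under which telomeric reads are simulated.

    A read is a subtelomeric anchor of ``anchor_len`` bases plus a telomeric
    tract whose length is drawn from a clipped normal over
    [tract_min, tract_max] with mean ``tract_mean`` (rounded to whole motif
    units).  Within the tract, a Binomial(units, p) number of units is
    replaced by the strand's artefact motif, laid out as contiguous blocks.
    The artefact proportion defaults differ by strand (the reverse,
    CCCTAA-facing strand is far more error-prone on real data); both are free
    parameters.  ``noise_rate`` adds independent per-base substitutions.
    """

    motif: str = "TTAGGG"
    tract_min: int = 1_000
    tract_mean: int = 3_000
    tract_max: int = 6_000
    anchor_len: int = 2_000
    artefact_forward: str = FORWARD_ARTEFACT
    artefact_reverse: tuple[str, ...] = REVERSE_ARTEFACTS
    p_forward: float = 0.3
    p_reverse: float = 0.9
    noise_rate: float = 0.0
    n_reads: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_forward <= 1.0 or not 0.0 <= self.p_reverse <= 1.0:
            raise ValueError("artefact proportions must be in [0, 1]")
        if min(self.tract_min, self.tract_mean, self.tract_max, self.anchor_len) <= 0:
            raise ValueError("lengths must be positive")
        if not self.tract_min <= self.tract_mean <= self.tract_max:
            raise ValueError("require tract_min <= tract_mean <= tract_max")


@dataclass
class SimulatedRead:
    """One simulated read with its generating truth labels."""

    read_id: str
    sequence: str
    chromosome: str
    arm: str                      # p: CCCTAA-strand read; q: TTAGGG-strand
    strand_motif: str             # telomeric motif as it appears on the read
    anchor_start: int             # aligned (anchor) interval on the reference
    anchor_end: int
    origin_start: int             # full generating interval on the reference
    origin_end: int
    tract_len: int
    n_units: int
    n_artefact: int

    @property
    def true_error_proportion(self) -> float | None:
        return self.n_artefact / self.n_units if self.n_units else None


def make_genome(
    n_chrom: int = 2,
    arm_tract: int = 3_000,
    core_len: int = 50_000,
    motif: str = "TTAGGG",
    seed: int = 0,
) -> Genome:
    """Synthetic genome with telomeric tracts at both ends of each chromosome.

    Each chromosome is revcomp(motif)-tract + random core + motif-tract, so
    the forward strand starts with (CCCTAA)-type repeats and ends with
    (TTAGGG)-type repeats, as a real assembly does.  Tract lengths are
    rounded down to whole motif units.
    """
    if min(n_chrom, arm_tract, core_len) <= 0:
        raise ValueError("n_chrom, arm_tract and core_len must be positive")
    L = len(motif)
    arm_tract = (arm_tract // L) * L
    if arm_tract == 0:
        raise ValueError("arm_tract shorter than one motif unit")
    rng = np.random.default_rng([int(seed), 0x6E0])
    left = revcomp(motif) * (arm_tract // L)
    right = motif * (arm_tract // L)
    rc = revcomp(motif)
    sequences = {}
    for i in range(n_chrom):
        core = list(
            np.array(list(ALPHABET))[rng.integers(0, 4, size=core_len)]
        )
        # sharp tract boundaries: the core must not extend either tract's
        # periodic run, so region coordinates are exactly recoverable
        if core[0] == rc[0]:
            core[0] = "G" if rc[0] != "G" else "A"
        if core[-1] == motif[-1]:
            core[-1] = "C" if motif[-1] != "C" else "A"
        sequences[f"chr{i + 1}"] = left + "".join(core) + right
    return Genome(sequences=sequences)


def _sample_tract_units(
    rng: np.random.Generator, spec: SyntheticReadSpec, max_bp: int, group: int = 3
) -> int:
    """Tract length in motif copies, rounded to whole ``group``-copy units."""
    L = len(spec.motif)
    sd = max((spec.tract_max - spec.tract_min) / 6.0, 1.0)
    bp = rng.normal(spec.tract_mean, sd)
    bp = float(np.clip(bp, spec.tract_min, min(spec.tract_max, max_bp)))
    return max(group, int(bp // (L * group)) * group)


def _artefact_layout(
    rng: np.random.Generator, units: int, p: float, group: int = 3
) -> np.ndarray:
    """Boolean per-copy artefact mask: a Binomial fraction p of the tract in
    contiguous blocks aligned to ``group``-copy boundaries.

    Artefact segments on real miscalled reads are block-like, not scattered
    single copies, so the injected copies are laid out as contiguous blocks
    (mean about MEAN_BLOCK_UNITS copies) separated by telomeric gaps.
    Aligning blocks to the ``group``-copy grid means block boundaries never
    split a counted (motif)_group unit, keeping greedy unit counting an
    unbiased readout of the injected fraction.
    """
    mask = np.zeros(units, dtype=bool)
    slots = units // group
    if slots == 0:
        n_art = int(rng.binomial(units, p))
        if n_art:
            start = int(rng.integers(units - n_art + 1))
            mask[start : start + n_art] = True
        return mask
    n_art = int(rng.binomial(slots, p))
    if n_art == 0:
        return mask
    slot_mask = np.zeros(slots, dtype=bool)
    if n_art == slots:
        slot_mask[:] = True
    else:
        n_blocks = max(1, round(n_art * group / MEAN_BLOCK_UNITS))
        n_blocks = min(n_blocks, n_art, slots - n_art + 1)
        cuts = (
            np.sort(rng.choice(np.arange(1, n_art), size=n_blocks - 1, replace=False))
            if n_blocks > 1
            else np.array([], dtype=int)
        )
        block_sizes = np.diff(np.concatenate(([0], cuts, [n_art])))
        gaps = rng.multinomial(slots - n_art, np.ones(n_blocks + 1) / (n_blocks + 1))
        pos = 0
        for gap, size in zip(gaps[:-1], block_sizes):
            pos += int(gap)
            slot_mask[pos : pos + int(size)] = True
            pos += int(size)
    mask[: slots * group] = np.repeat(slot_mask, group)
    return mask


def _apply_noise(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if not hit.any():
        return seq
    subs = np.array(list(ALPHABET))[rng.integers(0, 4, size=int(hit.sum()))]
    arr[hit] = subs
    return "".join(arr)


def simulate_reads(
    genome: Genome, spec: SyntheticReadSpec
) -> list[SimulatedRead]:
    """Simulate reads spanning chromosome ends with artefact-block injection.

    q-arm reads run anchor-then-tract on the TTAGGG strand; p-arm reads run
    tract-then-anchor on the CCCTAA strand (artefact motif drawn per block
    from the reverse-strand artefact set).  Truth labels carry the generating
    interval and the realised artefact unit fraction.
    """
    L = len(spec.motif)
    rng = np.random.default_rng([int(spec.seed), 0x51E4])
    names = list(genome.sequences)
    reads: list[SimulatedRead] = []
    rc_motif = revcomp(spec.motif)
    for idx in range(spec.n_reads):
        chrom = names[int(rng.integers(len(names)))]
        seq = genome[chrom]
        clen = len(seq)
        arm = "p" if rng.random() < 0.5 else "q"
        # the tract available on this arm of the synthetic genome
        arm_tract = _arm_tract_length(seq, rc_motif if arm == "p" else spec.motif, arm)
        core_available = clen - 2 * arm_tract
        if spec.anchor_len > core_available:
            raise ValueError(
                f"anchor_len {spec.anchor_len} exceeds the non-telomeric core "
                f"of {chrom} ({core_available} bp)"
            )
        units = _sample_tract_units(rng, spec, arm_tract)
        tract_len = units * L
        if arm == "q":
            boundary = clen - arm_tract
            anchor_start, anchor_end = boundary - spec.anchor_len, boundary
            origin = (anchor_start, boundary + tract_len)
            mask = _artefact_layout(rng, units, spec.p_forward)
            parts = [seq[anchor_start:boundary]]
            for j in range(units):
                parts.append(
                    spec.artefact_forward if mask[j] else seq[boundary + j * L : boundary + (j + 1) * L]
                )
            strand_motif = spec.motif
        else:
            boundary = arm_tract
            anchor_start, anchor_end = boundary, boundary + spec.anchor_len
            origin = (boundary - tract_len, anchor_end)
            mask = _artefact_layout(rng, units, spec.p_reverse)
            block_artefact: str | None = None
            parts = []
            for j in range(units):
                unit_start = boundary - (units - j) * L
                if mask[j]:
                    if j == 0 or not mask[j - 1]:
                        block_artefact = spec.artefact_reverse[
                            int(rng.integers(len(spec.artefact_reverse)))
                        ]
                    parts.append(block_artefact)
                else:
                    parts.append(seq[unit_start : unit_start + L])
            parts.append(seq[boundary:anchor_end])
            strand_motif = rc_motif
        read_seq = _apply_noise(rng, "".join(parts), spec.noise_rate)
        reads.append(
            SimulatedRead(
                read_id=f"read_{idx:05d}_{chrom}{arm}",
                sequence=read_seq,
                chromosome=chrom,
                arm=arm,
                strand_motif=strand_motif,
                anchor_start=anchor_start,
                anchor_end=anchor_end,
                origin_start=origin[0],
                origin_end=origin[1],
                tract_len=tract_len,
                n_units=units,
                n_artefact=int(mask.sum()),
            )
        )
    return reads


def _arm_tract_length(seq: str, motif: str, arm: str) -> int:
    """Length of the pure motif tract at the given end of the sequence."""
    L = len(motif)
    n = len(seq)
    length = 0
    if arm == "p":
        while length + L <= n and seq[length : length + L] == motif:
            length += L
    else:
        while length + L <= n and seq[n - length - L : n - length] == motif:
            length += L
    return length


def random_reads(
    n: int, length: int, seed: int = 0, prefix: str = "random"
) -> list[tuple[str, str]]:
    """Uniform-random non-telomeric reads (negative controls for triage)."""
    rng = np.random.default_rng([int(seed), 0xA11])
    bases = np.array(list(ALPHABET))
    return [
        (f"{prefix}_{i:05d}", "".join(bases[rng.integers(0, 4, size=length)]))
        for i in range(n)
    ]


def write_fastq(reads: Sequence, path: str | Path, quality: int = 20) -> None:
    """Reads as FASTQ (gzipped when the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read in reads:
            read_id, seq = (
                (read.read_id, read.sequence)
                if isinstance(read, SimulatedRead)
                else (read[0], read[1])
            )
            fh.write(f"@{read_id}\n{seq}\n+\n{chr(33 + quality) * len(seq)}\n")


def write_truth_table(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """Per-read generating truth labels as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\tchromosome\tarm\tstrand_motif\tanchor_start\tanchor_end\t"
            "origin_start\torigin_end\ttract_len\tn_units\tn_artefact\t"
            "true_error_proportion\n"
        )
        for r in reads:
            p = "" if r.true_error_proportion is None else f"{r.true_error_proportion:.6f}"
            fh.write(
                f"{r.read_id}\t{r.chromosome}\t{r.arm}\t{r.strand_motif}\t"
                f"{r.anchor_start}\t{r.anchor_end}\t{r.origin_start}\t"
                f"{r.origin_end}\t{r.tract_len}\t{r.n_units}\t{r.n_artefact}\t{p}\n"
            )


def write_fixture_bam(
    reads: Sequence[SimulatedRead], genome: Genome, path: str | Path
) -> Path:
    """Coordinate-sorted, indexed BAM placing each read's anchor at its origin.

    The telomeric tract is recorded as a soft clip on the telomere-facing end
    (left for p-arm reads, right for q-arm reads), which is how a real
    aligner represents the unalignable miscalled tract.
    """
    path = Path(path)
    lengths = genome.lengths
    names = list(lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": lengths[n]} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    unsorted = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
        for read in reads:
            if read.chromosome not in tid:
                raise ValueError(f"read {read.read_id} references unknown {read.chromosome}")
            if not 0 <= read.anchor_start < read.anchor_end <= lengths[read.chromosome]:
                raise ValueError(f"read {read.read_id} origin outside genome")
            anchor_len = read.anchor_end - read.anchor_start
            clip_len = len(read.sequence) - anchor_len
            a = pysam.AlignedSegment()
            a.query_name = read.read_id
            a.query_sequence = read.sequence
            a.flag = 0
            a.reference_id = tid[read.chromosome]
            a.reference_start = read.anchor_start
            a.mapping_quality = 60
            if read.arm == "q":
                a.cigartuples = [(0, anchor_len)] + ([(4, clip_len)] if clip_len else [])
            else:
                a.cigartuples = ([(4, clip_len)] if clip_len else []) + [(0, anchor_len)]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.sequence))
            bam.write(a)
    pysam.sort("-o", str(path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(path))
    return path
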