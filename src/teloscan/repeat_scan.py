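"""Scan reads for telomeric and artefact repeat units.

Per-read unit counts of the telomeric units (TTAGGG, CCCTAA) and the strand-
specific artefact units the basecaller substitutes for them (TTAAAA, CTTCTT,
CCCTGG) give an error proportion — artefact units over all units — and a
triage rule: reads carrying at least 10 units in total are candidates for
re-basecalling with a telomere-tuned model.  The module also builds the
motif co-occurrence matrix over a read set and locates tandem-repeat runs
(telomere-like regions) in a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .pore_model import ALPHABET, AlphabetError, _check_alphabet

TELOMERIC_MOTIFS = ("TTAGGG", "CCCTAA")
ARTEFACT_MOTIFS = ("TTAAAA", "CTTCTT", "CCCTGG")
TRIAGE_THRESHOLD = 10


@dataclass(frozen=True)
class MotifSet:
    """The motifs scanned per read and the unit conventions applied to them.

    ``unit_copies`` is the number of consecutive motif copies that make one
    counted unit (3: a unit is e.g. (TTAGGG)_3); ``cooccur_copies`` is the
    number of consecutive copies that defines motif presence for the
    co-occurrence matrix (4).
    """

    telomeric: tuple[str, ...] = TELOMERIC_MOTIFS
    artefact: tuple[str, ...] = ARTEFACT_MOTIFS
    unit_copies: int = 3
    cooccur_copies: int = 4

    def __post_init__(self) -> None:
        for m in self.telomeric + self.artefact:
            _check_alphabet(m, "motif")
        if self.unit_copies < 1 or self.cooccur_copies < 1:
            raise ValueError("unit_copies and cooccur_copies must be >= 1")

    @property
    def all(self) -> tuple[str, ...]:
        return self.telomeric + self.artefact


@dataclass
class ReadRepeatSummary:
    """Per-read unit counts, error proportion and triage decision.

    ``error_proportion`` is artefact units over all units; ``None`` when the
    read carries no unit at all.
    """

    read_id: str
    unit_counts: dict[str, int]
    telomeric_total: int
    artefact_total: int
    error_proportion: float | None
    triage_selected: bool


@dataclass
class CooccurrenceMatrix:
    """Read counts for motifs jointly present (>= cooccur_copies consecutive).

    Off-diagonal cell (i, j) counts reads containing runs of both motifs;
    diagonal cell (i, i) counts reads in which motif i is the only motif of
    the set present.
    """

    motifs: tuple[str, ...]
    counts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.motifs, columns=self.motifs)


@dataclass(frozen=True)
class RepeatRegion:
    """A tandem-repeat run in a reference sequence (0-based, half-open)."""

    name: str
    start: int
    end: int
    motif: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")

    @property
    def length(self) -> int:
        return self.end - self.start


def count_nonoverlapping_units(seq: str, motif: str, unit_copies: int = 3) -> int:
    """Greedy left-to-right count of non-overlapping (motif)_unit_copies units.

    Matching is exact substring matching on the literal sequence; N never
    matches, so runs are broken at N.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    _check_alphabet(motif, "motif")
    if unit_copies < 1:
        raise ValueError("unit_copies must be >= 1")
    return seq.upper().count(motif * unit_copies)


def has_consecutive(seq: str, motif: str, n: int) -> bool:
    """True iff the motif repeated n times occurs as an exact substring."""
    if not motif:
        raise ValueError("motif must be non-empty")
    _check_alphabet(motif, "motif")
    if n < 1:
        raise ValueError("n must be >= 1")
    return (motif * n) in seq.upper()


def _as_read(read) -> tuple[str, str]:
    """Accept a (id, sequence) pair or a SeqRecord-like object."""
    if isinstance(read, (tuple, list)) and len(read) == 2:
        return str(read[0]), str(read[1])
    if hasattr(read, "id") and hasattr(read, "seq"):
        return str(read.id), str(read.seq)
    raise TypeError(f"cannot interpret {type(read).__name__} as a read")


def triage(summary: ReadRepeatSummary, threshold: int = TRIAGE_THRESHOLD) -> bool:
    """Select the read for re-basecalling iff total units >= threshold."""
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    return summary.telomeric_total + summary.artefact_total >= threshold


def summarize_read(
    read,
    motifs: MotifSet | None = None,
    threshold: int = TRIAGE_THRESHOLD,
) -> ReadRepeatSummary:
    """Count telomeric and artefact units on one read and apply triage.

    Motifs are counted independently on the literal (as-basecalled) sequence:
    no reverse complementing, and a base may contribute to units of more than
    one motif.
    """
    motifs = motifs or MotifSet()
    read_id, seq = _as_read(read)
    counts = {
        m: count_nonoverlapping_units(seq, m, motifs.unit_copies)
        for m in motifs.all
    }
    telo = sum(counts[m] for m in motifs.telomeric)
    arte = sum(counts[m] for m in motifs.artefact)
    total = telo + arte
    summary = ReadRepeatSummary(
        read_id=read_id,
        unit_counts=counts,
        telomeric_total=telo,
        artefact_total=arte,
        error_proportion=(arte / total) if total else None,
        triage_selected=False,
    )
    summary.triage_selected = triage(summary, threshold)
    return summary


def cooccurrence(reads: Iterable, motifs: MotifSet | None = None) -> CooccurrenceMatrix:
    """Motif co-occurrence matrix over a read set.

    Presence of a motif on a read means >= cooccur_copies consecutive copies.
    Off-diagonal cells count reads with both motifs present; diagonal cells
    count reads where that motif is the only one of the set present.
    """
    motifs = motifs or MotifSet()
    names = motifs.all
    n = len(names)
    counts = np.zeros((n, n), dtype=int)
    for read in reads:
        _, seq = _as_read(read)
        present = [
            i for i, m in enumerate(names)
            if has_consecutive(seq, m, motifs.cooccur_copies)
        ]
        if len(present) == 1:
            counts[present[0], present[0]] += 1
        else:
            for a in range(len(present)):
                for b in range(a + 1, len(present)):
                    counts[present[a], present[b]] += 1
                    counts[present[b], present[a]] += 1
    return CooccurrenceMatrix(motifs=names, counts=counts)


def _periodic_run_length(seq: str, start: int, motif: str) -> int:
    """Longest extension at ``start`` matching some phase of the tiled motif."""
    L = len(motif)
    n = len(seq)
    best = 0
    for phase in range(L):
        t = 0
        while start + t < n and seq[start + t] == motif[(phase + t) % L]:
            t += 1
        if t > best:
            best = t
            if start + best == n:
                break
    return best


def find_repeat_regions(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    motif: str,
    min_len: int = 100,
) -> list[RepeatRegion]:
    """Maximal tandem runs of ``motif`` (any phase) of at least ``min_len`` bp.

    A run is a maximal substring of the infinite repetition of the motif; the
    phase is free, so runs may begin mid-unit.  N breaks runs.  Coordinates
    are 0-based half-open.
    """
    _check_alphabet(motif, "motif")
    if isinstance(sequences, Mapping):
        items: Iterable[tuple[str, str]] = sequences.items()
    else:
        items = sequences
    regions: list[RepeatRegion] = []
    for name, seq in items:
        seq = str(seq).upper()
        n = len(seq)
        i = 0
        while i < n:
            run = _periodic_run_length(seq, i, motif)
            if run >= min_len:
                regions.append(RepeatRegion(name=name, start=i, end=i + run, motif=motif))
                i += run
            else:
                # advance by one: short matches are phase-ambiguous, so a
                # maximal run may start anywhere inside them
                i += 1
    return regions


def summaries_to_dataframe(summaries: Sequence[ReadRepeatSummary]) -> pd.DataFrame:
    """Tabulate read summaries (one row per read)."""
    if not summaries:
        return pd.DataFrame()
    motif_names = list(summaries[0].unit_counts)
    rows = []
    for s in summaries:
        row = {"read_id": s.read_id}
        row.update({m: s.unit_counts.get(m, 0) for m in motif_names})
        row.update(
            telomeric_total=s.telomeric_total,
            artefact_total=s.artefact_total,
            error_proportion=np.nan if s.error_proportion is None else s.error_proportion,
            triage_selected=s.triage_selected,
        )
        rows.append(row)
    return pd.DataFrame(rows)
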