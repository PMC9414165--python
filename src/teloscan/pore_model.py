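"""Pore-model level tables and expected-current profiles for repeat motifs.

A nanopore reads out an ionic current whose mean level is, to first order, a
function of the k bases occupying the pore.  Oxford Nanopore publishes "pore
models": tables mapping every k-mer to its expected mean current in picoamperes
(for R9.4 chemistry, k = 6).  Tiling a repeat unit makes every circular
permutation of the unit pass through the pore in turn, so the expected current
trace of a perfect tandem repeat is periodic with the unit length.  This module
loads such tables, builds the periodic expected-current profile of any repeat
unit, and converts raw ADC signal to picoamperes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class PoreModelError(ValueError):
    """Malformed, incomplete or inconsistent pore-model table."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


class MissingKmerError(LookupError):
    """A k-mer required for profile construction is absent from the model."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise AlphabetError(f"empty {what}")
    if any(c not in ALPHABET for c in seq):
        bad = next(c for c in seq if c not in ALPHABET)
        raise AlphabetError(f"{what} {seq!r} contains non-ACGT character {bad!r}")


@dataclass(frozen=True)
class RawSignalMeta:
    """Channel calibration scalars carried alongside raw nanopore signal.

    ``offset`` is the ADC offset in counts, ``range`` the dynamic range in pA
    and ``digitisation`` the number of ADC levels; ``scale`` (pA per count) is
    ``range / digitisation``.
    """

    offset: float
    range: float
    digitisation: float

    def __post_init__(self) -> None:
        if self.digitisation <= 0:
            raise ValueError(f"digitisation must be > 0, got {self.digitisation}")

    @property
    def scale(self) -> float:
        return self.range / self.digitisation


@dataclass
class PoreModel:
    """Mapping from k-mer to expected mean current level (pA).

    A complete model holds all 4**k k-mers.  ``spread`` optionally carries a
    per-k-mer level standard deviation; it is not used by profile construction.
    """

    k: int
    levels: dict[str, float]
    spread: dict[str, float] | None = None
    model_id: str = ""

    def __post_init__(self) -> None:
        for kmer in self.levels:
            if len(kmer) != self.k:
                raise PoreModelError(
                    f"k-mer {kmer!r} has length {len(kmer)}, expected {self.k}"
                )
            _check_alphabet(kmer, "k-mer")
        if not all(np.isfinite(v) for v in self.levels.values()):
            raise PoreModelError("non-finite level in model")

    @property
    def is_complete(self) -> bool:
        return len(self.levels) == 4 ** self.k

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.levels

    def __getitem__(self, kmer: str) -> float:
        try:
            return self.levels[kmer]
        except KeyError:
            raise MissingKmerError(
                f"k-mer {kmer!r} absent from model {self.model_id or '<unnamed>'}"
            ) from None

    def __len__(self) -> int:
        return len(self.levels)


@dataclass
class CurrentProfile:
    """Ordered expected current values, one per position of a tiled repeat."""

    motif: str
    values: np.ndarray
    copies: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")

    def __len__(self) -> int:
        return self.values.size


def _find_column(header: Sequence[str], candidates: Iterable[str]) -> int | None:
    lowered = [h.strip().lstrip("#").lower() for h in header]
    for cand in candidates:
        if cand in lowered:
            return lowered.index(cand)
    return None


def load_pore_model(
    path: str | Path,
    allow_partial: bool = False,
    model_id: str | None = None,
) -> PoreModel:
    """Load a tab-separated k-mer level table.

    The table must have a header row naming a k-mer column (``kmer``) and a
    mean-level column (``level_mean`` or ``mean``); extra columns are ignored.
    k is inferred from the first k-mer.  Duplicate or missing k-mers are
    rejected; an incomplete table (fewer than 4**k rows) raises unless
    ``allow_partial`` is set.
    """
    path = Path(path)
    levels: dict[str, float] = {}
    spread: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        kcol = _find_column(header, ("kmer", "k-mer", "k_mer"))
        lcol = _find_column(header, ("level_mean", "mean", "mean_current"))
        scol = _find_column(header, ("level_stdv", "sd_mean", "level_sd"))
        if kcol is None or lcol is None:
            raise PoreModelError(
                f"{path}: header must name k-mer and level-mean columns, got {header!r}"
            )
        ncol = max(kcol, lcol) + 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < ncol:
                raise PoreModelError(
                    f"{path}:{lineno}: expected at least {ncol} tab-separated fields"
                )
            kmer = fields[kcol].strip().upper()
            try:
                level = float(fields[lcol])
            except ValueError:
                raise PoreModelError(
                    f"{path}:{lineno}: non-numeric level {fields[lcol]!r}"
                ) from None
            if kmer in levels:
                raise PoreModelError(f"{path}:{lineno}: duplicate k-mer {kmer}")
            levels[kmer] = level
            if scol is not None and len(fields) > scol:
                try:
                    spread[kmer] = float(fields[scol])
                except ValueError:
                    pass
    if not levels:
        raise PoreModelError(f"{path}: no k-mer rows")
    k = len(next(iter(levels)))
    model = PoreModel(
        k=k,
        levels=levels,
        spread=spread or None,
        model_id=model_id or path.stem,
    )
    if not model.is_complete and not allow_partial:
        raise PoreModelError(
            f"{path}: incomplete model, {len(levels)} of {4 ** k} {k}-mers present"
        )
    return model


def synthetic_pore_model(k: int = 6, seed: int = 0) -> PoreModel:
    """Deterministic synthetic stand-in for a published pore-model table.

    Levels follow a position-weighted base contribution (central bases dominate,
    as in real pores) plus small k-mer-specific noise, yielding values in a
    plausible 60-130 pA band with realistic correlation structure between
    k-mers that differ only at peripheral positions.  Synthetic: makes no claim
    of physical realism and carries none of the published table's values.
    """
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    rng = np.random.default_rng([int(seed), k, 0x7E10])
    # per-(position, base) contributions and a centre-heavy weight profile
    contrib = rng.uniform(-1.0, 1.0, size=(k, 4))
    centre = (k - 1) / 2.0
    width = max(k / 3.0, 1.0)
    weights = np.exp(-(((np.arange(k) - centre) / width) ** 2))
    weights /= weights.sum()
    base_index = {b: i for i, b in enumerate(ALPHABET)}
    levels: dict[str, float] = {}
    for kmer_tuple in itertools.product(ALPHABET, repeat=k):
        kmer = "".join(kmer_tuple)
        signal = sum(
            weights[i] * contrib[i, base_index[b]] for i, b in enumerate(kmer)
        )
        levels[kmer] = 95.0 + 28.0 * signal + rng.normal(0.0, 0.8)
    return PoreModel(k=k, levels=levels, model_id=f"synthetic_{k}mer_seed{seed}")


def rotations(motif: str) -> list[str]:
    """All left-circular shifts of a repeat unit, starting with the unit itself."""
    _check_alphabet(motif, "motif")
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def build_profile(motif: str, copies: int, model: PoreModel) -> CurrentProfile:
    """Expected-current profile of ``copies`` tandem copies of ``motif``.

    Construction is circular: the k-mer window at position j wraps across copy
    boundaries, so one period of a length-L unit yields exactly L values and
    the profile of c copies is that period tiled c times.  For L = k the one-
    period profile is the level of each circular permutation in rotation order.
    """
    _check_alphabet(motif, "motif")
    if copies < 1:
        raise ValueError(f"copies must be >= 1, got {copies}")
    L = len(motif)
    tiled = motif * (model.k // L + 2)
    period = np.array([model[tiled[j : j + model.k]] for j in range(L)])
    return CurrentProfile(motif=motif, values=np.tile(period, copies), copies=copies)


def raw_to_pA(raw_values: Sequence[float], meta: RawSignalMeta) -> np.ndarray:
    """Convert raw ADC counts to picoamperes: current = scale * (raw + offset)."""
    raw = np.asarray(raw_values, dtype=float)
    return meta.scale * (raw + meta.offset)
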