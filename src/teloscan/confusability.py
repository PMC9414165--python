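"""Confusability screen over repeat-unit current profiles.

Strand-specific repeat miscalls at telomeres (TTAGGG read as TTAAAA; CCCTAA
read as CTTCTT or CCCTGG) arise because the artefact unit's expected-current
profile is nearly indistinguishable from the true unit's.  This module
quantifies that similarity for any pair of units — Pearson correlation,
mean-centered Euclidean distance and mean current difference of their one-
period profiles — and screens all 4**k units pairwise for pairs a basecaller
is liable to confuse (default thresholds r >= 0.99 and distance <= 5 pA).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pore_model import (
    ALPHABET,
    CurrentProfile,
    PoreModel,
    _check_alphabet,
    build_profile,
)


@dataclass(frozen=True)
class ComparisonRecord:
    """Similarity statistics for one pair of repeat-unit profiles.

    ``pearson`` is NaN when either profile is constant (e.g. a homopolymer),
    where correlation is undefined; such pairs never pass the screen.
    """

    motif_a: str
    motif_b: str
    pearson: float
    euclid_centered: float
    mean_diff: float

    @property
    def pearson_defined(self) -> bool:
        return not math.isnan(self.pearson)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and unit length for the all-pairs screen."""

    r_min: float = 0.99
    d_max: float = 5.0
    k: int = 6

    def __post_init__(self) -> None:
        if not -1.0 <= self.r_min <= 1.0:
            raise ValueError(f"r_min must be in [-1, 1], got {self.r_min}")
        if self.d_max < 0:
            raise ValueError(f"d_max must be >= 0, got {self.d_max}")


def compare_profiles(a: CurrentProfile, b: CurrentProfile) -> ComparisonRecord:
    """Pearson r, mean-centered Euclidean distance and mean difference.

    Each profile is centered by its own mean before the Euclidean norm of the
    difference is taken, so the distance ignores any constant current offset
    between the two units.
    """
    va = np.asarray(a.values, dtype=float)
    vb = np.asarray(b.values, dtype=float)
    if va.size != vb.size:
        raise ValueError(
            f"profile length mismatch: {va.size} ({a.motif}) vs {vb.size} ({b.motif})"
        )
    if va.size < 2:
        raise ValueError("profiles must have at least 2 values")
    ca = va - va.mean()
    cb = vb - vb.mean()
    na, nb = np.linalg.norm(ca), np.linalg.norm(cb)
    if na == 0.0 or nb == 0.0:
        pearson = float("nan")
    else:
        pearson = float(np.dot(ca, cb) / (na * nb))
    return ComparisonRecord(
        motif_a=a.motif,
        motif_b=b.motif,
        pearson=pearson,
        euclid_centered=float(np.linalg.norm(ca - cb)),
        mean_diff=float(abs(va.mean() - vb.mean())),
    )


def all_motifs(k: int) -> list[str]:
    """All 4**k units of length k in lexicographic order (rotations distinct)."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


def all_pairs_screen(
    model: PoreModel, config: ScreenConfig | None = None
) -> tuple[list[ComparisonRecord], int]:
    """Screen every unordered pair of length-k units for confusability.

    One-period profiles (k values, the levels of the unit's circular
    permutations in rotation order) are compared for all C(4**k, 2) unordered
    pairs; pairs with Pearson r >= r_min and centered distance <= d_max are
    returned, sorted by descending r, then ascending distance, then unit pair.
    Pairs with undefined correlation are counted as compared but never pass.

    Returns ``(passing_records, total_comparisons)``.
    """
    config = config or ScreenConfig()
    k = config.k
    motifs = all_motifs(k)
    n = len(motifs)
    profiles = np.empty((n, k), dtype=float)
    for i, m in enumerate(motifs):
        profiles[i] = build_profile(m, 1, model).values

    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    defined = norms > 0.0
    safe = np.where(defined, norms, 1.0)
    unit = centered / safe[:, None]

    corr = unit @ unit.T
    gram = centered @ centered.T
    sq = np.square(norms)
    dist2 = np.clip(sq[:, None] + sq[None, :] - 2.0 * gram, 0.0, None)
    dist = np.sqrt(dist2)

    means = profiles.mean(axis=1)
    pass_mask = (
        (corr >= config.r_min)
        & (dist <= config.d_max)
        & defined[:, None]
        & defined[None, :]
    )
    iu, ju = np.triu_indices(n, k=1)
    sel = pass_mask[iu, ju]
    records = [
        ComparisonRecord(
            motif_a=motifs[i],
            motif_b=motifs[j],
            pearson=float(corr[i, j]),
            euclid_centered=float(dist[i, j]),
            mean_diff=float(abs(means[i] - means[j])),
        )
        for i, j in zip(iu[sel], ju[sel])
    ]
    records.sort(
        key=lambda r: (-r.pearson, r.euclid_centered, r.motif_a, r.motif_b)
    )
    total = n * (n - 1) // 2
    return records, total


def cross_length_overlay(
    motifs: list[str], copies: int, model: PoreModel
) -> list[CurrentProfile]:
    """Profiles of several units (possibly of different length) for overlay.

    Units of different period (e.g. the 6-mer CCCTCA against the 5-mer CCTCA)
    can share near-identical current traces; this returns their tiled profiles
    (length L_i * copies each) for plotting or tabulation.  No pairwise
    statistic is computed when the lengths differ.
    """
    for m in motifs:
        _check_alphabet(m, "motif")
    return [build_profile(m, copies, model) for m in motifs]


def records_to_dataframe(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Tabulate comparison records (screen catalogue layout)."""
    return pd.DataFrame(
        {
            "motif_a": [r.motif_a for r in records],
            "motif_b": [r.motif_b for r in records],
            "pearson": [r.pearson for r in records],
            "euclid_centered": [r.euclid_centered for r in records],
            "mean_diff": [r.mean_diff for r in records],
        }
    )
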