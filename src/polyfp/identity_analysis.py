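"""Duplicate verification and identity clustering over dosage profiles.

Two accessions are molecularly identical when their dosage profiles over a
robust marker panel match exactly. Pairwise comparison uses the Chebyshev
(maximum) distance over mutually scored markers; assumed-duplicate pairs
are categorised by their number of differing markers, with pairs missing
too many markers declared inconclusive. Marker-number combinatorics
(5^m profiles for m tetraploid biallelic markers) quantify the panel's
theoretical discriminatory power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError
from .io_formats import ScoreMatrix

__all__ = [
    "PairVerdict",
    "IdentityCluster",
    "max_distance_matrix",
    "classify_pair",
    "find_identical_clusters",
    "min_markers_required",
    "theoretical_capacity",
    "count_distinguishable_profiles",
]

# a pair with more than this many jointly missing markers is inconclusive
MAX_MISSING_MARKERS = 4


@dataclass(frozen=True)
class PairVerdict:
    """Verdict on one assumed-duplicate pair.

    A marker counts as missing for the pair when it is unscored in either
    member; with more than four missing markers the pair is inconclusive.
    Otherwise the category follows the difference count over mutually
    scored markers: 0 -> identical, 1-3 -> diff_1_3, >3 -> diff_gt3.
    """

    accession_a: str
    accession_b: str
    n_compared: int
    n_missing_markers: int
    n_differences: int
    category: str


@dataclass(frozen=True)
class IdentityCluster:
    """Accessions (>= 2) sharing one complete dosage profile."""

    members: tuple[str, ...]
    profile: tuple[int, ...]


def max_distance_matrix(matrix: ScoreMatrix) -> pd.DataFrame:
    """Pairwise Chebyshev distance over mutually scored markers.

    ``d(a, b) = max_m |dosage_a(m) − dosage_b(m)|`` over markers scored in
    both accessions; symmetric with a zero diagonal. Pairs sharing no
    scored marker get NaN (flagged undefined) rather than a fabricated
    extreme value.
    """
    arr = matrix.scores.to_numpy(dtype=float)
    n = arr.shape[0]
    with np.errstate(invalid="ignore"):
        diff = np.abs(arr[:, None, :] - arr[None, :, :])
        dist = np.full((n, n), np.nan)
        shared = (~np.isnan(diff)).any(axis=2)
        # nanmax over an all-NaN slice raises; mask it out first
        safe = np.where(np.isnan(diff), -np.inf, diff).max(axis=2)
        dist[shared] = safe[shared]
    np.fill_diagonal(dist, 0.0)
    idx = matrix.accessions
    return pd.DataFrame(dist, index=idx, columns=idx)


def classify_pair(
    profile_a: Sequence[float] | pd.Series,
    profile_b: Sequence[float] | pd.Series,
    accession_a: str = "a",
    accession_b: str = "b",
    max_missing: int = MAX_MISSING_MARKERS,
) -> PairVerdict:
    """Categorise an assumed-duplicate pair over a shared marker panel."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise UsageError("profiles must be indexed by the same panel")
    missing = np.isnan(a) | np.isnan(b)
    n_missing = int(missing.sum())
    compared = ~missing
    n_diff = int((a[compared] != b[compared]).sum())
    if n_missing > max_missing:
        category = "inconclusive"
    elif n_diff == 0:
        category = "identical"
    elif n_diff <= 3:
        category = "diff_1_3"
    else:
        category = "diff_gt3"
    return PairVerdict(
        accession_a=accession_a,
        accession_b=accession_b,
        n_compared=int(compared.sum()),
        n_missing_markers=n_missing,
        n_differences=n_diff,
        category=category,
    )


def find_identical_clusters(
    matrix: ScoreMatrix,
) -> tuple[list[IdentityCluster], list[str]]:
    """Group accessions with exactly identical complete profiles.

    The matrix must be complete (restrict it to the robust subset first).
    Returns (clusters of size >= 2, unique accession ids).
    """
    if matrix.scores.isna().to_numpy().any():
        raise ValidationError(
            "identity clustering requires a complete matrix; restrict to "
            "the robust accession subset first"
        )
    groups: dict[tuple[int, ...], list[str]] = {}
    for acc, row in matrix.scores.iterrows():
        key = tuple(int(v) for v in row)
        groups.setdefault(key, []).append(str(acc))
    clusters = [
        IdentityCluster(members=tuple(members), profile=profile)
        for profile, members in groups.items()
        if len(members) >= 2
    ]
    clusters.sort(key=lambda c: (-len(c.members), c.members))
    unique = sorted(
        m for profile, members in groups.items() if len(members) == 1
        for m in members
    )
    return clusters, unique


def min_markers_required(n_genotypes: int, n_classes: int = 5) -> int:
    """Smallest marker count m with ``n_classes**m >= n_genotypes``."""
    if n_genotypes < 1:
        raise ValidationError("n_genotypes must be >= 1")
    if n_classes < 2:
        raise ValidationError("n_classes must be >= 2")
    m = 0
    capacity = 1
    while capacity < n_genotypes:
        capacity *= n_classes
        m += 1
    return m


def theoretical_capacity(n_markers: int, n_classes: int = 5) -> int:
    """Number of distinct profiles m markers can encode (exact integer)."""
    if n_markers < 0:
        raise ValidationError("n_markers must be >= 0")
    return n_classes**n_markers


def count_distinguishable_profiles(
    matrix: ScoreMatrix, marker_subset: Sequence[str]
) -> int:
    """Distinct dosage-profile tuples over a marker subset."""
    if not len(marker_subset):
        raise UsageError("marker subset must be non-empty")
    sub = matrix.scores[list(marker_subset)]
    if sub.isna().to_numpy().any():
        raise ValidationError("restricted matrix must be complete")
    return int(len({tuple(int(v) for v in row) for _, row in sub.iterrows()}))
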