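"""Marker-level quality statistics and panel selection filters.

A fingerprinting marker is useful when its five dosage classes are well
occupied (high evenness — Shannon–Wiener index of the class proportions
normalised by ln of the class count), its call rate is high, and its
posterior assignments are confident. This module houses those statistics
plus the three chip-selection criteria and the chromosome-coverage check
used to assemble the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dosage_calling import DosageCall
from .errors import ValidationError
from .io_formats import PanelDefinition, ScoreMatrix

__all__ = [
    "EvennessResult",
    "ChipFilterResult",
    "ChromosomeCoverage",
    "compute_evenness",
    "dosage_proportions",
    "chip_filter",
    "check_chromosome_coverage",
    "marker_qc_report",
]

N_CLASSES = 5  # tetraploid: dosages 0..4


@dataclass(frozen=True)
class EvennessResult:
    """Dosage-class proportions with their Shannon–Wiener evenness.

    ``H_S`` is the Shannon–Wiener index −Σ p_i ln p_i (nats) over the S
    dosage classes; ``I = H_S / ln(S)`` lies in [0, 1], with 1 for a
    perfectly uniform class occupancy.
    """

    p: tuple[float, ...]
    S: int
    H_S: float
    I: float


@dataclass(frozen=True)
class ChipFilterResult:
    marker_id: str
    min_class_proportion: float
    frac_high_confidence: float
    mean_max_posterior: float
    passes_occupancy: bool
    passes_confident_fraction: bool
    passes_mean_confidence: bool

    @property
    def passed(self) -> bool:
        return (
            self.passes_occupancy
            and self.passes_confident_fraction
            and self.passes_mean_confidence
        )


@dataclass(frozen=True)
class ChromosomeCoverage:
    counts: dict[int, int]
    deficient: tuple[int, ...]

    @property
    def passed(self) -> bool:
        return not self.deficient


def compute_evenness(proportions: Sequence[float]) -> EvennessResult:
    """Shannon–Wiener evenness of dosage-class proportions.

    ``I = H_S / ln(S)`` where ``H_S = −Σ p_i ln p_i`` (0·ln 0 := 0) and S is
    the number of dosage classes (5 for a tetraploid). Proportions must be
    non-negative and sum to 1.
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValidationError("need at least two class proportions")
    if (p < 0).any():
        raise ValidationError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(
            f"proportions must sum to 1 (got {p.sum():.6f})"
        )
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    s = len(p)
    return EvennessResult(p=tuple(p.tolist()), S=s, H_S=h, I=h / np.log(s))


def dosage_proportions(
    calls: Iterable[DosageCall], n_classes: int = N_CLASSES
) -> np.ndarray:
    """Class proportions over called (non-missing, non-control) samples."""
    dosages = [
        c.dosage
        for c in calls
        if not c.is_negative_control and c.dosage is not None
    ]
    if not dosages:
        raise ValidationError(
            "dosage proportions undefined: no called samples"
        )
    counts = np.bincount(np.asarray(dosages, dtype=int), minlength=n_classes)
    return counts / counts.sum()


def chip_filter(
    posteriors: pd.DataFrame | np.ndarray,
    marker_id: str = "",
    min_class_proportion: float = 0.10,
    min_confident_fraction: float = 0.90,
    confident_posterior: float = 0.99,
    min_mean_max_posterior: float = 0.99,
) -> ChipFilterResult:
    """Apply the three chip-selection criteria to a posterior table.

    Given a samples x classes table of class posteriors (rows sum to 1):

    1. every dosage class holds at least 10% of samples (by argmax class);
    2. at least 90% of samples have a max posterior of at least 0.99;
    3. the mean per-sample max posterior is at least 0.99.

    The marker passes only if all three hold.
    """
    p = np.asarray(posteriors, dtype=float)
    if p.size == 0:
        raise ValidationError("empty posterior table")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("posterior rows must sum to 1")
    n, k = p.shape
    argmax = p.argmax(axis=1)
    occupancy = np.bincount(argmax, minlength=k) / n
    max_post = p.max(axis=1)
    frac_conf = float((max_post >= confident_posterior).mean())
    mean_max = float(max_post.mean())
    return ChipFilterResult(
        marker_id=marker_id,
        min_class_proportion=float(occupancy.min()),
        frac_high_confidence=frac_conf,
        mean_max_posterior=mean_max,
        passes_occupancy=bool(occupancy.min() >= min_class_proportion),
        passes_confident_fraction=bool(frac_conf >= min_confident_fraction),
        passes_mean_confidence=bool(mean_max >= min_mean_max_posterior),
    )


def check_chromosome_coverage(
    panel: Iterable[PanelDefinition],
    n_chromosomes: int = 7,
    min_per_chromosome: int = 2,
) -> ChromosomeCoverage:
    """Check that every chromosome carries at least two panel markers."""
    counts = {c: 0 for c in range(1, n_chromosomes + 1)}
    for marker in panel:
        counts[marker.chromosome] += 1
    deficient = tuple(
        c for c in counts if counts[c] < min_per_chromosome
    )
    return ChromosomeCoverage(counts=counts, deficient=deficient)


def marker_qc_report(matrix: ScoreMatrix) -> pd.DataFrame:
    """Per-marker dosage proportions and evenness from a score matrix.

    Mirrors the per-marker allele-distribution table: columns P0..P4 (2
    decimals in reports), evenness (3 decimals) and call rate.
    """
    rows = []
    for marker in matrix.markers:
        col = matrix.scores[marker]
        called = col.dropna().astype(int)
        rec: dict[str, float | str] = {"marker_id": marker}
        rec["call_rate"] = float(col.notna().mean())
        if len(called):
            counts = np.bincount(called, minlength=N_CLASSES)
            props = counts / counts.sum()
            ev = compute_evenness(props)
            for d in range(N_CLASSES):
                rec[f"P{d}"] = props[d]
            rec["evenness"] = ev.I
        else:
            for d in range(N_CLASSES):
                rec[f"P{d}"] = np.nan
            rec["evenness"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("marker_id")
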