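"""Dual-layout robustness analysis.

Endpoint-fluorescence dosage calling is relative: a sample's dosage is only
interpretable against the other samples in its analysis unit. The pipeline
therefore calls every marker twice — once per pooled analysis plate
("original" layout) and once per 95-sample source plate ("single" layout) —
compares the two score matrices, combines them, and drops markers whose
calls disagree too often between layouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError
from .io_formats import ScoreMatrix, SignalRecord

__all__ = [
    "LayoutComparison",
    "split_by_source_plate",
    "compare_layout_calls",
    "combine_layout_calls",
    "marker_robustness_filter",
    "robust_subset",
]


@dataclass
class LayoutComparison:
    """Per-marker agreement between two layout analyses.

    ``disagreement_fraction`` is taken over cells called in both layouts
    (NaN when no cell is called in both); ``magnitude_breakdown`` counts
    disagreements by absolute dosage difference 1..4.
    """

    marker_id: str
    n_both_called: int
    disagreement_fraction: float
    magnitude_breakdown: dict[int, int] = field(default_factory=dict)
    call_rate_single: float = float("nan")
    call_rate_original: float = float("nan")
    call_rate_combined: float = float("nan")


def split_by_source_plate(
    records: Sequence[SignalRecord],
) -> dict[str, list[SignalRecord]]:
    """Partition one analysis plate's records by 96-well source plate.

    Controls stay with their source plate. The groups are disjoint and
    cover all records; a non-control record without source-plate provenance
    is an error.
    """
    groups: dict[str, list[SignalRecord]] = {}
    for rec in records:
        if not rec.source_plate_id:
            raise ValidationError(
                f"record for sample {rec.sample_id!r} lacks a source_plate_id"
            )
        groups.setdefault(rec.source_plate_id, []).append(rec)
    return groups


def _check_indices(a: ScoreMatrix, b: ScoreMatrix) -> None:
    if list(a.accessions) != list(b.accessions) or list(a.markers) != list(
        b.markers
    ):
        raise UsageError(
            "score matrices must share identical accession and marker indices"
        )


def compare_layout_calls(
    calls_single: ScoreMatrix, calls_original: ScoreMatrix
) -> dict[str, LayoutComparison]:
    """Per-marker disagreement between the single- and pooled-layout calls."""
    _check_indices(calls_single, calls_original)
    combined, _ = combine_layout_calls(calls_single, calls_original)
    out: dict[str, LayoutComparison] = {}
    for marker in calls_single.markers:
        s = calls_single.scores[marker]
        o = calls_original.scores[marker]
        both = s.notna() & o.notna()
        n_both = int(both.sum())
        breakdown: dict[int, int] = {}
        if n_both:
            diff = (s[both] - o[both]).abs().astype(int)
            n_disagree = int((diff > 0).sum())
            for mag in range(1, 5):
                c = int((diff == mag).sum())
                if c:
                    breakdown[mag] = c
            frac = n_disagree / n_both
        else:
            frac = float("nan")
        out[marker] = LayoutComparison(
            marker_id=marker,
            n_both_called=n_both,
            disagreement_fraction=frac,
            magnitude_breakdown=breakdown,
            call_rate_single=float(s.notna().mean()),
            call_rate_original=float(o.notna().mean()),
            call_rate_combined=float(combined.scores[marker].notna().mean()),
        )
    return out


def combine_layout_calls(
    calls_single: ScoreMatrix, calls_original: ScoreMatrix
) -> tuple[ScoreMatrix, set[tuple[str, str]]]:
    """Merge two layout analyses cell-wise.

    A cell called in exactly one layout takes that call; called identically
    in both, the shared call; called differently, the call with the higher
    posterior wins and the cell is recorded in the conflict set (when no
    posteriors are attached the first argument wins). Conflicted cells
    count as called, so the combined call rate is >= each input's rate for
    every marker.
    """
    _check_indices(calls_single, calls_original)
    s = calls_single.scores
    o = calls_original.scores
    merged = s.where(s.notna(), o)
    conflicts: set[tuple[str, str]] = set()
    both = s.notna() & o.notna()
    disagree = both & (s != o)
    if disagree.to_numpy().any():
        ps = calls_single.posteriors
        po = calls_original.posteriors
        for acc, marker in zip(*np.where(disagree.to_numpy())):
            acc_id = s.index[acc]
            marker_id = s.columns[marker]
            conflicts.add((acc_id, marker_id))
            if ps is not None and po is not None:
                if po.loc[acc_id, marker_id] > ps.loc[acc_id, marker_id]:
                    merged.loc[acc_id, marker_id] = o.loc[acc_id, marker_id]
    post = None
    if calls_single.posteriors is not None and calls_original.posteriors is not None:
        post = calls_single.posteriors.combine(
            calls_original.posteriors, lambda a, b: np.fmax(a, b)
        )
    return ScoreMatrix(merged, layout="combined", posteriors=post), conflicts


def marker_robustness_filter(
    comparisons: Mapping[str, LayoutComparison] | Iterable[LayoutComparison],
    threshold: float = 0.10,
) -> tuple[list[str], list[str]]:
    """Split markers into (retained, excluded) by layout disagreement.

    A marker is excluded when its disagreement fraction strictly exceeds
    the threshold (default 10%); markers with an undefined fraction (no
    cell called in both layouts) are retained.
    """
    if isinstance(comparisons, Mapping):
        comparisons = list(comparisons.values())
    else:
        comparisons = list(comparisons)
    if not comparisons:
        raise ValidationError("no layout comparisons supplied")
    retained, excluded = [], []
    for comp in comparisons:
        frac = comp.disagreement_fraction
        if not np.isnan(frac) and frac > threshold:
            excluded.append(comp.marker_id)
        else:
            retained.append(comp.marker_id)
    return retained, excluded


def robust_subset(
    calls_single: ScoreMatrix,
    calls_original: ScoreMatrix,
    panel: Sequence[str],
) -> list[str]:
    """Accessions scored completely and identically under both layouts.

    An accession qualifies when every panel marker is called in both
    layouts and the two calls agree everywhere — the "proof of concept"
    subset used for identity clustering.
    """
    for marker in panel:
        if marker not in calls_single.markers or marker not in calls_original.markers:
            raise UsageError(f"panel marker {marker!r} missing from a matrix")
    s = calls_single.scores[list(panel)]
    o = calls_original.scores[list(panel)]
    common = s.index.intersection(o.index)
    s = s.loc[common]
    o = o.loc[common]
    complete = s.notna().all(axis=1) & o.notna().all(axis=1)
    agree = (s == o) | ~(s.notna() & o.notna())
    identical = agree.all(axis=1)
    return list(s.index[complete & identical])
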