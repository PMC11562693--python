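"""Amplicon-haplotype discrimination analysis.

Amplicon sequencing of a marker region yields, per genotype, read counts
over the distinct haplotype sequences of the locus. After read filtering
(genotypes under a total-read threshold dropped; haplotypes under a
per-genotype frequency threshold zeroed), a tetraploid genotype's four
chromosome copies are apportioned among its retained haplotypes by
largest-remainder rounding of the read fractions, giving a haplotype-dosage
multiset. Distinct multisets are the genotypes the marker can distinguish;
combining markers multiplies discriminatory power, summarised in a
pairwise combination table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError
from .io_formats import HaplotypeTable, ScoreMatrix

__all__ = [
    "AmpliconSummary",
    "filter_read_table",
    "count_polymorphic_sites",
    "haplotype_dosages",
    "genotype_multisets",
    "summarize_amplicon",
    "pairwise_combination_table",
    "concordance_with_reference",
]

DEFAULT_MIN_READS = 100
DEFAULT_MIN_FRACTION = 0.10
PLOIDY = 4


@dataclass(frozen=True)
class AmpliconSummary:
    marker_id: str
    n_genotypes_retained: int
    n_polymorphic_sites: int
    n_haplotypes: int
    n_distinguishable_genotypes: int
    flagged_genotypes: tuple[str, ...] = ()


def filter_read_table(
    table: HaplotypeTable,
    min_reads: int = DEFAULT_MIN_READS,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> HaplotypeTable:
    """Apply the read filters: low-coverage genotypes and rare haplotypes.

    Genotypes with total reads strictly below ``min_reads`` are removed;
    within each retained genotype, haplotypes holding strictly less than
    ``min_fraction`` of its total reads are zeroed (a haplotype at exactly
    the threshold is kept). The two rules are re-applied until stable so
    the operation is idempotent, and haplotypes left with zero reads
    everywhere are dropped.
    """
    counts = table.counts.copy()
    while True:
        totals = counts.sum(axis=1)
        keep = totals >= min_reads
        counts = counts.loc[keep]
        totals = totals[keep]
        if counts.empty:
            break
        frac_floor = (totals * min_fraction).to_numpy()[:, None]
        arr = counts.to_numpy()
        zeroed = np.where(arr < frac_floor, 0, arr)
        changed = (zeroed != arr).any() or not keep.all()
        counts = pd.DataFrame(zeroed, index=counts.index, columns=counts.columns)
        if not changed:
            break
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    sequences = {h: table.sequences[h] for h in counts.columns}
    return HaplotypeTable(
        marker_id=table.marker_id,
        sequences=sequences,
        counts=counts.astype(int),
        amplicon_length=table.amplicon_length,
    )


def count_polymorphic_sites(sequences: Mapping[str, str]) -> int:
    """Alignment columns with more than one distinct symbol (gap counts)."""
    seqs = list(sequences.values())
    if not seqs:
        return 0
    n = 0
    for col in zip(*seqs):
        if len(set(col)) > 1:
            n += 1
    return n


def haplotype_dosages(
    reads: Mapping[str, int] | pd.Series, ploidy: int = PLOIDY
) -> dict[str, int]:
    """Apportion a genotype's chromosome copies among its haplotypes.

    Largest-remainder rounding of ``ploidy x read fraction``, with every
    retained (nonzero-read) haplotype guaranteed a dosage of at least 1 and
    the dosages summing exactly to the ploidy. Ties break toward the
    higher-count haplotype, then lexicographic id.

    Raises :class:`ValidationError` when more haplotypes are retained than
    the ploidy allows (flag the genotype instead of forcing a dosage).
    """
    items = [(str(h), int(r)) for h, r in dict(reads).items() if r > 0]
    if not items:
        raise ValidationError("no retained haplotypes for genotype")
    if len(items) > ploidy:
        raise ValidationError(
            f"{len(items)} retained haplotypes exceed ploidy {ploidy}"
        )
    total = sum(r for _, r in items)
    quotas = [(h, ploidy * r / total, r) for h, r in items]
    dosage = {h: int(np.floor(q)) for h, q, _ in quotas}
    remaining = ploidy - sum(dosage.values())
    # largest remainder first; ties toward higher read count, then id
    order = sorted(
        quotas, key=lambda t: (-(t[1] - np.floor(t[1])), -t[2], t[0])
    )
    for h, _, _ in order[:remaining]:
        dosage[h] += 1
    # every retained haplotype carries at least one copy
    zeros = sorted(
        (h for h, d in dosage.items() if d == 0),
        key=lambda h: (-dict(items)[h], h),
    )
    for h in zeros:
        donor = max(
            dosage, key=lambda x: (dosage[x], dict(items)[x], x)
        )
        dosage[donor] -= 1
        dosage[h] += 1
    assert sum(dosage.values()) == ploidy
    return dosage


def genotype_multisets(
    table: HaplotypeTable, ploidy: int = PLOIDY
) -> tuple[dict[str, tuple[tuple[str, int], ...]], list[str]]:
    """Per-genotype haplotype-dosage multisets from a filtered table.

    Returns (multisets keyed by genotype, flagged genotypes that retained
    more haplotypes than the ploidy and are excluded from counting).
    """
    multisets: dict[str, tuple[tuple[str, int], ...]] = {}
    flagged: list[str] = []
    for gid, row in table.counts.iterrows():
        try:
            d = haplotype_dosages(row, ploidy=ploidy)
        except ValidationError:
            flagged.append(str(gid))
            continue
        multisets[str(gid)] = tuple(sorted(d.items()))
    return multisets, flagged


def summarize_amplicon(
    table: HaplotypeTable, ploidy: int = PLOIDY
) -> AmpliconSummary:
    """Marker-level discrimination summary of a filtered haplotype table."""
    if table.counts.empty:
        raise ValidationError(
            f"marker {table.marker_id!r}: no genotypes retained"
        )
    multisets, flagged = genotype_multisets(table, ploidy=ploidy)
    return AmpliconSummary(
        marker_id=table.marker_id,
        n_genotypes_retained=len(table.counts),
        n_polymorphic_sites=count_polymorphic_sites(table.sequences),
        n_haplotypes=len(table.counts.columns),
        n_distinguishable_genotypes=len(set(multisets.values())),
        flagged_genotypes=tuple(flagged),
    )


def pairwise_combination_table(
    tables: Sequence[HaplotypeTable], ploidy: int = PLOIDY
) -> pd.DataFrame:
    """Distinguishable-genotype counts for markers alone and in pairs.

    Diagonal entries are each marker's own distinguishable-genotype count;
    the (i, j) off-diagonal counts distinct joint multiset pairs over the
    genotypes retained (and unflagged) in both markers. Symmetric.
    """
    if len(tables) < 2:
        raise UsageError("need at least two markers to combine")
    ids = [t.marker_id for t in tables]
    per_marker = {t.marker_id: genotype_multisets(t, ploidy)[0] for t in tables}
    out = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, mi in enumerate(ids):
        out.loc[mi, mi] = len(set(per_marker[mi].values()))
        for mj in ids[i + 1 :]:
            shared = per_marker[mi].keys() & per_marker[mj].keys()
            joint = {
                (per_marker[mi][g], per_marker[mj][g]) for g in shared
            }
            out.loc[mi, mj] = out.loc[mj, mi] = len(joint)
    return out


def concordance_with_reference(
    amplicon_dosages: ScoreMatrix, reference_dosages: ScoreMatrix
) -> tuple[pd.DataFrame, float]:
    """Per-marker agreement between amplicon-derived and reference calls.

    For each shared marker: identical calls, differing calls, genotypes
    unscored in total / in the reference / in the amplicon analysis; the
    overall agreement fraction is taken over cells scored by both methods.
    """
    markers = [
        m for m in amplicon_dosages.markers if m in reference_dosages.markers
    ]
    accs = amplicon_dosages.accessions.intersection(
        reference_dosages.accessions
    )
    if not markers or not len(accs):
        raise UsageError("matrices share no markers or no accessions")
    rows = []
    total_same = total_both = 0
    for marker in markers:
        a = amplicon_dosages.scores.loc[accs, marker]
        r = reference_dosages.scores.loc[accs, marker]
        both = a.notna() & r.notna()
        same = int((a[both] == r[both]).sum())
        diff = int(both.sum()) - same
        rows.append(
            {
                "marker_id": marker,
                "n_identical": same,
                "n_differing": diff,
                "n_unscored_total": int((~both).sum()),
                "n_unscored_reference": int(r.isna().sum()),
                "n_unscored_amplicon": int(a.isna().sum()),
            }
        )
        total_same += same
        total_both += int(both.sum())
    report = pd.DataFrame(rows).set_index("marker_id")
    agreement = total_same / total_both if total_both else float("nan")
    return report, agreement
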