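"""Synthetic data with the statistical structure of plate-based polyploid
SNP fingerprinting.

The generator emulates the study conditions end to end: per-marker dosage
frequencies drawn from a symmetric Dirichlet, true dosages per accession,
plate structure (95 samples + 1 negative control per 96-well source plate,
four source plates pooled into a 384-well analysis plate), two-channel
fluorescence whose transformed ratio clusters at five dosage-specific
locations on [0, 1], per-sample dropout, injected duplicate accessions and
mislabel swaps, and multinomial amplicon read counts proportional to
haplotype dosage.

All randomness flows from a single seed through named substreams, so each
operation is independently reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import HaplotypeTable, SignalRecord

__all__ = [
    "SimulationTruth",
    "EASY_PRESET",
    "HARD_PRESET",
    "generate_truth_panel",
    "simulate_fluorescence",
    "inject_duplicates_and_mislabels",
    "simulate_amplicon_reads",
]

# transformed-ratio cluster locations for dosages 0..4 and within-cluster sd
DEFAULT_LOCATIONS = (0.1, 0.3, 0.5, 0.7, 0.9)
EASY_PRESET = {"cluster_scale": 0.02, "dropout_rate": 0.02}
HARD_PRESET = {"cluster_scale": 0.07, "dropout_rate": 0.02}

SOURCE_PLATE_SIZE = 95  # samples per 96-well DNA plate (1 well is a control)
SOURCE_PLATES_PER_ANALYSIS_PLATE = 4  # 380 samples + 4 controls = 384 wells


def _substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed, int.from_bytes(digest[:4], "big")])
    )


@dataclass
class SimulationTruth:
    """Ground truth for one simulated fingerprinting study."""

    seed: int
    dosages: pd.DataFrame  # accessions x markers, int 0..4
    marker_frequencies: pd.DataFrame  # markers x 5 dosage-class frequencies
    chromosomes: dict[str, int]
    cluster_locations: tuple[float, ...] = DEFAULT_LOCATIONS
    cluster_scale: float = EASY_PRESET["cluster_scale"]
    dropout_rate: float = EASY_PRESET["dropout_rate"]
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    mislabel_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not all(np.diff(self.cluster_locations) > 0):
            raise ValidationError("cluster locations must be increasing")
        sums = self.marker_frequencies.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("marker frequency vectors must sum to 1")

    @property
    def accessions(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def markers(self) -> list[str]:
        return list(self.dosages.columns)


def generate_truth_panel(
    n_accessions: int,
    n_markers: int,
    frequency_concentration: float = 5.0,
    seed: int = 0,
    cluster_locations: Sequence[float] = DEFAULT_LOCATIONS,
    cluster_scale: float = EASY_PRESET["cluster_scale"],
    dropout_rate: float = EASY_PRESET["dropout_rate"],
) -> SimulationTruth:
    """Draw a ground-truth panel: dosage frequencies and true dosages.

    Per-marker dosage-class frequencies come from a symmetric Dirichlet
    with the given concentration (larger -> more even class occupancy, as
    for the high-evenness markers of a well-chosen panel); each accession's
    dosage is drawn independently from its marker's frequencies.
    Chromosomes 1..7 are assigned round-robin so an 18-marker panel passes
    the two-per-chromosome coverage rule.
    """
    if n_accessions < 1 or n_markers < 1:
        raise ValidationError("need at least one accession and one marker")
    rng = _substream(seed, "truth")
    markers = [f"M{i + 1:03d}" for i in range(n_markers)]
    accessions = [f"ACC{i + 1:05d}" for i in range(n_accessions)]
    freqs = rng.dirichlet(
        np.full(len(cluster_locations), frequency_concentration), size=n_markers
    )
    dosages = np.column_stack(
        [
            rng.choice(len(cluster_locations), size=n_accessions, p=freqs[j])
            for j in range(n_markers)
        ]
    )
    return SimulationTruth(
        seed=seed,
        dosages=pd.DataFrame(dosages, index=accessions, columns=markers),
        marker_frequencies=pd.DataFrame(
            freqs, index=markers, columns=[f"P{d}" for d in range(len(cluster_locations))]
        ),
        chromosomes={m: (i % 7) + 1 for i, m in enumerate(markers)},
        cluster_locations=tuple(cluster_locations),
        cluster_scale=cluster_scale,
        dropout_rate=dropout_rate,
    )


def inject_duplicates_and_mislabels(
    truth: SimulationTruth,
    n_duplicates: int = 0,
    n_mislabels: int = 0,
    seed: int | None = None,
) -> SimulationTruth:
    """Add duplicate accessions and mislabel swaps to a truth panel.

    Duplicates copy an accession's true dosage vector under a new id
    (``<id>-DUP``); mislabels swap the dosage vectors behind two existing
    ids while the labels stay put. Both manipulations are recorded in the
    returned truth's manifest fields.
    """
    n_acc = len(truth.accessions)
    if n_duplicates + 2 * n_mislabels > n_acc:
        raise ValidationError("too many duplicates/mislabels for panel size")
    rng = _substream(seed if seed is not None else truth.seed, "inject")
    dosages = truth.dosages.copy()
    chosen = rng.choice(n_acc, size=n_duplicates + 2 * n_mislabels, replace=False)
    dup_ids = [truth.accessions[i] for i in chosen[:n_duplicates]]
    swap_ids = [truth.accessions[i] for i in chosen[n_duplicates:]]

    duplicate_pairs = []
    for acc in dup_ids:
        new_id = f"{acc}-DUP"
        dosages.loc[new_id] = dosages.loc[acc]
        duplicate_pairs.append((acc, new_id))
    mislabel_pairs = []
    for a, b in zip(swap_ids[::2], swap_ids[1::2]):
        row_a = dosages.loc[a].copy()
        dosages.loc[a] = dosages.loc[b]
        dosages.loc[b] = row_a
        mislabel_pairs.append((a, b))
    return replace(
        truth,
        dosages=dosages,
        duplicate_pairs=truth.duplicate_pairs + duplicate_pairs,
        mislabel_pairs=truth.mislabel_pairs + mislabel_pairs,
    )


def _well_name(index: int, n_cols: int = 24) -> str:
    row, col = divmod(index, n_cols)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def simulate_fluorescence(
    truth: SimulationTruth,
    total_signal: float = 1000.0,
    seed: int | None = None,
) -> list[SignalRecord]:
    """Emit two-channel fluorescence records with plate structure.

    Accessions fill 96-well source plates (95 samples + 1 negative
    control); four source plates pool into one 384-well analysis plate.
    Each sample x marker draws its transformed ratio from a normal at the
    dosage's cluster location (sd = ``cluster_scale``, clipped to [0, 1])
    and signals are back-computed so ``transform_signal`` recovers the
    ratio exactly. With probability ``dropout_rate`` the well fails (both
    channels zero -> missing call); control wells emit near-zero signal.
    """
    rng = _substream(seed if seed is not None else truth.seed, "fluor")
    locations = np.asarray(truth.cluster_locations)
    records: list[SignalRecord] = []
    accs = truth.accessions
    n_per_unit = SOURCE_PLATE_SIZE * SOURCE_PLATES_PER_ANALYSIS_PLATE
    for marker in truth.markers:
        dosage_col = truth.dosages[marker]
        for start in range(0, len(accs), n_per_unit):
            unit_accs = accs[start : start + n_per_unit]
            plate_no = start // n_per_unit + 1
            analysis_id = f"AP{plate_no:02d}"
            well_idx = 0
            for s_start in range(0, len(unit_accs), SOURCE_PLATE_SIZE):
                group = unit_accs[s_start : s_start + SOURCE_PLATE_SIZE]
                source_no = (start + s_start) // SOURCE_PLATE_SIZE + 1
                source_id = f"SP{source_no:03d}"
                for acc in group:
                    if rng.random() < truth.dropout_rate:
                        sig_a = sig_b = 0.0
                    else:
                        ratio = float(
                            np.clip(
                                rng.normal(
                                    locations[int(dosage_col[acc])],
                                    truth.cluster_scale,
                                ),
                                0.0,
                                1.0,
                            )
                        )
                        sig_b = total_signal * ratio
                        sig_a = total_signal - sig_b
                    records.append(
                        SignalRecord(
                            sample_id=acc,
                            marker_id=marker,
                            source_plate_id=source_id,
                            analysis_plate_id=analysis_id,
                            well=_well_name(well_idx),
                            signal_a=sig_a,
                            signal_b=sig_b,
                        )
                    )
                    well_idx += 1
                # one empty control well per source plate
                records.append(
                    SignalRecord(
                        sample_id=f"NC-{source_id}",
                        marker_id=marker,
                        source_plate_id=source_id,
                        analysis_plate_id=analysis_id,
                        well=_well_name(well_idx),
                        signal_a=float(rng.uniform(0, 5)),
                        signal_b=float(rng.uniform(0, 5)),
                        is_negative_control=True,
                    )
                )
                well_idx += 1
    return records


def simulate_amplicon_reads(
    haplotype_dosages: Mapping[str, Mapping[str, int]],
    sequences: Mapping[str, str],
    depth: int = 1000,
    seed: int = 0,
    marker_id: str = "amplicon",
    ploidy: int = 4,
) -> HaplotypeTable:
    """Multinomial read counts proportional to haplotype dosage.

    ``haplotype_dosages`` maps genotype id -> {haplotype id: dosage}; each
    genotype's dosages must sum to the ploidy. Reads are drawn multinomially
    with probabilities dosage/ploidy at the given depth.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    rng = _substream(seed, "amplicon")
    hap_ids = sorted(sequences)
    rows = {}
    for gid in sorted(haplotype_dosages):
        dosages = haplotype_dosages[gid]
        if sum(dosages.values()) != ploidy:
            raise ValidationError(
                f"genotype {gid!r}: dosages must sum to ploidy {ploidy}"
            )
        probs = np.array([dosages.get(h, 0) / ploidy for h in hap_ids])
        rows[gid] = rng.multinomial(depth, probs)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=hap_ids)
    return HaplotypeTable(
        marker_id=marker_id,
        sequences=dict(sequences),
        counts=counts.astype(int),
    )
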