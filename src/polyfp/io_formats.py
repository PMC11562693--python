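"""Readers and writers for the tabular formats the fingerprinting pipeline
touches.

Formats
-------
* Fluorescence export CSV — one row per well of an endpoint allele-specific
  PCR run: ``well,sample_id,marker_id,signal_a,signal_b``.
* Plate map TSV — assigns samples to their 96-well source plates and flags
  negative-control wells: ``well,sample_id,source_plate_id,is_control``.
* Score matrix CSV — accessions x markers allele-dosage table, cells in
  {0,1,2,3,4,NA}; a leading ``# layout=<tag>`` comment records which
  analysis-unit scheme produced the calls.
* Haplotype data — gap-aligned amplicon sequences (FASTA, gaps as ``-``) plus
  a read-count TSV ``genotype_id,haplotype_id,reads``.

All readers reject out-of-domain values instead of coercing them.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, IntegrityError, ValidationError

__all__ = [
    "SignalRecord",
    "PanelDefinition",
    "ScoreMatrix",
    "HaplotypeTable",
    "parse_fluorescence_export",
    "read_plate_map",
    "read_score_matrix",
    "write_score_matrix",
    "read_haplotype_data",
    "write_haplotype_data",
    "write_signal_records",
]

_WELL_RE = re.compile(r"^[A-P]([0-9]{2})$")

MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class SignalRecord:
    """One well's two-channel endpoint fluorescence for one sample x marker."""

    sample_id: str
    marker_id: str
    source_plate_id: str
    analysis_plate_id: str
    well: str
    signal_a: float
    signal_b: float
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if self.signal_a < 0 or self.signal_b < 0:
            raise IntegrityError(
                f"negative fluorescence signal for sample {self.sample_id!r}, "
                f"marker {self.marker_id!r}: ({self.signal_a}, {self.signal_b})"
            )


@dataclass(frozen=True)
class PanelDefinition:
    """One marker of the fingerprinting panel with its chromosome assignment."""

    marker_id: str
    chromosome: int
    allele_a: str = "A"
    allele_b: str = "T"

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= 7:
            raise ValidationError(
                f"marker {self.marker_id!r}: chromosome must be in 1..7, "
                f"got {self.chromosome}"
            )


class ScoreMatrix:
    """Accessions x markers table of allele dosages 0-4 (NaN = missing).

    Parameters
    ----------
    scores : DataFrame
        Float-valued frame indexed by accession id with one column per
        marker; cells are integers 0..4 or NaN.
    layout : str
        Tag for the analysis-unit scheme that produced the calls
        (e.g. ``"original"``, ``"single"``, ``"combined"``).
    posteriors : DataFrame, optional
        Same shape as *scores*; the posterior probability of each assigned
        (or best) dosage class. Used to resolve conflicts when combining
        layouts.
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        layout: str = "",
        posteriors: pd.DataFrame | None = None,
    ) -> None:
        scores = scores.astype(float)
        vals = scores.to_numpy()
        bad = ~(np.isnan(vals) | (np.isin(vals, [0.0, 1.0, 2.0, 3.0, 4.0])))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage out of range at accession {scores.index[i]!r}, "
                f"marker {scores.columns[j]!r}: {vals[i, j]!r}"
            )
        if posteriors is not None:
            posteriors = posteriors.reindex(
                index=scores.index, columns=scores.columns
            )
        self.scores = scores
        self.layout = layout
        self.posteriors = posteriors

    @property
    def accessions(self) -> pd.Index:
        return self.scores.index

    @property
    def markers(self) -> pd.Index:
        return self.scores.columns

    def call_rate(self) -> float:
        """Fraction of non-missing cells over the whole matrix."""
        return float(1.0 - self.scores.isna().to_numpy().mean())

    def marker_call_rates(self) -> pd.Series:
        return 1.0 - self.scores.isna().mean(axis=0)

    def equals(self, other: "ScoreMatrix") -> bool:
        return (
            self.layout == other.layout
            and self.scores.shape == other.scores.shape
            and list(self.scores.index) == list(other.scores.index)
            and list(self.scores.columns) == list(other.scores.columns)
            and self.scores.fillna(-1).equals(other.scores.fillna(-1))
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ScoreMatrix({self.scores.shape[0]} accessions x "
            f"{self.scores.shape[1]} markers, layout={self.layout!r})"
        )


@dataclass
class HaplotypeTable:
    """Per-genotype read counts over gap-aligned amplicon haplotypes.

    ``counts`` is a genotype x haplotype integer frame; ``sequences`` maps
    haplotype id to its aligned sequence (equal lengths, gaps as ``-``).
    """

    marker_id: str
    sequences: dict[str, str]
    counts: pd.DataFrame
    amplicon_length: int = 0
    flagged_genotypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"marker {self.marker_id!r}: aligned haplotype sequences have "
                f"unequal lengths {sorted(lengths)}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("read counts must be non-negative")
        unknown = set(self.counts.columns) - set(self.sequences)
        if unknown:
            raise IntegrityError(
                f"count table references unknown haplotype ids: "
                f"{sorted(unknown)}"
            )
        if self.amplicon_length == 0 and self.sequences:
            ref = next(iter(self.sequences.values()))
            self.amplicon_length = len(ref.replace("-", ""))

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.counts.index)


# ---------------------------------------------------------------------------
# fluorescence exports


def read_plate_map(path: str | Path) -> pd.DataFrame:
    """Read a plate-map TSV (``well,sample_id,source_plate_id,is_control``)."""
    pm = pd.read_csv(path, sep="\t", dtype=str)
    required = {"well", "sample_id", "source_plate_id", "is_control"}
    missing = required - set(pm.columns)
    if missing:
        raise FormatError(
            f"plate map {path} is missing required column(s): {sorted(missing)}"
        )
    pm["is_control"] = pm["is_control"].str.lower().isin(("1", "true", "yes"))
    return pm


def parse_fluorescence_export(
    path: str | Path,
    plate_map: str | Path | pd.DataFrame,
    analysis_plate_id: str | None = None,
) -> list[SignalRecord]:
    """Parse an endpoint-fluorescence export CSV into :class:`SignalRecord`s.

    The export covers one analysis plate (one fluorescence run); the plate
    map supplies each sample's source-plate provenance and flags
    negative-control wells.
    """
    path = Path(path)
    if analysis_plate_id is None:
        analysis_plate_id = path.stem
    df = pd.read_csv(path)
    required = ["well", "sample_id", "marker_id", "signal_a", "signal_b"]
    for col in required:
        if col not in df.columns:
            raise FormatError(
                f"fluorescence export {path} is missing required column "
                f"{col!r}"
            )
    if not isinstance(plate_map, pd.DataFrame):
        plate_map = read_plate_map(plate_map)
    by_sample = plate_map.drop_duplicates("sample_id").set_index("sample_id")

    records: list[SignalRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header=1
        sample = str(row.sample_id)
        try:
            sig_a = float(row.signal_a)
            sig_b = float(row.signal_b)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}, line {idx}: non-numeric signal value"
            ) from exc
        if sig_a < 0 or sig_b < 0:
            raise IntegrityError(
                f"{path}, line {idx}: negative signal value for sample "
                f"{sample!r}"
            )
        key = (sample, str(row.marker_id), analysis_plate_id)
        if key in seen:
            raise IntegrityError(
                f"{path}, line {idx}: duplicate (sample, marker, plate) "
                f"entry {key}"
            )
        seen.add(key)
        if sample in by_sample.index:
            source_plate = str(by_sample.loc[sample, "source_plate_id"])
            is_control = bool(by_sample.loc[sample, "is_control"])
        else:
            source_plate = ""
            is_control = False
        records.append(
            SignalRecord(
                sample_id=sample,
                marker_id=str(row.marker_id),
                source_plate_id=source_plate,
                analysis_plate_id=analysis_plate_id,
                well=str(row.well),
                signal_a=sig_a,
                signal_b=sig_b,
                is_negative_control=is_control,
            )
        )
    return records


def write_signal_records(
    records: Iterable[SignalRecord],
    export_path: str | Path,
    plate_map_path: str | Path,
) -> None:
    """Write records as a fluorescence-export CSV plus a plate-map TSV."""
    rows = list(records)
    export = pd.DataFrame(
        {
            "well": [r.well for r in rows],
            "sample_id": [r.sample_id for r in rows],
            "marker_id": [r.marker_id for r in rows],
            "signal_a": [r.signal_a for r in rows],
            "signal_b": [r.signal_b for r in rows],
        }
    )
    export.to_csv(export_path, index=False)
    pm = (
        pd.DataFrame(
            {
                "well": [r.well for r in rows],
                "sample_id": [r.sample_id for r in rows],
                "source_plate_id": [r.source_plate_id for r in rows],
                "is_control": [
                    "true" if r.is_negative_control else "false" for r in rows
                ],
            }
        )
        .drop_duplicates("sample_id")
    )
    pm.to_csv(plate_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# score matrices


def write_score_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    """Write a dosage score matrix as CSV with a ``# layout=`` header line."""
    out = matrix.scores.copy()
    # render integer dosages without a trailing ".0"
    rendered = out.map(
        lambda v: MISSING_TOKEN if pd.isna(v) else str(int(v))
    )
    rendered.index.name = "accession"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# layout={matrix.layout}\n")
        rendered.to_csv(fh)


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    """Read a dosage score matrix written by :func:`write_score_matrix`."""
    layout = ""
    body_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                m = re.match(r"#\s*layout=(.*)", line.strip())
                if m:
                    layout = m.group(1)
                continue
            body_lines.append(line)
    df = pd.read_csv(
        io.StringIO("".join(body_lines)),
        index_col="accession",
        dtype=str,
        keep_default_na=False,
    )
    df.index = df.index.astype(str)

    def _cell(v: str) -> float:
        v = v.strip()
        if v == MISSING_TOKEN or v == "":
            return np.nan
        if v not in {"0", "1", "2", "3", "4"}:
            raise FormatError(
                f"score matrix {path}: cell {v!r} is not a dosage 0-4 or "
                f"{MISSING_TOKEN!r}"
            )
        return float(v)

    parsed = df.map(_cell)
    return ScoreMatrix(parsed, layout=layout)


# ---------------------------------------------------------------------------
# amplicon haplotype data


def read_haplotype_data(
    fasta_path: str | Path,
    counts_path: str | Path,
    marker_id: str | None = None,
) -> HaplotypeTable:
    """Load gap-aligned haplotype sequences plus a genotype read-count TSV."""
    if marker_id is None:
        marker_id = Path(fasta_path).stem
    sequences = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not sequences:
        raise FormatError(f"{fasta_path}: no sequences found")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise FormatError(
            f"{fasta_path}: aligned sequences have unequal lengths "
            f"{sorted(lengths)}; input must be gap-aligned"
        )
    counts_long = pd.read_csv(counts_path, sep="\t", dtype=str)
    required = {"genotype_id", "haplotype_id", "reads"}
    missing = required - set(counts_long.columns)
    if missing:
        raise FormatError(
            f"{counts_path} is missing required column(s): {sorted(missing)}"
        )
    unknown = set(counts_long["haplotype_id"]) - set(sequences)
    if unknown:
        raise IntegrityError(
            f"{counts_path}: rows reference haplotype ids absent from the "
            f"FASTA: {sorted(unknown)}"
        )
    counts_long["reads"] = counts_long["reads"].astype(int)
    counts = (
        counts_long.pivot_table(
            index="genotype_id",
            columns="haplotype_id",
            values="reads",
            aggfunc="sum",
            fill_value=0,
        )
        .astype(int)
    )
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return HaplotypeTable(
        marker_id=marker_id, sequences=sequences, counts=counts
    )


def write_haplotype_data(
    table: HaplotypeTable,
    fasta_path: str | Path,
    counts_path: str | Path,
) -> None:
    """Write a haplotype table back to FASTA + counts TSV."""
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for hid, seq in table.sequences.items():
            fh.write(f">{hid}\n{seq}\n")
    long = (
        table.counts.stack()
        .rename("reads")
        .reset_index()
        .rename(columns={"level_0": "genotype_id", "level_1": "haplotype_id"})
    )
    long.columns = ["genotype_id", "haplotype_id", "reads"]
    long = long[long["reads"] > 0]
    long.to_csv(counts_path, sep="\t", index=False)
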