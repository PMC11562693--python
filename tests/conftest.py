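import numpy as np
import pandas as pd
import pytest

from polyfp import ScoreMatrix, SignalRecord


def make_records(ratios, marker="M1", unit="AP01", source="SP001", total=1000.0):
    """SignalRecords whose transformed ratio equals the given values."""
    recs = []
    for i, r in enumerate(np.asarray(ratios, dtype=float)):
        recs.append(
            SignalRecord(
                sample_id=f"s{i:04d}",
                marker_id=marker,
                source_plate_id=source,
                analysis_plate_id=unit,
                well=f"A{i % 24 + 1:02d}",
                signal_a=total * (1 - r),
                signal_b=total * r,
            )
        )
    return recs


def clustered_ratios(rng, counts, locations=(0.1, 0.3, 0.5, 0.7, 0.9), scale=0.02):
    """Draw per-class ratios; returns (ratios, true dosages)."""
    ratios, truth = [], []
    for dosage, n in enumerate(counts):
        ratios.append(np.clip(rng.normal(locations[dosage], scale, size=n), 0, 1))
        truth.extend([dosage] * n)
    return np.concatenate(ratios), np.array(truth)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def score_matrix_pair():
    """Two small score matrices sharing indices, with known differences."""
    accs = [f"a{i}" for i in range(6)]
    markers = ["M1", "M2", "M3"]
    single = pd.DataFrame(
        [
            [0, 1, 2],
            [4, 4, 0],
            [2, 2, 2],
            [1, np.nan, 3],
            [0, 0, np.nan],
            [3, 1, 1],
        ],
        index=accs,
        columns=markers,
        dtype=float,
    )
    original = single.copy()
    original.loc["a2", "M2"] = 3  # one disagreement, |diff| = 1
    original.loc["a3", "M2"] = 2  # called only in original
    original.loc["a5", "M1"] = np.nan  # called only in single
    return (
        ScoreMatrix(single, layout="single"),
        ScoreMatrix(original, layout="original"),
    )
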