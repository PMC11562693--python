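import itertools

import numpy as np
import pandas as pd
import pytest

from polyfp import (
    UsageError,
    ValidationError,
    concordance_with_reference,
    count_polymorphic_sites,
    filter_read_table,
    genotype_multisets,
    haplotype_dosages,
    pairwise_combination_table,
    summarize_amplicon,
)
from polyfp.io_formats import HaplotypeTable, ScoreMatrix


def make_table(counts: dict, seqs: dict | None = None, marker="MK"):
    frame = pd.DataFrame(counts).T.fillna(0).astype(int)
    if seqs is None:
        seqs = {h: "A" * 20 for h in frame.columns}
    return HaplotypeTable(marker_id=marker, sequences=seqs, counts=frame)


class TestReadFiltering:
    def test_low_coverage_genotype_removed(self):
        t = make_table({"g1": {"H1": 99}, "g2": {"H1": 100}})
        f = filter_read_table(t)
        assert f.genotype_ids == ["g2"]

    def test_fraction_boundary_strict(self):
        # 9.9% zeroed, exactly 10.0% retained
        t = make_table(
            {"g1": {"H1": 901, "H2": 99}, "g2": {"H1": 900, "H2": 100}}
        )
        f = filter_read_table(t)
        assert "H2" in f.counts.columns
        assert f.counts.loc["g1", "H2"] == 0
        assert f.counts.loc["g2", "H2"] == 100

    def test_all_zero_haplotypes_dropped(self):
        t = make_table({"g1": {"H1": 950, "H2": 50}, "g2": {"H1": 980, "H2": 20}})
        f = filter_read_table(t)
        assert f.haplotype_ids == ["H1"]
        assert set(f.sequences) == {"H1"}

    def test_idempotent(self, rng):
        counts = {
            f"g{i}": {
                f"H{j}": int(rng.integers(0, 400)) for j in range(5)
            }
            for i in range(20)
        }
        t = make_table(counts)
        once = filter_read_table(t)
        twice = filter_read_table(once)
        assert once.counts.equals(twice.counts)
        assert once.sequences == twice.sequences

    def test_lower_threshold_variant(self):
        # the 50-read sensitivity variant keeps genotypes the default drops
        t = make_table({"g1": {"H1": 60}, "g2": {"H1": 150}})
        assert filter_read_table(t).genotype_ids == ["g2"]
        assert filter_read_table(t, min_reads=50).genotype_ids == ["g1", "g2"]


class TestPolymorphicSites:
    def test_columns_with_gap_symbol(self):
        seqs = {"H1": "AAC-T", "H2": "AACAT", "H3": "GACAT"}
        # col0 A/A/G, col3 -/A/A polymorphic; others constant
        assert count_polymorphic_sites(seqs) == 2

    def test_identical_sequences(self):
        assert count_polymorphic_sites({"H1": "ACGT", "H2": "ACGT"}) == 0


class TestHaplotypeDosages:
    @pytest.mark.parametrize(
        "reads,expected",
        [
            ({"H1": 1000}, {"H1": 4}),
            ({"H1": 500, "H2": 500}, {"H1": 2, "H2": 2}),
            ({"H1": 750, "H2": 250}, {"H1": 3, "H2": 1}),
            ({"H1": 900, "H2": 100}, {"H1": 3, "H2": 1}),
            ({"H1": 400, "H2": 300, "H3": 200, "H4": 100},
             {"H1": 1, "H2": 1, "H3": 1, "H4": 1}),
        ],
    )
    def test_rounding(self, reads, expected):
        assert haplotype_dosages(reads) == expected

    def test_dosages_sum_to_ploidy(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 5))
            reads = {f"H{j}": int(rng.integers(1, 1000)) for j in range(k)}
            d = haplotype_dosages(reads)
            assert sum(d.values()) == 4
            assert all(v >= 1 for v in d.values())

    def test_excess_haplotypes_rejected(self):
        reads = {f"H{j}": 100 for j in range(5)}
        with pytest.raises(ValidationError):
            haplotype_dosages(reads)

    def test_flagged_genotypes_excluded_from_multisets(self):
        t = make_table(
            {
                "ok": {"H1": 500, "H2": 500},
                "excess": {f"H{j}": 200 for j in range(1, 6)},
            }
        )
        multisets, flagged = genotype_multisets(t)
        assert flagged == ["excess"]
        assert set(multisets) == {"ok"}


class TestSummarize:
    def test_constructed_alignment(self):
        seqs = {
            "H1": "AAAAT",
            "H2": "AACAT",
            "H3": "AAC-T",
            "H4": "GAAAT",
        }
        counts = {}
        patterns = [
            {"H1": 1000},
            {"H2": 1000},
            {"H1": 500, "H2": 500},
            {"H3": 750, "H4": 250},
            {"H1": 250, "H4": 750},
            {"H1": 500, "H3": 500},
        ]
        for i, p in enumerate(patterns):
            counts[f"g{2 * i}"] = p
            counts[f"g{2 * i + 1}"] = p  # duplicate genotype, same multiset
        t = make_table(counts, seqs)
        s = summarize_amplicon(filter_read_table(t))
        assert s.n_polymorphic_sites == 3  # cols 0, 2, 3
        assert s.n_haplotypes == 4
        assert s.n_genotypes_retained == 12
        assert s.n_distinguishable_genotypes == 6

    def test_monomorphic_marker(self):
        t = make_table({"g1": {"H1": 500}, "g2": {"H1": 800}})
        s = summarize_amplicon(t)
        assert s.n_polymorphic_sites == 0
        assert s.n_haplotypes == 1
        assert s.n_distinguishable_genotypes == 1

    def test_empty_table_rejected(self):
        t = make_table({"g1": {"H1": 10}})
        with pytest.raises(ValidationError):
            summarize_amplicon(filter_read_table(t))


class TestCombinationTable:
    def _tables(self):
        # marker A splits genotypes {1,2} vs {3,4}; marker B {1,3} vs {2,4}
        a = make_table(
            {
                "g1": {"A1": 1000},
                "g2": {"A1": 1000},
                "g3": {"A2": 1000},
                "g4": {"A2": 1000},
            },
            marker="A",
        )
        b = make_table(
            {
                "g1": {"B1": 1000},
                "g2": {"B2": 1000},
                "g3": {"B1": 1000},
                "g4": {"B2": 1000},
            },
            marker="B",
        )
        return a, b

    def test_pair_resolves_all_four(self):
        a, b = self._tables()
        table = pairwise_combination_table([a, b])
        assert table.loc["A", "A"] == 2
        assert table.loc["B", "B"] == 2
        assert table.loc["A", "B"] == 4
        assert table.loc["B", "A"] == 4

    def test_self_pairing_idempotent(self):
        a, _ = self._tables()
        a2 = make_table(
            {g: dict(row[row > 0]) for g, row in a.counts.iterrows()},
            seqs=dict(a.sequences),
            marker="A2",
        )
        table = pairwise_combination_table([a, a2])
        assert table.loc["A", "A2"] == table.loc["A", "A"]

    def test_matches_brute_force_oracle(self, rng):
        tables = []
        genotypes = [f"g{i}" for i in range(20)]
        for m in range(3):
            counts = {}
            for g in genotypes:
                k = int(rng.integers(1, 4))
                counts[g] = {
                    f"M{m}H{j}": int(rng.integers(100, 500)) for j in range(k)
                }
            tables.append(make_table(counts, marker=f"M{m}"))
        table = pairwise_combination_table(tables)
        for i, j in itertools.combinations(range(3), 2):
            mi, _ = genotype_multisets(tables[i])
            mj, _ = genotype_multisets(tables[j])
            joint = {(mi[g], mj[g]) for g in set(mi) & set(mj)}
            assert table.iloc[i, j] == len(joint)

    def test_bounds(self, rng):
        tables = []
        genotypes = [f"g{i}" for i in range(15)]
        for m in range(3):
            counts = {
                g: {f"M{m}H{int(rng.integers(0, 3))}": 1000} for g in genotypes
            }
            tables.append(make_table(counts, marker=f"M{m}"))
        table = pairwise_combination_table(tables)
        for i, j in itertools.combinations(range(3), 2):
            pair = table.iloc[i, j]
            di, dj = table.iloc[i, i], table.iloc[j, j]
            assert pair >= max(di, dj)
            assert pair <= min(len(genotypes), di * dj)

    def test_single_marker_rejected(self):
        a, _ = self._tables()
        with pytest.raises(UsageError):
            pairwise_combination_table([a])


class TestConcordance:
    def _matrices(self):
        idx = [f"g{i}" for i in range(6)]
        amp = pd.DataFrame(
            {"M1": [0, 1, 2, 3, np.nan, 4], "M2": [1.0] * 6}, index=idx
        )
        ref = pd.DataFrame(
            {"M1": [0, 1, 2, 2, 1, np.nan], "M2": [1.0] * 6}, index=idx
        )
        return ScoreMatrix(amp, "amplicon"), ScoreMatrix(ref, "reference")

    def test_identical_matrices(self):
        amp, _ = self._matrices()
        report, agreement = concordance_with_reference(amp, amp)
        assert agreement == 1.0
        assert report["n_differing"].sum() == 0

    def test_column_semantics(self):
        amp, ref = self._matrices()
        report, agreement = concordance_with_reference(amp, ref)
        m1 = report.loc["M1"]
        assert m1["n_identical"] == 3
        assert m1["n_differing"] == 1
        assert m1["n_unscored_total"] == 2
        assert m1["n_unscored_reference"] == 1
        assert m1["n_unscored_amplicon"] == 1
        # overall agreement over cells scored in both: (3 + 6) / (4 + 6)
        assert agreement == pytest.approx(9 / 10)

    def test_no_shared_index_rejected(self):
        amp, _ = self._matrices()
        other = ScoreMatrix(
            pd.DataFrame({"MX": [1.0]}, index=["z"]), "reference"
        )
        with pytest.raises(UsageError):
            concordance_with_reference(amp, other)
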