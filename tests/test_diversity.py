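"""Diversity statistics: dedupe, CDR3 uniqueness, repertoire summary."""

import itertools

import numpy as np
import pytest

import vnarkit as vk
from vnarkit.diversity import histogram_table

from .conftest import run_pipeline
from .test_regions import scaffold_protein


def _rec(cid, aa):
    return vk.CloneRecord(cid, "CCATGG", aa, 0, set(), True)


class TestRounding:
    @pytest.mark.parametrize(
        "x,ndigits,expected",
        [(41.4625, 1, 41.5), (15.2073, 1, 15.2), (72.7272, 0, 73.0),
         (37.5, 0, 38.0), (0.45, 1, 0.5), (23.955, 1, 24.0)],
    )
    def test_half_up(self, x, ndigits, expected):
        assert vk.round_half_up(x, ndigits) == expected

    def test_percentage_integer_mode(self):
        assert vk.percentage(12, 16, 0) == 75
        assert isinstance(vk.percentage(12, 16, 0), int)
        with pytest.raises(ValueError):
            vk.percentage(1, 0)


class TestDedupe:
    def test_basic_multiplicity(self):
        records = [_rec("a", "MAAS"), _rec("b", "MAAS"), _rec("c", "MTTS")]
        unique, mult = vk.dedupe_sequences(records)
        assert [r.clone_id for r in unique] == ["a", "c"]
        assert mult == {"MAAS": 2, "MTTS": 1}

    def test_all_distinct_identity(self):
        records = [_rec(f"c{i}", f"MA{i}S") for i in range(5)]
        unique, mult = vk.dedupe_sequences(records)
        assert unique == records
        assert all(v == 1 for v in mult.values())

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        pool = ["".join(rng.choice(list("ACDEFG"), 4)) for _ in range(60)]
        records = [_rec(f"c{i}", str(rng.choice(pool))) for i in range(1000)]
        unique, mult = vk.dedupe_sequences(records)
        # O(n^2) oracle: first-occurrence representative set
        oracle = []
        for i, rec in enumerate(records):
            if not any(prev.aa == rec.aa for prev in records[:i]):
                oracle.append(rec.clone_id)
        assert [r.clone_id for r in unique] == oracle
        assert sum(mult.values()) == len(records)

    def test_idempotence(self):
        records = [_rec("a", "MAAS"), _rec("b", "MAAS"), _rec("c", "MTTS")]
        once, _ = vk.dedupe_sequences(records)
        twice, _ = vk.dedupe_sequences(once)
        assert twice == once

    def test_missing_aa_raises(self):
        bad = vk.CloneRecord("x", "ACGT", None, 0, {"untranslatable"}, False)
        with pytest.raises(ValueError):
            vk.dedupe_sequences([bad])


class TestUniqueCdr3:
    def _maps(self, cdr3s):
        bodies = {"X": "NRALTDFDFA", "Y": "NRELTDFDFA", "Z": "NRSLTDFDFA"}
        return [
            vk.annotate_regions((f"c{i}", scaffold_protein(bodies[k])))
            for i, k in enumerate(cdr3s)
        ]

    def test_constructed_partition(self):
        maps = self._maps(["X", "X", "Y", "Z"])
        assert vk.unique_cdr3_partition(maps) == (2, 2)

    def test_all_distinct(self):
        maps = self._maps(["X", "Y", "Z"])
        assert vk.unique_cdr3_partition(maps) == (3, 0)

    def test_matches_hash_group_oracle(self, small_pipeline):
        maps = small_pipeline[2]
        n_unique, n_rest = vk.unique_cdr3_partition(maps)
        groups = {}
        for m in maps:
            groups.setdefault(m.cdr3_seq, []).append(m.clone_id)
        oracle = sum(1 for g in groups.values() if len(g) == 1)
        assert (n_unique, n_rest) == (oracle, len(maps) - oracle)
        assert n_unique + n_rest == len(maps)


class TestSummary:
    def test_published_count_arithmetic(self):
        pct = vk.type_percentages(vk.FIG3A_COUNTS)
        assert sum(vk.FIG3A_COUNTS.values()) == 238_415
        assert pct["I"] == 15.2
        assert pct["IIb"] == 41.5
        assert vk.percentage(vk.N_UNIQUE_CDR3, 238_415, 0) == 38
        assert vk.percentage(vk.FIG3C_CDR3_CYS_COUNTS[1], vk.N_UNIQUE_CDR3, 0) == 51
        assert vk.percentage(vk.FIG3C_CDR3_CYS_COUNTS[0], vk.N_UNIQUE_CDR3, 0) == 32

    def test_single_clone_degenerate(self):
        aa = scaffold_protein("NRALTDFDFA")
        maps = [vk.annotate_regions(("only", aa))]
        calls, _ = vk.classify_repertoire(maps, {"only": aa})
        summ = vk.summarize_repertoire(calls, maps)
        assert summ.n_total_unique == 1
        assert summ.per_type_pct["IV"] == 100.0
        assert summ.pct_unique_cdr3 == 100
        assert summ.cdr1_variability_pct == 0.0

    def test_conservation_invariants(self, small_pipeline):
        _, unique, maps, calls, _ = small_pipeline
        summ = vk.summarize_repertoire(calls, maps)
        assert sum(summ.per_type_counts.values()) == summ.n_total_unique
        assert sum(summ.cdr3_length_hist.values()) == summ.n_total_unique
        assert sum(summ.cdr3_cys_hist.values()) == summ.n_unique_cdr3
        n_u, n_rest = vk.unique_cdr3_partition(maps)
        assert n_u + n_rest == summ.n_total_unique

    def test_percentages_reproducible_from_counts(self, small_pipeline):
        _, _, maps, calls, _ = small_pipeline
        summ = vk.summarize_repertoire(calls, maps)
        assert summ.per_type_pct == vk.type_percentages(summ.per_type_counts)
        for k, count in summ.cdr3_cys_hist.items():
            assert summ.cdr3_cys_pct[k] == vk.percentage(count, summ.n_unique_cdr3, 0)

    def test_type_recovery_at_scale(self):
        # count apportionment makes the generated composition exact at n=10,000
        lib = vk.generate_library(vk.fig3a_spec(n_clones=10_000, seed=23))
        _, unique, maps, calls, _ = run_pipeline(lib)
        summ = vk.summarize_repertoire(calls, maps)
        props = vk.fig3a_proportions()
        for label, p in props.items():
            se = (p * (1 - p) / 10_000) ** 0.5
            assert abs(summ.per_type_counts[label] / 10_000 - p) <= max(3 * se, 1e-4)

    def test_mismatched_ids_raise(self, small_pipeline):
        _, _, maps, calls, _ = small_pipeline
        with pytest.raises(ValueError):
            vk.summarize_repertoire(calls[:-1], maps)


class TestCdr3LengthStats:
    def test_synthetic_bounds(self, small_pipeline):
        maps = small_pipeline[2]
        lo, hi, band = vk.cdr3_length_stats(maps)
        assert lo >= 6 and hi <= 28
        assert 0 <= band <= 1

    def test_all_same_length(self):
        maps = [
            vk.annotate_regions((f"c{i}", scaffold_protein("NRALTDFDF" + ch)))
            for i, ch in enumerate("AEST")
        ]
        assert vk.cdr3_length_stats(maps) == (10, 10, 0.0)

    def test_constructed_band_fraction(self):
        body15 = "NRALTDFDFANRALT"
        body10 = "NRALTDFDFA"
        maps = [
            vk.annotate_regions((f"a{i}", scaffold_protein(body15))) for i in range(5)
        ] + [
            vk.annotate_regions((f"b{i}", scaffold_protein(body10))) for i in range(5)
        ]
        assert vk.cdr3_length_stats(maps)[2] == pytest.approx(0.5)

    def test_default_model_band_mass(self):
        model = vk.simulate.default_cdr3_length_model()
        assert set(model) == set(range(6, 29))
        assert sum(model.values()) == pytest.approx(1.0)
        assert model[15] + model[16] == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            vk.cdr3_length_stats([])


def test_histogram_table():
    df = histogram_table({10: 3, 6: 1}, "cdr3_length")
    assert df["cdr3_length"].tolist() == [6, 10]
    assert df["count"].tolist() == [1, 3]
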