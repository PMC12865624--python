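"""Synthetic repertoire generator: determinism, apportionment, feasibility."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vnarkit as vk
from vnarkit.simulate import (
    DEFAULT_CDR3_CYS_MODELS,
    LibrarySpec,
    ground_truth_table,
    largest_remainder,
    write_library,
)

from .conftest import run_pipeline


def uniform_spec(n, seed=0, **overrides):
    props = {label: 0.2 for label in vk.TYPE_LABELS}
    return vk.fig3a_spec(n, seed=seed, type_proportions=props, **overrides)


class TestApportionment:
    def test_uniform_exact(self):
        lib = vk.generate_library(uniform_spec(100))
        counts = {label: 0 for label in vk.TYPE_LABELS}
        for c in lib:
            counts[c.true_label] += 1
        assert counts == {label: 20 for label in vk.TYPE_LABELS}

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n=st.integers(1, 5000))
    def test_largest_remainder_properties(self, n):
        props = vk.fig3a_proportions()
        counts = largest_remainder(props, n)
        assert sum(counts.values()) == n
        for label, p in props.items():
            # each count is the floor or ceiling of its exact quota
            assert abs(counts[label] - p * n) < 1

    def test_generated_counts_equal_apportionment(self):
        spec = vk.fig3a_spec(777, seed=2)
        expected = largest_remainder(spec.type_proportions, 777)
        lib = vk.generate_library(spec)
        counts = {label: 0 for label in vk.TYPE_LABELS}
        for c in lib:
            counts[c.true_label] += 1
        assert counts == expected


class TestDeterminism:
    def test_same_seed_identical(self):
        a = vk.generate_library(vk.fig3a_spec(150, seed=9))
        b = vk.generate_library(vk.fig3a_spec(150, seed=9))
        assert [(c.clone_id, c.nt, c.true_label) for c in a] == [
            (c.clone_id, c.nt, c.true_label) for c in b
        ]

    def test_different_seeds_differ(self):
        a = vk.generate_library(vk.fig3a_spec(150, seed=9))
        b = vk.generate_library(vk.fig3a_spec(150, seed=10))
        assert [c.nt for c in a] != [c.nt for c in b]

    def test_panning_deterministic(self):
        r1, t1 = vk.generate_panning_dataset([0.1, 0.4], 30, seed=3)
        r2, t2 = vk.generate_panning_dataset([0.1, 0.4], 30, seed=3)
        assert t1 == t2
        assert [(r.clone_id, r.od_antigen) for r in r1] == [
            (r.clone_id, r.od_antigen) for r in r2
        ]


class TestFeasibility:
    def test_defect_free_clones_translate_and_classify(self, small_library, small_pipeline):
        records = small_pipeline[0]
        assert all(r.qc_flags == set() for r in records)
        calls = small_pipeline[3]
        truth = {c.clone_id: c.true_label for c in small_library}
        assert all(c.label == truth[c.clone_id] for c in calls)

    def test_defect_counts_exact_by_apportionment(self):
        spec = vk.fig3a_spec(
            200, seed=4, defect_rates={"premature_stop": 0.03, "missing_flank": 0.02}
        )
        lib = vk.generate_library(spec)
        defects = [c.defect for c in lib if c.defect]
        assert defects.count("premature_stop") == 6
        assert defects.count("missing_flank") == 4

    def test_duplicate_rate_by_count(self):
        spec = uniform_spec(100, seed=6, duplicate_rate=0.1)
        lib = vk.generate_library(spec)
        records = [vk.translate_and_qc(c) for c in vk.library_to_clones(lib)]
        unique, mult = vk.dedupe_sequences(records)
        assert len(unique) <= 90  # 10 clones were made copies of earlier ones
        assert sum(mult.values()) == 100

    def test_lengths_within_bounds(self):
        lib = vk.generate_library(vk.fig3a_spec(2000, seed=8))
        lengths = [c.true_cdr3_span[1] - c.true_cdr3_span[0] + 1 for c in lib]
        assert min(lengths) >= 6 and max(lengths) <= 28

    def test_cys_models_respect_rules(self):
        for label, model in DEFAULT_CDR3_CYS_MODELS.items():
            if label == "I":
                assert all(k >= 2 and k % 2 == 0 for k in model)
            if label == "IV":
                assert set(model) == {0}
            assert all(0 <= k <= 5 for k in model)

    @pytest.mark.parametrize(
        "overrides",
        [
            dict(type_proportions={"I": 0.5, "IV": 0.4}),  # does not sum to 1
            dict(cdr3_cys_models={**DEFAULT_CDR3_CYS_MODELS, "I": {3: 1.0}}),
            dict(cdr3_cys_models={**DEFAULT_CDR3_CYS_MODELS, "IV": {1: 1.0}}),
            dict(defect_rates={"premature_stop": 1.5}),
            dict(defect_rates={"bogus": 0.1}),
            dict(leu31_prob=1.5),
            dict(n_clones=0),
        ],
    )
    def test_infeasible_specs_rejected(self, overrides):
        kwargs = dict(n_clones=10, seed=0)
        kwargs.update(overrides)
        with pytest.raises(ValueError):
            vk.generate_library(vk.fig3a_spec(**kwargs))

    def test_ground_truth_region_round_trip(self):
        lib = vk.generate_library(uniform_spec(100, seed=12))
        _, unique, maps, _, _ = run_pipeline(lib)
        truth = {c.clone_id: c.true_regions for c in lib}
        assert len(maps) == 100
        assert all(m.spans == truth[m.clone_id] for m in maps)


class TestPanningDataset:
    def test_exact_positive_counts(self):
        records, truth = vk.generate_panning_dataset([0.1, 0.2, 0.4], 30, seed=1)
        for rnd, frac in [(2, 0.1), (3, 0.2), (4, 0.4)]:
            assert sum(1 for (r, _), v in truth.items() if r == rnd and v) == int(frac * 30)

    def test_zero_fraction_all_negative(self):
        records, truth = vk.generate_panning_dataset([0.0, 0.0], 20, seed=1)
        assert not any(truth.values())
        for rnd in (2, 3):
            recs = [r for r in records if r.round_index == rnd]
            assert vk.summarize_round(recs).n_positive == 0

    def test_positives_clear_fourfold(self):
        records, truth = vk.generate_panning_dataset([0.5], 40, seed=2)
        for rec in records:
            call = vk.call_positive(rec)
            assert call.positive == truth[(rec.round_index, rec.clone_id)]

    def test_high_od_enrichment_by_round(self):
        # default OD model shifts positives toward OD > 1.0 in later rounds
        records, _ = vk.generate_panning_dataset([0.5, 0.5, 0.5], 200, seed=3)
        fracs = []
        for rnd in (2, 3, 4):
            recs = [r for r in records if r.round_index == rnd]
            fracs.append(vk.summarize_round(recs).high_od_fraction_of_positives)
        assert fracs[2] > fracs[0]
        assert 0.5 <= fracs[2] <= 0.9  # ~70% high-OD binders by the final round

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            vk.generate_panning_dataset([1.2], 10)


def test_library_files_round_trip(tmp_path):
    lib = vk.generate_library(uniform_spec(20, seed=1))
    fasta, truth = tmp_path / "lib.fasta", tmp_path / "truth.tsv"
    write_library(lib, fasta, truth)
    back = vk.read_sequences(fasta)
    assert [c.sequence for c in back] == [c.nt for c in lib]
    df = ground_truth_table(lib)
    assert df.shape[0] == 20
    assert set(df["true_label"]) <= set(vk.TYPE_LABELS)
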