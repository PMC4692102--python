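import numpy as np
import pytest
from scipy import stats as sps

from g4reps import (
    build_control_sets,
    build_query_regions,
    category_fractions,
    classify_conservation,
    classify_region,
    one_sample_t,
    parse_alignment_table,
    run_category_tests,
    write_alignment_table,
)
from g4reps.conservation import LocalAlignment, region_orientation
from g4reps.genome_io import ContractError, FormatError
from g4reps.synthetic_data import (
    SurveyParams,
    simulate_ortholog,
    simulate_survey,
)


@pytest.fixture(scope="module")
def survey():
    from g4reps import builtin_presets

    preset = builtin_presets()["xan"]
    genome, orfs, truth = simulate_survey(SurveyParams(seed=41), preset)
    return preset, genome, orfs, truth


@pytest.fixture(scope="module")
def control_setup():
    from g4reps import builtin_presets

    preset = builtin_presets()["xan"]
    params = SurveyParams(seed=43, n_repeats=20, genome_length=120_000)
    genome, orfs, truth = simulate_survey(params, preset)
    regions = build_query_regions(orfs, truth.planted_repeats)
    repeat_regions = [r for r in regions if r.contains_repeat]
    return orfs, repeat_regions, genome


class TestAlignmentTable:
    def test_parse_plus_and_minus_rows(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(
            "q1 s1 98.5 500 6 1 1 500 1000 1499 1e-100 900\n"
            "q1 s1 95.0 500 10 2 600 1099 2000 1501 1e-90 800\n"
        )
        alns = parse_alignment_table(p)
        assert (alns[0].qstart, alns[0].qend) == (1, 500)
        assert not alns[0].is_minus
        assert alns[1].is_minus

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q1 s1 98.5 500 6 1 1 500 1000 1499 1e-100\n")
        with pytest.raises(FormatError, match=":1"):
            parse_alignment_table(p)

    def test_roundtrip(self, tmp_path):
        a = LocalAlignment("q", "s", 100.0, 50, 0, 0, 11, 60, 101, 150, 0.0, 100.0)
        p = tmp_path / "rt.tsv"
        write_alignment_table([a], p)
        (b,) = parse_alignment_table(p)
        assert (b.qstart, b.qend, b.sstart, b.send) == (11, 60, 101, 150)

    def test_minus_interval_mapping(self):
        a = LocalAlignment("q", "s", 100.0, 100, 0, 0, 1, 100, 200, 101, 0.0, 200.0)
        # query [0,10) maps to the top of the descending subject interval
        lo, hi = a.map_query_interval(0, 10)
        assert (lo, hi) == (190, 200)


class TestClosedLoop:
    def test_zero_edit_ortholog_fully_conserved(self, survey):
        preset, genome, orfs, truth = survey
        subject, edits, alns = simulate_ortholog(
            genome, orfs, truth, seed=1, preset=preset
        )
        regions = build_query_regions(orfs, truth.planted_repeats)
        calls = classify_conservation(
            regions, {h.repeat_id: h for h in truth.planted_repeats},
            alns, subject, preset,
        )
        assert calls
        assert all(c.region_class == "no_change" for c in calls)
        assert all(c.repeat_status == "conserved" for c in calls)
        assert all(kind == "none" for _, kind, _ in edits)

    def test_planted_insertions_all_called(self, survey):
        preset, genome, orfs, truth = survey
        subject, edits, alns = simulate_ortholog(
            genome, orfs, truth, edit_rates={"insertion": 1.0},
            sizes={"insertion": (500, 500)}, seed=2, preset=preset,
        )
        regions = build_query_regions(orfs, truth.planted_repeats)
        calls = classify_conservation(
            regions, {h.repeat_id: h for h in truth.planted_repeats},
            alns, subject, preset,
        )
        assert calls and all(c.region_class == "insertion" for c in calls)
        assert all(c.repeat_status == "conserved" for c in calls)

    def test_flanking_and_locus_loss(self, survey):
        preset, genome, orfs, truth = survey
        for rates, expected_class, expected_status in [
            ({"flanking_loss": 1.0}, "flanking_change", "conserved"),
            ({"locus_loss": 1.0}, "no_homology", "no_alignment"),
        ]:
            subject, _, alns = simulate_ortholog(
                genome, orfs, truth, edit_rates=rates, seed=3, preset=preset
            )
            regions = build_query_regions(orfs, truth.planted_repeats)
            calls = classify_conservation(
                regions, {h.repeat_id: h for h in truth.planted_repeats},
                alns, subject, preset,
            )
            assert calls
            assert all(c.region_class == expected_class for c in calls)
            assert all(c.repeat_status == expected_status for c in calls)

    def test_large_deletions_called_with_wide_gaps(self):
        from g4reps import builtin_presets

        preset = builtin_presets()["xan"]
        params = SurveyParams(seed=42, n_repeats=12, genome_length=120_000,
                              flank_gap_range=(400, 500),
                              inverted_pair_fraction=0.0)
        genome, orfs, truth = simulate_survey(params, preset)
        subject, edits, alns = simulate_ortholog(
            genome, orfs, truth, edit_rates={"deletion": 1.0},
            sizes={"deletion": (350, 350)}, seed=4, preset=preset,
        )
        regions = build_query_regions(orfs, truth.planted_repeats)
        calls = classify_conservation(
            regions, {h.repeat_id: h for h in truth.planted_repeats},
            alns, subject, preset,
        )
        assert calls and all(c.region_class == "deletion" for c in calls)

    def test_category_fractions_sum_to_one(self, survey):
        preset, genome, orfs, truth = survey
        subject, _, alns = simulate_ortholog(
            genome, orfs, truth,
            edit_rates={"insertion": 0.3, "flanking_loss": 0.2},
            seed=5, preset=preset,
        )
        regions = build_query_regions(orfs, truth.planted_repeats)
        calls = classify_conservation(
            regions, {h.repeat_id: h for h in truth.planted_repeats},
            alns, subject, preset,
        )
        fr = category_fractions(calls)
        assert sum(fr.values()) == pytest.approx(1.0)


class TestRegionClassEdgeRules:
    def test_split_subject_coerced_to_flanking_change(self, survey):
        preset, genome, orfs, truth = survey
        regions = [r for r in build_query_regions(orfs, truth.planted_repeats)
                   if r.contains_repeat]
        r = regions[0]
        lo, ro = r.left_orf, r.right_orf
        alns = [
            LocalAlignment("q", "s1", 100.0, lo.end - lo.start, 0, 0,
                           lo.start + 1, lo.end, 1, lo.end - lo.start, 0.0, 100.0),
            LocalAlignment("q", "s2", 100.0, ro.end - ro.start, 0, 0,
                           ro.start + 1, ro.end, 1, ro.end - ro.start, 0.0, 100.0),
        ]
        assert classify_region(r, alns) == "flanking_change"

    def test_low_identity_alignments_do_not_qualify(self, survey):
        preset, genome, orfs, truth = survey
        regions = [r for r in build_query_regions(orfs, truth.planted_repeats)
                   if r.contains_repeat]
        r = regions[0]
        lo, ro = r.left_orf, r.right_orf
        weak = [
            LocalAlignment("q", "s", 60.0, lo.end - lo.start, 0, 0,
                           lo.start + 1, lo.end, 1, lo.end - lo.start, 0.0, 10.0),
            LocalAlignment("q", "s", 60.0, ro.end - ro.start, 0, 0,
                           ro.start + 1, ro.end, 1, ro.end - ro.start, 0.0, 10.0),
        ]
        assert classify_region(r, weak) == "no_homology"


class TestControlSets:
    def test_same_seed_is_deterministic(self, control_setup):
        orfs, repeat_regions, genome = control_setup
        kw = dict(pool_size=15, set_size=10, seed=7)
        a = build_control_sets(orfs, repeat_regions, genome, **kw)
        b = build_control_sets(orfs, repeat_regions, genome, **kw)
        assert [[r.region_id for r in s] for s in a["random"]] == [
            [r.region_id for r in s] for s in b["random"]
        ]

    def test_no_control_region_contains_a_repeat(self, control_setup):
        orfs, repeat_regions, genome = control_setup
        sets = build_control_sets(orfs, repeat_regions, genome,
                                  pool_size=15, set_size=10, seed=7)
        repeat_gaps = {(r.inter_start, r.inter_end) for r in repeat_regions}
        for set_list in sets.values():
            for s in set_list:
                assert all((r.inter_start, r.inter_end) not in repeat_gaps
                           for r in s)
                assert all(not r.contains_repeat for r in s)

    def test_orientation_matched_composition(self, control_setup):
        orfs, repeat_regions, genome = control_setup
        sets = build_control_sets(
            orfs, repeat_regions, genome, pool_size=16, set_size=10,
            designs=["orientation_matched"], seed=9,
        )
        (chosen,) = sets["orientation_matched"]
        from collections import Counter

        from g4reps.conservation import _largest_remainder

        rep = Counter(region_orientation(r) for r in repeat_regions)
        n = sum(rep.values())
        want = _largest_remainder(
            [rep.get(c, 0) / n for c in ("aligned", "convergent", "divergent")], 10
        )
        got = Counter(region_orientation(r) for r in chosen)
        assert [got.get(c, 0) for c in ("aligned", "convergent", "divergent")] == want

    def test_pool_deficit_reported(self, control_setup):
        orfs, repeat_regions, genome = control_setup
        with pytest.raises(ContractError, match="deficit"):
            build_control_sets(orfs, repeat_regions, genome,
                               pool_size=10_000, set_size=10)


class TestOneSampleT:
    def test_symmetric_case_gives_p_one(self):
        r = one_sample_t([0.1, 0.2, 0.3, 0.4, 0.5], 0.3)
        assert r.t_stat == pytest.approx(0.0)
        assert r.p_two_sided == pytest.approx(1.0)

    def test_worked_case(self):
        r = one_sample_t([0.1, 0.2, 0.3, 0.4, 0.5], 0.0)
        assert r.t_stat == pytest.approx(4.2426, abs=1e-4)
        assert r.df == 4
        assert r.p_two_sided == pytest.approx(0.01324, abs=5e-6)

    def test_degenerate_sample(self):
        with pytest.raises(ContractError, match="degenerate"):
            one_sample_t([0.5] * 5, 0.9)
        r = one_sample_t([0.5] * 5, 0.5)
        assert (r.t_stat, r.p_two_sided) == (0.0, 1.0)

    def test_matches_reference_implementation(self):
        """Cross-check against scipy's t-test on 1000 random samples."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            vals = rng.uniform(0, 1, size=n)
            ref = float(rng.uniform(0, 1))
            ours = one_sample_t(list(vals), ref)
            t_ref, p_ref = sps.ttest_1samp(vals, popmean=ref)
            assert ours.t_stat == pytest.approx(float(t_ref), abs=1e-9)
            assert ours.p_two_sided == pytest.approx(float(p_ref), abs=1e-9)

    def test_run_category_tests_shapes(self):
        rep = {"no_change": 0.9, "insertion": 0.05, "flanking_change": 0.05}
        controls = [
            {"no_change": 0.7 + 0.02 * i, "insertion": 0.2 - 0.01 * i,
             "flanking_change": 0.1 - 0.01 * i}
            for i in range(5)
        ]
        results = run_category_tests(rep, controls)
        assert len(results) == 5  # one per region class
        nc = next(r for r in results if r.category == "no_change")
        assert nc.df == 4
        assert len(nc.control_values) == 5
        assert nc.p_two_sided < 0.05
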