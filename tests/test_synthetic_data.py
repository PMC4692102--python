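import pytest

from g4reps import (
    annotate_contexts,
    build_query_regions,
    detect_inverted_pairs,
    scan_repeats,
)
from g4reps.genome_io import ContractError
from g4reps.synthetic_data import (
    SurveyParams,
    simulate_ortholog,
    simulate_survey,
    simulate_transcripts,
)
from g4reps.transcript_mapper import classify_all


def hit_key(h):
    return (h.start, h.end, h.strand, h.units, h.trailing_partial, h.g4_capable)


class TestDeterminism:
    def test_same_seed_same_survey(self, xan):
        params = SurveyParams(seed=101)
        g1, o1, t1 = simulate_survey(params, xan)
        g2, o2, t2 = simulate_survey(SurveyParams(seed=101), xan)
        assert g1.sequence == g2.sequence
        assert o1 == o2
        assert [hit_key(h) for h in t1.planted_repeats] == [
            hit_key(h) for h in t2.planted_repeats
        ]

    def test_different_seed_differs(self, xan):
        g1, _, _ = simulate_survey(SurveyParams(seed=101), xan)
        g2, _, _ = simulate_survey(SurveyParams(seed=102), xan)
        assert g1.sequence != g2.sequence

    def test_same_seed_same_ortholog_and_transcripts(self, xan, clean_survey):
        genome, orfs, truth = clean_survey
        s1, e1, a1 = simulate_ortholog(genome, orfs, truth,
                                       edit_rates={"insertion": 0.5},
                                       seed=5, preset=xan)
        s2, e2, a2 = simulate_ortholog(genome, orfs, truth,
                                       edit_rates={"insertion": 0.5},
                                       seed=5, preset=xan)
        assert s1.sequence == s2.sequence and e1 == e2 and a1 == a2
        t1 = simulate_transcripts(genome, orfs, truth, seed=5)
        t2 = simulate_transcripts(genome, orfs, truth, seed=5)
        assert t1 == t2


class TestScrubbing:
    def test_background_contains_no_stray_seeds(self, xan, clean_survey):
        genome, orfs, truth = clean_survey
        hits = scan_repeats(genome, xan)
        # every hit is planted — no background hit survives the scrub
        assert {hit_key(h) for h in hits} == {
            hit_key(h) for h in truth.planted_repeats
        }

    def test_zero_repeats_scan_empty(self, xan):
        params = SurveyParams(seed=103, n_repeats=0, genome_length=30_000,
                              inverted_pair_fraction=0.0)
        genome, orfs, truth = simulate_survey(params, xan)
        assert truth.planted_repeats == []
        assert scan_repeats(genome, xan) == []

    def test_too_small_genome_rejected(self, xan):
        with pytest.raises(ContractError, match="genome_length"):
            simulate_survey(SurveyParams(seed=1, genome_length=5_000), xan)


class TestSurveyTruth:
    def test_zero_noise_recovery_is_exact(self, xan, clean_survey):
        genome, orfs, truth = clean_survey
        got = {hit_key(h) for h in scan_repeats(genome, xan)}
        want = {hit_key(h) for h in truth.planted_repeats}
        assert got == want  # precision = recall = 1

    def test_noisy_recovery_is_exact_by_construction(self, xan, noisy_survey):
        genome, orfs, truth = noisy_survey
        got = {hit_key(h) for h in scan_repeats(genome, xan)}
        want = {hit_key(h) for h in truth.planted_repeats}
        assert got == want

    def test_ana_preset_survey_recovers(self, ana):
        params = SurveyParams(seed=104, n_repeats=20, genome_length=80_000,
                              gc_content=0.41)
        genome, orfs, truth = simulate_survey(params, ana)
        got = {hit_key(h) for h in scan_repeats(genome, ana)}
        assert got == {hit_key(h) for h in truth.planted_repeats}

    def test_planted_pairs_are_detected(self, xan, clean_survey):
        genome, orfs, truth = clean_survey
        pairs = detect_inverted_pairs(truth.planted_repeats, max_gap=100)
        planted = {(p.plus_repeat_id, p.minus_repeat_id)
                   for p in truth.planted_pairs}
        detected = {(p.plus_repeat_id, p.minus_repeat_id) for p in pairs}
        assert planted == detected

    def test_planted_location_classes_match_annotation(self, xan, clean_survey):
        genome, orfs, truth = clean_survey
        ctxs = annotate_contexts(truth.planted_repeats, orfs)
        for c in ctxs:
            loc, cat = truth.planted_classes[c.repeat_id]
            assert c.location_class == loc
            if loc == "intergenic":
                assert c.orientation_class == cat


class TestTranscriptGenerator:
    def test_closed_loop_all_classes(self, xan, clean_survey):
        genome, orfs, truth = clean_survey
        tx = simulate_transcripts(genome, orfs, truth, seed=7)
        ctxs = annotate_contexts(truth.planted_repeats, orfs)
        calls = classify_all(truth.planted_repeats, ctxs, tx)
        assert calls
        for c in calls:
            cls, content = truth.planted_transcript_classes[c.repeat_id]
            assert c.position_class == cls
            assert c.strand_content == content

    def test_single_class_mixes(self, xan, clean_survey):
        genome, orfs, truth0 = clean_survey
        for single in ("start", "stop", "middle", "no_transcript"):
            import copy

            truth = copy.deepcopy(truth0)
            tx = simulate_transcripts(genome, orfs, truth,
                                      class_mix={single: 1.0}, seed=8)
            ctxs = annotate_contexts(truth.planted_repeats, orfs)
            calls = classify_all(truth.planted_repeats, ctxs, tx)
            assert calls
            assert all(c.position_class == single for c in calls)
            if single == "no_transcript":
                assert tx == []


class TestOrthologGenerator:
    def test_zero_edit_alignment_covers_genome(self, xan, clean_survey):
        genome, orfs, truth = clean_survey
        subject, edits, alns = simulate_ortholog(genome, orfs, truth, seed=9,
                                                 preset=xan)
        assert subject.sequence == genome.sequence
        assert len(alns) == 1
        assert (alns[0].qstart, alns[0].qend) == (1, genome.length)

    def test_insertion_grows_subject(self, xan, clean_survey):
        genome, orfs, truth = clean_survey
        subject, edits, alns = simulate_ortholog(
            genome, orfs, truth, edit_rates={"insertion": 1.0},
            sizes={"insertion": (500, 500)}, seed=9, preset=xan,
        )
        n_gaps = len({(r, k, s) for r, k, s in edits if k == "insertion"})
        regions = build_query_regions(orfs, truth.planted_repeats)
        n_repeat_gaps = len(
            {(r.inter_start, r.inter_end)
             for r in regions if r.contains_repeat}
        )
        assert subject.length == genome.length + 500 * n_repeat_gaps
        assert all(k == "insertion" for _, k, _ in edits)

    def test_edit_rates_validated(self, xan, clean_survey):
        genome, orfs, truth = clean_survey
        with pytest.raises(ContractError):
            simulate_ortholog(genome, orfs, truth,
                              edit_rates={"insertion": 0.8, "deletion": 0.4})
        with pytest.raises(ContractError):
            simulate_ortholog(genome, orfs, truth, edit_rates={"bogus": 0.5})
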