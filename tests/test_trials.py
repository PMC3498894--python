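"""Training design, test sets, and synthesis manifests."""

from collections import Counter

import pytest

from framelang.frames import FrameTable
from framelang.language import CapacityError, build_lexicon, build_syllable_inventory
from framelang.trials import (
    TimingSpec,
    apportion_frame_counts,
    build_mapping_tests,
    build_segmentation_tests,
    export_pho,
    nominal_duration_ms,
    pair_objects,
    session_schedule,
)


class TestApportionment:
    def test_proportional_counts_on_inventory(self, frame_table):
        counts = apportion_frame_counts(frame_table, 216)
        assert sum(counts.values()) == 216
        assert counts["the OBJ"] == 26

    def test_degenerate_and_tied_cases(self):
        single = FrameTable.from_percentages({"the OBJ": 52.0})
        assert apportion_frame_counts(single, 10) == {"the OBJ": 10}
        two = FrameTable.from_percentages({"a OBJ": 50.0, "the OBJ": 50.0})
        counts = apportion_frame_counts(two, 3)
        assert sorted(counts.values()) == [1, 2]
        assert counts[list(counts)[0]] == 2  # tie goes to the first rank
        with pytest.raises(ValueError):
            apportion_frame_counts(FrameTable.from_percentages({}), 10)
        with pytest.raises(ValueError):
            apportion_frame_counts(single, 0)


class TestPairing:
    def test_regular_design(self):
        pairs = pair_objects(18, 12, seed=0)
        assert len(pairs) == 108
        deg = Counter(x for p in pairs for x in p)
        assert set(deg.values()) == {12}
        assert all(a != b for a, b in pairs)

    def test_tiny_design_allows_multi_edges(self):
        pairs = pair_objects(2, 2, seed=0)
        assert len(pairs) == 2
        assert all(set(p) == {0, 1} for p in pairs)

    def test_infeasible_inputs(self):
        with pytest.raises(ValueError):
            pair_objects(3, 3)  # odd stub count
        with pytest.raises(ValueError):
            pair_objects(1, 2, max_tries=50)  # self-pairs unavoidable


class TestTrialComposition:
    def test_conservation(self, full_design, frame_table):
        assert len(full_design.trials) == 108
        phrases = full_design.phrases
        assert len(phrases) == 216
        obj_count = Counter(o for t in full_design.trials for o in t.objects)
        assert set(obj_count.values()) == {12}
        label_count = Counter(p.referent for p in phrases)
        assert set(label_count.values()) == {12}
        frame_usage = Counter(p.frame_id for p in phrases)
        assert frame_usage == Counter(apportion_frame_counts(frame_table, 216))

    def test_each_trial_names_both_objects(self, full_design):
        for t in full_design.trials:
            assert t.phrases[0].referent != t.phrases[1].referent
            assert {p.referent for p in t.phrases} == set(t.objects)

    def test_determinism(self, languages, frame_table):
        from framelang.language import Condition
        from framelang.trials import generate_design

        lang = languages[Condition.FULL]
        a = generate_design(lang, frame_table, seed=5)
        b = generate_design(lang, frame_table, seed=5)
        assert a == b


class TestSegmentationTests:
    def test_design_counts_and_balance(self, lexicon):
        items = build_segmentation_tests(lexicon, seed=0)
        assert len(items) == 72
        for role in ("LABEL", "FRAME"):
            sub = [i for i in items if i.word_type == role]
            assert len(sub) == 36
            assert set(Counter(i.target for i in sub).values()) == {6}
            assert set(Counter(i.foil for i in sub).values()) == {6}

    def test_foils_are_part_words_not_words(self, lexicon):
        forms = set(lexicon.by_form)
        for item in build_segmentation_tests(lexicon, seed=1):
            assert item.foil not in forms
            assert item.foil == item.foil_syllables[0] + item.foil_syllables[1]
            assert item.target in forms

    def test_capacity_error_on_small_lexicon(self):
        inv = build_syllable_inventory(seed=0)
        small = build_lexicon(inv, n_labels=4, n_frame=4, seed=0)
        with pytest.raises(CapacityError):
            build_segmentation_tests(small)


class TestMappingTests:
    def test_one_item_per_label_with_balanced_distractors(self, lexicon):
        items = build_mapping_tests(lexicon, seed=0)
        assert len(items) == 18
        usage = Counter()
        for item in items:
            assert len(set(item.alternatives)) == 4
            assert item.correct in item.alternatives
            assert item.alternatives[item.correct_index] == item.correct
            usage.update(o for o in item.alternatives if o != item.correct)
        assert max(usage.values()) - min(usage.values()) <= 1

    def test_requires_enough_objects(self):
        inv = build_syllable_inventory(seed=0)
        small = build_lexicon(inv, n_labels=3, n_frame=2, seed=0)
        with pytest.raises(ValueError):
            build_mapping_tests(small)


class TestPhoExport:
    def test_single_cv_word_manifest(self, lexicon):
        word = next(w for w in lexicon.words if len(w.syllables) == 1)
        pho = export_pho([word.form], lexicon)
        lines = pho.strip().splitlines()
        c, v = word.form[0], word.form[1]
        assert lines[0] == f"{c} 94 11 200"
        assert lines[1] == f"{v} 292 37 221 100 200"
        assert lines[2] == "_ 20"

    def test_phrase_duration_arithmetic(self):
        # five CV syllables: 5*(94+292) + 4*1 + 20 = 1954 ms, about 2 s
        assert nominal_duration_ms(5) == 1954
        with pytest.raises(ValueError):
            nominal_duration_ms(0)

    def test_export_errors(self, lexicon):
        with pytest.raises(ValueError):
            export_pho([], lexicon)
        with pytest.raises(ValueError):
            export_pho(["OBJ"], lexicon)
        with pytest.raises(KeyError):
            export_pho(["zzzz"], lexicon)

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            TimingSpec(consonant_ms=0)


def test_session_schedule_trials_run_about_12s(full_design):
    sched = session_schedule(full_design)
    assert len(sched) == 216
    first = sched[sched.trial == 1]
    assert first.onset_s.iloc[0] == pytest.approx(2.0)
    # next trial starts after this trial's two phrases, their trailing
    # silences, and its own 2 s lead-in
    second_start = sched[sched.trial == 2].onset_s.iloc[0]
    expected = 2.0 + first.duration_s.sum() + 2 * 3.0 + 2.0
    assert second_start == pytest.approx(expected, abs=0.01)
    # trials average roughly 12 s (phrase lengths vary with frame length)
    starts = sched.groupby("trial").onset_s.first().to_numpy()
    spacing = (starts[1:] - starts[:-1]).mean()
    assert 10.0 < spacing < 15.0
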