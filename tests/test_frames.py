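"""Frame extraction: windows, tallies, coverage, cue set, regularities."""

import math
from collections import Counter

import numpy as np
import pytest

from framelang.corpus import CorpusConfig, generate_naming_corpus
from framelang.frames import (
    BLANK,
    CueSet,
    FrameTable,
    extract_frame_window,
    extract_windows,
    frame_word_types,
    infer_cue_set,
    regularity_stats,
    tally_frames,
    tokenize_corpus,
    tokenize_utterance,
    top_k_coverage,
)


@pytest.mark.parametrize(
    "line, tokens, positions",
    [
        ("The <label:toma> is blue", ("the", "toma", "is", "blue"), (1,)),
        ("look at the <label:dax>", ("look", "at", "the", "dax"), (3,)),
        ("Where's the ball?", ("where's", "the", "ball"), ()),
    ],
)
def test_tokenize_examples(line, tokens, positions):
    u = tokenize_utterance(line)
    assert u.tokens == tokens
    assert u.label_positions == positions


def test_tokenize_blank_line_skipped_and_malformed_rejected():
    assert tokenize_utterance("") is None
    assert tokenize_utterance("   ") is None
    with pytest.raises(ValueError, match="line 2"):
        tokenize_corpus(["fine line", "bad <label:dax here"])


def test_tokenize_with_label_inventory():
    u = tokenize_utterance("look at the dax", label_inventory=["dax", "toma"])
    assert u.label_positions == (3,)


@pytest.mark.parametrize(
    "tokens, pos, pre, post",
    [
        (("the", "toma", "is", "blue"), 1, (BLANK, BLANK, "the"), ("is", "blue", BLANK)),
        (("toma",), 0, (BLANK,) * 3, (BLANK,) * 3),
        (("can", "you", "say", "dax"), 3, ("can", "you", "say"), (BLANK,) * 3),
    ],
)
def test_window_extraction(tokens, pos, pre, post):
    from framelang.frames import Utterance

    w = extract_frame_window(Utterance(tokens, (pos,)), pos)
    assert w.pre == pre and w.post == post


def test_window_requires_label_position():
    from framelang.frames import Utterance

    with pytest.raises(ValueError):
        extract_frame_window(Utterance(("a", "dax"), (1,)), 0)


def _windows(lines):
    return extract_windows(tokenize_corpus(lines))


def test_tally_single_pattern_is_total():
    wins = _windows(["the <label:dax>"] * 10)
    t = tally_frames(wins)
    assert len(t) == 1
    assert t.entries[0].pattern == "the OBJ"
    assert t.entries[0].pct == 100.0


def test_tally_matches_brute_force_and_is_order_invariant():
    """On a small generated corpus the tally equals a naive dictionary count
    over pre-label contexts, regardless of input order."""
    cfg = CorpusConfig(n_utterances=50, n_labeled=40, n_single_word=10, seed=9)
    us = generate_naming_corpus(cfg)
    utts = tokenize_corpus(us.lines)
    wins = [w for w in extract_windows(utts) if not w.is_single_word]

    brute = Counter()
    for u in utts:
        for i in u.label_positions:
            if len(u.tokens) == 1:
                continue
            pre = [
                "OBJ" if j in u.label_positions else u.tokens[j]
                for j in range(max(0, i - 3), i)
            ]
            brute[" ".join([*pre, "OBJ"])] += 1

    t = tally_frames(wins)
    assert {e.pattern: e.count for e in t.entries} == dict(brute)
    assert abs(sum(e.pct for e in t.entries) - 100.0) < 1e-9

    shuffled = [wins[i] for i in np.random.default_rng(0).permutation(len(wins))]
    assert tally_frames(shuffled) == t


def test_coverage_monotone_and_bounds(frame_table):
    assert top_k_coverage(frame_table, 0) == 0.0
    vals = [top_k_coverage(frame_table, k) for k in range(len(frame_table) + 1)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        top_k_coverage(frame_table, -1)
    with pytest.raises(ValueError):
        top_k_coverage(frame_table, len(frame_table) + 1)
    single = FrameTable.from_percentages({"the OBJ": 41.0})
    assert top_k_coverage(single, 1) == 41.0


def test_cue_set_inference(frame_table):
    cues = infer_cue_set(frame_table, 0.99)
    assert cues.words == frozenset({"the", "a", "say", "and"})
    half = infer_cue_set(frame_table, 0.5)
    assert half.words == frozenset({"the"})
    assert half.mass == pytest.approx(27.66 / 52.46, abs=1e-9)
    only = infer_cue_set(FrameTable.from_percentages({"the OBJ": 10.0}), 0.9)
    assert only.words == frozenset({"the"}) and only.mass == pytest.approx(1.0)
    with pytest.raises(ValueError):
        infer_cue_set(frame_table, 0.0)
    with pytest.raises(ValueError):
        infer_cue_set(FrameTable.from_percentages({}), 0.5)


def test_cue_set_is_minimal(frame_table):
    """Dropping any member's mass takes the set below the threshold."""
    thr = 0.99
    cues = infer_cue_set(frame_table, thr)
    by_word = Counter()
    for e in frame_table.entries:
        by_word[e.pattern.split()[-2]] += e.pct
    total = frame_table.total_pct
    for w in cues.words:
        remaining = sum(by_word[x] for x in cues.words if x != w)
        assert remaining / total < thr


def test_frame_word_types_reports_extracted_count(frame_table):
    assert len(frame_word_types(frame_table)) == 22


def test_regularity_stats_counts_window_shapes():
    wins = _windows(["the <label:dax>", "the <label:dax> is blue"])
    cues = CueSet(frozenset({"the"}), 1.0)
    rs = regularity_stats(wins, cues)
    assert rs.label_final == 0.5
    assert rs.cue_preceded == 1.0
    with pytest.raises(ValueError):
        regularity_stats([], cues)


def test_label_final_rate_recovered_binomially():
    """A corpus generated with 60% label-final non-frequent frames yields a
    label-final estimate within 3 SE of 0.60 at n = 2000."""
    n = 2000
    cfg = CorpusConfig(
        n_utterances=n, n_labeled=n, n_single_word=0,
        offframe_rate=1.0, offframe_label_final=0.60, seed=13,
    )
    us = generate_naming_corpus(cfg)
    wins = [w for w in _windows(us.lines) if not w.is_single_word]
    cues = CueSet(frozenset({"the", "a", "say", "and"}), 1.0)
    rs = regularity_stats(wins, cues)
    se = math.sqrt(0.6 * 0.4 / n)
    assert abs(rs.label_final - 0.60) < 3 * se
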