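import pytest

from framelang import frames, language, trials
from framelang.language import Condition


@pytest.fixture(scope="session")
def frame_table():
    return frames.load_frequent_frames()


@pytest.fixture(scope="session")
def cue_set(frame_table):
    return frames.infer_cue_set(frame_table, mass_threshold=0.99)


@pytest.fixture(scope="session")
def lexicon(frame_table):
    """A lexicon large enough to encode every frame of the inventory.

    The inventory's 21 frames use 22 distinct word types, so the lexicon
    spans all 60 CV combinations (18 + 22 words demand exactly 60 syllables).
    """
    inv = language.build_syllable_inventory(seed=11, n_syllables=60)
    glosses = frames.frame_word_types(frame_table)
    return language.build_lexicon(
        inv, n_labels=18, n_frame=len(glosses), seed=11, frame_glosses=glosses
    )


@pytest.fixture(scope="session")
def languages(frame_table, lexicon, cue_set):
    return {
        c: language.encode_language(frame_table, lexicon, c, cue_set)
        for c in Condition
    }


@pytest.fixture(scope="session")
def full_design(languages, frame_table):
    return trials.generate_design(languages[Condition.FULL], frame_table, seed=0)
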