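"""Artificial-language construction: lexicon and the 2×2 frame orderings.

The artificial language re-expresses the frequent naming frames with nonsense
words so that adults can be exposed to them in a cross-situational learning
task.  Two regularities of the natural frames are manipulated independently,
yielding four conditions:

===============  =================  ==================
condition        label position     onset cue present
===============  =================  ==================
FULL             utterance-final    yes
ONSET_ONLY       medial             yes
POSITION_ONLY    utterance-final    no
CONTROL          medial             no
===============  =================  ==================

Every condition uses the same words per frame — only their order changes.
Each frame is first decomposed into its pre-cue words ``w1..wk``, the *cue*
(the word immediately before the label slot), and the label slot ``OBJ``;
the condition then permutes this canonical order:

* FULL:           ``w1 .. wk  cue  OBJ``
* ONSET_ONLY:     ``w2 .. wk  cue  OBJ  w1``   (first word rotated to the end)
* POSITION_ONLY:  ``cue  w1 .. wk  OBJ``       (cue fronted)
* CONTROL:        ``cue  w1 .. w(k-1)  OBJ  wk``

Two-word frames (k = 0, e.g. "the OBJ") are identical in all conditions.
These minimal-edit rules reproduce the published example row
("look at the OBJ" → "at the OBJ look" / "the look at OBJ" / "the look OBJ at")
and the checkable context entropies; see ``docs/methods.md`` for the two
design cells whose published entropies no minimal rule reproduces.

The lexicon draws 57 of the 60 possible CV syllables from 12 consonants × 5
vowels and assigns them randomly, each used exactly once, to 18 object labels
and (by default) 20 frame words, half of each role one syllable (CV) long and
half two (CVCV) — so word forms carry no cue to their role.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .frames import OBJ, CueSet, FrameTable

__all__ = [
    "CapacityError",
    "DecompositionError",
    "EncodingError",
    "DEFAULT_CONSONANTS",
    "DEFAULT_VOWELS",
    "SyllableInventory",
    "Word",
    "Lexicon",
    "CanonicalFrame",
    "Condition",
    "EncodedFrame",
    "LanguageSpec",
    "build_syllable_inventory",
    "build_lexicon",
    "decompose_frame",
    "reorder_frame",
    "reordered_gloss_frames",
    "encode_language",
]


class CapacityError(ValueError):
    """Syllable demand exceeds the inventory."""


class DecompositionError(ValueError):
    """Frame cannot be decomposed against the cue set."""


class EncodingError(ValueError):
    """Frame word types missing from the lexicon."""


DEFAULT_CONSONANTS = ("b", "d", "g", "k", "l", "m", "n", "p", "s", "t", "v", "z")
DEFAULT_VOWELS = ("a", "e", "i", "o", "u")


@dataclass(frozen=True)
class SyllableInventory:
    consonants: tuple[str, ...]
    vowels: tuple[str, ...]
    syllables: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.syllables)) != len(self.syllables):
            raise ValueError("duplicate syllables")
        universe = {c + v for c, v in product(self.consonants, self.vowels)}
        if not set(self.syllables) <= universe:
            raise ValueError("syllables must be consonant+vowel combinations")


def build_syllable_inventory(
    seed: int = 0,
    consonants: Sequence[str] = DEFAULT_CONSONANTS,
    vowels: Sequence[str] = DEFAULT_VOWELS,
    n_syllables: int = 57,
) -> SyllableInventory:
    """Sample ``n_syllables`` distinct CV syllables from all C×V combinations."""
    universe = [c + v for c, v in product(consonants, vowels)]
    if n_syllables > len(universe):
        raise CapacityError(
            f"{n_syllables} syllables requested from {len(universe)} combinations"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(universe), size=n_syllables, replace=False)
    return SyllableInventory(
        tuple(consonants), tuple(vowels), tuple(universe[i] for i in chosen)
    )


LABEL = "LABEL"
FRAME = "FRAME"


@dataclass(frozen=True)
class Word:
    form: str
    syllables: tuple[str, ...]
    role: str
    gloss: str


@dataclass(frozen=True)
class Lexicon:
    """Artificial words with role (LABEL/FRAME) and gloss.

    Label glosses are object ids; frame-word glosses are the English frame
    word types they stand for.
    """

    words: tuple[Word, ...]

    def __post_init__(self) -> None:
        forms = [w.form for w in self.words]
        if len(set(forms)) != len(forms):
            raise ValueError("duplicate word forms")

    @property
    def labels(self) -> tuple[Word, ...]:
        return tuple(w for w in self.words if w.role == LABEL)

    @property
    def frame_words(self) -> tuple[Word, ...]:
        return tuple(w for w in self.words if w.role == FRAME)

    @property
    def label_map(self) -> dict[str, str]:
        """object id -> label form."""
        return {w.gloss: w.form for w in self.labels}

    @property
    def form_by_gloss(self) -> dict[str, str]:
        return {w.gloss: w.form for w in self.words}

    @property
    def by_form(self) -> dict[str, Word]:
        return {w.form: w for w in self.words}

    def bisyllabic(self, role: str) -> tuple[Word, ...]:
        return tuple(
            w for w in self.words if w.role == role and len(w.syllables) == 2
        )


def syllable_demand(n_labels: int, n_frame: int) -> int:
    """Syllables consumed by the half-CV / half-CVCV split of each role."""
    demand = 0
    for n in (n_labels, n_frame):
        n_cv = (n + 1) // 2
        demand += n_cv + 2 * (n - n_cv)
    return demand


def build_lexicon(
    inv: SyllableInventory,
    n_labels: int = 18,
    n_frame: int = 20,
    seed: int = 0,
    frame_glosses: Sequence[str] | None = None,
    object_ids: Sequence[str] | None = None,
) -> Lexicon:
    """Assign inventory syllables randomly to words, each used at most once.

    Within each role half the words are CV and half CVCV (the extra word is
    CV when the count is odd); which gloss receives which length and which
    syllables is random, so nothing phonetic distinguishes the roles.
    """
    demand = syllable_demand(n_labels, n_frame)
    if demand > len(inv.syllables):
        raise CapacityError(
            f"{demand} syllables needed for {n_labels}+{n_frame} words, "
            f"inventory has {len(inv.syllables)}"
        )
    if object_ids is None:
        object_ids = [f"obj{i + 1:02d}" for i in range(n_labels)]
    if frame_glosses is None:
        frame_glosses = [f"fw{i + 1:02d}" for i in range(n_frame)]
    if len(object_ids) != n_labels or len(frame_glosses) != n_frame:
        raise ValueError("gloss lists must match the requested word counts")

    rng = np.random.default_rng(seed)
    pool = list(rng.permutation(inv.syllables))
    words: list[Word] = []
    for role, glosses in ((LABEL, object_ids), (FRAME, frame_glosses)):
        n = len(glosses)
        n_cv = (n + 1) // 2
        lengths = rng.permutation([1] * n_cv + [2] * (n - n_cv))
        for gloss, ln in zip(glosses, lengths):
            sylls = tuple(pool.pop() for _ in range(ln))
            words.append(Word("".join(sylls), sylls, role, gloss))
    return Lexicon(tuple(words))


@dataclass(frozen=True)
class CanonicalFrame:
    """A frame split into pre-cue words, the onset cue, and the label slot."""

    pre_words: tuple[str, ...]
    cue: str
    frequency: float = 0.0

    @property
    def k(self) -> int:
        return len(self.pre_words)


class Condition(str, Enum):
    FULL = "full"
    ONSET_ONLY = "onset_only"
    POSITION_ONLY = "position_only"
    CONTROL = "control"


def decompose_frame(
    pattern: str | Sequence[str], cues: CueSet | Iterable[str], frequency: float = 0.0
) -> CanonicalFrame:
    """Split a frame ending at OBJ into pre-cue words and its onset cue."""
    tokens = pattern.split() if isinstance(pattern, str) else list(pattern)
    if not tokens or tokens[-1] != OBJ:
        raise DecompositionError(f"frame {tokens!r} does not end with {OBJ}")
    if len(tokens) < 2:
        raise DecompositionError("bare OBJ frame has no cue")
    cue = tokens[-2]
    cue_words = cues.words if isinstance(cues, CueSet) else set(cues)
    if cue not in cue_words:
        raise DecompositionError(f"pre-label word {cue!r} is not in the cue set")
    return CanonicalFrame(tuple(tokens[:-2]), cue, frequency)


def reorder_frame(f: CanonicalFrame, c: Condition) -> tuple[str, ...]:
    """Order the frame's words for a condition; the token multiset is kept."""
    pre, cue = f.pre_words, f.cue
    if f.k == 0:
        return (cue, OBJ)
    if c is Condition.FULL:
        return (*pre, cue, OBJ)
    if c is Condition.ONSET_ONLY:
        return (*pre[1:], cue, OBJ, pre[0])
    if c is Condition.POSITION_ONLY:
        return (cue, *pre, OBJ)
    if c is Condition.CONTROL:
        return (cue, *pre[:-1], OBJ, pre[-1])
    raise ValueError(f"unknown condition {c!r}")


@dataclass(frozen=True)
class EncodedFrame:
    """One frame of a language: gloss order, artificial forms, frequency."""

    frame_id: str
    gloss_tokens: tuple[str, ...]
    tokens: tuple[str, ...]
    frequency: float


@dataclass(frozen=True)
class LanguageSpec:
    condition: Condition
    frames: tuple[EncodedFrame, ...]
    lexicon: Lexicon

    def to_dict(self) -> dict:
        return {
            "condition": self.condition.value,
            "frames": [
                {
                    "frame_id": f.frame_id,
                    "gloss_tokens": list(f.gloss_tokens),
                    "tokens": list(f.tokens),
                    "frequency": f.frequency,
                }
                for f in self.frames
            ],
            "lexicon": [
                {"form": w.form, "syllables": list(w.syllables),
                 "role": w.role, "gloss": w.gloss}
                for w in self.lexicon.words
            ],
        }


def reordered_gloss_frames(
    table: FrameTable, cues: CueSet, condition: Condition
) -> list[tuple[tuple[str, ...], float]]:
    """Reordered frames at the gloss level, paired with their frequencies.

    This is the lexicon-free view used for context statistics: entropies
    depend only on word identities and frequencies, not on artificial forms.
    """
    out = []
    for e in table.entries:
        cf = decompose_frame(e.pattern, cues, e.pct)
        out.append((reorder_frame(cf, condition), e.pct))
    return out


def encode_language(
    table: FrameTable, lex: Lexicon, condition: Condition, cues: CueSet
) -> LanguageSpec:
    """Encode every frame of the table into artificial words for a condition."""
    mapping = {w.gloss: w.form for w in lex.frame_words}
    needed = {
        w for e in table.entries for w in e.pattern.split() if w != OBJ
    }
    missing = sorted(needed - mapping.keys())
    if missing:
        raise EncodingError(f"no artificial word for frame types: {missing}")
    frames = []
    for e in table.entries:
        try:
            cf = decompose_frame(e.pattern, cues, e.pct)
        except DecompositionError as err:
            warnings.warn(f"excluding frame {e.pattern!r}: {err}", stacklevel=2)
            continue
        gloss_tokens = reorder_frame(cf, condition)
        tokens = tuple(OBJ if t == OBJ else mapping[t] for t in gloss_tokens)
        frames.append(EncodedFrame(e.pattern, gloss_tokens, tokens, e.pct))
    return LanguageSpec(condition, tuple(frames), lex)
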