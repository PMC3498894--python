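"""Statistical structure of a language and its training stream.

Three families of statistics characterize what a learner could exploit:

* **Label-context distributions and their Shannon entropy (bits).**  For each
  language condition we ask how predictable the token immediately before
  (onset) or after (offset) the label slot is, weighting each frame by its
  frequency.  An utterance edge counts as the ``BOUNDARY`` outcome.  Zero
  entropy means the context is fully predictable (e.g. the label is always
  utterance-final); entropy grows with the number and uniformity of
  alternatives.  By default these are computed from the continuous frame
  frequencies rather than from integer-apportioned trial counts, so they are
  properties of the language itself; pass a realized trial set for the
  empirical variant.

* **Syllable transitional probabilities** P(s2 | s1) within phrases —
  the segmentation statistic.  Bigrams never span phrase boundaries.

* **Word–object co-occurrence counts** over trials — the cross-situational
  mapping statistic: a word heard in a trial co-occurs with both objects
  shown on that trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .frames import OBJ, CueSet, FrameTable
from .language import Condition, LanguageSpec, reordered_gloss_frames
from .trials import TrialSet

__all__ = [
    "BOUNDARY",
    "ContextDistribution",
    "context_distribution",
    "shannon_entropy",
    "condition_entropies",
    "TPModel",
    "transitional_probabilities",
    "word_object_cooccurrence",
]

#: Context outcome when the label slot sits at an utterance edge.
BOUNDARY = "#"

FrameSeq = Iterable[tuple[Sequence[str], float]]


@dataclass(frozen=True)
class ContextDistribution:
    """Probability over the token adjacent to the label slot."""

    probs: dict[str, float]
    side: str

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if self.probs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total!r}")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("negative probability")


def _frame_pairs(lang: LanguageSpec | FrameSeq) -> list[tuple[Sequence[str], float]]:
    if isinstance(lang, LanguageSpec):
        return [(f.gloss_tokens, f.frequency) for f in lang.frames]
    return list(lang)


def context_distribution(
    lang: LanguageSpec | FrameSeq, side: str
) -> ContextDistribution:
    """Distribution of the token adjacent to OBJ, weighted by frame frequency.

    ``side`` is ``"onset"`` (token before the label) or ``"offset"`` (token
    after it); an utterance edge yields :data:`BOUNDARY`.
    """
    if side not in ("onset", "offset"):
        raise ValueError(f"side must be 'onset' or 'offset', got {side!r}")
    weights: dict[str, float] = {}
    total = 0.0
    for tokens, freq in _frame_pairs(lang):
        tokens = list(tokens)
        i = tokens.index(OBJ)
        if side == "onset":
            outcome = tokens[i - 1] if i > 0 else BOUNDARY
        else:
            outcome = tokens[i + 1] if i < len(tokens) - 1 else BOUNDARY
        weights[outcome] = weights.get(outcome, 0.0) + freq
        total += freq
    probs = {k: v / total for k, v in weights.items()} if total else {}
    return ContextDistribution(probs, side)


def shannon_entropy(d: ContextDistribution | Mapping[str, float]) -> float:
    """H = −Σ p·log2 p in bits, with 0·log 0 = 0."""
    probs = d.probs if isinstance(d, ContextDistribution) else d
    return -sum(p * math.log2(p) for p in probs.values() if p > 0.0) + 0.0


def condition_entropies(
    table: FrameTable,
    cues: CueSet,
    conditions: Sequence[Condition] = tuple(Condition),
) -> pd.DataFrame:
    """Onset/offset entropy per condition, straight from the frame table."""
    rows = []
    for c in conditions:
        frames = reordered_gloss_frames(table, cues, c)
        rows.append(
            {
                "condition": c.value,
                "onset_H": shannon_entropy(context_distribution(frames, "onset")),
                "offset_H": shannon_entropy(context_distribution(frames, "offset")),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TPModel:
    """Within-phrase syllable bigram counts and conditional probabilities."""

    counts: dict[tuple[str, str], int]
    left_totals: dict[str, int]

    def prob(self, s1: str, s2: str) -> float:
        total = self.left_totals.get(s1, 0)
        if total == 0:
            return 0.0
        return self.counts.get((s1, s2), 0) / total

    def conditionals(self) -> dict[tuple[str, str], float]:
        return {pair: self.prob(*pair) for pair in self.counts}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"s1": a, "s2": b, "count": c, "prob": self.prob(a, b)}
            for (a, b), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


def transitional_probabilities(trials: TrialSet) -> TPModel:
    """Fit syllable TPs on a trial set's phrases; boundaries reset context."""
    counts: dict[tuple[str, str], int] = {}
    left: dict[str, int] = {}
    for phrase in trials.phrases:
        s = phrase.syllables
        for a, b in zip(s, s[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
            left[a] = left.get(a, 0) + 1
    return TPModel(counts, left)


def word_object_cooccurrence(trials: TrialSet) -> pd.DataFrame:
    """Count matrix of (word heard in trial) × (object shown in trial)."""
    counts: dict[str, dict[str, int]] = {}
    objects: set[str] = set()
    for trial in trials.trials:
        objects.update(trial.objects)
        # token multiplicity counts, so a word's row sum is always
        # (number of occurrences) x (2 objects per trial)
        for p in trial.phrases:
            for w in p.words:
                row = counts.setdefault(w, {})
                for o in trial.objects:
                    row[o] = row.get(o, 0) + 1
    cols = sorted(objects)
    mat = pd.DataFrame(
        [[counts[w].get(o, 0) for o in cols] for w in sorted(counts)],
        index=sorted(counts),
        columns=cols,
        dtype=int,
    )
    return mat
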