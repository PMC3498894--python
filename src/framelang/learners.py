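"""Transparent ideal-observer learners over generated languages.

These reference learners make the scaffolding logic computationally explicit
without positing any memory or attention model: they are pure count-based
observers over exactly the statistics a session exposes.

* :func:`tp_word_score` / :func:`simulate_segmentation_test` — a segmenter
  that scores candidate words by their internal syllable transitional
  probabilities and answers each 2AFC item by score comparison.
* :func:`map_by_cooccurrence` — a cross-situational mapper that assigns each
  label the object it co-occurred with most often.
* :func:`cue_anchored_mapper` — a mapper that exploits the onset-cue
  regularity: it treats whatever token follows a cue word as a label
  candidate and builds candidate–object co-occurrences, i.e. it can begin
  mapping without fully segmenting the rest of the phrase.

Ties are always broken uniformly at random under the supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .streams import TPModel
from .trials import SegTestItem, TrialSet

__all__ = [
    "tp_word_score",
    "SegDecision",
    "SegReport",
    "simulate_segmentation_test",
    "MappingResult",
    "map_by_cooccurrence",
    "cue_anchored_mapper",
]


def tp_word_score(
    word_syllables: Sequence[str], tp: TPModel, aggregator: str = "min"
) -> float:
    """Aggregate a word's internal bigram conditionals (min or product).

    Unseen bigrams score 0; monosyllabic input has no internal bigram and is
    rejected.
    """
    if len(word_syllables) < 2:
        raise ValueError("word must have at least two syllables")
    probs = [tp.prob(a, b) for a, b in zip(word_syllables, word_syllables[1:])]
    if aggregator == "min":
        return min(probs)
    if aggregator == "product":
        out = 1.0
        for p in probs:
            out *= p
        return out
    raise ValueError(f"unknown aggregator {aggregator!r}")


@dataclass(frozen=True)
class SegDecision:
    item: SegTestItem
    target_score: float
    foil_score: float
    choice: str  # "target" or "foil"

    @property
    def correct(self) -> bool:
        return self.choice == "target"


@dataclass(frozen=True)
class SegReport:
    decisions: tuple[SegDecision, ...]

    def accuracy(self, word_type: str | None = None) -> float:
        ds = [
            d for d in self.decisions
            if word_type is None or d.item.word_type == word_type
        ]
        if not ds:
            return float("nan")
        return sum(d.correct for d in ds) / len(ds)

    def by_type(self) -> dict[str, float]:
        types = sorted({d.item.word_type for d in self.decisions})
        return {t: self.accuracy(t) for t in types}


def simulate_segmentation_test(
    items: Iterable[SegTestItem],
    tp: TPModel,
    seed: int = 0,
    aggregator: str = "min",
) -> SegReport:
    """Answer each 2AFC item by TP score; ties flip a seeded coin."""
    rng = np.random.default_rng(seed)
    decisions = []
    for item in items:
        ts = tp_word_score(item.target_syllables, tp, aggregator)
        fs = tp_word_score(item.foil_syllables, tp, aggregator)
        if ts > fs:
            choice = "target"
        elif fs > ts:
            choice = "foil"
        else:
            choice = "target" if rng.random() < 0.5 else "foil"
        decisions.append(SegDecision(item, ts, fs, choice))
    return SegReport(tuple(decisions))


@dataclass(frozen=True)
class MappingResult:
    mapping: dict[str, str]  # label form -> chosen object
    accuracy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


def _argmax_choice(
    row: dict[str, float], objects: Sequence[str], rng: np.random.Generator
) -> str:
    if not row:
        return objects[rng.integers(len(objects))]
    best = max(row.values())
    winners = sorted(o for o, v in row.items() if v == best)
    return winners[rng.integers(len(winners))]


def map_by_cooccurrence(
    cooc: pd.DataFrame, label_map: dict[str, str], seed: int = 0
) -> MappingResult:
    """Map each label to its most frequent co-occurring object.

    ``label_map`` is object id -> label form (the ground truth).  Labels with
    no co-occurrence evidence get a random object, so an empty matrix yields
    chance accuracy in expectation.
    """
    rng = np.random.default_rng(seed)
    truth = {form: obj for obj, form in label_map.items()}
    objects = sorted(label_map)
    mapping, correct = {}, 0
    for form, obj in sorted(truth.items()):
        if form in cooc.index:
            row = {o: float(v) for o, v in cooc.loc[form].items() if v > 0}
        else:
            row = {}
        choice = _argmax_choice(row, objects, rng)
        mapping[form] = choice
        correct += choice == obj
    return MappingResult(mapping, correct / len(truth))


def cue_anchored_mapper(
    trials: TrialSet,
    cue_forms: Iterable[str],
    label_map: dict[str, str],
    seed: int = 0,
) -> MappingResult:
    """Map labels via tokens that follow an onset cue, without segmentation.

    Every token immediately following a cue-word occurrence is treated as a
    label candidate and accumulated against the trial's on-screen objects;
    each true label is then mapped by argmax over its candidate counts.
    When the cue does not sit next to the label slot (the conditions without
    the onset regularity) the candidate set is contaminated with frame words
    and true labels may receive little or no evidence.
    """
    cue_set = set(cue_forms)
    rng = np.random.default_rng(seed)
    counts: dict[str, dict[str, int]] = {}
    for trial in trials.trials:
        for phrase in trial.phrases:
            words = phrase.words
            for i, w in enumerate(words[:-1]):
                if w in cue_set:
                    cand = words[i + 1]
                    row = counts.setdefault(cand, {})
                    for o in trial.objects:
                        row[o] = row.get(o, 0) + 1
    truth = {form: obj for obj, form in label_map.items()}
    objects = sorted(label_map)
    mapping, correct = {}, 0
    for form, obj in sorted(truth.items()):
        choice = _argmax_choice(counts.get(form, {}), objects, rng)
        mapping[form] = choice
        correct += choice == obj
    return MappingResult(mapping, correct / len(truth))
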