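"""Training-trial and test-set construction for the cross-situational task.

A session consists of 108 training trials, each presenting two objects on
screen together with two continuous-speech phrases, one naming each object.
Each of the 18 objects appears in exactly 12 trials, and each naming frame
supplies a number of the 216 phrases proportional to its frequency in the
child-directed-speech inventory (largest-remainder apportionment).  After
training come 72 two-alternative segmentation tests (real word vs part-word
foil, balanced within word type) and 18 four-alternative mapping tests (one
per label).

Phrases are destined for diphone synthesis; :func:`export_pho` emits the
timing/pitch manifest for one phrase in the ``.pho`` format consumed by
concatenative synthesizers (synthesis itself is out of scope).  With the
default timing — 94 ms consonants, 292 ms vowels, 1 ms between syllables and
a 20 ms terminal pause — a five-syllable phrase lasts 1954 ms, i.e. roughly
the two seconds per phrase of the original sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import OBJ, FrameTable
from .language import FRAME, LABEL, CapacityError, LanguageSpec, Lexicon

__all__ = [
    "apportion_frame_counts",
    "pair_objects",
    "Phrase",
    "Trial",
    "TrialSet",
    "compose_trials",
    "generate_design",
    "SegTestItem",
    "build_segmentation_tests",
    "MapTestItem",
    "build_mapping_tests",
    "TimingSpec",
    "nominal_duration_ms",
    "export_pho",
    "session_schedule",
]


def apportion_frame_counts(t: FrameTable, total_phrases: int = 216) -> dict[str, int]:
    """Integer phrase counts per frame, proportional to table frequencies.

    Largest-remainder apportionment: floors of the exact quotas, with the
    leftover phrases going to the largest fractional remainders (ties broken
    by table rank).  Counts sum exactly to ``total_phrases``.
    """
    if total_phrases <= 0:
        raise ValueError("total_phrases must be positive")
    if not t.entries:
        raise ValueError("cannot apportion over an empty table")
    total = t.total_pct
    quotas = [total_phrases * e.pct / total for e in t.entries]
    counts = [int(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    leftover = total_phrases - sum(counts)
    for i in sorted(range(len(counts)), key=lambda i: (-remainders[i], i))[:leftover]:
        counts[i] += 1
    return {e.pattern: c for e, c in zip(t.entries, counts)}


def pair_objects(
    n_objects: int = 18,
    appearances: int = 12,
    seed: int = 0,
    max_tries: int = 20000,
) -> list[tuple[int, int]]:
    """Pair objects into trials so each appears exactly ``appearances`` times.

    Configuration-model sampling: each object contributes ``appearances``
    stubs, a random perfect matching of stubs is drawn, and the whole draw is
    rejected if any pair matches an object with itself.  Repeated pairs
    (multi-edges) are allowed.
    """
    if n_objects <= 0 or appearances <= 0:
        raise ValueError("n_objects and appearances must be positive")
    if (n_objects * appearances) % 2:
        raise ValueError("n_objects * appearances must be even")
    rng = np.random.default_rng(seed)
    stubs = np.repeat(np.arange(n_objects), appearances)
    for _ in range(max_tries):
        perm = rng.permutation(stubs)
        a, b = perm[0::2], perm[1::2]
        if np.all(a != b):
            return [(int(x), int(y)) for x, y in zip(a, b)]
    raise ValueError(
        f"no self-pair-free matching found for {n_objects} objects x "
        f"{appearances} appearances in {max_tries} tries"
    )


@dataclass(frozen=True)
class Phrase:
    frame_id: str
    referent: str
    words: tuple[str, ...]
    syllables: tuple[str, ...]


@dataclass(frozen=True)
class Trial:
    objects: tuple[str, str]
    phrases: tuple[Phrase, Phrase]


@dataclass(frozen=True)
class TrialSet:
    trials: tuple[Trial, ...]
    seed: int
    frame_counts: dict[str, int] = field(default_factory=dict)

    @property
    def phrases(self) -> list[Phrase]:
        return [p for t in self.trials for p in t.phrases]


def compose_trials(
    pairs: list[tuple[int, int]],
    frame_counts: dict[str, int],
    lang: LanguageSpec,
    seed: int = 0,
) -> TrialSet:
    """Fill object pairs with frames drawn without replacement from the pool.

    Each pair becomes a trial whose two phrases name its two objects; the
    frame-to-referent assignment and the phrase order are random.
    """
    if sum(frame_counts.values()) != 2 * len(pairs):
        raise ValueError("frame counts must supply exactly two phrases per trial")
    rng = np.random.default_rng(seed)
    objects = sorted(w.gloss for w in lang.lexicon.labels)
    label_form = lang.lexicon.label_map
    by_form = lang.lexicon.by_form
    frame_by_id = {f.frame_id: f for f in lang.frames}
    missing = [fid for fid in frame_counts if fid not in frame_by_id]
    if missing:
        raise ValueError(f"frames not in language: {missing}")

    pool = [fid for fid, c in frame_counts.items() for _ in range(c)]
    pool = [pool[i] for i in rng.permutation(len(pool))]

    def make_phrase(fid: str, obj: str) -> Phrase:
        enc = frame_by_id[fid]
        words = tuple(label_form[obj] if t == OBJ else t for t in enc.tokens)
        sylls = tuple(s for w in words for s in by_form[w].syllables)
        return Phrase(fid, obj, words, sylls)

    trials = []
    for a, b in pairs:
        oa, ob = objects[a], objects[b]
        if oa == ob:
            raise ValueError("a trial's two objects must differ")
        p1 = make_phrase(pool.pop(), oa)
        p2 = make_phrase(pool.pop(), ob)
        if rng.random() < 0.5:
            p1, p2 = p2, p1
        trials.append(Trial((p1.referent, p2.referent), (p1, p2)))
    assert not pool, "frame pool not exhausted"
    return TrialSet(tuple(trials), seed, dict(frame_counts))


def generate_design(
    lang: LanguageSpec,
    table: FrameTable | None = None,
    n_trials: int = 108,
    appearances: int = 12,
    seed: int = 0,
) -> TrialSet:
    """Convenience: apportion, pair, and compose a full training session."""
    if table is None:
        counts = apportion_frame_counts(
            FrameTable.from_percentages(
                {f.frame_id: f.frequency for f in lang.frames}
            ),
            2 * n_trials,
        )
    else:
        counts = apportion_frame_counts(table, 2 * n_trials)
    n_objects = len(lang.lexicon.labels)
    pairs = pair_objects(n_objects, appearances, seed)
    if len(pairs) != n_trials:
        raise ValueError(
            f"{n_objects} objects x {appearances} appearances yields "
            f"{len(pairs)} trials, not {n_trials}"
        )
    return compose_trials(pairs, counts, lang, seed)


@dataclass(frozen=True)
class SegTestItem:
    """2AFC item: a real bisyllabic word against a part-word foil."""

    target: str
    target_syllables: tuple[str, str]
    foil: str
    foil_syllables: tuple[str, str]
    word_type: str


def build_segmentation_tests(
    lex: Lexicon, n_per_type: int = 6, seed: int = 0
) -> list[SegTestItem]:
    """Cross n targets with n same-role foils for each word type.

    Foils concatenate the first syllable of one bisyllabic word with the
    second syllable of another (same role); because every syllable occurs in
    exactly one word, no foil can collide with a real word form.  Each target
    and each foil appears in exactly ``n_per_type`` items; the default yields
    36 + 36 = 72 items.
    """
    rng = np.random.default_rng(seed)
    items: list[SegTestItem] = []
    forms = set(lex.by_form)
    for role in (LABEL, FRAME):
        bis = list(lex.bisyllabic(role))
        if len(bis) < max(n_per_type, 2):
            raise CapacityError(
                f"need at least {max(n_per_type, 2)} bisyllabic {role} words, "
                f"have {len(bis)}"
            )
        order = rng.permutation(len(bis))
        targets = [bis[i] for i in order[:n_per_type]]
        foils: list[tuple[str, tuple[str, str]]] = []
        seen: set[str] = set()
        guard = 0
        while len(foils) < n_per_type:
            guard += 1
            if guard > 10000:
                raise CapacityError("could not build enough distinct foils")
            i, j = rng.choice(len(bis), size=2, replace=False)
            form = bis[i].syllables[0] + bis[j].syllables[1]
            if form in forms or form in seen:
                continue
            seen.add(form)
            foils.append((form, (bis[i].syllables[0], bis[j].syllables[1])))
        for t in targets:
            for foil, fsyll in foils:
                items.append(
                    SegTestItem(t.form, t.syllables, foil, fsyll, role)  # type: ignore[arg-type]
                )
    return [items[i] for i in np.random.default_rng(seed + 1).permutation(len(items))]


@dataclass(frozen=True)
class MapTestItem:
    """4AFC item: a heard label and four candidate referents."""

    label: str
    correct: str
    alternatives: tuple[str, ...]

    @property
    def correct_index(self) -> int:
        return self.alternatives.index(self.correct)


def build_mapping_tests(
    lex: Lexicon, seed: int = 0, n_alternatives: int = 4
) -> list[MapTestItem]:
    """One 4AFC item per label, distractor usage balanced across objects.

    Distractors are drawn without replacement, preferring the least-used
    objects; the assignment is retried until usage counts differ by at most
    one across objects.
    """
    labels = lex.labels
    objects = sorted(w.gloss for w in labels)
    if len(objects) < n_alternatives:
        raise ValueError(f"need at least {n_alternatives} objects")
    label_form = lex.label_map
    rng = np.random.default_rng(seed)
    for _ in range(200):
        usage = {o: 0 for o in objects}
        order = rng.permutation(len(objects))
        assignment: list[tuple[str, list[str]]] = []
        for i in order:
            correct = objects[i]
            cands = [o for o in objects if o != correct]
            cands.sort(key=lambda o: (usage[o], rng.random()))
            distractors = cands[: n_alternatives - 1]
            for o in distractors:
                usage[o] += 1
            assignment.append((correct, distractors))
        if max(usage.values()) - min(usage.values()) <= 1:
            items = []
            for correct, distractors in assignment:
                alts = [correct, *distractors]
                alts = [alts[k] for k in rng.permutation(len(alts))]
                items.append(MapTestItem(label_form[correct], correct, tuple(alts)))
            return items
    raise RuntimeError("could not balance distractor usage")


@dataclass(frozen=True)
class TimingSpec:
    """Diphone-synthesis timing: durations in ms, pitch points as (ms, Hz)."""

    consonant_ms: int = 94
    consonant_pitch: tuple[tuple[int, int], ...] = ((10, 200),)
    vowel_ms: int = 292
    vowel_pitch: tuple[tuple[int, int], ...] = ((108, 221), (292, 200))
    inter_syllable_pause_ms: int = 1
    utterance_final_pause_ms: int = 20
    pre_trial_silence_s: float = 2.0
    post_phrase_silence_s: float = 3.0

    def __post_init__(self) -> None:
        if min(self.consonant_ms, self.vowel_ms, self.inter_syllable_pause_ms,
               self.utterance_final_pause_ms) <= 0:
            raise ValueError("durations must be positive")


def nominal_duration_ms(n_syllables: int, t: TimingSpec | None = None) -> int:
    """Nominal phrase duration for CV syllables under a timing spec."""
    t = t or TimingSpec()
    if n_syllables <= 0:
        raise ValueError("phrase must contain at least one syllable")
    per = t.consonant_ms + t.vowel_ms
    return (
        n_syllables * per
        + (n_syllables - 1) * t.inter_syllable_pause_ms
        + t.utterance_final_pause_ms
    )


def _pitch_fields(points: tuple[tuple[int, int], ...], dur_ms: int) -> str:
    return " ".join(
        f"{round(100 * ms / dur_ms)} {hz}" for ms, hz in points
    )


def export_pho(
    phrase: tuple[str, ...] | list[str],
    lex: Lexicon,
    timing: TimingSpec | None = None,
    phoneme_map: dict[str, str] | None = None,
) -> str:
    """Render one phrase (word forms, OBJ already filled) as a .pho manifest.

    Each line is ``phoneme duration_ms [position_pct pitch_hz ...]``; the
    pause phoneme is ``_``.  ``phoneme_map`` translates syllable characters
    to synthesizer phoneme symbols (identity by default).
    """
    t = timing or TimingSpec()
    if not phrase:
        raise ValueError("empty phrase")
    pm = phoneme_map or {}
    by_form = lex.by_form
    sylls: list[str] = []
    for w in phrase:
        if w == OBJ:
            raise ValueError("OBJ slot not filled")
        if w not in by_form:
            raise KeyError(f"unknown word form {w!r}")
        sylls.extend(by_form[w].syllables)
    lines = []
    for i, s in enumerate(sylls):
        c, v = s[0], s[1:]
        lines.append(
            f"{pm.get(c, c)} {t.consonant_ms} "
            f"{_pitch_fields(t.consonant_pitch, t.consonant_ms)}"
        )
        lines.append(
            f"{pm.get(v, v)} {t.vowel_ms} "
            f"{_pitch_fields(t.vowel_pitch, t.vowel_ms)}"
        )
        if i < len(sylls) - 1:
            lines.append(f"_ {t.inter_syllable_pause_ms}")
    lines.append(f"_ {t.utterance_final_pause_ms}")
    return "\n".join(lines) + "\n"


def session_schedule(
    trials: TrialSet, timing: TimingSpec | None = None
) -> pd.DataFrame:
    """Per-phrase presentation schedule with onsets in seconds."""
    t = timing or TimingSpec()
    rows = []
    clock = 0.0
    for i, trial in enumerate(trials.trials, start=1):
        clock += t.pre_trial_silence_s
        for m, phrase in enumerate(trial.phrases, start=1):
            dur = nominal_duration_ms(len(phrase.syllables), t) / 1000.0
            rows.append(
                {
                    "trial": i,
                    "phrase": m,
                    "onset_s": round(clock, 3),
                    "duration_s": round(dur, 3),
                    "frame_id": phrase.frame_id,
                    "referent": phrase.referent,
                    "objects": " ".join(trial.objects),
                    "words": " ".join(phrase.words),
                }
            )
            clock += dur + t.post_phrase_silence_s
    return pd.DataFrame(rows)


def export_trial_phos(
    trials: TrialSet,
    lex: Lexicon,
    outdir: str | Path,
    timing: TimingSpec | None = None,
    limit: int | None = None,
) -> list[Path]:
    """Write ``trial{n}_phrase{m}.pho`` manifests; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, trial in enumerate(trials.trials[: limit or len(trials.trials)], start=1):
        for m, phrase in enumerate(trial.phrases, start=1):
            p = outdir / f"trial{i}_phrase{m}.pho"
            p.write_text(export_pho(phrase.words, lex, timing), encoding="utf-8")
            paths.append(p)
    return paths
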