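"""Synthetic label-annotated transcripts of free-play child-directed speech.

The corpus this package analyzes was recorded during parent–child free play
with nine labeled toys and is not publicly deposited, so every downstream
stage is exercised on synthetic transcripts that reproduce its documented
composition: 3165 parental utterances, 1624 containing a toy label, 672 of
those being bare single-word labels, and the remaining 952 multi-word naming
events distributed over naming frames.  Frequent frames are drawn from the
packaged 21-frame inventory (renormalized over its own mass); the residual
mass goes to randomly constructed non-frequent frames whose label-final and
cue-preceded rates are configurable, mirroring the regularities observed in
the residual naming events (≈50% and ≈63%).

The generator is seeded and byte-deterministic; ground truth (naming status,
frame pattern, label type) is emitted alongside the transcript so parameter
recovery can be checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .frames import OBJ, load_frequent_frames

__all__ = [
    "ConfigurationError",
    "CorpusConfig",
    "UtteranceSet",
    "DEFAULT_LABELS",
    "FILLER_VOCAB",
    "generate_naming_corpus",
]


class ConfigurationError(ValueError):
    """Inconsistent corpus configuration."""


#: Nine toy-label word types: three toys in each of three toy sets.
DEFAULT_LABELS = ("dax", "toma", "gub", "wif", "blick", "fep", "zot", "modi", "kiv")

#: Closed filler vocabulary, disjoint from the frequent-frame word types.
FILLER_VOCAB = (
    "oh", "yeah", "good", "nice", "wow", "okay", "now", "see", "go", "get",
    "come", "give", "play", "ball", "baby", "more", "again", "little", "big",
    "red", "blue", "green", "down", "up", "over", "under", "right", "fun",
    "pretty", "silly",
)

#: Words that may immediately precede a label in non-frequent frames.
DEFAULT_CUE_WORDS = ("the", "a", "say", "and")


def _default_frame_distribution() -> dict[str, float]:
    table = load_frequent_frames()
    total = table.total_pct
    return {e.pattern: e.pct / total for e in table.entries}


@dataclass
class CorpusConfig:
    """Composition of a synthetic naming corpus.

    ``offframe_rate`` is the probability that a multi-word naming event uses
    a random non-frequent frame instead of one drawn from
    ``frame_distribution``.  Its default, 1 − 52.46/100, makes the frequent
    frames cover the same share of multi-word naming events as in the
    recorded corpus.
    """

    n_utterances: int = 3165
    n_labeled: int = 1624
    n_single_word: int = 672
    frame_distribution: dict[str, float] = field(
        default_factory=_default_frame_distribution
    )
    label_inventory: tuple[str, ...] = DEFAULT_LABELS
    offframe_rate: float = 1.0 - 52.46 / 100.0
    offframe_label_final: float = 0.50
    offframe_cue_preceded: float = 0.63
    offframe_cue_words: tuple[str, ...] = DEFAULT_CUE_WORDS
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_utterances, self.n_labeled, self.n_single_word) < 0:
            raise ConfigurationError("counts must be non-negative")
        if not self.n_single_word <= self.n_labeled <= self.n_utterances:
            raise ConfigurationError(
                "need n_single_word <= n_labeled <= n_utterances, got "
                f"{self.n_single_word}/{self.n_labeled}/{self.n_utterances}"
            )
        if self.n_labeled > 0 and not self.label_inventory:
            raise ConfigurationError("empty label inventory with n_labeled > 0")
        total = sum(self.frame_distribution.values())
        if self.frame_distribution and abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"frame_distribution sums to {total!r}, expected 1"
            )
        for p in (self.offframe_rate, self.offframe_label_final,
                  self.offframe_cue_preceded):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")

    @property
    def n_multiword(self) -> int:
        return self.n_labeled - self.n_single_word


@dataclass
class UtteranceSet:
    """A generated transcript with per-utterance ground truth.

    ``lines`` holds the transcript (one utterance per line, labels wrapped
    as ``<label:WORD>``); ``records`` holds parallel dicts with keys
    ``index, is_naming, is_single_word, frame, is_frequent, label``.
    This is a synthetic stand-in for the recorded free-play corpus.
    """

    lines: list[str]
    records: list[dict]
    config: CorpusConfig

    def to_text(self) -> str:
        return "\n".join(self.lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "transcript.txt").write_text(self.to_text(), encoding="utf-8")
        with (outdir / "ground_truth.jsonl").open("w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


def _offframe_event(
    rng: np.random.Generator, cfg: CorpusConfig
) -> tuple[list[str], str, list[str]]:
    """Random non-frequent frame; returns (pre_tokens, pattern, post_tokens)."""
    frequent = cfg.frame_distribution.keys()
    # the cue branch is decided once, before the collision-avoidance loop,
    # so the realized cue-preceded rate matches the configured probability
    cued = bool(cfg.offframe_cue_words) and rng.random() < cfg.offframe_cue_preceded
    for _ in range(200):
        n_pre = int(rng.integers(1, 4))
        pre = [FILLER_VOCAB[i] for i in rng.integers(0, len(FILLER_VOCAB), n_pre)]
        if cued:
            pre[-1] = cfg.offframe_cue_words[rng.integers(len(cfg.offframe_cue_words))]
        pattern = " ".join([*pre, OBJ])
        if pattern in frequent:
            continue
        tokens = list(pre)
        if rng.random() >= cfg.offframe_label_final:
            n_post = int(rng.integers(1, 4))
            post = [FILLER_VOCAB[i] for i in rng.integers(0, len(FILLER_VOCAB), n_post)]
        else:
            post = []
        return tokens, pattern, post
    raise RuntimeError("could not draw a non-frequent frame")


def generate_naming_corpus(config: CorpusConfig | None = None) -> UtteranceSet:
    """Generate a transcript with the configured composition, exactly.

    Counts are conserved for every seed: ``n_single_word`` bare labels,
    ``n_labeled - n_single_word`` multi-word naming events, and
    ``n_utterances - n_labeled`` filler utterances, shuffled together.
    """
    cfg = config or CorpusConfig()
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.label_inventory
    patterns = list(cfg.frame_distribution)
    probs = np.array([cfg.frame_distribution[p] for p in patterns], dtype=float)

    n_multi = cfg.n_multiword
    n_filler = cfg.n_utterances - cfg.n_labeled

    entries: list[tuple[str, dict]] = []

    # Multi-word naming events.
    if n_multi > 0 and not patterns and cfg.offframe_rate < 1.0:
        raise ConfigurationError("frame_distribution empty but frequent events requested")
    off_mask = rng.random(n_multi) < cfg.offframe_rate
    freq_idx = (
        rng.choice(len(patterns), size=n_multi, p=probs) if patterns and n_multi else
        np.zeros(n_multi, dtype=int)
    )
    lab_idx = rng.integers(0, len(labels), size=n_multi) if n_multi else []
    for j in range(n_multi):
        label = labels[lab_idx[j]]
        if off_mask[j]:
            pre, pattern, post = _offframe_event(rng, cfg)
            tokens = [*pre, f"<label:{label}>", *post]
            frequent = False
        else:
            pattern = patterns[freq_idx[j]]
            pre = pattern.split()[:-1]
            tokens = [*pre, f"<label:{label}>"]
            frequent = True
        entries.append(
            (
                " ".join(tokens),
                {"is_naming": True, "is_single_word": False,
                 "frame": pattern, "is_frequent": frequent, "label": label},
            )
        )

    # Single-word naming events.
    sw_idx = rng.integers(0, len(labels), size=cfg.n_single_word) if cfg.n_single_word else []
    for j in range(cfg.n_single_word):
        label = labels[sw_idx[j]]
        entries.append(
            (
                f"<label:{label}>",
                {"is_naming": True, "is_single_word": True,
                 "frame": None, "is_frequent": False, "label": label},
            )
        )

    # Filler utterances: closed vocabulary, geometric length with mean 4.
    if n_filler:
        lengths = np.minimum(rng.geometric(0.25, size=n_filler), 12)
        flat = rng.integers(0, len(FILLER_VOCAB), size=int(lengths.sum()))
        pos = 0
        for ln in lengths:
            toks = [FILLER_VOCAB[i] for i in flat[pos:pos + ln]]
            pos += ln
            entries.append(
                (
                    " ".join(toks),
                    {"is_naming": False, "is_single_word": False,
                     "frame": None, "is_frequent": False, "label": None},
                )
            )

    order = rng.permutation(len(entries))
    lines, records = [], []
    for new_i, old_i in enumerate(order):
        line, rec = entries[old_i]
        lines.append(line)
        records.append({"index": new_i, **rec})
    return UtteranceSet(lines, records, cfg)
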