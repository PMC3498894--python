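"""Build the artificial lexicon and the four language conditions.

Encodes the packaged 21-frame inventory into artificial words under each of
the four orderings (full / onset-only / position-only / control) and reports
the onset and offset label-context entropies per condition.  The inventory's
frames use 22 distinct word types, so the lexicon here spans all 60 CV
combinations (18 labels + 22 frame words demand exactly 60 syllables); the
57-syllable/38-word lexicon of the original materials is available through
the library defaults.  Languages are written to results/languages/.
"""

import argparse
import json
from pathlib import Path

from framelang import frames, language, streams

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "languages")
    args = ap.parse_args()

    table = frames.load_frequent_frames()
    cues = frames.infer_cue_set(table, 0.99)
    glosses = frames.frame_word_types(table)
    inv = language.build_syllable_inventory(seed=args.seed, n_syllables=60)
    lex = language.build_lexicon(
        inv, n_labels=18, n_frame=len(glosses),
        seed=args.seed, frame_glosses=glosses,
    )

    args.out.mkdir(parents=True, exist_ok=True)
    for cond in language.Condition:
        spec = language.encode_language(table, lex, cond, cues)
        path = args.out / f"language_{cond.value}.json"
        path.write_text(json.dumps(spec.to_dict(), indent=1) + "\n", encoding="utf-8")

    ent = streams.condition_entropies(table, cues)
    ent.to_csv(args.out / "context_entropies.csv", index=False)
    print(f"lexicon: {len(lex.words)} words over {len(inv.syllables)} syllables")
    print("label-context entropies (bits) per condition:")
    print(ent.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
    print(f"languages and entropies -> {args.out}")


if __name__ == "__main__":
    main()
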