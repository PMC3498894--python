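"""Run the ideal-observer learners across all four language conditions.

For each condition and each of several seeds, generates a full training
session and evaluates three count-based observers: a TP segmenter on the
2AFC items, a cross-situational argmax mapper on word-object co-occurrence,
and a cue-anchored mapper that uses only the token following an onset cue.
Writes per-seed accuracies to results/learners/accuracies.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from framelang import frames, language, learners, streams, trials

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-seeds", type=int, default=20)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "learners")
    args = ap.parse_args()

    table = frames.load_frequent_frames()
    cues = frames.infer_cue_set(table, 0.99)
    glosses = frames.frame_word_types(table)
    inv = language.build_syllable_inventory(seed=args.seed, n_syllables=60)
    lex = language.build_lexicon(inv, 18, len(glosses), seed=args.seed,
                                 frame_glosses=glosses)
    cue_forms = [lex.form_by_gloss[c] for c in cues.words]

    rows = []
    for cond in language.Condition:
        lang = language.encode_language(table, lex, cond, cues)
        for s in range(args.seed, args.seed + args.n_seeds):
            design = trials.generate_design(lang, table, seed=s)
            tp = streams.transitional_probabilities(design)
            seg = trials.build_segmentation_tests(lex, seed=s)
            rep = learners.simulate_segmentation_test(seg, tp, seed=s)
            cooc = streams.word_object_cooccurrence(design)
            xsit = learners.map_by_cooccurrence(cooc, lex.label_map, seed=s)
            cue = learners.cue_anchored_mapper(design, cue_forms, lex.label_map,
                                               seed=s)
            rows.append({
                "condition": cond.value, "seed": s,
                "seg_label": rep.accuracy("LABEL"),
                "seg_frame": rep.accuracy("FRAME"),
                "map_xsit": xsit.accuracy,
                "map_cue_anchored": cue.accuracy,
            })

    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "accuracies.csv", index=False)
    summary = df.groupby("condition").mean(numeric_only=True).drop(columns="seed")
    print(f"mean observer accuracy over {args.n_seeds} seeds:")
    print(summary.to_string(float_format=lambda x: f"{x:.3f}"))
    print(f"per-seed accuracies -> {args.out / 'accuracies.csv'}")


if __name__ == "__main__":
    main()
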