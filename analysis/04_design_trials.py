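"""Compose a training session and its test sets for one condition.

Apportions the 216 phrases over frames proportionally to their corpus
frequencies, pairs the 18 objects into 108 trials (12 appearances each),
fills the label slots, and builds the 72 segmentation and 18 mapping test
items.  Writes the session schedule, test sets, and a sample of synthesis
manifests (.pho) under results/design/<condition>/.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from framelang import frames, language, trials

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--condition", default="full",
                    choices=[c.value for c in language.Condition])
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--pho-trials", type=int, default=3,
                    help="number of trials to export .pho manifests for")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "design")
    args = ap.parse_args()

    cond = language.Condition(args.condition)
    table = frames.load_frequent_frames()
    cues = frames.infer_cue_set(table, 0.99)
    glosses = frames.frame_word_types(table)
    inv = language.build_syllable_inventory(seed=args.seed, n_syllables=60)
    lex = language.build_lexicon(inv, 18, len(glosses), seed=args.seed,
                                 frame_glosses=glosses)
    lang = language.encode_language(table, lex, cond, cues)
    design = trials.generate_design(lang, table, seed=args.seed)

    outdir = args.out / cond.value
    outdir.mkdir(parents=True, exist_ok=True)
    trials.session_schedule(design).to_csv(outdir / "schedule.csv", index=False)
    seg = trials.build_segmentation_tests(lex, seed=args.seed)
    maps = trials.build_mapping_tests(lex, seed=args.seed)
    (outdir / "segmentation_tests.json").write_text(
        json.dumps([asdict(i) for i in seg], indent=1) + "\n", encoding="utf-8")
    (outdir / "mapping_tests.json").write_text(
        json.dumps([asdict(i) for i in maps], indent=1) + "\n", encoding="utf-8")
    phos = trials.export_trial_phos(design, lex, outdir / "pho",
                                    limit=args.pho_trials)

    sched = trials.session_schedule(design)
    last = sched.iloc[-1]
    total_min = (last.onset_s + last.duration_s + 3.0) / 60.0
    print(f"{cond.value}: {len(design.trials)} trials, "
          f"{len(design.phrases)} phrases, session {total_min:.1f} min")
    print(f"{len(seg)} segmentation items, {len(maps)} mapping items, "
          f"{len(phos)} .pho manifests")
    print(f"outputs -> {outdir}")


if __name__ == "__main__":
    main()
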