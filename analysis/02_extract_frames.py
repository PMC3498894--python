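"""Extract naming frames from a transcript and summarize their structure.

Runs the windowed extraction on the synthetic corpus from step 01 (or any
transcript in the same format), tallies frames over multi-word naming
events, and reports: top-k coverage, the inferred onset cue set, and the two
structural regularities (label-final position, cue-preceded label).  Writes
the frame table to results/frames/frame_table.csv.
"""

import argparse
from pathlib import Path

from framelang import frames

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--transcript", type=Path,
        default=ROOT / "results" / "corpus" / "transcript.txt",
    )
    ap.add_argument("--top", type=int, default=21)
    ap.add_argument("--cue-mass", type=float, default=0.99)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "frames")
    args = ap.parse_args()

    lines = args.transcript.read_text(encoding="utf-8").splitlines()
    utts = frames.tokenize_corpus(lines)
    windows = frames.extract_windows(utts)
    multi = [w for w in windows if not w.is_single_word]
    table = frames.tally_frames(multi)

    args.out.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(args.out / "frame_table.csv", index=False)

    # the cue set is a property of the frequent frames; the two
    # regularities are then measured over the residual naming events
    k = min(args.top, len(table))
    top = frames.FrameTable(table.entries[:k], table.n_events)
    cues = frames.infer_cue_set(top, args.cue_mass)
    frequent = set(top.patterns)
    residual = [w for w in multi if w.pattern not in frequent]
    print(f"{len(windows)} naming events, {len(multi)} multi-word")
    print(f"{len(table)} distinct frames; top {k} cover "
          f"{frames.top_k_coverage(table, k):.2f}% of multi-word events")
    print(f"cue set at {args.cue_mass:.0%} of top-{k} mass: "
          f"{sorted(cues.words)} (mass {cues.mass:.3f})")
    if residual:
        reg = frames.regularity_stats(residual, cues)
        print(f"residual events ({len(residual)}): label-final "
              f"{reg.label_final:.1%}, cue-preceded {reg.cue_preceded:.1%}")
    print(f"frame table -> {args.out / 'frame_table.csv'}")


if __name__ == "__main__":
    main()
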