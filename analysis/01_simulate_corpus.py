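"""Generate the synthetic free-play naming corpus.

Emulates the documented composition of the recorded corpus — 3165 parental
utterances, 1624 containing a toy label, 672 of those single-word — with
multi-word naming events split between the 21 frequent frames (52.46% of
mass) and random non-frequent frames.  Writes the transcript and its ground
truth under results/corpus/.
"""

import argparse
from pathlib import Path

from framelang.corpus import CorpusConfig, generate_naming_corpus

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "corpus")
    args = ap.parse_args()

    cfg = CorpusConfig(seed=args.seed)
    corpus = generate_naming_corpus(cfg)
    corpus.write(args.out)

    naming = [r for r in corpus.records if r["is_naming"]]
    single = [r for r in naming if r["is_single_word"]]
    frequent = [r for r in naming if r["is_frequent"]]
    print(f"wrote {len(corpus.lines)} utterances to {args.out}")
    print(f"  naming events:        {len(naming)}")
    print(f"  single-word events:   {len(single)}")
    print(f"  multi-word events:    {len(naming) - len(single)}")
    print(f"  in a frequent frame:  {len(frequent)}")


if __name__ == "__main__":
    main()
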