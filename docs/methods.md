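# Methods

## The corpus model

The pipeline's input is a transcript of parental speech during free play
with labeled toys: one utterance per line, toy-label tokens marked as
`<label:word>`. Because the recorded corpus is not available, the
`framelang.corpus` generator emulates its documented composition. Its
defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_utterances` | 3165 | parental utterances |
| `n_labeled` | 1624 | utterances containing a toy label |
| `n_single_word` | 672 | bare single-word labelings |
| `frame_distribution` | 21-frame inventory, renormalized | frequent-frame probabilities among frequent events |
| `offframe_rate` | 1 − 0.5246 | probability a multi-word naming event uses a random non-frequent frame |
| `offframe_label_final` | 0.50 | label-final rate among non-frequent events |
| `offframe_cue_preceded` | 0.63 | cue-preceded rate among non-frequent events |
| `label_inventory` | 9 types | three toys in each of three toy sets |

The reported single-word share ("about 20%") is ambiguous between
672/3165 ≈ 21% and 672/1624 ≈ 41%; the generator therefore takes absolute
counts and defaults to the printed 3165/1624/672, sidestepping the
ambiguity. Frame percentages are interpreted with the multi-word naming
events (952) as denominator, which is what makes the 21 frequent frames sum
to 52.46% of "all naming events" and fixes `offframe_rate` at the residual
mass. Filler (non-naming) utterances are drawn from a closed 30-word
vocabulary, disjoint from the frame word types, with geometric lengths of
mean 4 tokens: fillers only need to exist; their internal statistics feed
no downstream stage. Each naming utterance carries exactly one label —
multi-label utterances are not modeled. Labels are dedicated marked word
types rather than inferred from orthography, mirroring the fact that the
original coders knew the taught toy labels.

What the generator deliberately does **not** emulate: prosody, audio, the
1-s-silence utterance segmentation of recordings, discourse coherence of
fillers, longitudinal or per-dyad structure, and Zipfian label frequencies
(labels are uniform). Tests passing on this corpus therefore certify the
extraction and design machinery, not robustness to those properties of real
speech.

## Frame extraction

A six-word window — three tokens on either side, padded with blanks at
utterance boundaries — is cut around every label occurrence and the label
replaced by `OBJ`. Frame *identity* for tallying is the pre-label triple
plus `OBJ`, because every frame in the reference inventory ends at the
label ("color is the OBJ" is the three-word tail of a longer utterance);
post-label slots are retained only for the regularity statistics. Leading
blanks are part of the identity, so "a OBJ" (utterance-initial) and "and a
OBJ" are distinct patterns; since blanks can only appear flush against the
utterance start, the blank-stripped display string is an equivalent key.
Tokenization lower-cases and strips punctuation (the inventory's mixed case
indicates case-insensitive matching). Ranking ties break lexicographically
for determinism.

The onset cue set is the smallest set of immediately-pre-label word types
reaching a mass threshold (default 99%) of the table, accumulated in
descending frequency order — which makes minimality automatic. On the
packaged inventory this yields {the, a, say, and}: "say" and "and" are
included because they immediately precede the label in "can you say OBJ"
and "and OBJ"; the membership is configurable. The inventory's 21 frames
contain 22 distinct non-OBJ word types; the package reports the extracted
count rather than forcing the materials' printed 20 (see Lexicon below).

## Lexicon and the 2×2 orderings

The syllable inventory samples 57 of the 60 CV combinations of 12
consonants × 5 vowels; words take syllables randomly, each syllable used at
most once overall, with half of each role CV and half CVCV, so word forms
carry no cue to their role. Single-use syllables also guarantee that no
concatenation of words reproduces another word's form, which is what makes
part-word foils well defined.

The default lexicon is 18 labels + 20 frame words, whose demand is exactly
57 syllables (19 CV + 19 CVCV). Because the extracted inventory has 22
frame word types, encoding all 21 frames verbatim requires 22 frame words
and hence 60 syllables (27 + 33); the analysis drivers do exactly that over
the full 60-combination inventory. Requesting 22 frame words from a
57-syllable inventory raises a capacity error by design — the printed
materials presumably merged or dropped two types, but no merger is
recoverable, so the package refuses to guess.

Each frame decomposes into pre-cue words `w1..wk`, the cue (the word
immediately before `OBJ`), and `OBJ`. The four orderings are:

* full: `w1 .. wk cue OBJ`
* onset-only: `w2 .. wk cue OBJ w1`
* position-only: `cue w1 .. wk OBJ`
* control: `cue w1 .. w(k-1) OBJ wk`

with two-word frames (k = 0) identical everywhere. These rules are
reverse-engineered: the design documentation fixes only one example frame
per condition plus the context entropies, and the rules above are the
minimal edits that reproduce the example row exactly and the checkable
entropies (full onset 1.455 ≈ 1.45; offsets 0 for the label-final
conditions; onset-only offset 3.502 ≈ 3.50; onset-only onset equal to
full's by construction). Two published cells — 2.71 for the no-cue onset
and 3.50 for the control offset — are *not* reproduced by these or any
minimal rule we could construct (we obtain 2.60 and 2.39); they are
reported by `streams.condition_entropies` but never asserted, and the
package treats them as unverifiable.

## Trials, tests, and timing

216 phrases are apportioned over frames by largest remainder on the frame
frequencies (remainder ties break by table rank), object pairs come from
configuration-model sampling (each of 18 objects contributes 12 stubs; a
whole shuffle is rejected if any pair is a self-pair; repeated pairs are
allowed, as only per-object counts are constrained), and frame-to-referent
assignment is unconstrained random. Segmentation foils concatenate the
first syllable of one bisyllabic word with the second of another within the
same role; 6 targets × 6 foils per role gives the 72 items with every
target and foil used equally often. Mapping tests present each of the 18
labels once with three distractors balanced to within one use across
objects (greedy least-used assignment, retried until balanced).

`.pho` manifests encode the synthesis timing — consonants 94 ms with a
200 Hz pitch point at 10 ms, vowels 292 ms with 221 Hz at 108 ms and
200 Hz at 292 ms, 1 ms between syllables, 20 ms utterance-final pause —
with pitch points expressed as percentages of phoneme duration, and an
identity phoneme map by default (a SAMPA table can be supplied). A
five-syllable phrase is nominally 1954 ms, matching the roughly-two-second
phrases of the original sessions; with 2 s lead-ins and 3 s post-phrase
silences a session runs just over 20 minutes.

## Stream statistics and ideal observers

Context entropies are computed from the continuous frame frequencies, not
from the integer-apportioned trial counts, so they are properties of the
language; computing them from a realized trial set instead is a one-line
variant (pass the realized frequencies to `context_distribution`).
"Binary entropy" is read as Shannon entropy in bits; published two-decimal
values are compared at ±0.02 absolute, since they are rounded and the
underlying corpus counts are unavailable.

Transitional probabilities are within-phrase syllable bigram conditionals;
bigrams never span phrase boundaries, and a conditional is defined over the
observed continuations of its left syllable. Word–object co-occurrence uses
token multiplicity, so a word's row always sums to its occurrence count
times two objects.

The learners are deliberately assumption-minimal count-based observers (no
memory decay, attention, or parametric choice model), because the behavioral
findings motivate but do not specify a learner: the TP segmenter answers
each 2AFC item by comparing aggregated internal TPs (min by default,
product available; ties flip a seeded coin); the cross-situational mapper
takes the argmax object per label; the cue-anchored mapper counts only the
token following each cue occurrence against the on-screen objects,
formalizing the idea of spotting the label inside a frame without
segmenting the rest. Because syllables are single-use, word-internal TPs in
any generated design are deterministic, so the TP observer is at ceiling in
every condition — the observers certify the *statistical sufficiency* of
each design's information, and the cue-adjacency contrast (perfect mapping
in cue-adjacent conditions, degraded otherwise), not human difficulty.

## Numerical and testing choices

Randomness everywhere flows through seeded `numpy` generators; identical
seeds give byte-identical outputs. Degenerate inputs fail loudly
(configuration errors for inconsistent counts, capacity errors for syllable
demand, decomposition errors for non-cue frames). The parameter-recovery
property (top-5 generating frames recovered in ≥ 18/20 seeds) is checked at
20 000 multi-word naming events per seed: the gap between the 5th and 6th
most frequent generating frames is only 0.4% of probability mass, so at the
corpus's natural 952 events the top-5 *set* is not statistically stable —
recovery at that scale is a property of the noise, not the extractor — and
a size where the generating order is resolvable is the meaningful test.
Other stochastic checks (binomial rate recovery, observer orderings) use
fixed seed ranges and three-standard-error or mean-comparison margins.

## Known limitations

* The reordering rules beyond the full condition are reconstructions
  constrained by one example and three checkable entropies; the two
  unreproduced published entropy cells mean the original position-only and
  control orderings may have differed per frame.
* The human results (segmentation and mapping accuracies, their
  correlations and ANOVAs) are out of scope; the ideal observers are not
  models of them.
* The synthetic corpus is a structural stand-in; claims about real
  child-directed speech rest on the original recordings, not on it.
* Audio is never synthesized; `.pho` manifests are the boundary.
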