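# retell

Analyses of **temporal compression in verbal retelling** and its neural
signature: when people recount a movie from memory, some utterances
pinpoint seconds ("she picked up the knife"), others summarize minutes
("they solved the case").  This package implements, as a tested and
reusable pipeline, the full chain from recall transcripts to brain maps:

1. **Utterance coding** — label each utterance *Temporally Precise*
   (describes ≤ 10 s of movie time) or *Summary* (> 10 s) from its
   micro-segment span; compute the temporal compression factor
   `TCF = 1 − words/second described` and per-scene **%Summary bias**
   (share of a scene's recalled content words coming from Summary
   utterances).
2. **Text validation** — embed movie annotations and utterances
   (deterministic hashed bag-of-words by default) and check that
   utterances resemble the segments they retell, with Summary retellings
   diverging more than Precise ones.
3. **Reinstatement** — within-subject pattern correlation between each
   movie micro-segment and the recall utterances describing it, split by
   condition, with permutation + FDR group maps.
4. **Memory transformation** — scene-level between-subject similarity:
   movie-to-recall (MR) and recall-to-recall (RR) correlations against
   the averaged other subjects, reliability-masked by scene-label
   permutation; the transformation score **T = RR − MR** is positive
   where recall patterns agree more with each other than with the
   original movie patterns, i.e. where encoding-to-recall change is
   consistent across people.
5. **Linking** — per parcel, correlate each subject's scene-level
   %Summary bias with the group per-scene T (random-effects t-test,
   FDR): do more-summarized scenes transform more?

Because the original scanner data are an external download, the package
ships a first-class **synthetic study generator** that emulates the
study conditions (17 subjects; 50 scenes of 57.7 ± 41.6 s; ~4-s
micro-segments; TR 1.5 s; ~14-word utterances with a roughly
half/quarter/quarter precise/summary/other mixture) under two generative accounts of
encoding-to-recall change: idiosyncratic noise only (Model 1) versus an
added event-specific shift shared across subjects (Model 2), optionally
scaled by each scene's summary bias in "linked" parcels.  Closed-form
expectations for MR, RR, T and reinstatement under this model serve as
independent oracles for the test suite.  See `docs/methods.md`.

## Worked example

The numbered drivers under `analysis/` run the whole study on one
synthetic dataset (6 parcels: 0–2 linked, 3–5 unlinked) and write their
tables under `results/`:

```bash
cd analysis
python 01_simulate_study.py
python 02_code_transcripts.py
...
python 05_transformation.py
```

`05_transformation.py` prints (abridged):

```
parcel  MR     RR     T      in_mask  positive_T  linked?
     0  0.499  0.789  +0.290     True        True  True
     1  0.502  0.791  +0.289     True        True  True
     2  0.499  0.789  +0.291     True        True  True
     3  0.679  0.681  +0.001     True        True  False
     4  0.681  0.681  +0.000     True        True  False
     5  0.678  0.678  -0.000     True       False  False
```

Parcels carrying a shared event-specific recall shift (0–2) show
RR clearly above MR — a positive transformation score — while parcels
whose encoding-to-recall change is pure noise (3–5) sit at T ≈ 0 even
though both their MR and RR are individually strong.  The linking driver
(`06_link_bias_transformation.py`) then recovers which parcels' shifts
scale with summarization:

```
parcel  t       q       significant  linked?
     0  +6.59  0.0000         True  True
     1  +6.58  0.0000         True  True
     2  +5.52  0.0001         True  True
     3  +0.05  0.9607        False  False
     ...
detected linked parcels: [0, 1, 2] (ground truth [0, 1, 2])
```

A `retell` command-line interface exposes the same stages
(`retell simulate`, `code-utterances`, `text-sim`, `reinstate`,
`transform`, `link`) for on-disk TSV/NPZ/NIfTI data.

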