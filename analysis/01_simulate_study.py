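"""Generate the synthetic study and summarise its behavioural shape.

Writes the movie segmentation and per-subject recall transcripts (text
formats only; neural runs are regenerated in memory by later drivers)
and prints how the simulated study compares with the naturalistic
free-recall conditions it emulates: ~50 scenes averaging ~58 s, ~4-s
micro-segments, ~200 utterances per subject of ~14 words, with roughly
half Temporally Precise, a quarter Summary and a quarter Other.
"""

import json
import os
from collections import Counter

import numpy as np

from retell import io_formats as iof
from study_config import STUDY, load_study, results_path

ds = load_study()
seg, transcripts = ds.segmentation, ds.transcripts

out_dir = results_path("synthetic_study")
os.makedirs(os.path.join(out_dir, "transcripts"), exist_ok=True)
iof.write_segmentation(seg, os.path.join(out_dir, "segmentation.tsv"))
for t in transcripts:
    iof.write_transcript(t, os.path.join(out_dir, "transcripts",
                                         f"{t.subject_id}.tsv"))
with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
    json.dump({
        "model": ds.truth.model,
        "linked_parcels": sorted(ds.truth.linked_parcels),
        "scene_shift_magnitude": {str(k): v for k, v in
                                  ds.truth.scene_shift_magnitude.items()},
    }, fh, indent=1)

scene_durs = [sc.duration_s for sc in seg.scenes]
seg_durs = [s.duration_s for s in seg.micro_segments]
utt_counts = [len(t.utterances) for t in transcripts]
labels = Counter(u.label.value for t in transcripts for u in t.utterances)
total = sum(labels.values())
words = [u.content_word_count for t in transcripts for u in t.utterances
         if u.content_word_count]

print(f"study written to {out_dir}")
print(f"scenes: {len(seg.scenes)} "
      f"(duration {np.mean(scene_durs):.1f} +/- {np.std(scene_durs):.1f} s)")
print(f"micro-segments: {len(seg.micro_segments)} "
      f"(duration {np.mean(seg_durs):.2f} +/- {np.std(seg_durs):.2f} s)")
print(f"utterances per subject: {np.mean(utt_counts):.1f} "
      f"+/- {np.std(utt_counts):.1f}; {np.mean(words):.1f} content words each")
print("label mixture: " + ", ".join(
    f"{k} {100 * v / total:.1f}%" for k, v in sorted(labels.items())))
print(f"neural runs: {STUDY.n_parcels} parcels x "
      f"{STUDY.features_per_parcel} features, TR {STUDY.tr_s} s "
      f"(regenerated in memory by later drivers)")
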