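"""Link summarization behaviour to neural memory transformation.

In every parcel with a positive transformation score, each subject's
scene-level %Summary bias is correlated with the group per-scene
transformation value; subject correlations go into a random-effects
t-test with FDR across parcels.  Ground truth says parcels 0-2 are
linked (shift scales with bias) and 3-5 are not.
"""

import numpy as np
import pandas as pd

from retell import coding, linking as lk, transformation as tr
from retell.io_formats import Parcellation
from study_config import ANALYSIS, STUDY, load_study, results_path, rng

ds = load_study()
sps = tr.build_scene_pattern_set(ds.neural, ds.transcripts, ds.segmentation,
                                 ANALYSIS)
res = tr.transformation_analysis(sps, ANALYSIS, rng(6))
behavior = coding.behavior_table(
    [coding.annotate_transcript(t, ds.segmentation, ANALYSIS)
     for t in ds.transcripts], ds.segmentation, ANALYSIS)
link = lk.link_bias_transformation(behavior, res, ANALYSIS)
link.parcels.to_csv(results_path("link.tsv"), sep="\t", index=False,
                    float_format="%.12g")

print("wrote results/link.tsv")
print("parcel  t       q       significant  linked?")
for row in link.parcels.itertuples():
    print(f"{row.parcel_id:>6}  {row.t:+.2f}  {row.q:.4f}  "
          f"{str(bool(row.significant)):>11}  "
          f"{row.parcel_id in ds.truth.linked_parcels}")
detected = set(link.parcels.loc[link.parcels.significant
                                & (link.parcels.t > 0), "parcel_id"])
truth = set(ds.truth.linked_parcels)
print(f"detected linked parcels: {sorted(detected)} "
      f"(ground truth {sorted(truth)})")
if detected - truth:
    print(f"false positives in this realisation: {sorted(detected - truth)} "
          "(the FDR level bounds their long-run rate, not any single study)")
if truth - detected:
    print(f"missed linked parcels: {sorted(truth - detected)}")

# where do the detected parcels sit? (toy network assignment for the demo)
networks = ["Default", "Default", "Frontoparietal", "Visual", "DorsAttn",
            "SomMot"]
parcellation = Parcellation([(i, networks[i], f"parcel_{i}")
                             for i in range(STUDY.n_parcels)])
tally = lk.network_tally(detected, parcellation)
print(tally.to_string(index=False))
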