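"""Scene-level inter-subject similarity and memory transformation.

Averages TRs within scenes, computes movie-to-recall (MR) and
recall-to-recall (RR) similarity against the averaged other subjects,
masks parcels by scene-label permutation + FDR, and scores
transformation T = RR - MR.  Linked parcels (0-2) carry an
event-specific shared recall shift scaling with scene summary bias, so
they should show RR > MR; unlinked parcels (3-5) have no shared shift
and should sit near T = 0.
"""

import pandas as pd

from retell import synthetic as syn, transformation as tr
from study_config import ANALYSIS, STUDY, load_study, results_path, rng

ds = load_study()
sps = tr.build_scene_pattern_set(ds.neural, ds.transcripts, ds.segmentation,
                                 ANALYSIS)
res = tr.transformation_analysis(sps, ANALYSIS, rng(5))
res.parcels.to_csv(results_path("transformation.tsv"), sep="\t", index=False,
                   float_format="%.12g")
scene_rows = [(pid, int(k), v) for pid, series in res.scene_t.items()
              for k, v in series.items()]
pd.DataFrame(scene_rows, columns=["parcel_id", "scene_id", "t"]).to_csv(
    results_path("transformation_scene_t.tsv"), sep="\t", index=False,
    float_format="%.12g")

print("wrote results/transformation.tsv and results/transformation_scene_t.tsv")
print("parcel  MR     RR     T      in_mask  positive_T  linked?")
for row in res.parcels.itertuples():
    linked = row.parcel_id in ds.truth.linked_parcels
    print(f"{row.parcel_id:>6}  {row.mr:.3f}  {row.rr:.3f}  "
          f"{row.t_score:+.3f}  {str(row.in_reliability_mask):>7}  "
          f"{str(row.positive_t):>10}  {linked}")
print(f"reliability mask: {int(res.parcels.in_reliability_mask.sum())}"
      f"/{len(res.parcels)} parcels; positive transformation: "
      f"{len(res.positive_parcels)}")
print("linked parcels transform (RR > MR); unlinked parcels do not -- the "
      "shared event-specific shift, not noise, drives T")
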