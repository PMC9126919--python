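"""Shared configuration for the numbered analysis drivers.

One synthetic study, regenerated deterministically by each driver from
the same seed so that no large neural arrays need to live on disk.  Six
parcels are simulated: in parcels 0-2 the event-specific recall shift
scales with the scene's group-mean summary bias (linked); parcels 3-5
carry no shared shift (unlinked).
"""

import os

import numpy as np

from retell import synthetic as syn
from retell.io_formats import AnalysisConfig

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

STUDY = syn.GeneratorConfig(
    seed=2026,
    n_parcels=6,
    features_per_parcel=150,
    linked_parcel_ids=(0, 1, 2),
    dtype="float32",
)

ANALYSIS = AnalysisConfig(lag_trs=0, n_perm=500)


def load_study() -> syn.SyntheticDataset:
    return syn.simulate_dataset(STUDY)


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)


def rng(offset: int = 0) -> np.random.Generator:
    return np.random.default_rng(STUDY.seed + offset)
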