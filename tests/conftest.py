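import numpy as np
import pytest

from retell import synthetic as syn
from retell.io_formats import (
    AnalysisConfig,
    Label,
    MicroSegment,
    MovieSegmentation,
    RecallTranscript,
    Utterance,
)


@pytest.fixture
def acfg():
    return AnalysisConfig(lag_trs=0, n_perm=100)


@pytest.fixture
def seg_small():
    """Two scenes, five micro-segments; hand-set durations."""
    return MovieSegmentation([
        MicroSegment(1, 1, 0.0, 4.0, "alpha beta gamma"),
        MicroSegment(2, 1, 4.0, 9.0, "delta epsilon zeta"),
        MicroSegment(3, 1, 9.0, 12.0, "eta theta iota"),
        MicroSegment(4, 2, 12.0, 18.0, "kappa lam mu"),
        MicroSegment(5, 2, 18.0, 25.0, "nu xi omicron"),
    ])


def make_utterance(uid=1, label=Label.PRECISE, start=1, end=1, text="alpha beta",
                   onset=None, subject="sub-01"):
    onset = float(uid * 10) if onset is None else onset
    return Utterance(subject_id=subject, utterance_id=uid, onset_s=onset,
                     offset_s=onset + 5.0, text=text, start_segment=start,
                     end_segment=end, label=label)


@pytest.fixture
def transcript_small(seg_small):
    """One summary spanning scene 1, one precise inside it, one other."""
    return RecallTranscript("sub-01", [
        make_utterance(1, Label.SUMMARY, 1, 3, "alpha delta eta"),
        make_utterance(2, Label.PRECISE, 2, 2, "delta epsilon"),
        Utterance(subject_id="sub-01", utterance_id=3, onset_s=30.0,
                  offset_s=34.0, text="um something else", start_segment=None,
                  end_segment=None, label=Label.OTHER),
        make_utterance(4, Label.PRECISE, 4, 4, "kappa lam", onset=40.0),
    ])


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small end-to-end synthetic study shared across structural tests."""
    cfg = syn.GeneratorConfig(seed=42, n_scenes=10, n_parcels=2,
                              features_per_parcel=30)
    return cfg, syn.simulate_dataset(cfg)
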