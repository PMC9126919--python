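"""Temporal-precision coding of recall utterances.

An utterance that retells movie content is mapped to a span of movie
micro-segments.  If the described movie time exceeds a threshold (10 s by
default) the utterance is a *Summary*; otherwise it is *Temporally
Precise*.  From content-word counts this module derives the temporal
compression factor (TCF = 1 - words / described seconds), per-scene
%Summary bias (the proportion of a scene's recalled content words coming
from Summary utterances), and descriptive overlap/agreement statistics.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AnalysisConfig,
    FormatError,
    Label,
    MovieSegmentation,
    RecallTranscript,
    Utterance,
)

__all__ = [
    "count_content_words",
    "described_duration",
    "auto_label",
    "compute_tcf",
    "annotate_transcript",
    "scene_summary_bias",
    "behavior_table",
    "scene_mean_tcf",
    "summary_precise_overlap",
    "label_agreement",
    "utterance_scenes",
]

_PUNCT = re.compile(r"[^\w\s']", flags=re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return _PUNCT.sub(" ", text.lower()).split()


def count_content_words(text: str, stopwords: Iterable[str] = (),
                        nonwords: Iterable[str] = ()) -> int:
    """Number of tokens left after dropping stop words and non-words."""
    drop = set(stopwords) | set(nonwords)
    return sum(1 for tok in tokenize(text) if tok not in drop)


def described_duration(u: Utterance, seg: MovieSegmentation) -> float:
    """Total movie seconds covered by the utterance's segment span."""
    if not u.has_range:
        raise FormatError(
            f"utterance {u.utterance_id} has no segment range")
    return float(sum(s.duration_s
                     for s in seg.segment_range(u.start_segment, u.end_segment)))


def auto_label(u: Utterance, seg: MovieSegmentation,
               cfg: AnalysisConfig) -> Label:
    """Automatic temporal-precision label from described movie time.

    Summary when the summed duration of the labelled movie segments
    exceeds ``cfg.threshold_s``; ties at exactly the threshold follow
    ``cfg.boundary_rule`` (default: Precise).
    """
    if not u.has_range:
        return Label.OTHER
    dur = described_duration(u, seg)
    if dur > cfg.threshold_s:
        return Label.SUMMARY
    if dur < cfg.threshold_s:
        return Label.PRECISE
    return Label.PRECISE if cfg.boundary_rule == "LE_PRECISE" else Label.SUMMARY


def compute_tcf(u: Utterance, seg: MovieSegmentation,
                stopwords: Iterable[str] = (),
                nonwords: Iterable[str] = ()) -> float:
    """Temporal compression factor: 1 - content words / described seconds.

    Higher values mean fewer words per second of retold movie time, i.e.
    more compression; 1 is the upper bound, negative values are possible
    for very verbose retellings.
    """
    if not u.has_range:
        return float("nan")
    dur = described_duration(u, seg)
    if dur <= 0:
        raise FormatError(
            f"utterance {u.utterance_id}: zero described duration")
    words = (u.content_word_count if u.content_word_count is not None
             else count_content_words(u.text, stopwords, nonwords))
    return 1.0 - words / dur


def annotate_transcript(t: RecallTranscript, seg: MovieSegmentation,
                        cfg: AnalysisConfig,
                        relabel: bool = False) -> RecallTranscript:
    """Fill content_word_count, TCF, and (optionally) automatic labels."""
    out = []
    for u in t.utterances:
        label = auto_label(u, seg, cfg) if relabel else u.label
        words = count_content_words(u.text, cfg.stopwords, cfg.nonwords)
        tcf = None
        if u.has_range and described_duration(u, seg) > 0:
            tcf = 1.0 - words / described_duration(u, seg)
        out.append(Utterance(
            subject_id=u.subject_id, utterance_id=u.utterance_id,
            onset_s=u.onset_s, offset_s=u.offset_s, text=u.text,
            start_segment=u.start_segment, end_segment=u.end_segment,
            label=label, content_word_count=words, tcf=tcf))
    return RecallTranscript(subject_id=t.subject_id, utterances=out)


def utterance_scenes(u: Utterance, seg: MovieSegmentation) -> list[int]:
    """Scene ids touched by the utterance's segment span (empty for OTHER)."""
    if not u.has_range:
        return []
    return sorted({s.scene_id
                   for s in seg.segment_range(u.start_segment, u.end_segment)})


_BEHAVIOR_COLUMNS = [
    "subject_id", "scene_id", "words_summary", "words_precise",
    "words_other", "summary_bias", "mean_tcf", "recalled",
]


def scene_summary_bias(t: RecallTranscript, seg: MovieSegmentation,
                       cfg: AnalysisConfig) -> pd.DataFrame:
    """Per-scene behaviour rows for one subject.

    Content words of each utterance are credited in full to every scene
    its span touches.  summary_bias = summary words / (summary + precise
    words); words from Other utterances are tallied but excluded from the
    denominator.  A scene counts as recalled if any non-Other utterance
    touches it.
    """
    words = {Label.SUMMARY: {}, Label.PRECISE: {}, Label.OTHER: {}}
    tcfs: dict[int, list[float]] = {}
    for u in t.utterances:
        n = (u.content_word_count if u.content_word_count is not None
             else count_content_words(u.text, cfg.stopwords, cfg.nonwords))
        for scene_id in utterance_scenes(u, seg):
            words[u.label][scene_id] = words[u.label].get(scene_id, 0) + n
            if u.label is not Label.OTHER:
                tcf = (u.tcf if u.tcf is not None
                       else compute_tcf(u, seg, cfg.stopwords, cfg.nonwords))
                tcfs.setdefault(scene_id, []).append(tcf)
    rows = []
    for scene in seg.scenes:
        k = scene.scene_id
        ws = words[Label.SUMMARY].get(k, 0)
        wp = words[Label.PRECISE].get(k, 0)
        wo = words[Label.OTHER].get(k, 0)
        recalled = (ws + wp) > 0 or k in tcfs
        bias = ws / (ws + wp) if (ws + wp) > 0 else np.nan
        mean_tcf = float(np.mean(tcfs[k])) if k in tcfs else np.nan
        rows.append((t.subject_id, k, ws, wp, wo, bias, mean_tcf, recalled))
    return pd.DataFrame(rows, columns=_BEHAVIOR_COLUMNS)


def behavior_table(transcripts: Sequence[RecallTranscript],
                   seg: MovieSegmentation,
                   cfg: AnalysisConfig) -> pd.DataFrame:
    """Stack scene_summary_bias over subjects."""
    return pd.concat(
        [scene_summary_bias(t, seg, cfg) for t in transcripts],
        ignore_index=True)


def scene_mean_tcf(t: RecallTranscript, seg: MovieSegmentation,
                   cfg: AnalysisConfig | None = None) -> dict[int, float]:
    """Scene-level TCF: mean over non-Other utterances touching the scene."""
    cfg = cfg or AnalysisConfig()
    out: dict[int, list[float]] = {}
    for u in t.utterances:
        if u.label is Label.OTHER or not u.has_range:
            continue
        tcf = (u.tcf if u.tcf is not None
               else compute_tcf(u, seg, cfg.stopwords, cfg.nonwords))
        for scene_id in utterance_scenes(u, seg):
            out.setdefault(scene_id, []).append(tcf)
    return {k: float(np.mean(v)) for k, v in out.items()}


def summary_precise_overlap(t: RecallTranscript) -> float:
    """Fraction of Summary utterances whose span intersects any Precise span."""
    precise_segments: set[int] = set()
    for u in t.utterances:
        if u.label is Label.PRECISE and u.has_range:
            precise_segments.update(range(u.start_segment, u.end_segment + 1))
    summaries = [u for u in t.utterances
                 if u.label is Label.SUMMARY and u.has_range]
    if not summaries:
        return float("nan")
    hits = sum(
        1 for u in summaries
        if precise_segments.intersection(range(u.start_segment, u.end_segment + 1)))
    return hits / len(summaries)


def label_agreement(a: Sequence[Label], b: Sequence[Label]) -> float:
    """Fraction of positions where two label sequences agree exactly."""
    if len(a) != len(b):
        raise FormatError(
            f"label sequences differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise FormatError("empty label sequences")
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)
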