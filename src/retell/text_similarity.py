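"""Text similarity between recall utterances and movie annotations.

Validates the temporal-precision rubric: an utterance's embedding should
resemble the annotations of the micro-segments it retells (matched) more
than annotations of other segments (mismatched), and Summary utterances
— which compress and paraphrase — should resemble their sources less
than Temporally Precise ones.

Embedders implement a minimal contract (name, dim, embed).  The built-in
model is a deterministic signed-hash bag of content words: no downloads,
identical text -> identical vector, disjoint vocabularies -> near-
orthogonal vectors.  A production sentence encoder (e.g. a 512-d
Universal Sentence Encoder) can be plugged in behind the same contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import stats
from .io_formats import (
    AnalysisConfig,
    FormatError,
    Label,
    MovieSegmentation,
    RecallTranscript,
    Utterance,
    DEFAULT_STOPWORDS,
    DEFAULT_NONWORDS,
)
from .coding import tokenize

__all__ = [
    "EmbeddingModel",
    "toy_embedder",
    "cosine",
    "utterance_similarity",
    "matched_vs_mismatched",
    "group_text_contrast",
]


@dataclass(frozen=True)
class EmbeddingModel:
    name: str
    dim: int
    embed: Callable[[Sequence[str]], np.ndarray]


def _token_index_sign(token: str, dim: int) -> tuple[int, float]:
    h = int.from_bytes(hashlib.blake2b(token.encode(), digest_size=8).digest(),
                       "big")
    return h % dim, 1.0 if (h >> 63) & 1 else -1.0


def toy_embedder(dim: int = 512,
                 stopwords: Sequence[str] = DEFAULT_STOPWORDS,
                 nonwords: Sequence[str] = DEFAULT_NONWORDS) -> EmbeddingModel:
    """Deterministic L2-normalised signed-hash bag-of-content-words model."""
    drop = set(stopwords) | set(nonwords)

    def embed(texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), dim))
        for i, text in enumerate(texts):
            for tok in tokenize(text):
                if tok in drop:
                    continue
                j, sign = _token_index_sign(tok, dim)
                out[i, j] += sign
            norm = np.linalg.norm(out[i])
            if norm > 0:
                out[i] /= norm
        return out

    return EmbeddingModel(name=f"hashed-bow-{dim}", dim=dim, embed=embed)


def _normalize_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return m / norms


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.dot(a, b) / (na * nb))


def utterance_similarity(u: Utterance, seg: MovieSegmentation,
                         model: EmbeddingModel) -> float:
    """Mean cosine between the utterance and each covered segment annotation."""
    if not u.has_range:
        return float("nan")
    segments = seg.segment_range(u.start_segment, u.end_segment)
    vecs = model.embed([u.text] + [s.annotation for s in segments])
    sims = [cosine(vecs[0], vecs[i + 1]) for i in range(len(segments))]
    return float(np.nanmean(sims)) if sims else float("nan")


_RESULT_COLUMNS = ["subject_id", "condition", "matched_mean",
                   "mismatched_mean", "difference", "n_utterances"]


def matched_vs_mismatched(t: RecallTranscript, seg: MovieSegmentation,
                          model: EmbeddingModel,
                          rng: np.random.Generator | None = None,
                          subsample: int | None = None) -> pd.DataFrame:
    """Matched vs mismatched annotation similarity per recall type.

    matched: mean over utterances of the composite (per-covered-segment
    averaged) cosine.  mismatched: mean cosine between each utterance and
    the segments *outside* its span — all of them by default, or a seeded
    subsample of fixed size for large corpora.
    """
    all_segments = seg.micro_segments
    seg_vecs = _normalize_rows(model.embed([s.annotation for s in all_segments]))
    seg_ids = np.array([s.segment_id for s in all_segments])
    rows = []
    for condition in (Label.PRECISE, Label.SUMMARY):
        utts = [u for u in t.utterances if u.label is condition and u.has_range]
        if not utts:
            continue
        utt_vecs = _normalize_rows(model.embed([u.text for u in utts]))
        matched, mismatched = [], []
        for i, u in enumerate(utts):
            covered = (seg_ids >= u.start_segment) & (seg_ids <= u.end_segment)
            sims = seg_vecs @ utt_vecs[i]
            m = sims[covered]
            matched.append(float(np.mean(m)))
            out_idx = np.flatnonzero(~covered)
            if out_idx.size == 0:
                continue
            if subsample is not None and out_idx.size > subsample:
                if rng is None:
                    raise FormatError("subsampling requires an rng")
                out_idx = rng.choice(out_idx, size=subsample, replace=False)
            mismatched.append(float(np.mean(sims[out_idx])))
        matched_mean = float(np.mean(matched))
        mismatched_mean = float(np.mean(mismatched)) if mismatched else np.nan
        rows.append((t.subject_id, condition.value, matched_mean,
                     mismatched_mean, matched_mean - mismatched_mean,
                     len(utts)))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def group_text_contrast(results: pd.DataFrame) -> dict[str, stats.GroupStat]:
    """Group-level paired contrasts over per-subject similarity means.

    Returns paired t-tests of matched vs mismatched within each recall
    type, and of matched(PRECISE) vs matched(SUMMARY).
    """
    subjects = results["subject_id"].unique()
    if len(subjects) < 2:
        raise FormatError("group contrast requires >= 2 subjects")
    wide = results.pivot(index="subject_id", columns="condition")
    out: dict[str, stats.GroupStat] = {}
    for condition in ("PRECISE", "SUMMARY"):
        if ("matched_mean", condition) not in wide.columns:
            continue
        sub = wide[[("matched_mean", condition),
                    ("mismatched_mean", condition)]].dropna()
        if len(sub) >= 2:
            out[f"matched_vs_mismatched_{condition}"] = stats.paired_t(
                sub[("matched_mean", condition)],
                sub[("mismatched_mean", condition)])
    if {("matched_mean", "PRECISE"),
            ("matched_mean", "SUMMARY")} <= set(wide.columns):
        sub = wide[[("matched_mean", "PRECISE"),
                    ("matched_mean", "SUMMARY")]].dropna()
        if len(sub) >= 2:
            out["matched_precise_vs_summary"] = stats.paired_t(
                sub[("matched_mean", "PRECISE")],
                sub[("matched_mean", "SUMMARY")])
    return out
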