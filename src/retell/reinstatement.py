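"""Within-subject encoding-to-recall reinstatement at the micro-segment level.

For each movie micro-segment later retold by a subject, the segment's
movie-viewing pattern is correlated with the (averaged) pattern of the
recall utterances that describe it, separately for segments retold in a
Temporally Precise versus a Summarized manner.  A segment described by
both kinds of utterance receives two scores.  Group statistics combine
one-sample and paired t-tests over subject means with a permutation null
that shuffles, within each subject, the assignment of utterance patterns
to segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .io_formats import (
    AnalysisConfig,
    Label,
    MovieSegmentation,
    ParcelTimeseries,
    RecallTranscript,
)

__all__ = [
    "interval_pattern",
    "SubjectSegmentPatterns",
    "subject_segment_patterns",
    "segment_reinstatement",
    "condition_means",
    "reinstatement_group_stats",
]

_CONDITIONS = (Label.PRECISE, Label.SUMMARY)


def _interval_indices(n_trs: int, tr_s: float, onset_s: float, offset_s: float,
                      lag_trs: int) -> np.ndarray:
    """TR indices i with onset <= (i - lag) * tr < offset; midpoint fallback.

    If the interval straddles no TR start, the single TR containing the
    interval midpoint is used.  An interval entirely outside the run is an
    error.
    """
    if offset_s <= onset_s:
        raise ValueError(f"empty interval [{onset_s}, {offset_s})")
    times = (np.arange(n_trs) - lag_trs) * tr_s
    idx = np.flatnonzero((times >= onset_s - 1e-9) & (times < offset_s - 1e-9))
    if idx.size == 0:
        if offset_s <= -lag_trs * tr_s or onset_s >= (n_trs - lag_trs) * tr_s:
            raise ValueError(
                f"interval [{onset_s}, {offset_s}) lies outside the run "
                f"({n_trs} TRs at {tr_s} s, lag {lag_trs})")
        mid = 0.5 * (onset_s + offset_s)
        i = lag_trs + int(np.floor(mid / tr_s))
        idx = np.array([min(max(i, 0), n_trs - 1)])
    return idx


def interval_pattern(ts: ParcelTimeseries, onset_s: float, offset_s: float,
                     lag_trs: int = 0) -> dict[int, np.ndarray]:
    """Lag-shifted TR-average pattern over an interval, per parcel."""
    idx = _interval_indices(ts.n_trs, ts.tr_s, onset_s, offset_s, lag_trs)
    return {pid: arr[:, idx].mean(axis=1, dtype=np.float64)
            for pid, arr in ts.data.items()}


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding rows of two (n, F) matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", ac, bc)
    den = np.sqrt(np.einsum("ij,ij->i", ac, ac)
                  * np.einsum("ij,ij->i", bc, bc))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _cross_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between all row pairs of (n, F) and (m, F) matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1, keepdims=True)
    nb = np.linalg.norm(bc, axis=1, keepdims=True)
    na[na == 0] = np.nan
    nb[nb == 0] = np.nan
    return (ac / na) @ (bc / nb).T


@dataclass
class SubjectSegmentPatterns:
    """Per-subject movie and averaged-recall patterns per retold segment.

    ``parcels[parcel_id][condition]`` holds ``(segment_ids, movie, recall)``
    where both matrices are (n_segments, features); recall rows are the
    average over that condition's utterances covering the segment.
    """

    subject_id: str
    parcels: dict[int, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]]


def subject_segment_patterns(movie: ParcelTimeseries, recall: ParcelTimeseries,
                             t: RecallTranscript, seg: MovieSegmentation,
                             cfg: AnalysisConfig) -> SubjectSegmentPatterns:
    if set(movie.data) != set(recall.data):
        raise ValueError("movie and recall runs cover different parcels")
    # which utterances of each condition cover each segment
    cover: dict[Label, dict[int, list[int]]] = {c: {} for c in _CONDITIONS}
    utts = [u for u in t.utterances if u.label in _CONDITIONS and u.has_range]
    utt_patterns = [interval_pattern(recall, u.onset_s, u.offset_s, cfg.lag_trs)
                    for u in utts]
    for ui, u in enumerate(utts):
        for sid in range(u.start_segment, u.end_segment + 1):
            seg.segment(sid)  # raises on unknown ids
            cover[u.label].setdefault(sid, []).append(ui)
    parcels: dict[int, dict[str, tuple]] = {pid: {} for pid in movie.data}
    for condition in _CONDITIONS:
        seg_ids = sorted(cover[condition])
        if not seg_ids:
            continue
        movie_pats = [interval_pattern(movie, seg.segment(sid).onset_s,
                                       seg.segment(sid).offset_s, cfg.lag_trs)
                      for sid in seg_ids]
        for pid in movie.data:
            mov = np.stack([mp[pid] for mp in movie_pats])
            rec = np.stack([
                np.mean([utt_patterns[ui][pid] for ui in cover[condition][sid]],
                        axis=0)
                for sid in seg_ids])
            parcels[pid][condition.value] = (np.array(seg_ids), mov, rec)
    return SubjectSegmentPatterns(subject_id=t.subject_id, parcels=parcels)


_ROW_COLUMNS = ["subject_id", "parcel_id", "segment_id", "condition", "r"]


def segment_reinstatement(movie: ParcelTimeseries, recall: ParcelTimeseries,
                          t: RecallTranscript, seg: MovieSegmentation,
                          cfg: AnalysisConfig) -> pd.DataFrame:
    """Per-segment movie-recall correlation rows for one subject."""
    sp = subject_segment_patterns(movie, recall, t, seg, cfg)
    rows = []
    for pid, conds in sp.parcels.items():
        for condition, (seg_ids, mov, rec) in conds.items():
            r = _rowwise_corr(mov, rec)
            rows.extend((sp.subject_id, pid, int(s), condition, float(v))
                        for s, v in zip(seg_ids, r))
    return pd.DataFrame(rows, columns=_ROW_COLUMNS)


def condition_means(rows: pd.DataFrame, fisher_z: bool = False) -> pd.DataFrame:
    """Mean r per subject x parcel x condition (raw r by default)."""
    def agg(x):
        if fisher_z:
            return float(np.tanh(np.mean(np.arctanh(np.clip(x, -1 + 1e-12,
                                                            1 - 1e-12)))))
        return float(np.mean(x))

    out = (rows.groupby(["subject_id", "parcel_id", "condition"])["r"]
           .agg(agg).rename("mean_r").reset_index())
    n = (rows.groupby(["subject_id", "parcel_id", "condition"])["r"]
         .size().rename("n_segments").reset_index())
    return out.merge(n, on=["subject_id", "parcel_id", "condition"])


def reinstatement_group_stats(subject_patterns: Sequence[SubjectSegmentPatterns],
                              cfg: AnalysisConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Parcel-wise group statistics for the two reinstatement maps.

    Per condition: one-sample two-tailed t of subject means against zero
    and a one-tailed permutation p obtained by shuffling, within each
    subject, which recall pattern goes with which segment.  The
    PRECISE - SUMMARY contrast is a paired two-tailed t.  BH-FDR is
    applied across parcels at ``fdr_q`` for the condition maps and at the
    more liberal ``fdr_q_contrast`` for the contrast map.
    """
    if cfg.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    parcel_ids = sorted({pid for sp in subject_patterns for pid in sp.parcels})
    rows = []
    for pid in parcel_ids:
        row: dict = {"parcel_id": pid}
        subj_means: dict[str, dict[str, float]] = {"PRECISE": {}, "SUMMARY": {}}
        for condition in ("PRECISE", "SUMMARY"):
            corr_mats, diag_means = [], []
            for sp in subject_patterns:
                entry = sp.parcels.get(pid, {}).get(condition)
                if entry is None:
                    continue
                _, mov, rec = entry
                cmat = _cross_corr(mov, rec)
                corr_mats.append(cmat)
                m = float(np.nanmean(np.diag(cmat)))
                diag_means.append(m)
                subj_means[condition][sp.subject_id] = m
            if len(diag_means) < 2:
                row[f"t_{condition.lower()}"] = np.nan
                row[f"p_{condition.lower()}"] = np.nan
                row[f"p_perm_{condition.lower()}"] = np.nan
                continue
            gs = stats.one_sample_t(diag_means)
            row[f"t_{condition.lower()}"] = gs.t
            row[f"p_{condition.lower()}"] = gs.p
            row[f"mean_{condition.lower()}"] = float(np.mean(diag_means))
            observed = float(np.mean(diag_means))
            null = np.empty(cfg.n_perm)
            for it in range(cfg.n_perm):
                vals = []
                for cmat in corr_mats:
                    n = cmat.shape[0]
                    perm = rng.permutation(n)
                    vals.append(float(np.nanmean(cmat[np.arange(n), perm])))
                null[it] = np.mean(vals)
            row[f"p_perm_{condition.lower()}"] = stats.perm_pvalue(
                observed, null, cfg.perm_smoothing)
        # paired contrast over subjects with both conditions defined
        both = sorted(set(subj_means["PRECISE"]) & set(subj_means["SUMMARY"]))
        paired = [(subj_means["PRECISE"][s], subj_means["SUMMARY"][s])
                  for s in both]
        if len(paired) >= 2:
            gs = stats.paired_t([p for p, _ in paired], [s for _, s in paired])
            row["t_paired"] = gs.t
            row["p_paired"] = gs.p
        else:
            row["t_paired"] = np.nan
            row["p_paired"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    for cond in ("precise", "summary"):
        rej, qv = stats.bh_fdr(df[f"p_perm_{cond}"].to_numpy(), cfg.fdr_q)
        df[f"q_{cond}"] = qv
        df[f"sig_{cond}"] = rej
    rej, qv = stats.bh_fdr(df["p_paired"].to_numpy(), cfg.fdr_q_contrast)
    df["q_paired"] = qv
    df["sig_paired"] = rej
    return df
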