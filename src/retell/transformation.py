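"""Scene-level inter-subject similarity and the memory-transformation score.

TRs are averaged within each of the coarse movie scenes, for the movie
run (shared scene boundaries) and the recall run (per-subject retelling
timestamps).  For each subject and scene, the movie-to-recall (MR)
correlation compares the subject's movie scene pattern with the average
recall pattern of the *other* subjects who retold that scene; the
recall-to-recall (RR) correlation does the same with the subject's own
recall pattern on the left.  If recall patterns agree more with each
other than with the original movie patterns (RR > MR), the
encoding-to-recall change is consistent across people: the parcel's
transformation score is T = RR - MR, evaluated inside a reliability mask
of parcels whose MR or RR survives a scene-label permutation test with
BH-FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
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
from .reinstatement import interval_pattern, _rowwise_corr, _cross_corr

__all__ = [
    "recall_scene_intervals",
    "scene_patterns",
    "ScenePatternSet",
    "build_scene_pattern_set",
    "SimilarityResult",
    "between_subject_similarity",
    "scene_label_permutation",
    "TransformationResult",
    "reliability_mask_and_T",
    "transformation_analysis",
]


def recall_scene_intervals(t: RecallTranscript, seg: MovieSegmentation
                           ) -> list[tuple[int, float, float]]:
    """Recall-time interval per retold scene: [first onset, last offset).

    Each content utterance is assigned to the scene holding the majority
    of its described movie time (ties go to the earlier scene).
    """
    bounds: dict[int, list[float]] = {}
    for u in t.utterances:
        if u.label is Label.OTHER or not u.has_range:
            continue
        dur_by_scene: dict[int, float] = {}
        for s in seg.segment_range(u.start_segment, u.end_segment):
            dur_by_scene[s.scene_id] = dur_by_scene.get(s.scene_id, 0.0) + s.duration_s
        scene = max(sorted(dur_by_scene), key=lambda k: dur_by_scene[k])
        if scene not in bounds:
            bounds[scene] = [u.onset_s, u.offset_s]
        else:
            bounds[scene][0] = min(bounds[scene][0], u.onset_s)
            bounds[scene][1] = max(bounds[scene][1], u.offset_s)
    return sorted(((k, on, off) for k, (on, off) in bounds.items()),
                  key=lambda x: x[1])


def scene_patterns(ts: ParcelTimeseries,
                   boundaries: Sequence[tuple[int, float, float]],
                   cfg: AnalysisConfig) -> dict[int, dict[int, np.ndarray]]:
    """Lag-shifted TR-average pattern per scene, per parcel.

    ``boundaries`` are (scene_id, onset_s, offset_s) tuples — the shared
    scene bounds for a movie run, or per-subject retelling timestamps for
    a recall run.  Scenes whose interval covers no TRs are omitted.
    """
    out: dict[int, dict[int, np.ndarray]] = {pid: {} for pid in ts.data}
    for scene_id, onset, offset in boundaries:
        try:
            pats = interval_pattern(ts, onset, offset, cfg.lag_trs)
        except ValueError:
            continue
        for pid, vec in pats.items():
            out[pid][scene_id] = vec
    return out


@dataclass
class ScenePatternSet:
    """Subjects x scenes x features arrays per parcel, with recall flags."""

    subject_ids: list[str]
    scene_ids: list[int]
    parcel_ids: list[int]
    movie: dict[int, np.ndarray]   # parcel -> (S, K, F)
    recall: dict[int, np.ndarray]  # parcel -> (S, K, F), NaN where unrecalled
    recalled: np.ndarray           # (S, K) bool

    def eligible_scenes(self, min_recallers: int) -> np.ndarray:
        """Boolean mask over scenes recalled by at least min_recallers."""
        return self.recalled.sum(axis=0) >= min_recallers


def build_scene_pattern_set(
        neural: Sequence[tuple[ParcelTimeseries, ParcelTimeseries]],
        transcripts: Sequence[RecallTranscript], seg: MovieSegmentation,
        cfg: AnalysisConfig) -> ScenePatternSet:
    scenes = seg.scenes
    scene_ids = [sc.scene_id for sc in scenes]
    movie_bounds = [(sc.scene_id, sc.onset_s, sc.offset_s) for sc in scenes]
    by_subject = {t.subject_id: t for t in transcripts}
    subject_ids = [m.subject_id for m, _ in neural]
    parcel_ids = sorted(neural[0][0].data)
    S, K = len(subject_ids), len(scene_ids)
    F = {pid: neural[0][0].data[pid].shape[0] for pid in parcel_ids}
    movie = {pid: np.empty((S, K, F[pid])) for pid in parcel_ids}
    recall = {pid: np.full((S, K, F[pid]), np.nan) for pid in parcel_ids}
    recalled = np.zeros((S, K), dtype=bool)
    for si, (mov_ts, rec_ts) in enumerate(neural):
        t = by_subject[mov_ts.subject_id]
        mov_p = scene_patterns(mov_ts, movie_bounds, cfg)
        rec_p = scene_patterns(rec_ts, recall_scene_intervals(t, seg), cfg)
        for ki, k in enumerate(scene_ids):
            for pid in parcel_ids:
                movie[pid][si, ki] = mov_p[pid][k]
                if k in rec_p[pid]:
                    recall[pid][si, ki] = rec_p[pid][k]
            recalled[si, ki] = k in rec_p[parcel_ids[0]]
    return ScenePatternSet(subject_ids=subject_ids, scene_ids=scene_ids,
                           parcel_ids=parcel_ids, movie=movie, recall=recall,
                           recalled=recalled)


@dataclass
class SimilarityResult:
    """Per-parcel (subject x scene) correlation cells and parcel means."""

    mode: str  # "MR" | "RR"
    scene_ids: list[int]
    subject_ids: list[str]
    eligible: np.ndarray            # (K,) bool
    cells: dict[int, np.ndarray]    # parcel -> (S, K) with NaN where undefined
    parcel_mean: dict[int, float]


def _averaged_others(recall: np.ndarray, recalled: np.ndarray) -> np.ndarray:
    """Leave-one-out average of recall patterns over recalling subjects.

    Returns (S, K, F): entry (i, k) averages recall[j, k] over the other
    subjects j who recalled scene k; NaN where no other subject did.
    """
    filled = np.where(recalled[:, :, None], recall, 0.0)
    total = filled.sum(axis=0, keepdims=True)          # (1, K, F)
    counts = recalled.sum(axis=0)[None, :, None]       # (1, K, 1)
    others = total - filled
    n_others = counts - recalled[:, :, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = others / n_others
    avg[np.broadcast_to(n_others == 0, avg.shape)] = np.nan
    return avg


def between_subject_similarity(sps: ScenePatternSet, mode: str,
                               cfg: AnalysisConfig) -> SimilarityResult:
    """MR or RR cells against the averaged-other-subjects recall pattern.

    Cells exist only for (subject, scene) pairs the subject retold, in
    scenes retold by at least ``min_recallers`` subjects.
    """
    if mode not in ("MR", "RR"):
        raise ValueError(f"mode must be MR or RR, got {mode!r}")
    if len(sps.subject_ids) < 2:
        raise ValueError("between-subject similarity requires >= 2 subjects")
    eligible = sps.eligible_scenes(cfg.min_recallers)
    if not eligible.any():
        raise ValueError(
            f"no scene recalled by >= {cfg.min_recallers} subjects")
    S, K = sps.recalled.shape
    cells = {}
    parcel_mean = {}
    for pid in sps.parcel_ids:
        left = sps.movie[pid] if mode == "MR" else sps.recall[pid]
        avg = _averaged_others(sps.recall[pid], sps.recalled)
        r = np.full((S, K), np.nan)
        for si in range(S):
            mask = sps.recalled[si] & eligible & ~np.isnan(avg[si, :, 0])
            if mask.any():
                r[si, mask] = _rowwise_corr(left[si, mask], avg[si, mask])
        cells[pid] = r
        parcel_mean[pid] = float(np.nanmean(r))
    return SimilarityResult(mode=mode, scene_ids=sps.scene_ids,
                            subject_ids=sps.subject_ids, eligible=eligible,
                            cells=cells, parcel_mean=parcel_mean)


def scene_label_permutation(sps: ScenePatternSet, mode: str,
                            cfg: AnalysisConfig,
                            rng: np.random.Generator) -> dict[int, float]:
    """One-tailed permutation p per parcel by shuffling scene labels.

    The null recomputes the parcel-mean similarity after permuting the
    scene labels of the averaged-others patterns (one shuffle per
    iteration, applied to every subject; permutations are drawn
    independently per parcel).  p is the proportion of null means >= the
    observed mean.
    """
    if cfg.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    eligible = sps.eligible_scenes(cfg.min_recallers)
    el_idx = np.flatnonzero(eligible)
    if el_idx.size == 0:
        raise ValueError("no eligible scenes")
    S = len(sps.subject_ids)
    Ke = el_idx.size
    out = {}
    for pid in sps.parcel_ids:
        left = sps.movie[pid] if mode == "MR" else sps.recall[pid]
        avg = _averaged_others(sps.recall[pid], sps.recalled)
        R = np.full((S, Ke, Ke), np.nan)
        mask = np.zeros((S, Ke), dtype=bool)
        for si in range(S):
            rec = sps.recalled[si][el_idx]
            ok_left = rec & ~np.isnan(left[si, el_idx, 0])
            ok_right = ~np.isnan(avg[si, el_idx, 0])
            if not ok_left.any():
                continue
            R[si][np.ix_(ok_left, ok_right)] = _cross_corr(
                left[si, el_idx[ok_left]], avg[si, el_idx[ok_right]])
            mask[si] = ok_left
        si_arr, ki_arr = np.nonzero(mask)
        observed = float(np.nanmean(R[si_arr, ki_arr, ki_arr]))
        null = np.empty(cfg.n_perm)
        for it in range(cfg.n_perm):
            perm = rng.permutation(Ke)
            null[it] = np.nanmean(R[si_arr, ki_arr, perm[ki_arr]])
        out[pid] = stats.perm_pvalue(observed, null, cfg.perm_smoothing)
    return out


@dataclass
class TransformationResult:
    """Parcel table with MR, RR, permutation p/q, mask and T = RR - MR."""

    parcels: pd.DataFrame
    scene_t: dict[int, pd.Series] = field(default_factory=dict)
    mr_cells: dict[int, np.ndarray] = field(default_factory=dict)
    rr_cells: dict[int, np.ndarray] = field(default_factory=dict)
    subject_ids: list[str] = field(default_factory=list)

    @property
    def positive_parcels(self) -> list[int]:
        df = self.parcels
        return df.loc[df["positive_t"], "parcel_id"].astype(int).tolist()


def reliability_mask_and_T(mr: SimilarityResult, rr: SimilarityResult,
                           p_mr: dict[int, float], p_rr: dict[int, float],
                           cfg: AnalysisConfig) -> TransformationResult:
    """FDR-mask parcels reliable in either map and score T = RR - MR.

    The per-scene group transformation uses only (subject, scene) cells
    defined in both the MR and RR matrices.
    """
    if set(mr.cells) != set(rr.cells):
        raise ValueError("MR and RR cover different parcels")
    parcel_ids = sorted(mr.cells)
    p_mr_v = np.array([p_mr[p] for p in parcel_ids])
    p_rr_v = np.array([p_rr[p] for p in parcel_ids])
    rej_mr, q_mr = stats.bh_fdr(p_mr_v, cfg.fdr_q)
    rej_rr, q_rr = stats.bh_fdr(p_rr_v, cfg.fdr_q)
    in_mask = rej_mr | rej_rr
    rows, scene_t = [], {}
    for i, pid in enumerate(parcel_ids):
        t_score = rr.parcel_mean[pid] - mr.parcel_mean[pid]
        positive = bool(in_mask[i] and t_score > 0)
        rows.append((pid, mr.parcel_mean[pid], rr.parcel_mean[pid],
                     p_mr_v[i], p_rr_v[i], q_mr[i], q_rr[i],
                     bool(in_mask[i]), t_score, positive))
        diff = rr.cells[pid] - mr.cells[pid]        # NaN unless both defined
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_scene = np.nanmean(diff, axis=0)
        scene_t[pid] = pd.Series(per_scene, index=mr.scene_ids)[
            np.asarray(mr.eligible)].dropna()
    df = pd.DataFrame(rows, columns=[
        "parcel_id", "mr", "rr", "p_mr", "p_rr", "q_mr", "q_rr",
        "in_reliability_mask", "t_score", "positive_t"])
    return TransformationResult(parcels=df, scene_t=scene_t,
                                mr_cells=mr.cells, rr_cells=rr.cells,
                                subject_ids=mr.subject_ids)


def transformation_analysis(sps: ScenePatternSet, cfg: AnalysisConfig,
                            rng: np.random.Generator) -> TransformationResult:
    """MR + RR + permutation + masking in one call."""
    mr = between_subject_similarity(sps, "MR", cfg)
    rr = between_subject_similarity(sps, "RR", cfg)
    p_mr = scene_label_permutation(sps, "MR", cfg, rng)
    p_rr = scene_label_permutation(sps, "RR", cfg, rng)
    return reliability_mask_and_T(mr, rr, p_mr, p_rr, cfg)
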