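"""Synthetic study generator.

Emulates the conditions of a naturalistic movie-viewing / free-recall
experiment: 17 subjects, a ~50-scene movie (scene durations ~57.7 s,
SD ~41.6 s, truncated to [11 s, 180 s]) partitioned into ~4-s
micro-segments, a 1.5-s TR, and spoken recall transcripts of ~14-word
utterances labelled Summary / Temporally Precise / Other.

Neural patterns follow two generative accounts of encoding-to-recall
pattern change.  For each parcel and scene k there is a shared movie
pattern m_k; subject i's movie-viewing TRs inside scene k carry
m_k + eta_ik (idiosyncratic noise, sd sigma_m) and their recall TRs carry
m_k + c_k * s_k + eps_ik, where s_k is a unit-scale shift direction
shared across subjects and c_k its magnitude.  Model 1 is the special
case c_k = 0 (all encoding-to-recall change is noise / idiosyncratic);
Model 2 adds the event-specific shared shift.  In "linked" parcels
c_k = a + b * (group-mean summary bias of scene k), so that scenes
retold more summarily shift more; in unlinked parcels c_k = a.

All randomness flows through one seeded generator; identical seeds
reproduce every output bit-for-bit, and configurations differing only in
shift parameters (a, b, c) consume the random stream identically, which
makes paired-seed comparisons across shift magnitudes exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import scipy.optimize
import scipy.stats as sps

from .io_formats import (
    Label,
    MicroSegment,
    MovieSegmentation,
    ParcelTimeseries,
    RecallTranscript,
    Run,
    Utterance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_segmentation",
    "simulate_transcripts",
    "simulate_neural",
    "simulate_dataset",
    "expected_mr",
    "expected_rr",
    "expected_transformation",
    "expected_reinstatement_r",
]

_FILLERS = ("the", "and", "a", "is", "uh", "um")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    Scene/segment statistics, utterance word counts and label mixture
    default to the study conditions; noise scales default to
    sigma_m = sigma_r = 1 with shift parameters a (baseline magnitude)
    and b (slope on group-mean summary bias in linked parcels).
    """

    n_subjects: int = 17
    n_scenes: int = 50
    segments_per_scene: int | None = None
    features_per_parcel: int = 100
    n_parcels: int = 6
    tr_s: float = 1.5
    movie_noise_sd: float = 1.0
    recall_noise_sd: float = 1.0
    shift_base: float = 0.0   # a
    shift_slope: float = 2.0  # b
    linked_parcel_ids: tuple[int, ...] | None = None
    mean_words: float = 14.0
    summary_word_inflation: float = 1.3
    p_other: float = 0.31
    p_recall: float = 0.9
    p_describe: float = 0.55
    p_redescribe: float = 0.3
    threshold_s: float = 10.0
    scene_mean_s: float = 57.7
    scene_sd_s: float = 41.6
    scene_min_s: float = 11.0
    scene_max_s: float = 180.0
    segment_mean_s: float = 3.95
    segment_min_s: float = 1.0
    segment_max_s: float = 9.5
    segment_shape: float = 3.3
    bias_alpha: float = 10.6
    bias_beta: float = 12.2
    bias_jitter_sd: float = 0.30
    utt_duration_mean_s: float = 6.83
    utt_duration_sd_s: float = 1.6
    utt_gap_s: float = 0.3
    utt_noise_sd_precise: float = 0.0
    utt_noise_sd_summary: float = 0.0
    summary_offpool_frac: float = 0.5
    precise_offpool_frac: float = 0.1
    null_recall: bool = False
    single_segment_utterances: bool = False
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("movie_noise_sd", "recall_noise_sd", "shift_base",
                     "utt_noise_sd_precise", "utt_noise_sd_summary"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_other", "p_recall", "p_describe", "p_redescribe",
                     "summary_offpool_frac", "precise_offpool_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.summary_word_inflation < 1.0:
            raise ValueError("summary_word_inflation must be >= 1")
        if self.segment_max_s > self.threshold_s:
            raise ValueError(
                "segment_max_s must not exceed threshold_s (single segments "
                "must admit a Precise span)")

    @property
    def linked(self) -> frozenset[int]:
        if self.linked_parcel_ids is not None:
            return frozenset(self.linked_parcel_ids)
        return frozenset(range(self.n_parcels // 2))

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("linked_parcel_ids") is not None:
            raw["linked_parcel_ids"] = tuple(raw["linked_parcel_ids"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        import dataclasses
        import yaml
        d = dataclasses.asdict(self)
        if d["linked_parcel_ids"] is not None:
            d["linked_parcel_ids"] = list(d["linked_parcel_ids"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def model1(cls, **kwargs) -> "GeneratorConfig":
        """Idiosyncratic-noise-only account: no shared shift anywhere."""
        return cls(shift_base=0.0, shift_slope=0.0, linked_parcel_ids=(),
                   **kwargs)

    @classmethod
    def model2(cls, c: float = 1.0, **kwargs) -> "GeneratorConfig":
        """Uniform shared shift of magnitude c in every parcel."""
        return cls(shift_base=c, shift_slope=0.0, linked_parcel_ids=(),
                   **kwargs)


@dataclass
class GroundTruth:
    """Exported generator state for parameter-recovery tests.

    ``scene_shift_magnitude`` is the per-scene feature driving linked
    shifts (the group-mean true summary bias; identically 0 for Model 1);
    ``true_summary_bias`` is the per-(subject, scene) target bias.
    """

    scene_shift_magnitude: dict[int, float]
    true_summary_bias: dict[tuple[str, int], float]
    linked_parcels: frozenset[int]
    model: str  # MODEL1 | MODEL2


@dataclass
class SyntheticDataset:
    segmentation: MovieSegmentation
    transcripts: list[RecallTranscript]
    truth: GroundTruth
    neural: list[tuple[ParcelTimeseries, ParcelTimeseries]]


# ---------------------------------------------------------------------------
# Closed-form oracles (large-feature-count expectations)

def expected_mr(sigma_m: float, sigma_r: float, c: float, n: int) -> float:
    """Expected movie-to-recall correlation against the averaged others."""
    return 1.0 / np.sqrt((1 + sigma_m ** 2) * (1 + c ** 2 + sigma_r ** 2 / (n - 1)))


def expected_rr(sigma_m: float, sigma_r: float, c: float, n: int) -> float:
    """Expected recall-to-recall correlation against the averaged others."""
    u = 1 + c ** 2
    return u / np.sqrt((u + sigma_r ** 2) * (u + sigma_r ** 2 / (n - 1)))


def expected_transformation(sigma_m: float, sigma_r: float, c: float,
                            n: int) -> float:
    return expected_rr(sigma_m, sigma_r, c, n) - expected_mr(sigma_m, sigma_r, c, n)


def expected_reinstatement_r(sigma_m: float, sigma_r: float, c: float = 0.0,
                             extra_sd: float = 0.0) -> float:
    """Expected within-subject movie-recall pattern correlation."""
    return 1.0 / np.sqrt(
        (1 + sigma_m ** 2) * (1 + c ** 2 + sigma_r ** 2 + extra_sd ** 2))


# ---------------------------------------------------------------------------
# Movie segmentation

@lru_cache(maxsize=8)
def _lognormal_params(mean: float, sd: float, lo: float, hi: float
                      ) -> tuple[float, float]:
    """(mu, sigma) of a lognormal whose [lo, hi] truncation matches mean/sd.

    A target mean outside the truncation window is clamped into it; if the
    moment matching fails to converge the untruncated parameters are used
    (the draws are truncated regardless).
    """
    mean = min(max(mean, lo * 1.001), hi * 0.999)

    def trunc_moment(mu, sigma, k):
        a = (np.log(lo) - mu) / sigma
        b = (np.log(hi) - mu) / sigma
        z = sps.norm.cdf(b) - sps.norm.cdf(a)
        num = sps.norm.cdf(b - k * sigma) - sps.norm.cdf(a - k * sigma)
        return np.exp(k * mu + 0.5 * k ** 2 * sigma ** 2) * num / z

    def residual(params):
        mu, sigma = params
        m1 = trunc_moment(mu, sigma, 1)
        m2 = trunc_moment(mu, sigma, 2)
        return [m1 - mean, np.sqrt(max(m2 - m1 ** 2, 1e-12)) - sd]

    sigma0 = np.sqrt(np.log(1 + (sd / mean) ** 2))
    mu0 = np.log(mean) - 0.5 * sigma0 ** 2
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sol, _, ier, _ = scipy.optimize.fsolve(residual, [mu0, sigma0],
                                                   full_output=True)
    if ier != 1 or not np.all(np.isfinite(sol)) or sol[1] <= 0:
        return mu0, sigma0
    return float(sol[0]), float(sol[1])


def _draw_truncated_lognormal(mu: float, sigma: float, lo: float, hi: float,
                              size: int, rng: np.random.Generator) -> np.ndarray:
    a = sps.norm.cdf((np.log(lo) - mu) / sigma)
    b = sps.norm.cdf((np.log(hi) - mu) / sigma)
    u = rng.uniform(a, b, size=size)
    return np.exp(mu + sigma * sps.norm.ppf(u))


def _partition_duration(total: float, n: int, lo: float, hi: float,
                        shape: float, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` into n contiguous pieces, each within [lo, hi]."""
    w = rng.gamma(shape, 1.0, size=n)
    d = total * w / w.sum()
    for _ in range(100):
        d = np.clip(d, lo, hi)
        excess = total - d.sum()
        if abs(excess) < 1e-10:
            break
        room = (hi - d) if excess > 0 else (d - lo)
        movable = room > 1e-12
        if not movable.any():
            break
        d[movable] += excess * room[movable] / room[movable].sum()
    return d


def draw_scene_durations(cfg: GeneratorConfig, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Scene durations from the calibrated truncated lognormal."""
    mu, sigma = _lognormal_params(cfg.scene_mean_s, cfg.scene_sd_s,
                                  cfg.scene_min_s, cfg.scene_max_s)
    return _draw_truncated_lognormal(mu, sigma, cfg.scene_min_s,
                                     cfg.scene_max_s, n, rng)


def _scene_vocab(scene_id: int, size: int = 30) -> list[str]:
    return [f"s{scene_id}w{j}" for j in range(size)]


_SHARED_VOCAB = tuple(f"common{j}" for j in range(8))


def simulate_segmentation(cfg: GeneratorConfig,
                          rng: np.random.Generator) -> MovieSegmentation:
    durations = draw_scene_durations(cfg, cfg.n_scenes, rng)
    segments: list[MicroSegment] = []
    onset = 0.0
    seg_id = 1
    for k, dur in enumerate(durations, start=1):
        if cfg.segments_per_scene is not None:
            # explicit override: honour the count, relax the upper bound
            n_seg = cfg.segments_per_scene
            hi = dur
        else:
            n_seg = int(round(dur / cfg.segment_mean_s))
            n_seg = max(n_seg, int(np.ceil(dur / cfg.segment_max_s)), 1)
            n_seg = min(n_seg, int(dur / cfg.segment_min_s)) or 1
            hi = cfg.segment_max_s
        seg_durs = _partition_duration(dur, n_seg, cfg.segment_min_s,
                                       hi, cfg.segment_shape, rng)
        vocab = _scene_vocab(k)
        for d in seg_durs:
            words = list(rng.choice(vocab, size=7, replace=False))
            words.append(str(rng.choice(_SHARED_VOCAB)))
            segments.append(MicroSegment(
                segment_id=seg_id, scene_id=k, onset_s=onset,
                offset_s=onset + d, annotation=" ".join(words)))
            onset += d
            seg_id += 1
    return MovieSegmentation(segments)


# ---------------------------------------------------------------------------
# Recall transcripts

def _utterance_text(n_words: int, covered: list[MicroSegment],
                    off_frac: float, scene_id: int, n_scenes: int,
                    rng: np.random.Generator) -> str:
    pool = [tok for s in covered for tok in s.annotation.split()]
    n_off = int(round(n_words * off_frac))
    n_on = n_words - n_off
    words = list(rng.choice(pool, size=n_on, replace=True)) if n_on else []
    for _ in range(n_off):
        other = int(rng.integers(1, n_scenes + 1))
        if n_scenes > 1:
            while other == scene_id:
                other = int(rng.integers(1, n_scenes + 1))
        words.append(str(rng.choice(_scene_vocab(other))))
    n_fill = max(1, int(round(0.25 * n_words)))
    words.extend(rng.choice(_FILLERS, size=n_fill, replace=True))
    order = rng.permutation(len(words))
    return " ".join(words[i] for i in order)


def _other_text(n_scenes: int, rng: np.random.Generator) -> str:
    words = [str(rng.choice(_scene_vocab(int(rng.integers(1, n_scenes + 1)))))
             for _ in range(4)]
    words.extend(rng.choice(_FILLERS, size=4, replace=True))
    return " ".join(words)


def _spans_for_scene(segs: list[MicroSegment], beta: float, cfg: GeneratorConfig,
                     rng: np.random.Generator
                     ) -> list[tuple[Label, int, int]]:
    """Partition a scene's segments into labelled utterance spans.

    Summary spans cover > threshold_s of movie time, Precise spans <=
    threshold_s, so the automatic duration rule reproduces the labels
    exactly.  Span types are allocated so the summary word share tracks
    the target bias ``beta``: summary is chosen while the running summary
    fraction is below target.  Each candidate span is actually retold
    with probability ``p_describe`` (subjects do not describe every
    moment), and skipped spans do not count towards the running share.
    """
    durs = np.array([s.duration_s for s in segs])
    gamma = cfg.summary_word_inflation
    spans: list[tuple[Label, int, int]] = []  # (label, first_idx, last_idx)
    if cfg.single_segment_utterances:
        # calibration mode: every utterance retells exactly one segment
        return [(Label.PRECISE, i, i) for i in range(len(segs))
                if rng.random() < cfg.p_describe]
    w_s = w_p = 0.0
    i = 0
    n = len(segs)
    while i < n:
        remaining = float(durs[i:].sum())
        if beta >= 1.0:
            want_summary = True
        elif beta <= 0.0:
            want_summary = False
        else:
            # choose the type with the probability that makes the expected
            # post-choice summary word share equal the target bias, so the
            # realised share is unbiased at every step
            share_if_s = (w_s + gamma) / (w_s + gamma + w_p)
            share_if_p = w_s / (w_s + w_p + 1.0)
            p_s = (beta - share_if_p) / (share_if_s - share_if_p)
            want_summary = rng.random() < min(max(p_s, 0.0), 1.0)
            # last position where a Summary span still fits: settle any
            # outstanding summary deficit now (all-or-nothing for a scene
            # that opens this close to its end)
            if (not want_summary
                    and remaining <= cfg.threshold_s + 2 * cfg.segment_mean_s):
                share_now = w_s / (w_s + w_p) if w_s + w_p > 0 else 0.0
                if share_now < beta and share_if_s > share_now:
                    p_fix = (beta - share_now) / (share_if_s - share_now)
                    want_summary = rng.random() < min(p_fix, 1.0)
        if want_summary and remaining <= cfg.threshold_s:
            if spans and spans[-1][0] is Label.SUMMARY:
                spans[-1] = (Label.SUMMARY, spans[-1][1], n - 1)
                break
            want_summary = False
        if want_summary:
            j = i
            cum = 0.0
            while j < n and cum <= cfg.threshold_s:
                cum += durs[j]
                j += 1
            while j < n and float(durs[j:].sum()) > cfg.threshold_s \
                    and rng.random() < 0.25:
                j += 1
            if rng.random() < cfg.p_describe:
                spans.append((Label.SUMMARY, i, j - 1))
                w_s += gamma
                # expected brief precise re-description that trails a
                # summary span (word weight p_redescribe * 0.4)
                w_p += cfg.p_redescribe * 0.4
        else:
            max_j = i
            cum = 0.0
            while max_j < n and cum + durs[max_j] <= cfg.threshold_s:
                cum += durs[max_j]
                max_j += 1
            take = int(rng.integers(1, max(max_j - i, 1) + 1))
            if rng.random() < cfg.p_describe:
                spans.append((Label.PRECISE, i, i + take - 1))
                w_p += 1.0
            j = i + take
        i = j
    return spans


def simulate_transcripts(cfg: GeneratorConfig, seg: MovieSegmentation,
                         rng: np.random.Generator
                         ) -> tuple[list[RecallTranscript], GroundTruth]:
    scenes = seg.scenes
    by_scene = {sc.scene_id: [s for s in seg.micro_segments
                              if s.scene_id == sc.scene_id]
                for sc in scenes}
    group_bias = {sc.scene_id: float(rng.beta(cfg.bias_alpha, cfg.bias_beta))
                  for sc in scenes}
    short = [sc.scene_id for sc in scenes if sc.duration_s <= cfg.threshold_s]
    for k in short:
        logger.warning("scene %d too short for any Summary span; bias set to 0", k)
        group_bias[k] = 0.0

    transcripts: list[RecallTranscript] = []
    true_bias: dict[tuple[str, int], float] = {}
    for si in range(cfg.n_subjects):
        subject = f"sub-{si + 1:02d}"
        utterances: list[Utterance] = []
        uid = 1
        t_cursor = 0.0
        for sc in scenes:
            k = sc.scene_id
            beta = float(np.clip(
                group_bias[k] + rng.normal(0.0, cfg.bias_jitter_sd), 0.0, 1.0))
            if k in short:
                beta = 0.0
            elif sc.duration_s <= cfg.threshold_s + 2 * cfg.segment_mean_s:
                # scene only admits an all-or-nothing summary span; the
                # recorded target is a mean-preserving feasible share
                beta = 1.0 if rng.random() < beta else 0.0
            recalled = rng.random() < cfg.p_recall
            true_bias[(subject, k)] = beta
            if not recalled:
                t_cursor += float(rng.uniform(8.0, 15.0))  # silent gap
                continue
            spans = _spans_for_scene(by_scene[k], beta, cfg, rng)
            # brief Temporally Precise re-descriptions of already-summarized
            # content: a zoomed-in retelling of one covered micro-segment
            extended = []
            for span in spans:
                extended.append(span)
                if span[0] is Label.SUMMARY and rng.random() < cfg.p_redescribe:
                    j = int(rng.integers(span[1], span[2] + 1))
                    extended.append((Label.PRECISE, j, j, 0.4))
            spans = extended
            n_other = sum(1 for _ in spans if rng.random() < cfg.p_other)
            for label, a, b, *word_scale in spans:
                covered = by_scene[k][a:b + 1]
                lam = cfg.mean_words * (cfg.summary_word_inflation
                                        if label is Label.SUMMARY else 1.0)
                if word_scale:
                    lam *= word_scale[0]
                n_words = max(1, int(rng.poisson(lam)))
                off = (cfg.summary_offpool_frac if label is Label.SUMMARY
                       else cfg.precise_offpool_frac)
                text = _utterance_text(n_words, covered, off, k,
                                       cfg.n_scenes, rng)
                dur = float(np.clip(
                    rng.normal(cfg.utt_duration_mean_s, cfg.utt_duration_sd_s),
                    2.0, 20.0))
                utterances.append(Utterance(
                    subject_id=subject, utterance_id=uid, onset_s=t_cursor,
                    offset_s=t_cursor + dur, text=text,
                    start_segment=covered[0].segment_id,
                    end_segment=covered[-1].segment_id, label=label,
                    content_word_count=n_words))
                uid += 1
                t_cursor += dur + cfg.utt_gap_s
            # Other utterances (inaccurate / meta statements) trail the
            # scene's retelling so retold-scene intervals stay contiguous
            for _ in range(n_other):
                dur = float(np.clip(
                    rng.normal(cfg.utt_duration_mean_s, cfg.utt_duration_sd_s),
                    2.0, 20.0))
                utterances.append(Utterance(
                    subject_id=subject, utterance_id=uid, onset_s=t_cursor,
                    offset_s=t_cursor + dur, text=_other_text(cfg.n_scenes, rng),
                    start_segment=None, end_segment=None, label=Label.OTHER))
                uid += 1
                t_cursor += dur + cfg.utt_gap_s
        transcripts.append(RecallTranscript(subject_id=subject,
                                            utterances=utterances))

    model1 = cfg.shift_base == 0.0 and (cfg.shift_slope == 0.0 or not cfg.linked)
    truth = GroundTruth(
        scene_shift_magnitude=({k: 0.0 for k in group_bias} if model1
                               else dict(group_bias)),
        true_summary_bias=true_bias,
        linked_parcels=cfg.linked,
        model="MODEL1" if model1 else "MODEL2",
    )
    return transcripts, truth


# ---------------------------------------------------------------------------
# Neural time series

def _scene_blocks(t: RecallTranscript, seg: MovieSegmentation
                  ) -> dict[int, tuple[float, float]]:
    """Recall-time interval [first onset, last offset] per retold scene."""
    from .transformation import recall_scene_intervals
    return {k: (on, off) for k, on, off in recall_scene_intervals(t, seg)}


def simulate_neural(cfg: GeneratorConfig, seg: MovieSegmentation,
                    transcripts: list[RecallTranscript], truth: GroundTruth,
                    rng: np.random.Generator
                    ) -> list[tuple[ParcelTimeseries, ParcelTimeseries]]:
    scenes = seg.scenes
    scene_ids = [sc.scene_id for sc in scenes]
    if set(truth.scene_shift_magnitude) - set(scene_ids):
        raise ValueError("ground truth references scenes absent from "
                         "segmentation")
    K = len(scene_ids)
    F = cfg.features_per_parcel
    tr = cfg.tr_s
    dt = np.dtype(cfg.dtype)

    n_mov_trs = int(np.ceil(seg.offset_s / tr))
    mov_times = np.arange(n_mov_trs) * tr
    scene_edges = np.array([sc.onset_s for sc in scenes] + [seg.offset_s])
    mov_scene_idx = np.clip(np.searchsorted(scene_edges, mov_times,
                                            side="right") - 1, 0, K - 1)

    # shared components, drawn identically regardless of shift magnitudes
    shared_m = [rng.standard_normal((K, F), dtype=dt) for _ in range(cfg.n_parcels)]
    shared_s = [rng.standard_normal((K, F), dtype=dt) for _ in range(cfg.n_parcels)]
    c = np.zeros((cfg.n_parcels, K))
    for p in range(cfg.n_parcels):
        for ki, k in enumerate(scene_ids):
            mag = truth.scene_shift_magnitude.get(k, 0.0)
            c[p, ki] = cfg.shift_base + (cfg.shift_slope * mag
                                         if p in truth.linked_parcels else 0.0)

    extra_sd = {Label.PRECISE: cfg.utt_noise_sd_precise,
                Label.SUMMARY: cfg.utt_noise_sd_summary}
    out = []
    for t in transcripts:
        blocks = _scene_blocks(t, seg)
        end_s = max([u.offset_s for u in t.utterances], default=tr) + 2 * tr
        n_rec_trs = max(int(np.ceil(end_s / tr)), 1)
        rec_times = np.arange(n_rec_trs) * tr
        movie_data: dict[int, np.ndarray] = {}
        recall_data: dict[int, np.ndarray] = {}
        for p in range(cfg.n_parcels):
            eta = rng.standard_normal((K, F), dtype=dt) * dt.type(cfg.movie_noise_sd)
            eps = rng.standard_normal((K, F), dtype=dt) * dt.type(cfg.recall_noise_sd)
            movie_patterns = shared_m[p] + eta                  # (K, F)
            movie_data[p] = movie_patterns[mov_scene_idx].T     # (F, T)

            rec = rng.standard_normal((F, n_rec_trs), dtype=dt) * dt.type(cfg.recall_noise_sd)
            if not cfg.null_recall:
                # retold-scene blocks carry the scene's recall pattern;
                # under the null the run stays pure TR-wise noise
                recall_patterns = (shared_m[p]
                                   + c[p][:, None].astype(dt) * shared_s[p]
                                   + eps)
                for ki, k in enumerate(scene_ids):
                    if k not in blocks:
                        continue
                    on, off = blocks[k]
                    sel = (rec_times >= on - 1e-9) & (rec_times < off + 1e-9)
                    rec[:, sel] = recall_patterns[ki][:, None]
            for u in t.utterances:
                sd = extra_sd.get(u.label, 0.0)
                if sd <= 0:
                    continue
                sel = (rec_times >= u.onset_s - 1e-9) & (rec_times < u.offset_s)
                rec[:, sel] += (rng.standard_normal(F, dtype=dt)
                                * dt.type(sd))[:, None]
            recall_data[p] = rec
        out.append((
            ParcelTimeseries(subject_id=t.subject_id, run=Run.MOVIE,
                             tr_s=tr, data=movie_data),
            ParcelTimeseries(subject_id=t.subject_id, run=Run.RECALL,
                             tr_s=tr, data=recall_data),
        ))
    return out


def simulate_dataset(cfg: GeneratorConfig,
                     rng: np.random.Generator | None = None) -> SyntheticDataset:
    """Full synthetic study: segmentation, transcripts, neural runs, truth."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    seg = simulate_segmentation(cfg, rng)
    transcripts, truth = simulate_transcripts(cfg, seg, rng)
    neural = simulate_neural(cfg, seg, transcripts, truth, rng)
    return SyntheticDataset(segmentation=seg, transcripts=transcripts,
                            truth=truth, neural=neural)
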