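"""Domain types and on-disk formats.

The pipeline's common coordinate frame is a two-level segmentation of a
movie: coarse narrative *scenes* partitioned into fine *micro-segments*
(a few seconds each), all expressed in seconds as half-open intervals
[onset, offset).  Recall behaviour arrives as per-subject transcripts of
utterances, each mapped to a span of micro-segments and labelled by
temporal precision (PRECISE / SUMMARY / OTHER).  Neural data are
parcel-wise feature x TR matrices for a movie run and a recall run.

The canonical exchange format for all tables is TSV with mandatory
headers; NIfTI volumes are supported as an ingestion convenience for
neural data, NPZ archives as the packed exchange format, and YAML for the
analysis configuration.  Missing numeric values are written as empty
fields.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "Label",
    "Run",
    "MicroSegment",
    "Scene",
    "MovieSegmentation",
    "Utterance",
    "RecallTranscript",
    "ParcelTimeseries",
    "Parcellation",
    "AnalysisConfig",
    "DEFAULT_STOPWORDS",
    "DEFAULT_NONWORDS",
    "read_segmentation",
    "write_segmentation",
    "read_transcript",
    "write_transcript",
    "read_parcellation",
    "write_parcellation",
    "read_timeseries",
    "read_timeseries_nifti",
    "write_timeseries",
    "write_parcel_map",
    "read_parcel_map",
]


class FormatError(ValueError):
    """Structured parse/validation error naming the offending row."""

    def __init__(self, message: str, path: str | None = None, row: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if row is not None:
            loc += f" row {row}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.row = row


class Label(enum.Enum):
    PRECISE = "PRECISE"
    SUMMARY = "SUMMARY"
    OTHER = "OTHER"

    @classmethod
    def parse(cls, token: str) -> "Label":
        try:
            return cls[str(token).strip().upper()]
        except KeyError:
            raise FormatError(f"unknown label token {token!r}") from None


class Run(enum.Enum):
    MOVIE = "MOVIE"
    RECALL = "RECALL"


@dataclass(frozen=True)
class MicroSegment:
    segment_id: int
    scene_id: int
    onset_s: float
    offset_s: float
    annotation: str = ""

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class Scene:
    scene_id: int
    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class MovieSegmentation:
    """Contiguous, ordered micro-segments nested inside coarse scenes."""

    micro_segments: list[MicroSegment]

    _by_id: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.micro_segments = sorted(self.micro_segments, key=lambda s: s.onset_s)
        self.validate()
        self._by_id = {s.segment_id: s for s in self.micro_segments}

    def validate(self) -> None:
        segs = self.micro_segments
        if not segs:
            raise FormatError("segmentation contains no micro-segments")
        ids = [s.segment_id for s in segs]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate segment_id in segmentation")
        scene_rows: dict[int, list[MicroSegment]] = {}
        for i, s in enumerate(segs):
            if not s.offset_s > s.onset_s:
                raise FormatError(
                    f"segment {s.segment_id} has offset <= onset", row=i + 1)
            if i > 0 and s.onset_s < segs[i - 1].offset_s - 1e-9:
                raise FormatError(
                    f"segment {s.segment_id} overlaps segment "
                    f"{segs[i - 1].segment_id}", row=i + 1)
            if i > 0 and s.onset_s > segs[i - 1].offset_s + 1e-6:
                raise FormatError(
                    f"gap before segment {s.segment_id}: micro-segments "
                    "must be contiguous", row=i + 1)
            scene_rows.setdefault(s.scene_id, []).append(s)
        # a scene's segments must be one contiguous block
        for scene_id, rows in scene_rows.items():
            lo = min(r.onset_s for r in rows)
            hi = max(r.offset_s for r in rows)
            for s in segs:
                if s.scene_id != scene_id and lo < s.onset_s + 1e-9 and s.offset_s <= hi + 1e-9:
                    raise FormatError(
                        f"segment {s.segment_id} of scene {s.scene_id} lies "
                        f"inside scene {scene_id}")

    @property
    def scenes(self) -> list[Scene]:
        out: dict[int, list[float]] = {}
        for s in self.micro_segments:
            if s.scene_id not in out:
                out[s.scene_id] = [s.onset_s, s.offset_s]
            else:
                out[s.scene_id][0] = min(out[s.scene_id][0], s.onset_s)
                out[s.scene_id][1] = max(out[s.scene_id][1], s.offset_s)
        return [Scene(k, lo, hi) for k, (lo, hi) in sorted(out.items(), key=lambda kv: kv[1][0])]

    def segment(self, segment_id: int) -> MicroSegment:
        try:
            return self._by_id[segment_id]
        except KeyError:
            raise FormatError(f"unknown segment_id {segment_id}") from None

    def segment_range(self, start: int, end: int) -> list[MicroSegment]:
        """Micro-segments with start <= segment_id <= end, in timeline order."""
        if end < start:
            raise FormatError(f"segment range end {end} < start {start}")
        out = [self.segment(i) for i in range(start, end + 1)]
        return out

    @property
    def onset_s(self) -> float:
        return self.micro_segments[0].onset_s

    @property
    def offset_s(self) -> float:
        return self.micro_segments[-1].offset_s


@dataclass
class Utterance:
    subject_id: str
    utterance_id: int
    onset_s: float
    offset_s: float
    text: str
    start_segment: int | None
    end_segment: int | None
    label: Label
    content_word_count: int | None = None
    tcf: float | None = None

    def __post_init__(self):
        if not self.offset_s > self.onset_s:
            raise FormatError(
                f"utterance {self.utterance_id}: offset <= onset")
        if self.label is not Label.OTHER:
            if self.start_segment is None or self.end_segment is None:
                raise FormatError(
                    f"utterance {self.utterance_id}: {self.label.value} "
                    "requires a segment range")
            if self.end_segment < self.start_segment:
                raise FormatError(
                    f"utterance {self.utterance_id}: end_segment < start_segment")

    @property
    def has_range(self) -> bool:
        return self.start_segment is not None and self.end_segment is not None


@dataclass
class RecallTranscript:
    subject_id: str
    utterances: list[Utterance]

    def __post_init__(self):
        ids = [u.utterance_id for u in self.utterances]
        if len(set(ids)) != len(ids):
            raise FormatError(
                f"subject {self.subject_id}: duplicate utterance_id")
        onsets = [u.onset_s for u in self.utterances]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise FormatError(
                f"subject {self.subject_id}: utterance onsets must be "
                "non-decreasing")


@dataclass
class ParcelTimeseries:
    """Per-subject, per-run parcel -> features x TRs arrays."""

    subject_id: str
    run: Run
    tr_s: float
    data: dict[int, np.ndarray]

    def __post_init__(self):
        if not self.tr_s > 0:
            raise FormatError("tr_s must be positive")
        n_trs = {v.shape[1] for v in self.data.values()}
        if len(n_trs) > 1:
            raise FormatError(
                f"subject {self.subject_id} {self.run.value}: parcels have "
                f"differing TR counts {sorted(n_trs)}")

    @property
    def n_trs(self) -> int:
        return next(iter(self.data.values())).shape[1]

    @property
    def parcel_ids(self) -> list[int]:
        return sorted(self.data)


SEVEN_NETWORKS = (
    "Default", "Frontoparietal", "Visual", "VentAttn", "DorsAttn",
    "SomMot", "Limbic",
)


@dataclass
class Parcellation:
    """Parcel -> functional network table (seven-network scheme)."""

    parcels: list[tuple[int, str, str]]  # (parcel_id, network, name)
    atlas_volume: str | None = None

    def __post_init__(self):
        ids = [p[0] for p in self.parcels]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate parcel_id in parcellation")
        for pid, network, _ in self.parcels:
            if network not in SEVEN_NETWORKS:
                raise FormatError(
                    f"parcel {pid}: unknown network {network!r}")

    @property
    def parcel_ids(self) -> list[int]:
        return [p[0] for p in self.parcels]

    def network_of(self, parcel_id: int) -> str:
        for pid, network, _ in self.parcels:
            if pid == parcel_id:
                return network
        raise FormatError(f"unknown parcel_id {parcel_id}")


# Standard English function words plus transcription fillers; the list is
# user-overridable through AnalysisConfig and recorded in output provenance.
DEFAULT_STOPWORDS = (
    "a an the and or but if then else when while of at by for with about "
    "against between into through during before after above below to from "
    "up down in out on off over under again further once here there all "
    "any both each few more most other some such no nor not only own same "
    "so than too very s t can will just don should now i me my myself we "
    "our ours ourselves you your yours yourself yourselves he him his "
    "himself she her hers herself it its itself they them their theirs "
    "themselves what which who whom this that these those am is are was "
    "were be been being have has had having do does did doing would could "
    "ought as until because"
).split()

DEFAULT_NONWORDS = ("uh", "um", "er", "mm", "hmm")


@dataclass
class AnalysisConfig:
    """Run configuration shared by every analysis stage.

    ``threshold_s`` is the temporal-precision boundary (described movie
    time above which an utterance counts as Summary); ``boundary_rule``
    decides ties at exactly the threshold (default: precise).  ``lag_trs``
    shifts neural intervals to compensate for hemodynamic delay (default
    3 TRs = 4.5 s at TR 1.5 s); synthetic data are generated without
    lag, so generator-driven runs set it to 0.
    """

    lag_trs: int = 3
    threshold_s: float = 10.0
    n_perm: int = 1000
    fdr_q: float = 0.05
    fdr_q_contrast: float = 0.10
    min_recallers: int = 5
    min_scenes_per_subject: int = 3
    seed: int = 0
    stopwords: tuple[str, ...] = tuple(DEFAULT_STOPWORDS)
    nonwords: tuple[str, ...] = tuple(DEFAULT_NONWORDS)
    boundary_rule: str = "LE_PRECISE"  # or LT_PRECISE
    perm_smoothing: bool = False
    fisher_z: bool = False
    mismatch_subsample: int | None = None

    def __post_init__(self):
        if not 0.0 < self.fdr_q < 1.0 or not 0.0 < self.fdr_q_contrast < 1.0:
            raise FormatError("fdr_q must lie in (0, 1)")
        if self.n_perm < 1:
            raise FormatError("n_perm must be >= 1")
        if self.lag_trs < 0:
            raise FormatError("lag_trs must be >= 0")
        if self.boundary_rule not in ("LE_PRECISE", "LT_PRECISE"):
            raise FormatError(f"unknown boundary_rule {self.boundary_rule!r}")
        self.stopwords = tuple(self.stopwords)
        self.nonwords = tuple(self.nonwords)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["stopwords"] = list(self.stopwords)
        d["nonwords"] = list(self.nonwords)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# TSV readers / writers

_SEG_COLUMNS = ["segment_id", "scene_id", "onset_s", "offset_s", "annotation"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns {missing}", path=path)


def read_segmentation(path: str) -> MovieSegmentation:
    df = pd.read_csv(path, sep="\t", dtype={"annotation": str},
                     keep_default_na=False, na_values=[""])
    _require_columns(df, _SEG_COLUMNS, path)
    segs = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            segs.append(MicroSegment(
                segment_id=int(row.segment_id), scene_id=int(row.scene_id),
                onset_s=float(row.onset_s), offset_s=float(row.offset_s),
                annotation="" if pd.isna(row.annotation) else str(row.annotation)))
        except (TypeError, ValueError) as exc:
            raise FormatError(str(exc), path=path, row=i + 1) from exc
    try:
        return MovieSegmentation(segs)
    except FormatError as exc:
        raise FormatError(str(exc), path=path) from exc


def write_segmentation(seg: MovieSegmentation, path: str) -> None:
    df = pd.DataFrame(
        [(s.segment_id, s.scene_id, s.onset_s, s.offset_s, s.annotation)
         for s in seg.micro_segments],
        columns=_SEG_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


_TRANSCRIPT_COLUMNS = [
    "subject_id", "utterance_id", "onset_s", "offset_s", "text",
    "start_segment", "end_segment", "label",
]


def read_transcript(path: str) -> RecallTranscript:
    df = pd.read_csv(path, sep="\t", dtype={"text": str, "subject_id": str},
                     keep_default_na=False, na_values=[""])
    _require_columns(df, _TRANSCRIPT_COLUMNS, path)
    utts = []
    subjects = set()
    for i, row in enumerate(df.itertuples(index=False)):
        label = Label.parse(row.label)
        start = None if pd.isna(row.start_segment) else int(row.start_segment)
        end = None if pd.isna(row.end_segment) else int(row.end_segment)
        try:
            u = Utterance(
                subject_id=str(row.subject_id),
                utterance_id=int(row.utterance_id),
                onset_s=float(row.onset_s), offset_s=float(row.offset_s),
                text="" if pd.isna(row.text) else str(row.text),
                start_segment=start, end_segment=end, label=label,
                content_word_count=(
                    None if "content_word_count" not in df.columns
                    or pd.isna(getattr(row, "content_word_count", np.nan))
                    else int(row.content_word_count)),
                tcf=(None if "tcf" not in df.columns
                     or pd.isna(getattr(row, "tcf", np.nan))
                     else float(row.tcf)),
            )
        except FormatError as exc:
            raise FormatError(str(exc), path=path, row=i + 1) from exc
        subjects.add(u.subject_id)
        utts.append(u)
    if len(subjects) != 1:
        raise FormatError(
            f"transcript must contain exactly one subject, got {sorted(subjects)}",
            path=path)
    return RecallTranscript(subject_id=subjects.pop(), utterances=utts)


def write_transcript(t: RecallTranscript, path: str) -> None:
    rows = []
    for u in t.utterances:
        rows.append((
            u.subject_id, u.utterance_id, u.onset_s, u.offset_s, u.text,
            "" if u.start_segment is None else u.start_segment,
            "" if u.end_segment is None else u.end_segment,
            u.label.value,
            "" if u.content_word_count is None else u.content_word_count,
            "" if u.tcf is None else u.tcf,
        ))
    df = pd.DataFrame(rows, columns=_TRANSCRIPT_COLUMNS + ["content_word_count", "tcf"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_parcellation(path: str, atlas_volume: str | None = None) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["parcel_id", "network", "name"], path)
    parcels = [(int(r.parcel_id), str(r.network), str(r.name))
               for r in df.itertuples(index=False)]
    return Parcellation(parcels=parcels, atlas_volume=atlas_volume)


def write_parcellation(p: Parcellation, path: str) -> None:
    df = pd.DataFrame(p.parcels, columns=["parcel_id", "network", "name"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Neural time series

def write_timeseries(ts: ParcelTimeseries, path: str) -> None:
    """Packed NPZ archive: one array per parcel plus metadata."""
    arrays = {f"parcel_{pid}": arr for pid, arr in ts.data.items()}
    np.savez_compressed(
        path, __subject_id=np.array(ts.subject_id),
        __run=np.array(ts.run.value), __tr_s=np.array(ts.tr_s), **arrays)


def read_timeseries(path: str, parcellation: Parcellation | None = None
                    ) -> ParcelTimeseries:
    with np.load(path, allow_pickle=False) as npz:
        subject_id = str(npz["__subject_id"])
        run = Run(str(npz["__run"]))
        tr_s = float(npz["__tr_s"])
        data = {int(k[len("parcel_"):]): np.asarray(npz[k])
                for k in npz.files if k.startswith("parcel_")}
    if parcellation is not None:
        missing = set(parcellation.parcel_ids) - set(data)
        if missing:
            raise FormatError(
                f"parcels {sorted(missing)} absent from archive", path=path)
    return ParcelTimeseries(subject_id=subject_id, run=run, tr_s=tr_s, data=data)


def read_timeseries_nifti(data_path: str, atlas_path: str,
                          parcellation: Parcellation, subject_id: str,
                          run: Run, tr_s: float | None = None
                          ) -> ParcelTimeseries:
    """Extract parcel-wise time series from a 4-D volume and a label atlas.

    Each parcel's feature vector is the ordered (C-flat-index) set of voxel
    time courses whose atlas label equals the parcel id; label 0 and labels
    outside the parcellation are ignored.  Parcels missing from the atlas
    yield empty (0-feature) arrays and a warning.
    """
    import warnings
    import nibabel as nib

    img = nib.load(data_path)
    atlas = nib.load(atlas_path)
    if img.shape[:3] != atlas.shape[:3]:
        raise FormatError(
            f"atlas grid {atlas.shape[:3]} does not match data grid "
            f"{img.shape[:3]}", path=atlas_path)
    vol = np.asarray(img.dataobj)
    if vol.ndim != 4:
        raise FormatError(f"expected 4-D volume, got shape {vol.shape}",
                          path=data_path)
    labels = np.asarray(atlas.dataobj).astype(int)
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    if tr_s is None or tr_s <= 0:
        raise FormatError("TR not present in header; pass tr_s explicitly",
                          path=data_path)
    flat_labels = labels.reshape(-1)
    flat_data = vol.reshape(-1, vol.shape[3])
    data = {}
    for pid in parcellation.parcel_ids:
        idx = np.flatnonzero(flat_labels == pid)
        if idx.size == 0:
            warnings.warn(f"parcel {pid} absent from atlas {atlas_path}")
        data[pid] = np.asarray(flat_data[idx], dtype=float)
    return ParcelTimeseries(subject_id=subject_id, run=run, tr_s=tr_s, data=data)


# ---------------------------------------------------------------------------
# Parcel-wise result maps

def write_parcel_map(values: Mapping[int, float], parcellation: Parcellation,
                     path: str, value_name: str = "value",
                     nifti_path: str | None = None,
                     missing_value: float = np.nan) -> None:
    """Write a parcel -> value map as TSV (and optionally as a volume)."""
    known = set(parcellation.parcel_ids)
    unknown = set(values) - known
    if unknown:
        raise FormatError(f"unknown parcel_id(s) {sorted(unknown)}")
    rows = [(pid, network, values.get(pid, np.nan))
            for pid, network, _ in parcellation.parcels]
    df = pd.DataFrame(rows, columns=["parcel_id", "network", value_name])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    if nifti_path is not None:
        if parcellation.atlas_volume is None:
            raise FormatError("parcellation has no atlas volume")
        import nibabel as nib
        atlas = nib.load(parcellation.atlas_volume)
        labels = np.asarray(atlas.dataobj).astype(int)
        out = np.full(labels.shape, missing_value, dtype=float)
        for pid, val in values.items():
            out[labels == pid] = val
        nib.save(nib.Nifti1Image(out, atlas.affine), nifti_path)


def read_parcel_map(path: str, value_name: str = "value") -> dict[int, float]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["parcel_id", value_name], path)
    out = {}
    for r in df.itertuples(index=False):
        v = getattr(r, value_name)
        if not pd.isna(v):
            out[int(r.parcel_id)] = float(v)
    return out
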