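"""Linking summarization behaviour to neural memory transformation.

In each parcel that shows a positive transformation effect, every
subject's scene-level %Summary bias is correlated with the group
per-scene transformation value; subject correlations go into a
random-effects one-sample t-test against zero (two-tailed) with BH-FDR
across the tested parcels.  A scene-duration control repeats the
subject-level correlation with scene duration in place of transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .io_formats import AnalysisConfig, MovieSegmentation, Parcellation
from .transformation import TransformationResult

logger = logging.getLogger(__name__)

__all__ = [
    "LinkResult",
    "link_bias_transformation",
    "control_duration_correlation",
    "network_tally",
]


@dataclass
class LinkResult:
    """Per-parcel linking table plus the per-subject correlation matrix."""

    parcels: pd.DataFrame          # parcel_id, t, p, d, q, significant, direction, n_subjects
    subject_r: pd.DataFrame        # parcel_id, subject_id, r, n_scenes


def _subject_scene_series(behavior: pd.DataFrame, column: str
                          ) -> dict[str, pd.Series]:
    out = {}
    for subject_id, grp in behavior.groupby("subject_id"):
        sub = grp[grp["recalled"]].dropna(subset=[column])
        out[subject_id] = pd.Series(sub[column].to_numpy(),
                                    index=sub["scene_id"].to_numpy())
    return out


def link_bias_transformation(behavior: pd.DataFrame,
                             transform: TransformationResult,
                             cfg: AnalysisConfig,
                             bias_column: str = "summary_bias") -> LinkResult:
    """Correlate per-subject scene bias with group scene transformation.

    Only parcels with a positive transformation score are tested; only
    scenes the subject recalled with a defined bias enter, and subjects
    contributing fewer than ``min_scenes_per_subject`` scenes (or with
    constant bias) are dropped.
    """
    bias = _subject_scene_series(behavior, bias_column)
    rows, subj_rows = [], []
    tested = transform.positive_parcels
    for pid in tested:
        scene_t = transform.scene_t[pid]
        rs = []
        for subject_id, series in bias.items():
            common = series.index.intersection(scene_t.index)
            if len(common) < cfg.min_scenes_per_subject:
                logger.warning("subject %s: only %d scenes for parcel %d; dropped",
                               subject_id, len(common), pid)
                continue
            r = stats.pearson_r(series.loc[common].to_numpy(),
                                scene_t.loc[common].to_numpy())
            if np.isnan(r):
                logger.warning("subject %s: degenerate correlation in parcel %d;"
                               " dropped", subject_id, pid)
                continue
            rs.append(r)
            subj_rows.append((pid, subject_id, r, len(common)))
        if len(rs) < 2:
            rows.append((pid, np.nan, np.nan, np.nan, len(rs)))
            continue
        gs = stats.one_sample_t(rs)
        rows.append((pid, gs.t, gs.p, gs.d, gs.n))
    df = pd.DataFrame(rows, columns=["parcel_id", "t", "p", "d", "n_subjects"])
    rej, qv = stats.bh_fdr(df["p"].to_numpy(), cfg.fdr_q)
    df["q"] = qv
    df["significant"] = rej
    df["direction"] = np.where(df["t"] >= 0, "POSITIVE", "NEGATIVE")
    subject_r = pd.DataFrame(subj_rows, columns=["parcel_id", "subject_id",
                                                 "r", "n_scenes"])
    return LinkResult(parcels=df, subject_r=subject_r)


def control_duration_correlation(behavior: pd.DataFrame,
                                 seg: MovieSegmentation,
                                 cfg: AnalysisConfig | None = None,
                                 bias_column: str = "summary_bias"
                                 ) -> tuple[stats.GroupStat, pd.Series]:
    """Scene duration vs summary bias, per subject, t-tested at the group level."""
    cfg = cfg or AnalysisConfig()
    durations = pd.Series({sc.scene_id: sc.duration_s for sc in seg.scenes})
    bias = _subject_scene_series(behavior, bias_column)
    rs = {}
    for subject_id, series in bias.items():
        common = series.index.intersection(durations.index)
        if len(common) < cfg.min_scenes_per_subject:
            continue
        r = stats.pearson_r(series.loc[common].to_numpy(),
                            durations.loc[common].to_numpy())
        if not np.isnan(r):
            rs[subject_id] = r
    if len(rs) < 2:
        raise ValueError("insufficient scenes: fewer than 2 subjects with a "
                         "defined duration-bias correlation")
    return stats.one_sample_t(list(rs.values())), pd.Series(rs)


def network_tally(significant_parcels, parcellation: Parcellation
                  ) -> pd.DataFrame:
    """Count and proportion of above-threshold parcels per functional network."""
    sig = set(significant_parcels)
    networks = [n for _, n, _ in parcellation.parcels]
    counts = {n: 0 for n in dict.fromkeys(networks)}
    for pid, network, _ in parcellation.parcels:
        if pid in sig:
            counts[network] += 1
    total = sum(counts.values())
    rows = [(n, c, (c / total if total else 0.0)) for n, c in counts.items()]
    return pd.DataFrame(rows, columns=["network", "count", "proportion"])
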