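"""Individual movement measures, base-model feature sets and cohort tests.

Five base models, each a participants x features matrix combining both
conversation tasks:

====================  =======================================  ========
model                 channels                                 features
====================  =======================================  ========
``FACEsync``          12 retained AU intensities (following)   168
``HEADsync``          global head movement, pitch, yaw, roll   56
``BODYsync``          body motion energy (following)           14
``INTRAsync``         own head x body coordination (pooled)    14
``MovEx``             total head/body movement, expressivity   6
====================  =======================================  ========

Synchrony-based cells hold the seven distributional summaries of the
per-window peak profile; ``MovEx`` holds per-task scalars.  Missing cells
(unusable channels) are preserved as NaN at assembly — imputation happens
inside the cross-validation loops only, never here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from . import synchrony
from .types import (
    DEFAULT_RETAINED_AUS,
    ChannelSeries,
    DyadRoster,
    FeatureSet,
    LabelVector,
    SyncSummary,
    TimeSeriesBundle,
)
from .types import STAT_NAMES

__all__ = [
    "global_head_movement",
    "facial_expressiveness",
    "total_movement",
    "compute_sync_summaries",
    "compute_movement_scalars",
    "assemble_feature_set",
    "assemble_all_feature_sets",
    "dyad_labels",
    "cohort_stats",
    "sex_group_chi2",
    "CohortStats",
    "feature_name",
    "parse_feature_name",
    "MODEL_NAMES",
]

MODEL_NAMES = ("FACEsync", "HEADsync", "BODYsync", "INTRAsync", "MovEx")

MOVEX_MEASURES = ("expressiveness", "total_body", "total_head")


def global_head_movement(
    pitch: ChannelSeries, yaw: ChannelSeries, roll: ChannelSeries
) -> ChannelSeries:
    """Global head movement: per-frame Euclidean norm of the change in the
    three rotation angles; first frame 0 by convention."""
    if not (len(pitch) == len(yaw) == len(roll)):
        raise ValueError("pose channels must have equal length")
    arr = np.stack([pitch.values, yaw.values, roll.values])
    deltas = np.diff(arr, axis=1)
    norm = np.sqrt((deltas**2).sum(axis=0))
    values = np.concatenate(([0.0], norm))
    m = pitch.valid_mask & yaw.valid_mask & roll.valid_mask
    mask = np.concatenate(([m[0]], m[1:] & m[:-1]))
    return ChannelSeries("head_movement", values, pitch.fps, mask)


def facial_expressiveness(au_channels: Sequence[ChannelSeries]) -> float:
    """General facial expressiveness: mean AU intensity over valid frames
    of all usable retained AU channels.  NaN when nothing is usable."""
    usable = [c for c in au_channels if c.usable]
    if not usable:
        return float("nan")
    means = []
    for c in usable:
        v = c.values[c.valid_mask]
        if len(v):
            means.append(float(np.mean(v)))
    return float(np.mean(means)) if means else float("nan")


def total_movement(series: ChannelSeries) -> float:
    """Total movement as a per-frame rate: mean over valid frames (robust
    to how many frames survived preprocessing)."""
    if not series.usable:
        return float("nan")
    v = series.values[series.valid_mask]
    return float(np.mean(v)) if len(v) else float("nan")


# ---------------------------------------------------------------------------
# feature-name codec: "<channel>|<task>|<statistic>"


def feature_name(channel: str, task: str, statistic: str) -> str:
    return f"{channel}|{task}|{statistic}"


def parse_feature_name(name: str) -> Tuple[str, str, str]:
    channel, task, statistic = name.split("|")
    return channel, task, statistic


# ---------------------------------------------------------------------------
# summary computation over a simulated or loaded cohort


def compute_sync_summaries(
    bundles: Mapping[Tuple[str, str], TimeSeriesBundle],
    roster: DyadRoster,
    configs: Optional[Mapping[str, object]] = None,
    retained_aus: Sequence[str] = DEFAULT_RETAINED_AUS,
    preprocess: Optional[synchrony.PreprocessConfig] = None,
    tasks: Sequence[str] = ("hobbies", "mealplanning"),
    parts: Sequence[str] = ("face", "head", "body", "intra"),
) -> Dict[Tuple[str, str], Dict[str, SyncSummary]]:
    """All per-participant synchrony summaries needed by the base models.

    Returns ``{(participant_id, task): {channel_key: SyncSummary}}`` where
    channel keys are the retained AU names, ``head_movement``, ``pitch``,
    ``yaw``, ``roll``, ``body`` (each the participant's *following* of
    their partner) and ``intra_head_body`` (pooled intrapersonal).
    ``parts`` restricts computation to a subset of channel groups when
    only some base models are needed.
    """
    active = roster.finalized()
    fps = next(iter(bundles.values())).fps if bundles else 30.0
    if configs is None:
        configs = {g: synchrony.default_sync_config(g, fps) for g in ("face", "head", "body")}
    out: Dict[Tuple[str, str], Dict[str, SyncSummary]] = {}
    au_names = [f"{a}_r" for a in retained_aus]
    for p in active.active():
        partner = active.partner_of(p.participant_id)
        for task in tasks:
            me = bundles[(p.participant_id, task)]
            other = bundles[(partner.participant_id, task)]
            cell: Dict[str, SyncSummary] = {}
            if "face" in parts:
                for au in au_names:
                    cell[au] = synchrony.interpersonal_following_summary(
                        me, other, au, configs["face"], preprocess
                    )
            # derive global head movement on the fly for both members
            for b in (me, other):
                if b.head_movement is None and b.pose:
                    b.head_movement = global_head_movement(
                        b.pose["pitch"], b.pose["yaw"], b.pose["roll"]
                    )
            if "head" in parts:
                for ch in ("head_movement", "pitch", "yaw", "roll"):
                    cell[ch] = synchrony.interpersonal_following_summary(
                        me, other, ch, configs["head"], preprocess
                    )
            if "body" in parts:
                cell["body"] = synchrony.interpersonal_following_summary(
                    me, other, "body", configs["body"], preprocess
                )
            if "intra" in parts:
                head_ch = me.head_movement
                body_ch = me.body
                if preprocess is not None:
                    head_ch = synchrony.preprocess_series(head_ch, me.confidence, preprocess)
                    body_ch = synchrony.preprocess_series(body_ch, None, preprocess)
                cell["intra_head_body"] = synchrony.intrapersonal_summary(
                    head_ch, body_ch, configs["body"]
                )
            out[(p.participant_id, task)] = cell
    return out


def compute_movement_scalars(
    bundles: Mapping[Tuple[str, str], TimeSeriesBundle],
    roster: DyadRoster,
    retained_aus: Sequence[str] = DEFAULT_RETAINED_AUS,
    tasks: Sequence[str] = ("hobbies", "mealplanning"),
) -> Dict[Tuple[str, str], Dict[str, float]]:
    """Per-task individual movement scalars for the ``MovEx`` model."""
    active = roster.finalized()
    au_names = [f"{a}_r" for a in retained_aus]
    out: Dict[Tuple[str, str], Dict[str, float]] = {}
    for p in active.active():
        for task in tasks:
            b = bundles[(p.participant_id, task)]
            if b.head_movement is None and b.pose:
                b.head_movement = global_head_movement(
                    b.pose["pitch"], b.pose["yaw"], b.pose["roll"]
                )
            out[(p.participant_id, task)] = {
                "expressiveness": facial_expressiveness(
                    [b.au[a] for a in au_names if a in b.au]
                ),
                "total_body": total_movement(b.body),
                "total_head": total_movement(b.head_movement),
            }
    return out


_MODEL_CHANNELS = {
    "HEADsync": ("head_movement", "pitch", "roll", "yaw"),
    "BODYsync": ("body",),
    "INTRAsync": ("intra_head_body",),
}


def assemble_feature_set(
    model_name: str,
    roster: DyadRoster,
    sync_summaries: Mapping[Tuple[str, str], Mapping[str, SyncSummary]],
    movement_scalars: Optional[Mapping[Tuple[str, str], Mapping[str, float]]] = None,
    retained_aus: Sequence[str] = DEFAULT_RETAINED_AUS,
    tasks: Sequence[str] = ("hobbies", "mealplanning"),
) -> FeatureSet:
    """Build one base model's participants x features matrix.

    Column order is deterministic: channels sorted, then tasks, then the
    seven statistics in canonical order.  Missing summaries stay NaN; an
    absent (participant, task, channel) cell raises with its name.
    """
    active = roster.finalized()
    pids = [p.participant_id for p in active.active()]
    if model_name == "MovEx":
        if movement_scalars is None:
            raise ValueError("MovEx requires movement scalars")
        names = [feature_name(m, t, "value") for m in sorted(MOVEX_MEASURES) for t in tasks]
        rows = []
        for pid in pids:
            row = []
            for m in sorted(MOVEX_MEASURES):
                for t in tasks:
                    try:
                        row.append(movement_scalars[(pid, t)][m])
                    except KeyError:
                        raise ValueError(f"missing movement cell: {pid}/{t}/{m}") from None
            rows.append(row)
        return FeatureSet(model_name, np.array(rows, dtype=float), names, pids)

    if model_name == "FACEsync":
        channels = sorted(f"{a}_r" for a in retained_aus)
    elif model_name in _MODEL_CHANNELS:
        channels = sorted(_MODEL_CHANNELS[model_name])
    else:
        raise ValueError(f"unknown model {model_name!r}")
    names = [
        feature_name(ch, t, s) for ch in channels for t in tasks for s in STAT_NAMES
    ]
    rows = []
    for pid in pids:
        row = []
        for ch in channels:
            for t in tasks:
                try:
                    summ = sync_summaries[(pid, t)][ch]
                except KeyError:
                    raise ValueError(f"missing summary cell: {pid}/{t}/{ch}") from None
                d = summ.as_dict()
                row.extend(d[s] for s in STAT_NAMES)
        rows.append(row)
    return FeatureSet(model_name, np.array(rows, dtype=float), names, pids)


def assemble_all_feature_sets(
    roster: DyadRoster,
    sync_summaries,
    movement_scalars,
    retained_aus: Sequence[str] = DEFAULT_RETAINED_AUS,
    tasks: Sequence[str] = ("hobbies", "mealplanning"),
) -> Dict[str, FeatureSet]:
    return {
        m: assemble_feature_set(m, roster, sync_summaries, movement_scalars, retained_aus, tasks)
        for m in MODEL_NAMES
    }


def dyad_labels(roster: DyadRoster, scheme: str = "dyad_type") -> LabelVector:
    """Binary labels: dyad type (both members share the label) or, as the
    supplementary variant, individual diagnosis."""
    active = roster.finalized()
    pids, groups, labels = [], [], []
    for p in active.active():
        pids.append(p.participant_id)
        groups.append(p.dyad_id)
        if scheme == "dyad_type":
            labels.append(1 if active.dyad_type(p.dyad_id) == "mixed" else -1)
        elif scheme == "diagnosis":
            labels.append(1 if p.diagnosis == "ASD" else -1)
        else:
            raise ValueError(f"unknown labeling scheme {scheme!r}")
    positive = "mixed" if scheme == "dyad_type" else "ASD"
    return LabelVector(scheme, np.array(labels), positive, pids, groups)


# ---------------------------------------------------------------------------
# cohort statistics


@dataclass
class CohortStats:
    table: pd.DataFrame  # rows: covariates; cols: statistic, p_raw, p_adjusted
    chi2: float
    chi2_p: float
    sex_counts: pd.DataFrame


def sex_group_chi2(counts: np.ndarray) -> Tuple[float, float]:
    """Yates-continuity-corrected chi-square of independence on a 2x2
    sex x group table."""
    res = sp_stats.chi2_contingency(np.asarray(counts), correction=True)
    return float(res.statistic), float(res.pvalue)


def cohort_stats(roster: DyadRoster, use_welch: bool = False) -> CohortStats:
    """Group comparisons between diagnosis groups on the final roster.

    Rank-sum tests (normal approximation) for age and both IQ measures,
    Benjamini-Hochberg adjusted across the three tests; Yates-corrected
    chi-square of independence for sex x group.  ``use_welch`` swaps the
    rank-sum tests for Welch t-tests.
    """
    df = roster.finalized().to_frame()
    df = df[~df["excluded"]]
    groups = {g: df[df["diagnosis"] == g] for g in ("ASD", "TD")}
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("both diagnosis groups must be non-empty")
    rows = []
    pvals = []
    for covar in ("age", "iq_crystalline", "iq_nonverbal"):
        a = groups["ASD"][covar].dropna().to_numpy(float)
        b = groups["TD"][covar].dropna().to_numpy(float)
        if use_welch:
            stat, p = sp_stats.ttest_ind(a, b, equal_var=False)
        else:
            stat, p = sp_stats.ranksums(a, b)
        rows.append({"covariate": covar, "statistic": float(stat), "p_raw": float(p)})
        pvals.append(float(p))
    adj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(rows)
    table["p_adjusted"] = adj
    counts = pd.crosstab(df["sex"], df["diagnosis"])
    chi2, chi2_p = sex_group_chi2(counts.to_numpy())
    return CohortStats(table, chi2, chi2_p, counts)
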