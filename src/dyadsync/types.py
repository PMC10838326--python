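"""Core data containers shared across the pipeline.

Everything per-frame is a :class:`ChannelSeries`; everything per-participant
and per-task is a :class:`TimeSeriesBundle`.  Synchrony summaries, feature
matrices and cross-validation bookkeeping have small dedicated containers so
invariants (dimensions, dyad grouping, bounded correlations) can be asserted
where they are produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantRecord",
    "DyadRoster",
    "CouplingProfile",
    "ROISpec",
    "ChannelSeries",
    "TimeSeriesBundle",
    "SyncConfig",
    "CrossCorrMatrix",
    "PeakProfile",
    "SyncSummary",
    "FeatureSet",
    "LabelVector",
    "CVScheme",
    "LinearModel",
    "Metrics",
    "ModelResult",
    "PermutationResult",
    "StackingInput",
    "ImportanceMap",
    "EXPECTED_DIMS",
]

DIAGNOSES = ("ASD", "TD")
DYAD_TYPES = ("mixed", "control")
EXCLUSION_REASONS = (
    "unverified_diagnosis",
    "tracking_loss",
    "partner_excluded",
    "technical",
)

#: default retained facial action units (12 intensity channels; the
#: channel-exclusion threshold of any given dataset may retain a different
#: set — configurable wherever used)
DEFAULT_RETAINED_AUS = (
    "AU01", "AU04", "AU06", "AU07", "AU10", "AU12",
    "AU15", "AU17", "AU20", "AU25", "AU26", "AU45",
)

#: printed per-model feature-vector widths (channels x 7 stats x 2 tasks,
#: or 3 scalars x 2 tasks for the movement/expressiveness model)
EXPECTED_DIMS = {
    "FACEsync": 168,
    "HEADsync": 56,
    "BODYsync": 14,
    "INTRAsync": 14,
    "MovEx": 6,
}


@dataclass
class ParticipantRecord:
    participant_id: str
    dyad_id: str
    diagnosis: str  # "ASD" | "TD"
    sex: Optional[str] = None  # "female" | "male"
    age: Optional[float] = None
    iq_crystalline: Optional[float] = None
    iq_nonverbal: Optional[float] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.exclusion_reason is not None and self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")


class DyadRoster:
    """Roster of participants organised in dyads.

    A dyad is *mixed* iff exactly one member carries an ASD diagnosis,
    *control* iff both are TD.  Two ASD members in one dyad are rejected:
    the study design pairs each autistic participant with a non-autistic
    partner.
    """

    def __init__(self, participants: Sequence[ParticipantRecord]):
        self.participants: List[ParticipantRecord] = list(participants)
        by_dyad: Dict[str, List[ParticipantRecord]] = {}
        for p in self.participants:
            by_dyad.setdefault(p.dyad_id, []).append(p)
        for dyad_id, members in by_dyad.items():
            if len(members) != 2:
                raise ValueError(f"dyad {dyad_id!r} has {len(members)} members, expected 2")
            n_asd = sum(m.diagnosis == "ASD" for m in members)
            if n_asd == 2:
                raise ValueError(f"dyad {dyad_id!r} pairs two ASD diagnoses")
        self._by_dyad = by_dyad

    # -- queries ---------------------------------------------------------
    @property
    def dyad_ids(self) -> List[str]:
        return list(self._by_dyad)

    def members(self, dyad_id: str) -> List[ParticipantRecord]:
        return list(self._by_dyad[dyad_id])

    def partner_of(self, participant_id: str) -> ParticipantRecord:
        p = self.get(participant_id)
        a, b = self._by_dyad[p.dyad_id]
        return b if a.participant_id == participant_id else a

    def get(self, participant_id: str) -> ParticipantRecord:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(f"unknown participant id {participant_id!r}")

    def dyad_type(self, dyad_id: str) -> str:
        members = self._by_dyad[dyad_id]
        n_asd = sum(m.diagnosis == "ASD" for m in members)
        return "mixed" if n_asd == 1 else "control"

    @property
    def dyad_types(self) -> Dict[str, str]:
        return {d: self.dyad_type(d) for d in self._by_dyad}

    def count_dyads(self, dyad_type: Optional[str] = None) -> int:
        if dyad_type is None:
            return len(self._by_dyad)
        return sum(1 for d in self._by_dyad if self.dyad_type(d) == dyad_type)

    def active(self) -> List[ParticipantRecord]:
        return [p for p in self.participants if not p.excluded]

    def finalized(self) -> "DyadRoster":
        """Roster restricted to non-excluded participants (complete dyads only)."""
        kept = [p for p in self.participants if not p.excluded]
        by_dyad: Dict[str, int] = {}
        for p in kept:
            by_dyad[p.dyad_id] = by_dyad.get(p.dyad_id, 0) + 1
        incomplete = [d for d, n in by_dyad.items() if n != 2]
        if incomplete:
            raise ValueError(f"dyads with a single active member remain: {incomplete}")
        return DyadRoster(kept)

    def __len__(self) -> int:
        return len(self.participants)

    # -- frame round trip ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.participants],
                "dyad_id": [p.dyad_id for p in self.participants],
                "diagnosis": [p.diagnosis for p in self.participants],
                "sex": [p.sex for p in self.participants],
                "age": [p.age for p in self.participants],
                "iq_crystalline": [p.iq_crystalline for p in self.participants],
                "iq_nonverbal": [p.iq_nonverbal for p in self.participants],
                "excluded": [p.excluded for p in self.participants],
                "exclusion_reason": [p.exclusion_reason for p in self.participants],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DyadRoster":
        records = []
        for row in df.itertuples(index=False):
            reason = getattr(row, "exclusion_reason", None)
            if isinstance(reason, float) and math.isnan(reason):
                reason = None
            records.append(
                ParticipantRecord(
                    participant_id=str(row.participant_id),
                    dyad_id=str(row.dyad_id),
                    diagnosis=str(row.diagnosis),
                    sex=None if pd.isna(row.sex) else str(row.sex),
                    age=None if pd.isna(row.age) else float(row.age),
                    iq_crystalline=None if pd.isna(row.iq_crystalline) else float(row.iq_crystalline),
                    iq_nonverbal=None if pd.isna(row.iq_nonverbal) else float(row.iq_nonverbal),
                    excluded=bool(row.excluded),
                    exclusion_reason=reason,
                )
            )
        return cls(records)


CHANNEL_GROUPS = ("face", "head", "body")


@dataclass
class CouplingProfile:
    """Generative coupling parameters for one simulated dyad.

    ``coupling_strength`` maps each channel group to either a single float
    (member B unilaterally follows member A with that strength) or a pair
    ``(a_follows, b_follows)`` giving each member's tendency to trail the
    partner's latent process.  ``coupling_lag`` is in seconds and must be a
    whole number of frames at the simulation frame rate.
    """

    coupling_strength: Mapping[str, object] = field(
        default_factory=lambda: {"face": 0.6, "head": 0.6, "body": 0.6}
    )
    coupling_lag: float = 0.5
    base_process: float = 0.9
    noise_sd: float = 0.3
    intrapersonal_coupling: float = 0.4

    def strengths(self, group: str) -> Tuple[float, float]:
        c = self.coupling_strength.get(group, 0.0)
        if isinstance(c, (tuple, list)):
            a, b = float(c[0]), float(c[1])
        else:
            a, b = 0.0, float(c)
        for v in (a, b):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"coupling strength {v} outside [0, 1]")
        return a, b

    def __post_init__(self) -> None:
        for g in self.coupling_strength:
            self.strengths(g)
        if self.coupling_lag < 0:
            raise ValueError("coupling_lag must be >= 0")
        if not -1.0 < self.base_process < 1.0:
            raise ValueError("base_process must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.intrapersonal_coupling <= 1.0:
            raise ValueError("intrapersonal_coupling must lie in [0, 1]")

    def lag_frames(self, fps: float) -> int:
        lf = self.coupling_lag * fps
        if abs(lf - round(lf)) > 1e-9:
            raise ValueError(
                f"coupling_lag {self.coupling_lag}s is not a whole number of frames at {fps} fps"
            )
        return int(round(lf))


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest, 0-based, half-open [x0,x1) x [y0,y1)."""

    label: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("ROI must have positive extent (x1 > x0, y1 > y0)")

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def check_within(self, frame_shape: Tuple[int, int]) -> None:
        h, w = frame_shape[:2]
        if self.x0 < 0 or self.y0 < 0 or self.x1 > w or self.y1 > h:
            raise ValueError(f"ROI {self} outside frame of shape {(h, w)}")


@dataclass
class ChannelSeries:
    """One per-frame signal with a validity mask."""

    name: str
    values: np.ndarray
    fps: float
    valid_mask: Optional[np.ndarray] = None
    usable: bool = True
    unusable_reason: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("channel values must be 1-D")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValueError("valid_mask must match values in length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - self.valid_mask.mean()) if len(self) else 0.0

    def copy(self) -> "ChannelSeries":
        return ChannelSeries(
            self.name,
            self.values.copy(),
            self.fps,
            self.valid_mask.copy(),
            self.usable,
            self.unusable_reason,
        )


@dataclass
class TimeSeriesBundle:
    """All per-frame channels for one participant in one task."""

    participant_id: str
    task: str
    fps: float
    au: Dict[str, ChannelSeries] = field(default_factory=dict)
    pose: Dict[str, ChannelSeries] = field(default_factory=dict)  # pitch/yaw/roll
    head_movement: Optional[ChannelSeries] = None  # derived global head movement
    body: Optional[ChannelSeries] = None  # motion-energy channel
    confidence: Optional[ChannelSeries] = None

    def channel(self, name: str) -> ChannelSeries:
        if name in self.au:
            return self.au[name]
        if name in self.pose:
            return self.pose[name]
        if name == "head_movement":
            if self.head_movement is None:
                raise KeyError("no derived head-movement channel present")
            return self.head_movement
        if name == "body":
            if self.body is None:
                raise KeyError("no body motion-energy channel present")
            return self.body
        raise KeyError(f"unknown channel {name!r}")

    @property
    def n_frames(self) -> int:
        for group in (self.au, self.pose):
            for s in group.values():
                return len(s)
        if self.body is not None:
            return len(self.body)
        return 0


@dataclass(frozen=True)
class SyncConfig:
    """Windowing parameters for the cross-lagged correlation machinery."""

    window_frames: int
    step_frames: int
    max_lag_frames: int
    min_valid_fraction: float = 0.8
    peak_rule: str = "max_positive"  # or "max_absolute"

    def __post_init__(self) -> None:
        if self.window_frames <= 2 * self.max_lag_frames:
            raise ValueError("window_frames must exceed 2 x max_lag_frames")
        if self.step_frames < 1:
            raise ValueError("step_frames must be >= 1")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must lie in (0, 1]")
        if self.peak_rule not in ("max_positive", "max_absolute"):
            raise ValueError(f"unknown peak rule {self.peak_rule!r}")


@dataclass
class CrossCorrMatrix:
    """Windows x lags grid of Pearson correlations (NaN = missing)."""

    values: np.ndarray
    lag_axis: np.ndarray
    window_starts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lag_axis = np.asarray(self.lag_axis, dtype=int)
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        if self.values.shape != (len(self.window_starts), len(self.lag_axis)):
            raise ValueError("values grid does not match axes")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("correlations outside [-1, 1]")
        if not np.array_equal(self.lag_axis, -self.lag_axis[::-1]):
            raise ValueError("lag axis must be symmetric about 0")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


@dataclass
class PeakProfile:
    """Per-window peak synchrony in one lag direction."""

    values: np.ndarray
    direction: str  # "A_leads" | "B_leads" | "pooled"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.direction not in ("A_leads", "B_leads", "pooled"):
            raise ValueError(f"unknown direction {self.direction!r}")


STAT_NAMES = ("mean", "median", "sd", "min", "max", "skewness", "kurtosis")


@dataclass
class SyncSummary:
    """The seven distributional summaries of a per-window peak profile."""

    mean: float = math.nan
    median: float = math.nan
    sd: float = math.nan
    min: float = math.nan
    max: float = math.nan
    skewness: float = math.nan
    kurtosis: float = math.nan
    missing_reason: Optional[str] = None

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in STAT_NAMES}

    @property
    def all_missing(self) -> bool:
        return all(math.isnan(getattr(self, k)) for k in STAT_NAMES)


@dataclass
class FeatureSet:
    """Participants x features matrix for one base model."""

    model_name: str
    matrix: np.ndarray
    feature_names: List[str]
    participant_ids: List[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.model_name not in EXPECTED_DIMS:
            raise ValueError(f"unknown model {self.model_name!r}")
        expected = EXPECTED_DIMS[self.model_name]
        if self.matrix.shape != (len(self.participant_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match row/column labels")
        if len(self.feature_names) != expected:
            raise ValueError(
                f"{self.model_name} expects {expected} features, got {len(self.feature_names)}"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def expected_dim(self) -> int:
        return EXPECTED_DIMS[self.model_name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.participant_ids, columns=self.feature_names)


@dataclass
class LabelVector:
    scheme: str  # "dyad_type" | "diagnosis"
    labels: np.ndarray  # +1 positive class, -1 negative class
    positive_class: str
    participant_ids: List[str]
    group_ids: List[str]  # dyad id per participant

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if set(np.unique(self.labels)) - {-1, 1}:
            raise ValueError("labels must be coded -1/+1")
        if len(self.labels) != len(self.participant_ids) or len(self.labels) != len(self.group_ids):
            raise ValueError("labels, participants and groups must align")


@dataclass
class CVScheme:
    """Dyad-grouped stratified fold assignments, repeated over permutations.

    ``assignments[p, i]`` is the outer test-fold index of participant ``i``
    in repetition ``p``.
    """

    outer_folds: int
    outer_permutations: int
    inner_folds: int
    inner_permutations: int
    group_ids: List[str]
    assignments: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.shape != (self.outer_permutations, len(self.group_ids)):
            raise ValueError("assignment grid does not match permutations x participants")


@dataclass
class LinearModel:
    weights: np.ndarray
    bias: float
    C: float
    class_weights: Dict[int, float]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias


@dataclass
class Metrics:
    sensitivity: float
    specificity: float
    bac: float
    auc: float
    ppv: float
    npv: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "bac": self.bac,
            "auc": self.auc,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass
class ModelResult:
    model_name: str
    participant_ids: List[str]
    scores: np.ndarray  # participants x outer permutations, out-of-fold
    aggregated_scores: np.ndarray
    predictions: np.ndarray  # -1/+1
    metrics: Metrics
    fold_weights: Optional[np.ndarray]  # models x features (linear only)
    fold_biases: Optional[np.ndarray]
    chosen_params: List[Dict[str, float]]
    feature_names: Optional[List[str]] = None


@dataclass
class PermutationResult:
    observed_bac: float
    null_bacs: np.ndarray
    n_perm: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.null_bacs = np.asarray(self.null_bacs, dtype=float)
        if len(self.null_bacs) != self.n_perm:
            raise ValueError("null sample size must equal n_perm")

    @property
    def p_value(self) -> float:
        # add-one estimator: never returns 0
        return (1.0 + float((self.null_bacs >= self.observed_bac - 1e-12).sum())) / (1.0 + self.n_perm)

    def significant(self, alpha: Optional[float] = None) -> bool:
        return self.p_value <= (self.alpha if alpha is None else alpha)


@dataclass
class StackingInput:
    """Participants x base-models matrix of aggregated out-of-fold scores."""

    matrix: np.ndarray
    model_names: List[str]
    participant_ids: List[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.participant_ids), len(self.model_names)):
            raise ValueError("score matrix does not match rows/columns")
        if not np.isfinite(self.matrix).all():
            raise ValueError("stacking inputs must not contain missing scores")


@dataclass
class ImportanceMap:
    feature_names: List[str]
    mean_weight: np.ndarray
    cv_ratio: np.ndarray  # mean / SE across CV models; +-inf where SE == 0
    sign_consistency: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_weight": self.mean_weight,
                "cv_ratio": self.cv_ratio,
                "sign_consistency": self.sign_consistency,
            },
            index=self.feature_names,
        )
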