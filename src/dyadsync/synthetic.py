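"""Synthetic dyad cohorts and lag-coupled behavioral time series.

The study design this package analyses — two strangers seated face to
face, two ten-minute conversation tasks recorded at 30 frames per second,
facial action-unit intensities and head pose from automated face tracking
plus a body motion-energy channel — involves clinical recordings that are
never public.  This module generates rosters and per-frame signals with
the statistical structure the analysis assumes, so the whole pipeline is
exercisable and testable without any download.

Generative model (per channel): each member owns a stationary AR(1)
latent process with unit variance.  The weaker follower's observed
signal mixes their own latent with the partner's lag-shifted latent at
their following strength ``c``; the stronger follower then mixes their
own latent with the partner's lag-shifted *composite* signal (see
:func:`_coupled_pair`).  Measurement noise is white.  Coupling strength
is the single dial linking the generator to the synchrony estimates
downstream: the follower's peak windowed cross-correlation grows
monotonically with ``c``, its argmax lag recovers the planted lag, and
``c = 1`` with zero noise is an exact delayed copy.

Dyad-type contrast (defaults): control (TD-TD) dyads couple symmetrically
at 0.6 in both directions; mixed (ASD-TD) dyads are asymmetric — the TD
member follows at 0.6 while the autistic member follows at 0.2 — and their
coupling is drawn with doubled spread across dyads.  This encodes the
*direction* of the elevated-and-more-varied adaptation contrast the
analysis is designed to detect, without claiming empirical magnitudes
(none are published for these conditions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import (
    DEFAULT_RETAINED_AUS,
    ChannelSeries,
    CouplingProfile,
    DyadRoster,
    ParticipantRecord,
    ROISpec,
    TimeSeriesBundle,
)

__all__ = [
    "CovariateConfig",
    "CouplingContrast",
    "generate_roster",
    "generate_cohort_covariates",
    "apply_exclusions",
    "draw_coupling_profile",
    "simulate_dyad_timeseries",
    "simulate_cohort",
    "render_motion_frames",
    "TASKS",
]

TASKS = ("hobbies", "mealplanning")


@dataclass(frozen=True)
class CovariateConfig:
    """Per-diagnosis covariate distributions (cohort-table defaults).

    Ages are normal, clipped to the study's 18-60 inclusion range; IQ is
    normal clipped below at 70 (normal-intelligence inclusion criterion);
    sex is Bernoulli on the female proportion.
    """

    age_mean: Mapping[str, float] = field(default_factory=lambda: {"ASD": 37.18, "TD": 31.48})
    age_sd: Mapping[str, float] = field(default_factory=lambda: {"ASD": 13.14, "TD": 10.78})
    iq_crystalline_mean: Mapping[str, float] = field(
        default_factory=lambda: {"ASD": 113.68, "TD": 113.98}
    )
    iq_crystalline_sd: Mapping[str, float] = field(
        default_factory=lambda: {"ASD": 16.90, "TD": 16.69}
    )
    iq_nonverbal_mean: Mapping[str, float] = field(
        default_factory=lambda: {"ASD": 119.75, "TD": 117.03}
    )
    iq_nonverbal_sd: Mapping[str, float] = field(
        default_factory=lambda: {"ASD": 23.44, "TD": 17.37}
    )
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"ASD": 18 / 28, "TD": 26 / 60}
    )
    age_range: Tuple[float, float] = (18.0, 60.0)
    iq_floor: float = 70.0


def generate_roster(
    n_mixed: int,
    n_control: int,
    seed: int,
    covariates: Optional[CovariateConfig] = CovariateConfig(),
) -> DyadRoster:
    """Random cohort of ``n_mixed`` ASD-TD and ``n_control`` TD-TD dyads.

    Mixed dyads pair exactly one ASD with one TD member; control dyads are
    two TD members.  Covariates (sex, age, both IQ measures) are drawn per
    diagnosis group from ``covariates`` (pass ``None`` to leave them
    blank).  Deterministic given ``seed``.
    """
    if n_mixed < 0 or n_control < 0:
        raise ValueError("dyad counts must be non-negative")
    records: List[ParticipantRecord] = []
    idx = 0
    for d in range(n_mixed):
        dyad_id = f"D{d + 1:03d}"
        for diag in ("ASD", "TD"):
            records.append(ParticipantRecord(f"P{idx + 1:03d}", dyad_id, diag))
            idx += 1
    for d in range(n_control):
        dyad_id = f"D{n_mixed + d + 1:03d}"
        for _ in range(2):
            records.append(ParticipantRecord(f"P{idx + 1:03d}", dyad_id, "TD"))
            idx += 1
    roster = DyadRoster(records)
    if covariates is not None:
        roster = generate_cohort_covariates(roster, covariates, seed)
    return roster


def generate_cohort_covariates(
    roster: DyadRoster, config: CovariateConfig, seed: int
) -> DyadRoster:
    """Fill sex/age/IQ per diagnosis group from the configured distributions."""
    rng = np.random.default_rng([seed, 0x0C0F])
    records = []
    for p in roster.participants:
        g = p.diagnosis
        age = float(
            np.clip(
                rng.normal(config.age_mean[g], config.age_sd[g]),
                *config.age_range,
            )
        )
        iqc = float(max(config.iq_floor, rng.normal(config.iq_crystalline_mean[g], config.iq_crystalline_sd[g])))
        iqn = float(max(config.iq_floor, rng.normal(config.iq_nonverbal_mean[g], config.iq_nonverbal_sd[g])))
        sex = "female" if rng.random() < config.female_fraction[g] else "male"
        records.append(
            ParticipantRecord(
                p.participant_id,
                p.dyad_id,
                p.diagnosis,
                sex=sex,
                age=age,
                iq_crystalline=iqc,
                iq_nonverbal=iqn,
                excluded=p.excluded,
                exclusion_reason=p.exclusion_reason,
            )
        )
    return DyadRoster(records)


def apply_exclusions(
    raw_roster: DyadRoster, exclusion_events: Sequence[Tuple[str, str]]
) -> DyadRoster:
    """Exclusion bookkeeping with partner cascading.

    Excluding any participant also excludes their dyad partner (reason
    ``partner_excluded``), so the active roster always consists of
    complete dyads.  Use ``.active()`` for the remaining participants.
    """
    known = {p.participant_id for p in raw_roster.participants}
    for pid, _ in exclusion_events:
        if pid not in known:
            raise KeyError(f"unknown participant id {pid!r}")
    excluded: Dict[str, str] = {}
    for pid, reason in exclusion_events:
        excluded.setdefault(pid, reason)
    for pid in list(excluded):
        partner = raw_roster.partner_of(pid)
        excluded.setdefault(partner.participant_id, "partner_excluded")
    records = []
    for p in raw_roster.participants:
        records.append(
            ParticipantRecord(
                p.participant_id,
                p.dyad_id,
                p.diagnosis,
                sex=p.sex,
                age=p.age,
                iq_crystalline=p.iq_crystalline,
                iq_nonverbal=p.iq_nonverbal,
                excluded=p.excluded or p.participant_id in excluded,
                exclusion_reason=excluded.get(p.participant_id, p.exclusion_reason),
            )
        )
    return DyadRoster(records)


@dataclass(frozen=True)
class CouplingContrast:
    """How coupling strengths are drawn per dyad type.

    Control dyads draw both members' following strengths around
    ``control_mean``; mixed dyads draw the TD member around
    ``mixed_td_mean`` and the autistic member around ``mixed_asd_mean``,
    with doubled spread (``mixed_sd``) encoding more heterogeneous
    adaptation.  All draws are clipped to [0, 1].
    """

    control_mean: float = 0.6
    control_sd: float = 0.1
    mixed_td_mean: float = 0.6
    mixed_asd_mean: float = 0.2
    mixed_sd: float = 0.2
    coupling_lag: float = 0.5
    base_process: float = 0.9
    noise_sd: float = 0.3
    intrapersonal_coupling: float = 0.4


def draw_coupling_profile(
    dyad_type: str,
    rng: np.random.Generator,
    contrast: CouplingContrast = CouplingContrast(),
    member_a_diagnosis: str = "ASD",
) -> CouplingProfile:
    """Draw one dyad's coupling profile under the dyad-type contrast.

    Member A is the first member of the dyad; for mixed dyads
    ``member_a_diagnosis`` says which member carries the ASD diagnosis so
    the asymmetry lands on the right person.
    """
    if dyad_type == "control":
        a = float(np.clip(rng.normal(contrast.control_mean, contrast.control_sd), 0, 1))
        b = float(np.clip(rng.normal(contrast.control_mean, contrast.control_sd), 0, 1))
    elif dyad_type == "mixed":
        asd = float(np.clip(rng.normal(contrast.mixed_asd_mean, contrast.mixed_sd), 0, 1))
        td = float(np.clip(rng.normal(contrast.mixed_td_mean, contrast.mixed_sd), 0, 1))
        a, b = (asd, td) if member_a_diagnosis == "ASD" else (td, asd)
    else:
        raise ValueError(f"unknown dyad type {dyad_type!r}")
    strength = {g: (a, b) for g in ("face", "head", "body")}
    return CouplingProfile(
        coupling_strength=strength,
        coupling_lag=contrast.coupling_lag,
        base_process=contrast.base_process,
        noise_sd=contrast.noise_sd,
        intrapersonal_coupling=contrast.intrapersonal_coupling,
    )


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) sample of length n."""
    from scipy.signal import lfilter

    innov_sd = np.sqrt(max(1.0 - phi * phi, 1e-12))
    eps = np.empty(n)
    eps[0] = rng.normal()  # stationary start: z[0] ~ N(0, 1)
    eps[1:] = rng.normal(size=n - 1) * innov_sd
    return lfilter([1.0], [1.0, -phi], eps)


def _coupled_pair(
    rng: np.random.Generator,
    T: int,
    lagf: int,
    phi: float,
    c_a: float,
    c_b: float,
    noise_sd: float,
    latent_a: Optional[np.ndarray] = None,
    latent_b: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Observed signals for two lag-coupled members.

    The weaker follower's signal is built first from its own latent mixed
    with the partner's lagged latent; the stronger follower then mixes its
    own latent with the partner's lagged *composite* signal, so high
    coupling really does show up as high observed-signal synchrony at the
    planted lag.  Latents carry ``2 * lagf`` lead-in frames.
    """
    ua = _ar1(rng, T + 2 * lagf, phi) if latent_a is None else latent_a
    ub = _ar1(rng, T + 2 * lagf, phi) if latent_b is None else latent_b

    def build(u_first, u_second, c_first, c_second):
        # first member: own latent + lagged partner latent
        first_full = (1.0 - c_first) * u_first[lagf:] + c_first * u_second[: T + lagf]
        first = first_full[lagf:]
        # second member: own latent + lagged composite partner signal
        second = (1.0 - c_second) * u_second[2 * lagf :] + c_second * first_full[:T]
        return first, second

    if c_b >= c_a:
        xa, xb = build(ua, ub, c_a, c_b)
    else:
        xb, xa = build(ub, ua, c_b, c_a)
    if noise_sd > 0:
        xa = xa + rng.normal(scale=noise_sd, size=T)
        xb = xb + rng.normal(scale=noise_sd, size=T)
    return xa, xb


def simulate_dyad_timeseries(
    profile: CouplingProfile,
    duration: float,
    fps: float,
    n_au_channels: int = len(DEFAULT_RETAINED_AUS),
    seed: int = 0,
    participant_ids: Tuple[str, str] = ("A", "B"),
    task: str = "hobbies",
) -> Tuple[TimeSeriesBundle, TimeSeriesBundle]:
    """Simulate one dyad's channels for one task.

    Every channel gets ``duration * fps`` frames.  AU intensities live on
    the 0-5 intensity scale; head pose channels are in degrees around 0;
    the body channel is a non-negative motion-energy-like signal.  The
    body latent shares a component with the head latents at strength
    ``intrapersonal_coupling`` so head-body coordination is above chance.
    Deterministic given ``seed``.
    """
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    T = int(round(duration * fps))
    lagf = profile.lag_frames(fps)
    phi = profile.base_process
    rng = np.random.default_rng([seed, 0xDA])

    au_names = [f"{a}_r" for a in DEFAULT_RETAINED_AUS[:n_au_channels]]
    if n_au_channels > len(DEFAULT_RETAINED_AUS):
        au_names += [f"AU{90 + i:02d}_r" for i in range(n_au_channels - len(DEFAULT_RETAINED_AUS))]

    bundles = [
        TimeSeriesBundle(participant_ids[0], task, fps),
        TimeSeriesBundle(participant_ids[1], task, fps),
    ]

    c_face = profile.strengths("face")
    for name in au_names:
        xa, xb = _coupled_pair(rng, T, lagf, phi, *c_face, profile.noise_sd)
        for bundle, x in zip(bundles, (xa, xb)):
            vals = np.clip(2.5 + 1.0 * x, 0.0, 5.0)
            bundle.au[name] = ChannelSeries(name, vals, fps)

    # head: shared per-member head latent feeding pitch/yaw/roll, so the
    # derived global head movement is meaningful and the body channel can
    # couple to the head intrapersonally
    c_head = profile.strengths("head")
    head_common = [_ar1(rng, T + 2 * lagf, phi) for _ in range(2)]
    share = 0.7
    for pose_name in ("pitch", "yaw", "roll"):
        own = [_ar1(rng, T + 2 * lagf, phi) for _ in range(2)]
        lat = [
            share * head_common[i] + np.sqrt(1 - share**2) * own[i] for i in range(2)
        ]
        xa, xb = _coupled_pair(
            rng, T, lagf, phi, *c_head, profile.noise_sd, latent_a=lat[0], latent_b=lat[1]
        )
        for bundle, x in zip(bundles, (xa, xb)):
            bundle.pose[pose_name] = ChannelSeries(pose_name, 10.0 * x, fps)

    ic = profile.intrapersonal_coupling
    own_body = [_ar1(rng, T + 2 * lagf, phi) for _ in range(2)]
    body_lat = [
        ic * head_common[i] + np.sqrt(max(1 - ic * ic, 0.0)) * own_body[i] for i in range(2)
    ]
    c_body = profile.strengths("body")
    xa, xb = _coupled_pair(
        rng, T, lagf, phi, *c_body, profile.noise_sd, latent_a=body_lat[0], latent_b=body_lat[1]
    )
    for bundle, x in zip(bundles, (xa, xb)):
        bundle.body = ChannelSeries("body", np.clip(1.0 + 0.4 * x, 0.0, None), fps)
        bundle.confidence = ChannelSeries("confidence", np.ones(T), fps)
    return bundles[0], bundles[1]


def simulate_cohort(
    roster: DyadRoster,
    duration: float,
    fps: float,
    seed: int,
    contrast: CouplingContrast = CouplingContrast(),
    tasks: Sequence[str] = TASKS,
    n_au_channels: int = len(DEFAULT_RETAINED_AUS),
) -> Dict[Tuple[str, str], TimeSeriesBundle]:
    """Simulate all tasks for every active dyad of a roster.

    The coupling profile is drawn once per dyad (adaptation style treated
    as a dyad trait) and shared across tasks; the realized signals differ
    per task.  Returns ``{(participant_id, task): bundle}``.
    """
    rng = np.random.default_rng([seed, 0xC0])
    out: Dict[Tuple[str, str], TimeSeriesBundle] = {}
    active = roster.finalized()
    for di, dyad_id in enumerate(sorted(active.dyad_ids)):
        members = active.members(dyad_id)
        profile = draw_coupling_profile(
            active.dyad_type(dyad_id), rng, contrast, member_a_diagnosis=members[0].diagnosis
        )
        for ti, task in enumerate(tasks):
            ba, bb = simulate_dyad_timeseries(
                profile,
                duration,
                fps,
                n_au_channels=n_au_channels,
                seed=int(rng.integers(0, 2**31 - 1)),
                participant_ids=(members[0].participant_id, members[1].participant_id),
                task=task,
            )
            out[(members[0].participant_id, task)] = ba
            out[(members[1].participant_id, task)] = bb
    return out


def render_motion_frames(
    body_series: ChannelSeries,
    roi: ROISpec,
    frame_shape: Tuple[int, int],
    seed: int = 0,
) -> np.ndarray:
    """Synthetic grayscale frame stack whose motion energy replays a series.

    All ROI pixels share a common float intensity that drifts by exactly
    ``body_series.values[t]`` between frames ``t-1`` and ``t``, so feeding
    the stack through :func:`dyadsync.motion_energy.motion_energy_series`
    with ``noise_threshold=0`` recovers the input series exactly (identity
    scaling; the first recovered value is 0 by convention).  Pixels outside
    the ROI hold a static random texture.  Frames are float grayscale — a
    synthetic fixture for the motion-energy machinery, not rendered video.
    """
    v = np.asarray(body_series.values, dtype=float)
    if (v < 0).any():
        raise ValueError("body series must be non-negative")
    roi.check_within(frame_shape)
    rng = np.random.default_rng([seed, 0xF2])
    background = rng.uniform(0, 255, size=frame_shape)
    levels = np.concatenate(([0.0], np.cumsum(v[1:])))  # level[0] = 0
    frames = np.repeat(background[None, :, :], len(v), axis=0)
    frames[:, roi.y0 : roi.y1, roi.x0 : roi.x1] = levels[:, None, None]
    return frames
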