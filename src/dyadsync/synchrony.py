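"""Windowed cross-lagged synchrony estimation.

The analysis core: split two per-frame signals into overlapping windows,
correlate one window against lag-shifted windows of the other, take the
per-window peak correlation in a lag direction, and summarize the peak
profile with seven distributional statistics (mean, median, sd, min, max,
skewness, excess kurtosis).

Lag-sign convention (fixed pipeline-wide): positive lag means the *second*
series trails the first.  "Following" a partner therefore means peak
synchrony at positive lags of ``wclc(partner, self)``.

Windowing uses a symmetric-anchor, full-overlap policy: for lag ``k`` the
first series' window starts at ``w + max(-k, 0)`` and the second's at
``w + max(k, 0)``; no zero padding ever occurs, window starts ``w`` advance
by ``step_frames`` and the number of windows is
``floor((T - W - 2L) / step) + 1``.  Anchoring the *pair* rather than the
first series makes the pooled-direction analysis exactly symmetric in its
two arguments, which the intrapersonal head-body coordination summary
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import (
    ChannelSeries,
    CrossCorrMatrix,
    PeakProfile,
    SyncConfig,
    SyncSummary,
    TimeSeriesBundle,
)

__all__ = [
    "PreprocessConfig",
    "preprocess_series",
    "windowed_cross_lagged_correlation",
    "n_windows",
    "peak_synchrony_profile",
    "summarize_profile",
    "interpersonal_following_summary",
    "intrapersonal_summary",
    "pseudo_dyad_baseline",
    "PseudoDyadNull",
    "default_sync_config",
    "DEFAULT_SYNC_PARAMS",
]

# Window/step/max-lag defaults per channel group, in seconds.  Facial and
# head channels evolve on a faster time scale than gross body movement, so
# body windows are longer and allow larger lags.
DEFAULT_SYNC_PARAMS: Dict[str, Dict[str, float]] = {
    "face": {"window_s": 5.0, "step_s": 1.0, "max_lag_s": 2.0},
    "head": {"window_s": 5.0, "step_s": 1.0, "max_lag_s": 2.0},
    "body": {"window_s": 10.0, "step_s": 2.0, "max_lag_s": 5.0},
}


def default_sync_config(group: str, fps: float, **overrides) -> SyncConfig:
    """Default :class:`SyncConfig` for a channel group at a frame rate."""
    p = DEFAULT_SYNC_PARAMS[group]
    kwargs = dict(
        window_frames=int(round(p["window_s"] * fps)),
        step_frames=int(round(p["step_s"] * fps)),
        max_lag_frames=int(round(p["max_lag_s"] * fps)),
    )
    kwargs.update(overrides)
    return SyncConfig(**kwargs)


@dataclass(frozen=True)
class PreprocessConfig:
    """Validity handling ahead of the synchrony machinery.

    Frames whose tracking confidence falls below ``confidence_threshold``
    are marked invalid.  Invalid gaps of at most ``max_gap_frames`` flanked
    by valid frames are linearly interpolated and re-validated; longer gaps
    stay invalid.  A channel whose remaining invalid fraction exceeds
    ``exclusion_threshold`` is flagged unusable (never silently dropped).
    """

    confidence_threshold: float = 0.75
    max_gap_frames: int = 15
    exclusion_threshold: float = 0.10


def preprocess_series(
    raw: ChannelSeries,
    confidence: Optional[ChannelSeries] = None,
    config: PreprocessConfig = PreprocessConfig(),
) -> ChannelSeries:
    """Confidence-gate, gap-fill and usability-flag one channel."""
    out = raw.copy()
    if confidence is not None:
        if len(confidence) != len(raw):
            raise ValueError("confidence series length must match channel length")
        out.valid_mask &= confidence.values >= config.confidence_threshold
    out.valid_mask &= np.isfinite(out.values)

    mask = out.valid_mask
    n = len(mask)
    # interpolate short interior gaps
    t = 0
    while t < n:
        if mask[t]:
            t += 1
            continue
        start = t
        while t < n and not mask[t]:
            t += 1
        end = t  # gap is [start, end)
        gap = end - start
        if start > 0 and end < n and gap <= config.max_gap_frames:
            a, b = out.values[start - 1], out.values[end]
            frac = np.arange(1, gap + 1) / (gap + 1)
            out.values[start:end] = a + frac * (b - a)
            mask[start:end] = True
    out.valid_mask = mask
    if out.invalid_fraction > config.exclusion_threshold:
        out.usable = False
        out.unusable_reason = (
            f"invalid fraction {out.invalid_fraction:.3f} exceeds "
            f"threshold {config.exclusion_threshold:.3f}"
        )
    return out


def n_windows(n_frames: int, cfg: SyncConfig) -> int:
    """Number of full-overlap windows for a series of ``n_frames`` frames."""
    span = n_frames - cfg.window_frames - 2 * cfg.max_lag_frames
    return 0 if span < 0 else span // cfg.step_frames + 1


# variance guard on globally-standardized data: windows whose variance term
# falls below this (relative to window length) are treated as constant
_VAR_EPS = 1e-14


def windowed_cross_lagged_correlation(
    x: ChannelSeries, y: ChannelSeries, cfg: SyncConfig
) -> CrossCorrMatrix:
    """Pearson correlation of ``x`` against lag-shifted ``y``, per window.

    Entry ``(w, k)`` correlates a window of ``x`` with a window of ``y``
    shifted ``k`` frames later (positive ``k`` = ``y`` trails ``x``).
    Entries are missing (NaN) when fewer than ``min_valid_fraction`` of the
    overlapping frames are jointly valid, or when either segment has zero
    variance over the jointly valid frames.
    """
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if x.fps != y.fps:
        raise ValueError("series must share a frame rate")
    T = len(x)
    W, L, step = cfg.window_frames, cfg.max_lag_frames, cfg.step_frames
    nw = n_windows(T, cfg)
    lags = np.arange(-L, L + 1)
    starts = np.arange(nw) * step
    grid = np.full((nw, len(lags)), np.nan)

    if nw == 0:
        return CrossCorrMatrix(grid, lags, starts)

    # global standardization: Pearson is shift/scale invariant, this keeps
    # the moment-based windowed computation numerically stable
    def _std(v: np.ndarray, m: np.ndarray) -> np.ndarray:
        vv = np.where(m & np.isfinite(v), v, np.nan)
        mu = np.nanmean(vv) if np.isfinite(vv).any() else 0.0
        sd = np.nanstd(vv) if np.isfinite(vv).any() else 1.0
        out = (np.where(np.isfinite(v), v, 0.0) - mu) / (sd if sd > 0 else 1.0)
        return np.where(m, out, 0.0)

    xv = x.valid_mask & np.isfinite(x.values)
    yv = y.valid_mask & np.isfinite(y.values)
    xs_full = _std(x.values, xv)
    ys_full = _std(y.values, yv)

    if xv.all() and yv.all():
        # fast path: per-window standardized segments, correlation = dot
        from numpy.lib.stride_tricks import sliding_window_view

        def norm_windows(v: np.ndarray) -> np.ndarray:
            Wv = sliding_window_view(v, W).astype(float)
            mu = Wv.mean(axis=1, keepdims=True)
            Z = Wv - mu
            nrm = np.sqrt((Z * Z).sum(axis=1, keepdims=True))
            ok = nrm[:, 0] > np.sqrt(_VAR_EPS) * W
            with np.errstate(invalid="ignore", divide="ignore"):
                Z = Z / nrm
            Z[~ok] = np.nan  # zero-variance windows propagate as missing
            return Z

        Xn = norm_windows(xs_full)
        Yn = norm_windows(ys_full)
        for j, k in enumerate(lags):
            a, b = max(-k, 0), max(k, 0)
            r = np.einsum("ij,ij->i", Xn[starts + a], Yn[starts + b])
            grid[:, j] = np.clip(r, -1.0, 1.0)
        return CrossCorrMatrix(grid, lags, starts)

    min_count = cfg.min_valid_fraction * W
    for j, k in enumerate(lags):
        a, b = max(-k, 0), max(k, 0)
        m = T - abs(k)
        xa = xs_full[a : a + m]
        yb = ys_full[b : b + m]
        va = xv[a : a + m] & yv[b : b + m]
        vf = va.astype(float)
        xm = xa * vf
        ym = yb * vf
        # windowed sums via cumulative sums (prepend 0)
        def wsum(arr: np.ndarray) -> np.ndarray:
            c = np.concatenate(([0.0], np.cumsum(arr)))
            return c[starts + W] - c[starts]

        nvs = wsum(vf)
        sx, sy = wsum(xm), wsum(ym)
        sxx, syy, sxy = wsum(xm * xa), wsum(ym * yb), wsum(xm * yb)
        with np.errstate(invalid="ignore", divide="ignore"):
            varx = nvs * sxx - sx * sx
            vary = nvs * syy - sy * sy
            cov = nvs * sxy - sx * sy
            denom = np.sqrt(np.clip(varx, 0, None) * np.clip(vary, 0, None))
            r = cov / denom
        bad = (
            (nvs < min_count)
            | (varx <= _VAR_EPS * nvs * nvs)
            | (vary <= _VAR_EPS * nvs * nvs)
        )
        r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
        grid[:, j] = r

    return CrossCorrMatrix(grid, lags, starts)


def peak_synchrony_profile(
    m: CrossCorrMatrix, direction: str, peak_rule: str = "max_positive"
) -> PeakProfile:
    """Per-window peak correlation over one lag half (lag 0 in both halves).

    ``A_leads`` scans positive lags (the second series trails the first, so
    the first argument of the cross-correlation leads); ``B_leads`` scans
    negative lags; ``pooled`` scans all lags.
    """
    if direction == "A_leads":
        cols = m.lag_axis >= 0
    elif direction == "B_leads":
        cols = m.lag_axis <= 0
    elif direction == "pooled":
        cols = np.ones_like(m.lag_axis, dtype=bool)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    sub = m.values[:, cols]
    out = np.full(m.n_windows, np.nan)
    any_def = np.isfinite(sub).any(axis=1)
    if peak_rule == "max_positive":
        with np.errstate(invalid="ignore"):
            out[any_def] = np.nanmax(sub[any_def], axis=1)
    elif peak_rule == "max_absolute":
        filled = np.where(np.isfinite(sub), np.abs(sub), -np.inf)
        idx = np.argmax(filled, axis=1)
        vals = sub[np.arange(sub.shape[0]), idx]
        out[any_def] = vals[any_def]
    else:
        raise ValueError(f"unknown peak rule {peak_rule!r}")
    return PeakProfile(out, direction)


def summarize_profile(p: PeakProfile) -> SyncSummary:
    """The seven summary statistics over the non-missing windows.

    Sample (n-1) standard deviation, moment skewness g1, excess kurtosis
    g2.  Fewer than two non-missing windows gives an all-missing summary;
    a constant profile leaves skewness/kurtosis undefined (NaN).
    """
    vals = p.values[np.isfinite(p.values)]
    if len(vals) < 2:
        return SyncSummary(missing_reason="fewer than 2 non-missing windows")
    if vals.min() == vals.max():  # exactly constant: sd 0, moments undefined
        c = float(vals[0])
        return SyncSummary(mean=c, median=c, sd=0.0, min=c, max=c,
                           skewness=float("nan"), kurtosis=float("nan"))
    sd = float(np.std(vals, ddof=1))
    if sd > 0:
        import warnings

        with warnings.catch_warnings():
            # near-constant profiles trigger a precision-loss warning; the
            # constant case is already routed to NaN below
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = float(stats.skew(vals, bias=True))
            kurt = float(stats.kurtosis(vals, fisher=True, bias=True))
    else:
        skew = kurt = float("nan")
    return SyncSummary(
        mean=float(np.mean(vals)),
        median=float(np.median(vals)),
        sd=sd,
        min=float(np.min(vals)),
        max=float(np.max(vals)),
        skewness=skew,
        kurtosis=kurt,
    )


def _get_preprocessed(bundle: TimeSeriesBundle, channel: str, pp: Optional[PreprocessConfig]) -> ChannelSeries:
    s = bundle.channel(channel)
    if pp is not None:
        s = preprocess_series(s, bundle.confidence, pp)
    return s


def interpersonal_following_summary(
    self_bundle: TimeSeriesBundle,
    partner_bundle: TimeSeriesBundle,
    channel: str,
    cfg: SyncConfig,
    preprocess: Optional[PreprocessConfig] = None,
) -> SyncSummary:
    """How strongly one participant *follows* (imitates with a delay) the
    partner on a channel: peak synchrony in the lag direction where the
    participant's own signal trails the partner's.

    Swapping the two bundles yields the partner's following summary.
    """
    if self_bundle.fps != partner_bundle.fps:
        raise ValueError("bundles must share a frame rate")
    if self_bundle.task != partner_bundle.task:
        raise ValueError("bundles must come from the same task")
    s_self = _get_preprocessed(self_bundle, channel, preprocess)
    s_partner = _get_preprocessed(partner_bundle, channel, preprocess)
    for s in (s_self, s_partner):
        if not s.usable:
            return SyncSummary(missing_reason=f"channel unusable: {s.unusable_reason}")
    # x = partner, y = self; positive lags = self trails partner = following
    m = windowed_cross_lagged_correlation(s_partner, s_self, cfg)
    profile = peak_synchrony_profile(m, "A_leads", cfg.peak_rule)
    return summarize_profile(profile)


def intrapersonal_summary(
    head: ChannelSeries,
    body: ChannelSeries,
    cfg: SyncConfig,
) -> SyncSummary:
    """Pooled-direction peak synchrony between one participant's own
    head-movement and body motion-energy series (argument order immaterial)."""
    for s in (head, body):
        if not s.usable:
            return SyncSummary(missing_reason=f"channel unusable: {s.unusable_reason}")
    m = windowed_cross_lagged_correlation(head, body, cfg)
    profile = peak_synchrony_profile(m, "pooled", cfg.peak_rule)
    return summarize_profile(profile)


@dataclass
class PseudoDyadNull:
    """Null distribution of mean following synchrony from surrogate pairings."""

    samples: np.ndarray
    pairings: List[Tuple[str, str]]

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.samples[np.isfinite(self.samples)], q)


def pseudo_dyad_baseline(
    bundles: Sequence[TimeSeriesBundle],
    channel: str,
    cfg: SyncConfig,
    n_pairings: int,
    seed: int,
    partner_map: Optional[Mapping[str, str]] = None,
    preprocess: Optional[PreprocessConfig] = None,
) -> PseudoDyadNull:
    """Chance-level synchrony from randomly re-paired non-partners.

    Each surrogate pairing scores the first member's following of the
    second via :func:`interpersonal_following_summary`; genuine partners
    (per ``partner_map``) are never paired with each other.
    """
    if len(bundles) < 2:
        raise ValueError("need at least 2 bundles")
    if n_pairings < 1:
        raise ValueError("n_pairings must be >= 1")
    partner_map = dict(partner_map or {})
    rng = np.random.default_rng(seed)
    samples = np.full(n_pairings, np.nan)
    pairings: List[Tuple[str, str]] = []
    n = len(bundles)
    for it in range(n_pairings):
        while True:
            i, j = rng.choice(n, size=2, replace=False)
            pi, pj = bundles[i].participant_id, bundles[j].participant_id
            if partner_map.get(pi) != pj and partner_map.get(pj) != pi:
                break
        summ = interpersonal_following_summary(bundles[i], bundles[j], channel, cfg, preprocess)
        samples[it] = summ.mean
        pairings.append((pi, pj))
    return PseudoDyadNull(samples, pairings)
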