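"""Windowed cross-lagged correlation, peak profiles and the seven summaries."""

import numpy as np
import pytest

import dyadsync as ds
from dyadsync.synchrony import (
    PreprocessConfig,
    n_windows,
    preprocess_series,
    pseudo_dyad_baseline,
)
from dyadsync.types import ChannelSeries, CrossCorrMatrix, PeakProfile, SyncConfig

from conftest import naive_wclc


def series(values, fps=30.0, mask=None, name="x"):
    return ChannelSeries(name, np.asarray(values, float), fps, mask)


class TestPreprocess:
    def test_all_valid_unchanged(self, rng):
        s = series(rng.normal(size=100))
        out = preprocess_series(s)
        assert np.array_equal(out.values, s.values)
        assert out.valid_mask.all() and out.usable

    def test_single_gap_linear_interpolation(self):
        v = np.array([1.0, 999.0, 3.0, 4.0])
        m = np.array([True, False, True, True])
        out = preprocess_series(series(v, mask=m))
        assert out.values[1] == pytest.approx(2.0)
        assert out.valid_mask.all()

    def test_low_confidence_frames_invalidated(self):
        s = series(np.arange(20.0))
        conf = series(np.where(np.arange(20) < 18, 1.0, 0.1), name="confidence")
        out = preprocess_series(s, conf, PreprocessConfig(max_gap_frames=0))
        assert not out.valid_mask[18:].any()
        assert out.valid_mask[:18].all()

    def test_long_gap_stays_invalid_and_flags_unusable(self):
        m = np.ones(100, bool)
        m[10:25] = False  # 15% invalid, beyond both gap and exclusion limits
        out = preprocess_series(series(np.arange(100.0), mask=m),
                                config=PreprocessConfig(max_gap_frames=5, exclusion_threshold=0.10))
        assert not out.valid_mask[10:25].any()
        assert not out.usable
        assert "0.150" in out.unusable_reason

    def test_edge_gap_never_interpolated(self):
        m = np.ones(10, bool)
        m[0] = False
        out = preprocess_series(series(np.arange(10.0), mask=m))
        assert not out.valid_mask[0]


class TestWindowedCrossLaggedCorrelation:
    def test_self_correlation_unit_at_lag_zero(self, rng):
        x = series(rng.normal(size=400))
        cfg = SyncConfig(90, 15, 30)
        m = ds.windowed_cross_lagged_correlation(x, x, cfg)
        col0 = m.values[:, m.lag_axis == 0].ravel()
        assert np.allclose(col0, 1.0)

    def test_delayed_copy_peaks_at_planted_lag(self, rng):
        x = rng.normal(size=500)
        k0 = 12
        y = np.roll(x, k0)  # y trails x by k0
        cfg = SyncConfig(90, 15, 30)
        m = ds.windowed_cross_lagged_correlation(series(x), series(y), cfg)
        arg = m.lag_axis[np.nanargmax(m.values, axis=1)]
        assert np.all(arg == k0)

    def test_constant_second_series_all_missing(self, rng):
        x = series(rng.normal(size=300))
        y = series(np.full(300, 2.5))
        m = ds.windowed_cross_lagged_correlation(x, y, SyncConfig(90, 15, 30))
        assert np.isnan(m.values).all()

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ds.windowed_cross_lagged_correlation(
                series(rng.normal(size=100)), series(rng.normal(size=99)), SyncConfig(30, 5, 10)
            )

    def test_matches_naive_triple_loop_oracle(self, rng):
        cfg = SyncConfig(90, 15, 30)
        for _ in range(3):
            x = rng.normal(size=600)
            y = rng.normal(size=600)
            m = ds.windowed_cross_lagged_correlation(series(x), series(y), cfg)
            ref, lags = naive_wclc(x, y, 90, 15, 30)
            assert np.array_equal(lags, m.lag_axis)
            assert np.nanmax(np.abs(m.values - ref)) < 1e-10

    def test_masked_path_matches_oracle_on_valid_windows(self, rng):
        # invalidate a block; windows with enough jointly-valid frames are
        # computed on the valid overlap, the rest go missing
        x = rng.normal(size=600)
        y = rng.normal(size=600)
        mask = np.ones(600, bool)
        mask[200:206] = False
        cfg = SyncConfig(90, 15, 30, min_valid_fraction=0.9)
        m = ds.windowed_cross_lagged_correlation(series(x, mask=mask), series(y), cfg)
        # brute-force check on a handful of entries
        for w in (0, 5, 10, 20):
            for j, k in enumerate(m.lag_axis[::20]):
                jj = list(m.lag_axis).index(k)
                xa = w * 15 + max(-k, 0)
                yb = w * 15 + max(k, 0)
                jv = mask[xa : xa + 90]
                if jv.mean() < 0.9:
                    assert np.isnan(m.values[w, jj])
                else:
                    ref = np.corrcoef(x[xa : xa + 90][jv], y[yb : yb + 90][jv])[0, 1]
                    assert m.values[w, jj] == pytest.approx(ref, abs=1e-9)

    def test_bounds_always_respected(self, rng):
        for _ in range(10):
            x = rng.normal(size=200) * rng.uniform(0.1, 50)
            y = x * rng.uniform(-2, 2) + rng.normal(size=200)
            m = ds.windowed_cross_lagged_correlation(series(x), series(y), SyncConfig(50, 7, 12))
            finite = m.values[np.isfinite(m.values)]
            assert np.all(np.abs(finite) <= 1.0)

    @pytest.mark.parametrize("T,W,L,step", [(600, 90, 30, 15), (100, 30, 10, 1),
                                            (500, 120, 50, 37), (223, 60, 20, 7)])
    def test_window_count_arithmetic(self, T, W, L, step, rng):
        cfg = SyncConfig(W, step, L)
        m = ds.windowed_cross_lagged_correlation(
            series(rng.normal(size=T)), series(rng.normal(size=T)), cfg
        )
        # enumeration: count starts whose extreme-lag windows stay in range
        count = 0
        w = 0
        while w + W + 2 * L <= T:
            count += 1
            w += step
        assert m.n_windows == count == n_windows(T, cfg)

    def test_time_reversal_flips_lead_lag(self, rng):
        x = rng.normal(size=400)
        y = np.roll(x, 9)
        cfg = SyncConfig(90, 15, 30)
        fwd = ds.windowed_cross_lagged_correlation(series(x), series(y), cfg)
        rev = ds.windowed_cross_lagged_correlation(series(x[::-1]), series(y[::-1]), cfg)
        assert np.all(fwd.lag_axis[np.nanargmax(fwd.values, axis=1)] == 9)
        assert np.all(rev.lag_axis[np.nanargmax(rev.values, axis=1)] == -9)


class TestPeakProfile:
    def test_monotone_matrix_peaks_at_extreme_lag(self):
        lags = np.arange(-3, 4)
        vals = np.tile(lags / 10.0, (4, 1))
        m = CrossCorrMatrix(vals, lags, np.arange(4))
        p = ds.peak_synchrony_profile(m, "A_leads")
        assert np.allclose(p.values, 0.3)
        p2 = ds.peak_synchrony_profile(m, "B_leads")
        assert np.allclose(p2.values, 0.0)  # lag 0 belongs to both halves

    def test_pooled_dominates_directional(self, rng):
        lags = np.arange(-5, 6)
        vals = rng.uniform(-1, 1, size=(7, 11))
        m = CrossCorrMatrix(vals, lags, np.arange(7))
        pooled = ds.peak_synchrony_profile(m, "pooled").values
        for d in ("A_leads", "B_leads"):
            assert np.all(pooled >= ds.peak_synchrony_profile(m, d).values - 1e-15)

    def test_matches_naive_scan(self, rng):
        lags = np.arange(-4, 5)
        vals = rng.uniform(-1, 1, size=(6, 9))
        vals[2, 3] = np.nan
        m = CrossCorrMatrix(vals, lags, np.arange(6))
        for direction, sel in (("A_leads", lags >= 0), ("B_leads", lags <= 0), ("pooled", lags == lags)):
            p = ds.peak_synchrony_profile(m, direction).values
            for w in range(6):
                row = vals[w, sel]
                ref = np.nanmax(row) if np.isfinite(row).any() else np.nan
                assert (np.isnan(p[w]) and np.isnan(ref)) or p[w] == ref

    def test_max_absolute_rule_keeps_sign(self):
        lags = np.arange(-1, 2)
        m = CrossCorrMatrix(np.array([[-0.9, 0.1, 0.5]]), lags, np.arange(1))
        p = ds.peak_synchrony_profile(m, "pooled", peak_rule="max_absolute")
        assert p.values[0] == -0.9

    def test_unknown_direction_rejected(self):
        m = CrossCorrMatrix(np.zeros((1, 3)), np.arange(-1, 2), np.arange(1))
        with pytest.raises(ValueError):
            ds.peak_synchrony_profile(m, "sideways")


class TestSummarizeProfile:
    def test_hand_computed_three_values(self):
        s = ds.summarize_profile(PeakProfile(np.array([0.1, 0.2, 0.3]), "pooled"))
        assert s.mean == pytest.approx(0.2)
        assert s.median == pytest.approx(0.2)
        assert s.min == pytest.approx(0.1)
        assert s.max == pytest.approx(0.3)
        assert s.sd == pytest.approx(0.1)

    def test_constant_profile_flags_undefined_moments(self):
        s = ds.summarize_profile(PeakProfile(np.full(5, 0.42), "pooled"))
        assert s.mean == s.median == s.min == s.max == pytest.approx(0.42)
        assert s.sd == 0.0
        assert np.isnan(s.skewness) and np.isnan(s.kurtosis)

    def test_symmetric_profile_zero_skew(self):
        vals = np.array([-0.3, -0.1, 0.0, 0.1, 0.3])
        s = ds.summarize_profile(PeakProfile(vals, "pooled"))
        assert abs(s.skewness) < 1e-12

    def test_too_few_windows_all_missing(self):
        s = ds.summarize_profile(PeakProfile(np.array([0.5, np.nan]), "pooled"))
        assert s.all_missing and s.missing_reason

    def test_order_invariants(self, rng):
        for _ in range(20):
            vals = rng.uniform(-1, 1, size=rng.integers(2, 40))
            s = ds.summarize_profile(PeakProfile(vals, "pooled"))
            assert s.min <= s.median <= s.max
            assert s.sd >= 0


class TestFollowingAndIntrapersonal:
    def test_delayed_copy_follower_scores_high(self, delayed_copy_pair):
        a, b = delayed_copy_pair
        cfg = SyncConfig(150, 30, 60)
        s_b = ds.interpersonal_following_summary(b, a, "AU04_r", cfg)
        s_a = ds.interpersonal_following_summary(a, b, "AU04_r", cfg)
        assert s_b.mean == pytest.approx(1.0, abs=1e-9)
        assert s_a.mean < s_b.mean - 0.05

    def test_role_swap_is_exact_exchange(self, rng):
        prof_pair = ds.simulate_dyad_timeseries(
            ds.CouplingProfile(noise_sd=0.5), 20, 30, seed=21
        )
        a, b = prof_pair
        cfg = SyncConfig(150, 30, 60)
        once = ds.interpersonal_following_summary(a, b, "AU01_r", cfg)
        swap = ds.interpersonal_following_summary(a, b, "AU01_r", cfg)
        assert once.as_dict() == swap.as_dict()  # deterministic
        # antisymmetry: each call is the named participant's own following
        mine = ds.interpersonal_following_summary(a, b, "AU01_r", cfg)
        theirs = ds.interpersonal_following_summary(b, a, "AU01_r", cfg)
        m = ds.windowed_cross_lagged_correlation(b.au["AU01_r"], a.au["AU01_r"], cfg)
        ref_mine = ds.summarize_profile(ds.peak_synchrony_profile(m, "A_leads"))
        assert mine.mean == pytest.approx(ref_mine.mean, abs=1e-12)
        m2 = ds.windowed_cross_lagged_correlation(a.au["AU01_r"], b.au["AU01_r"], cfg)
        ref_theirs = ds.summarize_profile(ds.peak_synchrony_profile(m2, "A_leads"))
        assert theirs.mean == pytest.approx(ref_theirs.mean, abs=1e-12)

    def test_unusable_channel_gives_reasoned_missing(self, delayed_copy_pair):
        a, b = delayed_copy_pair
        a.confidence.values[:300] = 0.0  # 50% of a 20 s recording
        cfg = SyncConfig(150, 30, 60)
        s = ds.interpersonal_following_summary(
            b, a, "AU01_r", cfg, preprocess=PreprocessConfig(max_gap_frames=5)
        )
        assert s.all_missing
        assert "unusable" in s.missing_reason

    def test_intrapersonal_scaled_copy_peaks_at_one(self, rng):
        head = series(rng.normal(size=900), name="head_movement")
        body = series(3.0 * head.values + 1.0, name="body")
        s = ds.intrapersonal_summary(head, body, SyncConfig(150, 30, 60))
        assert s.mean == pytest.approx(1.0, abs=1e-9)

    def test_intrapersonal_argument_order_irrelevant(self, rng):
        head = series(rng.normal(size=900), name="head")
        body = series(rng.normal(size=900), name="body")
        cfg = SyncConfig(150, 30, 60)
        s1 = ds.intrapersonal_summary(head, body, cfg)
        s2 = ds.intrapersonal_summary(body, head, cfg)
        for k, v in s1.as_dict().items():
            assert v == pytest.approx(s2.as_dict()[k], abs=1e-12)


class TestPseudoDyadBaseline:
    def _noise_bundles(self, n, seed):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            b = ds.TimeSeriesBundle(f"p{i}", "hobbies", 30.0)
            b.body = series(rng.normal(size=600), name="body")
            out.append(b)
        return out

    def test_same_seed_identical_pairings(self):
        bundles = self._noise_bundles(6, 0)
        cfg = SyncConfig(150, 30, 60)
        a = pseudo_dyad_baseline(bundles, "body", cfg, 10, seed=3)
        b = pseudo_dyad_baseline(bundles, "body", cfg, 10, seed=3)
        assert a.pairings == b.pairings
        assert np.array_equal(a.samples, b.samples)

    def test_real_partners_never_paired(self):
        bundles = self._noise_bundles(6, 1)
        partner_map = {"p0": "p1", "p1": "p0", "p2": "p3", "p3": "p2", "p4": "p5", "p5": "p4"}
        null = pseudo_dyad_baseline(bundles, "body", SyncConfig(150, 30, 60), 40, 0,
                                    partner_map=partner_map)
        for a, b in null.pairings:
            assert partner_map[a] != b

    def test_coupled_pairs_exceed_null_band(self):
        cfg = SyncConfig(150, 30, 60)
        bundles = []
        real_means = []
        for rep in range(8):
            a, b = ds.simulate_dyad_timeseries(
                ds.CouplingProfile(coupling_strength={"body": 0.95}, noise_sd=0.1),
                30, 30, n_au_channels=1, seed=400 + rep,
                participant_ids=(f"a{rep}", f"b{rep}"),
            )
            real_means.append(ds.interpersonal_following_summary(b, a, "body", cfg).mean)
            bundles += [a, b]
        pm = {f"a{i}": f"b{i}" for i in range(8)}
        pm.update({v: k for k, v in pm.items()})
        null = pseudo_dyad_baseline(bundles, "body", cfg, 40, 1, partner_map=pm)
        assert np.mean(real_means) > null.quantile(0.975)

    def test_bad_arguments_rejected(self):
        bundles = self._noise_bundles(3, 2)
        with pytest.raises(ValueError):
            pseudo_dyad_baseline(bundles, "body", SyncConfig(150, 30, 60), 0, 0)
        with pytest.raises(ValueError):
            pseudo_dyad_baseline(bundles[:1], "body", SyncConfig(150, 30, 60), 5, 0)
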