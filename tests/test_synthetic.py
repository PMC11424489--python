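"""Synthetic landscape generator: distributions, determinism, injection."""

import datetime as dt

import numpy as np
import pytest
from scipy import stats

from pyrodelta import (SyntheticConfig, generate_active_fires, generate_fire_sizes,
                       generate_scene, injected_effect)
from pyrodelta.synthetic import FOREST_TYPES, PlacementError


class TestFireSizes:
    def test_empty(self):
        assert generate_fire_sizes(0, 0.5, 0.3).size == 0

    def test_zero_variance_degenerate(self):
        sizes = generate_fire_sizes(10_000, 0.5, 0.0, min_size=1.0, seed=1)
        assert np.allclose(sizes, 10 ** 0.5)

    def test_truncation(self):
        sizes = generate_fire_sizes(5000, 0.0, 1.0, min_size=1.0, seed=2)
        assert sizes.min() >= 1.0

    def test_truncated_mean_matches_rejection_oracle(self):
        """Sample mean of log10(size) agrees with a brute-force rejection
        sampler of the same truncated distribution within 3 s.e."""
        mu, sigma, min_size, n = 0.8, 0.5, 1.0, 100_000
        sizes = generate_fire_sizes(n, mu, sigma, min_size, seed=3)
        # independent oracle: plain normal draws, rejected below the cut
        rng = np.random.default_rng(12345)
        draws = rng.normal(mu, sigma, size=600_000)
        oracle = draws[draws >= np.log10(min_size)][:200_000]
        obs = np.log10(sizes)
        se = np.sqrt(obs.var() / n + oracle.var() / oracle.size)
        assert abs(obs.mean() - oracle.mean()) < 3 * se

    @pytest.mark.parametrize("kwargs", [
        dict(n=10, mu=0, sigma=-0.1), dict(n=10, mu=0, sigma=1, min_size=0.0),
        dict(n=-1, mu=0, sigma=1),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            generate_fire_sizes(**kwargs)


class TestSceneGeneration:
    def test_no_fires_scene_differs_only_by_background(self):
        cfg = SyntheticConfig(grid_nx=30, grid_ny=30, n_fires=0, seed=7,
                              noise_sd={k: 0.0 for k in
                                        SyntheticConfig().noise_sd})
        scene, events = generate_scene(cfg)
        assert events == []
        assert (scene.burn_year == -1).all()
        # without noise, a year-to-year difference is one scalar per field/season
        for name in ("T_day", "albedo", "ET"):
            diff = scene.fields[name][1] - scene.fields[name][0]
            for si in range(diff.shape[0]):
                assert np.ptp(diff[si]) < 1e-12

    def test_injection_rule_direct_evaluation(self):
        """Zero-noise single fire: burnt-pixel lag-1 summer gross change
        equals intercept + slope * log10(size) exactly."""
        slopes = {"T": {t: 0.44 for t in FOREST_TYPES}}
        intercepts = {"T": {t: 0.2 for t in FOREST_TYPES}}
        cfg = SyntheticConfig(
            grid_nx=40, grid_ny=40, n_fires=1, seed=21,
            lognormal_mu=1.0, lognormal_sigma=0.0,  # exactly 10 km2
            effect_slopes=slopes, effect_intercepts=intercepts,
            forest_fractions={"ENF": 1.0},
        ).zero_noise()
        scene, (ev,) = generate_scene(cfg)
        assert ev.size_km2 == pytest.approx(10.0)
        yi_pre = scene.year_index(ev.fire_year - 1)
        yi_post = scene.year_index(ev.fire_year + 1)
        si = scene.season_index("JJA")
        r, c = ev.pixels[0]
        gross = scene.field("T")[yi_post, si, r, c] - scene.field("T")[yi_pre, si, r, c]
        assert gross == pytest.approx(0.2 + 0.44 * 1.0, abs=1e-12)

    def test_determinism_bit_identical(self):
        cfg = SyntheticConfig(grid_nx=40, grid_ny=40, n_fires=5, seed=9)
        s1, e1 = generate_scene(cfg)
        s2, e2 = generate_scene(cfg)
        for name in s1.fields:
            assert np.array_equal(s1.fields[name], s2.fields[name])
        assert np.array_equal(s1.burn_year, s2.burn_year)
        assert np.array_equal(s1.loss_count, s2.loss_count)
        assert [ev.pixel_set for ev in e1] == [ev.pixel_set for ev in e2]
        assert [ev.start_date for ev in e1] == [ev.start_date for ev in e2]

    def test_events_disjoint_and_compact(self, noisy_scene):
        _, scene, events = noisy_scene
        seen = set()
        for ev in events:
            px = ev.pixel_set
            assert not (px & seen)
            seen |= px
            # 4-connectivity: every pixel beyond the first touches the patch
            for r, c in sorted(px)[1:]:
                assert any((r + dr, c + dc) in px
                           for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)))

    def test_size_consistent_with_pixel_count(self, noisy_scene):
        cfg, _, events = noisy_scene
        for ev in events:
            assert ev.size_km2 == pytest.approx(ev.n_pixels * cfg.pixel_area_km2)
            assert ev.duration_days >= 1 and ev.end_date >= ev.start_date
            assert ev.spread_rate == pytest.approx(ev.size_km2 / ev.duration_days)

    def test_injection_linear_in_log_size(self):
        """Two noiseless single-fire scenes pin the injected line exactly."""
        deltas = []
        for mu in (0.0, 2.0):  # 1 km2 and 100 km2
            cfg = SyntheticConfig(grid_nx=60, grid_ny=60, n_fires=1, seed=3,
                                  lognormal_mu=mu, lognormal_sigma=0.0,
                                  forest_fractions={"ENF": 1.0}).zero_noise()
            scene, (ev,) = generate_scene(cfg)
            yi0, yi1 = scene.year_index(ev.fire_year - 1), scene.year_index(ev.fire_year + 1)
            si = scene.season_index("JJA")
            r, c = ev.pixels[0]
            deltas.append((np.log10(ev.size_km2),
                           scene.field("T")[yi1, si, r, c] - scene.field("T")[yi0, si, r, c]))
        (x0, y0), (x1, y1) = deltas
        slope = (y1 - y0) / (x1 - x0)
        intercept = y0 - slope * x0
        assert slope == pytest.approx(0.55, abs=1e-10)   # ENF summer T slope
        assert intercept == pytest.approx(0.20, abs=1e-10)

    def test_placement_error_names_constraint(self):
        cfg = SyntheticConfig(grid_nx=8, grid_ny=8, n_fires=5,
                              lognormal_mu=1.5, lognormal_sigma=0.0, seed=1)
        with pytest.raises(PlacementError, match="without overlap"):
            generate_scene(cfg)

    def test_physical_bounds(self, noisy_scene):
        _, scene, _ = noisy_scene
        assert scene.fields["albedo"].min() >= 0 and scene.fields["albedo"].max() <= 1
        for b in ("e29", "e31", "e32"):
            assert scene.fields[b].min() >= 0 and scene.fields[b].max() <= 1
        assert scene.fields["ET"].min() >= 0 and scene.fields["LAI"].min() >= 0
        assert (scene.loss_fraction >= 0).all() and (scene.loss_fraction <= 1).all()


class TestActiveFires:
    def test_zero_rate_empty(self, noisy_scene):
        _, _, events = noisy_scene
        assert generate_active_fires(events, detections_per_km2=0.0, seed=0) == []

    def test_poisson_mean_matches_oracle(self):
        """One 4-km2 event at rate 2/km2: mean count over 200 seeds within
        3 s.e. of the Poisson mean 8."""
        cfg = SyntheticConfig(grid_nx=30, grid_ny=30, n_fires=1, seed=2,
                              lognormal_mu=np.log10(4.0), lognormal_sigma=0.0)
        _, events = generate_scene(cfg)
        assert events[0].size_km2 == pytest.approx(4.0)
        counts = [len(generate_active_fires(events, detections_per_km2=2.0, seed=s))
                  for s in range(200)]
        lam = 8.0
        se = np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_dates_within_event_window_and_validity(self, noisy_scene):
        _, _, events = noisy_scene
        by_id = {}
        dets = generate_active_fires(events, detections_per_km2=1.0, seed=4)
        for ev in events:
            by_id[ev.event_id] = ev
        # every detection falls in *some* event window (they are generated
        # per event in order); check global invariants
        for d in dets:
            assert d.frp_mw >= 0
            assert 0 <= d.scan_angle_deg <= 55
        starts = min(ev.start_date for ev in events)
        ends = max(ev.end_date for ev in events)
        assert all(starts <= d.date <= ends for d in dets)

    def test_determinism(self, noisy_scene):
        _, _, events = noisy_scene
        a = generate_active_fires(events, seed=7)
        b = generate_active_fires(events, seed=7)
        assert a == b


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="forest_fractions"):
            SyntheticConfig(forest_fractions={"ENF": 0.5, "none": 0.4})

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="s.d."):
            SyntheticConfig(noise_sd={"T_day": -1.0})

    def test_min_size_positive(self):
        with pytest.raises(ValueError, match="min_size"):
            SyntheticConfig(min_size_km2=0.0)
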