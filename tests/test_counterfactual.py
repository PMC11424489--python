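"""Space-and-time counterfactual: control rules, deltas, aggregation."""

import numpy as np
import pandas as pd
import pytest

from pyrodelta import (ControlCriteria, SyntheticConfig, daily_lst, event_delta,
                       generate_scene, injected_effect, pixel_delta,
                       seasonal_mean, select_controls)
from pyrodelta.synthetic import FIELDS, GriddedScene


def tiny_scene(ny=21, nx=21, years=(2000, 2001, 2002, 2003, 2004)):
    """Hand-built constant scene, all ENF, no burns, no loss."""
    years = np.asarray(years)
    shape = (len(years), 3, ny, nx)
    fields = {name: np.full(shape, 1.0) for name in FIELDS}
    return GriddedScene(
        years=years, fields=fields,
        forest_type=np.ones((ny, nx), dtype=np.int8),
        burn_year=np.full((ny, nx), -1, dtype=np.int32),
        loss_count=np.zeros((len(years), ny, nx), dtype=np.int32),
        forest_subpixels=np.full((ny, nx), 100, dtype=np.int32),
        n_subpixels=100, pixel_size_m=500.0)


CRIT = ControlCriteria(window_x_km=5.0, window_y_km=5.0)  # 10x10 px window


class TestSelectControls:
    def test_clean_candidate_accepted(self):
        scene = tiny_scene()
        scene.burn_year[10, 10] = 2001
        scene.loss_count[1, 10, 12] = 5   # cumulative loss 0.10 over 2 yrs
        scene.loss_count[2, 10, 12] = 5
        ctrl = select_controls((10, 10), scene, 2001, 1, CRIT)
        assert (10, 12) in ctrl

    def test_burnt_in_following_year_rejected(self):
        scene = tiny_scene()
        scene.burn_year[10, 10] = 2001
        scene.burn_year[10, 12] = 2002
        assert (10, 12) not in select_controls((10, 10), scene, 2001, 1, CRIT)

    def test_burnt_same_year_rejected_but_old_burn_allowed(self):
        scene = tiny_scene()
        scene.burn_year[10, 10] = 2002
        scene.burn_year[10, 12] = 2002
        scene.burn_year[10, 13] = 2000  # before the fire year: stated rule admits it
        ctrl = select_controls((10, 10), scene, 2002, 1, CRIT)
        assert (10, 12) not in ctrl
        assert (10, 13) in ctrl

    def test_cumulative_loss_filter(self):
        scene = tiny_scene()
        scene.burn_year[10, 10] = 2001
        scene.loss_count[1, 10, 12] = 15  # 0.15 + 0.10 = 0.25 >= 0.20 cut
        scene.loss_count[2, 10, 12] = 10
        scene.loss_count[1, 10, 13] = 19  # 0.19 < 0.20 passes
        ctrl = select_controls((10, 10), scene, 2001, 1, CRIT)
        assert (10, 12) not in ctrl
        assert (10, 13) in ctrl

    def test_longer_lag_extends_loss_window(self):
        scene = tiny_scene()
        scene.burn_year[10, 10] = 2001
        scene.loss_count[3, 10, 12] = 15  # year 2003 only
        assert (10, 12) in select_controls((10, 10), scene, 2001, 1, CRIT)
        scene.loss_count[2, 10, 12] = 10  # now 0.25 cumulative by lag 2
        assert (10, 12) not in select_controls((10, 10), scene, 2001, 2, CRIT)

    def test_different_forest_type_rejected(self):
        scene = tiny_scene()
        scene.burn_year[10, 10] = 2001
        scene.forest_type[10, 12] = 3  # DBF
        assert (10, 12) not in select_controls((10, 10), scene, 2001, 1, CRIT)

    def test_window_geometry(self):
        scene = tiny_scene()
        scene.burn_year[10, 10] = 2001
        ctrl = select_controls((10, 10), scene, 2001, 1, CRIT)
        # half extent is floor(5 km / 0.5 km) // 2 = 5 px in each direction
        assert (10, 16) not in ctrl and (10, 15) in ctrl
        assert (16, 10) not in ctrl and (15, 10) in ctrl
        assert (10, 10) not in ctrl  # target excluded

    def test_never_selects_window_burnt_pixel(self, noisy_scene):
        """No control is burnt anywhere in fire_year..fire_year+lag."""
        _, scene, events = noisy_scene
        for ev in events[:10]:
            for lag in (1, 2):
                if ev.fire_year + lag > scene.years[-1]:
                    continue
                for px in map(tuple, ev.pixels[:2]):
                    for r, c in select_controls(px, scene, ev.fire_year, lag):
                        by = scene.burn_year[r, c]
                        assert by < ev.fire_year or by > ev.fire_year + lag


class TestPixelAndEventDelta:
    def test_direct_evaluation(self):
        """Target gross +2.0, controls {+0.4, +0.6} -> delta 1.5."""
        scene = tiny_scene()
        scene.burn_year[10, 10] = 2001
        yi0, yi2 = 0, 2
        si = 0
        scene.fields["T_day"][yi2, si, 10, 10] += 2.0
        scene.fields["T_day"][yi2, si, 10, 12] += 0.4
        scene.fields["T_day"][yi2, si, 10, 13] += 0.6
        d = pixel_delta((10, 10), "T_day", "JJA", 2001, 1,
                        [(10, 12), (10, 13)], scene)
        assert d == pytest.approx(2.0 - 0.5)

    def test_shared_gross_change_gives_zero(self):
        scene = tiny_scene()
        scene.fields["T_day"][2] += 3.0  # everyone changes alike
        d = pixel_delta((10, 10), "T_day", "JJA", 2001, 1,
                        [(10, 12), (10, 13)], scene)
        assert d == pytest.approx(0.0)

    def test_too_few_controls_dropped(self):
        scene = tiny_scene()
        assert np.isnan(pixel_delta((10, 10), "T_day", "JJA", 2001, 1, [], scene))

    def test_missing_value_dropped(self):
        scene = tiny_scene()
        scene.fields["T_day"][2, 0, 10, 10] = np.nan
        assert np.isnan(pixel_delta((10, 10), "T_day", "JJA", 2001, 1,
                                    [(10, 12)], scene))

    def test_event_mean_and_drop_accounting(self, oracle_config, oracle_scene):
        scene, events = oracle_scene
        ev = events[0]
        rec = event_delta(ev, "T", "JJA", 1, scene)
        assert rec.n_pixels_used + rec.n_pixels_dropped == ev.n_pixels
        assert rec.n_pixels_dropped == 0
        assert rec.delta == pytest.approx(
            injected_effect(oracle_config, "T", ev.dominant_type, ev.size_km2),
            abs=1e-10)

    def test_all_pixels_dropped_gives_missing_record(self):
        scene = tiny_scene(ny=5, nx=5)
        # isolate the target: every candidate is a different forest type
        scene.forest_type[:] = 3
        scene.forest_type[2, 2] = 1
        scene.burn_year[2, 2] = 2001
        from pyrodelta import FireEvent
        import datetime as dt
        ev = FireEvent(event_id=0, pixels=[(2, 2)], start_date=dt.date(2001, 6, 1),
                       end_date=dt.date(2001, 6, 2), size_km2=0.25,
                       duration_days=2, spread_rate=0.125, fire_year=2001)
        rec = event_delta(ev, "T_day", "JJA", 1, scene, CRIT)
        assert np.isnan(rec.delta) and rec.n_pixels_used == 0
        assert rec.n_pixels_dropped == 1


class TestExactRecovery:
    def test_zero_noise_recovery_all_variables_seasons_lags(
            self, oracle_config, oracle_scene):
        """With noise off and a uniform background, event deltas equal the
        injected effects to machine precision everywhere."""
        scene, events = oracle_scene
        for ev in events:
            for var in ("T", "T_day", "T_night", "albedo", "ET", "LAI", "emissivity"):
                v_eff = "T" if var in ("T_day", "T_night") else var
                for lag in (1, 3, 6):
                    for season in ("JJA", "DJF", "annual"):
                        rec = event_delta(ev, var, season, lag, scene)
                        expected = injected_effect(
                            oracle_config, v_eff, ev.dominant_type,
                            ev.size_km2, season, lag)
                        assert rec.delta == pytest.approx(expected, abs=1e-10)

    def test_unbiased_under_noise(self):
        """Mean bias of event deltas over 500 noisy events within 3 s.e. of 0."""
        slopes = {"T": {t: 0.0 for t in ("ENF", "DNF", "DBF", "MF")}}
        cfg = SyntheticConfig(
            grid_nx=170, grid_ny=170, n_fires=500, seed=17,
            lognormal_mu=0.0, lognormal_sigma=0.05,  # ~4-pixel fires
            years=tuple(range(2002, 2006)), fire_years=(2003,),
            effect_slopes=slopes, effect_intercepts={"T": slopes["T"]},
            background_sd={"T_day": 0.5, "T_night": 0.5},
            noise_sd={"T_day": 0.8, "T_night": 0.8},
            forest_fractions={"ENF": 1.0},
        )
        scene, events = generate_scene(cfg)
        crit = ControlCriteria(window_x_km=10, window_y_km=10)
        deltas = np.array([event_delta(ev, "T", "JJA", 1, scene, crit).delta
                           for ev in events])
        deltas = deltas[np.isfinite(deltas)]
        assert len(deltas) >= 450
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se


class TestTemporalAggregation:
    def test_daily_lst(self):
        assert daily_lst(300.0, 280.0) == pytest.approx(290.0)
        assert daily_lst(285.0, 285.0) == pytest.approx(285.0)
        assert daily_lst(300.0, None) is None
        assert np.isnan(daily_lst(300.0, np.nan))

    def test_jja_mean(self):
        idx = pd.date_range("2005-01-01", "2005-12-01", freq="MS")
        vals = pd.Series(0.0, index=idx)
        vals[idx.month == 6] = 1
        vals[idx.month == 7] = 2
        vals[idx.month == 8] = 3
        out = seasonal_mean(vals, "JJA")
        assert out[2005] == pytest.approx(2.0)

    def test_djf_labelled_by_jan_feb_year(self):
        idx = pd.date_range("2004-12-01", "2005-02-01", freq="MS")
        vals = pd.Series([0.0, 2.0, 4.0], index=idx)
        out = seasonal_mean(vals, "DJF")
        assert out[2005] == pytest.approx(2.0)
        assert 2004 not in out.index

    def test_annual_mean_and_missing(self):
        idx = pd.date_range("2005-01-01", "2005-12-01", freq="MS")
        out = seasonal_mean(pd.Series(5.0, index=idx), "annual")
        assert out[2005] == pytest.approx(5.0)
        all_nan = pd.Series(np.nan, index=idx[5:8])
        assert 2005 not in seasonal_mean(all_nan, "JJA").index
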