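"""Synthetic-study generator: stated statistical structure and determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dielrhythms as dr


class TestGenEnvSeries:
    def test_cosine_extrema_and_length(self, sampling):
        spec = dr.EnvDriverSpec("x", baseline=0.0,
                                components=[(24.0, 1.0, 0.0)], noise_sd=0.0)
        s = dr.gen_env_series(spec, sampling)
        assert len(s.values) == 24 * sampling.n_days
        assert s.values[0] == pytest.approx(1.0)
        assert s.values[12] == pytest.approx(-1.0)

    def test_degenerate_constant(self, sampling):
        s = dr.gen_env_series(dr.EnvDriverSpec("x", baseline=5.0), sampling)
        assert np.all(s.values == 5.0)

    def test_noise_variance_matches_independent_sampler(self):
        # residual variance vs an independent normal sampler at the same
        # sd: both must land within 30% of sigma^2 = 0.01
        spec = dr.EnvDriverSpec("x", baseline=0.0,
                                components=[(24.0, 1.0, 0.0)], noise_sd=0.1)
        samp = dr.SamplingSpec(rng_seed=42)
        noisy = dr.gen_env_series(spec, samp)
        clean = dr.gen_env_series(
            dr.EnvDriverSpec("x", baseline=0.0, components=[(24.0, 1.0, 0.0)],
                             noise_sd=0.0), samp)
        resid_var = np.var(noisy.values - clean.values, ddof=1)
        assert resid_var == pytest.approx(0.01, rel=0.30)
        oracle = np.random.RandomState(2042).normal(0, 0.1, 120)
        assert np.var(oracle, ddof=1) == pytest.approx(0.01, rel=0.30)

    def test_reproducible_under_seed(self, sampling):
        spec = dr.EnvDriverSpec("x", baseline=1.0, noise_sd=0.5)
        a = dr.gen_env_series(spec, sampling)
        b = dr.gen_env_series(spec, sampling)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError, match="period"):
            dr.EnvDriverSpec("x", components=[(0.0, 1.0, 0.0)])


class TestGenFlowComponents:
    @pytest.mark.parametrize(
        "mag,dir_deg,ns_expect,ew_expect",
        [(0.1, 90.0, 0.0, 0.1), (0.2, 0.0, 0.2, 0.0)],
    )
    def test_axis_cases(self, sampling, mag, dir_deg, ns_expect, ew_expect):
        spec = dr.EnvDriverSpec("flow_magnitude", baseline=mag)
        ns, ew = dr.gen_flow_components(spec, dir_deg, sampling)
        np.testing.assert_allclose(ns.values, ns_expect, atol=1e-15)
        np.testing.assert_allclose(ew.values, ew_expect, atol=1e-15)

    @given(dir_deg=st.floats(0.0, 359.99), baseline=st.floats(0.01, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_polar_round_trip(self, dir_deg, baseline):
        sampling = dr.SamplingSpec(rng_seed=1, n_days=1)
        spec = dr.EnvDriverSpec("flow_magnitude", baseline=baseline)
        ns, ew = dr.gen_flow_components(spec, dir_deg, sampling)
        mag, direction = dr.flow_vector_to_polar(ns, ew)
        np.testing.assert_allclose(mag.values, baseline, atol=1e-9)
        err = np.abs(np.mod(direction.values - dir_deg + 180.0, 360.0) - 180.0)
        assert np.max(err) < 1e-9


class TestGenCountSeries:
    def test_zero_rate_gives_zero_counts(self, sampling):
        recs = dr.gen_count_series(
            dr.RhythmSpec(amplitude=0.0, mesor_level=0.0), sampling, taxon="t")
        assert all(r.counts["t"] == 0 for r in recs)
        assert len(recs) == 2 * sampling.n_bio

    def test_poisson_mean_recovers_mesor(self):
        # mean normalized slot value over 200 seeds ~ mesor within 3 SE
        means = []
        for seed in range(200):
            samp = dr.SamplingSpec(rng_seed=seed)
            recs = dr.gen_count_series(
                dr.RhythmSpec(amplitude=0.0, mesor_level=6.0), samp, taxon="t")
            means.append(dr.pair_and_normalize(recs, "t").dropna().values.mean())
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - 6.0) <= 3 * se

    def test_acrophase_lands_in_expected_waveform_bin(self):
        # acrophase 11:00 with strong amplitude -> peak bin 08:00-12:00
        hits = 0
        for seed in range(100):
            samp = dr.SamplingSpec(rng_seed=seed)
            recs = dr.gen_count_series(
                dr.RhythmSpec(period_h=24.0, amplitude=8.0, mesor_level=8.0,
                              acrophase_h=11.0), samp, taxon="t")
            wf = dr.compute_waveform(dr.pair_and_normalize(recs, "t"))
            hits += 8.0 in wf.peak_bins_h
        assert hits >= 90

    def test_counts_nonneg_integers_and_rate_nonneg(self, sampling):
        # amplitude > mesor forces rate clipping at zero
        recs = dr.gen_count_series(
            dr.RhythmSpec(amplitude=5.0, mesor_level=1.0, acrophase_h=3.0),
            sampling, taxon="t")
        counts = np.array([r.counts["t"] for r in recs])
        assert np.all(counts >= 0) and np.all(counts == counts.astype(int))

    def test_gain_zero_independent_of_driver(self):
        # flat taxon with gain=0: CCF against the driver stays inside the
        # white-noise band in >=90% of seeds
        inside = 0
        n_seeds = 30
        for seed in range(n_seeds):
            samp = dr.SamplingSpec(rng_seed=seed)
            driver = dr.gen_env_series(
                dr.EnvDriverSpec("d", baseline=0.0,
                                 components=[(24.0, 1.0, 0.0)]), samp)
            recs = dr.gen_count_series(
                dr.RhythmSpec(amplitude=0.0, mesor_level=6.0), samp,
                coupling=dr.CouplingSpec("d", lag_h=12.0, gain=0.0),
                driver=driver, taxon="t")
            cs = dr.pair_and_normalize(recs, "t")
            env4 = dr.average_4h(driver, bio_grid=cs.timestamps)
            res = dr.cross_correlation(env4, cs, max_lag_steps=3)
            inside += np.all(np.abs(res.ccf) < res.crit_05)
        assert inside >= 0.9 * n_seeds * 0.8  # joint band over 4 lags

    def test_negative_footage_rejected(self):
        with pytest.raises(ValueError, match="footage|negative"):
            dr.gen_count_series(
                dr.RhythmSpec(mesor_level=1.0),
                dr.SamplingSpec(rng_seed=0, footage_minutes_per_leg=-1.0),
                taxon="t")


class TestGenStudy:
    def test_table_shapes_and_grid(self):
        cfg = dr.default_study_config(seed=3)
        bundle = dr.gen_study(cfg)
        assert set(bundle.transects) == {"june", "july", "december"}
        for df in bundle.transects.values():
            assert len(df) == 30 * 2  # 30 slots x 2 legs
            assert set(df.columns) >= {"timestamp", "leg_id", "usable_minutes",
                                       "swimmer", "burrower", "walker"}
            slots = pd.DatetimeIndex(sorted(df["timestamp"].unique()))
            assert (np.diff(slots.asi8) == 4 * 3.6e12).all()
        for df in bundle.env_hourly.values():
            assert len(df) == 120

    def test_deterministic_files(self, tmp_path):
        for sub in ("a", "b"):
            dr.gen_study(dr.default_study_config(seed=11)).write(tmp_path / sub)
        for p in sorted((tmp_path / "a").iterdir()):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_clashing_variable_names_rejected(self):
        cfg = dr.default_study_config(seed=0)
        cfg.env_specs.append(dr.EnvDriverSpec("flow_magnitude", baseline=1.0))
        with pytest.raises(ValueError, match="clash"):
            dr.gen_study(cfg)

    def test_manifest_records_generator_choices(self):
        bundle = dr.gen_study(dr.default_study_config(seed=0))
        assert "count_noise_model" in bundle.manifest
        assert "leg_split_rule" in bundle.manifest
        assert bundle.manifest["rng_seed"] == 0
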