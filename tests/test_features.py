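"""The 38 component features: temporal, spectral and spatial blocks."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from icaclean import features as F
from icaclean.core_io import DegenerateInputError, reference_cap
from icaclean.synthetic import simulate_sources


@pytest.fixture(scope="module")
def ref_leadfield():
    return F.build_leadfield()


def _silently(fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kwargs)


class TestTemporalFeatures:
    def test_variance_uses_pattern_scale(self, rng):
        source = rng.standard_normal(20000)
        source /= source.std()
        pattern = np.array([2.0, -2.0, 2.0, -2.0])   # std exactly 2
        out = _silently(F.compute_temporal_features, source, pattern, 100.0)
        assert out["Variance"] == pytest.approx(np.log(4.0), abs=0.01)

    def test_nonstationarity_raises_var_local_var(self, rng):
        fs, n = 100.0, 60000
        base = rng.standard_normal(n)
        burst = base.copy()
        burst[10000:12000] *= 10.0
        f_base = _silently(F.compute_temporal_features, base, np.ones(3), fs)
        f_burst = _silently(F.compute_temporal_features, burst, np.ones(3), fs)
        assert f_burst["VarLocalVar15s"] > f_base["VarLocalVar15s"]

    def test_blink_train_has_larger_local_skewness(self, rng):
        fs = 200.0
        blink = simulate_sources(["blink"], fs, 120.0, seed=2)[0]
        sym = rng.standard_normal(len(blink))
        f_blink = _silently(F.compute_temporal_features, blink, np.ones(3), fs)
        f_sym = _silently(F.compute_temporal_features, sym, np.ones(3), fs)
        assert f_blink["MeanLocalSkew15s"] > f_sym["MeanLocalSkew15s"]

    def test_constant_source_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            F.compute_temporal_features(np.ones(1000), np.ones(3), 100.0)

    def test_short_recording_shrinks_window_with_warning(self, rng):
        source = rng.standard_normal(500)        # 5 s < 15 s window
        with pytest.warns(UserWarning, match="shorter"):
            out = F.compute_temporal_features(source, np.ones(3), 100.0)
        assert np.isfinite(out["MeanLocalVar15s"])


class TestSpectrum:
    def test_sine_peaks_at_its_frequency(self):
        fs, t = 200.0, np.arange(0, 30, 1 / 200.0)
        s = np.sin(2 * np.pi * 10 * t) + 0.001 * np.sin(2 * np.pi * 3 * t)
        freqs, logp = F.estimate_log_spectrum(s, fs)
        assert freqs[np.argmax(logp)] == pytest.approx(10.0, abs=0.5)

    def test_white_noise_spectrum_flat(self, rng):
        s = rng.standard_normal(5 * 60 * 200)
        freqs, logp = F.estimate_log_spectrum(s, 200.0)
        band = (freqs >= 2) & (freqs <= 45)
        assert logp[band].max() - logp[band].min() < 1.0

    def test_parseval_total_power_matches_variance(self, rng):
        s = rng.standard_normal(60 * 200)
        freqs, logp = F.estimate_log_spectrum(s, 200.0)
        total = np.trapezoid(np.exp(logp), freqs)
        assert total == pytest.approx(1.0, rel=0.05)   # unit-variance input

    def test_low_sampling_rate_rejected(self, rng):
        with pytest.raises(ValueError, match="45 Hz"):
            F.estimate_log_spectrum(rng.standard_normal(1000), 80.0)


class TestSpectralCurve:
    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.5, 20.0), st.floats(0.3, 3.0), st.floats(1e-3, 0.5))
    def test_exact_recovery_from_curve_family(self, k1, lam, k2):
        freqs = np.arange(0.0, 51.0)
        power = k1 * np.maximum(freqs, 1e-9) ** -lam + k2
        logp = np.log(power)
        logp[0] = logp[1]
        fit = F.fit_spectral_curve(freqs, logp)
        assert fit.k1 == pytest.approx(k1, rel=1e-6)
        assert fit.lam == pytest.approx(lam, rel=1e-6)
        assert fit.k2 == pytest.approx(k2, rel=1e-6)
        assert fit.mse < 1e-12

    def test_alpha_peak_increases_fit_error(self):
        freqs = np.arange(0.0, 51.0)
        logp = np.log(5.0 * np.maximum(freqs, 1e-9) ** -1.2 + 0.05)
        logp[0] = logp[1]
        peaked = logp.copy()
        peaked[9:12] += [1.0, 2.5, 1.0]
        assert (F.fit_spectral_curve(freqs, peaked).mse
                > F.fit_spectral_curve(freqs, logp).mse)

    def test_muscle_like_spectrum_has_larger_lambda(self):
        freqs = np.arange(0.0, 51.0)
        one_over_f = np.log(5.0 * np.maximum(freqs, 1e-9) ** -1.2 + 0.05)
        one_over_f[0] = one_over_f[1]
        muscle = np.where(freqs < 15, -2.0,
                          np.minimum(-2.0 + 0.25 * (freqs - 15), 1.5))
        fit_m = F.fit_spectral_curve(freqs, muscle)
        fit_f = F.fit_spectral_curve(freqs, one_over_f)
        assert fit_m.lam > fit_f.lam


class TestBandPowers:
    def test_sine_dominates_alpha_band(self):
        t = np.arange(0, 60, 1 / 200.0)
        s = np.sin(2 * np.pi * 10 * t) + 0.01 * np.random.default_rng(0).standard_normal(len(t))
        freqs, logp = F.estimate_log_spectrum(s, 200.0)
        bp = F.compute_band_powers(freqs, logp)
        assert max(bp, key=bp.get) == "BP_8_13"

    def test_white_noise_bands_close(self, rng):
        s = rng.standard_normal(5 * 60 * 200)
        freqs, logp = F.estimate_log_spectrum(s, 200.0)
        bp = F.compute_band_powers(freqs, logp)
        values = np.array(list(bp.values()))
        assert values.max() - values.min() < 0.5

    def test_amplitude_invariance_through_standardization(self, rng):
        s = rng.standard_normal(30 * 200)
        f1, l1 = F.estimate_log_spectrum(s, 200.0)
        f2, l2 = F.estimate_log_spectrum(7.5 * s, 200.0)
        bp1, bp2 = F.compute_band_powers(f1, l1), F.compute_band_powers(f2, l2)
        for name in bp1:
            assert bp2[name] == pytest.approx(bp1[name], abs=1e-9)


class TestPatternGeometry:
    def test_constant_pattern_floored_and_flagged(self, cap32):
        with pytest.warns(F.DegenerateFeatureWarning):
            out = F.compute_pattern_geometry_features(np.ones(32), cap32)
        assert out["RangeWithinPattern"] == pytest.approx(np.log(F.EPS))

    def test_two_point_extrema_distance(self, cap64):
        # +1 at the most anterior site, -1 at the most posterior one
        front = int(np.argmax(cap64.pos2d[:, 1]))
        back = int(np.argmin(cap64.pos2d[:, 1]))
        pattern = np.zeros(64)
        pattern[front], pattern[back] = 1.0, -1.0
        out = F.compute_pattern_geometry_features(pattern, cap64)
        expected = np.linalg.norm(cap64.pos2d[front] - cap64.pos2d[back])
        assert out["SpatialDistExtrema"] == pytest.approx(np.log(expected))

    def test_left_lateralized_pattern(self, cap64, leadfield64):
        j = int(np.argmin(np.linalg.norm(
            leadfield64.grid - np.array([-4.0, 0.0, 5.0]), axis=1)))
        pattern = leadfield64.F[:, 3 * j:3 * j + 3] @ np.array([0.0, 1.0, 0.5])
        out = F.compute_pattern_geometry_features(pattern, cap64)
        assert out["SM_Left"] > out["SM_Right"]

    def test_missing_group_rejected(self, cap64):
        crippled = type(cap64)(names=cap64.names, pos3d=cap64.pos3d,
                               groups={g: m for g, m in cap64.groups.items()
                                       if g != "central"},
                               border_set=cap64.border_set)
        with pytest.raises(ValueError, match="central"):
            F.compute_pattern_geometry_features(np.arange(64.0), crippled)


class TestSpatialFrequency:
    def test_constant_pattern_laplacian_floored(self, cap32):
        with pytest.warns(F.DegenerateFeatureWarning):
            out = F.compute_spatial_frequency_features(np.ones(32), cap32)
        assert out["LaplaceFilter"] == pytest.approx(np.log(F.EPS))

    def test_shuffled_pattern_rougher_than_smooth(self, cap64, leadfield64, rng):
        j = int(np.argmin(np.linalg.norm(
            leadfield64.grid - np.array([0.0, 2.0, 6.0]), axis=1)))
        smooth = leadfield64.F[:, 3 * j:3 * j + 3] @ np.array([1.0, 0.0, 0.5])
        shuffled = rng.permutation(smooth)
        f_smooth = F.compute_spatial_frequency_features(smooth, cap64)
        f_shuf = F.compute_spatial_frequency_features(shuffled, cap64)
        assert f_shuf["DFT2D"] > f_smooth["DFT2D"]
        assert f_shuf["LaplaceFilter"] > f_smooth["LaplaceFilter"]

    def test_checkerboard_near_maximal_spatial_frequency(self, cap64, rng):
        # alternating signs along the anterior-posterior sorting: rough
        order = np.argsort(cap64.pos2d[:, 1])
        checker = np.empty(64)
        checker[order] = np.where(np.arange(64) % 2 == 0, 1.0, -1.0)
        f_checker = F.compute_spatial_frequency_features(checker, cap64)
        smooth_vals = []
        for _ in range(5):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            smooth_vals.append(F.compute_spatial_frequency_features(
                cap64.pos3d @ direction, cap64)["DFT2D"])
        assert f_checker["DFT2D"] > max(smooth_vals)


class TestBorderActivation:
    def test_peak_at_hull_electrode(self, cap64):
        pattern = 0.01 * cap64.pos3d[:, 2]
        i = cap64.index(cap64.border_set[0])
        pattern[i] = 1.0
        assert F.compute_border_activation(pattern, cap64) == 1.0

    def test_smooth_central_dipole_is_interior(self, cap64, leadfield64):
        # tangential centro-parietal dipole: both potential extrema sit at
        # interior electrodes (a radial one drives its return pole to the rim)
        j = int(np.argmin(np.linalg.norm(
            leadfield64.grid - np.array([0.0, 0.0, 6.0]), axis=1)))
        pattern = leadfield64.F[:, 3 * j:3 * j + 3] @ np.array([0.0, 1.0, 0.0])
        assert F.compute_border_activation(pattern, cap64) == -1.0

    def test_sign_invariance(self, cap64):
        pattern = 0.01 * cap64.pos3d[:, 1]
        pattern[cap64.index(cap64.border_set[2])] = 1.0
        assert F.compute_border_activation(pattern, cap64) == 1.0
        assert F.compute_border_activation(-pattern, cap64) == 1.0


class TestLeadfield:
    def test_grid_has_2142_sources(self):
        grid = F.source_grid()
        assert grid.shape == (2142, 3)
        assert np.linalg.norm(grid, axis=1).max() < F.SHELL_RADII[0] * 10

    def test_regularization_constants(self, ref_leadfield):
        assert ref_leadfield.reg_lambda == 100.0
        assert 100.0 in F.REG_LAMBDA_CANDIDATES
        assert F.REG_LAMBDA_CANDIDATES == (0.0, 1.0, 10.0, 100.0, 1000.0)

    def test_depth_equalization(self, ref_leadfield):
        lf = ref_leadfield
        m = lf.grid.shape[0]
        b = lf.F / np.repeat(lf.gamma, 3)[None, :]
        norms = np.sqrt((b.reshape(b.shape[0], m, 3) ** 2).sum(axis=(0, 2)))
        assert norms.max() / norms.min() <= 1.1

    def test_unknown_channels_rejected(self, ref_leadfield):
        from icaclean.core_io import Montage
        bogus = Montage(names=["nope1", "nope2", "nope3"],
                        pos3d=np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0.2]]))
        with pytest.raises(ValueError, match="nope1"):
            F.build_leadfield(bogus)


class TestCurrentDensity:
    def test_dipolar_beats_random_patterns(self, cap64, leadfield64, rng):
        radii = np.linalg.norm(leadfield64.grid, axis=1)
        sup = np.where((radii > 5) & (radii < 7.9)
                       & (leadfield64.grid[:, 2] > 0))[0]
        wins = 0
        for _ in range(25):
            j = int(rng.choice(sup))
            pat = leadfield64.F[:, 3 * j:3 * j + 3] @ rng.standard_normal(3)
            pat += 0.01 * np.linalg.norm(pat) / 8.0 * rng.standard_normal(64)
            cdn_d = F.compute_current_density_features(pat, cap64, leadfield64)
            cdn_r = F.compute_current_density_features(
                rng.standard_normal(64), cap64, leadfield64)
            wins += cdn_d["CurrentDensityNorm"] < cdn_r["CurrentDensityNorm"]
        assert wins == 25

    def test_scaling_invariance(self, cap64, leadfield64):
        pattern = leadfield64.F[:, :3] @ np.array([1.0, 2.0, 3.0])
        a = F.compute_current_density_features(pattern, cap64, leadfield64)
        b = F.compute_current_density_features(10.0 * pattern, cap64,
                                               leadfield64)
        assert a == b

    def test_localization_of_superficial_dipoles(self, ref_leadfield, rng):
        cap = reference_cap()
        lf = ref_leadfield
        radii = np.linalg.norm(lf.grid, axis=1)
        sup = np.where((radii > 6) & (radii < 7.9) & (lf.grid[:, 2] > 2))[0]
        errors = []
        for _ in range(30):
            j = int(rng.choice(sup))
            pat = lf.F[:, 3 * j:3 * j + 3] @ rng.standard_normal(3)
            out = F.compute_current_density_features(pat, cap, lf)
            errors.append(np.linalg.norm(
                np.array([out["x"], out["y"], out["z"]]) - lf.grid[j]))
        assert np.median(errors) <= 2.0

    def test_zero_pattern_rejected(self, cap64, leadfield64):
        with pytest.raises(DegenerateInputError):
            F.compute_current_density_features(np.zeros(64), cap64, leadfield64)


class TestAssembly:
    def test_feature_count_and_determinism(self, cap32, rng):
        source = simulate_sources(["alpha"], 200.0, 30.0, seed=1)[0]
        pattern = rng.standard_normal(32)
        row1 = _silently(F.compute_component_features, source, pattern,
                         200.0, cap32)
        row2 = _silently(F.compute_component_features, source, pattern,
                         200.0, cap32)
        assert list(row1) == F.FEATURE_NAMES and len(row1) == 38
        assert row1 == row2

    def test_muscle_vs_alpha_direction(self, cap32):
        srcs = simulate_sources(["muscle", "alpha"], 200.0, 60.0, seed=4)
        rng = np.random.default_rng(1)
        pattern = rng.standard_normal(32)
        f_muscle = _silently(F.compute_component_features, srcs[0], pattern,
                             200.0, cap32)
        f_alpha = _silently(F.compute_component_features, srcs[1], pattern,
                            200.0, cap32)
        assert f_muscle["lambda"] > f_alpha["lambda"]
        assert f_muscle["BP_31_45"] > f_alpha["BP_31_45"]

    def test_sign_invariance_of_all_features(self, cap32):
        source = simulate_sources(["blink"], 200.0, 60.0, seed=5)[0]
        rng = np.random.default_rng(2)
        pattern = rng.standard_normal(32)
        a = _silently(F.compute_component_features, source, pattern, 200.0,
                      cap32)
        b = _silently(F.compute_component_features, -source, -pattern, 200.0,
                      cap32)
        for name in F.FEATURE_NAMES:
            if name in ("x", "y", "z"):
                continue                       # grid coordinates, not logs
            assert b[name] == pytest.approx(a[name], abs=1e-8), name

    def test_scale_reparameterization_invariance(self, cap32):
        source = simulate_sources(["alpha"], 200.0, 60.0, seed=6)[0]
        rng = np.random.default_rng(3)
        pattern = rng.standard_normal(32)
        c = 3.7
        a = _silently(F.compute_component_features, source, pattern, 200.0,
                      cap32)
        b = _silently(F.compute_component_features, source / c, c * pattern,
                      200.0, cap32)
        for name in F.FEATURE_NAMES:
            assert b[name] == pytest.approx(a[name], abs=1e-6), name

    def test_corpus_feature_separation(self, fset_train):
        """Key features separate planted artifact from neural components."""
        frame = pd.DataFrame(fset_train.features,
                             columns=fset_train.feature_names)
        y = fset_train.labels > 0
        for name in ("CurrentDensityNorm", "lambda", "BP_8_13",
                     "RangeWithinPattern"):
            auc = roc_auc_score(y, frame[name])
            assert max(auc, 1 - auc) >= 0.8, name
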