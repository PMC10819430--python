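"""Spectral containers, inner-filter correction, CSV round-trips, peaks."""

import numpy as np
import pytest

from pfasbind import (
    EEMGrid,
    EmissionSpectrum,
    SimulationConfig,
    TitrationPoint,
    TitrationSeries,
    correct_inner_filter,
    eem_peaks,
    peak_metrics,
    read_fixture,
    read_titration_csv,
    series_intensities,
    simulate_titration,
    write_fixture,
)
from pfasbind.spectra import FormatError, ValidationError


class TestValidation:
    def test_nonmonotone_wavelengths_rejected(self):
        with pytest.raises(ValidationError):
            EmissionSpectrum([300.0, 299.0, 301.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            EmissionSpectrum([300.0, 301.0], [1.0])

    def test_absorbances_must_come_in_pairs(self, gaussian_spectrum):
        with pytest.raises(ValidationError):
            TitrationPoint(ligand_conc=0.0, spectrum=gaussian_spectrum(), a_ex=0.1)

    def test_series_requires_single_zero_point(self, gaussian_spectrum):
        pts = tuple(
            TitrationPoint(ligand_conc=c, spectrum=gaussian_spectrum())
            for c in (3e-6, 6e-6, 9e-6)
        )
        with pytest.raises(ValidationError, match="zero"):
            TitrationSeries(series_id="x", temperature_K=298.0, points=pts)


class TestInnerFilter:
    @pytest.mark.parametrize(
        "f_obs, a_ex, a_em, expected",
        [
            (100.0, 0.0, 0.0, 100.0),
            (100.0, 0.1, 0.1, 100.0 * 10**0.1),
            (50.0, 0.2, 0.0, 50.0 * 10**0.1),
        ],
    )
    def test_direct_values(self, f_obs, a_ex, a_em, expected):
        assert correct_inner_filter(f_obs, a_ex, a_em) == pytest.approx(expected, rel=1e-12)

    def test_correction_never_decreases(self):
        assert correct_inner_filter(7.0, 0.3, 0.05) >= 7.0

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            correct_inner_filter(100.0, -0.1, 0.0)

    def test_inverts_simulated_attenuation(self, noshift_config):
        """Applying the correction to an attenuated simulation restores the
        unattenuated intensities to <= 1e-9 relative error."""
        a = [0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.12]
        clean, _ = simulate_titration(noshift_config())
        dimmed, _ = simulate_titration(noshift_config(ife_a_ex=a, ife_a_em=a))
        for p_clean, p_dim in zip(clean.points, dimmed.points):
            restored = np.array(
                [
                    correct_inner_filter(f, p_dim.a_ex, p_dim.a_em)
                    for f in p_dim.spectrum.intensities
                ]
            )
            np.testing.assert_allclose(restored, p_clean.spectrum.intensities, rtol=1e-9)


class TestSeriesIntensities:
    def test_first_pair_is_f0(self, simulated_series):
        series, truth = simulated_series
        pairs = series_intensities(series, policy="fixed_reference")
        assert pairs[0][0] == 0.0
        assert pairs[0][1] == pytest.approx(truth.f0, rel=1e-12)
        assert len(pairs) == len(series.points)

    def test_static_quenching_gives_decreasing_f(self, simulated_series):
        series, _ = simulated_series
        f = [v for _, v in series_intensities(series)]
        assert all(b < a for a, b in zip(f, f[1:]))

    def test_per_spectrum_max_tracks_each_maximum(self):
        series, _ = simulate_titration(SimulationConfig(kb_true=1e5))  # drifting peak
        pairs = series_intensities(series, policy="per_spectrum_max")
        for point, (_, f) in zip(series.points, pairs):
            assert f == pytest.approx(float(point.spectrum.intensities.max()), rel=1e-12)

    def test_reference_outside_range_rejected(self, simulated_series):
        series, _ = simulated_series
        with pytest.raises(ValueError):
            series_intensities(series, reference_nm=600.0)


class TestPeakMetrics:
    def test_identity_spectrum(self, gaussian_spectrum):
        ref = gaussian_spectrum(337.0)
        m = peak_metrics(ref, ref)
        assert m.delta_lambda_nm == 0.0
        assert m.shift_class == "none"
        assert m.quench_pct == 0.0

    def test_blue_shift_and_quench(self, gaussian_spectrum):
        """A band at 317 nm at 69.4% of the 337 nm reference height reads as a
        -20 nm blue shift with 30.6% quenching."""
        ref = gaussian_spectrum(337.0, height=1000.0)
        spec = gaussian_spectrum(317.0, height=694.0)
        m = peak_metrics(spec, ref)
        assert m.delta_lambda_nm == pytest.approx(-20.0)
        assert m.shift_class == "blue"
        assert m.quench_pct == pytest.approx(30.6)

    def test_shift_antisymmetric(self, gaussian_spectrum):
        a, b = gaussian_spectrum(330.0), gaussian_spectrum(345.0)
        assert peak_metrics(a, b).delta_lambda_nm == -peak_metrics(b, a).delta_lambda_nm

    def test_tolerance_partitions_classes(self, gaussian_spectrum):
        ref = gaussian_spectrum(337.0)
        assert peak_metrics(gaussian_spectrum(336.7), ref, shift_tolerance_nm=0.5).shift_class == "none"
        assert peak_metrics(gaussian_spectrum(338.0), ref, shift_tolerance_nm=0.5).shift_class == "red"

    def test_parabolic_refinement_beats_grid(self, gaussian_spectrum):
        """On a 1 nm grid a band truly centred at 336.4 nm refines to within
        0.1 nm (grid argmax alone is only good to half the spacing)."""
        ref = gaussian_spectrum(337.0)
        spec = gaussian_spectrum(336.4)
        m = peak_metrics(spec, ref, refine=True)
        assert m.lambda_max_nm == pytest.approx(336.4, abs=0.1)

    def test_zero_reference_rejected(self, gaussian_spectrum):
        ref = EmissionSpectrum([300.0, 301.0, 302.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            peak_metrics(gaussian_spectrum(), ref)


class TestEEM:
    @staticmethod
    def _grid(height_a=1000.0, height_b=800.0):
        # humps on-grid at (280, 336) and (230, 340): 5 nm excitation steps,
        # 2 nm emission steps
        ex = np.arange(220.0, 401.0, 5.0)
        em = np.arange(280.0, 551.0, 2.0)
        EX, EM = np.meshgrid(ex, em, indexing="ij")
        z = height_a * np.exp(-0.5 * (((EX - 280) / 10) ** 2 + ((EM - 336) / 12) ** 2))
        z += height_b * np.exp(-0.5 * (((EX - 230) / 10) ** 2 + ((EM - 340) / 12) ** 2))
        return EEMGrid(ex, em, z)

    def test_finds_both_humps(self):
        peaks = eem_peaks(self._grid(), [("A", 280, 337), ("B", 230, 340)])
        assert (peaks[0].excitation_nm, peaks[0].emission_nm) == (280.0, 336.0)
        assert (peaks[1].excitation_nm, peaks[1].emission_nm) == (230.0, 340.0)

    def test_intensity_ratio_between_grids(self):
        """A second grid built at 62.2% of the first hump's height reports a
        37.8% intensity reduction."""
        a = eem_peaks(self._grid(1000.0, height_b=0.0), [("A", 280, 337)])[0]
        b = eem_peaks(self._grid(622.0, height_b=0.0), [("A", 280, 337)])[0]
        assert (1 - b.intensity / a.intensity) * 100 == pytest.approx(37.8, abs=1e-9)

    def test_radius_limits_search_window(self):
        grid = self._grid()
        near = eem_peaks(grid, [("A", 260, 337)], search_radius_nm=30)[0]
        far = eem_peaks(grid, [("A", 260, 337)], search_radius_nm=5)[0]
        assert near.intensity > far.intensity  # small window misses the true hump

    def test_seed_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            eem_peaks(self._grid(), [("A", 100, 337)])


class TestTitrationCSV:
    def test_fixture_round_trip_identity(self, tmp_path, noshift_config):
        series, truth = simulate_titration(noshift_config(noise_sd_rel=0.01, seed=7))
        path = tmp_path / "fx.csv"
        write_fixture(series, truth, path)
        back, truth_back = read_fixture(path)
        assert truth_back == truth
        assert back.series_id == series.series_id
        assert back.temperature_K == series.temperature_K
        for p0, p1 in zip(series.points, back.points):
            assert p1.ligand_conc == pytest.approx(p0.ligand_conc, rel=1e-11)
            np.testing.assert_allclose(
                p1.spectrum.intensities, p0.spectrum.intensities, rtol=1e-11
            )

    def test_ife_columns_round_trip(self, tmp_path, noshift_config):
        a = [0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.12]
        series, truth = simulate_titration(noshift_config(ife_a_ex=a, ife_a_em=a))
        path = tmp_path / "fx.csv"
        write_fixture(series, truth, path)
        back, _ = read_fixture(path)
        assert [p.a_ex for p in back.points] == pytest.approx(a)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("series_id,temperature_K,wavelength_nm,intensity\ns,298,300,1\n")
        with pytest.raises(FormatError, match="ligand_conc_M"):
            read_titration_csv(path)

    def test_missing_zero_concentration_rejected(self, tmp_path):
        rows = ["series_id,temperature_K,ligand_conc_M,wavelength_nm,intensity"]
        for c in (3e-6, 6e-6, 9e-6):
            for w in (300, 301, 302):
                rows.append(f"s,298,{c},{w},10")
        path = tmp_path / "nozero.csv"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValidationError, match="zero"):
            read_titration_csv(path)

    def test_synchronous_scan_representable(self, tmp_path):
        """A synchronous-fluorescence series (wavelength axis = excitation)
        reads as an ordinary titration series; no dedicated type needed."""
        rows = ["series_id,temperature_K,ligand_conc_M,wavelength_nm,intensity"]
        for c, h in [(0.0, 100.0), (3e-6, 90.0), (6e-6, 82.0)]:
            for w in range(200, 401, 50):
                rows.append(f"sync15,298,{c},{w},{h * np.exp(-((w - 280) / 30) ** 2)}")
        path = tmp_path / "sync.csv"
        path.write_text("\n".join(rows) + "\n")
        series = read_titration_csv(path)
        assert len(series.points) == 3
        assert series.points[0].spectrum.wavelengths_nm[0] == 200.0
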