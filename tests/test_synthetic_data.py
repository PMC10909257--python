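"""Design fixture integrity, Beer-Lambert mixing and the dosage-form simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specresolve import (
    ANALYTES,
    DEFAULT_LEVEL_GRIDS,
    AnalyteSpec,
    DesignMatrix,
    SpectraSet,
    default_pure_spectra,
    generate_design,
    simulate_dosage_form,
    simulate_spectra,
    table1_design,
)
from specresolve.synthetic_data import CYCLIC_LEVEL_SEQUENCE


class TestDesign:
    def test_fixture_blocks(self, design):
        assert len(design.calibration) == 25
        assert len(design.validation) == 5
        np.testing.assert_allclose(design.nominal[0], [12.0, 9.0, 7.5, 5.0])
        # duplicated centre point, as printed
        np.testing.assert_allclose(design.nominal[0], design.nominal[24])
        np.testing.assert_allclose(design.coded[0], [0, 0, 0, 0])

    def test_coded_lookup(self, design):
        # (20, 15, 2.5, 1) sits at the outer levels
        row = design.nominal.tolist().index([20.0, 15.0, 2.5, 1.0])
        np.testing.assert_allclose(design.coded[row], [2, 2, -2, -2])

    def test_coded_nominal_round_trip(self, design):
        for j, name in enumerate(ANALYTES):
            grid = np.asarray(DEFAULT_LEVEL_GRIDS[name])
            coded = design.coded[:, j]
            on_grid = ~np.isnan(coded)
            np.testing.assert_allclose(
                design.nominal[on_grid, j], grid[coded[on_grid].astype(int) + 2]
            )
        # every calibration entry sits on its grid
        assert not np.isnan(design.calibration.coded).any()

    def test_cyclic_generator_structure(self):
        d = generate_design(source="cyclic")
        cal = d.calibration
        assert len(cal) == 25 and len(d.validation) == 5
        np.testing.assert_allclose(cal.coded[0], 0)
        seq = np.array(CYCLIC_LEVEL_SEQUENCE)
        for j in range(4):
            np.testing.assert_array_equal(cal.coded[1:, j], np.roll(seq, -j))
        # each factor uses all five levels
        for j in range(4):
            assert set(np.unique(cal.coded[:, j])) == {-2, -1, 0, 1, 2}
        # validation block is the printed hold-out
        np.testing.assert_allclose(d.validation.nominal, table1_design().validation.nominal)

    def test_bad_grids_rejected(self):
        bad = dict(DEFAULT_LEVEL_GRIDS, PARA=(4.0, 8.0, 8.0, 16.0, 20.0))
        with pytest.raises(ValueError):
            generate_design(level_grids=bad, source="cyclic")
        short = dict(DEFAULT_LEVEL_GRIDS, ASC=(3.0, 6.0, 9.0))
        with pytest.raises(ValueError):
            generate_design(level_grids=short)

    def test_csv_round_trip(self, design, tmp_path):
        path = tmp_path / "design.csv"
        design.to_csv(path)
        back = DesignMatrix.from_csv(path)
        np.testing.assert_allclose(back.nominal, design.nominal)
        assert list(back.role) == list(design.role)
        assert back.sample_ids == design.sample_ids

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(-2, 2), min_size=4, max_size=4))
    def test_from_nominal_recovers_codes(self, codes):
        nominal = [
            DEFAULT_LEVEL_GRIDS[name][c + 2] for name, c in zip(ANALYTES, codes)
        ]
        d = DesignMatrix.from_nominal(np.array([nominal]), "calibration")
        np.testing.assert_allclose(d.coded[0], codes)


class TestPureSpectra:
    def test_grid_arithmetic(self):
        assert default_pure_spectra(1.0).wavelengths_nm.size == 201
        assert default_pure_spectra(0.5).wavelengths_nm.size == 401
        with pytest.raises(ValueError):
            default_pure_spectra(3.0)

    def test_nonnegative_and_ordered(self, pure):
        assert pure.analytes == ANALYTES
        assert np.all(pure.unit_absorptivity >= 0)

    def test_window_overlap_correlations(self, pure_windowed):
        # severe overlap is the point: every pair shares band structure
        corr = np.corrcoef(pure_windowed.T)
        off = corr[np.triu_indices(4, 1)]
        assert np.all(off > 0.3)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            AnalyteSpec("X", bands=((250.0, -1.0, 0.1),), level_grid=(1, 2, 3, 4, 5))
        with pytest.raises(ValueError):
            AnalyteSpec("X", bands=((500.0, 5.0, 0.1),), level_grid=(1, 2, 3, 4, 5))
        with pytest.raises(ValueError):
            AnalyteSpec("X", bands=((250.0, 5.0, 0.1),), level_grid=(1, 2, 2, 4, 5))


class TestSimulation:
    def test_beer_lambert_linearity_and_additivity(self, pure):
        singles = np.eye(4) * [8.0, 6.0, 5.0, 4.0]
        d = DesignMatrix.from_nominal(singles, "calibration")
        spectra = simulate_spectra(d, pure, noise_sd=0.0)
        doubled = DesignMatrix.from_nominal(2 * singles, "calibration")
        np.testing.assert_allclose(
            simulate_spectra(doubled, pure, noise_sd=0.0).absorbance,
            2 * spectra.absorbance,
        )
        mix = DesignMatrix.from_nominal(singles.sum(axis=0, keepdims=True), "calibration")
        np.testing.assert_allclose(
            simulate_spectra(mix, pure, noise_sd=0.0).absorbance[0],
            spectra.absorbance.sum(axis=0),
            atol=1e-12,
        )

    def test_noiseless_rank_four(self, noiseless):
        s = np.linalg.svd(noiseless.absorbance, compute_uv=False)
        assert s[4] / s[0] < 1e-8

    def test_noise_scale(self, design, pure):
        clean = simulate_spectra(design, pure, noise_sd=0.0).absorbance
        noisy = simulate_spectra(design, pure, noise_sd=0.002, seed=42).absorbance
        sd = np.std(noisy - clean)
        assert abs(sd - 0.002) < 0.1 * 0.002

    def test_seeded_determinism(self, design, pure):
        a = simulate_spectra(design, pure, noise_sd=0.002, seed=7).absorbance
        b = simulate_spectra(design, pure, noise_sd=0.002, seed=7).absorbance
        c = simulate_spectra(design, pure, noise_sd=0.002, seed=8).absorbance
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_spectra_csv_round_trip(self, noiseless, tmp_path):
        path = tmp_path / "spectra.csv"
        noiseless.to_csv(path)
        back = SpectraSet.from_csv(path)
        np.testing.assert_allclose(back.wavelengths_nm, noiseless.wavelengths_nm)
        np.testing.assert_allclose(back.absorbance, noiseless.absorbance, atol=1e-6)


class TestDosageForm:
    def test_spike_arithmetic(self, pure):
        _, d = simulate_dosage_form(pure, spike_cpm=0.75, noise_sd=0.0)
        np.testing.assert_allclose(d.nominal[0], [20.0, 15.0, 2.5, 1.0])
        _, d0 = simulate_dosage_form(pure, spike_cpm=0.0, noise_sd=0.0)
        np.testing.assert_allclose(d0.nominal[0], [20.0, 15.0, 2.5, 0.25])
        # 80:1:10:60 PARA:CPM:CAF:ASC scaled to PARA 20, before spiking
        para, asc, caf, cpm = d0.nominal[0]
        np.testing.assert_allclose(
            [para, cpm, caf, asc], np.array([80, 1, 10, 60]) / 80 * 20
        )

    def test_replicates(self, pure):
        spectra, d = simulate_dosage_form(pure, noise_sd=0.002, seed=1)
        assert len(spectra) == 3 and len(d) == 3
        assert np.ptp(d.nominal, axis=0).max() == 0  # identical nominals

    def test_negative_spike_rejected(self, pure):
        with pytest.raises(ValueError):
            simulate_dosage_form(pure, spike_cpm=-0.1)
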