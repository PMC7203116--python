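"""Projection images, power spectra, layer-line detection and scoring."""

import numpy as np
import pytest

import pilax as px
from pilax.builder import Atom, SubunitModel
from pilax.diffraction import (
    ScoreSettings,
    average_power_spectrum,
    estimate_pitch,
)


def point_subunit(position):
    return SubunitModel(
        atoms=[Atom("CA", "C", "GLY", 1, np.asarray(position, float))]
    )


class TestProjectModel:
    def test_single_atom_peak_position(self):
        fil = px.FilamentModel(
            subunits=[point_subunit([0.0, 3.0, -5.0])],
            symmetry=px.HelicalSymmetry(1.0, 90.0),
        )
        img = px.project_model(fil, pixel_size=1.0, box=64, blur_sigma=1.5)
        row, col = np.unravel_index(np.argmax(img.grid), img.grid.shape)
        # single atom is centred in the box by construction
        assert (row, col) == (32, 32)
        assert img.grid[row, col] == img.grid.max() > 0

    def test_intensity_linear_in_atom_count(self, toy_subunit, wide_sym):
        f5 = px.build_filament(toy_subunit, wide_sym, 5)
        f6 = px.build_filament(toy_subunit, wide_sym, 6)
        i5 = px.project_model(f5, box=192).grid.sum()
        i6 = px.project_model(f6, box=192).grid.sum()
        assert i6 / i5 == pytest.approx(6.0 / 5.0, rel=1e-6)

    def test_box_too_small(self, toy_subunit, wide_sym):
        fil = px.build_filament(toy_subunit, wide_sym, 40)
        with pytest.raises(ValueError, match="box"):
            px.project_model(fil, box=128)


class TestPowerSpectrum:
    def test_constant_image_all_energy_at_dc(self):
        img = px.ProjectionImage(grid=np.ones((64, 64)), pixel_size=1.0)
        ps = px.power_spectrum(img, taper=0.0)
        dc = ps.grid[ps.equator_row, ps.meridian_col]
        assert dc == pytest.approx(ps.grid.sum(), rel=1e-9)

    def test_vertical_cosine_peaks(self):
        n, period = 128, 16
        rows = np.arange(n)[:, None]
        img = px.ProjectionImage(
            grid=np.cos(2 * np.pi * rows / period) * np.ones((1, n)),
            pixel_size=1.0,
        )
        ps = px.power_spectrum(img, taper=0.0)
        col = ps.meridian_col
        peak_rows = np.argsort(ps.grid[:, col])[-2:]
        freqs = sorted(ps.axial_freq[r] for r in peak_rows)
        assert freqs[0] == pytest.approx(-1.0 / period, abs=1e-12)
        assert freqs[1] == pytest.approx(+1.0 / period, abs=1e-12)

    def test_parseval(self, rng):
        img = px.ProjectionImage(grid=rng.standard_normal((96, 96)), pixel_size=1.0)
        ps = px.power_spectrum(img, taper=0.1)
        from scipy.signal.windows import tukey

        win = np.outer(tukey(96, 0.2), tukey(96, 0.2))
        energy = np.sum((img.grid * win) ** 2)
        assert ps.grid.sum() == pytest.approx(energy, rel=1e-6)

    def test_amplitudes_invariant_under_axial_shift(self, toy_subunit, wide_sym):
        fil = px.build_filament(toy_subunit, wide_sym, 24)
        shifted = px.build_filament(toy_subunit, wide_sym, 24, start_index=3)
        ps_a = px.power_spectrum(px.project_model(fil, box=320))
        ps_b = px.power_spectrum(px.project_model(shifted, box=320))
        # spectra agree up to small interpolation error from the box recentring
        corr = np.corrcoef(
            np.log1p(ps_a.grid).ravel(), np.log1p(ps_b.grid).ravel()
        )[0, 1]
        assert corr > 0.99


class TestDetectLayerLines:
    def test_wide_meridional_at_rise(self, wide_sym):
        img, _ = px.make_filament_image(wide_sym, n_subunits=48, seed=1, box=512)
        lines = px.detect_layer_lines(px.power_spectrum(img))
        meridionals = [L for L in lines if L.is_meridional]
        assert meridionals
        # within one Fourier sample of the true rise
        df = 1.0 / 512
        f = 1.0 / meridionals[0].axial_spacing
        assert abs(f - 1.0 / 9.33) <= df

    def test_narrow_pitch_line(self, narrow_sym):
        # the strongest off-meridional line is the order-1 line at 1/pitch
        img, _ = px.make_filament_image(narrow_sym, n_subunits=40, seed=2, box=512)
        from pilax.diffraction import average_power_spectrum, estimate_pitch

        pitch, lines = estimate_pitch(average_power_spectrum([img]))
        assert lines
        assert abs(1.0 / pitch - 1.0 / 48.1) <= 1.0 / 512

    def test_featureless_rod_gives_no_layer_lines(self):
        # continuous axial density (atoms covering the rise along the axis)
        # projects to a uniform rod with no off-equatorial structure
        rise = 9.33
        sub = SubunitModel(
            atoms=[
                Atom("CA", "C", "GLY", i + 1,
                     np.array([0.0, 0.0, i * rise / 12]))
                for i in range(12)
            ]
        )
        fil = px.build_filament(sub, px.HelicalSymmetry(rise, 92.5), 24)
        img = px.project_model(fil, box=320)
        lines = px.detect_layer_lines(px.power_spectrum(img))
        assert lines == []


@pytest.fixture(scope="module")
def wide_observation():
    sym = px.HelicalSymmetry(9.33, 92.5)
    img, _ = px.make_filament_image(sym, n_subunits=48, seed=4, box=512)
    subunit, _ = px.make_toy_subunit(4, radial_extent=35.0)
    return px.power_spectrum(img), subunit


class TestScoring:
    def test_self_score_near_one(self, wide_observation):
        ps, subunit = wide_observation
        truth = px.LatticeEstimate(36.3, 3.892)
        c = px.score_candidate(ps, truth, subunit, 1.0, 512)
        assert c.score > 0.97

    def test_truth_beats_wrong_candidates(self, wide_observation):
        ps, subunit = wide_observation
        truth = px.score_candidate(ps, px.LatticeEstimate(36.3, 3.892), subunit, 1.0, 512)
        for upt in (3.79, 3.99, 4.10, 4.30):
            wrong = px.score_candidate(
                ps, px.LatticeEstimate(36.3, upt), subunit, 1.0, 512
            )
            assert truth.score > wrong.score

    def test_half_pitch_scores_lower(self, wide_observation):
        ps, subunit = wide_observation
        truth = px.score_candidate(ps, px.LatticeEstimate(36.3, 3.892), subunit, 1.0, 512)
        half = px.score_candidate(ps, px.LatticeEstimate(18.15, 3.892), subunit, 1.0, 512)
        assert truth.score > half.score

    def test_handedness_blind(self, wide_observation):
        # a left-handed filament built from the mirrored subunit projects to
        # the mirror image of the right-handed one, and mirroring an image
        # only flips its amplitude spectrum: amplitudes alone cannot fix the
        # hand of the helix
        ps, subunit = wide_observation
        lat = px.LatticeEstimate(36.3, 3.892)
        sym_r = px.symmetry_from_lattice(lat, handedness=+1)
        sym_l = px.symmetry_from_lattice(lat, handedness=-1)
        from copy import deepcopy

        mirrored = deepcopy(subunit)
        for a in mirrored.atoms:
            a.position[1] *= -1
        img_r = px.project_model(px.build_filament(subunit, sym_r, 24), box=320)
        img_l = px.project_model(px.build_filament(mirrored, sym_l, 24), box=320)
        np.testing.assert_allclose(
            img_l.grid, np.roll(img_r.grid[:, ::-1], 1, axis=1), atol=1e-12
        )
        ps_r = px.power_spectrum(img_r, taper=0.0)
        ps_l = px.power_spectrum(img_l, taper=0.0)
        # column-flip maps frequency +f to -f (first fftshift column has no
        # positive twin at even size, hence the roll)
        np.testing.assert_allclose(
            ps_l.grid, np.roll(ps_r.grid[:, ::-1], 1, axis=1), atol=1e-9
        )


class TestRecoverSymmetry:
    def test_empty_image_list(self, toy_subunit):
        with pytest.raises(ValueError):
            px.recover_symmetry([], toy_subunit)

    def test_pitch_estimate_without_hint(self, wide_sym):
        img, _ = px.make_filament_image(wide_sym, n_subunits=48, seed=6, box=512)
        ps = average_power_spectrum([img])
        pitch, lines = estimate_pitch(ps)
        # one Fourier sample at the pitch frequency
        assert abs(1 / pitch - 1 / wide_sym.pitch) <= 1.0 / 512

    def test_deterministic(self, wide_sym):
        img, _ = px.make_filament_image(
            wide_sym, n_subunits=48, seed=6, box=512, noise_sigma=0.2
        )
        subunit, _ = px.make_toy_subunit(6, radial_extent=35.0)
        kwargs = dict(pitch_hint=36.3, units_range=(3.85, 3.95), step=0.01)
        a = px.recover_symmetry([img], subunit, **kwargs)
        b = px.recover_symmetry([img], subunit, **kwargs)
        assert [(c.lattice.units_per_turn, c.score) for c in a] == [
            (c.lattice.units_per_turn, c.score) for c in b
        ]
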