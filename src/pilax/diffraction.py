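"""Projection images, power spectra and layer-line based symmetry scoring.

A filament model is rendered into a 2D projection image (atoms as Gaussian
blobs summed along the viewing axis, filament axis vertical), Fourier
transformed, and its power spectrum searched for layer lines: rows of
intensity at axial frequency l / repeat-length. The meridional reflection
(intensity at near-zero radial frequency) sits at 1/rise; the order-1 layer
line sits at 1/pitch. Candidate helical symmetries are scored by
correlating the log-amplitude spectrum of a simulated filament against the
observed spectrum, mirroring how simulated and experimental Fourier
transforms are compared during helical reconstruction.

Amplitude spectra are blind to the hand of the helix: a candidate and its
mirror score identically, so only the magnitude of the twist is recovered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .builder import FilamentModel, SubunitModel, build_filament, filament_diameter
from .lattice import (
    HelicalSymmetry,
    LatticeEstimate,
    LayerLine,
    symmetry_from_lattice,
)


@dataclass
class ProjectionImage:
    """2D projection of a filament; axis vertical (along image rows axis 0)."""

    grid: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class PowerSpectrum:
    """Squared amplitudes with zero frequency at the grid centre.

    axial_freq indexes rows (along the filament axis), radial_freq columns.
    """

    grid: np.ndarray
    axial_freq: np.ndarray
    radial_freq: np.ndarray

    @property
    def equator_row(self) -> int:
        return int(np.argmin(np.abs(self.axial_freq)))

    @property
    def meridian_col(self) -> int:
        return int(np.argmin(np.abs(self.radial_freq)))


@dataclass
class CandidateScore:
    lattice: LatticeEstimate
    score: float


def _raised_cosine_window(n: int, taper: float) -> np.ndarray:
    """Tukey window: flat centre with cosine tapers of fractional width *taper*."""
    return signal.windows.tukey(n, alpha=2.0 * taper)


def project_model(
    filament: FilamentModel,
    pixel_size: float = 1.0,
    box: int = 256,
    blur_sigma: float = 1.5,
) -> ProjectionImage:
    """Render a filament as a 2D image of Gaussian atom densities.

    The viewing direction is x; each atom contributes a unit-integral 2D
    Gaussian of width *blur_sigma* (Å) at its (y, z) position. The filament
    axis (z) runs along image rows (vertical); the image is centred on the
    filament's bounding box.
    """
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    coords = filament.coords
    y, z = coords[:, 1], coords[:, 2]
    cy, cz = (y.min() + y.max()) / 2.0, (z.min() + z.max()) / 2.0
    half = box * pixel_size / 2.0
    pad = 4.0 * blur_sigma + 2.0 * pixel_size
    if (np.abs(y - cy).max() + pad > half) or (np.abs(z - cz).max() + pad > half):
        raise ValueError(
            "filament does not fit in the box; increase box or pixel_size"
        )
    img = np.zeros((box, box))
    # Stamp each Gaussian on a local patch; box-scale separable evaluation
    # would be slower for sparse atoms.
    r = max(1, int(math.ceil(4.0 * blur_sigma / pixel_size)))
    offsets = np.arange(-r, r + 1)
    for yi, zi in zip(y, z):
        col_f = (yi - cy) / pixel_size + box / 2.0
        row_f = (zi - cz) / pixel_size + box / 2.0
        row0, col0 = int(round(row_f)), int(round(col_f))
        rows = row0 + offsets
        cols = col0 + offsets
        gz = np.exp(-0.5 * ((rows - row_f) * pixel_size / blur_sigma) ** 2)
        gy = np.exp(-0.5 * ((cols - col_f) * pixel_size / blur_sigma) ** 2)
        norm = pixel_size**2 / (2.0 * math.pi * blur_sigma**2)
        img[np.ix_(rows, cols)] += norm * np.outer(gz, gy)
    return ProjectionImage(grid=img, pixel_size=pixel_size)


def power_spectrum(image: ProjectionImage, taper: float = 0.1) -> PowerSpectrum:
    """Windowed 2D power spectrum, zero frequency centred.

    A raised-cosine (Tukey) taper suppresses box-edge ringing. The unitary
    FFT normalisation makes the total spectral energy equal the windowed
    image energy (Parseval).
    """
    grid = image.grid
    if grid.size == 0:
        raise ValueError("empty image")
    win = np.outer(
        _raised_cosine_window(grid.shape[0], taper),
        _raised_cosine_window(grid.shape[1], taper),
    )
    ft = np.fft.fftshift(np.fft.fft2(grid * win, norm="ortho"))
    ps = np.abs(ft) ** 2
    axial = np.fft.fftshift(np.fft.fftfreq(grid.shape[0], d=image.pixel_size))
    radial = np.fft.fftshift(np.fft.fftfreq(grid.shape[1], d=image.pixel_size))
    return PowerSpectrum(grid=ps, axial_freq=axial, radial_freq=radial)


def _refine_peak(profile: np.ndarray, idx: int) -> float:
    """Sub-sample peak position by quadratic interpolation of log amplitude."""
    if idx <= 0 or idx >= len(profile) - 1:
        return float(idx)
    y0, y1, y2 = np.log(profile[idx - 1 : idx + 2] + 1e-300)
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(idx)
    return idx + 0.5 * (y0 - y2) / denom


def detect_layer_lines(
    ps: PowerSpectrum,
    min_prominence: float = 0.1,
    meridian_tolerance: int = 2,
) -> List[LayerLine]:
    """Find layer lines as peaks of the per-row maximum amplitude profile.

    The equator is excluded; a line is flagged meridional when its peak
    amplitude lies within *meridian_tolerance* columns of zero radial
    frequency. Returns lines sorted by axial spacing, largest first.
    """
    eq = ps.equator_row
    n_rows = ps.grid.shape[0]
    rows = np.arange(eq + 1, n_rows)  # positive axial frequencies
    if len(rows) < 3:
        return []
    profile = ps.grid[rows].max(axis=1)
    global_max = profile.max()
    if global_max <= 0:
        return []
    peaks, _ = signal.find_peaks(profile, prominence=min_prominence * global_max)
    lines: List[LayerLine] = []
    df = ps.axial_freq[1] - ps.axial_freq[0]
    for p in peaks:
        row_sub = _refine_peak(profile, p) + rows[0]
        freq = ps.axial_freq[rows[0]] + (row_sub - rows[0]) * df
        if freq <= 0:
            continue
        lo = max(rows[0] + p - 1, rows[0])
        hi = min(rows[0] + p + 2, n_rows)
        block = ps.grid[lo:hi]
        peak_col = int(np.unravel_index(np.argmax(block), block.shape)[1])
        meridional = abs(peak_col - ps.meridian_col) <= meridian_tolerance
        lines.append(
            LayerLine(
                axial_spacing=1.0 / freq,
                is_meridional=meridional,
                amplitude=float(profile[p]),
            )
        )
    lines.sort(key=lambda L: -L.axial_spacing)
    return lines


@dataclass
class ScoreSettings:
    """Geometry and masking used when scoring symmetry candidates."""

    n_subunits: int = 48
    blur_sigma: float = 1.5
    taper: float = 0.1
    min_radial_freq: Optional[float] = None  # default 1/diameter
    max_freq: Optional[float] = None


def _log_amp(ps: PowerSpectrum) -> np.ndarray:
    return np.log1p(np.sqrt(ps.grid))


def _annulus_mask(
    ps: PowerSpectrum, min_radial: float, max_freq: Optional[float]
) -> np.ndarray:
    ax = ps.axial_freq[:, None]
    ra = ps.radial_freq[None, :]
    mask = (np.abs(ra) >= min_radial) & (np.abs(ax) > 0)  # no equator row
    if max_freq is not None:
        mask = mask & (np.sqrt(ax**2 + ra**2) <= max_freq)
    return mask


def score_candidate(
    observed: PowerSpectrum,
    lattice: LatticeEstimate,
    subunit: SubunitModel,
    pixel_size: float,
    box: int,
    settings: ScoreSettings = ScoreSettings(),
) -> CandidateScore:
    """Correlate the observed spectrum with one simulated from a candidate.

    Builds a filament with the candidate's rise/twist, projects it with the
    observed geometry, and returns the Pearson correlation of log(1 +
    amplitude) over an annulus that excludes the equator and radial
    frequencies below 1/diameter (where the equatorial envelope dominates).
    """
    if observed.grid.shape != (box, box):
        raise ValueError(
            f"observed spectrum shape {observed.grid.shape} does not match box {box}"
        )
    sym = symmetry_from_lattice(lattice)
    coords = subunit.coords
    zspan = float(coords[:, 2].max() - coords[:, 2].min())
    avail = box * pixel_size - 2 * (4 * settings.blur_sigma + 2 * pixel_size) - 2
    n_fit = max(2, int((avail - zspan) / sym.rise) + 1)
    n = min(settings.n_subunits, n_fit)
    filament = build_filament(subunit, sym, n)
    img = project_model(filament, pixel_size=pixel_size, box=box,
                        blur_sigma=settings.blur_sigma)
    sim = power_spectrum(img, taper=settings.taper)
    min_radial = settings.min_radial_freq
    if min_radial is None:
        min_radial = 1.0 / filament_diameter(filament)
    mask = _annulus_mask(observed, min_radial, settings.max_freq)
    a = _log_amp(observed)[mask]
    b = _log_amp(sim)[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    score = float(a @ b / denom) if denom > 0 else 0.0
    return CandidateScore(lattice=lattice, score=score)


def average_power_spectrum(
    images: Sequence[ProjectionImage], taper: float = 0.1
) -> PowerSpectrum:
    """Arithmetic mean of the power spectra of several images."""
    if not images:
        raise ValueError("need at least one image")
    spectra = [power_spectrum(im, taper=taper) for im in images]
    shape = spectra[0].grid.shape
    if any(s.grid.shape != shape for s in spectra):
        raise ValueError("all images must share the same box size")
    mean_grid = np.mean([s.grid for s in spectra], axis=0)
    return PowerSpectrum(
        grid=mean_grid,
        axial_freq=spectra[0].axial_freq,
        radial_freq=spectra[0].radial_freq,
    )


def estimate_pitch(
    ps: PowerSpectrum, min_prominence: float = 0.1
) -> Tuple[float, List[LayerLine]]:
    """Pitch estimate from the strongest off-meridional layer line.

    The order-1 line (at 1/pitch) dominates the low-resolution layer lines
    of a 1-start helix; weaker higher-order Bessel lines can appear at even
    larger spacings when the exact repeat is long, so the strongest
    off-meridional line — not the largest-spacing one — estimates the pitch.
    """
    lines = detect_layer_lines(ps, min_prominence=min_prominence)
    if not lines:
        raise ValueError("no layer lines detected; supply a pitch hint")
    off_meridional = [L for L in lines if not L.is_meridional]
    pool = off_meridional if off_meridional else lines
    chosen = max(pool, key=lambda L: L.amplitude)
    return chosen.axial_spacing, lines


def recover_symmetry(
    images: Sequence[ProjectionImage],
    subunit: SubunitModel,
    pitch_hint: Optional[float] = None,
    units_range: Tuple[float, float] = (3.5, 4.5),
    step: float = 0.01,
    settings: ScoreSettings = ScoreSettings(),
) -> List[CandidateScore]:
    """Full symmetry determination pipeline on a set of filament images.

    Averages the power spectra, reads the pitch off the order-1 layer line
    (or takes the supplied hint), enumerates a grid of subunits-per-turn
    candidates at that pitch, scores each against the averaged spectrum and
    returns the candidates ranked best-first. Deterministic given inputs.
    """
    if not images:
        raise ValueError("need at least one image")
    from .lattice import enumerate_symmetry_candidates

    ps = average_power_spectrum(images, taper=settings.taper)
    if pitch_hint is not None:
        pitch = pitch_hint
    else:
        pitch, _ = estimate_pitch(ps)
    box = images[0].grid.shape[0]
    pixel = images[0].pixel_size
    candidates = enumerate_symmetry_candidates(pitch, units_range, step)
    scores = [
        score_candidate(ps, cand, subunit, pixel, box, settings)
        for cand in candidates
    ]
    scores.sort(key=lambda c: -c.score)
    return scores
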