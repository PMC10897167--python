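"""Detector geometry, calibration, and reduction of 2-D frames to 1-D profiles.

A scattering frame records photon counts on a flat area detector a distance
``L`` behind the specimen.  A periodic structure with repeat distance ``d``
produces a Debye-Scherrer ring at scattering angle ``2theta`` with
``sin(theta) = lambda / (2 d)``, i.e. at radius ``r = L tan(2theta)`` from the
beam center and at momentum transfer ``q = 4 pi sin(theta) / lambda = 2 pi / d``.
The exact ``2theta`` geometry is used throughout (no small-angle
approximation), so the same code serves the small-angle (collagen, ~67 nm)
and wide-angle (hydroxyapatite (002), ~3.44 A) regimes.

Azimuth ``chi`` is measured in degrees, counterclockwise from the detector +x
axis (with +y pointing up, i.e. against the row index), in ``[-180, 180)``.
The tensile axis is assumed along ``chi = 0`` unless stated otherwise.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, signal

__all__ = [
    "HC_KEV_A",
    "DetectorFrame",
    "Geometry",
    "RadialProfile",
    "AzimuthalProfile",
    "energy_to_wavelength",
    "find_beam_center",
    "calibrate_distance",
    "integrate_radial",
    "integrate_azimuthal",
]

#: Planck constant times speed of light, keV * Angstrom.
HC_KEV_A = 12.39842


def energy_to_wavelength(energy_kev: float) -> float:
    """X-ray wavelength in Angstrom for a photon energy in keV.

    ``lambda = hc / E`` with ``hc = 12.39842 keV A``; 10 keV -> 1.2398 A.
    """
    if not energy_kev > 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_A / energy_kev


@dataclass
class DetectorFrame:
    """One exposure: a 2-D grid of photon counts plus acquisition metadata."""

    data: np.ndarray
    time_s: float = 0.0
    exposure_s: float = 0.5
    dose_kgy: float = 0.0  # dose increment delivered by this exposure
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("frame data must be a 2-D array")


def _frame_data(frame) -> np.ndarray:
    return frame.data if isinstance(frame, DetectorFrame) else np.asarray(frame)


@dataclass(frozen=True)
class Geometry:
    """Calibrated scattering geometry of a flat detector.

    beam_center_xy : (x, y) pixel coordinates of the direct beam, 0-based,
        x along columns, y along rows, origin at the top-left pixel center.
    distance_mm : sample-to-detector distance L.
    wavelength_a : X-ray wavelength in Angstrom.
    pixel_size_um : square pixel pitch.
    detector_shape : (rows, cols).  Default is a Pilatus-class 2M grid.
    """

    beam_center_xy: tuple[float, float]
    distance_mm: float
    wavelength_a: float
    pixel_size_um: float = 172.0
    detector_shape: tuple[int, int] = (1679, 1475)

    def __post_init__(self) -> None:
        object.__setattr__(self, "beam_center_xy", tuple(float(v) for v in self.beam_center_xy))
        object.__setattr__(self, "detector_shape", tuple(int(v) for v in self.detector_shape))
        if not self.distance_mm > 0:
            raise ValueError("sample-detector distance must be positive")
        if not self.wavelength_a > 0:
            raise ValueError("wavelength must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel size must be positive")
        rows, cols = self.detector_shape
        cx, cy = self.beam_center_xy
        if not (-0.5 * cols <= cx <= 1.5 * cols and -0.5 * rows <= cy <= 1.5 * rows):
            raise ValueError(f"beam center {self.beam_center_xy} is far outside the frame bounds")

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um * 1e-3

    def ring_radius_mm(self, d_spacing_a: float) -> float:
        """Radius of the Debye-Scherrer ring for repeat distance d (A)."""
        s = self.wavelength_a / (2.0 * d_spacing_a)
        if s >= 1.0:
            raise ValueError(f"d={d_spacing_a} A is below lambda/2; no Bragg condition")
        return self.distance_mm * np.tan(2.0 * np.arcsin(s))

    def q_of_radius(self, r_mm):
        """Momentum transfer (1/A) at radial distance r (mm) from the center."""
        two_theta = np.arctan(np.asarray(r_mm, dtype=float) / self.distance_mm)
        return 4.0 * np.pi / self.wavelength_a * np.sin(0.5 * two_theta)

    def max_radius_mm(self) -> float:
        """Distance from the beam center to the farthest detector corner."""
        rows, cols = self.detector_shape
        cx, cy = self.beam_center_xy
        dx = max(abs(0 - cx), abs(cols - 1 - cx))
        dy = max(abs(0 - cy), abs(rows - 1 - cy))
        return float(np.hypot(dx, dy)) * self.pixel_size_mm


@functools.lru_cache(maxsize=8)
def _pixel_maps(geometry: Geometry):
    """Per-pixel (q [1/A], chi [deg], r [mm]) maps, cached per geometry."""
    rows, cols = geometry.detector_shape
    cx, cy = geometry.beam_center_xy
    x = (np.arange(cols, dtype=np.float64) - cx)[None, :]
    y_down = (np.arange(rows, dtype=np.float64) - cy)[:, None]
    r_mm = np.hypot(x, y_down) * geometry.pixel_size_mm
    q = geometry.q_of_radius(r_mm)
    # +chi counterclockwise from +x with +y pointing up (row index increases down)
    chi = np.degrees(np.arctan2(-y_down, x))
    chi[chi >= 180.0] -= 360.0
    return q, chi, r_mm


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity vs momentum transfer.

    Bins with no contributing pixels carry ``intensity = nan`` (flagged, never
    zero-filled).  ``sum(intensity * n_pixels)`` over populated bins equals the
    summed counts of the selected pixels.
    """

    q: np.ndarray  # bin centers, 1/A, strictly increasing
    intensity: np.ndarray  # mean counts per pixel in bin
    n_pixels: np.ndarray
    chi_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        populated = self.n_pixels > 0
        if np.any(self.intensity[populated] < 0):
            raise ValueError("negative mean intensity in a populated bin")


@dataclass
class AzimuthalProfile:
    """Mean intensity vs azimuth chi within a q band."""

    chi: np.ndarray  # bin centers, degrees in [-180, 180), strictly increasing
    intensity: np.ndarray
    n_pixels: np.ndarray
    q_band: tuple[float, float]

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels)
        if np.any(np.diff(self.chi) <= 0):
            raise ValueError("chi grid must be strictly increasing")
        lo, hi = self.q_band
        if not lo < hi:
            raise ValueError("q band must have q_lo < q_hi")


def _ring_pixels(data: np.ndarray, min_pixels: int = 50):
    """Bright pixels likely to belong to rings, with weights; error if none."""
    flat = data.ravel()
    background = float(np.median(flat))
    # Poisson-scale contrast test: a ring must rise well above counting noise
    threshold = background + 6.0 * np.sqrt(background + 1.0)
    mask = data > threshold
    if mask.sum() < min_pixels:
        raise ValueError("no ring detected: frame lacks pixels above background")
    ys, xs = np.nonzero(mask)
    weights = data[ys, xs].astype(float) - background
    return xs.astype(float), ys.astype(float), weights


def find_beam_center(
    frame,
    initial_guess: tuple[float, float] | None = None,
    refine_tol: float = 1e-3,
) -> tuple[float, float]:
    """Locate the direct-beam position from ring curvature, to sub-pixel.

    Bright ring pixels are grouped into rings by their radius histogram at the
    initial guess; the center is then the point minimizing the weighted radial
    variance within each ring (rings are circles, so the spread of radii is
    minimal at the true center).  Returns (x, y) in pixels.
    """
    data = _frame_data(frame).astype(float)
    if initial_guess is None:
        initial_guess = ((data.shape[1] - 1) / 2.0, (data.shape[0] - 1) / 2.0)
    xs, ys, w = _ring_pixels(data)

    def ring_labels(center):
        r = np.hypot(xs - center[0], ys - center[1])
        hist, edges = np.histogram(r, bins=np.arange(0.0, r.max() + 2.0), weights=w)
        peaks, _ = signal.find_peaks(hist, height=hist.max() * 0.05, distance=8)
        if len(peaks) == 0:
            raise ValueError("no ring detected: radius histogram has no peak")
        radii = 0.5 * (edges[peaks] + edges[peaks + 1])
        labels = np.argmin(np.abs(r[:, None] - radii[None, :]), axis=1)
        keep = np.abs(r - radii[labels]) < 15.0
        return labels, keep

    center = np.asarray(initial_guess, dtype=float)
    for _ in range(2):  # label, refine, relabel once at the improved center
        labels, keep = ring_labels(center)
        lx, ly, lw, ll = xs[keep], ys[keep], w[keep], labels[keep]

        def objective(c):
            r = np.hypot(lx - c[0], ly - c[1])
            total = 0.0
            for k in np.unique(ll):
                sel = ll == k
                wk = lw[sel]
                rk = r[sel]
                mean = np.average(rk, weights=wk)
                total += float(np.sum(wk * (rk - mean) ** 2))
            return total

        res = optimize.minimize(
            objective, center, method="Nelder-Mead",
            options={"xatol": refine_tol, "fatol": 1e-9, "maxiter": 400},
        )
        center = res.x
    return float(center[0]), float(center[1])


def _radial_peak_mm(data: np.ndarray, center, pixel_size_mm: float):
    """Sub-pixel radii (mm) of ring peaks in the radial intensity profile."""
    xs, ys, w = _ring_pixels(data)
    r_px = np.hypot(xs - center[0], ys - center[1])
    bins = np.arange(0.0, r_px.max() + 2.0)
    hist, edges = np.histogram(r_px, bins=bins, weights=w)
    npx, _ = np.histogram(r_px, bins=bins)
    profile = np.where(npx > 0, hist / np.maximum(npx, 1), 0.0)
    peaks, _ = signal.find_peaks(profile, height=profile.max() * 0.1, distance=8)
    if len(peaks) == 0:
        raise ValueError("ring not found in radial profile")
    centers_px = 0.5 * (edges[:-1] + edges[1:])
    refined = []
    for p in peaks:
        lo, hi = max(p - 6, 0), min(p + 7, len(profile))
        sel = npx[lo:hi] > 0
        x, yv = centers_px[lo:hi][sel], profile[lo:hi][sel]
        refined.append(float(np.average(x, weights=yv)))  # intensity centroid
    return np.array(sorted(refined)) * pixel_size_mm


def calibrate_distance(
    frame,
    center: tuple[float, float],
    wavelength_a: float,
    known_d: float,
    pixel_size_um: float = 172.0,
) -> Geometry:
    """Fit the sample-detector distance from a calibrant ring of known d.

    The innermost ring in the radial profile is taken as the first-order
    reflection of the calibrant (silver behenate d(001) = 58.38 A by
    convention); ``L = r / tan(2 theta)`` with ``sin(theta) = lambda / (2 d)``.
    """
    data = _frame_data(frame)
    s = wavelength_a / (2.0 * known_d)
    if s >= 1.0:
        raise ValueError(f"known_d={known_d} A gives no Bragg reflection at this wavelength")
    radii_mm = _radial_peak_mm(data, center, pixel_size_um * 1e-3)
    r_ring = radii_mm[0]
    distance = float(r_ring / np.tan(2.0 * np.arcsin(s)))
    return Geometry(
        beam_center_xy=tuple(center),
        distance_mm=distance,
        wavelength_a=wavelength_a,
        pixel_size_um=pixel_size_um,
        detector_shape=data.shape,
    )


def _chi_mask(chi_map: np.ndarray, chi_range: tuple[float, float], mirror: bool) -> np.ndarray:
    lo, hi = float(chi_range[0]), float(chi_range[1])
    if hi <= lo:
        raise ValueError(f"empty chi range {chi_range}")
    # membership via signed angular distance from the sector midpoint (wrap-safe)
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    delta = (chi_map - mid + 180.0) % 360.0 - 180.0
    mask = np.abs(delta) <= half
    if mirror:
        delta_op = (chi_map - (mid + 180.0) + 180.0) % 360.0 - 180.0
        mask |= np.abs(delta_op) <= half
    return mask


def integrate_radial(
    frame,
    geometry: Geometry,
    chi_range: tuple[float, float] = (-180.0, 180.0),
    q_range: tuple[float, float] | None = None,
    n_bins: int = 800,
    mirror: bool = False,
    mask: np.ndarray | None = None,
) -> RadialProfile:
    """Cake-integrate a frame onto a linear q grid within an azimuthal sector.

    Each unmasked pixel is point-sampled at its center, mapped to (q, chi),
    and averaged into its q bin; ``mirror=True`` additionally includes the
    sector rotated by 180 deg (both ends of a diameter).
    """
    data = _frame_data(frame)
    if data.shape != geometry.detector_shape:
        raise ValueError("frame shape does not match geometry.detector_shape")
    q_map, chi_map, _ = _pixel_maps(geometry)
    sel = _chi_mask(chi_map, chi_range, mirror)
    if mask is not None:
        sel &= ~np.asarray(mask, dtype=bool)
    q_sel = q_map[sel]
    counts = data[sel].astype(np.float64)
    if q_range is None:
        q_lo, q_hi = float(q_sel.min()), float(q_sel.max()) * (1 + 1e-12)
    else:
        q_lo, q_hi = map(float, q_range)
        if not q_lo < q_hi:
            raise ValueError("q_range must have q_lo < q_hi")
    width = (q_hi - q_lo) / n_bins
    idx = np.floor((q_sel - q_lo) / width).astype(np.int64)
    inside = (idx >= 0) & (idx <= n_bins)
    idx = np.where(idx == n_bins, n_bins - 1, idx)[inside]  # close the top edge
    n_pixels = np.bincount(idx, minlength=n_bins)
    totals = np.bincount(idx, weights=counts[inside], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        intensity = np.where(n_pixels > 0, totals / np.maximum(n_pixels, 1), np.nan)
    centers = q_lo + (np.arange(n_bins) + 0.5) * width
    return RadialProfile(centers, intensity, n_pixels, (float(chi_range[0]), float(chi_range[1])))


def integrate_azimuthal(
    frame,
    geometry: Geometry,
    q_band: tuple[float, float],
    chi_bins: int = 360,
    mask: np.ndarray | None = None,
) -> AzimuthalProfile:
    """Average pixels with q in [q_lo, q_hi] into chi bins over [-180, 180)."""
    data = _frame_data(frame)
    if data.shape != geometry.detector_shape:
        raise ValueError("frame shape does not match geometry.detector_shape")
    q_lo, q_hi = map(float, q_band)
    if not q_lo < q_hi:
        raise ValueError("q band must have q_lo < q_hi")
    q_map, chi_map, _ = _pixel_maps(geometry)
    q_max_cover = float(geometry.q_of_radius(geometry.max_radius_mm()))
    if q_lo >= q_max_cover:
        raise ValueError(
            f"q band {q_band} lies outside detector coverage (q_max={q_max_cover:.4g})"
        )
    sel = (q_map >= q_lo) & (q_map <= q_hi)
    if mask is not None:
        sel &= ~np.asarray(mask, dtype=bool)
    if not sel.any():
        raise ValueError(f"no pixels fall inside q band {q_band}")
    chi_sel = chi_map[sel]
    counts = data[sel].astype(np.float64)
    width = 360.0 / chi_bins
    idx = np.floor((chi_sel + 180.0) / width).astype(np.int64)
    idx = np.clip(idx, 0, chi_bins - 1)
    n_pixels = np.bincount(idx, minlength=chi_bins)
    totals = np.bincount(idx, weights=counts, minlength=chi_bins)
    with np.errstate(invalid="ignore"):
        intensity = np.where(n_pixels > 0, totals / np.maximum(n_pixels, 1), np.nan)
    centers = -180.0 + (np.arange(chi_bins) + 0.5) * width
    return AzimuthalProfile(centers, intensity, n_pixels, (q_lo, q_hi))
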