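"""Bragg-peak fitting, d-spacing strain, and the P2 orientation parameter.

Material strain is the fractional change of a Bragg periodicity relative to
its unloaded reference: ``eps = (d - d0) / d0`` with ``d = 2 pi / q``.  The
collagen phase uses the first-order ~67 nm axial reflection (SAXS); the
mineral phase uses the hydroxyapatite (002) lattice reflection (WAXD).

Fibril/crystallite alignment is summarized by the second Legendre orientation
parameter of the azimuthal intensity,

    P2 = < (3 cos^2 chi - 1) / 2 >_{I(chi) sin chi},

the sin(chi)-weighted, intensity-weighted average with chi measured from the
tensile axis.  P2 = 1 for perfect axial alignment, 0 for isotropy, -0.5 for
fully transverse orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .geometry import AzimuthalProfile, RadialProfile

__all__ = [
    "PeakFit",
    "StrainSeries",
    "OrientationSeries",
    "fit_peak",
    "d_from_q",
    "strain_series",
    "p2_orientation",
    "delta_p2",
]


@dataclass
class PeakFit:
    """One fitted Bragg peak: position +/- SE, shape, and convergence flag."""

    q_center: float
    q_center_se: float
    width: float  # Gaussian sigma or Lorentzian HWHM, 1/A
    amplitude: float
    background: tuple[float, float]  # (slope, intercept)
    r_squared: float
    converged: bool
    window: tuple[float, float]
    model: str = "gaussian"


def _gaussian(q, center, sigma, amp, slope, intercept):
    return amp * np.exp(-0.5 * ((q - center) / sigma) ** 2) + slope * q + intercept


def _lorentzian(q, center, gamma, amp, slope, intercept):
    return amp / (1.0 + ((q - center) / gamma) ** 2) + slope * q + intercept


_MODELS = {"gaussian": _gaussian, "lorentzian": _lorentzian}


def fit_peak(
    profile: RadialProfile,
    window: tuple[float, float],
    model: str = "gaussian",
    min_bins: int = 8,
) -> PeakFit:
    """Nonlinear least squares of peak + linear background inside a q window.

    A failed or degenerate fit is reported with ``converged=False`` (never an
    exception); too few populated bins or a window outside the profile raise.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown peak model {model!r}")
    lo, hi = map(float, window)
    if hi <= lo:
        raise ValueError("fit window must have q_lo < q_hi")
    if hi < profile.q[0] or lo > profile.q[-1]:
        raise ValueError(f"window {window} lies outside the profile q range")
    sel = (profile.q >= lo) & (profile.q <= hi) & (profile.n_pixels > 0)
    sel &= np.isfinite(profile.intensity)
    q = profile.q[sel]
    y = profile.intensity[sel]
    if q.size < min_bins:
        raise ValueError(f"only {q.size} populated bins in window; need >= {min_bins}")

    edge = max(2, q.size // 10)
    bg0 = 0.5 * (y[:edge].mean() + y[-edge:].mean())
    amp0 = float(y.max() - bg0)
    center0 = float(q[np.argmax(y)])
    width0 = max((hi - lo) / 10.0, float(np.diff(q).mean()))
    p0 = [center0, width0, max(amp0, 1e-12), 0.0, bg0]

    failed = PeakFit(center0, np.nan, np.nan, np.nan, (np.nan, np.nan),
                     0.0, False, (lo, hi), model)
    try:
        popt, pcov = optimize.curve_fit(
            _MODELS[model], q, y, p0=p0,
            bounds=([lo, 1e-12 * (hi - lo), 0.0, -np.inf, -np.inf],
                    [hi, (hi - lo), np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return failed
    center, width, amp, slope, intercept = popt
    residuals = y - _MODELS[model](q, *popt)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    amp_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    converged = bool(
        np.isfinite(se) and se > 0 and amp > 2.0 * amp_se
        and amp > 1e-6 * max(float(np.abs(y).max()), 1e-300)  # not a null fit
        and lo < center < hi
    )
    return PeakFit(float(center), se, float(width), float(amp),
                   (float(slope), float(intercept)), r2, converged, (lo, hi), model)


def d_from_q(q):
    """Bragg relation ``d = 2 pi / q`` (A from 1/A); q must be positive."""
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr <= 0):
        raise ValueError("q must be positive to convert to a d-spacing")
    d = 2.0 * np.pi / q_arr
    return float(d) if np.isscalar(q) else d


@dataclass
class StrainSeries:
    """Per-frame material strain for one phase of one specimen.

    Frames whose peak fit did not converge carry ``nan`` strain; they are
    flagged, never silently interpolated.
    """

    time_s: np.ndarray
    material_strain: np.ndarray
    phase: str  # "collagen" | "mineral"
    d0: float
    reference_policy: str

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.material_strain = np.asarray(self.material_strain, dtype=float)
        if self.time_s.shape != self.material_strain.shape:
            raise ValueError("time and strain must have equal lengths")
        if self.phase not in ("collagen", "mineral"):
            raise ValueError(f"phase must be 'collagen' or 'mineral', got {self.phase!r}")


def strain_series(
    peaks: Sequence[PeakFit],
    times: Sequence[float],
    phase: str,
    n_reference: int = 5,
) -> StrainSeries:
    """Convert per-frame peak positions to strain against a preload reference.

    ``d0`` is the mean d-spacing over the first ``n_reference`` frames (the
    frames acquired before load is applied); ``eps_i = (d_i - d0) / d0``.
    """
    if n_reference < 1:
        raise ValueError("at least one preload reference frame is required")
    if len(peaks) != len(times):
        raise ValueError("peaks and times must have equal lengths")
    if len(peaks) < n_reference:
        raise ValueError("fewer frames than requested reference frames")
    d = np.array([d_from_q(p.q_center) if p.converged else np.nan for p in peaks])
    d_ref = d[:n_reference]
    if np.all(np.isnan(d_ref)):
        raise ValueError("no converged peak fit among the preload reference frames")
    d0 = float(np.nanmean(d_ref))
    eps = (d - d0) / d0
    return StrainSeries(np.asarray(times, float), eps, phase, d0,
                        reference_policy=f"first_n_preload({n_reference})")


@dataclass
class OrientationSeries:
    """Per-frame P2 orientation parameter."""

    time_s: np.ndarray
    p2: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        finite = self.p2[np.isfinite(self.p2)]
        if np.any(finite < -0.5 - 1e-9) or np.any(finite > 1.0 + 1e-9):
            raise ValueError("P2 values must lie in [-0.5, 1]")


def _fold_integrals(theta_lo: float, theta_hi: float) -> tuple[float, float]:
    """Exact integrals of |sin t| and |sin t| cos^2 t over [theta_lo, theta_hi].

    Antiderivatives on [0, pi]: W(x) = 1 - cos x and S(x) = (1 - cos^3 x)/3;
    both extend to the whole line by even reflection at 0 and periodic
    continuation of |sin| (kinks at multiples of pi).
    """

    def cumulative(x: float, anti) -> float:
        sign = 1.0
        if x < 0:
            x, sign = -x, -1.0
        n, rem = divmod(x, np.pi)
        return sign * (n * anti(np.pi) + anti(rem))

    w_anti = lambda x: 1.0 - np.cos(x)
    s_anti = lambda x: (1.0 - np.cos(x) ** 3) / 3.0
    return (
        cumulative(theta_hi, w_anti) - cumulative(theta_lo, w_anti),
        cumulative(theta_hi, s_anti) - cumulative(theta_lo, s_anti),
    )


def p2_orientation(profile: AzimuthalProfile, axis_deg: float = 0.0) -> float:
    """Second Legendre orientation parameter of an azimuthal profile.

    The intensity is treated as piecewise constant over each chi bin and the
    sin-weighted Legendre average is integrated bin-by-bin in closed form, so
    a uniform profile returns exactly 0 and any nonnegative profile stays in
    [-0.5, 1].  Requires at least 180 deg of azimuthal coverage.
    """
    chi = profile.chi
    good = np.isfinite(profile.intensity) & (profile.n_pixels > 0)
    intensity = np.where(good, profile.intensity, 0.0)
    if np.any(intensity < 0):
        raise ValueError("azimuthal intensity must be nonnegative for P2")
    if intensity.sum() <= 0:
        raise ValueError("all-zero azimuthal intensity; P2 undefined")
    span = chi[-1] - chi[0] + (chi[1] - chi[0])
    if span < 180.0 - 1e-9:
        raise ValueError("P2 requires at least 180 deg of azimuthal coverage")
    half = 0.5 * float(np.mean(np.diff(chi)))
    w_sum = 0.0
    s_sum = 0.0
    for c, i_k in zip(chi, intensity):
        if i_k == 0.0:
            continue
        theta = np.radians(c - axis_deg)
        w, s = _fold_integrals(theta - np.radians(half), theta + np.radians(half))
        w_sum += i_k * w
        s_sum += i_k * s
    cos2 = s_sum / w_sum
    return float((3.0 * cos2 - 1.0) / 2.0)


class SlopeEstimate(NamedTuple):
    slope: float
    se: float


def delta_p2(series: OrientationSeries, tissue_strain: Sequence[float]) -> SlopeEstimate:
    """OLS slope of P2 on tissue strain: the realignment rate under load.

    A positive slope means the phase reorients toward the tensile axis as the
    tissue is stretched; failure to realign (slope ~ 0) suggests inter-fibril
    sliding instead of fibril stretching.
    """
    eps = np.asarray(tissue_strain, dtype=float)
    good = np.isfinite(series.p2) & np.isfinite(eps)
    if good.sum() < 3:
        raise ValueError("need at least 3 paired (P2, tissue strain) points")
    res = stats.linregress(eps[good], series.p2[good])
    return SlopeEstimate(float(res.slope), float(res.stderr))
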