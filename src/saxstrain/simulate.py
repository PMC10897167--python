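"""Synthetic data with known ground truth for every stage of the pipeline.

The generator emulates an in situ tensile test at a synchrotron SAXS/WAXD
beamline: ring-shaped scattering patterns whose d-spacings track the applied
tissue strain through programmable coupling slopes, a 0.5 s exposure every
5 s at 10 keV with a 30 kGy cumulative dose cap, optical marker tables that
encode the bulk tissue strain analytically, three-point-bend load-displacement
curves with programmable stiffness/yield/post-yield behavior, and balanced
factorial outcome tables for the group statistics.

Counting noise is Poisson on the expected per-pixel intensity.  Rings have a
Gaussian radial profile in q and an azimuthal intensity ``I(chi) proportional
to exp(kappa cos 2 chi)``; ``kappa`` is solved numerically so that the
sin-weighted second Legendre orientation parameter P2 of the pattern equals
the programmed value.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import DetectorFrame, Geometry, _pixel_maps

__all__ = [
    "AGBE_D001",
    "DOSE_CAP_KGY",
    "TensileTruth",
    "ExperimentBundle",
    "LoadDisplacementCurve",
    "kappa_for_p2",
    "p2_of_kappa",
    "simulate_calibrant_frame",
    "simulate_tensile_experiment",
    "simulate_load_displacement",
    "simulate_group_outcomes",
    "default_saxs_geometry",
    "default_waxd_geometry",
]

#: Silver behenate first-order d-spacing (A); the standard SAXS calibrant.
AGBE_D001 = 58.38
#: Cumulative radiation dose cap (kGy) that terminates X-ray acquisition.
DOSE_CAP_KGY = 30.0

_LEG_U, _LEG_W = np.polynomial.legendre.leggauss(400)


def p2_of_kappa(kappa: float) -> float:
    """P2 orientation parameter of the azimuthal model I ~ exp(kappa cos 2chi).

    With u = cos(chi): P2(kappa) = <(3u^2-1)/2> under the weight
    exp(kappa (2u^2 - 1)) on u in [-1, 1] (the sin(chi)-weighted average).
    Limits: kappa -> +inf gives 1 (axial), -inf gives -0.5 (transverse).
    """
    f = np.exp(kappa * (2.0 * _LEG_U**2 - 1.0) - abs(kappa))
    num = float(np.sum(_LEG_W * f * (3.0 * _LEG_U**2 - 1.0) / 2.0))
    den = float(np.sum(_LEG_W * f))
    return num / den


def kappa_for_p2(p2: float) -> float:
    """Solve exp(kappa cos 2chi) concentration parameter for a target P2."""
    if not -0.5 < p2 < 1.0:
        raise ValueError(f"target P2 must lie in (-0.5, 1), got {p2}")
    if abs(p2) < 1e-12:
        return 0.0
    return brentq(lambda k: p2_of_kappa(k) - p2, -80.0, 80.0, xtol=1e-10)


def default_saxs_geometry(
    beam_center_xy: tuple[float, float] = (737.0, 839.0),
    distance_mm: float = 4000.0,
    wavelength_a: float = 1.239842,
) -> Geometry:
    """Pilatus-class geometry resolving the collagen 67 nm reflection."""
    return Geometry(beam_center_xy, distance_mm, wavelength_a)


def default_waxd_geometry(
    beam_center_xy: tuple[float, float] = (737.0, 839.0),
    distance_mm: float = 200.0,
    wavelength_a: float = 1.239842,
) -> Geometry:
    """Short-distance geometry resolving the hydroxyapatite (002) ring."""
    return Geometry(beam_center_xy, distance_mm, wavelength_a)


@dataclass(frozen=True)
class TensileTruth:
    """Ground-truth parameters of a simulated in situ tensile experiment.

    The material-to-tissue strain coupling is linear: at tissue strain eps the
    collagen ring sits at ``d0_collagen * (1 + slope_collagen * eps)`` and the
    mineral ring at ``d0_mineral * (1 + slope_mineral * eps)``.  Tissue strain
    is held at zero for ``n_preload_frames`` frames (the unloaded reference)
    and then ramps linearly at ``tissue_strain_rate``.
    """

    slope_collagen: float = 0.7482
    slope_mineral: float = 0.3561
    tissue_strain_rate: float = 4.0e-5  # 1/s
    d0_collagen: float = 670.0  # A (67 nm first-order reflection)
    d0_mineral: float = 3.44  # A (hydroxyapatite (002))
    p2_initial: float = 0.25
    p2_rate: float = 2.0  # dP2 per unit tissue strain
    frame_interval: float = 5.0  # s
    exposure: float = 0.5  # s
    dose_per_exposure: float = 0.5  # kGy
    noise_level: float = 50.0  # expected peak counts per pixel on the ring
    background_level: float = 3.0  # expected counts per pixel off-ring
    ring_width_frac: float = 0.04  # Gaussian sigma in q, as a fraction of q0
    failure_strain: float = 0.015
    n_preload_frames: int = 5
    ccd_rate_hz: float = 1.0
    gauge_px: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("slope_collagen", "slope_mineral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.5:
                raise ValueError(f"{name}={v} outside the plausible range [0, 1.5]")
        if not -0.5 <= self.p2_initial <= 1.0:
            raise ValueError("p2_initial must lie in [-0.5, 1]")
        if not self.exposure < self.frame_interval:
            raise ValueError("exposure must be shorter than the frame interval")
        if not self.dose_per_exposure > 0:
            raise ValueError("dose_per_exposure must be positive")
        for name in ("d0_collagen", "d0_mineral", "tissue_strain_rate", "failure_strain"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def n_frames(self) -> int:
        """Frames acquired: capped by failure and by the 30 kGy dose budget."""
        ramp_s = self.failure_strain / self.tissue_strain_rate
        to_failure = self.n_preload_frames + int(np.ceil(ramp_s / self.frame_interval))
        dose_cap = int(np.floor(DOSE_CAP_KGY / self.dose_per_exposure))
        return min(to_failure, dose_cap)

    def tissue_strain_at(self, time_s):
        """Analytic tissue strain ramp (zero during the preload hold)."""
        t0 = self.n_preload_frames * self.frame_interval
        return self.tissue_strain_rate * np.maximum(0.0, np.asarray(time_s, float) - t0)


@dataclass
class SampleMeta:
    """Identity, grouping, and exclusion flags for one specimen."""

    sample_id: str
    group: tuple[str, str, str]  # (age, sex, genotype)
    slipped: bool = False
    depotted: bool = False
    fracture_site: str = "diaphyseal"  # or "nondiaphyseal"
    cumulative_dose_kgy: float = 0.0


@dataclass
class ExperimentBundle:
    """Everything the pipeline consumes for one specimen, plus the truth."""

    frames: list[DetectorFrame]
    ccd_markers: pd.DataFrame  # columns: time_s, marker_id, x_px, y_px
    sample_meta: SampleMeta
    truth: TensileTruth  # retained for testing only
    geometry: Geometry  # generating geometry (recoverable via calibration)

    def __post_init__(self) -> None:
        times = np.array([f.time_s for f in self.frames])
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")
        mt = self.ccd_markers["time_s"]
        if len(times) and not (mt.min() <= times[0] and mt.max() >= times[-1]):
            raise ValueError("marker table must span the frame time range")


def _expected_pattern(geometry, rings, background):
    """Expected counts/pixel for rings = [(q0, sigma_q, amplitude, kappa)]."""
    q_map, chi_map, _ = _pixel_maps(geometry)
    expected = np.full(geometry.detector_shape, float(background))
    cos2chi = None
    for q0, sigma_q, amplitude, kappa in rings:
        radial = np.exp(-0.5 * ((q_map - q0) / sigma_q) ** 2)
        if kappa != 0.0:
            if cos2chi is None:
                cos2chi = np.cos(2.0 * np.radians(chi_map))
            radial = radial * np.exp(kappa * cos2chi - abs(kappa))
        expected += amplitude * radial
    return expected


def simulate_calibrant_frame(
    geometry: Geometry,
    ring_d: Sequence[float] | None = None,
    seed: int = 0,
    amplitude: float = 500.0,
    background: float = 2.0,
    ring_sigma_px: float = 2.0,
) -> DetectorFrame:
    """Azimuthally uniform calibrant rings (silver behenate by default).

    ``ring_d`` lists the d-spacings (A) to place; an empty list yields a pure
    background frame; a ring whose radius falls entirely off the detector is
    an error naming the offending d.
    """
    if ring_d is None:
        ring_d = [AGBE_D001, AGBE_D001 / 2.0]
    rings = []
    for d in ring_d:
        if not d > 0:
            raise ValueError(f"ring d-spacing must be positive, got {d}")
        r_mm = geometry.ring_radius_mm(d)
        if r_mm > geometry.max_radius_mm():
            raise ValueError(
                f"ring for d={d} A (radius {r_mm:.1f} mm) lies beyond the detector"
            )
        q0 = 2.0 * np.pi / d
        # convert a radial width in pixels to a width in q at the ring
        dq = geometry.q_of_radius(r_mm + geometry.pixel_size_mm) - geometry.q_of_radius(r_mm)
        rings.append((q0, ring_sigma_px * float(dq), amplitude, 0.0))
    expected = _expected_pattern(geometry, rings, background)
    rng = np.random.default_rng(seed)
    data = rng.poisson(expected).astype(np.uint32)
    return DetectorFrame(
        data, time_s=0.0, exposure_s=0.5, dose_kgy=0.0,
        meta={"kind": "calibrant", "ring_d": list(ring_d), "seed": seed,
              "truth_geometry": geometry},
    )


def simulate_tensile_experiment(
    truth: TensileTruth,
    geometry: Geometry,
    sample_id: str = "S1",
    group: tuple[str, str, str] = ("4mo", "M", "Ctrl"),
    seed: int | None = None,
) -> ExperimentBundle:
    """Simulate the frame sequence and marker table of one tensile test.

    At each frame time the programmed tissue strain displaces the collagen
    and mineral rings through their coupling slopes; only rings that land on
    the supplied detector geometry are rendered (the collagen 67 nm ring under
    a SAXS geometry, the mineral (002) ring under a WAXD geometry).  The
    azimuthal anisotropy follows P2 = p2_initial + p2_rate * tissue_strain.
    The marker table encodes the tissue strain ramp exactly.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = truth.n_frames()
    r_max = geometry.max_radius_mm()
    frames: list[DetectorFrame] = []
    for i in range(n):
        t = i * truth.frame_interval
        eps = float(truth.tissue_strain_at(t))
        p2 = float(np.clip(truth.p2_initial + truth.p2_rate * eps, -0.499, 0.999))
        kappa = kappa_for_p2(p2)
        rings = []
        for d0, slope in (
            (truth.d0_collagen, truth.slope_collagen),
            (truth.d0_mineral, truth.slope_mineral),
        ):
            d = d0 * (1.0 + slope * eps)
            if geometry.ring_radius_mm(d) <= r_max:
                q0 = 2.0 * np.pi / d
                rings.append((q0, truth.ring_width_frac * q0, truth.noise_level, kappa))
        expected = _expected_pattern(geometry, rings, truth.background_level)
        data = rng.poisson(expected).astype(np.uint32)
        frames.append(
            DetectorFrame(
                data, time_s=t, exposure_s=truth.exposure,
                dose_kgy=truth.dose_per_exposure,
                meta={"frame": i, "tissue_strain": eps, "p2": p2},
            )
        )
    t_end = (n - 1) * truth.frame_interval
    ccd_t = np.arange(0.0, t_end + 1e-9, 1.0 / truth.ccd_rate_hz)
    eps_t = truth.tissue_strain_at(ccd_t)
    cx, cy = geometry.beam_center_xy
    half = truth.gauge_px / 2.0
    markers = pd.DataFrame(
        {
            "time_s": np.repeat(ccd_t, 2),
            "marker_id": np.tile(np.array(["A", "B"]), len(ccd_t)),
            "x_px": np.stack([cx - half * (1 + eps_t), cx + half * (1 + eps_t)], axis=1).ravel(),
            "y_px": np.full(2 * len(ccd_t), cy),
        }
    )
    meta = SampleMeta(sample_id, group, cumulative_dose_kgy=n * truth.dose_per_exposure)
    return ExperimentBundle(frames, markers, meta, truth, geometry)


@dataclass
class LoadDisplacementCurve:
    """Sampled three-point-bend load-displacement record."""

    displacement_mm: np.ndarray
    load_n: np.ndarray
    sampling_hz: float = 50.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.load_n = np.asarray(self.load_n, dtype=float)
        if self.displacement_mm.shape != self.load_n.shape:
            raise ValueError("displacement and load must have equal lengths")
        if np.any(np.diff(self.displacement_mm) < 0):
            raise ValueError("displacement must be nondecreasing")


def simulate_load_displacement(
    stiffness: float,
    yield_point: tuple[float, float],
    postyield_disp: float,
    fracture_drop: float = 0.95,
    sampling_hz: float = 50.0,
    seed: int = 0,
    noise_n: float = 0.0,
    ultimate_force: float | None = None,
    rate_mm_s: float = 0.1,
) -> LoadDisplacementCurve:
    """Piecewise bend curve: elastic ramp, hardening to ultimate, failure.

    The curve rises linearly at ``stiffness`` to the yield point, hardens
    along a quarter-sine to ``ultimate_force`` over ``postyield_disp``
    (``postyield_disp=0`` gives a brittle record), then collapses by
    ``fracture_drop`` of the ultimate force.  Additive Gaussian load noise of
    scale ``noise_n`` is seeded.  The analytic metrics implied by the
    noiseless curve are recorded in ``meta['truth']``.
    """
    if not stiffness > 0:
        raise ValueError("stiffness must be positive")
    if postyield_disp < 0:
        raise ValueError("postyield displacement cannot be negative")
    if not 0.0 < fracture_drop <= 1.0:
        raise ValueError("fracture_drop must be a fraction in (0, 1]")
    d_y, f_y = map(float, yield_point)
    if not (d_y > 0 and f_y > 0):
        raise ValueError("yield point must have positive displacement and load")
    if abs(f_y - stiffness * d_y) > 0.05 * f_y:
        raise ValueError("yield point is inconsistent with the elastic stiffness")
    f_u = float(ultimate_force) if ultimate_force is not None else 1.08 * f_y
    if f_u < f_y:
        raise ValueError("ultimate force cannot be below the yield load")
    if postyield_disp == 0:
        f_u = f_y  # brittle: no hardening segment exists
    d_frac = d_y + postyield_disp
    step = rate_mm_s / sampling_hz
    disp = np.arange(0.0, d_frac + step, step)
    disp = disp[disp <= d_frac]
    if disp[-1] < d_frac:
        disp = np.append(disp, d_frac)
    load = np.where(
        disp <= d_y,
        stiffness * disp,
        f_y + (f_u - f_y) * np.sin(0.5 * np.pi * (disp - d_y) / max(postyield_disp, 1e-12)),
    )
    if postyield_disp == 0:
        load[disp >= d_y] = np.minimum(stiffness * disp[disp >= d_y], f_u)
    # terminal collapse: two post-fracture samples at the residual load
    residual = f_u * (1.0 - fracture_drop)
    disp = np.concatenate([disp, [d_frac + step, d_frac + 2 * step]])
    load = np.concatenate([load, [residual, residual]])
    rng = np.random.default_rng(seed)
    if noise_n > 0:
        load = np.clip(load + rng.normal(0.0, noise_n, load.shape), 0.0, None)
    hardening_area = f_y * postyield_disp + (f_u - f_y) * postyield_disp * (2.0 / np.pi)
    truth = {
        "stiffness": stiffness,
        "yield_point": (d_y, f_y),
        "ultimate_force": f_u,
        "fracture_point": (d_frac, f_u if postyield_disp > 0 else f_y),
        "postyield_disp": postyield_disp,
        "work_to_fracture": 0.5 * f_y * d_y + hardening_area,
    }
    return LoadDisplacementCurve(disp, load, sampling_hz, {"truth": truth, "seed": seed})


def simulate_group_outcomes(
    levels_age: Sequence[str],
    levels_genotype: Sequence[str],
    cell_means: dict,
    sd,
    n_per_cell: int,
    seed: int = 0,
    sex: str = "M",
) -> pd.DataFrame:
    """Long-format factorial outcome table with normal within-cell scatter.

    ``cell_means`` maps (age, genotype) to the cell mean; ``sd`` is a scalar
    or a mapping per cell.  Every cell of the age x genotype cross must be
    specified.
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be at least 2")
    rng = np.random.default_rng(seed)
    rows = []
    for age in levels_age:
        for genotype in levels_genotype:
            key = (age, genotype)
            if key not in cell_means:
                raise ValueError(f"missing cell mean for (age={age}, genotype={genotype})")
            cell_sd = sd[key] if isinstance(sd, dict) else float(sd)
            if cell_sd < 0:
                raise ValueError("cell standard deviation cannot be negative")
            values = cell_means[key] + rng.normal(0.0, 1.0, n_per_cell) * cell_sd
            for j, v in enumerate(values):
                rows.append(
                    {
                        "sample_id": f"{age}_{genotype}_{sex}_{j}",
                        "age": str(age),
                        "genotype": str(genotype),
                        "sex": sex,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)
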