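"""Three-point-bend structural metrics and elliptical-section material props.

Structural metrics come straight off the load-displacement record: stiffness
(max slope of a sliding-window linear fit in the pre-yield region), yield
point (offset method by default; the criterion is a convention, not a
measurement, and is configurable), ultimate force (max load), fracture point
(terminal collapse), postyield displacement, and work to fracture (trapezoid
area).  Material properties normalize the structural ones by an elliptical
hollow cross-section: ``I = (pi/64) (w_o h_o^3 - w_i h_i^3)``,
``E = k L^3 / (48 I)``, ``sigma = F L c / (4 I)`` with ``c = h_o / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simulate import LoadDisplacementCurve

__all__ = [
    "CrossSection",
    "BendSummary",
    "bend_metrics",
    "elliptical_moi",
    "material_properties",
]


@dataclass
class CrossSection:
    """Hollow elliptical cross-section (mm): periosteal outer, endosteal inner.

    Heights run along the load direction; widths across it.
    """

    outer_width: float
    outer_height: float
    inner_width: float
    inner_height: float
    bending_axis: str = "medial-lateral"

    def __post_init__(self) -> None:
        for name in ("outer_width", "outer_height", "inner_width", "inner_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cannot be negative")
        if self.inner_width > self.outer_width or self.inner_height > self.outer_height:
            raise ValueError("endosteal (inner) dimensions exceed periosteal (outer)")


def elliptical_moi(section: CrossSection) -> float:
    """Area moment of inertia (mm^4) of the hollow ellipse about the bend axis."""
    return (np.pi / 64.0) * (
        section.outer_width * section.outer_height**3
        - section.inner_width * section.inner_height**3
    )


@dataclass
class BendSummary:
    """Whole-bone bend metrics; material fields are filled by
    :func:`material_properties`."""

    stiffness: float  # N/mm
    yield_point: tuple[float, float]  # (mm, N)
    ultimate_force: float  # N
    fracture_point: tuple[float, float]  # (mm, N)
    postyield_displacement: float  # mm
    work_to_fracture: float  # N*mm
    yield_method: str = "offset"
    moi: float | None = None  # mm^4
    modulus: float | None = None  # MPa
    yield_stress: float | None = None  # MPa
    ultimate_stress: float | None = None  # MPa

    def __post_init__(self) -> None:
        if self.ultimate_force < self.yield_point[1] - 1e-9:
            raise ValueError("ultimate force cannot be below the yield load")
        if self.work_to_fracture < 0 or self.postyield_displacement < 0:
            raise ValueError("work and postyield displacement must be nonnegative")


def _sliding_stiffness(disp, load, window_frac=0.2, load_ceiling_frac=0.5):
    """Max slope of a sliding linear fit below half the ultimate load."""
    ultimate = load.max()
    region = np.nonzero(load <= load_ceiling_frac * ultimate)[0]
    stop = max(int(region[-1]) + 1 if region.size else 0, 3)
    # window: 20% of the record, never wider than the sub-half-ultimate region
    window = min(max(3, int(np.ceil(window_frac * len(load)))), stop)
    best = -np.inf
    for start in range(0, stop - window + 1):
        d = disp[start : start + window]
        f = load[start : start + window]
        if np.ptp(d) == 0:
            continue
        slope = np.polyfit(d, f, 1)[0]
        best = max(best, slope)
    if not np.isfinite(best):
        raise ValueError("could not establish a linear pre-yield region")
    return float(best)


def bend_metrics(
    curve: LoadDisplacementCurve,
    yield_method: str = "offset",
    span_mm: float = 8.0,
    offset_strain: float = 0.002,
    secant_loss: float = 0.10,
    window_frac: float = 0.2,
    fracture_floor: float = 0.10,
    drop_frac: float = 0.50,
) -> BendSummary:
    """Extract structural bend metrics from a load-displacement record.

    Yield criteria (the record alone does not define yield):
      - ``offset``: first crossing of the curve below a line at the measured
        stiffness offset by ``offset_strain * span_mm`` of displacement (the
        0.2 %-offset convention transplanted to the structural curve);
      - ``secant``: first point where the secant stiffness load/displacement
        falls below ``(1 - secant_loss)`` of the measured stiffness.
    If the criterion never fires before fracture (a brittle record), the
    yield point is the fracture point and postyield displacement is 0.

    Fracture is the last point before the load collapses below
    ``fracture_floor`` of ultimate; a record whose load never drops below
    ``drop_frac`` of ultimate raises "no fracture detected".
    """
    disp = curve.displacement_mm
    load = curve.load_n
    if len(disp) < 5:
        raise ValueError("load-displacement record is too short")
    i_ult = int(np.argmax(load))
    ultimate = float(load[i_ult])
    post = load[i_ult:]
    if post.min() > drop_frac * ultimate:
        raise ValueError("no fracture detected: load never collapses after the peak")
    below = np.nonzero(post < fracture_floor * ultimate)[0]
    i_frac = i_ult + (below[0] - 1 if below.size else len(post) - 1)
    i_frac = max(i_frac, i_ult)
    fracture = (float(disp[i_frac]), float(load[i_frac]))

    stiffness = _sliding_stiffness(disp[: i_ult + 1], load[: i_ult + 1], window_frac)

    d_pre, f_pre = disp[: i_frac + 1], load[: i_frac + 1]
    if yield_method == "offset":
        d_off = offset_strain * span_mm
        line = stiffness * (d_pre - d_off)
        crossing = np.nonzero((d_pre > d_off) & (f_pre <= line))[0]
    elif yield_method == "secant":
        with np.errstate(divide="ignore", invalid="ignore"):
            secant = np.where(d_pre > 0, f_pre / d_pre, np.inf)
        crossing = np.nonzero(secant <= (1.0 - secant_loss) * stiffness)[0]
    else:
        raise ValueError(f"unknown yield method {yield_method!r}")
    if crossing.size:
        i_y = int(crossing[0])
        if yield_method == "offset" and i_y > 0:
            # linear interpolation between the bracketing samples
            g = (f_pre - stiffness * (d_pre - d_off))
            t = g[i_y - 1] / (g[i_y - 1] - g[i_y])
            d_yield = float(d_pre[i_y - 1] + t * (d_pre[i_y] - d_pre[i_y - 1]))
            f_yield = float(f_pre[i_y - 1] + t * (f_pre[i_y] - f_pre[i_y - 1]))
        else:
            d_yield, f_yield = float(d_pre[i_y]), float(f_pre[i_y])
        yield_pt = (min(d_yield, fracture[0]), min(f_yield, ultimate))
    else:
        yield_pt = fracture
    postyield = max(fracture[0] - yield_pt[0], 0.0)
    work = float(np.trapezoid(load[: i_frac + 1], disp[: i_frac + 1]))
    return BendSummary(
        stiffness=stiffness,
        yield_point=yield_pt,
        ultimate_force=ultimate,
        fracture_point=fracture,
        postyield_displacement=postyield,
        work_to_fracture=work,
        yield_method=yield_method,
    )


def material_properties(
    summary: BendSummary,
    moi_mm4: float,
    span_mm: float,
    outer_height_mm: float | None = None,
    c_mm: float | None = None,
) -> BendSummary:
    """Convert structural metrics to material ones for a span-L bend test.

    ``E = k L^3 / (48 I)``; ``sigma = F L c / (4 I)`` at the yield and
    ultimate loads, with the outer-fiber distance ``c = h_o / 2`` (supply
    either the periosteal height or c directly).
    """
    if not moi_mm4 > 0:
        raise ValueError("moment of inertia must be positive")
    if not span_mm > 0:
        raise ValueError("span must be positive")
    if c_mm is None:
        if outer_height_mm is None:
            raise ValueError("supply the periosteal height or the outer-fiber distance c")
        c_mm = outer_height_mm / 2.0
    modulus = summary.stiffness * span_mm**3 / (48.0 * moi_mm4)
    sigma = lambda force: force * span_mm * c_mm / (4.0 * moi_mm4)
    return replace(
        summary,
        moi=float(moi_mm4),
        modulus=float(modulus),
        yield_stress=float(sigma(summary.yield_point[1])),
        ultimate_stress=float(sigma(summary.ultimate_force)),
    )
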