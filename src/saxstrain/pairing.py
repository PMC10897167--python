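"""Tissue strain from optical markers, time-matching, dose, and exclusions.

Bulk tissue strain is a two-marker gauge: the inter-marker distance projected
on the tensile axis, normalized by its pre-load mean.  X-ray material strains
are then time-matched to the tissue strain by linear interpolation onto the
frame timestamps.  The dose ledger enforces the cumulative radiation cap, and
``apply_exclusions`` implements the specimen-level rejection rules (clamp
slip, early removal from the potting resin, non-diaphyseal fracture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaks import StrainSeries
from .simulate import DOSE_CAP_KGY, SampleMeta

__all__ = [
    "PairedStrainSeries",
    "tissue_strain_from_markers",
    "time_match",
    "dose_ledger",
    "apply_exclusions",
]


@dataclass
class PairedStrainSeries:
    """Time-matched (tissue strain, material strain) points for one specimen.

    Material strains are carried over bit-exactly from the X-ray series; only
    the tissue strain is interpolated.  A decreasing tissue-strain step before
    failure is flagged in ``monotonic_violations``, not raised.
    """

    time_s: np.ndarray
    tissue_strain: np.ndarray
    material_strain: np.ndarray
    phase: str
    sample_id: str = ""
    n_dropped: int = 0  # frames outside CCD coverage
    monotonic_violations: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.tissue_strain = np.asarray(self.tissue_strain, dtype=float)
        self.material_strain = np.asarray(self.material_strain, dtype=float)
        if not (len(self.time_s) == len(self.tissue_strain) == len(self.material_strain)):
            raise ValueError("paired series fields must have equal lengths")
        steps = np.diff(self.tissue_strain)
        self.monotonic_violations = int(np.sum(steps < -1e-12))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "time_s": self.time_s,
                "tissue_strain": self.tissue_strain,
                "material_strain": self.material_strain,
                "phase": self.phase,
            }
        )


def tissue_strain_from_markers(
    markers: pd.DataFrame,
    axis_deg: float = 0.0,
    n_reference: int = 1,
) -> pd.DataFrame:
    """Gauge strain ``eps(t) = (L(t) - L0) / L0`` from a marker table.

    ``markers`` holds columns (time_s, marker_id, x_px, y_px).  L(t) is the
    spread of the marker positions projected on the tensile axis; L0 is its
    mean over the first ``n_reference`` time points.  Rigid-body translations
    cancel exactly.  Returns a frame with columns (time_s, tissue_strain).
    """
    required = {"time_s", "marker_id", "x_px", "y_px"}
    if not required.issubset(markers.columns):
        raise ValueError(f"marker table must have columns {sorted(required)}")
    ux, uy = np.cos(np.radians(axis_deg)), np.sin(np.radians(axis_deg))
    proj = markers["x_px"].to_numpy() * ux - markers["y_px"].to_numpy() * uy
    table = markers.assign(_proj=proj)
    gauge = table.groupby("time_s", sort=True)["_proj"].agg(lambda s: s.max() - s.min())
    if (table.groupby("time_s")["marker_id"].nunique() < 2).any():
        raise ValueError("need at least two markers at every time point")
    if n_reference < 1 or n_reference > len(gauge):
        raise ValueError("invalid number of reference time points")
    l0 = float(gauge.iloc[:n_reference].mean())
    if l0 <= 0:
        raise ValueError("markers are collinear across the axis: zero gauge length")
    return pd.DataFrame(
        {"time_s": gauge.index.to_numpy(dtype=float),
         "tissue_strain": gauge.to_numpy(dtype=float) / l0 - 1.0}
    )


def time_match(
    material: StrainSeries,
    tissue: pd.DataFrame,
    sample_id: str = "",
) -> PairedStrainSeries:
    """Interpolate tissue strain onto the X-ray frame timestamps.

    Tissue strain is linearly interpolated inside the CCD coverage; frames
    beyond either end are matched to the nearest CCD sample when within one
    median CCD interval and dropped (and counted) otherwise.
    """
    t_ccd = tissue["time_s"].to_numpy(dtype=float)
    eps_ccd = tissue["tissue_strain"].to_numpy(dtype=float)
    if len(t_ccd) < 2:
        raise ValueError("tissue strain series needs at least two time points")
    order = np.argsort(t_ccd)
    t_ccd, eps_ccd = t_ccd[order], eps_ccd[order]
    t_frames = material.time_s
    if t_frames.max() < t_ccd[0] or t_frames.min() > t_ccd[-1]:
        raise ValueError("no temporal overlap between X-ray frames and CCD record")
    interval = float(np.median(np.diff(t_ccd)))
    keep = (t_frames >= t_ccd[0] - interval) & (t_frames <= t_ccd[-1] + interval)
    n_dropped = int((~keep).sum())
    t_kept = t_frames[keep]
    eps_tissue = np.interp(t_kept, t_ccd, eps_ccd)  # clamps to nearest at the ends
    return PairedStrainSeries(
        time_s=t_kept,
        tissue_strain=eps_tissue,
        material_strain=material.material_strain[keep],
        phase=material.phase,
        sample_id=sample_id,
        n_dropped=n_dropped,
    )


def dose_ledger(
    frames,
    dose_per_exposure: float | None = None,
    cap_kgy: float = DOSE_CAP_KGY,
) -> pd.DataFrame:
    """Running radiation dose per frame with the cumulative-cap exclusion.

    ``frames`` is a sequence of DetectorFrame (their ``dose_kgy`` increments
    are used unless ``dose_per_exposure`` overrides them) or an integer frame
    count (then ``dose_per_exposure`` is required).  Frames acquired after the
    cumulative dose crosses ``cap_kgy`` are marked ``excluded``.
    """
    if dose_per_exposure is not None and dose_per_exposure <= 0:
        raise ValueError("dose per exposure must be positive")
    if isinstance(frames, (int, np.integer)):
        if dose_per_exposure is None:
            raise ValueError("dose_per_exposure is required with a bare frame count")
        increments = np.full(int(frames), float(dose_per_exposure))
    else:
        increments = np.array(
            [dose_per_exposure if dose_per_exposure is not None else f.dose_kgy
             for f in frames],
            dtype=float,
        )
        if np.any(increments <= 0):
            raise ValueError("dose per exposure must be positive")
    cumulative = np.cumsum(increments)
    excluded = cumulative > cap_kgy + 1e-12
    return pd.DataFrame(
        {"frame": np.arange(len(increments)),
         "dose_kgy": increments,
         "cumulative_kgy": cumulative,
         "excluded": excluded}
    )


def apply_exclusions(samples: list[SampleMeta]) -> tuple[list[SampleMeta], dict]:
    """Drop specimens that slipped, de-potted, or fractured off the diaphysis.

    Returns the retained list and a report with per-reason counts.  The
    operation is idempotent; an all-excluded input warns and returns empty.
    """
    report = {"slipped": 0, "depotted": 0, "nondiaphyseal_fracture": 0,
              "n_input": len(samples), "n_retained": 0}
    retained = []
    for s in samples:
        excluded = False
        if s.slipped:
            report["slipped"] += 1
            excluded = True
        if s.depotted:
            report["depotted"] += 1
            excluded = True
        if s.fracture_site != "diaphyseal":
            report["nondiaphyseal_fracture"] += 1
            excluded = True
        if not excluded:
            retained.append(s)
    report["n_retained"] = len(retained)
    if samples and not retained:
        warnings.warn("all samples excluded; retained set is empty", stacklevel=2)
    return retained, report
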