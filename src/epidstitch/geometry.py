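"""Plan geometry: plane conversions, couch shifts, overlaps, stitch layout.

Multi-isocenter craniospinal plans shift only the couch longitudinal axis
between isocenters; the overlap between adjacent fields is therefore fully
determined by the field height and the couch shift.  This module converts
couch shifts (cm) into integer pixel offsets on a common stitching canvas,
tracking the sub-pixel residual introduced by the cm -> pixel rounding.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .fluence import FluenceMap


@dataclass(frozen=True)
class Isocenter:
    index: int
    couch_longitudinal_cm: float


@dataclass
class PlanGeometry:
    """Ordered isocenters (superior -> inferior) with couch positions.

    Increasing couch longitudinal value moves the treated region inferiorly;
    positions must therefore be strictly increasing in isocenter order.
    """

    isocenters: list[Isocenter]
    reference_plane_mm: float = 1000.0

    def __post_init__(self) -> None:
        if not self.isocenters:
            raise ValueError("geometry needs at least one isocenter")
        idx = [iso.index for iso in self.isocenters]
        if idx != list(range(len(idx))):
            raise ValueError(
                "isocenter indices must be unique and contiguous from 0 "
                f"in superior->inferior order, got {idx}"
            )
        pos = [iso.couch_longitudinal_cm for iso in self.isocenters]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                "couch longitudinal positions must be strictly increasing "
                "(superior -> inferior)"
            )
        if not self.reference_plane_mm > 0:
            raise ValueError("reference_plane_mm must be > 0")

    @property
    def n_isocenters(self) -> int:
        return len(self.isocenters)

    def shifts_cm(self) -> list[float]:
        """Longitudinal separation of each adjacent isocenter pair, cm."""
        pos = [iso.couch_longitudinal_cm for iso in self.isocenters]
        return [b - a for a, b in zip(pos, pos[1:])]

    def to_dict(self) -> dict:
        return {
            "reference_plane_mm": self.reference_plane_mm,
            "isocenters": [
                {"index": iso.index,
                 "couch_longitudinal_cm": iso.couch_longitudinal_cm}
                for iso in self.isocenters
            ],
        }


def load_plan_geometry(path) -> PlanGeometry:
    """Read a PlanGeometry from a YAML key-value file.

    Expected layout::

        reference_plane_mm: 1000
        isocenters:
          - {index: 0, couch_longitudinal_cm: 0.0}
          - {index: 1, couch_longitudinal_cm: 21.0}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "isocenters" not in raw:
        raise ValueError(f"{path}: geometry file must define 'isocenters'")
    isos = [
        Isocenter(int(rec["index"]), float(rec["couch_longitudinal_cm"]))
        for rec in raw["isocenters"]
    ]
    isos.sort(key=lambda iso: iso.index)
    return PlanGeometry(
        isocenters=isos,
        reference_plane_mm=float(raw.get("reference_plane_mm", 1000.0)),
    )


def back_project(
    fmap: FluenceMap,
    target_plane_mm: float,
    scale_values: bool = False,
) -> FluenceMap:
    """Rescale a map's geometry from its plane to ``target_plane_mm``.

    Fluence measured at the imager plane (e.g. SID 1540 mm) is brought to the
    isocenter plane (1000 mm) by similar triangles: the pixel spacing scales
    by ``target / current`` while the grid and pixel values are untouched.
    Pixel values stay in the calibration of the measurement plane — the
    downstream comparison is relative and thresholded, so an inverse-square
    rescale would cancel; pass ``scale_values=True`` for fluence-at-plane
    semantics, which multiplies values by ``(current / target) ** 2``.
    """
    if not target_plane_mm > 0:
        raise ValueError("target_plane_mm must be > 0")
    factor = target_plane_mm / fmap.plane_distance_mm
    pixels = fmap.pixels
    if scale_values:
        pixels = pixels * (fmap.plane_distance_mm / target_plane_mm) ** 2
    return fmap.replace(
        pixels=pixels,
        row_spacing_mm=fmap.row_spacing_mm * factor,
        col_spacing_mm=fmap.col_spacing_mm * factor,
        plane_distance_mm=float(target_plane_mm),
    )


@dataclass(frozen=True)
class JunctionOverlap:
    """Overlap bookkeeping for one adjacent isocenter pair."""

    junction_index: int          # junction j joins isocenters j and j+1
    overlap_px: int              # rows shared on the canvas
    overlap_cm: float            # physical overlap: map height - couch shift
    residual_mm: float           # |shift/spacing - round(...)| * spacing


@dataclass
class StitchLayout:
    """Integer placement of per-isocenter maps on the composite canvas."""

    canvas_rows: int
    canvas_cols: int
    row_offsets_px: list[int]
    overlaps: list[JunctionOverlap]
    row_spacing_mm: float
    col_spacing_mm: float
    plane_distance_mm: float
    map_rows: list[int] = field(default_factory=list)

    def junction_bands(self) -> list[tuple[int, int]]:
        """Canvas row ranges ``[start, stop)`` jointly covered at junctions."""
        bands = []
        for j in range(len(self.overlaps)):
            start = self.row_offsets_px[j + 1]
            stop = self.row_offsets_px[j] + self.map_rows[j]
            bands.append((start, stop))
        return bands


def compute_layout(
    maps: list[FluenceMap],
    geom: PlanGeometry,
) -> StitchLayout:
    """Turn couch shifts into integer row offsets and overlap factors.

    The row offset of isocenter ``k`` is ``round(sum of shifts up to k /
    row_spacing)`` (ties to even); overlaps use the full image extent of the
    summed per-isocenter map.  The rounding residual per junction,
    ``|shift/spacing - round(shift/spacing)| * spacing``, is surfaced because
    the cm -> pixel interpolation is a genuine uncertainty of the stitching.
    """
    if len(maps) != geom.n_isocenters:
        raise ValueError(
            f"got {len(maps)} maps but geometry lists {geom.n_isocenters} "
            "isocenters"
        )
    sp_r = maps[0].row_spacing_mm
    sp_c = maps[0].col_spacing_mm
    plane = maps[0].plane_distance_mm
    cols = maps[0].cols
    if not np.isclose(plane, geom.reference_plane_mm, rtol=1e-6):
        raise ValueError(
            f"maps are at plane {plane} mm but stitching is defined at the "
            f"reference plane {geom.reference_plane_mm} mm; back_project "
            "first (couch shifts are patient-space lengths)"
        )
    for m in maps[1:]:
        if not (
            np.isclose(m.row_spacing_mm, sp_r, rtol=1e-9)
            and np.isclose(m.col_spacing_mm, sp_c, rtol=1e-9)
            and np.isclose(m.plane_distance_mm, plane, rtol=1e-9)
        ):
            raise ValueError(
                "all per-isocenter maps must share spacing and plane; "
                "resample_to_grid / back_project first"
            )
        if m.cols != cols:
            raise ValueError(
                "all per-isocenter maps must share their column count; "
                "resample or conform first"
            )

    shifts_mm = [s * 10.0 for s in geom.shifts_cm()]
    offsets = [0]
    cum = 0.0
    for dz in shifts_mm:
        cum += dz
        offsets.append(int(round(cum / sp_r)))  # banker's rounding at ties

    overlaps: list[JunctionOverlap] = []
    for j, dz in enumerate(shifts_mm):
        sup, inf = maps[j], maps[j + 1]
        overlap_cm = (sup.height_mm - dz) / 10.0
        if overlap_cm < -1e-9:
            raise ValueError(
                f"junction {j} (isocenters {j}-{j + 1}): couch shift "
                f"{dz / 10:.2f} cm exceeds field height "
                f"{sup.height_mm / 10:.2f} cm — gap between fields"
            )
        if dz <= 0 or overlap_cm * 10.0 >= min(sup.height_mm, inf.height_mm) - 1e-9:
            raise ValueError(
                f"junction {j}: fields fully nested (overlap "
                f"{overlap_cm:.2f} cm >= field height)"
            )
        q = dz / sp_r
        residual = abs(q - round(q)) * sp_r
        overlap_px = offsets[j] + sup.rows - offsets[j + 1]
        overlaps.append(
            JunctionOverlap(j, int(overlap_px), overlap_cm, residual)
        )

    canvas_rows = offsets[-1] + maps[-1].rows
    return StitchLayout(
        canvas_rows=int(canvas_rows),
        canvas_cols=cols,
        row_offsets_px=offsets,
        overlaps=overlaps,
        row_spacing_mm=sp_r,
        col_spacing_mm=sp_c,
        plane_distance_mm=plane,
        map_rows=[m.rows for m in maps],
    )
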