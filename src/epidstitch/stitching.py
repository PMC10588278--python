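"""Per-isocenter field summation and composite assembly.

Each isocenter delivers several arcs; their fluences add.  The per-isocenter
sums are then placed on one canvas covering the whole craniospinal axis.
Inside a feathered junction both neighbouring isocenters irradiate the same
anatomy, so by default the composite ACCUMULATES contributions there — the
junction signal is precisely the sum of the two ramps.  An ``overwrite``
mode (later isocenter wins) is kept for reproduction studies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluence import FluenceMap
from .geometry import StitchLayout

OVERLAP_SUM = "sum"
OVERLAP_OVERWRITE = "overwrite"


@dataclass
class CompositeFluence:
    """The stitched whole-axis fluence plus junction bookkeeping."""

    pixels: np.ndarray
    row_spacing_mm: float
    col_spacing_mm: float
    plane_distance_mm: float
    layout: StitchLayout
    contribution_count: np.ndarray   # per-pixel number of contributing isocenters
    source_kind: str

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


def sum_isocenter_fields(fields: list[FluenceMap]) -> FluenceMap:
    """Pixelwise sum of all fields (arcs) belonging to one isocenter."""
    if not fields:
        raise ValueError("need at least one field")
    first = fields[0]
    for f in fields[1:]:
        if f.isocenter_index != first.isocenter_index:
            raise ValueError(
                "mixed isocenter indices "
                f"({f.isocenter_index} vs {first.isocenter_index})"
            )
        if f.pixels.shape != first.pixels.shape:
            raise ValueError(
                "field grid shapes differ within an isocenter; "
                "resample_to_grid / conform_to first"
            )
        if not (
            np.isclose(f.row_spacing_mm, first.row_spacing_mm, rtol=1e-6)
            and np.isclose(f.col_spacing_mm, first.col_spacing_mm, rtol=1e-6)
            and np.isclose(f.plane_distance_mm, first.plane_distance_mm,
                           rtol=1e-6)
        ):
            raise ValueError(
                "field spacings/planes differ within an isocenter; "
                "resample_to_grid / back_project first"
            )
        if f.source_kind != first.source_kind:
            raise ValueError("cannot sum measured with calculated fields")
    total = np.zeros_like(first.pixels)
    for f in fields:  # fixed order for bit reproducibility
        total += f.pixels
    return first.replace(
        pixels=total,
        field_label="+".join(f.field_label for f in fields),
        clipped_negative_count=sum(f.clipped_negative_count for f in fields),
    )


def stitch(
    per_isocenter: list[FluenceMap],
    layout: StitchLayout,
    overlap_mode: str = OVERLAP_SUM,
) -> CompositeFluence:
    """Assemble per-isocenter summed maps into one composite fluence.

    Maps are added (or, in ``overwrite`` mode, copied) at their layout row
    offsets in superior -> inferior order.  Pixels outside every placement
    stay 0 CU with contribution count 0.
    """
    if overlap_mode not in (OVERLAP_SUM, OVERLAP_OVERWRITE):
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    if len(per_isocenter) != len(layout.row_offsets_px):
        raise ValueError("layout does not match the number of maps")
    kinds = {m.source_kind for m in per_isocenter}
    if len(kinds) != 1:
        raise ValueError("cannot stitch measured with calculated maps")

    canvas = np.zeros((layout.canvas_rows, layout.canvas_cols))
    count = np.zeros(canvas.shape, dtype=np.int32)
    for m, off in zip(per_isocenter, layout.row_offsets_px):
        if off < 0 or off + m.rows > layout.canvas_rows or m.cols != layout.canvas_cols:
            raise ValueError(
                f"placement of isocenter {m.isocenter_index} exceeds the "
                "canvas — layout inconsistent with the maps"
            )
        sl = canvas[off:off + m.rows, :]
        if overlap_mode == OVERLAP_SUM:
            sl += m.pixels
        else:
            np.copyto(sl, m.pixels)
        count[off:off + m.rows, :] += 1
    return CompositeFluence(
        pixels=canvas,
        row_spacing_mm=layout.row_spacing_mm,
        col_spacing_mm=layout.col_spacing_mm,
        plane_distance_mm=layout.plane_distance_mm,
        layout=layout,
        contribution_count=count,
        source_kind=kinds.pop(),
    )
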