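"""Synthetic multi-isocenter fluence phantoms with known truth.

The generator emulates the structure of a multi-isocenter VMAT craniospinal
plan as delivered and imaged: rectangular modulated fields of up to
28 x 28 cm² at the isocenter plane, two arcs per isocenter, purely
longitudinal couch shifts producing 5-8 cm feathered overlaps whose
complementary ramps sum to one, an imager-plane pixel grid (default
0.336 mm at SID 1540 mm), multiplicative measurement noise, and injectable
longitudinal setup errors or per-isocenter dose scalings.  Everything is
seeded; identical scenario + seed reproduce the fixture bit for bit.

The feathering ramps are laid out on the same integer canvas the stitcher
will compute from the couch shifts, so the noiseless stitched composite is
exactly the modulation texture (uniform when modulation is off).
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml
from scipy import ndimage

from .fluence import FluenceMap, CALCULATED, MEASURED
from .geometry import Isocenter, PlanGeometry

LINEAR = "linear"
COSINE = "cosine"

_MAX_FIELD_CM = 28.0  # platform field-size cap at the isocenter plane


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameterization of a generated multi-isocenter phantom.

    ``couch_shifts_cm`` has one entry per junction; ``None`` picks 21 cm
    everywhere, i.e. a 7 cm overlap for the default 28 cm field height.
    ``injected_error`` is either ``None`` or a mapping with the keys
    ``"junction_shift_mm"`` (``{junction_index: shift_mm}``; the inferior
    isocenter of that junction is translated longitudinally, positive =
    inferior) and/or ``"dose_scale"`` (``{isocenter_index: factor}``).
    """

    n_isocenters: int = 3
    field_height_cm: float = 28.0
    field_width_cm: float = 16.0
    couch_shifts_cm: tuple[float, ...] | None = None
    feather_ramp: str = LINEAR
    fields_per_isocenter: int = 2
    modulation: bool = True
    modulation_amplitude: float = 0.2
    modulation_corr_cm: float = 2.0
    noise_sd_fraction: float = 0.01
    injected_error: dict | None = None
    seed: int = 0
    spacing_mm: float = 0.336
    plane_distance_mm: float = 1540.0

    def shifts(self) -> tuple[float, ...]:
        if self.couch_shifts_cm is not None:
            return tuple(float(s) for s in self.couch_shifts_cm)
        return (21.0,) * (self.n_isocenters - 1)

    def validate(self) -> None:
        if self.n_isocenters < 2:
            raise ValueError("need at least 2 isocenters")
        if not (0 < self.field_height_cm <= _MAX_FIELD_CM):
            raise ValueError(f"field_height_cm must be in (0, {_MAX_FIELD_CM}]")
        if not (0 < self.field_width_cm <= _MAX_FIELD_CM):
            raise ValueError(f"field_width_cm must be in (0, {_MAX_FIELD_CM}]")
        shifts = self.shifts()
        if len(shifts) != self.n_isocenters - 1:
            raise ValueError(
                "couch_shifts_cm needs one entry per junction "
                f"({self.n_isocenters - 1}), got {len(shifts)}"
            )
        for j, s in enumerate(shifts):
            overlap = self.field_height_cm - s
            if not (0.0 < overlap < self.field_height_cm):
                raise ValueError(
                    f"junction {j}: shift {s} cm gives overlap "
                    f"{overlap:.2f} cm, outside (0, {self.field_height_cm})"
                )
        if self.fields_per_isocenter < 1:
            raise ValueError("fields_per_isocenter must be >= 1")
        if self.feather_ramp not in (LINEAR, COSINE):
            raise ValueError("feather_ramp must be 'linear' or 'cosine'")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if self.injected_error:
            bad = set(self.injected_error) - {"junction_shift_mm", "dose_scale"}
            if bad:
                raise ValueError(f"unknown injected_error keys: {sorted(bad)}")
        if not (self.spacing_mm > 0 and self.plane_distance_mm > 0):
            raise ValueError("spacing_mm and plane_distance_mm must be > 0")


@dataclass
class ScenarioData:
    """Everything :func:`generate_scenario` produces."""

    calculated: list[FluenceMap]
    measured: list[FluenceMap]
    geometry: PlanGeometry
    truth: dict
    scenario: SyntheticScenario = dc_field(repr=False, default=None)


def _ramp_up(length: int, kind: str) -> np.ndarray:
    t = (np.arange(length) + 0.5) / length
    if kind == LINEAR:
        return t
    return np.sin(0.5 * np.pi * t) ** 2


def generate_scenario(scenario: SyntheticScenario) -> ScenarioData:
    """Generate per-field calculated/measured fluences plus the truth record.

    Calculated fields are noiseless; measured fields are the calculated ones
    with the injected error applied (longitudinal shifts use continuous
    bilinear translation, not whole-pixel rolls) followed by multiplicative
    Gaussian noise floored at zero.
    """
    s = scenario
    s.validate()
    rng = np.random.default_rng(s.seed)

    mag = s.plane_distance_mm / 1000.0       # imager-plane magnification
    sp = s.spacing_mm                        # spacing at the generation plane
    sp_iso = sp * (1000.0 / s.plane_distance_mm)
    rows = int(round(s.field_height_cm * 10.0 * mag / sp))
    cols = int(round(s.field_width_cm * 10.0 * mag / sp))
    shifts_cm = s.shifts()

    # integer canvas offsets, same arithmetic as geometry.compute_layout
    offsets = [0]
    cum = 0.0
    for shift in shifts_cm:
        cum += shift * 10.0
        offsets.append(int(round(cum / sp_iso)))
    canvas_rows = offsets[-1] + rows

    if s.modulation and s.modulation_amplitude > 0:
        sigma_px = s.modulation_corr_cm * 10.0 / sp_iso
        white = rng.standard_normal((canvas_rows, cols))
        smooth = ndimage.gaussian_filter(white, sigma=sigma_px, mode="reflect")
        smooth /= smooth.std()
        texture = np.clip(1.0 + s.modulation_amplitude * smooth, 0.05, None)
    else:
        texture = np.ones((canvas_rows, cols))

    err = s.injected_error or {}
    junction_shifts = {int(k): float(v)
                       for k, v in err.get("junction_shift_mm", {}).items()}
    dose_scales = {int(k): float(v)
                   for k, v in err.get("dose_scale", {}).items()}

    calculated: list[FluenceMap] = []
    measured: list[FluenceMap] = []
    for k in range(s.n_isocenters):
        w = np.ones(rows)
        if k > 0:  # up-ramp over the overlap with the superior neighbour
            length = offsets[k - 1] + rows - offsets[k]
            w[:length] *= _ramp_up(length, s.feather_ramp)
        if k < s.n_isocenters - 1:  # down-ramp, complementary to k+1's up-ramp
            length = offsets[k] + rows - offsets[k + 1]
            start = rows - length
            w[start:] *= 1.0 - _ramp_up(length, s.feather_ramp)
        window = texture[offsets[k]:offsets[k] + rows, :]
        iso_calc = window * w[:, None]

        shift_mm = junction_shifts.get(k - 1, 0.0)  # error at junction k-1
        shift_px = shift_mm * mag / sp
        scale = dose_scales.get(k, 1.0)

        for f in range(s.fields_per_isocenter):
            calc_px = iso_calc / s.fields_per_isocenter
            label = f"iso{k}_arc{f}"
            calculated.append(FluenceMap(
                pixels=calc_px, row_spacing_mm=sp, col_spacing_mm=sp,
                plane_distance_mm=s.plane_distance_mm,
                source_kind=CALCULATED, field_label=label,
                isocenter_index=k,
            ))
            meas_px = calc_px
            if shift_px != 0.0:
                meas_px = ndimage.shift(meas_px, (shift_px, 0.0), order=1,
                                        mode="constant", cval=0.0,
                                        prefilter=False)
            if scale != 1.0:
                meas_px = meas_px * scale
            if s.noise_sd_fraction > 0:
                noise = rng.standard_normal(meas_px.shape)
                meas_px = meas_px * (1.0 + s.noise_sd_fraction * noise)
            meas_px = np.clip(meas_px, 0.0, None)
            measured.append(FluenceMap(
                pixels=meas_px, row_spacing_mm=sp, col_spacing_mm=sp,
                plane_distance_mm=s.plane_distance_mm,
                source_kind=MEASURED, field_label=label,
                isocenter_index=k,
            ))

    positions = [0.0]
    for shift in shifts_cm:
        positions.append(positions[-1] + shift)
    geometry = PlanGeometry(
        isocenters=[Isocenter(k, positions[k])
                    for k in range(s.n_isocenters)],
        reference_plane_mm=1000.0,
    )

    truth = {
        "seed": s.seed,
        "rows_per_isocenter": rows,
        "cols": cols,
        "canvas_rows": canvas_rows,
        "row_offsets_px": offsets,
        "overlap_px": [offsets[j] + rows - offsets[j + 1]
                       for j in range(len(shifts_cm))],
        "overlap_cm": [s.field_height_cm - shift for shift in shifts_cm],
        "junction_bands_rows": [
            [offsets[j + 1], offsets[j] + rows]
            for j in range(len(shifts_cm))
        ],
        "iso_plane_spacing_mm": sp_iso,
        "injected_error": {
            "junction_shift_mm": junction_shifts,
            "dose_scale": dose_scales,
        },
    }
    return ScenarioData(calculated=calculated, measured=measured,
                        geometry=geometry, truth=truth, scenario=s)


def load_scenario(path) -> SyntheticScenario:
    """Read a SyntheticScenario from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "couch_shifts_cm" in raw and raw["couch_shifts_cm"] is not None:
        raw["couch_shifts_cm"] = tuple(raw["couch_shifts_cm"])
    return SyntheticScenario(**raw)
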