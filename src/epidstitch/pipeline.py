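"""End-to-end stitch-and-QA pipeline and report generation.

The pipeline mirrors the clinical procedure: read every field's portal-dose
DICOM, sum the arcs of each isocenter, back-project to the isocenter plane,
align grids, compute the overlap layout from the couch shifts, stitch the
calculated and measured composites independently, then compare them with
gamma analysis and superior-inferior profiles.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dicom_io
from .fluence import FluenceMap, conform_to, resample_to_grid, CALCULATED, MEASURED
from .gamma import GammaCriteria, GammaResult, band_failure_stats, gamma_map, pass_rate_table
from .geometry import PlanGeometry, StitchLayout, back_project, compute_layout, load_plan_geometry
from .profiles import Profile, ProfileComparison, compare_profiles, extract_profile, plot_profile_overlay
from .stitching import CompositeFluence, OVERLAP_SUM, stitch, sum_isocenter_fields
from .synthetic import ScenarioData

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated inputs for one full stitch-QA run."""

    calculated_manifest: Path
    measured_manifest: Path
    geometry_file: Path
    out_dir: Path
    criteria: list[GammaCriteria] = field(
        default_factory=lambda: [GammaCriteria()]
    )
    overlap_mode: str = OVERLAP_SUM
    flip_orientation: bool = False
    make_figures: bool = True

    def validate(self) -> None:
        for name in ("calculated_manifest", "measured_manifest",
                     "geometry_file"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if not self.criteria:
            raise ValueError("need at least one gamma criteria set")


@dataclass
class QAOutcome:
    """All in-memory products of one pipeline run."""

    layout: StitchLayout
    calculated_composite: CompositeFluence
    measured_composite: CompositeFluence
    gamma_results: list[GammaResult]
    profile_calculated: Profile
    profile_measured: Profile
    profile_comparison: ProfileComparison
    junction_stats: list[dict]


def load_manifest(path) -> list[tuple[Path, int]]:
    """Read a field manifest: YAML list of ``{path, isocenter}`` records.

    Paths are resolved relative to the manifest file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "fields" not in raw:
        raise ValueError(f"{path}: manifest must define a 'fields' list")
    out = []
    for rec in raw["fields"]:
        p = Path(rec["path"])
        if not p.is_absolute():
            p = path.parent / p
        out.append((p, int(rec["isocenter"])))
    return out


def read_fields(manifest_path, source_kind: str) -> list[FluenceMap]:
    fields = []
    for p, iso in load_manifest(manifest_path):
        if not p.exists():
            raise FileNotFoundError(
                f"read stage: field file {p} (isocenter {iso}) is missing"
            )
        fields.append(dicom_io.read_portal_dose(p, isocenter_index=iso,
                                                source_kind=source_kind))
    if not fields:
        raise ValueError(f"{manifest_path}: manifest lists no fields")
    return fields


def _per_isocenter_sums(
    fields: list[FluenceMap],
    n_isocenters: int,
    reference_plane_mm: float,
) -> list[FluenceMap]:
    by_iso: dict[int, list[FluenceMap]] = {}
    for f in fields:
        by_iso.setdefault(f.isocenter_index, []).append(f)
    if sorted(by_iso) != list(range(n_isocenters)):
        raise ValueError(
            f"fields cover isocenters {sorted(by_iso)} but geometry lists "
            f"0..{n_isocenters - 1}"
        )
    return [
        back_project(sum_isocenter_fields(by_iso[k]), reference_plane_mm)
        for k in range(n_isocenters)
    ]


def run_qa(
    calculated_fields: list[FluenceMap],
    measured_fields: list[FluenceMap],
    geometry: PlanGeometry,
    criteria: list[GammaCriteria] | None = None,
    overlap_mode: str = OVERLAP_SUM,
    flip_orientation: bool = False,
) -> QAOutcome:
    """Stitch both field sets and compare them (pure in-memory pipeline)."""
    criteria = criteria or [GammaCriteria()]
    n = geometry.n_isocenters
    plane = geometry.reference_plane_mm
    calc = _per_isocenter_sums(calculated_fields, n, plane)
    meas = _per_isocenter_sums(measured_fields, n, plane)

    # common grid: the calculated maps define it (aspect-ratio or cropped
    # measured images are resampled/padded onto it)
    target = calc[0]
    calc = [
        m if m is target else conform_to(m, target)
        for m in calc
    ]
    meas = [conform_to(m, c) for m, c in zip(meas, calc)]

    layout = compute_layout(calc, geometry)
    calc_comp = stitch(calc, layout, overlap_mode)
    meas_comp = stitch(meas, layout, overlap_mode)
    if flip_orientation:
        for comp in (calc_comp, meas_comp):
            comp.pixels = comp.pixels[::-1, :].copy()
            comp.contribution_count = comp.contribution_count[::-1, :].copy()

    results = [
        gamma_map(calc_comp, meas_comp, c, label="calculated vs measured")
        for c in criteria
    ]

    bands = layout.junction_bands()
    junction_stats = []
    for res in results:
        margin_px = int(np.ceil(res.criteria.dta_mm / layout.row_spacing_mm))
        st = band_failure_stats(res, bands, margin_px)
        st["criteria"] = res.criteria.label
        junction_stats.append(st)

    prof_c = extract_profile(calc_comp, "center")
    prof_m = extract_profile(meas_comp, prof_c.lateral_position_mm)
    comparison = compare_profiles(prof_c, prof_m, junction_bands=bands)

    return QAOutcome(
        layout=layout,
        calculated_composite=calc_comp,
        measured_composite=meas_comp,
        gamma_results=results,
        profile_calculated=prof_c,
        profile_measured=prof_m,
        profile_comparison=comparison,
        junction_stats=junction_stats,
    )


def _format_report(outcome: QAOutcome, geometry: PlanGeometry) -> str:
    lay = outcome.layout
    lines = []
    lines.append("epidstitch composite QA report")
    lines.append("=" * 34)
    lines.append("")
    lines.append("Plan geometry (echo of parsed input):")
    for iso in geometry.isocenters:
        lines.append(
            f"  isocenter {iso.index}: couch longitudinal "
            f"{iso.couch_longitudinal_cm!r} cm"
        )
    lines.append(f"  reference plane: {geometry.reference_plane_mm:.1f} mm")
    lines.append("")
    lines.append(
        f"Stitch layout ({lay.canvas_rows} x {lay.canvas_cols} px at "
        f"{lay.row_spacing_mm:.5f} x {lay.col_spacing_mm:.5f} mm):"
    )
    lines.append("  overlap extents use the full image extent of each "
                 "summed per-isocenter map")
    for off, k in zip(lay.row_offsets_px, range(len(lay.row_offsets_px))):
        lines.append(f"  isocenter {k}: row offset {off} px")
    for ov in lay.overlaps:
        lines.append(
            f"  junction {ov.junction_index}: overlap {ov.overlap_cm:.2f} cm"
            f" = {ov.overlap_px} px, rounding residual "
            f"{ov.residual_mm:.4f} mm"
        )
    lines.append("")
    lines.append("Gamma analysis (reference = calculated composite):")
    for res, st in zip(outcome.gamma_results, outcome.junction_stats):
        lines.append(
            f"  {res.criteria.label}: pass rate "
            f"{res.pass_rate_percent:.1f} % "
            f"({res.evaluated_count} evaluated, "
            f"{res.excluded_count} below threshold)"
        )
        frac = st["fraction_in_band"]
        frac_s = f"{100 * frac:.1f} %" if np.isfinite(frac) else "n/a"
        lines.append(
            f"    failures: {st['failures']} total, "
            f"{st['failures_in_band']} within junction bands +- DTA "
            f"({frac_s})"
        )
    lines.append("")
    cmp_ = outcome.profile_comparison
    lines.append(
        "Superior-inferior profile comparison "
        f"(lateral position {outcome.profile_calculated.lateral_position_mm:.2f} mm):"
    )
    lines.append(f"  max |calc - meas|: {cmp_.max_abs_diff:.4f} CU")
    lines.append(f"  RMS difference:    {cmp_.rms_diff:.4f} CU")
    for j, d in enumerate(cmp_.junction_max_diffs):
        lines.append(f"  junction {j} band max difference: {d:.4f} CU")
    lines.append(f"  body-region max difference:     {cmp_.body_max_diff:.4f} CU")
    lines.append("")
    return "\n".join(lines)


def run_stitch_qa(config: RunConfig) -> QAOutcome:
    """Full file-to-report pipeline.

    Writes composite DICOMs, a gamma DICOM and CSV summary, a profile CSV,
    overlay/gamma figures and a plain-text report into ``config.out_dir``.
    Re-running on identical inputs reproduces the CSV/report bytes.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geometry = load_plan_geometry(config.geometry_file)
    calc_fields = read_fields(config.calculated_manifest, CALCULATED)
    meas_fields = read_fields(config.measured_manifest, MEASURED)

    outcome = run_qa(calc_fields, meas_fields, geometry,
                     criteria=config.criteria,
                     overlap_mode=config.overlap_mode,
                     flip_orientation=config.flip_orientation)

    dicom_io.write_composite(outcome.calculated_composite,
                             out / "composite_calculated.dcm")
    dicom_io.write_composite(outcome.measured_composite,
                             out / "composite_measured.dcm")
    first = outcome.gamma_results[0]
    dicom_io.write_gamma_map(
        first.gamma_map,
        outcome.layout.row_spacing_mm, outcome.layout.col_spacing_mm,
        outcome.layout.plane_distance_mm,
        out / "gamma_map.dcm",
    )

    table = pass_rate_table(outcome.gamma_results)
    table.to_csv(out / "gamma_summary.csv", index=False,
                 float_format="%.6f")

    prof_c, prof_m = outcome.profile_calculated, outcome.profile_measured
    with open(out / "profiles.csv", "w") as fh:
        fh.write("position_mm,calculated_CU,measured_CU\n")
        for z, c, m in zip(prof_c.positions_mm, prof_c.values, prof_m.values):
            fh.write(f"{z:.4f},{c:.6f},{m:.6f}\n")

    report = _format_report(outcome, geometry)
    (out / "report.txt").write_text(report)

    if config.make_figures:
        plot_profile_overlay(prof_c, prof_m, out / "profiles_overlay.png")
        _plot_qa_panel(outcome, out / "qa_panel.png")
    return outcome


def _plot_qa_panel(outcome: QAOutcome, path) -> None:
    """Four-panel figure: reference, evaluated, gamma map, gamma histogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = outcome.gamma_results[0]
    fig, axes = plt.subplots(1, 4, figsize=(14, 4))
    for ax, img, title in (
        (axes[0], outcome.calculated_composite.pixels, "calculated (CU)"),
        (axes[1], outcome.measured_composite.pixels, "measured (CU)"),
    ):
        im = ax.imshow(img, aspect="auto", cmap="viridis")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    im = axes[2].imshow(res.gamma_map, aspect="auto", cmap="coolwarm",
                        vmin=0, vmax=2)
    axes[2].set_title(f"gamma {res.criteria.label}")
    fig.colorbar(im, ax=axes[2], shrink=0.8)
    g = res.gamma_map[np.isfinite(res.gamma_map)]
    if g.size:
        axes[3].hist(g, bins=50)
    axes[3].set_title(f"pass {res.pass_rate_percent:.1f} %")
    axes[3].set_xlabel("gamma")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_scenario_tree(data: ScenarioData, out_dir) -> dict:
    """Write a generated scenario as a DICOM fixture tree with manifests.

    Layout: ``calculated/``, ``measured/`` field DICOMs, the two manifests,
    ``geometry.yaml`` and ``truth.json``.  Returns the paths written.
    """
    out = Path(out_dir)
    (out / "calculated").mkdir(parents=True, exist_ok=True)
    (out / "measured").mkdir(parents=True, exist_ok=True)

    manifests = {}
    for kind, fields in (("calculated", data.calculated),
                         ("measured", data.measured)):
        records = []
        for f in fields:
            rel = f"{kind}/{f.field_label}.dcm"
            dicom_io.write_field(f, out / rel)
            records.append({"path": rel, "isocenter": f.isocenter_index})
        mpath = out / f"{kind}_manifest.yaml"
        with open(mpath, "w") as fh:
            yaml.safe_dump({"fields": records}, fh, sort_keys=False)
        manifests[kind] = mpath

    gpath = out / "geometry.yaml"
    with open(gpath, "w") as fh:
        yaml.safe_dump(data.geometry.to_dict(), fh, sort_keys=False)
    tpath = out / "truth.json"
    tpath.write_text(json.dumps(data.truth, indent=2, sort_keys=True))
    return {
        "calculated_manifest": manifests["calculated"],
        "measured_manifest": manifests["measured"],
        "geometry": gpath,
        "truth": tpath,
    }
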