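import numpy as np
import pytest
from hypothesis import given, strategies as st

from epidstitch.geometry import (
    Isocenter,
    PlanGeometry,
    back_project,
    compute_layout,
    load_plan_geometry,
)

from conftest import make_map


def geom(positions_cm, plane=1000.0):
    return PlanGeometry(
        isocenters=[Isocenter(i, p) for i, p in enumerate(positions_cm)],
        reference_plane_mm=plane,
    )


class TestPlanGeometry:
    def test_requires_contiguous_indices(self):
        with pytest.raises(ValueError, match="contiguous"):
            PlanGeometry([Isocenter(0, 0.0), Isocenter(2, 20.0)])

    def test_requires_increasing_couch_positions(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            geom([0.0, -5.0])

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        g = geom([0.0, 21.0, 42.0])
        p = tmp_path / "geometry.yaml"
        p.write_text(yaml.safe_dump(g.to_dict()))
        g2 = load_plan_geometry(p)
        assert g2.shifts_cm() == g.shifts_cm()
        assert g2.reference_plane_mm == 1000.0


class TestBackProject:
    def test_epid_to_isocenter_plane_scaling(self):
        # 0.336 mm at SID 1540 mm scales to 0.336 * 1000/1540 at 1000 mm
        m = make_map(np.ones((4, 4)), row_sp=0.336, col_sp=0.336, plane=1540.0)
        out = back_project(m, 1000.0)
        assert out.row_spacing_mm == pytest.approx(0.336 * 1000 / 1540,
                                                   rel=1e-12)
        assert out.row_spacing_mm == pytest.approx(0.21818, abs=5e-6)
        assert out.plane_distance_mm == 1000.0
        assert np.array_equal(out.pixels, m.pixels)

    def test_identity_when_target_equals_current(self):
        m = make_map(np.ones((4, 4)), plane=1540.0)
        out = back_project(m, 1540.0)
        assert out.row_spacing_mm == m.row_spacing_mm

    def test_round_trip_restores_spacing(self):
        m = make_map(np.ones((4, 4)), row_sp=0.336, plane=1540.0)
        out = back_project(back_project(m, 1000.0), 1540.0)
        assert abs(out.row_spacing_mm - 0.336) / 0.336 < 1e-12

    def test_optional_inverse_square_value_scaling(self):
        m = make_map(np.full((4, 4), 2.0), plane=1540.0)
        out = back_project(m, 1000.0, scale_values=True)
        assert np.allclose(out.pixels, 2.0 * (1540 / 1000) ** 2)

    @given(st.floats(500, 2000), st.floats(500, 2000))
    def test_composing_projections_multiplies_factors(self, p1, p2):
        m = make_map(np.ones((4, 4)), row_sp=0.4, plane=1540.0)
        via = back_project(back_project(m, p1), p2)
        direct = back_project(m, p2)
        assert via.row_spacing_mm == pytest.approx(direct.row_spacing_mm,
                                                   rel=1e-12)
        assert np.array_equal(via.pixels, m.pixels)  # values untouched


class TestComputeLayout:
    def test_paper_regime_overlap(self):
        # two 28 cm maps with a 20 cm couch shift overlap by 8 cm
        maps = [make_map(np.ones((280, 50)), iso=i) for i in range(2)]
        layout = compute_layout(maps, geom([0.0, 20.0]))
        assert layout.overlaps[0].overlap_cm == pytest.approx(8.0)
        assert layout.overlaps[0].overlap_px == 80
        assert layout.canvas_rows == 280 + 280 - 80

    def test_shift_equal_to_height_gives_pure_concatenation(self):
        maps = [make_map(np.ones((100, 10)), iso=i) for i in range(2)]
        layout = compute_layout(maps, geom([0.0, 10.0]))
        assert layout.overlaps[0].overlap_px == 0
        assert layout.overlaps[0].overlap_cm == pytest.approx(0.0)
        assert layout.canvas_rows == 200

    @pytest.mark.parametrize("shift_cm,offset,residual", [
        (20.0, 800, 0.0),
        (20.01, 800, 0.1),   # round(800.4) = 800, residual 0.4 px = 0.1 mm
    ])
    def test_subpixel_rounding_and_residual(self, shift_cm, offset, residual):
        maps = [make_map(np.ones((900, 10)), row_sp=0.25, col_sp=0.25, iso=i)
                for i in range(2)]
        layout = compute_layout(maps, geom([0.0, shift_cm]))
        assert layout.row_offsets_px[1] == offset
        assert layout.overlaps[0].residual_mm == pytest.approx(residual,
                                                               abs=1e-9)

    def test_gap_between_fields_names_the_junction(self):
        maps = [make_map(np.ones((100, 10)), iso=i) for i in range(2)]
        with pytest.raises(ValueError, match="junction 0.*gap"):
            compute_layout(maps, geom([0.0, 15.0]))

    def test_fully_nested_fields_rejected(self):
        # a short inferior field entirely inside the overlap region
        maps = [make_map(np.ones((100, 10)), iso=0),
                make_map(np.ones((30, 10)), iso=1)]
        with pytest.raises(ValueError, match="nested"):
            compute_layout(maps, geom([0.0, 5.0]))

    def test_mismatched_grids_rejected(self):
        maps = [make_map(np.ones((100, 10)), row_sp=1.0, iso=0),
                make_map(np.ones((100, 10)), row_sp=0.5, iso=1)]
        with pytest.raises(ValueError, match="resample"):
            compute_layout(maps, geom([0.0, 5.0]))

    @given(st.floats(-50, 50),
           st.lists(st.floats(3.0, 9.0), min_size=1, max_size=3))
    def test_translation_invariance_of_offsets(self, origin, shifts):
        # shifting every couch position by a constant changes no offset
        maps = [make_map(np.ones((100, 10)), iso=i)
                for i in range(len(shifts) + 1)]
        pos = np.concatenate([[0.0], np.cumsum(shifts)])
        a = compute_layout(maps, geom(list(pos)))
        b = compute_layout(maps, geom(list(pos + origin)))
        assert a.row_offsets_px == b.row_offsets_px
        assert [o.overlap_px for o in a.overlaps] == \
               [o.overlap_px for o in b.overlaps]

    @given(st.lists(st.floats(3.0, 9.9), min_size=1, max_size=4))
    def test_residuals_below_half_spacing_and_canvas_identity(self, shifts):
        maps = [make_map(np.ones((100, 10)), iso=i)
                for i in range(len(shifts) + 1)]
        pos = list(np.concatenate([[0.0], np.cumsum(shifts)]))
        layout = compute_layout(maps, geom(pos))
        for ov in layout.overlaps:
            assert ov.residual_mm <= 0.5 + 1e-9  # spacing/2 for 1 mm pixels
        total = sum(m.rows for m in maps) - sum(o.overlap_px
                                                for o in layout.overlaps)
        assert layout.canvas_rows == total
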