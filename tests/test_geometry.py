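"""Parametric bifurcation geometry, lesions and virtual angioplasty."""

import numpy as np
import pytest

from graftflow.errors import ValidationError
from graftflow.geometry import (
    BifurcationGeometry,
    LesionSpec,
    VesselSpec,
    build_geometry,
    lubrication_pressure_drop,
    virtual_angioplasty,
)

BASE_SPEC = {
    "vessels": [
        {"name": "CFA", "radius": 4e-3, "length": 0.020, "angle_deg": 0.0},
        {"name": "SFA", "radius": 3e-3, "length": 0.030, "angle_deg": 12.0},
        {"name": "DFA", "radius": 2.5e-3, "length": 0.018, "angle_deg": -40.0},
    ]
}


def geom_with(lesions=()):
    spec = dict(BASE_SPEC)
    spec["lesions"] = list(lesions)
    return build_geometry(spec)


class TestWidthField:
    def test_zero_severity_is_identity(self):
        g = geom_with(
            [dict(vessel="SFA", center_s=0.010, length=0.008, severity=0.0)]
        )
        s = np.linspace(0, 0.030, 200)
        np.testing.assert_allclose(g.width("SFA", s), 3e-3, rtol=1e-15)

    def test_half_area_stenosis_halves_local_width(self):
        g = geom_with(
            [dict(vessel="CFA", center_s=0.010, length=0.008,
                  kind="stenosis", severity=0.5)]
        )
        assert g.width("CFA", 0.010) == pytest.approx(2e-3, rel=1e-12)
        # outside the lesion support the width is nominal
        assert g.width("CFA", 0.002) == pytest.approx(4e-3, rel=1e-15)

    def test_widening_increases_width(self):
        g = geom_with(
            [dict(vessel="CFA", center_s=0.010, length=0.008,
                  kind="widening", severity=0.4)]
        )
        assert g.width("CFA", 0.010) == pytest.approx(5.6e-3, rel=1e-12)

    def test_severity_recovered_from_width_at_center(self):
        # area law: configured severity is reproduced by the width field
        for sev in (0.2, 0.5, 0.65):
            g = geom_with(
                [dict(vessel="SFA", center_s=0.012, length=0.006,
                      severity=sev)]
            )
            got = 1.0 - g.width("SFA", 0.012) / 3e-3
            assert got == pytest.approx(sev, abs=1e-6)

    def test_width_profile_is_c1(self):
        g = geom_with(
            [dict(vessel="SFA", center_s=0.012, length=0.006, severity=0.6)]
        )
        s = np.linspace(0.005, 0.020, 4001)
        w = g.width("SFA", s)
        dw = np.gradient(w, s)
        # derivative continuous: no jumps beyond discretization of gradient
        assert np.max(np.abs(np.diff(dw))) < 5e-3


class TestValidation:
    def test_overlapping_lesions_rejected_with_pair_named(self):
        with pytest.raises(ValidationError, match="overlap"):
            geom_with(
                [
                    dict(vessel="SFA", center_s=0.010, length=0.008),
                    dict(vessel="SFA", center_s=0.013, length=0.006),
                ]
            )

    def test_lesion_outside_vessel_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            geom_with([dict(vessel="DFA", center_s=0.017, length=0.004)])

    def test_needs_one_inlet_two_outlets(self):
        with pytest.raises(ValidationError):
            BifurcationGeometry(
                vessels=(
                    VesselSpec("A", 3e-3, 0.02, 0.0),
                    VesselSpec("B", 3e-3, 0.02, 0.3),
                )
            )

    def test_outlets_on_opposite_sides(self):
        with pytest.raises(ValidationError, match="opposite"):
            BifurcationGeometry(
                vessels=(
                    VesselSpec("A", 3e-3, 0.02, 0.0),
                    VesselSpec("B", 3e-3, 0.02, 0.3),
                    VesselSpec("C", 3e-3, 0.02, 0.5),
                )
            )

    @pytest.mark.parametrize("sev", [-0.1, 1.0, 1.5])
    def test_severity_range(self, sev):
        with pytest.raises(ValidationError):
            LesionSpec(vessel="SFA", center_s=0.01, length=0.004, severity=sev)


class TestVirtualAngioplasty:
    LESION = dict(
        vessel="SFA", center_s=0.012, length=0.006, kind="stenosis",
        severity=0.5,
    )

    def test_no_lesion_in_interval_is_identity(self):
        g = geom_with([self.LESION])
        g2 = virtual_angioplasty(g, "DFA", (0.004, 0.012))
        s = np.linspace(0, 0.018, 300)
        np.testing.assert_allclose(
            g2.width("DFA", s), g.width("DFA", s), rtol=1e-15
        )
        s = np.linspace(0, 0.030, 300)
        np.testing.assert_allclose(
            g2.width("SFA", s), g.width("SFA", s), rtol=1e-15
        )

    def test_inflation_restores_nominal_radius(self):
        g = geom_with([self.LESION])
        g2 = virtual_angioplasty(g, "SFA", (0.006, 0.018))
        s = np.linspace(0.006, 0.018, 500)
        np.testing.assert_allclose(g2.width("SFA", s), 3e-3, rtol=1e-9)

    def test_input_not_mutated(self):
        g = geom_with([self.LESION])
        virtual_angioplasty(g, "SFA", (0.006, 0.018))
        assert g.inflations == ()
        assert g.width("SFA", 0.012) == pytest.approx(1.5e-3)

    def test_idempotent_on_same_interval(self):
        g = geom_with([self.LESION])
        g2 = virtual_angioplasty(g, "SFA", (0.006, 0.018))
        g3 = virtual_angioplasty(g2, "SFA", (0.006, 0.018))
        assert g3 is g2

    def test_interval_outside_vessel_rejected(self):
        g = geom_with([self.LESION])
        with pytest.raises(ValidationError):
            virtual_angioplasty(g, "SFA", (0.025, 0.035))

    def test_stokes_pressure_drop_decreases(self):
        # lubrication (locally-Poiseuille) oracle for the direction and size
        # of the treatment effect at vanishing Reynolds number
        g = geom_with([self.LESION])
        g2 = virtual_angioplasty(g, "SFA", (0.006, 0.018))
        mu, q = 3.5e-3, 1e-5
        dp_pre = lubrication_pressure_drop(g, "SFA", q, mu)
        dp_post = lubrication_pressure_drop(g2, "SFA", q, mu)
        assert dp_post < dp_pre
        # the treated vessel approaches the lesion-free resistance
        g0 = geom_with([])
        dp_free = lubrication_pressure_drop(g0, "SFA", q, mu)
        assert dp_post == pytest.approx(dp_free, rel=0.02)


class TestBoundary:
    def test_boundary_pieces_close_and_tag(self):
        g = geom_with([])
        pieces = g.boundary_pieces()
        tags = [p["tag"] for p in pieces]
        assert tags.count("inlet") == 1
        assert sum(1 for t in tags if t.startswith("outlet_")) == 2
        for a, b in zip(pieces, pieces[1:] + pieces[:1]):
            np.testing.assert_allclose(a["points"][-1], b["points"][0])

    def test_symmetric_bifurcation_has_mirror_symmetric_boundary(self):
        g = build_geometry(
            {
                "vessels": [
                    {"name": "P", "radius": 3e-3, "length": 0.02, "angle_deg": 0},
                    {"name": "A", "radius": 2.2e-3, "length": 0.02,
                     "angle_deg": 30.0},
                    {"name": "B", "radius": 2.2e-3, "length": 0.02,
                     "angle_deg": -30.0},
                ]
            }
        )
        pts = np.vstack([p["points"] for p in g.boundary_pieces()])
        mirrored = pts * np.array([1.0, -1.0])
        # every boundary point has a mirror partner within tolerance
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(mirrored)
        assert np.max(d) < 1e-6
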