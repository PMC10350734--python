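"""Parametric planar femoral-bifurcation geometry.

The common femoral artery (CFA) bifurcates into the superficial (SFA) and
deep (DFA) femoral arteries.  Instead of a patient lumen segmented from CTA,
this module synthesizes an in-plane 2D analogue: three straight-centerline
vessels with smoothly varying half-width, joined at a junction, with
configurable lesions:

* ``stenosis`` — a cosine-bump narrowing; severity is the fractional
  reduction of local cross-section (in the planar analogue, width), so a
  severity-0.5 lesion halves the local lumen, matching how "50%-area
  stenosis" is reported clinically;
* ``widening`` — the same bump with opposite sign, emulating the bulge left
  by patch angioplasty of the CFA.

An endograft is a wall-segment annotation only (the device's luminal surface
is smooth at CTA resolution); an *edge stenosis* is simply a stenosis placed
at the proximal end of that annotation.  Virtual angioplasty restores a
chosen interval to nominal caliber ("cylindrical inflation") with C1 blends
at the interval ends, recorded declaratively so the operation is idempotent.

Coordinates: arc length ``s`` in meters, measured from the inlet plane for
the CFA and from the junction origin for the daughters.  The inlet
centerline runs along +x with the junction at the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import GeometryError, ValidationError

__all__ = [
    "VesselSpec",
    "LesionSpec",
    "BifurcationGeometry",
    "build_geometry",
    "virtual_angioplasty",
    "lubrication_resistance",
    "lubrication_inertance",
    "lubrication_pressure_drop",
]

DEFAULT_BLEND_LENGTH = 1.5e-3  # m, C1 blend at angioplasty interval ends


@dataclass(frozen=True)
class VesselSpec:
    """One straight-centerline vessel of the bifurcation.

    ``nominal_radius`` is the lesion-free half-width of the planar channel
    (the 2D stand-in for the vessel radius); ``angle`` is measured from the
    parent (inlet) axis, 0 for the inlet vessel itself.
    """

    name: str
    nominal_radius: float
    length: float
    angle: float = 0.0

    def __post_init__(self):
        if self.nominal_radius <= 0:
            raise ValidationError(f"vessel {self.name!r}: radius must be > 0")
        if self.length <= 0:
            raise ValidationError(f"vessel {self.name!r}: length must be > 0")
        if not abs(self.angle) < math.pi / 2:
            raise ValidationError(
                f"vessel {self.name!r}: |angle| must be < pi/2"
            )


@dataclass(frozen=True)
class LesionSpec:
    """A smooth axisymmetric lesion on one vessel.

    ``severity`` is the fractional change of local cross-section at the
    lesion center relative to nominal: a severity-0.5 stenosis halves the
    local lumen.  The default ``cosine`` profile is C1 at its shoulders,
    avoiding spurious shear singularities.
    """

    vessel: str
    center_s: float
    length: float
    kind: str = "stenosis"
    severity: float = 0.5
    profile: str = "cosine"

    def __post_init__(self):
        if self.kind not in ("stenosis", "widening"):
            raise ValidationError(f"unknown lesion kind {self.kind!r}")
        if not (0.0 <= self.severity < 1.0):
            raise ValidationError("severity must be in [0, 1)")
        if self.length <= 0:
            raise ValidationError("lesion length must be > 0")
        if self.profile != "cosine":
            raise ValidationError(f"unknown lesion profile {self.profile!r}")

    @property
    def s_start(self) -> float:
        return self.center_s - 0.5 * self.length

    @property
    def s_end(self) -> float:
        return self.center_s + 0.5 * self.length

    def bump(self, s) -> np.ndarray:
        """Unit cosine bump: 1 at the center, 0 with zero slope at the ends."""
        s = np.asarray(s, dtype=float)
        x = (s - self.center_s) / self.length  # in [-1/2, 1/2] inside
        inside = np.abs(x) < 0.5
        out = np.zeros_like(s)
        out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[inside]))
        return out

    def width_deviation(self, s, nominal: float) -> np.ndarray:
        sign = -1.0 if self.kind == "stenosis" else 1.0
        return sign * self.severity * nominal * self.bump(s)


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _inflation_mask(s, s0, s1, blend):
    """1 inside the inflated interval (C1 ramps of width ``blend``), 0 outside."""
    s = np.asarray(s, dtype=float)
    d = min(blend, 0.25 * (s1 - s0))
    up = _smoothstep((s - s0) / d) if d > 0 else (s >= s0).astype(float)
    down = _smoothstep((s1 - s) / d) if d > 0 else (s <= s1).astype(float)
    return up * down


@dataclass(frozen=True)
class BifurcationGeometry:
    """A CFA -> SFA/DFA tree with lesions and angioplasty annotations.

    ``vessels[0]`` is the inlet; the two daughters must leave the junction on
    opposite sides of the inlet axis.  ``wall_segments`` names arc-length
    intervals ``(vessel, s0, s1)`` used for wall shear reporting.
    """

    vessels: tuple[VesselSpec, ...]
    lesions: tuple[LesionSpec, ...] = ()
    endograft_extent: tuple[str, float, float] | None = None
    wall_segments: Mapping[str, tuple[str, float, float]] = field(
        default_factory=dict
    )
    inflations: tuple[tuple[str, float, float], ...] = ()
    blend_length: float = DEFAULT_BLEND_LENGTH

    def __post_init__(self):
        object.__setattr__(self, "vessels", tuple(self.vessels))
        object.__setattr__(self, "lesions", tuple(self.lesions))
        object.__setattr__(self, "inflations", tuple(self.inflations))
        object.__setattr__(self, "wall_segments", dict(self.wall_segments))
        if len(self.vessels) != 3:
            raise ValidationError("geometry needs exactly one inlet and two outlets")
        names = [v.name for v in self.vessels]
        if len(set(names)) != 3:
            raise ValidationError("vessel names must be unique")
        if self.vessels[0].angle != 0.0:
            raise ValidationError("inlet vessel (first) must have angle 0")
        a1, a2 = self.vessels[1].angle, self.vessels[2].angle
        if not (a1 > 0 > a2 or a2 > 0 > a1):
            raise ValidationError(
                "the two outlet vessels must leave on opposite sides of the "
                "inlet axis (one positive, one negative angle)"
            )
        by_vessel: dict[str, list[LesionSpec]] = {}
        for les in self.lesions:
            if les.vessel not in names:
                raise ValidationError(f"lesion references unknown vessel {les.vessel!r}")
            v = self.vessel(les.vessel)
            if les.s_start < 0 or les.s_end > v.length:
                raise ValidationError(
                    f"lesion on {les.vessel!r} at s=[{les.s_start:.4g}, "
                    f"{les.s_end:.4g}] m lies outside the vessel extent "
                    f"[0, {v.length:.4g}] m"
                )
            by_vessel.setdefault(les.vessel, []).append(les)
        for vname, group in by_vessel.items():
            group = sorted(group, key=lambda l: l.s_start)
            for a, b in zip(group, group[1:]):
                if b.s_start < a.s_end:
                    raise ValidationError(
                        f"overlapping lesions on {vname!r}: "
                        f"[{a.s_start:.4g}, {a.s_end:.4g}] and "
                        f"[{b.s_start:.4g}, {b.s_end:.4g}] m"
                    )
        for name, (vname, s0, s1) in self.wall_segments.items():
            if vname not in names:
                raise ValidationError(
                    f"wall segment {name!r} references unknown vessel {vname!r}"
                )
            if not (0 <= s0 < s1):
                raise ValidationError(f"wall segment {name!r}: need 0 <= s0 < s1")
        for vname, s0, s1 in self.inflations:
            v = self.vessel(vname)
            if not (0.0 <= s0 < s1 <= v.length):
                raise ValidationError(
                    f"angioplasty interval [{s0:.4g}, {s1:.4g}] m outside "
                    f"vessel {vname!r} extent [0, {v.length:.4g}] m"
                )

    # -- structure ----------------------------------------------------------

    @property
    def inlet(self) -> VesselSpec:
        return self.vessels[0]

    @property
    def outlets(self) -> tuple[VesselSpec, VesselSpec]:
        return self.vessels[1], self.vessels[2]

    def vessel(self, name: str) -> VesselSpec:
        for v in self.vessels:
            if v.name == name:
                return v
        raise ValidationError(f"unknown vessel {name!r}")

    # -- centerline frame ---------------------------------------------------

    def centerline_origin(self, name: str) -> np.ndarray:
        if name == self.inlet.name:
            return np.array([-self.inlet.length, 0.0])
        return np.zeros(2)

    def centerline_direction(self, name: str) -> np.ndarray:
        v = self.vessel(name)
        return np.array([math.cos(v.angle), math.sin(v.angle)])

    def centerline_normal(self, name: str) -> np.ndarray:
        d = self.centerline_direction(name)
        return np.array([-d[1], d[0]])

    def centerline_point(self, name: str, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return (
            self.centerline_origin(name)[None, :]
            + s[:, None] * self.centerline_direction(name)[None, :]
        )

    def arclength_of(self, name: str, points: np.ndarray) -> np.ndarray:
        """Project points onto the vessel centerline; returns s (clamped)."""
        pts = np.atleast_2d(points)
        rel = pts - self.centerline_origin(name)[None, :]
        s = rel @ self.centerline_direction(name)
        return np.clip(s, 0.0, self.vessel(name).length)

    # -- width field --------------------------------------------------------

    def width(self, name: str, s) -> np.ndarray:
        """Local half-width of vessel ``name`` at arc length ``s`` (m)."""
        v = self.vessel(name)
        s = np.asarray(s, dtype=float)
        dev = np.zeros_like(s, dtype=float)
        for les in self.lesions:
            if les.vessel == name:
                dev = dev + les.width_deviation(s, v.nominal_radius)
        mask = np.ones_like(s, dtype=float)
        for vname, s0, s1 in self.inflations:
            if vname == name:
                mask = mask * (1.0 - _inflation_mask(s, s0, s1, self.blend_length))
        return v.nominal_radius + mask * dev

    def min_width(self) -> float:
        wmin = np.inf
        for v in self.vessels:
            s = np.linspace(0.0, v.length, 400)
            wmin = min(wmin, float(np.min(self.width(v.name, s))))
        return wmin

    # -- boundary polyline --------------------------------------------------

    def _wall_curve(self, name: str, side: int, n: int = 1200) -> np.ndarray:
        """Dense polyline of one wall: centerline + side * width * normal.

        ``side`` is +1 for the left wall (positive normal) and -1 for the
        right wall.  For daughters the curve is extended a little upstream of
        the junction origin (negative s at nominal width) so that
        junction-region intersections with the parent walls exist.
        """
        v = self.vessel(name)
        daughters = [x for x in self.vessels[1:]]
        margin = 2.0 * (
            self.inlet.nominal_radius + max(d.nominal_radius for d in daughters)
        )
        if name == self.inlet.name:
            s = np.linspace(0.0, v.length + margin, n)
        else:
            s = np.linspace(-margin, v.length, n)
        w = self.width(name, np.clip(s, 0.0, v.length))
        pts = (
            self.centerline_origin(name)[None, :]
            + s[:, None] * self.centerline_direction(name)[None, :]
            + (side * w)[:, None] * self.centerline_normal(name)[None, :]
        )
        return pts

    def boundary_pieces(self) -> list[dict]:
        """Closed CCW boundary as tagged pieces.

        Returns a list of dicts with keys ``points`` (polyline, consecutive
        pieces share endpoints), ``tag`` (``wall`` | ``inlet`` |
        ``outlet_<name>``) and, for wall pieces, ``vessel`` and ``side``.
        The junction trims wall curves at their pairwise intersections
        (parent/daughter outer walls; daughter/daughter apex).
        """
        from shapely.geometry import LineString

        inlet = self.inlet
        up = self.vessels[1] if self.vessels[1].angle > 0 else self.vessels[2]
        lo = self.vessels[2] if up is self.vessels[1] else self.vessels[1]

        def cut(curve_a, curve_b):
            la, lb = LineString(curve_a), LineString(curve_b)
            inter = la.intersection(lb)
            if inter.is_empty:
                raise GeometryError(
                    "junction walls do not intersect; check daughter angles "
                    "and widths near the bifurcation"
                )
            if inter.geom_type == "Point":
                p = np.array([inter.x, inter.y])
            else:
                geoms = getattr(inter, "geoms", [inter])
                pts = [g for g in geoms if g.geom_type == "Point"]
                if not pts:
                    raise GeometryError("degenerate junction wall intersection")
                p = np.array([pts[0].x, pts[0].y])
            return p

        def trim_after(curve, p):
            """Part of the dense curve from intersection point p to its end."""
            d = np.linalg.norm(curve - p[None, :], axis=1)
            i = int(np.argmin(d))
            return np.vstack([p, curve[i + 1 :]])

        def trim_before(curve, p):
            d = np.linalg.norm(curve - p[None, :], axis=1)
            i = int(np.argmin(d))
            return np.vstack([curve[:i], p])

        # wall curves (dense)
        cfa_left = self._wall_curve(inlet.name, +1)
        cfa_right = self._wall_curve(inlet.name, -1)
        up_left = self._wall_curve(up.name, +1)
        up_right = self._wall_curve(up.name, -1)
        lo_left = self._wall_curve(lo.name, +1)
        lo_right = self._wall_curve(lo.name, -1)

        p_outer_up = cut(cfa_left, up_left)  # parent left wall meets upper daughter
        p_outer_lo = cut(cfa_right, lo_right)
        p_apex = cut(up_right, lo_left)

        cfa_left_t = trim_before(cfa_left, p_outer_up)
        cfa_right_t = trim_before(cfa_right, p_outer_lo)
        up_left_t = trim_after(up_left, p_outer_up)
        up_right_t = trim_after(up_right, p_apex)
        lo_left_t = trim_after(lo_left, p_apex)
        lo_right_t = trim_after(lo_right, p_outer_lo)

        def cap(vname):
            v = self.vessel(vname)
            end = self.centerline_point(vname, v.length)[0]
            nrm = self.centerline_normal(vname)
            w = float(self.width(vname, v.length))
            return end - w * nrm, end + w * nrm  # (right corner, left corner)

        lo_cap_r, lo_cap_l = cap(lo.name)
        up_cap_r, up_cap_l = cap(up.name)
        in_r = np.array([-inlet.length, -float(self.width(inlet.name, 0.0))])
        in_l = np.array([-inlet.length, float(self.width(inlet.name, 0.0))])

        pieces = [
            dict(points=cfa_right_t, tag="wall", vessel=inlet.name, side=-1),
            dict(points=lo_right_t, tag="wall", vessel=lo.name, side=-1),
            dict(points=np.vstack([lo_cap_r, lo_cap_l]), tag=f"outlet_{lo.name}"),
            dict(points=lo_left_t[::-1], tag="wall", vessel=lo.name, side=+1),
            dict(points=up_right_t, tag="wall", vessel=up.name, side=-1),
            dict(points=np.vstack([up_cap_r, up_cap_l]), tag=f"outlet_{up.name}"),
            dict(points=up_left_t[::-1], tag="wall", vessel=up.name, side=+1),
            dict(points=cfa_left_t[::-1], tag="wall", vessel=inlet.name, side=+1),
            dict(points=np.vstack([in_l, in_r]), tag="inlet"),
        ]
        # snap shared endpoints exactly
        for a, b in zip(pieces, pieces[1:] + pieces[:1]):
            b["points"][0] = a["points"][-1]
        return pieces

    def segment_of(self, vessel: str, s: float) -> list[str]:
        """Names of all wall segments containing (vessel, s)."""
        out = []
        for name, (vname, s0, s1) in self.wall_segments.items():
            if vname == vessel and s0 <= s <= s1:
                out.append(name)
        return out


# -- construction and operators ----------------------------------------------


def build_geometry(spec: Mapping) -> BifurcationGeometry:
    """Build a validated geometry from a plain config mapping.

    Expected keys: ``vessels`` (list of {name, radius, length, angle_deg or
    angle}), optional ``lesions`` (list of {vessel, center_s, length, kind,
    severity}), optional ``endograft`` ({vessel, s_start, s_end}), optional
    ``wall_segments`` ({name: [vessel, s0, s1]}).  SI units; angles may be
    given in degrees via ``angle_deg``.
    """
    try:
        vessels = tuple(
            VesselSpec(
                name=v["name"],
                nominal_radius=float(v["radius"]),
                length=float(v["length"]),
                angle=float(
                    v.get("angle", math.radians(v.get("angle_deg", 0.0)))
                ),
            )
            for v in spec["vessels"]
        )
    except KeyError as exc:
        raise ValidationError(f"vessel config missing key {exc}") from exc
    lesions = tuple(
        LesionSpec(
            vessel=l["vessel"],
            center_s=float(l["center_s"]),
            length=float(l["length"]),
            kind=l.get("kind", "stenosis"),
            severity=float(l.get("severity", 0.5)),
            profile=l.get("profile", "cosine"),
        )
        for l in spec.get("lesions", [])
    )
    endo = spec.get("endograft")
    endograft_extent = None
    segments = {k: tuple(v) for k, v in spec.get("wall_segments", {}).items()}
    if endo is not None:
        endograft_extent = (
            endo["vessel"],
            float(endo["s_start"]),
            float(endo["s_end"]),
        )
        segments.setdefault(
            "endograft proximal edge",
            (
                endo["vessel"],
                max(0.0, float(endo["s_start"]) - 2e-3),
                float(endo["s_start"]) + 5e-3,
            ),
        )
    geom = BifurcationGeometry(
        vessels=vessels,
        lesions=lesions,
        endograft_extent=endograft_extent,
        wall_segments=segments,
        blend_length=float(spec.get("blend_length", DEFAULT_BLEND_LENGTH)),
    )
    if not segments:
        # default reporting segments
        inlet, (o1, o2) = geom.inlet, geom.outlets
        segments = {
            inlet.name: (inlet.name, 0.0, inlet.length),
            f"proximal {o1.name}": (o1.name, 0.0, min(0.03, o1.length)),
            f"proximal {o2.name}": (o2.name, 0.0, min(0.03, o2.length)),
        }
        geom = replace(geom, wall_segments=segments)
    return geom


def virtual_angioplasty(
    geom: BifurcationGeometry, vessel: str, s_interval: Sequence[float]
) -> BifurcationGeometry:
    """Restore an interval of a vessel to nominal caliber (cylindrical
    inflation) with C1 blends at the interval ends.

    Declarative and non-mutating: the interval is recorded on the returned
    geometry and masks lesion deviations there, so re-applying the same
    interval is a no-op (idempotent).
    """
    s0, s1 = float(s_interval[0]), float(s_interval[1])
    v = geom.vessel(vessel)
    if not (0.0 <= s0 < s1 <= v.length):
        raise ValidationError(
            f"angioplasty interval [{s0:.4g}, {s1:.4g}] m outside vessel "
            f"{vessel!r} extent [0, {v.length:.4g}] m"
        )
    entry = (vessel, s0, s1)
    if entry in geom.inflations:
        return geom
    return replace(geom, inflations=geom.inflations + (entry,))


# -- lubrication (locally-Poiseuille) oracle ----------------------------------


def lubrication_resistance(
    geom: BifurcationGeometry, vessel: str, mu: float, n: int = 2000
) -> float:
    """Viscous resistance of a vessel in the lubrication limit (per unit
    depth): R = int 3 mu / (2 w(s)^3) ds, so that dP = R q for per-depth
    flow q.  Exact for slowly varying width at vanishing Reynolds number."""
    v = geom.vessel(vessel)
    s = np.linspace(0.0, v.length, n)
    w = geom.width(vessel, s)
    return float(np.trapezoid(3.0 * mu / (2.0 * w**3), s))


def lubrication_inertance(
    geom: BifurcationGeometry, vessel: str, rho: float, n: int = 2000
) -> float:
    """Fluid inertance per unit depth: L = int rho / (2 w(s)) ds."""
    v = geom.vessel(vessel)
    s = np.linspace(0.0, v.length, n)
    w = geom.width(vessel, s)
    return float(np.trapezoid(rho / (2.0 * w), s))


def lubrication_pressure_drop(
    geom: BifurcationGeometry, vessel: str, q: float, mu: float
) -> float:
    """Steady Stokes pressure drop along one vessel at per-depth flow q."""
    return lubrication_resistance(geom, vessel, mu) * q
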