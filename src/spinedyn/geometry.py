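"""Idealized dendritic-spine geometries and axisymmetric meridian meshes.

The spine head is modeled as a shell between an outer membrane (plasma
membrane, PM) and an optional inner membrane (the spine-apparatus / ER
surface).  Four families are supported:

``sphere_shell``
    concentric spheres, outer radius ``R_o`` and inner radius ``R_i = rho*R_o``.
``oblate_shell``
    oblate spheroids: outer semi-axes ``(a_o, b_o=e_o*a_o)``, inner
    ``(a_i=rho*a_o, b_i=e_i*a_i)``.
``mushroom``
    the oblate shell with the intersection of a flat "cut" spheroid
    (centered at ``(0, b_o)`` with semi-axes ``(a_o, b_o/10)``) removed,
    which flattens the top of the head.
``sphere_solid``
    a solid sphere of radius ``R_o`` (no inner membrane); used for the
    anti-periodic influx/efflux analysis.

All domains are axisymmetric.  Meshing happens in the meridian half-plane
(r, z) with r >= 0 and the symmetry axis at r = 0; every volume or surface
integral downstream carries the 2*pi*r revolution weight.  Canonical units
are micrometers throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SpineGeometry",
    "BoundaryLayout",
    "MeshedDomain",
    "build_geometry",
    "mesh_axisymmetric",
    "characteristic_length",
    "cut_lens_volume",
]

_FAMILIES = ("sphere_shell", "oblate_shell", "mushroom", "sphere_solid")

# tags used on boundary facets of the meridian mesh
TAG_PM_INFLUX = "PM_influx"
TAG_PM_NECK = "PM_neck"
TAG_PM_EFFLUX = "PM_efflux"  # prescribed efflux cap (anti-periodic layout)
TAG_PM_INERT = "PM_inert"  # outer membrane with no flux
TAG_ER = "ER"
TAG_AXIS = "axis"


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent spine geometries."""


@dataclass(frozen=True)
class SpineGeometry:
    """A parametrized spine-head domain.

    Attributes
    ----------
    family : str
        One of ``sphere_shell``, ``oblate_shell``, ``mushroom``,
        ``sphere_solid``.
    R_o : float
        Outer radius / major semi-axis ``a_o`` in um.
    rho : float
        Inner/outer size ratio ``R_i/R_o`` (``a_i/a_o``); 0 for solid.
    e_i, e_o : float
        Inner and outer eccentricities (minor/major axis ratio), in (0, 1].
    """

    family: str
    R_o: float
    rho: float = 0.0
    e_i: float = 1.0
    e_o: float = 1.0

    # derived dimensions
    @property
    def a_o(self) -> float:
        return self.R_o

    @property
    def a_i(self) -> float:
        return self.rho * self.R_o

    @property
    def R_i(self) -> float:
        return self.rho * self.R_o

    @property
    def b_o(self) -> float:
        return self.e_o * self.a_o

    @property
    def b_i(self) -> float:
        return self.e_i * self.a_i

    @property
    def has_inner(self) -> bool:
        return self.family != "sphere_solid"

    # --- boundary radius along a ray from the origin -------------------
    def outer_radius(self, phi: np.ndarray) -> np.ndarray:
        """Distance from the origin to the outer boundary along polar angle phi."""
        phi = np.asarray(phi, dtype=float)
        t = _spheroid_ray(phi, self.a_o, self.b_o)
        if self.family == "mushroom":
            t_cut = _cut_ray(phi, self.a_o, self.b_o)
            t = np.where(np.isnan(t_cut), t, np.minimum(t, t_cut))
        return t

    def inner_radius(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        if not self.has_inner:
            return np.zeros_like(phi)
        return _spheroid_ray(phi, self.a_i, self.b_i)


def _spheroid_ray(phi: np.ndarray, a: float, b: float) -> np.ndarray:
    s, c = np.sin(phi), np.cos(phi)
    return 1.0 / np.sqrt((s / a) ** 2 + (c / b) ** 2)


def _cut_ray(phi: np.ndarray, a_o: float, b_o: float) -> np.ndarray:
    """Smallest positive ray parameter hitting the mushroom cut spheroid.

    The cut spheroid is centered at (0, b_o) with semi-axes (a_o, b_o/10).
    Returns NaN where the ray misses it.
    """
    s, c = np.sin(phi), np.cos(phi)
    b_c = b_o / 10.0
    A = (s / a_o) ** 2 + (c / b_c) ** 2
    B = -2.0 * c * b_o / b_c**2
    C = (b_o / b_c) ** 2 - 1.0
    disc = B * B - 4.0 * A * C
    with np.errstate(invalid="ignore"):
        sq = np.sqrt(disc)
        t = (-B - sq) / (2.0 * A)  # smaller root = lower surface of the cut
    t = np.where((disc >= 0.0) & (t > 0.0), t, np.nan)
    return t


def build_geometry(
    family: str,
    R_o: float,
    rho: float = 0.0,
    e_i: float = 1.0,
    e_o: float = 1.0,
) -> SpineGeometry:
    """Validate parameters and construct a :class:`SpineGeometry`.

    For the sphere families the eccentricities are forced to 1.  Shell
    families require ``0 < rho < 1`` with a strictly positive gap between
    the two membranes everywhere; the mushroom cut must not reach the
    inner spheroid.
    """
    if family not in _FAMILIES:
        raise GeometryError(
            f"unknown geometry family {family!r}; expected one of {_FAMILIES}"
        )
    if R_o <= 0:
        raise GeometryError(f"outer radius must be positive, got {R_o}")
    if family in ("sphere_shell", "sphere_solid"):
        e_i = e_o = 1.0
    if not (0.0 < e_o <= 1.0) or not (0.0 < e_i <= 1.0):
        raise GeometryError(f"eccentricities must lie in (0, 1], got e_i={e_i}, e_o={e_o}")

    if family == "sphere_solid":
        geom = SpineGeometry(family, R_o, 0.0, 1.0, 1.0)
        return geom

    if not (0.0 < rho < 1.0):
        raise GeometryError(
            f"shell families need 0 < rho < 1 (rho={rho}): rho >= 1 gives a "
            "zero-thickness or inverted shell"
        )
    geom = SpineGeometry(family, R_o, rho, e_i, e_o)
    # inner strictly inside outer: a_i < a_o holds by rho < 1; minor axes:
    if not geom.b_i < geom.b_o:
        raise GeometryError(
            f"inner spheroid not strictly inside outer: b_i={geom.b_i:.4g} >= "
            f"b_o={geom.b_o:.4g} (e_i*rho must be < e_o)"
        )
    if family == "mushroom":
        # cut floor on the axis sits at z = 0.9*b_o; the inner spheroid top
        # must stay below it, otherwise the cut removes the whole shell gap
        if geom.b_i >= 0.9 * geom.b_o:
            raise GeometryError(
                f"mushroom cut reaches the inner spheroid (b_i={geom.b_i:.4g} "
                f">= 0.9*b_o={0.9 * geom.b_o:.4g}); head would be severed"
            )
    # thickness check along a dense fan of rays; a gap below 1e-3*R_o
    # (sub-nanometer at physiological sizes) is treated as zero thickness
    phi = np.linspace(0.0, math.pi, 721)
    gap = geom.outer_radius(phi) - geom.inner_radius(phi)
    if np.nanmin(gap) <= 1e-3 * R_o:
        raise GeometryError(
            f"degenerate shell: minimum membrane gap {np.nanmin(gap):.3g} um "
            f"(rho={rho}, e_i={e_i}, e_o={e_o})"
        )
    return geom


def characteristic_length(rho: float, e_o: float, R_o: float) -> float:
    """Diffusion length scale of the shell, L = R_o*pi*sqrt((e_o^2+rho^2)/2).

    L approximates the semi-perimeter of the ellipse with semi-axes
    ``rho*R_o`` and ``e_o*R_o`` — the longest path a molecule must travel
    around the spine apparatus.  Used in the theoretical gradient lifetime
    ``L^2 / 6D``.
    """
    if not (0.0 <= rho <= 1.0 and 0.0 <= e_o <= 1.0):
        raise ValueError(f"rho and e_o must lie in [0, 1], got {rho}, {e_o}")
    return R_o * math.pi * math.sqrt((e_o**2 + rho**2) / 2.0)


@dataclass(frozen=True)
class BoundaryLayout:
    """Spatial localization of influx/efflux on the outer membrane.

    ``influx`` is one of:

    - ``"uniform"``: influx over the whole outer membrane, no neck outlet.
    - ``"uniform_minus_neck"``: influx everywhere except the neck cap.
    - ``"pole_cap"``: influx on a cap at the top pole (the PSD).
    - ``"side_leaf"``: influx on a band centered at ``center_polar_angle``.
    - ``"antiperiodic"``: prescribed influx on the top cap and an equal
      prescribed efflux on the antipodal cap (solid sphere analysis).

    The neck outlet is a cap of chord diameter ``neck_diameter`` at the
    bottom pole carrying the Robin efflux J_N = K_N * C; it is present for
    every layout except ``uniform`` and ``antiperiodic``.
    """

    influx: str = "uniform_minus_neck"
    cap_diameter: float = 0.2  # um, chord diameter of pole/side influx patch
    center_polar_angle: float = math.pi / 3  # side_leaf center
    phi0: Optional[float] = None  # antiperiodic cap half-angle, rad
    neck_diameter: float = 0.2  # um

    _KINDS = ("uniform", "uniform_minus_neck", "pole_cap", "side_leaf", "antiperiodic")

    def __post_init__(self):
        if self.influx not in self._KINDS:
            raise ValueError(
                f"unknown influx layout {self.influx!r}; expected one of {self._KINDS}"
            )
        if self.cap_diameter <= 0 or self.neck_diameter <= 0:
            raise ValueError("cap diameters must be positive")
        if self.influx == "antiperiodic":
            phi0 = self.phi0
            if phi0 is None or not (0.0 < phi0 < math.pi / 2):
                raise ValueError(
                    "antiperiodic layout needs 0 < phi0 < pi/2 (non-overlapping caps)"
                )

    @property
    def has_neck(self) -> bool:
        return self.influx in ("uniform_minus_neck", "pole_cap", "side_leaf")


@dataclass
class MeshedDomain:
    """Triangulated meridian half-plane with tagged boundary facets.

    Nodes are (r, z) coordinates; ``tris`` index into nodes with positive
    orientation.  ``facets`` are boundary segments (node pairs) with one tag
    each from {PM_influx, PM_efflux, PM_neck, PM_inert, ER, axis}.  Areas
    and volumes reported by the helper methods include the full 2*pi*r
    revolution weight.
    """

    geom: SpineGeometry
    layout: BoundaryLayout
    nodes: np.ndarray  # (n_nodes, 2): columns r, z
    tris: np.ndarray  # (n_tris, 3) int
    facets: np.ndarray  # (n_facets, 2) int
    facet_tags: np.ndarray  # (n_facets,) object/str
    h_min: float = 0.0
    h_max: float = 0.0

    def __post_init__(self):
        r = self.nodes[:, 0]
        if np.any(r < -1e-12):
            raise GeometryError("mesh node with negative r")
        areas = tri_areas(self.nodes, self.tris)
        if np.any(areas <= 0):
            raise GeometryError("inverted or degenerate mesh cell")
        edge = np.sqrt(areas)
        self.h_min = float(edge.min())
        self.h_max = float(edge.max())

    # --- quadrature helpers -------------------------------------------
    def cell_volumes(self) -> np.ndarray:
        """Revolved volume of each triangle, 2*pi*r_bar*A."""
        A = tri_areas(self.nodes, self.tris)
        r_bar = self.nodes[self.tris, 0].mean(axis=1)
        return 2.0 * math.pi * r_bar * A

    def volume(self) -> float:
        return float(self.cell_volumes().sum())

    def facet_lengths(self) -> np.ndarray:
        p = self.nodes[self.facets[:, 0]]
        q = self.nodes[self.facets[:, 1]]
        return np.linalg.norm(q - p, axis=1)

    def tagged_area(self, tag: str) -> float:
        """Revolved surface area of all facets with the given tag."""
        sel = self.facet_tags == tag
        p = self.nodes[self.facets[sel, 0]]
        q = self.nodes[self.facets[sel, 1]]
        ln = np.linalg.norm(q - p, axis=1)
        r_bar = 0.5 * (p[:, 0] + q[:, 0])
        return float((2.0 * math.pi * r_bar * ln).sum())

    def min_interior_angle(self) -> float:
        """Smallest interior angle over all triangles, radians."""
        pts = self.nodes[self.tris]
        ang = np.empty((len(self.tris), 3))
        for k in range(3):
            a = pts[:, (k + 1) % 3] - pts[:, k]
            b = pts[:, (k + 2) % 3] - pts[:, k]
            cosang = (a * b).sum(axis=1) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            ang[:, k] = np.arccos(np.clip(cosang, -1.0, 1.0))
        return float(ang.min())


def tri_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])


def _cap_polar_extent(geom: SpineGeometry, diameter: float, top: bool) -> float:
    """Polar-angle extent of a cap of given chord diameter at a pole.

    The cap rim is the circle of cylindrical radius ``diameter/2``; the
    returned angle is the polar angle of the rim point on the outer surface.
    """
    r_rim = diameter / 2.0
    if r_rim >= geom.a_o:
        raise GeometryError(
            f"cap diameter {diameter} um exceeds the head width {2 * geom.a_o} um"
        )
    lo, hi = (0.0, math.pi / 2) if top else (math.pi / 2, math.pi)
    # bisect on cylindrical radius along the outer boundary
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        r_mid = geom.outer_radius(np.array(mid)) * math.sin(mid)
        if top:
            lo, hi = (mid, hi) if r_mid < r_rim else (lo, mid)
        else:
            lo, hi = (lo, mid) if r_mid < r_rim else (mid, hi)
    return 0.5 * (lo + hi)


def mesh_axisymmetric(
    geom: SpineGeometry,
    layout: BoundaryLayout,
    n_s: int = 16,
    n_phi: int = 96,
    target_h: Optional[float] = None,
) -> MeshedDomain:
    """Build a structured triangulated mesh of the meridian half-plane.

    Nodes lie on rays from the origin at ``n_phi+1`` polar angles, with
    ``n_s+1`` points from the inner to the outer boundary per ray (all
    supported domains are star-shaped about the origin).  If ``target_h``
    is given it overrides ``n_s``/``n_phi`` so that both the thinnest gap
    and the outer arc are resolved at roughly that element size.
    """
    if target_h is not None:
        phi_probe = np.linspace(0.0, math.pi, 721)
        gap = geom.outer_radius(phi_probe) - geom.inner_radius(phi_probe)
        if target_h >= np.nanmin(gap):
            raise GeometryError(
                f"target_h={target_h} um does not resolve the thinnest shell "
                f"gap ({np.nanmin(gap):.4g} um)"
            )
        arc = math.pi * geom.R_o  # upper bound on the outer half-meridian
        n_s = max(4, int(math.ceil(np.nanmin(gap) / target_h)) + 2)
        n_phi = max(16, int(math.ceil(arc / target_h)))

    phi = np.linspace(0.0, math.pi, n_phi + 1)
    R_out = geom.outer_radius(phi)
    R_in = geom.inner_radius(phi)
    s = np.linspace(0.0, 1.0, n_s + 1)

    solid = not geom.has_inner
    nodes = []
    index = np.empty((n_s + 1, n_phi + 1), dtype=int)
    if solid:
        nodes.append((0.0, 0.0))  # single collapsed center node
    for i in range(n_s + 1):
        for j in range(n_phi + 1):
            if solid and i == 0:
                index[i, j] = 0
                continue
            rad = R_in[j] + s[i] * (R_out[j] - R_in[j])
            r = rad * math.sin(phi[j])
            z = rad * math.cos(phi[j])
            if j in (0, n_phi):
                r = 0.0  # snap to the symmetry axis
            index[i, j] = len(nodes)
            nodes.append((r, z))
    nodes = np.asarray(nodes, dtype=float)

    tris = []
    for i in range(n_s):
        for j in range(n_phi):
            n00, n01 = index[i, j], index[i, j + 1]
            n10, n11 = index[i + 1, j], index[i + 1, j + 1]
            for tri in ((n00, n10, n11), (n00, n11, n01)):
                if len(set(tri)) < 3:
                    continue
                p = nodes[list(tri)]
                a2 = (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1]) - (
                    p[1, 1] - p[0, 1]
                ) * (p[2, 0] - p[0, 0])
                if abs(a2) < 1e-16:
                    continue
                tris.append(tri if a2 > 0 else (tri[0], tri[2], tri[1]))
    tris = np.asarray(tris, dtype=int)

    # --- boundary facets ----------------------------------------------
    facets, tags = [], []
    # outer boundary (i = n_s), tag by layout
    outer_tagger = _make_outer_tagger(geom, layout)
    for j in range(n_phi):
        a, b = index[n_s, j], index[n_s, j + 1]
        phim = 0.5 * (phi[j] + phi[j + 1])
        facets.append((a, b))
        tags.append(outer_tagger(phim))
    # inner boundary (i = 0) for shells
    if not solid:
        for j in range(n_phi):
            facets.append((index[0, j], index[0, j + 1]))
            tags.append(TAG_ER)
    # axis facets: radial edges at phi = 0 and phi = pi (r = 0)
    for j in (0, n_phi):
        for i in range(n_s):
            a, b = index[i, j], index[i + 1, j]
            if a == b:
                continue
            facets.append((a, b))
            tags.append(TAG_AXIS)
    facets = np.asarray(facets, dtype=int)
    tags = np.asarray(tags, dtype=object)

    return MeshedDomain(geom, layout, nodes, tris, facets, tags)


def _make_outer_tagger(geom: SpineGeometry, layout: BoundaryLayout):
    """Return a function mapping a facet-midpoint polar angle to a tag."""
    kind = layout.influx
    if kind == "uniform":
        return lambda phim: TAG_PM_INFLUX

    if kind == "antiperiodic":
        phi0 = layout.phi0

        def tagger(phim):
            if phim <= phi0:
                return TAG_PM_INFLUX
            if phim >= math.pi - phi0:
                return TAG_PM_EFFLUX
            return TAG_PM_INERT

        return tagger

    phi_neck = _cap_polar_extent(geom, layout.neck_diameter, top=False)
    if kind == "uniform_minus_neck":
        return lambda phim: TAG_PM_NECK if phim >= phi_neck else TAG_PM_INFLUX

    if kind == "pole_cap":
        phi_cap = _cap_polar_extent(geom, layout.cap_diameter, top=True)
        if phi_cap >= phi_neck:
            raise GeometryError("pole influx cap overlaps the neck outlet")

        def tagger(phim):
            if phim <= phi_cap:
                return TAG_PM_INFLUX
            if phim >= phi_neck:
                return TAG_PM_NECK
            return TAG_PM_INERT

        return tagger

    # side_leaf: band centered at center_polar_angle with meridian arc
    # length equal to cap_diameter
    phi_dense = np.linspace(0.0, math.pi, 4001)
    pts_r = geom.outer_radius(phi_dense) * np.sin(phi_dense)
    pts_z = geom.outer_radius(phi_dense) * np.cos(phi_dense)
    seg = np.hypot(np.diff(pts_r), np.diff(pts_z))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s_c = float(np.interp(layout.center_polar_angle, phi_dense, arc))
    lo_s, hi_s = s_c - layout.cap_diameter / 2, s_c + layout.cap_diameter / 2
    phi_lo = float(np.interp(lo_s, arc, phi_dense))
    phi_hi = float(np.interp(hi_s, arc, phi_dense))
    if phi_hi >= phi_neck:
        raise GeometryError("side influx patch overlaps the neck outlet")

    def tagger(phim):
        if phi_lo <= phim <= phi_hi:
            return TAG_PM_INFLUX
        if phim >= phi_neck:
            return TAG_PM_NECK
        return TAG_PM_INERT

    return tagger


def cut_lens_volume(geom: SpineGeometry, n: int = 20000) -> float:
    """Revolved volume of the lens removed by the mushroom cut.

    Integrates 2*pi*r*(z_outer - z_cut_lower) over the cylindrical radii
    where the cut spheroid dips below the outer spheroid surface.
    """
    a, b = geom.a_o, geom.b_o
    b_c = b / 10.0
    # rim: z_outer(r) = z_cut_lower(r)  ->  sqrt(1-u^2)*(1+1/10) = 1
    u_rim = math.sqrt(1.0 - (10.0 / 11.0) ** 2)
    r = np.linspace(0.0, u_rim * a, n)
    u = r / a
    z_outer = b * np.sqrt(1.0 - u**2)
    z_cut = b - b_c * np.sqrt(1.0 - u**2)
    dz = np.clip(z_outer - z_cut, 0.0, None)
    return float(np.trapezoid(2.0 * math.pi * r * dz, r))
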