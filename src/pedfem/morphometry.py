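"""Simulated-radiograph morphometry.

Seven alignment parameters are measured on orthographic projections of the
(optionally deformed) bone surfaces, emulating weight-bearing radiographs:

* antero-posterior (AP) view — beam perpendicular to the XY plane tilted
  15 degrees proximally about the X axis: M1M5 (first-fifth intermetatarsal
  angle), APTM (AP talar - first metatarsal angle), TNC (talonavicular
  coverage angle);
* lateral view — beam perpendicular to the YZ plane, viewed from medial:
  LTM (lateral talar - first metatarsal angle, Meary; negative with arch
  collapse), CP (calcaneal pitch), TC (talocalcaneal angle);
* C5MH — vertical distance between the lowest point of the medial
  cuneiform and the lowest point of the fifth metatarsal, taken directly
  from the 3-D deformed configuration (mm).

Long-bone axes (metatarsals) are principal axes of the projected outline's
area moments; talar and calcaneal axes use the generator's planted axis
landmarks (a declared surrogate for the radiographic protocols), measured
after projection into the view plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .mesh import boundary_faces

__all__ = [
    "ProjectionView",
    "MorphoReport",
    "ap_view",
    "lateral_view",
    "project_silhouette",
    "bone_axis_2d",
    "measure_radiographic",
]


@dataclass(frozen=True)
class ProjectionView:
    """Orthographic view: beam ``direction`` and two in-plane basis axes."""

    name: str
    direction: np.ndarray
    plane_basis: np.ndarray       # (2, 3), orthonormal, both ⟂ direction

    def project(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.plane_basis.T


def ap_view(tilt_deg: float = 15.0) -> ProjectionView:
    """Dorsoplantar beam tilted ``tilt_deg`` proximally about the X axis."""
    th = math.radians(tilt_deg)
    d = np.array([0.0, -math.sin(th), -math.cos(th)])
    e1 = np.array([1.0, 0.0, 0.0])                       # medial
    e2 = np.cross(d, e1)
    e2 /= np.linalg.norm(e2)                             # ~anterior
    if e2[1] < 0:
        e2 = -e2
    return ProjectionView("AP", d, np.stack([e1, e2]))


def lateral_view() -> ProjectionView:
    """Beam along X, viewed from the medial side; axes (anterior, up)."""
    return ProjectionView(
        "lateral",
        np.array([-1.0, 0.0, 0.0]),
        np.stack([np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])]),
    )


def project_silhouette(model, view: ProjectionView, bones=None,
                       displacements=None) -> dict[str, Polygon]:
    """2-D outline polygon of each bone's projected boundary surface."""
    nodes = model.nodes if displacements is None else \
        model.nodes + displacements
    out = {}
    names = bones if bones is not None else [
        b for b in model.tet_sets if b not in ("cartilage", "soft_tissue")]
    for name in names:
        ids = model.tet_sets[name]
        if len(ids) == 0:
            raise ValueError(f"bone '{name}' has no elements")
        faces = boundary_faces(model.tets[ids])
        p2 = view.project(nodes)
        tris = p2[faces]
        polys = [Polygon(t) for t in tris]
        polys = [p if p.is_valid else p.buffer(0) for p in polys]
        merged = unary_union(polys)
        if merged.geom_type == "MultiPolygon":
            merged = max(merged.geoms, key=lambda g: g.area)
        out[name] = merged
    return out


def _polygon_moments(poly: Polygon):
    """Area, centroid and central second moments by Green's theorem."""
    x, y = np.asarray(poly.exterior.coords.xy)
    x0, x1 = x[:-1], x[1:]
    y0, y1 = y[:-1], y[1:]
    cross = x0 * y1 - x1 * y0
    A = cross.sum() / 2.0
    cx = ((x0 + x1) * cross).sum() / (6.0 * A)
    cy = ((y0 + y1) * cross).sum() / (6.0 * A)
    Ixx = ((y0 ** 2 + y0 * y1 + y1 ** 2) * cross).sum() / 12.0
    Iyy = ((x0 ** 2 + x0 * x1 + x1 ** 2) * cross).sum() / 12.0
    Ixy = ((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross).sum() / 24.0
    # central moments
    Ixx -= A * cy ** 2
    Iyy -= A * cx ** 2
    Ixy -= A * cx * cy
    return A, (cx, cy), np.array([[Iyy, -Ixy], [-Ixy, Ixx]])


def bone_axis_2d(outline: Polygon, orient_hint=None) -> np.ndarray:
    """Principal long axis (unit 2-vector) of an outline's area moments.

    ``orient_hint`` flips the axis so that it points proximal -> distal
    (positive dot product with the hint).
    """
    if outline.is_empty or len(outline.exterior.coords) < 4:
        raise ValueError("degenerate outline polygon")
    A, _, M = _polygon_moments(outline)
    if abs(A) < 1e-12:
        raise ValueError("degenerate outline polygon (zero area)")
    # M is the inertia tensor [[Iyy, -Ixy], [-Ixy, Ixx]]; the covariance
    # (second-moment) form is [[<x^2>, <xy>], [<xy>, <y^2>]].  Signed area
    # keeps the form positive regardless of ring orientation.
    cov = np.array([[M[0, 0], -M[0, 1]], [-M[0, 1], M[1, 1]]]) / A
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    if orient_hint is not None and float(np.dot(axis, orient_hint)) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


@dataclass(frozen=True)
class MorphoReport:
    """Seven radiographic alignment parameters (degrees; C5MH in mm)."""

    M1M5: float
    APTM: float
    TNC: float
    LTM: float
    CP: float
    TC: float
    C5MH: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("M1M5", "APTM", "TNC", "LTM", "CP", "TC", "C5MH")}


def _signed_angle(a: np.ndarray, b: np.ndarray) -> float:
    """CCW angle (degrees) from a to b in the projection plane."""
    return math.degrees(math.atan2(
        a[0] * b[1] - a[1] * b[0], float(np.dot(a, b))))


def _decl(axis_2d: np.ndarray) -> float:
    """Declination (degrees, plunging-anterior positive) of a lateral-view
    axis oriented toward anterior; lateral coords are (anterior, up)."""
    return math.degrees(math.atan2(-axis_2d[1], axis_2d[0]))


def _landmark_pos(model, disp, name):
    """Deformed position of a landmark: the analytic point carried by the
    displacement of its bound mesh node (avoids voxel snapping bias)."""
    p = model.landmark_points[name]
    if disp is None:
        return p
    return p + disp[model.landmarks[name]]


def _landmark_axis(model, disp, view, a_name, b_name):
    a = _landmark_pos(model, disp, a_name)
    b = _landmark_pos(model, disp, b_name)
    v = view.project(b[None])[0] - view.project(a[None])[0]
    return v / np.linalg.norm(v)


def measure_radiographic(model, result=None) -> MorphoReport:
    """Measure the seven alignment parameters on a (deformed) foot model.

    Left feet are mirrored to the right-foot convention before measuring.
    Raises ``KeyError`` naming the missing bone if a required element set
    is absent.
    """
    disp = None if result is None else result.displacements
    work = model
    if model.params.side == "left":
        work = model.mirrored()
        if disp is not None:
            disp = disp * np.array([-1.0, 1.0, 1.0])
    nodes = work.nodes if disp is None else work.nodes + disp

    for bone in ("metatarsal_1", "metatarsal_5", "talus", "calcaneus",
                 "cuneiform_1", "navicular"):
        if bone not in work.tet_sets:
            raise KeyError(f"cannot measure alignment: bone '{bone}' missing")

    apv = ap_view()
    latv = lateral_view()

    sil_ap = project_silhouette(
        work, apv, bones=["metatarsal_1", "metatarsal_5"], displacements=disp)
    m1_ap = bone_axis_2d(sil_ap["metatarsal_1"], orient_hint=(0.0, 1.0))
    m5_ap = bone_axis_2d(sil_ap["metatarsal_5"], orient_hint=(0.0, 1.0))
    talus_ap = _landmark_axis(work, disp, apv,
                              "talus_body_center", "talus_head_center")

    M1M5 = abs(_signed_angle(m5_ap, m1_ap))
    # medial-deviation positive: +u is medial, axes oriented anterior (+v)
    ang = lambda a: math.degrees(math.atan2(a[0], a[1]))
    APTM = ang(talus_ap) - ang(m1_ap)

    head_chord = _landmark_axis(work, disp, apv,
                                "talar_head_chord_lateral",
                                "talar_head_chord_medial")
    nav_chord = _landmark_axis(work, disp, apv,
                               "navicular_chord_lateral",
                               "navicular_chord_medial")
    TNC = _signed_angle(head_chord, nav_chord)

    lat_bones = ["metatarsal_1"]
    sil_lat = project_silhouette(work, latv, bones=lat_bones,
                                 displacements=disp)
    m1_lat = bone_axis_2d(sil_lat["metatarsal_1"], orient_hint=(1.0, 0.0))
    talus_lat = _landmark_axis(work, disp, latv,
                               "talus_body_center", "talus_head_center")
    calc_lat = _landmark_axis(work, disp, latv,
                              "calcaneus_axis_posterior",
                              "calcaneus_axis_anterior")
    LTM = _decl(m1_lat) - _decl(talus_lat)
    TC = _decl(talus_lat) - _decl(calc_lat)

    CP = _calcaneal_pitch(work, latv, disp)

    c1 = nodes[work.bone_nodes("cuneiform_1")]
    m5 = nodes[work.bone_nodes("metatarsal_5")]
    C5MH = float(c1[:, 2].min() - m5[:, 2].min())

    return MorphoReport(M1M5=float(M1M5), APTM=float(APTM), TNC=float(TNC),
                        LTM=float(LTM), CP=float(CP), TC=float(TC),
                        C5MH=C5MH)


def plot_overlay(model, path, result=None, view: str = "lateral",
                 bones=("calcaneus", "talus", "metatarsal_1")) -> None:
    """Audit plot: projected bone outlines with measured axes, as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = lateral_view() if view == "lateral" else ap_view()
    disp = None if result is None else result.displacements
    sil = project_silhouette(model, v, bones=list(bones),
                             displacements=disp)
    fig, ax = plt.subplots(figsize=(7, 5))
    for name, poly in sil.items():
        x, y = poly.exterior.xy
        ax.plot(x, y, lw=1.2, label=name)
        try:
            axis = bone_axis_2d(poly, orient_hint=(1.0, 0.0))
            c = np.array(poly.centroid.coords[0])
            seg = np.array([c - 30 * axis, c + 30 * axis])
            ax.plot(seg[:, 0], seg[:, 1], "--", lw=0.8)
        except ValueError:
            pass
    ax.set_aspect("equal")
    ax.legend(fontsize=7)
    ax.set_title(f"{v.name} view outlines")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _calcaneal_pitch(model, latv, disp) -> float:
    """Inferior calcaneal tangent vs the ground line, lateral view."""
    sets = [model.tet_sets["calcaneus"]]
    if "calcaneus_posterior" in model.tet_sets:
        sets.append(model.tet_sets["calcaneus_posterior"])
    ids = np.concatenate(sets)
    nodes = model.nodes if disp is None else model.nodes + disp
    pts = latv.project(nodes[np.unique(model.tets[ids])])
    hull = shapely.MultiPoint(pts).convex_hull
    hx, hy = np.asarray(hull.exterior.coords.xy)
    u0, u1 = hx.min(), hx.max()
    post = hx < u0 + 0.35 * (u1 - u0)
    ant = hx > u0 + 0.6 * (u1 - u0)
    p_post = np.array([hx[post][np.argmin(hy[post])],
                       hy[post][np.argmin(hy[post])]])
    p_ant = np.array([hx[ant][np.argmin(hy[ant])],
                      hy[ant][np.argmin(hy[ant])]])
    v = p_ant - p_post
    return math.degrees(math.atan2(v[1], v[0]))
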