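"""Parametric synthetic flatfoot generator.

A right foot is built from lofted convex primitives (capsules/ellipsoids)
for 15 bone solids (tibia, fibula, talus, calcaneus, navicular, cuboid,
three cuneiforms, five metatarsals, two toe blocks), embedded in a
soft-tissue envelope over a hex-meshed ground slab.  Everything is meshed
on a single conforming voxel grid (six tets per cube), so bones, joint
cartilage and soft tissue share interface nodes.  Ligaments and the plantar
fascia are two-node trusses bound to named landmark nodes.

Anatomical fidelity is *not* the goal: the generator only guarantees that
the morphometric landmarks, articular facets, ligament attachments and the
plantar footprint exist and respond to the single ``severity`` parameter,
which collapses the medial longitudinal arch: calcaneal pitch falls, the
talar axis plunges (Meary's angle goes negative), the navicular subluxes
laterally and the forefoot abducts as severity rises from 0 (normal arch)
to 1 (severe flatfoot).

Frame convention: Z up from the sole, ground top at Z = 0, +X medial and
+Y anterior (right-foot convention); left feet are produced by mirroring X.
Units mm / N / MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import (
    boundary_faces,
    fix_nonmanifold_mask,
    largest_component,
    prune_nonmanifold_mask,
    surface_is_closed,
    tets_from_voxels,
    TetMesh,
)

__all__ = [
    "FootParams",
    "FootModel",
    "TrussTable",
    "MeshingError",
    "generate_foot",
    "attach_trusses",
    "default_ligament_table",
    "BONE_NAMES",
]

BONE_NAMES = [
    "tibia", "fibula", "talus", "calcaneus", "navicular", "cuboid",
    "cuneiform_1", "cuneiform_2", "cuneiform_3",
    "metatarsal_1", "metatarsal_2", "metatarsal_3", "metatarsal_4",
    "metatarsal_5", "toes_hallux", "toes_lesser",
]

#: default truss table: (name, tissue class, origin landmark, insertion landmark)
DEFAULT_LIGAMENTS = [
    # slip 1 inserts on the hallux block (own bone); slips 2-5 insert on
    # their metatarsal heads so each ray carries its slip independently
    ("plantar_fascia_1", "fascia", "calcaneal_tuberosity_plantar", "toe_plantar_1"),
    ("plantar_fascia_2", "fascia", "calcaneal_tuberosity_plantar", "metatarsal_2_head_plantar"),
    ("plantar_fascia_3", "fascia", "calcaneal_tuberosity_plantar", "metatarsal_3_head_plantar"),
    ("plantar_fascia_4", "fascia", "calcaneal_tuberosity_plantar", "metatarsal_4_head_plantar"),
    ("plantar_fascia_5", "fascia", "calcaneal_tuberosity_plantar", "metatarsal_5_head_plantar"),
    ("spring_ligament", "ligament", "sustentaculum", "navicular_plantar"),
    ("long_plantar", "ligament", "calcaneus_plantar_anterior", "metatarsal_5_base_plantar"),
    ("short_plantar", "ligament", "calcaneus_plantar_anterior", "cuboid_plantar"),
    ("deltoid_tibiocalcaneal", "ligament", "medial_malleolus", "sustentaculum"),
    ("deltoid_tibiotalar", "ligament", "medial_malleolus", "talus_medial"),
    ("deltoid_tibionavicular", "ligament", "medial_malleolus", "navicular_medial"),
    ("calcaneofibular", "ligament", "lateral_malleolus", "cfl_insertion"),
    ("anterior_talofibular", "ligament", "lateral_malleolus", "talus_lateral"),
    ("interosseous_talocalcaneal", "ligament", "talus_inferior", "calcaneus_superior_mid"),
]

LIGAMENT_AREA = 18.4   # mm^2, cross-section of every ligament truss
FASCIA_AREA = 58.6     # mm^2, cross-section of every plantar-fascia truss

_TEMPLATE_LENGTH = 240.0
_TEMPLATE_WIDTH = 92.0


class MeshingError(RuntimeError):
    """Raised when a bone cannot be meshed into a watertight solid."""


@dataclass(frozen=True)
class FootParams:
    """Generator inputs; ``severity`` in [0, 1] collapses the arch."""

    body_weight: float = 600.0
    severity: float = 0.5
    foot_length: float = 250.0
    foot_width: float = 95.0
    mesh_size: float = 6.5
    side: str = "right"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.foot_length <= 0 or self.foot_width <= 0:
            raise ValueError("foot dimensions must be positive")
        if self.mesh_size <= 0:
            raise ValueError("mesh_size must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass
class TrussTable:
    """Ligament / fascia truss elements bound to mesh nodes."""

    names: list[str] = field(default_factory=list)
    tissue_class: list[str] = field(default_factory=list)
    conn: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    area: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class FootModel:
    """A meshed foot over a ground slab, ready for assembly and solving."""

    params: FootParams
    nodes: np.ndarray                       # all nodes (foot grid + ground)
    tets: np.ndarray                        # foot tets
    tet_sets: dict[str, np.ndarray]         # bone / cartilage / soft_tissue
    ground_hexes: np.ndarray
    ground_top_tris: np.ndarray
    ground_base_nodes: np.ndarray
    trusses: TrussTable
    landmarks: dict[str, int]               # node ids
    landmark_points: dict[str, np.ndarray]  # analytic positions
    facet_sets: dict[str, np.ndarray]       # articular element sets
    contact_pairs: list[dict]
    meta: dict

    # -- convenience -----------------------------------------------------

    def bone_mesh(self, name: str) -> TetMesh:
        """Standalone compact tet mesh of one bone (or element set)."""
        ids = self.tet_sets[name]
        tets = self.tets[ids]
        used, inv = np.unique(tets, return_inverse=True)
        return TetMesh(self.nodes[used].copy(), inv.reshape(-1, 4))

    def bone_nodes(self, name: str) -> np.ndarray:
        return np.unique(self.tets[self.tet_sets[name]])

    def mirrored(self) -> "FootModel":
        """Mirror across the YZ plane (right <-> left)."""
        nodes = self.nodes.copy()
        nodes[:, 0] = -nodes[:, 0]
        tets = self.tets[:, [0, 2, 1, 3]].copy()
        gh = self.ground_hexes[:, [3, 2, 1, 0, 7, 6, 5, 4]].copy()
        gt = self.ground_top_tris[:, [0, 2, 1]].copy()
        lp = {k: v * np.array([-1.0, 1.0, 1.0]) for k, v in
              self.landmark_points.items()}
        side = "left" if self.params.side == "right" else "right"
        return FootModel(
            params=replace(self.params, side=side),
            nodes=nodes,
            tets=tets,
            tet_sets=self.tet_sets,
            ground_hexes=gh,
            ground_top_tris=gt,
            ground_base_nodes=self.ground_base_nodes,
            trusses=self.trusses,
            landmarks=self.landmarks,
            landmark_points=lp,
            facet_sets=self.facet_sets,
            contact_pairs=self.contact_pairs,
            meta=dict(self.meta, mirrored=not self.meta.get("mirrored", False)),
        )

    def export(self, directory) -> None:
        """Write bones + soft tissue as ASCII STL, full model as VTU, and
        the ligament table as CSV."""
        from pathlib import Path

        import pandas as pd

        from .meshio_lite import write_stl, write_vtu

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in list(self.tet_sets):
            m = self.bone_mesh(name)
            write_stl(d / f"{name}.stl", m.nodes, m.boundary())
        labels = np.zeros(len(self.tets), dtype=np.int64)
        for i, name in enumerate(sorted(self.tet_sets)):
            labels[self.tet_sets[name]] = i
        write_vtu(
            d / "model.vtu", self.nodes,
            [("tetra", self.tets), ("hexahedron", self.ground_hexes)],
            cell_data={"element_set": np.concatenate(
                [labels, np.full(len(self.ground_hexes), -1)])},
        )
        pd.DataFrame({
            "name": self.trusses.names,
            "class": self.trusses.tissue_class,
            "node_origin": self.trusses.conn[:, 0] if len(self.trusses.conn) else [],
            "node_insertion": self.trusses.conn[:, 1] if len(self.trusses.conn) else [],
            "area_mm2": self.trusses.area,
        }).to_csv(d / "ligaments.csv", index=False)


# ---------------------------------------------------------------------------
# implicit primitives


def _capsule(pts, a, b, r0, r1):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    L2 = float(ab @ ab)
    t = np.clip(((pts - a) @ ab) / max(L2, 1e-12), 0.0, 1.0)
    closest = a + t[:, None] * ab
    d = np.linalg.norm(pts - closest, axis=1)
    return d - (r0 + t * (r1 - r0))


def _ellipsoid(pts, c, radii):
    c = np.asarray(c, float)
    radii = np.asarray(radii, float)
    q = (pts - c) / radii
    return (np.linalg.norm(q, axis=1) - 1.0) * radii.min()


def _bone_phi(pts, prims):
    phi = np.full(len(pts), np.inf)
    for p in prims:
        if p[0] == "capsule":
            phi = np.minimum(phi, _capsule(pts, p[1], p[2], p[3], p[4]))
        else:
            phi = np.minimum(phi, _ellipsoid(pts, p[1], p[2]))
    return phi


# ---------------------------------------------------------------------------
# skeleton template


def _skeleton(params: FootParams, rng: np.random.Generator):
    """Template bone primitives, landmarks and planted morphometry.

    Returns everything in template coordinates (length 240, width 92);
    the caller rescales to the requested foot size.
    """
    s = params.severity
    jit = rng.normal(0.0, 1.0, size=8)

    # per-subject anatomic variation is drawn once per seed; the spreads
    # approximate the between-patient dispersion of a flatfoot cohort
    cp_deg = 22.0 - 14.0 * s + 2.5 * jit[0]          # planted calcaneal pitch
    cp = math.radians(cp_deg)
    decl_t_deg = 25.0 + 7.0 * s + 1.5 * jit[1]       # talar axis declination
    decl_t = math.radians(decl_t_deg)
    fore_shift = -6.0 * s + 0.8 * jit[2]             # forefoot abduction (lateral)
    tnc_planted = 3.0 + 10.0 * s + 4.0 * jit[3]

    bones: dict[str, list] = {}

    # calcaneus: body along the pitched inferior axis + posterior tuberosity
    cal_a = np.array([0.0, 22.0, 18.0])
    cal_b = np.array([0.0, 88.0, 18.0 + 66.0 * math.tan(cp)])
    bones["calcaneus"] = [
        ("capsule", cal_a, cal_b, 11.0, 11.0),
        ("capsule", (0.0, 20.0, 21.0), (0.0, 23.0, 36.0), 9.5, 9.5),
    ]

    def calc_axis_z(y):
        return 18.0 + (y - 22.0) * math.tan(cp)

    calc_top = calc_axis_z(70.0) + 11.0
    tz = calc_top + 2.5 + 9.0                        # talar body centre height
    head_x = 3.0 + 12.0 * s + 0.5 * jit[4]
    head_y = 94.0
    head_z = tz - 24.0 * math.tan(decl_t)
    bones["talus"] = [
        ("ellipsoid", (1.0, 70.0, tz), (13.0, 15.0, 9.5)),
        ("capsule", (1.0, 74.0, tz), (head_x, head_y, head_z), 9.5, 8.5),
    ]

    z_pl = tz + 9.5 + 2.5                            # tibial plafond level
    bones["tibia"] = [
        ("capsule", (0.0, 68.0, z_pl + 13.0), (0.0, 70.0, 125.0), 13.0, 13.0),
    ]
    bones["fibula"] = [
        ("capsule", (-24.0, 66.0, z_pl + 1.0), (-21.0, 68.0, 122.0), 6.5, 6.5),
    ]

    # anterior process of the calcaneus toward the calcaneocuboid joint,
    # kept just above the inferior tangent line so it never drives CP
    proc_z = calc_axis_z(96.0)
    bones["calcaneus"].append(
        ("capsule", (0.0, 80.0, calc_axis_z(80.0)), (-12.0, 96.0, proc_z),
         9.5, 9.5))

    nav_x = head_x + 1.0 - 4.0 * s
    nav_y = head_y + 14.0
    nav_z = head_z - 14.0 * math.tan(0.8 * decl_t)
    bones["navicular"] = [("ellipsoid", (nav_x, nav_y, nav_z), (11.0, 7.0, 8.5))]
    cub_z = 19.0 - 1.5 * s
    bones["cuboid"] = [("ellipsoid", (-20.0, 104.0, cub_z), (9.0, 12.0, 8.5))]

    c1 = np.array([16.0, 125.0, nav_z - 5.0])
    bones["cuneiform_1"] = [("ellipsoid", c1, (7.0, 9.0, 9.0))]
    bones["cuneiform_2"] = [
        ("ellipsoid", (0.0, 125.0, nav_z - 4.0), (6.5, 9.0, 8.0))]
    bones["cuneiform_3"] = [
        ("ellipsoid", (-13.0, 125.0, nav_z - 4.5), (5.5, 9.0, 8.0))]

    met = {
        1: ((13.0, 142.0, c1[2] - 1.0),
            (33.0 + fore_shift + 2.8 * jit[6], 188.0, 13.0), 6.5, 7.5),
        2: ((0.0, 142.0, nav_z - 5.0), (8.0 + fore_shift, 190.0, 12.0), 5.4, 6.0),
        3: ((-12.0, 142.0, nav_z - 5.5), (-4.0 + 0.6 * fore_shift, 188.0, 12.0), 5.2, 5.6),
        4: ((-20.0, 122.0, 18.5), (-22.0 + 0.5 * fore_shift, 184.0, 12.0), 5.6, 5.8),
        5: ((-26.0, 120.0, 19.0),
            (-34.0 + 0.4 * fore_shift - 2.8 * jit[5], 180.0, 15.0), 5.4, 5.8),
    }
    for i, (b, h, r0, r1) in met.items():
        bones[f"metatarsal_{i}"] = [("capsule", b, h, r0, r1)]

    m1h = np.array(met[1][1])
    m2h = np.array(met[2][1])
    m5h = np.array(met[5][1])
    bones["toes_hallux"] = [
        ("capsule", (m1h[0] + 1.0, 204.0, 11.5), (m1h[0] + 2.0, 220.0, 11.0), 7.5, 7.0)]
    bones["toes_lesser"] = [
        ("capsule", (m2h[0] + 1.0, 203.0, 11.0), (m5h[0] - 1.0, 192.0, 11.0), 6.5, 5.5)]

    # ---- landmarks (bone, analytic point) -------------------------------
    m1b = np.array(met[1][0])
    m5b = np.array(met[5][0])
    lm = {
        "achilles_insertion": ("calcaneus", (0.0, 13.0, 32.0)),
        "cfl_insertion": ("calcaneus", (-10.0, 55.0, calc_axis_z(55.0) + 8.0)),
        "calcaneal_tuberosity_plantar": ("calcaneus", (0.0, 26.0, 8.0)),
        "sustentaculum": ("calcaneus", (10.0, 80.0, calc_axis_z(80.0) + 6.0)),
        "calcaneus_plantar_anterior": ("calcaneus", (0.0, 72.0, calc_axis_z(72.0) - 10.0)),
        "calcaneus_superior_mid": ("calcaneus", (1.0, 72.0, calc_axis_z(72.0) + 10.0)),
        "cuboid_plantar": ("cuboid", (-20.0, 104.0, cub_z - 8.0)),
        "navicular_plantar": ("navicular", (nav_x, nav_y, nav_z - 7.5)),
        "navicular_medial": ("navicular", (nav_x + 10.0, nav_y, nav_z)),
        "talus_medial": ("talus", (13.0, 70.0, tz)),
        "talus_lateral": ("talus", (-11.0, 68.0, tz)),
        "talus_inferior": ("talus", (1.0, 70.0, tz - 9.0)),
        "medial_malleolus": ("tibia", (12.0, 68.0, z_pl + 6.0)),
        "lateral_malleolus": ("fibula", (-24.0, 66.0, z_pl + 2.0)),
        "metatarsal_5_base_plantar": ("metatarsal_5", (-26.0, 120.0, 14.0)),
        # axis seeds
        "talus_head_center": ("talus", (head_x, head_y, head_z)),
        "talus_body_center": ("talus", (1.0, 70.0, tz)),
        "calcaneus_axis_posterior": ("calcaneus", tuple(cal_a)),
        "calcaneus_axis_anterior": ("calcaneus", tuple(cal_b)),
    }
    for i in range(1, 6):
        b, h, r0, r1 = met[i]
        lm[f"metatarsal_{i}_head_plantar"] = (
            f"metatarsal_{i}", (h[0], h[1], h[2] - r1 + 1.0))
        lm[f"metatarsal_{i}_base"] = (f"metatarsal_{i}", b)
        lm[f"metatarsal_{i}_head"] = (f"metatarsal_{i}", h)

    # plantar-fascia insertions: base of the hallux and four points along
    # the underside of the lesser-toe block (proximal-phalanx bases)
    lm["toe_plantar_1"] = ("toes_hallux", (m1h[0] + 1.0, 203.0, 4.0))
    la, lb = np.array([m2h[0] + 1.0, 203.0, 4.5]), \
        np.array([m5h[0] - 1.0, 192.0, 5.0])
    for i, t in zip(range(2, 6), (0.0, 0.33, 0.66, 1.0)):
        p = la + t * (lb - la)
        lm[f"toe_plantar_{i}"] = ("toes_lesser", tuple(p))

    # talonavicular chord seeds: head chord perpendicular to the talar axis
    ax_xy = np.array([head_x - 1.0, head_y - 70.0])
    ax_xy /= np.linalg.norm(ax_xy)
    perp = np.array([-ax_xy[1], ax_xy[0]])
    for sign, tag in ((1.0, "medial"), (-1.0, "lateral")):
        p = np.array([head_x, head_y]) + sign * 8.0 * perp
        lm[f"talar_head_chord_{tag}"] = ("talus", (p[0], p[1], head_z))
    th = math.radians(tnc_planted)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    nperp = rot @ perp
    for sign, tag in ((1.0, "medial"), (-1.0, "lateral")):
        p = np.array([nav_x, nav_y]) + sign * 9.0 * nperp
        lm[f"navicular_chord_{tag}"] = ("navicular", (p[0], p[1], nav_z))

    # ---- planted morphometry -------------------------------------------
    def decl(base, head):
        return math.degrees(math.atan2(base[2] - head[2], head[1] - base[1]))

    m1_decl = decl(np.r_[m1b], np.r_[np.array(met[1][1])])
    ap_angle = lambda b, h: math.degrees(math.atan2(h[0] - b[0], h[1] - b[1]))
    m1_ap = ap_angle(m1b, np.array(met[1][1]))
    m5_ap = ap_angle(m5b, m5h)
    talus_ap = math.degrees(math.atan2(head_x - 1.0, head_y - 70.0))
    planted = {
        "CP": cp_deg,
        "LTM": m1_decl - decl_t_deg,
        "TC": decl_t_deg + cp_deg,
        "M1M5": abs(m1_ap - m5_ap),
        "APTM": talus_ap - m1_ap,
        "TNC": tnc_planted,
        "C5MH": (c1[2] - 9.0) - (m5h[2] - 5.8),
    }

    # ---- soft tissue envelope ------------------------------------------
    env = {
        "foot_segments": [
            ((0.0, 34.0), (-4.0, 100.0), 33.0, 31.0),
            ((-4.0, 100.0), (0.0, 182.0), 31.0, 48.0),
            ((0.0, 182.0), (2.0, 208.0), 47.0, 42.0),
        ],
        "cuff_center": (0.0, 69.0),
        "cuff_radius": 32.0,
        "cuff_top": z_pl + 16.0,
        "arch_bump": 8.0 - 5.0 * s,
        # sole starts in grazing contact (1 um penetration): the contact
        # active set exists from the first iterate, which keeps the
        # quasi-Newton tangent consistent during touchdown
        "sole_z": -0.001,
    }

    facets = {
        "trochlea_center": (1.0, 70.0, tz + 9.5),
        "subtalar_posterior": (1.0, 64.0, calc_axis_z(64.0) + 11.0),
        "subtalar_middle": (6.0, 80.0, calc_axis_z(80.0) + 9.0),
        "subtalar_anterior": (2.0, 88.0, calc_axis_z(88.0) + 9.0),
    }
    return bones, lm, planted, env, facets


def _foot_top_z(y, env):
    """Skin height profile over the dorsum."""
    # low over the forefoot, rising toward the ankle
    pts_y = np.asarray(y, dtype=float)
    top = np.interp(pts_y, [0.0, 55.0, 80.0, 110.0, 150.0, 240.0],
                    [52.0, 54.0, 58.0, 54.0, 44.0, 34.0])
    return top


def _envelope_mask(pts, env):
    xy = pts[:, :2]
    z = pts[:, 2]
    d2 = np.full(len(pts), np.inf)
    for a, b, r0, r1 in env["foot_segments"]:
        d2 = np.minimum(d2, _capsule_2d(xy, a, b, r0, r1))
    sole = env["sole_z"] + _arch_lift(xy, env)
    foot = (d2 < 0.0) & (z >= sole) & (z <= _foot_top_z(pts[:, 1], env))
    cc = np.asarray(env["cuff_center"])
    cuff = (np.linalg.norm(xy - cc, axis=1) < env["cuff_radius"]) & \
        (z >= env["sole_z"]) & (z <= env["cuff_top"])
    return foot | cuff


def _capsule_2d(xy, a, b, r0, r1):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    t = np.clip(((xy - a) @ ab) / float(ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    d = np.linalg.norm(xy - closest, axis=1)
    return d - (r0 + t * (r1 - r0))


def _arch_lift(xy, env):
    """Medial-arch concavity of the sole (fades with severity)."""
    h = env["arch_bump"]
    if h <= 0:
        return np.zeros(len(xy))
    med = h * np.exp(-((xy[:, 1] - 112.0) / 36.0) ** 2
                     - ((xy[:, 0] - 16.0) / 20.0) ** 2)
    lat = 5.0 * np.exp(-((xy[:, 1] - 115.0) / 32.0) ** 2
                       - ((xy[:, 0] + 22.0) / 15.0) ** 2)
    return np.maximum(med, lat)


# ---------------------------------------------------------------------------
# generation


def generate_foot(params: FootParams) -> FootModel:
    """Generate a meshed synthetic foot model.

    Deterministic for a fixed seed; ``severity`` monotonically lowers the
    arch of the unloaded model.  Left feet are produced by mirroring X.
    """
    rng = np.random.default_rng(params.seed)
    bones, lm, planted, env, facets = _skeleton(params, rng)

    sx = params.foot_width / _TEMPLATE_WIDTH
    sy = params.foot_length / _TEMPLATE_LENGTH
    sz = 0.5 * (sx + sy)
    scale = np.array([sx, sy, sz])

    def sc(p):
        return np.asarray(p, float) * scale

    # scale primitives (radii by the mean in-plane factor)
    rs = float((sx + sy + sz) / 3.0)
    for name, prims in bones.items():
        out = []
        for p in prims:
            if p[0] == "capsule":
                out.append(("capsule", sc(p[1]), sc(p[2]), p[3] * rs, p[4] * rs))
            else:
                out.append(("ellipsoid", sc(p[1]), np.asarray(p[2]) * scale))
        bones[name] = out
    lm = {k: (b, sc(p)) for k, (b, p) in lm.items()}
    env = dict(env)
    env["foot_segments"] = [
        (tuple(np.asarray(a) * scale[:2]), tuple(np.asarray(b) * scale[:2]),
         r0 * rs, r1 * rs)
        for a, b, r0, r1 in env["foot_segments"]
    ]
    env["cuff_center"] = tuple(np.asarray(env["cuff_center"]) * scale[:2])
    env["cuff_radius"] = env["cuff_radius"] * rs
    env["cuff_top"] = env["cuff_top"] * sz
    facets = {k: sc(v) for k, v in facets.items()}
    planted["C5MH"] = planted["C5MH"] * sz

    # ---- voxel grid -----------------------------------------------------
    h = params.mesh_size
    lo = np.array([-52.0 * sx, 0.0, env["sole_z"]])
    hi = np.array([46.0 * sx, 238.0 * sy, 132.0 * sz])
    nvox = np.maximum(((hi - lo) / h).astype(int) + 1, 2)
    centers_1d = [lo[i] + (np.arange(nvox[i]) + 0.5) * h for i in range(3)]
    gx, gy, gz = np.meshgrid(*centers_1d, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    nbone = len(BONE_NAMES)
    phi = np.empty((len(pts), nbone))
    for k, name in enumerate(BONE_NAMES):
        phi[:, k] = _bone_phi(pts, bones[name])
    bone_id = np.where(phi.min(axis=1) < 0.0, phi.argmin(axis=1), -1)
    bone_id = bone_id.reshape(tuple(nvox))
    phi_grid = phi.reshape(tuple(nvox) + (nbone,))

    env_mask = _envelope_mask(pts, env).reshape(tuple(nvox))

    own_phi = np.take_along_axis(
        phi_grid, np.clip(bone_id, 0, None)[..., None], axis=-1)[..., 0]
    own_phi = np.where(bone_id >= 0, own_phi, -np.inf)

    # 1. demote voxels of *different* bones that touch anywhere in the
    #    26-neighbourhood (they would weld through shared mesh nodes): the
    #    cell closer to its own bone surface loses, but a bone is never
    #    demoted below a survival floor of voxels — thin bones keep their
    #    cells even if that leaves an occasional weld
    min_keep = 10
    cart = np.zeros(tuple(nvox), dtype=bool)
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) > (0, 0, 0)]
    for _ in range(6):
        changed = False
        counts = np.bincount(bone_id.ravel()[bone_id.ravel() >= 0],
                             minlength=nbone)
        protected = counts <= min_keep
        for off in offsets:
            sa = tuple(slice(None, -1) if o > 0 else
                       (slice(1, None) if o < 0 else slice(None))
                       for o in off)
            sb = tuple(slice(1, None) if o > 0 else
                       (slice(None, -1) if o < 0 else slice(None))
                       for o in off)
            ida, idb = bone_id[sa], bone_id[sb]
            clash = (ida >= 0) & (idb >= 0) & (ida != idb)
            if clash.any():
                pa, pb = own_phi[sa], own_phi[sb]
                prot_a = protected[np.clip(ida, 0, None)]
                prot_b = protected[np.clip(idb, 0, None)]
                da = clash & (((pa >= pb) & ~prot_a) | (prot_b & ~prot_a))
                db = clash & ~da & ~prot_b
                cart[sa] |= da
                cart[sb] |= db
                bone_id[sa] = np.where(da, -1, ida)
                bone_id[sb] = np.where(db, -1, idb)
                changed = bool(da.any() or db.any()) or changed
        if not changed:
            break

    # 2. per-bone cleanup: largest connected component, additive manifold
    #    fix (only into cells untouched by other bones), then pruning of
    #    any remaining edge-non-manifold pattern
    claimed = bone_id >= 0
    for k, name in enumerate(BONE_NAMES):
        mask = bone_id == k
        if not mask.any():
            raise MeshingError(
                f"bone '{name}' vanished during meshing (mesh too coarse)")
        other = claimed & ~mask
        # cells adjacent (26-n) to another bone are off limits
        from scipy import ndimage
        forbid = ndimage.binary_dilation(
            other, structure=np.ones((3, 3, 3), bool))
        keep = largest_component(mask)
        cart |= mask & ~keep
        mask = keep
        mask = fix_nonmanifold_mask(mask, allowed=~forbid & ~cart)
        mask = prune_nonmanifold_mask(mask, phi_grid[..., k])
        mask = largest_component(mask)
        cart |= (bone_id == k) & ~mask
        claimed &= ~(bone_id == k)
        bone_id[bone_id == k] = -1
        bone_id[mask] = k
        claimed |= mask

    cart &= bone_id < 0

    # 3. cartilage: unclaimed cells bridging two different bones
    gap_c = max(3.2, 0.65 * h)
    near = phi_grid < gap_c
    near_count = near.sum(axis=-1)
    cart |= (bone_id < 0) & (near_count >= 2)

    soft = env_mask & (bone_id < 0) & ~cart
    # guarantee every bone below the ankle is buried: one dilated shell of
    # soft tissue around each bone (the skin profile is approximate)
    from scipy import ndimage
    leg = (bone_id == BONE_NAMES.index("tibia")) | \
        (bone_id == BONE_NAMES.index("fibula"))
    nonleg = (bone_id >= 0) & ~leg
    shell = ndimage.binary_dilation(nonleg, np.ones((3, 3, 3), bool))
    soft |= shell & (bone_id < 0) & ~cart
    occupied = (bone_id >= 0) | cart | soft
    origin = lo  # voxel (i,j,k) spans origin + [i, i+1]*h etc.

    nodes, tets, owner = tets_from_voxels(occupied, origin, h)

    vox_class = np.full(tuple(nvox), -2, dtype=np.int64)   # -2 soft, -3 cart
    vox_class[soft] = -2
    vox_class[cart] = -3
    vox_class[bone_id >= 0] = bone_id[bone_id >= 0]
    owner_class = vox_class.ravel()[owner]

    tet_sets: dict[str, np.ndarray] = {}
    for k, name in enumerate(BONE_NAMES):
        ids = np.nonzero(owner_class == k)[0]
        if len(ids) == 0:
            raise MeshingError(
                f"bone '{name}' produced no elements (mesh_size too coarse?)")
        tet_sets[name] = ids
    tet_sets["cartilage"] = np.nonzero(owner_class == -3)[0]
    tet_sets["soft_tissue"] = np.nonzero(owner_class == -2)[0]

    # watertightness of each bone
    for name in BONE_NAMES:
        if not surface_is_closed(tets[tet_sets[name]]):
            raise MeshingError(f"bone '{name}' surface is not watertight")

    # ---- ground slab ----------------------------------------------------
    gnodes, ghex, gtop, gbase = _ground_slab(lo, hi, sx, sy)
    goffset = len(nodes)
    nodes = np.vstack([nodes, gnodes])
    ghex = ghex + goffset
    gtop = gtop + goffset
    gbase = gbase + goffset

    # ---- landmarks ------------------------------------------------------
    landmarks: dict[str, int] = {}
    landmark_points: dict[str, np.ndarray] = {}
    for name, (bone, p) in lm.items():
        bnodes = np.unique(tets[tet_sets[bone]])
        d = np.linalg.norm(nodes[bnodes] - p, axis=1)
        landmarks[name] = int(bnodes[int(np.argmin(d))])
        landmark_points[name] = np.asarray(p, float)

    # ---- facet element sets --------------------------------------------
    # articular sets are the *top element layer* of the bone within an XY
    # window around each analytic facet centre (robust to how much of the
    # joint surface was demoted to cartilage)
    cent = nodes[tets].mean(axis=1)
    facet_sets: dict[str, np.ndarray] = {}

    def top_layer(ids, center, rad_xy, depth=1.35):
        cand = ids[(np.abs(cent[ids, 0] - center[0]) < rad_xy)
                   & (np.abs(cent[ids, 1] - center[1]) < rad_xy)]
        if len(cand) == 0:
            return cand
        zmax = cent[cand, 2].max()
        return cand[cent[cand, 2] > zmax - depth * h]

    tal = tet_sets["talus"]
    tc = facets["trochlea_center"]
    facet_sets["talar_trochlea"] = _trim_equal(
        top_layer(tal, tc, 14.0 * rs), cent, 9)

    cal = tet_sets["calcaneus"]
    sel = {}
    centers = {}
    for tag, rad in (("posterior", 12.0), ("middle", 8.0), ("anterior", 8.0)):
        c = facets[f"subtalar_{tag}"]
        centers[tag] = c
        sel[tag] = top_layer(cal, c, rad * rs)
    # resolve overlaps: an element claimed twice goes to the nearest centre
    for a in sel:
        for b in sel:
            if a >= b:
                continue
            both = np.intersect1d(sel[a], sel[b])
            if len(both):
                da = np.linalg.norm(cent[both] - centers[a], axis=1)
                db = np.linalg.norm(cent[both] - centers[b], axis=1)
                sel[a] = np.setdiff1d(sel[a], both[da >= db])
                sel[b] = np.setdiff1d(sel[b], both[da < db])
    for tag in ("posterior", "middle", "anterior"):
        ids = sel[tag]
        if tag == "posterior":
            ids = _trim_equal(ids, cent, 4)
        facet_sets[f"subtalar_{tag}"] = ids

    # ---- sole contact nodes and footprint -------------------------------
    bf = boundary_faces(tets)
    bnodes = np.unique(bf)
    sole_nodes = bnodes[nodes[bnodes, 2] < env["sole_z"] + 0.3 * h]

    meta = {
        "planted_morphometry": planted,
        "sole_nodes": sole_nodes,
        "sole_outline_segments": env["foot_segments"],
        "grid_origin": origin,
        "grid_shape": tuple(int(v) for v in nvox),
        "foot_node_count": goffset,
        "ties": np.empty((0, 2), np.int64),
        "mirrored": False,
    }
    # toe masks for the plantar partition (XY hulls, padded by soft margin)
    for tag, bone in (("hallux", "toes_hallux"), ("lesser", "toes_lesser")):
        bn = np.unique(tets[tet_sets[bone]])
        meta[f"toe_mask_{tag}"] = nodes[bn][:, :2]

    contact_pairs = [
        {"surface_a": "sole", "surface_b": "ground_top",
         "tangential": "coulomb", "mu": 0.6, "separation_allowed": True},
    ]

    model = FootModel(
        params=params,
        nodes=nodes,
        tets=tets,
        tet_sets=tet_sets,
        ground_hexes=ghex,
        ground_top_tris=gtop,
        ground_base_nodes=gbase,
        trusses=TrussTable(),
        landmarks=landmarks,
        landmark_points=landmark_points,
        facet_sets=facet_sets,
        contact_pairs=contact_pairs,
        meta=meta,
    )
    model = attach_trusses(model, default_ligament_table())
    if params.side == "left":
        model = model.mirrored()
    return model


def _trim_equal(ids: np.ndarray, cent: np.ndarray, k: int) -> np.ndarray:
    """Trim an element set to a multiple of ``k`` members by dropping the
    elements farthest from the set centroid, so equal-count partitions
    come out exactly equal."""
    ids = np.asarray(ids)
    if len(ids) < k:
        return ids
    drop = len(ids) % k
    if drop == 0:
        return ids
    c = cent[ids].mean(axis=0)
    d = np.linalg.norm(cent[ids] - c, axis=1)
    keep = np.argsort(d, kind="stable")[: len(ids) - drop]
    return ids[np.sort(keep)]


def _ground_slab(lo, hi, sx, sy, spacing: float = 10.0, depth: float = 20.0,
                 layers: int = 2):
    """Hex-meshed ground slab with top surface on the XY plane (Z = 0)."""
    margin = 12.0
    x0, x1 = lo[0] - margin, hi[0] + margin
    y0, y1 = lo[1] - margin, hi[1] + margin
    nx = max(int((x1 - x0) / spacing), 2)
    ny = max(int((y1 - y0) / spacing), 2)
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    zs = np.linspace(-depth, 0.0, layers + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (layers + 1) + k

    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(layers):
                hexes.append([
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
    hexes = np.array(hexes, dtype=np.int64)
    tris = []
    k = layers
    for i in range(nx):
        for j in range(ny):
            a, b = nid(i, j, k), nid(i + 1, j, k)
            c, d = nid(i + 1, j + 1, k), nid(i, j + 1, k)
            tris.append([a, b, c])       # outward normal +Z
            tris.append([a, c, d])
    base = np.array([nid(i, j, 0) for i in range(nx + 1)
                     for j in range(ny + 1)], dtype=np.int64)
    return nodes, hexes, np.array(tris, dtype=np.int64), base


# ---------------------------------------------------------------------------
# trusses


def default_ligament_table():
    import pandas as pd

    return pd.DataFrame(
        DEFAULT_LIGAMENTS,
        columns=["name", "tissue_class", "origin_landmark", "insertion_landmark"],
    )


def attach_trusses(model: FootModel, ligament_table) -> FootModel:
    """Bind ligament/fascia trusses to landmark nodes.

    Cross-sectional areas are fixed per tissue class: ligaments 18.4 mm^2,
    plantar fascia 58.6 mm^2.  An empty table leaves the model unchanged
    with zero trusses.
    """
    import pandas as pd

    table = pd.DataFrame(ligament_table)
    names, classes, conn, areas = [], [], [], []
    for _, row in table.iterrows():
        for key in (row["origin_landmark"], row["insertion_landmark"]):
            if key not in model.landmarks:
                raise KeyError(
                    f"ligament '{row['name']}': landmark '{key}' not found")
        cls = row["tissue_class"]
        if cls not in ("ligament", "fascia"):
            raise ValueError(f"unknown tissue class '{cls}'")
        names.append(row["name"])
        classes.append(cls)
        conn.append([model.landmarks[row["origin_landmark"]],
                     model.landmarks[row["insertion_landmark"]]])
        areas.append(FASCIA_AREA if cls == "fascia" else LIGAMENT_AREA)
    trusses = TrussTable(
        names=names,
        tissue_class=classes,
        conn=np.asarray(conn, dtype=np.int64).reshape(-1, 2),
        area=np.asarray(areas, dtype=float),
    )
    out = replace(model)
    out.trusses = trusses
    return out
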