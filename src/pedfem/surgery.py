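"""Virtual medial displacement calcaneal osteotomy (MDCO).

The calcaneus is cut by a plane tilted 45 degrees from the ground plane,
posterior to the calcaneofibular-ligament insertion, sloping from
posterosuperior to anteroinferior.  The posterior (tuberosity) fragment is
rigidly translated medially along +X by the requested distance (4, 8 or
12 mm in the study protocol); the cut surfaces are reconnected by
equal-displacement tie couplings, and the surrounding soft tissue (heel
pad, Achilles insertion, fascia origins) follows the fragment through a
smooth local remap.

The cut itself is an element-centroid split on the voxel mesh: every
calcaneal tet is assigned to the anterior or posterior fragment by the
side of the plane its centroid falls on.  This conserves element count and
volume exactly; the cut surface is jagged at voxel scale, which the tie
couplings absorb.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from .foot import FootModel

__all__ = [
    "OsteotomyPlan",
    "plan_osteotomy",
    "perform_mdco",
    "fragment_displacement",
]


@dataclass(frozen=True)
class OsteotomyPlan:
    """Cut-plane pose and translation of an MDCO.

    The plane contains a line parallel to the X axis through
    ``reference_point`` and is tilted ``angle_from_ground`` degrees from
    the ground plane; its normal lies in the YZ plane.
    """

    angle_from_ground: float
    reference_point: np.ndarray
    translation_mm: float
    translation_axis: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self):
        if not 0.0 < self.angle_from_ground < 90.0:
            raise ValueError("cut angle must lie strictly between 0 and 90 deg")
        if self.translation_mm < 0:
            raise ValueError("translation distance must be non-negative")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the cut plane (in the YZ plane)."""
        th = np.radians(self.angle_from_ground)
        return np.array([0.0, np.sin(th), np.cos(th)])

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance to the plane; negative on the posterior side."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = (pts - self.reference_point) @ self.normal
        return d if d.size > 1 else d


def plan_osteotomy(model: FootModel, translation_mm: float,
                   angle: float = 45.0,
                   posterior_offset: float = 10.0) -> OsteotomyPlan:
    """Plan an MDCO cut for a foot model.

    The reference point sits ``posterior_offset`` mm posterior (-Y) to the
    calcaneofibular-ligament insertion landmark; with the default 45-degree
    tilt the plane slopes posterosuperior to anteroinferior.
    """
    if "cfl_insertion" not in model.landmarks:
        raise KeyError("model lacks the 'cfl_insertion' landmark")
    cfl = model.nodes[model.landmarks["cfl_insertion"]]
    ref = cfl + np.array([0.0, -abs(posterior_offset), 0.0])
    return OsteotomyPlan(
        angle_from_ground=angle,
        reference_point=ref,
        translation_mm=float(translation_mm),
    )


def perform_mdco(model: FootModel, plan: OsteotomyPlan,
                 remap_radius: float = 30.0) -> FootModel:
    """Cut, translate and tie: returns a new model with the MDCO applied.

    * calcaneal elements split by centroid side of the plane into
      ``calcaneus`` (anterior, kept in place) and ``calcaneus_posterior``;
    * interface nodes are duplicated; the posterior copies are translated
      with the fragment and tied back to their anterior originals
      (equal-displacement couplings, the paper-style "tie constraint");
    * soft-tissue nodes near the posterior fragment follow it with a
      smooth falloff so the heel pad and Achilles insertion medialize.
    """
    if "calcaneus" not in model.tet_sets:
        raise ValueError("model has no calcaneus to cut")
    out = copy.deepcopy(model)
    d = float(plan.translation_mm)
    axis = np.asarray(plan.translation_axis, dtype=float)

    cal_ids = out.tet_sets["calcaneus"]
    cal_tets = out.tets[cal_ids]
    cent = out.nodes[cal_tets].mean(axis=1)
    side = plan.signed_distance(cent)
    post = side < 0.0
    if post.all() or (~post).all():
        raise ValueError("cut plane misses the calcaneus entirely")
    vol = np.abs(np.linalg.det(
        out.nodes[cal_tets[:, 1:]] - out.nodes[cal_tets[:, :1]])) / 6.0
    frac = vol[post].sum() / vol.sum()
    if min(frac, 1.0 - frac) < 0.05:
        warnings.warn("osteotomy cut is very peripheral "
                      f"(posterior fragment {100 * frac:.1f}% of volume)")

    post_ids = cal_ids[post]
    ant_ids = cal_ids[~post]

    post_nodes = np.unique(out.tets[post_ids])
    ant_nodes = np.unique(out.tets[ant_ids])
    interface = np.intersect1d(post_nodes, ant_nodes)

    # duplicate interface nodes for the posterior fragment and tie the
    # copies (slave) to the anterior originals (master)
    n0 = len(out.nodes)
    new_ids = np.arange(n0, n0 + len(interface))
    out.nodes = np.vstack([out.nodes, out.nodes[interface]])
    remap = dict(zip(interface.tolist(), new_ids.tolist()))
    ptets = out.tets[post_ids]
    flat = ptets.ravel()
    mask = np.isin(flat, interface)
    flat[mask] = np.array([remap[v] for v in flat[mask]])
    out.tets[post_ids] = flat.reshape(-1, 4)

    # fragment node set after duplication
    frag_nodes = np.unique(out.tets[post_ids])

    # landmarks on duplicated nodes follow the posterior copy
    for name, nid in out.landmarks.items():
        if nid in remap and name in (
                "achilles_insertion", "calcaneal_tuberosity_plantar"):
            out.landmarks[name] = remap[nid]
    tr = out.trusses
    if len(tr.conn):
        flat = tr.conn.ravel()
        m = np.isin(flat, interface)
        # fascia/achilles-side attachments stay with the fragment only if
        # the landmark they bind sits posterior of the plane
        for i in np.nonzero(m)[0]:
            p = out.nodes[flat[i]]
            if plan.signed_distance(p)[0] < 0:
                flat[i] = remap[int(flat[i])]
        tr.conn = flat.reshape(-1, 2)

    # displacement field: fragment moves rigidly; nearby soft tissue and
    # cartilage follow with a smooth falloff.  Follower weights are
    # reduced locally until no reference tet is inverted by the remap.
    w = np.zeros(len(out.nodes))
    w[frag_nodes] = 1.0
    if d > 0.0:
        free = _soft_follow_weights(out, frag_nodes, remap_radius)
        w = np.maximum(w, free)
        base = out.nodes.copy()
        frag_set = np.zeros(len(out.nodes), dtype=bool)
        frag_set[frag_nodes] = True
        released = np.zeros(len(out.tets), dtype=bool)
        soft_like = np.zeros(len(out.tets), dtype=bool)
        for key in ("soft_tissue", "cartilage"):
            soft_like[out.tet_sets.get(key, np.empty(0, np.int64))] = True
        for _ in range(80):
            new_nodes = base + np.outer(w, axis * d)
            e = new_nodes[out.tets[:, 1:]] - new_nodes[out.tets[:, :1]]
            vol = np.linalg.det(e) / 6.0
            bad = (vol <= 1e-9) & ~released
            if not bad.any():
                break
            bad_nodes = np.unique(out.tets[bad])
            shrink = bad_nodes[~frag_set[bad_nodes] & (w[bad_nodes] > 0)]
            if len(shrink) == 0:
                # tissue trapped between the sliding fragment and another
                # bone cannot deform compatibly: it is surgically released
                stuck = np.nonzero(bad & soft_like)[0]
                if len(stuck) == 0:
                    raise RuntimeError(
                        "osteotomy remap produced an inverted bone element")
                released[stuck] = True
                continue
            w[shrink] *= 0.6
            w[shrink] = np.where(w[shrink] < 0.02, 0.0, w[shrink])
        else:
            raise RuntimeError("osteotomy remap failed to untangle the mesh")
        out.nodes = new_nodes
        if released.any():
            rel_ids = np.nonzero(released)[0]
            for key in ("soft_tissue", "cartilage"):
                out.tet_sets[key] = np.setdiff1d(
                    out.tet_sets.get(key, np.empty(0, np.int64)), rel_ids)
            out.tet_sets["released"] = np.union1d(
                out.tet_sets.get("released", np.empty(0, np.int64)), rel_ids)
            # nodes used only by released elements must be pinned
            alive = np.ones(len(out.tets), dtype=bool)
            alive[out.tet_sets["released"]] = False
            used = np.zeros(len(out.nodes), dtype=bool)
            used[np.unique(out.tets[alive])] = True
            used[out.ground_hexes.ravel()] = True
            if len(out.trusses.conn):
                used[out.trusses.conn.ravel()] = True
            orphans = np.unique(out.tets[~alive])
            orphans = orphans[~used[orphans]]
            prev_orph = out.meta.get("pinned_orphans",
                                     np.empty(0, np.int64))
            out.meta["pinned_orphans"] = np.union1d(prev_orph, orphans)

    # tie the translated cut-face nodes to the anterior cut face at their
    # *post-translation* positions (nearest-point pairing after
    # translation): each slave follows an inverse-distance weighted blend
    # of its nearest anterior partners, which smooths the jagged voxel
    # interface and transmits the healed-interface force (and moment) at
    # the shifted location
    from scipy.spatial import cKDTree

    tree = cKDTree(out.nodes[interface])
    k = min(4, len(interface))
    dist, nearest = tree.query(out.nodes[new_ids], k=k)
    dist = np.atleast_2d(dist)
    nearest = np.atleast_2d(nearest)
    ties = []
    for i, s in enumerate(new_ids):
        w = 1.0 / np.maximum(dist[i], 0.5)
        ties.append((int(s), interface[nearest[i]], w / w.sum()))
    prev = out.meta.get("ties", [])
    if isinstance(prev, np.ndarray):
        prev = [(int(a), np.array([b]), np.array([1.0]))
                for a, b in prev.reshape(-1, 2)]
    out.meta["ties"] = list(prev) + ties

    # analytic landmark points on the fragment follow it
    if d > 0.0:
        frag_lookup = np.zeros(len(out.nodes), dtype=bool)
        frag_lookup[frag_nodes] = True
        for name, nid in out.landmarks.items():
            if frag_lookup[nid]:
                out.landmark_points[name] = \
                    out.landmark_points[name] + axis * d

    out.tet_sets = dict(out.tet_sets)
    out.tet_sets["calcaneus"] = ant_ids
    out.tet_sets["calcaneus_posterior"] = post_ids
    # subtalar facets live on the anterior fragment; keep only elements
    # that remained anterior (they all should)
    for k in list(out.facet_sets):
        if k.startswith("subtalar_"):
            out.facet_sets[k] = np.intersect1d(out.facet_sets[k], ant_ids)
    out.meta["mdco"] = {
        "translation_mm": d,
        "angle_from_ground": plan.angle_from_ground,
        "reference_point": np.asarray(plan.reference_point).tolist(),
        "posterior_fraction": float(frac),
    }
    return out


def _soft_follow_weights(model: FootModel, frag_nodes: np.ndarray,
                         radius: float) -> np.ndarray:
    """Smoothstep falloff (1 -> 0 over ``radius``) of the fragment shift
    on soft-tissue nodes; bone and ground nodes never move."""
    from scipy.spatial import cKDTree

    w = np.zeros(len(model.nodes))
    movable = np.unique(np.concatenate([
        model.tets[model.tet_sets["soft_tissue"]].ravel(),
        model.tets[model.tet_sets["cartilage"]].ravel(),
    ]))
    # nodes belonging to any *other* bone (or ground) are pinned
    pinned = set()
    for name, ids in model.tet_sets.items():
        if name in ("soft_tissue", "cartilage", "calcaneus_posterior"):
            continue
        pinned.update(np.unique(model.tets[ids]).tolist())
    pinned.update(range(model.meta["foot_node_count"], len(model.nodes)))
    frag = set(frag_nodes.tolist())
    cand = np.array(sorted(set(movable.tolist()) - pinned - frag),
                    dtype=np.int64)
    if len(cand) == 0:
        return w
    tree = cKDTree(model.nodes[frag_nodes])
    dist, _ = tree.query(model.nodes[cand])
    t = np.clip(1.0 - dist / radius, 0.0, 1.0)
    w[cand] = t * t * (3.0 - 2.0 * t)
    return w


def fragment_displacement(before: FootModel, after: FootModel,
                          fragment: str = "calcaneus_posterior") -> np.ndarray:
    """Rigid translation of the posterior-fragment centroid (mm, 3-vector)."""
    if fragment in before.tet_sets:
        ids_b = before.tet_sets[fragment]
    elif fragment == "calcaneus_posterior" and "calcaneus" in before.tet_sets:
        # the pre-cut model carries the whole calcaneus; use the elements
        # that became the posterior fragment
        if fragment not in after.tet_sets:
            raise KeyError("'after' model has no posterior fragment")
        ids_b = after.tet_sets[fragment]
        if ids_b.max() >= len(before.tets):
            raise KeyError("fragment labels do not match between models")
    else:
        raise KeyError(f"fragment '{fragment}' not found")
    if fragment not in after.tet_sets:
        if np.array_equal(before.nodes.shape, after.nodes.shape):
            return np.zeros(3)
        raise KeyError(f"fragment '{fragment}' not found in 'after' model")
    ids_a = after.tet_sets[fragment]
    cb = before.nodes[before.tets[ids_b]].mean(axis=(0, 1))
    ca = after.nodes[after.tets[ids_a]].mean(axis=(0, 1))
    return ca - cb
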