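"""Region partitions and von Mises stress-percentage scoring.

Three partition schemes mirror the evaluation protocol:

* ``plantar8`` — eight areas on the ground: 1 = hallux, 2 = lesser toes;
  the toe-excluded footprint is split into three equal-length thirds
  (forefoot / midfoot / hindfoot); the forefoot third into three
  equal-width bands (3 medial, 4 middle, 5 lateral), the midfoot into two
  (6 medial, 7 lateral), and the hindfoot is area 8.
* ``talocrural9`` — the talar trochlea elements ranked into a 3x3 grid of
  equal-count sets: columns medial (1-3) / middle (4-6) / lateral (7-9),
  rows anterior (1, 4, 7) / middle (2, 5, 8) / posterior (3, 6, 9).
* ``subtalar`` — anterior / middle / posterior facet sets on the
  calcaneus, with the posterior facet further split into four equal-count
  quadrants: medial (1, 2), lateral (3, 4), anterior (1, 3),
  posterior (2, 4).

A region's score is the unweighted sum of element von Mises stresses; the
table reports each region as a percentage of the total over the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

__all__ = [
    "RegionPartition",
    "StressPercentages",
    "Footprint",
    "footprint_from_model",
    "partition_plantar",
    "partition_talocrural",
    "partition_subtalar",
    "stress_percentages",
    "TALOCRURAL_GROUPS",
    "POST_SUBTALAR_GROUPS",
]

TALOCRURAL_GROUPS = {
    "medial": [1, 2, 3], "middle_ml": [4, 5, 6], "lateral": [7, 8, 9],
    "anterior": [1, 4, 7], "middle_ap": [2, 5, 8], "posterior": [3, 6, 9],
}
POST_SUBTALAR_GROUPS = {
    "medial": [1, 2], "lateral": [3, 4],
    "anterior": [1, 3], "posterior": [2, 4],
}


@dataclass
class RegionPartition:
    scheme: str
    labels: dict                       # region id -> member element ids
    grouping_axes: dict = field(default_factory=dict)

    def members(self) -> np.ndarray:
        return np.concatenate([np.asarray(v) for v in self.labels.values()])


@dataclass
class StressPercentages:
    per_region: dict
    per_group: dict


@dataclass
class Footprint:
    """Ground contact cells (element ids + XY centroids) with toe masks."""

    cell_ids: np.ndarray
    centroids_xy: np.ndarray
    hallux_poly: object
    lesser_poly: object
    medial_sign: float = 1.0


def sole_outline_polygon(model):
    """Footprint outline from the generator's sole capsule segments."""
    parts = []
    for a, b, r0, r1 in model.meta["sole_outline_segments"]:
        parts += [Point(a).buffer(r0), Point(b).buffer(r1),
                  LineString([a, b]).buffer(min(r0, r1))]
    return unary_union(parts)


def _toe_poly(model, tag):
    from shapely.geometry import MultiPoint

    pts = model.meta[f"toe_mask_{tag}"]
    return MultiPoint(pts.tolist()).convex_hull.buffer(6.0)


def footprint_from_model(model) -> Footprint:
    """Ground top-layer cells under the sole outline or the toe masks."""
    cents = model.nodes[model.ground_hexes].mean(axis=1)
    top = cents[:, 2] > cents[:, 2].max() - 1e-9
    outline = sole_outline_polygon(model)
    hal = _toe_poly(model, "hallux")
    les = _toe_poly(model, "lesser")
    combined = unary_union([outline, hal, les])
    ids = np.nonzero(top)[0]
    keep = np.array([
        combined.contains(Point(c[0], c[1])) for c in cents[ids]
    ])
    ids = ids[keep]
    if len(ids) == 0:
        raise ValueError("empty footprint: no ground cells under the sole")
    sign = 1.0 if model.params.side == "right" else -1.0
    return Footprint(
        cell_ids=ids,
        centroids_xy=cents[ids, :2],
        hallux_poly=hal,
        lesser_poly=les,
        medial_sign=sign,
    )


def partition_plantar(footprint: Footprint) -> RegionPartition:
    """Eight plantar areas on the ground contact cells."""
    ids = footprint.cell_ids
    xy = footprint.centroids_xy
    if len(ids) == 0:
        raise ValueError("empty footprint")
    in_hal = np.array([footprint.hallux_poly.contains(Point(p)) for p in xy])
    in_les = np.array([footprint.lesser_poly.contains(Point(p)) for p in xy]) \
        & ~in_hal
    rest = ~(in_hal | in_les)
    labels = {1: ids[in_hal], 2: ids[in_les]}

    ry = xy[rest, 1]
    y0, y1 = ry.min(), ry.max()
    t1 = y0 + (y1 - y0) / 3.0
    t2 = y0 + 2.0 * (y1 - y0) / 3.0
    hind = rest.copy()
    hind[rest] = ry < t1
    mid = rest.copy()
    mid[rest] = (ry >= t1) & (ry < t2)
    fore = rest.copy()
    fore[rest] = ry >= t2

    m = footprint.medial_sign

    def xbands(mask, nbands):
        xs = m * xy[mask, 0]                      # medial-positive coordinate
        lo, hi = xs.min(), xs.max()
        edges = np.linspace(lo, hi, nbands + 1)
        edges[-1] += 1e-9
        band = np.digitize(xs, edges) - 1
        return [ids[mask][band == (nbands - 1 - b)] for b in range(nbands)]
        # band nbands-1 = most medial

    fb = xbands(fore, 3)
    labels[3], labels[4], labels[5] = fb[0], fb[1], fb[2]
    mb = xbands(mid, 2)
    labels[6], labels[7] = mb[0], mb[1]
    labels[8] = ids[hind]
    groups = {"toes": [1, 2], "forefoot": [3, 4, 5],
              "midfoot": [6, 7], "hindfoot": [8]}
    return RegionPartition("plantar8", labels, groups)


def _rank_split(ids, key, n):
    order = np.argsort(-key, kind="stable")
    return [ids[part] for part in np.array_split(order, n)]


def partition_talocrural(centroids: np.ndarray, element_ids=None,
                         medial_sign: float = 1.0) -> RegionPartition:
    """3x3 equal-count grid over the talar trochlea elements."""
    centroids = np.asarray(centroids, dtype=float)
    if element_ids is None:
        element_ids = np.arange(len(centroids))
    element_ids = np.asarray(element_ids)
    if len(element_ids) < 9:
        raise ValueError("talocrural partition needs at least 9 elements")
    cols = _rank_split(np.arange(len(element_ids)),
                       medial_sign * centroids[:, 0], 3)
    labels = {}
    for c, col in enumerate(cols):                 # 0 medial, 2 lateral
        rows = _rank_split(col, centroids[col, 1], 3)  # 0 anterior
        for r, row in enumerate(rows):
            labels[3 * c + r + 1] = element_ids[row]
    return RegionPartition("talocrural9", labels, dict(TALOCRURAL_GROUPS))


def partition_subtalar(facet_sets: dict, centroids: np.ndarray,
                       medial_sign: float = 1.0) -> tuple[RegionPartition,
                                                          RegionPartition]:
    """Facet-level partition and the 2x2 posterior-facet quadrants.

    ``facet_sets`` maps 'anterior' / 'middle' / 'posterior' to calcaneal
    element ids; ``centroids`` is indexed by element id.
    Returns (facets, posterior_quadrants).
    """
    for k in ("anterior", "middle", "posterior"):
        if k not in facet_sets or len(facet_sets[k]) == 0:
            raise ValueError(f"missing subtalar facet set '{k}'")
    facets = RegionPartition(
        "subtalar_facets",
        {k: np.asarray(facet_sets[k]) for k in
         ("anterior", "middle", "posterior")},
    )
    post = np.asarray(facet_sets["posterior"])
    if len(post) < 4:
        raise ValueError("posterior facet needs at least 4 elements")
    c = centroids[post]
    halves = _rank_split(np.arange(len(post)), medial_sign * c[:, 0], 2)
    labels = {}
    for i, half in enumerate(halves):              # 0 medial, 1 lateral
        rows = _rank_split(half, c[half, 1], 2)    # 0 anterior
        labels[2 * i + 1] = post[rows[0]]          # 1 med-ant / 3 lat-ant
        labels[2 * i + 2] = post[rows[1]]          # 2 med-post / 4 lat-post
    quad = RegionPartition("post_subtalar4", labels,
                           dict(POST_SUBTALAR_GROUPS))
    return facets, quad


def stress_percentages(values: np.ndarray,
                       partition: RegionPartition) -> StressPercentages:
    """Percentage of the summed von Mises stress captured by each region.

    ``values`` is indexed by element id (full-length array covering every
    partition member).  Region percentages sum to exactly 100; group
    percentages sum member regions.
    """
    values = np.asarray(values, dtype=float)
    sums = {k: float(values[np.asarray(v, dtype=np.int64)].sum())
            for k, v in partition.labels.items()}
    total = sum(sums.values())
    if total <= 0.0:
        raise ValueError("no load transmitted: total region stress is zero")
    pct = {k: 100.0 * v / total for k, v in sums.items()}
    groups = {g: float(sum(pct[r] for r in rs))
              for g, rs in partition.grouping_axes.items()}
    return StressPercentages(per_region=pct, per_group=groups)
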