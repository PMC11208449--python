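"""Penalty contact: node-to-surface with optional Coulomb friction.

Contact is enforced by a stiff normal penalty ("hard" contact approximated
by penalty), separation after contact is always allowed.  Tangential
behaviour is either frictionless (articular surfaces) or Coulomb friction
with a stick/slip return mapping (sole-ground, mu = 0.6).

Each :class:`ContactPair` couples *slave nodes* (the unique nodes of
``surface_a``) against *master triangles* (``surface_b``).  Pairing is by
nearest master triangle of the deformed configuration, refreshed every time
the residual is evaluated; the friction anchor is carried across increments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ContactPair", "ContactState"]


@dataclass
class ContactState:
    """Per-slave mutable contact state (friction anchors, activity)."""

    active: np.ndarray
    anchor: np.ndarray          # reference-frame stick anchor per slave (3,)
    normal_force: np.ndarray
    sliding: np.ndarray | None = None


@dataclass
class ContactPair:
    """A penalty contact pair between two triangle surfaces.

    Parameters
    ----------
    slave_nodes : node ids whose penetration is penalized.
    master_tris : (m, 3) node-id triangles, outward normals pointing toward
        the slave side.
    normal_penalty : stiffness k_n in N/mm per slave node.
    mu : Coulomb friction coefficient; 0 = frictionless.
    tangent_penalty : stick stiffness k_t in N/mm (defaults to k_n / 50).
    """

    slave_nodes: np.ndarray
    master_tris: np.ndarray
    normal_penalty: float
    mu: float = 0.0
    tangent_penalty: float | None = None
    regularization: float = 0.0
    smoothing: float = 0.0              # quadratic blend band (mm penetration)
    separation_allowed: bool = True     # always true; kept for the contract
    state: ContactState | None = None

    def __post_init__(self):
        self.slave_nodes = np.asarray(self.slave_nodes, dtype=np.int64)
        self.master_tris = np.asarray(self.master_tris, dtype=np.int64)
        if self.mu < 0:
            raise ValueError("friction coefficient must be non-negative")
        if self.tangent_penalty is None:
            # compliant stick regularization: keeps the stick/slide return
            # mapping well-conditioned under a quasi-Newton tangent
            self.tangent_penalty = self.normal_penalty / 50.0
        ns = len(self.slave_nodes)
        self.state = ContactState(
            active=np.zeros(ns, dtype=bool),
            anchor=np.full((ns, 3), np.nan),
            normal_force=np.zeros(ns),
            sliding=np.zeros(ns, dtype=bool),
        )

    # -- geometry ---------------------------------------------------------

    def _project(self, x: np.ndarray, coords: np.ndarray):
        """Closest point on the master surface for each slave position.

        Returns (gap, normal, foot_point, tri_index, bary) arrays.
        """
        tri = coords[self.master_tris]                     # (m, 3, 3)
        cent = tri.mean(axis=1)
        cache = getattr(self, "_tree_cache", None)
        char = _char_len(coords, self.master_tris)
        if cache is not None and \
                np.abs(cache[1] - cent).max() < 0.05 * char:
            tree = cache[0]
        else:
            tree = cKDTree(cent)
            self._tree_cache = (tree, cent.copy())
        # a few nearest candidate triangles per slave
        k = min(8, len(cent))
        _, cand = tree.query(x, k=k)
        cand = np.atleast_2d(cand)
        best_d2 = np.full(len(x), np.inf)
        foot = np.zeros((len(x), 3))
        tidx = np.zeros(len(x), dtype=np.int64)
        for c in range(cand.shape[1]):
            ti = cand[:, c]
            p = _closest_on_triangle(x, tri[ti])
            d2 = ((x - p) ** 2).sum(axis=1)
            take = d2 < best_d2
            best_d2[take] = d2[take]
            foot[take] = p[take]
            tidx[take] = ti[take]
        t = tri[tidx]
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        gap = ((x - foot) * n).sum(axis=1)
        return gap, n, foot, tidx

    # -- mechanics --------------------------------------------------------

    def _normal_law(self, pen: np.ndarray) -> np.ndarray:
        """Penalty force magnitude; C1 (quadratically blended) when a
        smoothing band is set."""
        d = self.smoothing
        if d <= 0.0:
            return self.normal_penalty * pen
        kn = self.normal_penalty
        return np.where(pen < d, kn * pen ** 2 / (2.0 * d),
                        kn * (pen - 0.5 * d))

    def _normal_slope(self, pen: np.ndarray) -> np.ndarray:
        d = self.smoothing
        if d <= 0.0:
            return np.full_like(pen, self.normal_penalty)
        return self.normal_penalty * np.minimum(pen / d, 1.0)

    def forces(self, coords0: np.ndarray, u: np.ndarray, update_state: bool,
               drag_anchors: bool = False):
        """Physical contact forces applied to the nodes.

        Returns a (nnodes, 3) array of applied forces (slave pushed off the
        master along the normal, equal and opposite reaction distributed on
        the master triangle nodes) plus the per-slave activity mask, normals
        and normal-force magnitudes.
        """
        x = coords0 + u
        f = np.zeros_like(x)
        xs = x[self.slave_nodes]
        gap, n, foot, tidx = self._project(xs, x)
        pen = np.maximum(0.0, -gap)
        fn = self._normal_law(pen)
        if self.regularization > 0.0:
            fn = fn - self.regularization * gap * (pen == 0.0)
        active = pen > 0.0

        # normal force: push slave along +n, reaction on master triangle nodes
        fvec = fn[:, None] * n
        np.add.at(f, self.slave_nodes, fvec)
        bary = _barycentric(foot, x[self.master_tris[tidx]])
        for j in range(3):
            np.add.at(
                f, self.master_tris[tidx, j], -bary[:, j:j + 1] * fvec
            )

        st = self.state
        if self.mu > 0.0:
            x0s = coords0[self.slave_nodes]
            newly = active & ~st.active
            lost = ~active
            st.anchor[newly] = x0s[newly]
            # stick spring: in-plane part of (current position - anchor),
            # saturated smoothly at the Coulomb bound mu*fn (tanh law)
            rel = xs - np.where(np.isnan(st.anchor), xs, st.anchor)
            rel_t = rel - ((rel * n).sum(axis=1))[:, None] * n
            ft = -self.tangent_penalty * rel_t
            ftn = np.linalg.norm(ft, axis=1)
            bound = self.mu * np.maximum(fn, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                xi = np.where(bound > 0.0, ftn / np.maximum(bound, 1e-30),
                              np.inf)
                scale = np.where(
                    (xi > 1e-9) & np.isfinite(xi), np.tanh(xi) / np.maximum(xi, 1e-30), 1.0)
            slide = active & (xi > 1.0)
            scale = np.where(np.isfinite(xi), scale, 0.0)
            ft *= scale[:, None]
            ft[~active] = 0.0
            np.add.at(f, self.slave_nodes, ft)
            for j in range(3):
                np.add.at(
                    f, self.master_tris[tidx, j], -bary[:, j:j + 1] * ft
                )
            if update_state:
                st.sliding = slide
            if drag_anchors:
                # end of increment: slip accumulates — drag each sliding
                # anchor back to the Coulomb surface (trial stretch -> xi=1)
                drag = np.zeros_like(rel_t)
                if slide.any():
                    ratio = (1.0 - 1.0 / xi[slide])[:, None]
                    drag[slide] = rel_t[slide] * ratio
                st.anchor += drag
                st.anchor[lost] = np.nan
        if update_state:
            st.active = active
            st.normal_force = fn
        return f, active, n, fn

    def stiffness_entries(self, coords0: np.ndarray, u: np.ndarray):
        """Penalty stiffness triplets (rows, cols, vals) in full DOF space.

        Uses the current active set; normal springs along the master normal
        for active (or nearly active) slaves, plus tangential stick springs
        when friction is present.
        """
        x = coords0 + u
        xs = x[self.slave_nodes]
        gap, n, foot, tidx = self._project(xs, x)
        near = gap < 0.0        # consistent with the force: closed gaps only
        rows, cols, vals = [], [], []
        bary = _barycentric(foot, x[self.master_tris[tidx]])
        for i in range(len(self.slave_nodes)):
            s = self.slave_nodes[i]
            mnodes = self.master_tris[tidx[i]]
            w = np.concatenate([[1.0], -bary[i]])
            nodesi = np.concatenate([[s], mnodes])
            ni = n[i]
            kn = float(self._normal_slope(np.array([-gap[i]]))[0]) \
                if near[i] else self.regularization
            kn = max(kn, self.regularization)
            kmats = [kn * np.outer(ni, ni)]
            if self.mu > 0.0 and near[i]:
                kt_eff = self.tangent_penalty
                anchor = self.state.anchor[i]
                fn_i = max(float(self.state.normal_force[i]), 0.0)
                if np.all(np.isfinite(anchor)) and fn_i > 0.0:
                    rel = (x[self.slave_nodes[i]] - anchor)
                    rel_t = rel - np.dot(rel, ni) * ni
                    nt = np.linalg.norm(rel_t)
                    xi = self.tangent_penalty * nt / (self.mu * fn_i)
                    # d/d|rel| of mu*fn*tanh(kt|rel|/(mu fn)) = kt sech^2
                    kt_eff = self.tangent_penalty / np.cosh(min(xi, 20.0)) ** 2
                    if nt > 1e-12 and xi > 0.5:
                        # saturated: friction magnitude follows mu*fn
                        d_dir = -rel_t / nt
                        kmats.append(np.tanh(xi) * self.mu * kn *
                                     np.outer(d_dir, ni))
                kmats.append(kt_eff * (np.eye(3) - np.outer(ni, ni)))
            ktot = sum(kmats)
            if not near[i] and self.regularization <= 0.0:
                continue
            for a in range(4):
                for b in range(4):
                    blk = w[a] * w[b] * ktot
                    for p in range(3):
                        for q in range(3):
                            if blk[p, q] != 0.0:
                                rows.append(3 * nodesi[a] + p)
                                cols.append(3 * nodesi[b] + q)
                                vals.append(blk[p, q])
        return rows, cols, vals


def _char_len(coords, tris):
    t = coords[tris]
    return float(np.mean(np.linalg.norm(t[:, 1] - t[:, 0], axis=1)))


def _closest_on_triangle(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Vectorized closest point on triangles (Ericson's method)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)

    out = np.zeros_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]; done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]; done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]; done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0)
    out[m] = a[m] + v[m, None] * ab[m]; done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0)
    out[m] = a[m] + w[m, None] * ac[m]; done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m]); done |= m

    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def _barycentric(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0, v1, v2 = b - a, c - a, p - a
    d00 = (v0 * v0).sum(1)
    d01 = (v0 * v1).sum(1)
    d11 = (v1 * v1).sum(1)
    d20 = (v2 * v0).sum(1)
    d21 = (v2 * v1).sum(1)
    den = d00 * d11 - d01 * d01
    den = np.where(np.abs(den) < 1e-30, 1.0, den)
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    return np.clip(np.stack([1.0 - v - w, v, w], axis=1), 0.0, 1.0)
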