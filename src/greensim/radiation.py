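"""Long-wave radiation: pairwise net exchange and computed view factors.

The net exchange between two grey opaque surfaces S1, S2 separated by
partially transparent media (screens) is

    Q = eps1*eps2*FF12*A1*prod(tau_x)*sigma*(T1^4 - T2^4)
        / (1 - rho1*rho2*FF12*FF21*prod(tau_x)^2)

View factors for the greenhouse scene are computed numerically: every
surface is meshed into planar quadrilateral cells, cell-to-cell factors
come from the contour double line integral

    F_ab = 1/(2 pi A_a) * closed-int_Ca closed-int_Cb ln|r| dl_a . dl_b

with a centre-ray triangle test for obstacle occlusion, aggregated to
surface level, regressed against crop-row height/width with a bivariate
quadratic, and finally row-normalised so each surface's factors sum to 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import SIGMA_SB

__all__ = [
    "SurfaceNode",
    "RadLink",
    "net_radiative_exchange",
    "compute_view_factor_cellpair",
    "view_factor_between_meshes",
    "subdivide_quad",
    "quad_area",
    "Scene",
    "viewfactor_pipeline",
    "ViewFactorSet",
    "tilt_split_factors",
    "sky_and_boundary_exchange",
    "screen_medium_transmissivity",
]


# ---------------------------------------------------------------------------
# Pairwise exchange
# ---------------------------------------------------------------------------

@dataclass
class SurfaceNode:
    """A radiating/convecting surface: grey, opaque (rho = 1 - eps)."""
    name: str
    area: float
    emissivity: float

    def __post_init__(self):
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError(f"{self.name}: emissivity outside (0, 1]")
        if self.area <= 0.0:
            raise ValueError(f"{self.name}: area must be > 0")

    @property
    def reflectivity(self) -> float:
        return 1.0 - self.emissivity


@dataclass(frozen=True)
class RadLink:
    """A radiative pair with the transmissivities of intervening media."""
    pair: tuple[str, str]
    tau_media: tuple[float, ...] = ()

    def __post_init__(self):
        for t in self.tau_media:
            if not 0.0 <= t <= 1.0:
                raise ValueError("media transmissivity outside [0, 1]")


def screen_medium_transmissivity(u: float, tau_screen_lw: float) -> float:
    """A screen deployed over fraction u acts as a medium with areal-mix
    transmissivity 1 - u*(1 - tau_screen)."""
    return 1.0 - u * (1.0 - tau_screen_lw)


def net_radiative_exchange(node1: SurfaceNode, node2: SurfaceNode,
                           FF12: float, FF21: float,
                           T1: float, T2: float,
                           tau_media: tuple[float, ...] | list[float] = ()
                           ) -> float:
    """Signed net long-wave flux S1 -> S2 (W); temperatures in K."""
    tau_prod = 1.0
    for t in tau_media:
        tau_prod *= t
    num = (node1.emissivity * node2.emissivity * FF12 * node1.area
           * tau_prod * SIGMA_SB * (T1 ** 4 - T2 ** 4))
    den = 1.0 - (node1.reflectivity * node2.reflectivity
                 * FF12 * FF21 * tau_prod ** 2)
    return num / den


# ---------------------------------------------------------------------------
# Geometry helpers: quads and meshing
# ---------------------------------------------------------------------------

def quad_area(quad: np.ndarray) -> float:
    """Area of a planar quadrilateral given as 4x3 corner array."""
    d1 = quad[2] - quad[0]
    d2 = quad[3] - quad[1]
    return 0.5 * float(np.linalg.norm(np.cross(d1, d2)))


def subdivide_quad(quad: np.ndarray, max_cell: float) -> np.ndarray:
    """Split a quad into roughly square cells of edge <= max_cell.
    Returns an (n, 4, 3) array (bilinear subdivision)."""
    quad = np.asarray(quad, dtype=float)
    lu = np.linalg.norm(quad[1] - quad[0])
    lv = np.linalg.norm(quad[3] - quad[0])
    nu = max(1, int(math.ceil(lu / max_cell)))
    nv = max(1, int(math.ceil(lv / max_cell)))
    us = np.linspace(0.0, 1.0, nu + 1)
    vs = np.linspace(0.0, 1.0, nv + 1)

    def P(u, v):
        return ((1 - u) * (1 - v))[..., None] * quad[0] \
            + (u * (1 - v))[..., None] * quad[1] \
            + (u * v)[..., None] * quad[2] \
            + ((1 - u) * v)[..., None] * quad[3]

    cells = []
    for i in range(nu):
        for j in range(nv):
            cells.append([P(np.array(us[i]), np.array(vs[j])),
                          P(np.array(us[i + 1]), np.array(vs[j])),
                          P(np.array(us[i + 1]), np.array(vs[j + 1])),
                          P(np.array(us[i]), np.array(vs[j + 1]))])
    return np.array(cells)


_GAUSS_N = 4
_GX, _GW = np.polynomial.legendre.leggauss(_GAUSS_N)
_GX = 0.5 * (_GX + 1.0)       # map to [0, 1]
_GW = 0.5 * _GW


def _contour_integral(cells_a: np.ndarray, cells_b: np.ndarray) -> np.ndarray:
    """Double contour integral sum_(edges) int int ln|r| dl_a.dl_b for every
    cell pair; shapes (Na,4,3) x (Nb,4,3) -> (Na, Nb)."""
    ea0 = cells_a                                  # (Na,4,3) edge starts
    ea1 = np.roll(cells_a, -1, axis=1)             # edge ends
    eb0 = cells_b
    eb1 = np.roll(cells_b, -1, axis=1)
    da = ea1 - ea0                                 # (Na,4,3)
    db = eb1 - eb0
    # Gauss points along each edge: (N,4,g,3)
    pa = ea0[:, :, None, :] + _GX[None, None, :, None] * da[:, :, None, :]
    pb = eb0[:, :, None, :] + _GX[None, None, :, None] * db[:, :, None, :]
    dot = np.einsum("aid,bjd->aibj", da, db)       # (Na,4,Nb,4)
    # pairwise distances between gauss points: (Na,4,g,Nb,4,g)
    diff = pa[:, :, :, None, None, None, :] - pb[None, None, None, :, :, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    lnr = np.log(np.maximum(r, 1e-12))
    w = _GW[None, None, :, None, None, None] * _GW[None, None, None, None, None, :]
    integ = np.sum(lnr * w, axis=(2, 5))           # (Na,4,Nb,4)
    return np.einsum("aibj,aibj->ab", integ, dot.transpose(0, 1, 2, 3))


def _K_collinear(u: float) -> float:
    """Second antiderivative of ln|u| (K'' = ln|u|), K(0) = 0."""
    if u == 0.0:
        return 0.0
    return u * u * (2.0 * math.log(abs(u)) - 3.0) / 4.0


def _edgepair_integral(p0, p1, q0, q1) -> float:
    """Careful edge-pair term of the contour integral:
    (e_a . e_b) * int int ln|r| over unit parameters, robust to touching
    and collinear (shared) edges."""
    ea = p1 - p0
    eb = q1 - q0
    la = float(np.linalg.norm(ea))
    lb = float(np.linalg.norm(eb))
    if la < 1e-12 or lb < 1e-12:
        return 0.0
    dot = float(ea @ eb)
    if abs(dot) < 1e-14:
        return 0.0
    ua = ea / la
    # collinear test: parallel and q0 on the line through p0
    cross = np.cross(ea, eb)
    off = q0 - p0
    perp = off - (off @ ua) * ua
    if (np.linalg.norm(cross) < 1e-9 * la * lb
            and np.linalg.norm(perp) < 1e-9 * max(la, lb, 1.0)):
        al, ah = 0.0, la
        b0 = float(off @ ua)
        b1 = float((q1 - p0) @ ua)
        bl, bh = min(b0, b1), max(b0, b1)
        I_arc = (_K_collinear(ah - bl) + _K_collinear(al - bh)
                 - _K_collinear(ah - bh) - _K_collinear(al - bl))
        sgn = 1.0 if dot > 0 else -1.0
        return sgn * I_arc
    # near-singular but not collinear: subdivided Gauss quadrature
    ns = 8
    offs = (np.arange(ns)[:, None] + _GX[None, :]).ravel() / ns   # (ns*g,)
    wts = np.tile(_GW, ns) / ns
    pa = p0[None, :] + offs[:, None] * ea[None, :]
    pb = q0[None, :] + offs[:, None] * eb[None, :]
    r = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    lnr = np.log(np.maximum(r, 1e-12))
    return dot * float(wts @ lnr @ wts)


def _cellpair_integral_careful(cell_a: np.ndarray, cell_b: np.ndarray) -> float:
    """Contour integral for one cell pair with singular edge handling."""
    total = 0.0
    for i in range(4):
        p0, p1 = cell_a[i], cell_a[(i + 1) % 4]
        for j in range(4):
            q0, q1 = cell_b[j], cell_b[(j + 1) % 4]
            total += _edgepair_integral(p0, p1, q0, q1)
    return total


def _min_corner_distance(cell_a: np.ndarray, cell_b: np.ndarray) -> float:
    d = cell_a[:, None, :] - cell_b[None, :, :]
    return float(np.sqrt((d * d).sum(-1)).min())


def _cell_scale(cell: np.ndarray) -> float:
    return float(max(np.linalg.norm(cell[1] - cell[0]),
                     np.linalg.norm(cell[3] - cell[0])))


def _cell_centers(cells: np.ndarray) -> np.ndarray:
    return cells.mean(axis=1)


def _triangulate(quads: np.ndarray) -> np.ndarray:
    """(N,4,3) quads -> (2N,3,3) triangles."""
    t1 = quads[:, [0, 1, 2], :]
    t2 = quads[:, [0, 2, 3], :]
    return np.concatenate([t1, t2], axis=0)


def _rays_blocked(origins: np.ndarray, targets: np.ndarray,
                  triangles: np.ndarray) -> np.ndarray:
    """Moeller-Trumbore: for each ray origin->target, is any triangle
    strictly between them?  origins/targets (M,3), triangles (T,3,3)."""
    if len(triangles) == 0:
        return np.zeros(len(origins), dtype=bool)
    d = targets - origins                          # (M,3)
    v0 = triangles[:, 0]                           # (T,3)
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    blocked = np.zeros(len(origins), dtype=bool)
    # loop over triangles (T is small), vectorise over rays
    for k in range(len(triangles)):
        h = np.cross(d, e2[k])                     # (M,3)
        a = np.einsum("md,d->m", h, e1[k])
        ok = np.abs(a) > 1e-12
        f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        s = origins - v0[k]
        u = f * np.einsum("md,md->m", s, h)
        q = np.cross(s, e1[k])
        v = f * np.einsum("md,md->m", q, d)
        t = f * np.einsum("md,d->m", q, e2[k])
        hit = (ok & (u >= -1e-9) & (u <= 1 + 1e-9) & (v >= -1e-9)
               & (u + v <= 1 + 1e-9) & (t > 1e-6) & (t < 1 - 1e-6))
        blocked |= hit
    return blocked


def compute_view_factor_cellpair(cell_a: np.ndarray, cell_b: np.ndarray,
                                 obstacles: np.ndarray | None = None) -> float:
    """Cell-to-cell view factor by the contour method; zero when the
    centre-connecting ray is blocked by an obstacle triangle."""
    cell_a = np.asarray(cell_a, dtype=float)
    cell_b = np.asarray(cell_b, dtype=float)
    if quad_area(cell_a) <= 1e-12 or quad_area(cell_b) <= 1e-12:
        raise ValueError("degenerate polygon")
    if obstacles is not None and len(obstacles):
        if _rays_blocked(_cell_centers(cell_a[None]),
                         _cell_centers(cell_b[None]), obstacles)[0]:
            return 0.0
    # |.|: the integral's sign follows the relative winding of the two
    # contours; the view factor itself is positive
    val = abs(_cellpair_integral_careful(cell_a, cell_b))
    return float(val / (2.0 * math.pi * quad_area(cell_a)))


def view_factor_between_meshes(cells_a: np.ndarray, cells_b: np.ndarray,
                               obstacles: np.ndarray | None = None
                               ) -> float:
    """Surface-to-surface view factor: area-weighted aggregation of
    cell-pair factors (occluded pairs zeroed)."""
    areas_a = np.array([quad_area(c) for c in cells_a])
    vals = _contour_integral(cells_a, cells_b)
    # touching / near-touching cell pairs: redo with singular-edge handling
    ca = cells_a[:, :, None, None, :] - cells_b[None, None, :, :, :]
    mind = np.sqrt((ca * ca).sum(-1)).min(axis=(1, 3))        # (Na, Nb)
    scales = np.maximum(
        np.array([_cell_scale(c) for c in cells_a])[:, None],
        np.array([_cell_scale(c) for c in cells_b])[None, :])
    redo = np.argwhere(mind < 0.1 * scales)
    for ia, ib in redo:
        vals[ia, ib] = _cellpair_integral_careful(cells_a[ia], cells_b[ib])
    vals = np.abs(vals) / (2.0 * math.pi)          # A_a * F_ab
    if obstacles is not None and len(obstacles):
        ca = _cell_centers(cells_a)
        cb = _cell_centers(cells_b)
        Na, Nb = len(cells_a), len(cells_b)
        orig = np.repeat(ca, Nb, axis=0)
        targ = np.tile(cb, (Na, 1))
        blocked = _rays_blocked(orig, targ, obstacles).reshape(Na, Nb)
        vals = np.where(blocked, 0.0, vals)
    vals = np.maximum(vals, 0.0)
    return float(vals.sum() / areas_a.sum())


# ---------------------------------------------------------------------------
# Scene and pipeline
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """Named surfaces, each a (n,4,3) array of quads.  ``mutual_obstacles``
    lists surface names that occlude radiation between other surfaces."""
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)
    occluders: list[str] = field(default_factory=list)

    def add(self, name: str, quads: np.ndarray, occludes: bool = False):
        quads = np.asarray(quads, dtype=float)
        if quads.ndim == 2:
            quads = quads[None]
        self.surfaces[name] = quads
        if occludes:
            self.occluders.append(name)

    def area(self, name: str) -> float:
        return float(sum(quad_area(q) for q in self.surfaces[name]))

    def mesh(self, name: str, cell_size: float) -> np.ndarray:
        return np.concatenate([subdivide_quad(q, cell_size)
                               for q in self.surfaces[name]])

    def obstacle_triangles(self, exclude: tuple[str, str]) -> np.ndarray:
        quads = [self.surfaces[n] for n in self.occluders if n not in exclude]
        if not quads:
            return np.empty((0, 3, 3))
        return _triangulate(np.concatenate(quads))


@dataclass
class ViewFactorSet:
    """Crop-size-dependent view factors: per-pair bivariate quadratic
    regressions FF(h, w), with global row normalization on evaluation."""
    names: list[str]
    coeffs: dict[tuple[str, str], np.ndarray]
    areas: dict[str, float]
    r_squared: dict[tuple[str, str], float] = field(default_factory=dict)
    reciprocity_max_err: float = 0.0

    @staticmethod
    def _design(h: float, w: float) -> np.ndarray:
        return np.array([1.0, h, w, h * h, h * w, w * w])

    def raw_matrix(self, crop_height: float, crop_width: float) -> np.ndarray:
        x = self._design(crop_height, crop_width)
        n = len(self.names)
        M = np.zeros((n, n))
        for (a, b), c in self.coeffs.items():
            i, j = self.names.index(a), self.names.index(b)
            M[i, j] = max(0.0, float(c @ x))
        return M

    def matrix(self, crop_height: float, crop_width: float) -> np.ndarray:
        """Row-normalised view-factor matrix (each row sums to 1)."""
        M = self.raw_matrix(crop_height, crop_width)
        rows = M.sum(axis=1, keepdims=True)
        rows[rows <= 0] = 1.0
        return M / rows

    def to_json(self, path):
        data = {
            "names": self.names,
            "areas": self.areas,
            "coeffs": {f"{a}|{b}": c.tolist() for (a, b), c in self.coeffs.items()},
            "r_squared": {f"{a}|{b}": v for (a, b), v in self.r_squared.items()},
            "reciprocity_max_err": self.reciprocity_max_err,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        coeffs = {tuple(k.split("|")): np.array(v) for k, v in d["coeffs"].items()}
        rsq = {tuple(k.split("|")): v for k, v in d.get("r_squared", {}).items()}
        return cls(names=d["names"], coeffs=coeffs, areas=d["areas"],
                   r_squared=rsq,
                   reciprocity_max_err=d.get("reciprocity_max_err", 0.0))


def viewfactor_pipeline(scene_builder, crop_heights, crop_widths,
                        cell_size: float = 2.0,
                        reciprocity_tol: float = 0.05) -> ViewFactorSet:
    """Batch view-factor computation over a crop-size grid.

    ``scene_builder(h, w) -> Scene``; all surface pairs present in the
    scene are meshed, integrated (with occlusion), symmetrised through the
    reciprocity theorem, then regressed as FF(h, w) with a bivariate
    quadratic.  Row normalisation happens at evaluation time.
    """
    samples: dict[tuple[str, str], list[float]] = {}
    pts = []
    names = None
    areas = None
    max_rec_err = 0.0
    for h in crop_heights:
        for w in crop_widths:
            scene = scene_builder(h, w)
            if names is None:
                names = list(scene.surfaces)
            areas = {n: scene.area(n) for n in names}
            meshes = {n: scene.mesh(n, cell_size) for n in names}
            pts.append((h, w))
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    obst = scene.obstacle_triangles(exclude=(a, b))
                    Fab = view_factor_between_meshes(meshes[a], meshes[b], obst)
                    Fba = view_factor_between_meshes(meshes[b], meshes[a], obst)
                    # reciprocity check then symmetrisation
                    lhs, rhs = areas[a] * Fab, areas[b] * Fba
                    if max(lhs, rhs) > 1e-9:
                        err = abs(lhs - rhs) / max(lhs, rhs)
                        max_rec_err = max(max_rec_err, err)
                    sym = 0.5 * (lhs + rhs)
                    samples.setdefault((a, b), []).append(sym / areas[a])
                    samples.setdefault((b, a), []).append(sym / areas[b])
    X = np.array([ViewFactorSet._design(h, w) for h, w in pts])
    coeffs = {}
    rsq = {}
    for pair, ys in samples.items():
        y = np.array(ys)
        if len(pts) >= 6:
            c, *_ = np.linalg.lstsq(X, y, rcond=None)
        else:
            # fewer sample points than the quadratic basis: fit the
            # affine part only
            c_aff, *_ = np.linalg.lstsq(X[:, :min(3, len(pts))], y, rcond=None)
            c = np.zeros(6)
            c[:len(c_aff)] = c_aff
        pred = X @ c
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        rsq[pair] = 1.0 - ss_res / ss_tot if ss_tot > 1e-15 else 1.0
        coeffs[pair] = c
    return ViewFactorSet(names=names, coeffs=coeffs, areas=areas,
                         r_squared=rsq, reciprocity_max_err=max_rec_err)


# ---------------------------------------------------------------------------
# Sky / outdoor-boundary exchange
# ---------------------------------------------------------------------------

def tilt_split_factors(tilt_deg: float) -> tuple[float, float]:
    """Isotropic split of the external view of a tilted surface into
    (sky, ground) shares: ((1+cos t)/2, (1-cos t)/2)."""
    c = math.cos(math.radians(tilt_deg))
    return (1.0 + c) / 2.0, (1.0 - c) / 2.0


def sky_and_boundary_exchange(node: SurfaceNode, T_surface: float,
                              T_sky: float, T_ground: float,
                              tilt_deg: float = 0.0) -> float:
    """Net long-wave loss (W) of an exterior surface toward the sky (black
    body at T_sky) and the outdoor ground (black body at T_ground), split
    by the isotropic tilt factors."""
    f_sky, f_gnd = tilt_split_factors(tilt_deg)
    e = node.emissivity * node.area * SIGMA_SB
    return e * (f_sky * (T_surface ** 4 - T_sky ** 4)
                + f_gnd * (T_surface ** 4 - T_ground ** 4))
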