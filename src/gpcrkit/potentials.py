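"""Analytic and bead-spring potential models used as desk-scale sampling systems.

Every model exposes a two-term energy decomposition ``(soft, rest)``:

* ``soft`` collects the slow conformational terms (hinge/orientation double
  wells, the nucleotide pocket well).  In dual-boost accelerated sampling it
  plays the role the dihedral energy term plays in all-atom work.
* ``rest`` collects stiff bonds, tethers and walls.

The total potential is the sum of the two.  Forces are analytic; a
finite-difference consistency check is provided (`check_forces`).
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kbt

__all__ = [
    "PotentialModel",
    "DoubleWell1D",
    "MultiWell2D",
    "GaussianWell",
    "ToyGProteinSpec",
    "GProteinToy",
    "make_double_well",
    "make_2d_multiwell",
    "make_gprotein_toy",
    "wt_analog_spec",
    "r291a_analog_spec",
    "check_forces",
]


class PotentialModel(abc.ABC):
    """An energy/force-evaluable model over ``ndim`` Cartesian-like coordinates.

    Attributes
    ----------
    ndim : int
        Number of degrees of freedom.
    masses : ndarray, shape (ndim,)
        Mass per degree of freedom, amu.
    term_names : tuple of str
        Names of the two energy terms, ``("soft", "rest")``.
    default_start : ndarray
        A sensible starting configuration for dynamics.
    """

    term_names = ("soft", "rest")

    ndim: int
    masses: np.ndarray
    default_start: np.ndarray

    @abc.abstractmethod
    def energy_force(self, x: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
        """Return ``(V_soft, V_rest, F_soft, F_rest)`` at configuration ``x``."""

    # -- conveniences -------------------------------------------------------
    def energy_terms(self, x) -> dict[str, float]:
        vs, vr, _, _ = self.energy_force(np.asarray(x, dtype=float))
        return {"soft": vs, "rest": vr}

    def energy(self, x) -> float:
        vs, vr, _, _ = self.energy_force(np.asarray(x, dtype=float))
        return vs + vr

    def force(self, x) -> np.ndarray:
        _, _, fs, fr = self.energy_force(np.asarray(x, dtype=float))
        return fs + fr


def check_forces(model: PotentialModel, x, h: float = 1e-5, rel_tol: float = 1e-4) -> float:
    """Central-difference force consistency check.

    Returns the relative error ``||F_num - F_ana|| / max(||F_num||, 1e-8)``
    and raises ``AssertionError`` if it exceeds ``rel_tol``.
    """
    x = np.asarray(x, dtype=float)
    f_ana = model.force(x)
    f_num = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        f_num[i] = -(model.energy(xp) - model.energy(xm)) / (2 * h)
    denom = max(float(np.linalg.norm(f_num)), 1e-8)
    rel = float(np.linalg.norm(f_num - f_ana)) / denom
    if rel > rel_tol:
        raise AssertionError(f"force/energy inconsistency: relative error {rel:.3e} at x={x!r}")
    return rel


# ---------------------------------------------------------------------------
# 1-D double well
# ---------------------------------------------------------------------------


class DoubleWell1D(PotentialModel):
    """Quartic double well ``V(x) = a (x^2 - b^2)^2``.

    Minima at ``x = +-b`` with ``V = 0``; barrier height ``a b^4`` at the
    origin.  The whole potential lives in the ``soft`` term.
    """

    def __init__(self, a: float, b: float, mass: float = 10.0):
        if a <= 0 or b <= 0:
            raise ValueError("double well requires a > 0 and b > 0")
        self.a = float(a)
        self.b = float(b)
        self.ndim = 1
        self.masses = np.full(1, float(mass))
        self.default_start = np.array([-self.b])

    @property
    def barrier(self) -> float:
        return self.a * self.b**4

    def energy_force(self, x):
        x = np.asarray(x, dtype=float)
        q = x[0]
        d = q * q - self.b * self.b
        v = self.a * d * d
        f = np.array([-4.0 * self.a * q * d])
        return v, 0.0, f, np.zeros(1)

    def reference_pmf(self, edges: np.ndarray, temperature: float = DEFAULT_TEMPERATURE,
                      n_quad: int = 400) -> np.ndarray:
        """Numerically exact binned PMF by quadrature of ``exp(-V/kBT)``.

        ``n_quad`` midpoint sub-points per bin; min-normalized over bins.
        """
        return _quadrature_pmf_1d(lambda q: self.a * (q * q - self.b**2) ** 2,
                                  edges, temperature, n_quad)


def _quadrature_pmf_1d(vfun, edges, temperature, n_quad):
    edges = np.asarray(edges, dtype=float)
    beta = 1.0 / kbt(temperature)
    z = np.empty(edges.size - 1)
    for j in range(edges.size - 1):
        qs = np.linspace(edges[j], edges[j + 1], n_quad + 1)
        mid = 0.5 * (qs[:-1] + qs[1:])
        z[j] = np.mean(np.exp(-beta * vfun(mid))) * (edges[j + 1] - edges[j])
    f = -kbt(temperature) * np.log(z)
    return f - f.min()


# ---------------------------------------------------------------------------
# 2-D multiwell
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianWell:
    """A single attractive Gaussian well: depth > 0 lowers the energy."""

    cx: float
    cy: float
    depth: float
    width: float

    def __post_init__(self):
        if self.depth <= 0 or self.width <= 0:
            raise ValueError("well depth and width must be positive")


class MultiWell2D(PotentialModel):
    """Sum of attractive 2-D Gaussian wells inside a soft quartic box.

    ``V(x, y) = -sum_i d_i exp(-r_i^2 / (2 w_i^2)) + wall`` where the wall is
    ``k_w * max(|x| - L, 0)^4`` per axis.  Wells form the ``soft`` term, the
    wall the ``rest`` term.
    """

    def __init__(self, wells: list[GaussianWell], box: float = 5.0,
                 wall_k: float = 1.0, mass: float = 10.0):
        if len(wells) < 1:
            raise ValueError("at least one well required")
        centers = {(w.cx, w.cy) for w in wells}
        if len(centers) != len(wells):
            raise ValueError("degenerate wells with identical centers rejected")
        self.wells = list(wells)
        self.box = float(box)
        self.wall_k = float(wall_k)
        self.ndim = 2
        self.masses = np.full(2, float(mass))
        self.default_start = np.array([wells[0].cx, wells[0].cy])

    def _wells_v(self, x, y):
        v = np.zeros(np.broadcast(x, y).shape)
        for w in self.wells:
            v -= w.depth * np.exp(-(((x - w.cx) ** 2 + (y - w.cy) ** 2) / (2 * w.width**2)))
        return v

    def energy_force(self, x):
        x = np.asarray(x, dtype=float)
        px, py = x
        vs = 0.0
        fs = np.zeros(2)
        for w in self.wells:
            dx, dy = px - w.cx, py - w.cy
            g = w.depth * np.exp(-(dx * dx + dy * dy) / (2 * w.width**2))
            vs -= g
            # F = -dV/dr; V = -g  =>  F = -g * r / w^2
            fs[0] -= g * dx / w.width**2
            fs[1] -= g * dy / w.width**2
        vr = 0.0
        fr = np.zeros(2)
        for i, q in enumerate((px, py)):
            over = abs(q) - self.box
            if over > 0:
                vr += self.wall_k * over**4
                fr[i] = -4.0 * self.wall_k * over**3 * np.sign(q)
        return vs, vr, fs, fr

    def reference_pmf_2d(self, edges_x, edges_y, temperature: float = DEFAULT_TEMPERATURE,
                         n_quad: int = 400):
        """Exact binned 2-D PMF over (x, y) by midpoint quadrature.

        ``n_quad`` points per dimension across the full binned domain.
        """
        edges_x = np.asarray(edges_x, dtype=float)
        edges_y = np.asarray(edges_y, dtype=float)
        beta = 1.0 / kbt(temperature)

        def _nested(edges):
            # per-bin midpoint sub-grids so refinement nests inside bins
            nb = edges.size - 1
            m = max(int(np.ceil(n_quad / nb)), 2)
            pts = np.empty(nb * m)
            widths = np.empty(nb * m)
            for j in range(nb):
                sub = np.linspace(edges[j], edges[j + 1], m + 1)
                pts[j * m:(j + 1) * m] = 0.5 * (sub[:-1] + sub[1:])
                widths[j * m:(j + 1) * m] = sub[1] - sub[0]
            idx = np.repeat(np.arange(nb), m)
            return pts, widths, idx

        mx, wx, ix = _nested(edges_x)
        my, wy, iy = _nested(edges_y)
        X, Y = np.meshgrid(mx, my, indexing="ij")
        v = self._wells_v(X, Y)
        for Q in (X, Y):
            over = np.maximum(np.abs(Q) - self.box, 0.0)
            v = v + self.wall_k * over**4
        w = np.exp(-beta * v) * (wx[:, None] * wy[None, :])
        z = np.zeros((edges_x.size - 1, edges_y.size - 1))
        np.add.at(z, (np.broadcast_to(ix[:, None], w.shape),
                      np.broadcast_to(iy[None, :], w.shape)), w)
        with np.errstate(divide="ignore"):
            f = -kbt(temperature) * np.log(z)
        return f - f[np.isfinite(f)].min()

    def reference_pmf_1d(self, edges_x, temperature: float = DEFAULT_TEMPERATURE,
                         n_quad: int = 400, y_range: tuple[float, float] | None = None):
        """Exact binned PMF over x, marginalizing y by quadrature."""
        if y_range is None:
            y_range = (-self.box - 2.0, self.box + 2.0)

        def vfun(qx):
            ys = np.linspace(y_range[0], y_range[1], n_quad + 1)
            my = 0.5 * (ys[:-1] + ys[1:])
            X, Y = np.meshgrid(np.atleast_1d(qx), my, indexing="ij")
            v = self._wells_v(X, Y)
            overx = np.maximum(np.abs(X) - self.box, 0.0)
            overy = np.maximum(np.abs(Y) - self.box, 0.0)
            v = v + self.wall_k * (overx**4 + overy**4)
            beta = 1.0 / kbt(temperature)
            z = np.mean(np.exp(-beta * v), axis=1)
            return -np.log(z) * kbt(temperature)

        edges_x = np.asarray(edges_x, dtype=float)
        beta = 1.0 / kbt(temperature)
        zz = np.empty(edges_x.size - 1)
        for j in range(edges_x.size - 1):
            qs = np.linspace(edges_x[j], edges_x[j + 1], max(n_quad // (edges_x.size - 1), 8) + 1)
            mid = 0.5 * (qs[:-1] + qs[1:])
            zz[j] = np.mean(np.exp(-beta * vfun(mid))) * (edges_x[j + 1] - edges_x[j])
        f = -kbt(temperature) * np.log(zz)
        return f - f.min()


# ---------------------------------------------------------------------------
# Coarse-grained receptor / G-protein toy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyGProteinSpec:
    """Specification of the coarse-grained receptor-G-protein bead system.

    Angles in degrees, energies kcal/mol, lengths A, masses amu.  The system
    caricatures the slow conformational coordinates of a receptor-bound
    heterotrimeric G protein: an alpha5-helix hinge with two poses, an
    AHD-orientation double well (closed / partially open) and a nucleotide
    bead confined in a binding pocket by a radial barrier ring.
    """

    hinge_minima: tuple[float, float] = (110.0, 150.0)
    pocket_barrier: float = 5.0
    ahd_minima: tuple[float, float] = (20.0, 50.0)
    bead_masses: float = 50.0
    hinge_barrier: float = 3.0
    ahd_barrier: float = 2.0
    pocket_radius: float = 6.0      # barrier-ring radius, A
    pocket_width: float = 1.2       # barrier-ring Gaussian width, A
    bound_depth: float = 1.5        # shallow attractive well holding the bead
    bound_width: float = 2.5
    wall_radius: float = 13.0       # outer reflecting wall

    def __post_init__(self):
        if self.pocket_barrier < 0 or self.hinge_barrier < 0 or self.ahd_barrier < 0:
            raise ValueError("barriers must be >= 0")
        if self.hinge_minima[0] == self.hinge_minima[1]:
            raise ValueError("hinge minima must be distinct")
        if self.ahd_minima[0] == self.ahd_minima[1]:
            raise ValueError("AHD minima must be distinct")


def wt_analog_spec() -> ToyGProteinSpec:
    """Low pocket barrier: the released plateau is reachable under boosting."""
    return ToyGProteinSpec(pocket_barrier=2.0)


def r291a_analog_spec() -> ToyGProteinSpec:
    """High pocket barrier: only partial excursions of the nucleotide bead."""
    return ToyGProteinSpec(pocket_barrier=12.0)


def _angle_grad(a, b, c):
    """Angle a-b-c (rad) and its gradients w.r.t. a, b, c."""
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    uh = u / nu
    vh = v / nv
    ct = float(np.clip(uh @ vh, -1.0, 1.0))
    st = np.sqrt(max(1.0 - ct * ct, 1e-12))
    theta = np.arccos(ct)
    da = (ct * uh - vh) / (nu * st)
    dc = (ct * vh - uh) / (nv * st)
    return theta, da, -(da + dc), dc


def _dw_angle(theta, t1, t2, height):
    """Quartic angular double well with minima t1 < t2 and midpoint barrier ``height``."""
    delta = t2 - t1
    c = 16.0 * height / delta**4
    p = (theta - t1) * (theta - t2)
    v = c * p * p
    dv = c * 2.0 * p * (2.0 * theta - t1 - t2)
    return v, dv


class GProteinToy(PotentialModel):
    """Five-bead receptor-G-protein toy system.

    Beads: 0 receptor/Ras core (tethered at the origin), 1-2 alpha5 chain with
    a hinge-angle double well at vertex bead 1, 3 AHD bead whose orientation
    angle from the laboratory z axis has a double well, 4 nucleotide (GDP)
    bead in a radial pocket about the core: a shallow bound well, a Gaussian
    barrier ring of height ``pocket_barrier`` at ``pocket_radius`` and a
    quartic wall at ``wall_radius``.

    Soft term: hinge + AHD + pocket radial potential.  Rest: bonds, tether,
    wall.
    """

    N_BEADS = 5
    K_TETHER = 50.0
    K_BOND = 20.0
    R_A5 = 5.0
    R_AHD = 6.0
    K_WALL = 2.0

    def __init__(self, spec: ToyGProteinSpec):
        self.spec = spec
        self.ndim = 3 * self.N_BEADS
        m = np.asarray(spec.bead_masses, dtype=float)
        if m.ndim == 0:
            m = np.full(self.N_BEADS, float(m))
        if m.size != self.N_BEADS or np.any(m <= 0):
            raise ValueError("bead_masses must be a positive scalar or length-5 array")
        self.masses = np.repeat(m, 3)
        self._t1, self._t2 = np.deg2rad(sorted(spec.hinge_minima))
        self._a1, self._a2 = np.deg2rad(sorted(spec.ahd_minima))
        self.default_start = self._build_start()

    def _build_start(self):
        s = self.spec
        r = np.zeros((self.N_BEADS, 3))
        r[1] = (self.R_A5, 0.0, 0.0)
        th = self._t1
        r[2] = r[1] + self.R_A5 * np.array([-np.cos(th), np.sin(th), 0.0])
        ph = self._a1
        r[3] = self.R_AHD * np.array([0.0, np.sin(ph), np.cos(ph)])
        r[4] = (0.0, -1.5, 0.0)
        return r.ravel()

    # coordinate helpers -----------------------------------------------------
    @staticmethod
    def _beads(x):
        return np.asarray(x, dtype=float).reshape(-1, 3)

    def hinge_angle(self, x) -> float:
        """alpha5 hinge angle (deg) at bead 1."""
        r = self._beads(x)
        theta, *_ = _angle_grad(r[0], r[1], r[2])
        return float(np.rad2deg(theta))

    def ahd_angle(self, x) -> float:
        """AHD orientation angle from z (deg)."""
        r = self._beads(x)
        u = r[3] - r[0]
        ct = np.clip(u[2] / np.linalg.norm(u), -1.0, 1.0)
        return float(np.rad2deg(np.arccos(ct)))

    def gdp_distance(self, x) -> float:
        """Radial distance of the nucleotide bead from the core (A)."""
        r = self._beads(x)
        return float(np.linalg.norm(r[4] - r[0]))

    # energy/forces ----------------------------------------------------------
    def energy_force(self, x):
        s = self.spec
        r = self._beads(x)
        fs = np.zeros_like(r)
        fr = np.zeros_like(r)
        vs = 0.0
        vr = 0.0

        # tether bead 0 at origin
        vr += 0.5 * self.K_TETHER * float(r[0] @ r[0])
        fr[0] -= self.K_TETHER * r[0]

        # stiff bonds
        for (i, j, r0) in ((0, 1, self.R_A5), (1, 2, self.R_A5), (0, 3, self.R_AHD)):
            d = r[i] - r[j]
            dist = np.linalg.norm(d)
            vr += 0.5 * self.K_BOND * (dist - r0) ** 2
            g = self.K_BOND * (dist - r0) / max(dist, 1e-10)
            fr[i] -= g * d
            fr[j] += g * d

        # hinge double well (soft)
        theta, da, db, dc = _angle_grad(r[0], r[1], r[2])
        v, dv = _dw_angle(theta, self._t1, self._t2, s.hinge_barrier)
        vs += v
        fs[0] -= dv * da
        fs[1] -= dv * db
        fs[2] -= dv * dc

        # AHD orientation double well (soft); angle between (r3 - r0) and z
        u = r[3] - r[0]
        nu = np.linalg.norm(u)
        uh = u / nu
        zh = np.array([0.0, 0.0, 1.0])
        ct = float(np.clip(uh @ zh, -1.0, 1.0))
        st = np.sqrt(max(1.0 - ct * ct, 1e-12))
        phi = np.arccos(ct)
        v, dv = _dw_angle(phi, self._a1, self._a2, s.ahd_barrier)
        vs += v
        dphi_du = (ct * uh - zh) / (nu * st)
        fs[3] -= dv * dphi_du
        fs[0] += dv * dphi_du

        # nucleotide pocket: radial about bead 0
        d = r[4] - r[0]
        dist = np.linalg.norm(d)
        if dist > 1e-8:
            rh = d / dist
            ring = s.pocket_barrier * np.exp(-(((dist - s.pocket_radius) / s.pocket_width) ** 2))
            bound = -s.bound_depth * np.exp(-((dist / s.bound_width) ** 2))
            vs += ring + bound
            dvdr = (ring * (-2.0 * (dist - s.pocket_radius) / s.pocket_width**2)
                    + (-bound) * (2.0 * dist / s.bound_width**2))
            fs[4] -= dvdr * rh
            fs[0] += dvdr * rh
            over = dist - s.wall_radius
            if over > 0:
                vr += self.K_WALL * over**4
                g = 4.0 * self.K_WALL * over**3
                fr[4] -= g * rh
                fr[0] += g * rh
        else:
            vs += s.pocket_barrier * np.exp(-((s.pocket_radius / s.pocket_width) ** 2)) - s.bound_depth

        return vs, vr, fs.ravel(), fr.ravel()


# ---------------------------------------------------------------------------
# factories (validated entry points)
# ---------------------------------------------------------------------------


def make_double_well(a: float, b: float, mass: float = 10.0) -> DoubleWell1D:
    """1-D quartic double well with minima at +-b and barrier ``a * b**4``."""
    return DoubleWell1D(a, b, mass=mass)


def make_2d_multiwell(wells, box: float = 5.0, wall_k: float = 1.0) -> MultiWell2D:
    """2-D landscape from a list of ``GaussianWell`` (or ``(cx, cy, depth, width)``)."""
    parsed = [w if isinstance(w, GaussianWell) else GaussianWell(*w) for w in wells]
    if len(parsed) < 1:
        raise ValueError("at least one well required")
    return MultiWell2D(parsed, box=box, wall_k=wall_k)


def make_gprotein_toy(spec: ToyGProteinSpec) -> GProteinToy:
    """Bead-spring receptor-G-protein caricature from a validated spec."""
    return GProteinToy(spec)
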