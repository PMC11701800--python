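"""Staggered-grid (MAC) finite-volume Stokes--Brinkman solver.

Unknowns: velocity components on cell faces, pressure at cell centers.
The momentum balance in a fluid cell is ``0 = -grad p + mu lap u + f`` and in
a porous cell carries the additional Brinkman drag ``-(mu/kappa) u``.  The
discrete saddle system is solved by an Uzawa conjugate-gradient iteration on
the pressure Schur complement; the three velocity blocks decouple (constant
viscosity vector Laplacian) and are LU-factorised once per geometry, so each
CG step only costs triangular back-substitutions.

Boundary conditions per domain face: ``wall`` (no slip), ``symmetry`` (free
slip), ``inflow`` (Dirichlet normal velocity array, zero tangential),
``dirichlet`` (all three components from a callable, for manufactured
solutions), ``outflow`` (boundary pressure 0, zero normal gradient) and
``periodic`` (must be set on both sides of an axis).

Interior solid voxels (resolved scaffold beams) impose no slip on every
adjacent face.  Everything is SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = ["MacGrid", "MacStokesSolution", "solve_mac_stokes", "divergence"]

_FACE_KEYS = ("x-", "x+", "y-", "y+", "z-", "z+")
_BC_TYPES = {"wall", "symmetry", "inflow", "dirichlet", "outflow", "periodic"}


@dataclass(frozen=True)
class MacGrid:
    """Rectilinear cell grid defined by its face coordinates (m)."""

    xf: np.ndarray
    yf: np.ndarray
    zf: np.ndarray

    def __post_init__(self):
        for name in ("xf", "yf", "zf"):
            f = np.asarray(getattr(self, name), dtype=float)
            if f.ndim != 1 or f.size < 2 or np.any(np.diff(f) <= 0):
                raise ValueError(f"{name} must be strictly increasing, >= 2 entries")
            object.__setattr__(self, name, f)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.xf.size - 1, self.yf.size - 1, self.zf.size - 1)

    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.xf[1:] + self.xf[:-1])

    @property
    def yc(self) -> np.ndarray:
        return 0.5 * (self.yf[1:] + self.yf[:-1])

    @property
    def zc(self) -> np.ndarray:
        return 0.5 * (self.zf[1:] + self.zf[:-1])

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.xf)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.yf)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.zf)

    def cell_volumes(self) -> np.ndarray:
        return (self.dx[:, None, None] * self.dy[None, :, None]
                * self.dz[None, None, :])

    def extent(self) -> tuple[float, float, float]:
        return (self.xf[-1] - self.xf[0], self.yf[-1] - self.yf[0],
                self.zf[-1] - self.zf[0])


@dataclass
class MacStokesSolution:
    """Converged MAC solution; velocity arrays include Dirichlet faces."""

    grid: MacGrid
    u: np.ndarray            # (nx+1, ny, nz) x-face normal velocities, m/s
    v: np.ndarray            # (nx, ny+1, nz)
    w: np.ndarray            # (nx, ny, nz+1)
    p: np.ndarray            # (nx, ny, nz), Pa; NaN in solid cells
    solid: np.ndarray        # (nx, ny, nz) bool
    iterations: int = 0
    residual: float = 0.0
    residual_history: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def cell_velocity(self) -> np.ndarray:
        """Collocated (cell-centred) velocity, shape (nx, ny, nz, 3)."""
        uc = 0.5 * (self.u[1:, :, :] + self.u[:-1, :, :]) if self.u.shape[0] > self.grid.shape[0] \
            else 0.5 * (self.u + np.roll(self.u, -1, axis=0))
        vc = 0.5 * (self.v[:, 1:, :] + self.v[:, :-1, :]) if self.v.shape[1] > self.grid.shape[1] \
            else 0.5 * (self.v + np.roll(self.v, -1, axis=1))
        wc = 0.5 * (self.w[:, :, 1:] + self.w[:, :, :-1]) if self.w.shape[2] > self.grid.shape[2] \
            else 0.5 * (self.w + np.roll(self.w, -1, axis=2))
        return np.stack([uc, vc, wc], axis=-1)

    def scaled(self, factor: float) -> "MacStokesSolution":
        """Rescaled solution (Stokes linearity)."""
        return MacStokesSolution(
            grid=self.grid, u=self.u * factor, v=self.v * factor,
            w=self.w * factor, p=self.p * factor, solid=self.solid,
            iterations=self.iterations, residual=self.residual * abs(factor),
            residual_history=list(self.residual_history),
            meta=dict(self.meta, scaled_by=factor),
        )


def _normalize_bc(bc: dict) -> dict:
    out = {}
    for key in _FACE_KEYS:
        spec = bc.get(key, {"type": "wall"})
        if isinstance(spec, str):
            spec = {"type": spec}
        if spec["type"] not in _BC_TYPES:
            raise ValueError(f"unknown bc type {spec['type']!r} on {key}")
        out[key] = spec
    for ax, (lo, hi) in zip("xyz", [("x-", "x+"), ("y-", "y+"), ("z-", "z+")]):
        if (out[lo]["type"] == "periodic") != (out[hi]["type"] == "periodic"):
            raise ValueError(f"periodic bc on axis {ax} must be set on both sides")
    return out


class _CompGeom:
    """Geometry seen from one velocity component: component axis first."""

    def __init__(self, grid: MacGrid, axis: int, periodic: tuple[bool, bool, bool]):
        axes = (axis,) + tuple(a for a in range(3) if a != axis)
        self.axes = axes
        faces = [grid.xf, grid.yf, grid.zf]
        self.af = faces[axes[0]]
        self.bf = faces[axes[1]]
        self.cf = faces[axes[2]]
        self.ac = 0.5 * (self.af[1:] + self.af[:-1])
        self.bc = 0.5 * (self.bf[1:] + self.bf[:-1])
        self.cc = 0.5 * (self.cf[1:] + self.cf[:-1])
        self.da = np.diff(self.af)
        self.db = np.diff(self.bf)
        self.dc = np.diff(self.cf)
        self.na, self.nb, self.nc = self.da.size, self.db.size, self.dc.size
        self.pa = periodic[axes[0]]
        self.pb = periodic[axes[1]]
        self.pc = periodic[axes[2]]
        self.nfa = self.na if self.pa else self.na + 1
        self.fshape = (self.nfa, self.nb, self.nc)
        # control-volume width along the component axis per face index
        wa = np.empty(self.nfa)
        L = self.af[-1] - self.af[0]
        if self.pa:
            wa[0] = self.ac[0] - (self.ac[-1] - L)
            wa[1:] = self.ac[1:] - self.ac[:-1]
        else:
            wa[0] = self.ac[0] - self.af[0]
            wa[-1] = self.af[-1] - self.ac[-1]
            if self.nfa > 2:
                wa[1:-1] = self.ac[1:] - self.ac[:-1]
        self.wa = wa

    def permute_cells(self, arr: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(np.transpose(arr, self.axes))


def _unpermute(arr: np.ndarray, axes: tuple[int, int, int]) -> np.ndarray:
    inv = np.argsort(axes)
    return np.transpose(arr, inv)


def _eval_dirichlet(spec, comp_axis: int, X, Y, Z):
    """Velocity component ``comp_axis`` of a dirichlet bc at given points."""
    vals = spec["values"](X, Y, Z)
    return np.asarray(vals[comp_axis], dtype=float)


def _component_system(grid: MacGrid, comp: int, mu: float, bc: dict,
                      solid: np.ndarray, invk: np.ndarray, force):
    """Assemble one velocity component.

    Returns (A csr, rhs, G csr faces x ncells, unknown mask, dir values,
    geometry helper).  Cell indexing for G uses the *permuted* flat order;
    the caller keeps a consistent permutation per component.
    """
    periodic = tuple(bc[k]["type"] == "periodic" for k in ("x-", "y-", "z-"))
    g = _CompGeom(grid, comp, periodic)
    na, nb, nc, nfa = g.na, g.nb, g.nc, g.nfa
    fshape = g.fshape
    sol_p = g.permute_cells(solid)
    invk_p = g.permute_cells(invk)

    lo_key = _FACE_KEYS[2 * comp]
    hi_key = _FACE_KEYS[2 * comp + 1]
    other = [a for a in range(3) if a != comp]

    # ---- face coordinates (physical x,y,z) of this component's faces
    Ag, Bg, Cg = np.meshgrid(g.af[:nfa], g.bc, g.cc, indexing="ij")
    coords = [None, None, None]
    coords[comp] = Ag
    coords[other[0]] = Bg
    coords[other[1]] = Cg
    X, Y, Z = coords

    # ---- Dirichlet classification
    dirm = np.zeros(fshape, dtype=bool)
    dirv = np.zeros(fshape)
    if not g.pa:
        for side, i in ((bc[lo_key], 0), (bc[hi_key], nfa - 1)):
            t = side["type"]
            if t in ("wall", "symmetry"):
                dirm[i] = True
            elif t == "inflow":
                dirm[i] = True
                prof = np.asarray(side["normal"], dtype=float)
                if prof.shape != (nb, nc):
                    raise ValueError("inflow profile shape mismatch")
                dirv[i] = prof
            elif t == "dirichlet":
                dirm[i] = True
                dirv[i] = _eval_dirichlet(side, comp, X[i], Y[i], Z[i])
            # outflow: face remains unknown
    # solid adjacency (either straddling cell solid -> no slip face)
    adj = np.zeros(fshape, dtype=bool)
    if g.pa:
        adj |= sol_p
        adj |= np.roll(sol_p, 1, axis=0)
    else:
        adj[1:] |= sol_p
        adj[:-1] |= sol_p
    dirv[adj] = 0.0
    dirm |= adj

    unknown = ~dirm
    nun = int(unknown.sum())
    num = -np.ones(fshape, dtype=np.int64)
    num[unknown] = np.arange(nun)

    diag = np.zeros(fshape)
    rhs = np.zeros(fshape)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    I, J, K = np.meshgrid(np.arange(nfa), np.arange(nb), np.arange(nc),
                          indexing="ij")

    WA = g.wa[:, None, None] + np.zeros(fshape)
    DB = g.db[None, :, None] + np.zeros(fshape)
    DC = g.dc[None, None, :] + np.zeros(fshape)
    A_a = DB * DC          # area normal to component axis
    VOL = WA * DB * DC

    def couple(mask, nI, nJ, nK, coef):
        """Viscous coupling of unknown faces (under mask) to neighbour faces."""
        m = mask & unknown
        if not m.any():
            return
        ni, nj, nk = nI[m], nJ[m], nK[m]
        c = coef[m]
        diag[m] += c
        nbr_dir = dirm[ni, nj, nk]
        mm = np.where(m)
        # off-diagonal toward unknown neighbours
        keep = ~nbr_dir
        rows.append(num[mm[0][keep], mm[1][keep], mm[2][keep]])
        cols.append(num[ni[keep], nj[keep], nk[keep]])
        vals.append(-c[keep])
        # Dirichlet neighbours fold into the rhs
        rhs[mm[0][nbr_dir], mm[1][nbr_dir], mm[2][nbr_dir]] += \
            c[nbr_dir] * dirv[ni[nbr_dir], nj[nbr_dir], nk[nbr_dir]]

    # ---------- normal-direction viscous fluxes (through cells) ----------
    # +a: neighbour face i+1 through cell i
    if g.pa:
        mask = np.ones(fshape, bool)
        nI = (I + 1) % nfa
        dist = g.da[I % na]
        coef = mu * A_a / dist
        couple(mask, nI, J, K, coef)
        nI = (I - 1) % nfa
        dist = g.da[(I - 1) % na]
        couple(mask, nI, J, K, mu * A_a / dist)
    else:
        mask = I < nfa - 1          # has an east cell/face
        nI = np.minimum(I + 1, nfa - 1)
        dist = g.da[np.minimum(I, na - 1)]
        couple(mask, nI, J, K, mu * A_a / dist)
        mask = I > 0
        nI = np.maximum(I - 1, 0)
        dist = g.da[np.maximum(I - 1, 0)]
        couple(mask, nI, J, K, mu * A_a / dist)

    # ---------- tangential-direction fluxes ----------
    for tang in (0, 1):   # 0 -> b axis, 1 -> c axis
        if tang == 0:
            n_t, p_t = nb, g.pb
            tf, tcn, dt = g.bf, g.bc, g.db
            TI = J
            A_t = WA * DC
            bc_lo = bc[_FACE_KEYS[2 * other[0]]]
            bc_hi = bc[_FACE_KEYS[2 * other[0] + 1]]
            t_axis_phys = other[0]
        else:
            n_t, p_t = nc, g.pc
            tf, tcn, dt = g.cf, g.cc, g.dc
            TI = K
            A_t = WA * DB
            bc_lo = bc[_FACE_KEYS[2 * other[1]]]
            bc_hi = bc[_FACE_KEYS[2 * other[1] + 1]]
            t_axis_phys = other[1]

        for sgn in (+1, -1):
            if p_t:
                nT = (TI + sgn) % n_t
            else:
                nT = TI + sgn
            # solid blockage: the two cells on the sgn side of the crossing
            blocked = np.zeros(fshape, bool)
            inside = np.ones(fshape, bool)
            if not p_t:
                inside = (nT >= 0) & (nT < n_t)
            tclip = np.clip(nT, 0, n_t - 1) if not p_t else nT
            # straddling cells of the neighbour layer along the component axis
            for da_off in (0, -1):
                ci = I + da_off
                if g.pa:
                    ci = ci % na
                    cvalid = np.ones(fshape, bool)
                else:
                    cvalid = (ci >= 0) & (ci <= na - 1)
                cic = np.clip(ci, 0, na - 1)
                if tang == 0:
                    s = sol_p[cic, tclip, K]
                else:
                    s = sol_p[cic, J, tclip]
                blocked |= (s & cvalid & inside)

            # distance from face centre to the crossing interface
            if sgn > 0:
                wall_pos = tf[np.clip(TI + 1, 0, n_t)]
            else:
                wall_pos = tf[np.clip(TI, 0, n_t)]
            face_t = tcn[TI]
            dist_wall = np.abs(wall_pos - face_t)

            # 1) interior blocked -> one-sided wall at the interface
            m = blocked & inside & unknown
            if m.any():
                c = (mu * A_t / dist_wall)[m]
                diag[m] += c

            # 2) domain boundary crossing (not periodic)
            if not p_t:
                at_bnd = (nT < 0) if sgn < 0 else (nT > n_t - 1)
                side = bc_lo if sgn < 0 else bc_hi
                t = side["type"]
                if t in ("wall", "dirichlet", "inflow"):
                    m = at_bnd & unknown
                    if m.any():
                        c = (mu * A_t / dist_wall)[m]
                        diag[m] += c
                        if t == "dirichlet":
                            # tangential boundary value at the wall point
                            pts = [X.copy(), Y.copy(), Z.copy()]
                            pts[t_axis_phys] = np.full(fshape, tf[0] if sgn < 0 else tf[-1])
                            bv = _eval_dirichlet(side, comp, pts[0], pts[1], pts[2])
                            rhs[m] += c * bv[m]
                        # wall & inflow tangential value = 0
                # symmetry / outflow: zero tangential flux
            # 3) plain neighbour coupling
            m_nb = inside & ~blocked
            if p_t:
                if tang == 0:
                    L = tf[-1] - tf[0]
                    dd = np.abs(tcn[nT] - face_t)
                    dd = np.minimum(dd, L - dd)
                else:
                    L = tf[-1] - tf[0]
                    dd = np.abs(tcn[nT] - face_t)
                    dd = np.minimum(dd, L - dd)
            else:
                dd = np.abs(tcn[tclip] - face_t)
            coef = mu * A_t / np.where(dd > 0, dd, 1.0)
            if tang == 0:
                couple(m_nb, I, tclip, K, coef)
            else:
                couple(m_nb, I, J, tclip, coef)

    # ---------- Brinkman drag ----------
    if invk_p.any():
        kf = np.zeros(fshape)
        if g.pa:
            kf = 0.5 * (invk_p + np.roll(invk_p, 1, axis=0))
        else:
            kf[1:-1] = 0.5 * (invk_p[1:] + invk_p[:-1])
            kf[0] = invk_p[0]
            kf[-1] = invk_p[-1]
        diag += mu * kf * VOL

    # ---------- body force ----------
    if force is not None:
        fv = force(X, Y, Z) if callable(force) else force
        fc = np.asarray(fv[comp] if isinstance(fv, (tuple, list)) else fv,
                        dtype=float)
        rhs += np.broadcast_to(fc, fshape) * VOL

    # ---------- pressure gradient operator ----------
    # (G p)[face] = (p_E - p_W) * A_a ; E cell = i (wrapped), W cell = i-1
    cell_num = np.arange(na * nb * nc).reshape(na, nb, nc)
    gr, gc_, gv = [], [], []
    mm = np.where(unknown)
    fi, fj, fk = mm
    fn = num[mm]
    Aface = (g.db[fj] * g.dc[fk])
    if g.pa:
        eci = fi % na
        wci = (fi - 1) % na
        gr += [fn, fn]
        gc_ += [cell_num[eci, fj, fk], cell_num[wci, fj, fk]]
        gv += [Aface, -Aface]
    else:
        has_e = fi <= na - 1
        has_w = fi >= 1
        gr += [fn[has_e], fn[has_w]]
        gc_ += [cell_num[fi[has_e], fj[has_e], fk[has_e]],
                cell_num[fi[has_w] - 1, fj[has_w], fk[has_w]]]
        gv += [Aface[has_e], -Aface[has_w]]

    ncell = na * nb * nc
    G = sp.coo_matrix((np.concatenate(gv),
                       (np.concatenate(gr), np.concatenate(gc_))),
                      shape=(nun, ncell)).tocsr()

    Amat = sp.coo_matrix(
        (np.concatenate([diag[unknown]] + vals),
         (np.concatenate([num[unknown]] + rows),
          np.concatenate([num[unknown]] + cols))),
        shape=(nun, nun)).tocsr()
    b = rhs[unknown]
    return Amat, b, G, unknown, dirv, g


def _dirichlet_outflux(grid: MacGrid, comp: int, g: _CompGeom,
                       unknown: np.ndarray, dirv: np.ndarray) -> np.ndarray:
    """Net outflux (m^3/s) through this component's Dirichlet faces, per cell
    in the component's permuted ordering."""
    na, nb, nc = g.na, g.nb, g.nc
    A = g.db[None, :, None] * g.dc[None, None, :]
    vals = np.where(~unknown, dirv, 0.0)
    if g.pa:
        out = (np.roll(vals, -1, axis=0) - vals) * A
    else:
        out = (vals[1:, :, :] - vals[:-1, :, :]) * A
    return out


def divergence(sol: MacStokesSolution) -> np.ndarray:
    """Per-cell net volume outflux (m^3/s)."""
    grid = sol.grid
    nx, ny, nz = grid.shape
    dx, dy, dz = grid.dx, grid.dy, grid.dz
    Ax = dy[None, :, None] * dz[None, None, :]
    Ay = dx[:, None, None] * dz[None, None, :]
    Az = dx[:, None, None] * dy[None, :, None]
    u, v, w = sol.u, sol.v, sol.w
    if u.shape[0] == nx:      # periodic x
        du = (np.roll(u, -1, axis=0) - u) * Ax
    else:
        du = (u[1:] - u[:-1]) * Ax
    if v.shape[1] == ny:
        dv = (np.roll(v, -1, axis=1) - v) * Ay
    else:
        dv = (v[:, 1:] - v[:, :-1]) * Ay
    if w.shape[2] == nz:
        dw = (np.roll(w, -1, axis=2) - w) * Az
    else:
        dw = (w[:, :, 1:] - w[:, :, :-1]) * Az
    return du + dv + dw


def solve_mac_stokes(grid: MacGrid, mu: float, bc: dict,
                     solid: np.ndarray | None = None,
                     inv_kappa: np.ndarray | None = None,
                     body_force=None,
                     tol: float = 1e-11, maxiter: int = 10000,
                     pin_pressure: bool | None = None) -> MacStokesSolution:
    """Solve steady Stokes--Brinkman flow on a MAC grid.

    Parameters
    ----------
    mu : dynamic viscosity, Pa s.
    bc : mapping of ``x-/x+/y-/y+/z-/z+`` to boundary specs.
    solid : bool cell mask of resolved solid voxels (no slip).
    inv_kappa : per-cell inverse permeability 1/m^2 (0 in free fluid).
    body_force : callable ``f(X, Y, Z) -> (fx, fy, fz)`` or tuple of
        constants, N/m^3.
    tol : relative tolerance on the continuity residual.
    """
    bc = _normalize_bc(bc)
    nx, ny, nz = grid.shape
    if solid is None:
        solid = np.zeros(grid.shape, dtype=bool)
    solid = np.asarray(solid, dtype=bool)
    if inv_kappa is None:
        inv_kappa = np.zeros(grid.shape)
    inv_kappa = np.broadcast_to(np.asarray(inv_kappa, dtype=float), grid.shape)

    comps = []
    for comp in range(3):
        comps.append(_component_system(grid, comp, mu, bc, solid, inv_kappa,
                                       body_force))

    # pressure unknowns: non-solid cells, in the *natural* (x,y,z) order
    fluid = ~solid
    ncell_tot = nx * ny * nz
    pnum = -np.ones(grid.shape, dtype=np.int64)
    npre = int(fluid.sum())
    pnum[fluid] = np.arange(npre)

    has_outflow = any(bc[k]["type"] == "outflow" for k in _FACE_KEYS)
    if pin_pressure is None:
        pin_pressure = not has_outflow

    lus, Gs, fs = [], [], []
    g_rhs = np.zeros(npre)
    for comp, (Amat, b, G, unknown, dirv, g) in enumerate(comps):
        # remap G columns from permuted cell order to pressure numbering
        perm_cells = np.transpose(pnum, g.axes).reshape(-1)
        keep = perm_cells[G.indices] >= 0
        G = sp.csr_matrix((G.data * keep, np.where(keep, perm_cells[G.indices], 0),
                           G.indptr), shape=(G.shape[0], npre))
        G.eliminate_zeros()
        Gs.append(G.tocsr())
        fs.append(b)
        lus.append(splu(Amat.tocsc()) if Amat.shape[0] else None)
        # continuity rhs from this component's Dirichlet faces
        outflux = _dirichlet_outflux(grid, comp, g, unknown, dirv)
        flat = np.transpose(pnum, g.axes).reshape(-1)
        of = outflux.reshape(-1)
        m = flat >= 0
        np.add.at(g_rhs, flat[m], of[m])
    # continuity: G^T u = g' with g' = +sum dirichlet outflux  (see notes)
    gp = g_rhs

    if pin_pressure and npre > 0:
        pin = 0
    else:
        pin = None

    def Ainv_f():
        outs = []
        for lu, b in zip(lus, fs):
            outs.append(lu.solve(b) if lu is not None else np.zeros(0))
        return outs

    u0 = Ainv_f()
    rhs_p = sum(G.T @ x for G, x in zip(Gs, u0)) - gp
    if pin is not None:
        rhs_p[pin] = 0.0

    Vc = grid.cell_volumes()[fluid]
    Minv = mu / Vc

    def Smul(pvec):
        if pin is not None:
            pvec = pvec.copy()
            pvec[pin] = 0.0
        acc = np.zeros_like(pvec)
        for lu, G in zip(lus, Gs):
            if lu is None or G.shape[0] == 0:
                continue
            acc += G.T @ lu.solve(G @ pvec)
        if pin is not None:
            acc[pin] = 0.0
        return acc

    # ---- preconditioned CG on the Schur complement ----
    p = np.zeros(npre)
    r = rhs_p.copy()
    norm0 = float(np.linalg.norm(rhs_p))
    scale = max(norm0, 1e-300)
    hist = []
    it = 0
    if norm0 > 0:
        converged = False
        z = Minv * r
        if pin is not None:
            z[pin] = 0.0
        d = z.copy()
        rz = float(r @ z)
        for it in range(1, maxiter + 1):
            Sd = Smul(d)
            dSd = float(d @ Sd)
            if dSd <= 0:
                converged = hist and hist[-1] < tol * 10
                break
            alpha = rz / dSd
            p += alpha * d
            r -= alpha * Sd
            res = float(np.linalg.norm(r)) / scale
            hist.append(res)
            if res < tol:
                converged = True
                break
            z = Minv * r
            if pin is not None:
                z[pin] = 0.0
            rz_new = float(r @ z)
            d = z + (rz_new / rz) * d
            rz = rz_new
        if not converged:
            raise RuntimeError(
                f"Stokes pressure iteration did not converge: residual "
                f"{hist[-1] if hist else np.nan:.3e} after {it} iterations "
                f"(history tail {hist[-5:]})")

    # recover velocities
    vel_full = []
    for comp, (Amat, b, G, unknown, dirv, g) in enumerate(comps):
        lu = lus[comp]
        x = lu.solve(fs[comp] - Gs[comp] @ p) if lu is not None else np.zeros(0)
        full = dirv.copy()
        full[unknown] = x
        # un-permute from (a,b,c) to (x,y,z) face array
        vel_full.append(_unpermute(full, g.axes))

    pfield = np.full(grid.shape, np.nan)
    pfield[fluid] = p

    sol = MacStokesSolution(grid=grid, u=vel_full[0], v=vel_full[1],
                            w=vel_full[2], p=pfield, solid=solid,
                            iterations=it,
                            residual=hist[-1] if hist else 0.0,
                            residual_history=hist)
    return sol
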