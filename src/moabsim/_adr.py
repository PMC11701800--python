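"""Cell-centred finite-volume advection--diffusion solver.

Steady transport of a dilute species on the same rectilinear grids used by
the flow solver.  Convection is first-order upwind against the staggered
face velocities of a (divergence-free) MAC solution, diffusion is a
standard two-point flux.  Sinks are supplied as *linear* per-cell and
per-floor-face coefficients so that the caller can wrap the solve in a
Picard iteration for saturating (Michaelis--Menten) kinetics; with
non-negative coefficients the discrete operator is an M-matrix and the
solution is bounded by its boundary data.

Boundary types per domain face: ``dirichlet`` (fixed concentration),
``outflow`` (advective outflow, zero diffusive flux), ``noflux``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, gmres, splu

from ._mac import MacGrid

__all__ = ["solve_adr"]

_ADR_TYPES = {"dirichlet", "outflow", "noflux"}


def _bc_value(spec, shape, coords):
    val = spec.get("value", 0.0)
    if callable(val):
        return np.asarray(val(*coords), dtype=float)
    return np.full(shape, float(val))


def solve_adr(grid: MacGrid, face_u, D: float, bc: dict,
              sink_lin: np.ndarray | None = None,
              floor_sink_lin: np.ndarray | None = None,
              source: np.ndarray | None = None,
              solid: np.ndarray | None = None,
              solver_cache: dict | None = None) -> np.ndarray:
    """Solve one linear transport problem; returns cell concentrations.

    Parameters
    ----------
    face_u : tuple of staggered velocity arrays ``(u, v, w)`` (Dirichlet
        faces filled in), m/s.  In porous regions these are superficial
        velocities, which is what a volume-averaged balance needs.
    D : diffusion coefficient, m^2/s.
    bc : mapping ``x-/x+/y-/y+/z-/z+`` -> {"type": ..., "value": ...}.
    sink_lin : per-cell linear sink coefficient, 1/s (consumption =
        sink_lin * C * V); non-negative.
    floor_sink_lin : per-cell coefficient, m/s, applied on the z- floor
        face of bottom-layer cells (flux = coef * C * A_floor).
    source : explicit volumetric source, mol/(m^3 s).
    solver_cache : mutable dict shared across calls whose matrices differ
        only mildly (Picard iterations): the first call's LU factorization
        preconditions the later solves (GMRES), with a fresh factorization
        as fallback.
    """
    nx, ny, nz = grid.shape
    u, v, w = face_u
    if solid is None:
        solid = np.zeros(grid.shape, bool)
    fluid = ~solid
    ncell = int(fluid.sum())
    num = -np.ones(grid.shape, dtype=np.int64)
    num[fluid] = np.arange(ncell)

    dx, dy, dz = grid.dx, grid.dy, grid.dz
    xc, yc, zc = grid.xc, grid.yc, grid.zc
    Ax = dy[None, :, None] * dz[None, None, :]          # (1,ny,nz) x-face area
    Ay = dx[:, None, None] * dz[None, None, :]
    Az = dx[:, None, None] * dy[None, :, None]
    V = grid.cell_volumes()

    bcn = {}
    for key in ("x-", "x+", "y-", "y+", "z-", "z+"):
        s = bc.get(key, {"type": "noflux"})
        if isinstance(s, str):
            s = {"type": s}
        if s["type"] not in _ADR_TYPES:
            raise ValueError(f"unknown transport bc {s['type']!r} on {key}")
        bcn[key] = s

    diag = np.zeros(grid.shape)
    rhs = np.zeros(grid.shape)
    rows, cols, vals = [], [], []

    # normal face velocity arrays per axis with shapes (nx+1,..) etc.
    # for periodic MAC solutions the wrap face is duplicated here
    def faces_of(axis):
        arr = (u, v, w)[axis]
        n = grid.shape[axis]
        if arr.shape[axis] == n:          # periodic flow field
            pad = np.take(arr, [0], axis=axis)
            arr = np.concatenate([arr, pad], axis=axis)
        return arr

    uf = [faces_of(0), faces_of(1), faces_of(2)]
    areas = [Ax, Ay, Az]
    centers = [xc, yc, zc]
    fcoords = [grid.xf, grid.yf, grid.zf]

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    IDX = [I, J, K]

    for axis in range(3):
        n = grid.shape[axis]
        A = np.broadcast_to(areas[axis], grid.shape)
        cpos = centers[axis]
        lo_spec = bcn[("x-", "y-", "z-")[axis]]
        hi_spec = bcn[("x+", "y+", "z+")[axis]]
        for sgn in (+1, -1):
            ii = IDX[axis]
            # face index between cell and its sgn-neighbour
            fi = ii + (1 if sgn > 0 else 0)
            Fv = np.take_along_axis(uf[axis], fi, axis=axis)
            Fout = Fv * A * sgn              # volumetric outflux if positive
            nb = ii + sgn
            interior = (nb >= 0) & (nb <= n - 1)
            nbc = np.clip(nb, 0, n - 1)
            nb_idx = [IDX[0].copy(), IDX[1].copy(), IDX[2].copy()]
            nb_idx[axis] = nbc
            nb_solid = solid[nb_idx[0], nb_idx[1], nb_idx[2]]

            m = fluid & interior & ~nb_solid
            if m.any():
                dist = np.abs(cpos[nbc] - cpos[ii])
                dcoef = D * A / np.where(dist > 0, dist, 1.0)
                adv_diag = np.maximum(Fout, 0.0)
                adv_off = np.minimum(Fout, 0.0)
                diag[m] += adv_diag[m] + dcoef[m]
                rows.append(num[m])
                cols.append(num[nb_idx[0][m], nb_idx[1][m], nb_idx[2][m]])
                vals.append(adv_off[m] - dcoef[m])
            # solid neighbour: no flux (face velocity is zero there anyway)

            bnd = fluid & ~interior
            spec = hi_spec if sgn > 0 else lo_spec
            if bnd.any():
                if spec["type"] == "dirichlet":
                    half = np.diff(fcoords[axis])[ii] / 2.0
                    dcoef = D * A / half
                    # boundary value at face centres
                    pts = [np.broadcast_to(xc[IDX[0]], grid.shape),
                           np.broadcast_to(yc[IDX[1]], grid.shape),
                           np.broadcast_to(zc[IDX[2]], grid.shape)]
                    pts[axis] = np.full(grid.shape,
                                        fcoords[axis][-1 if sgn > 0 else 0])
                    cb = _bc_value(spec, grid.shape, pts)
                    adv_diag = np.maximum(Fout, 0.0)
                    adv_in = np.minimum(Fout, 0.0)
                    diag[bnd] += adv_diag[bnd] + dcoef[bnd]
                    rhs[bnd] += (dcoef[bnd] - adv_in[bnd]) * cb[bnd]
                elif spec["type"] == "outflow":
                    diag[bnd] += np.maximum(Fout[bnd], 0.0)
                # noflux: nothing

    if sink_lin is not None:
        diag += np.asarray(sink_lin) * V
    if floor_sink_lin is not None:
        coef = np.zeros(grid.shape)
        coef[:, :, 0] = np.asarray(floor_sink_lin)[:, :, 0] \
            if np.asarray(floor_sink_lin).ndim == 3 else np.asarray(floor_sink_lin)
        diag += coef * np.broadcast_to(Az, grid.shape)
    if source is not None:
        rhs += np.broadcast_to(np.asarray(source, dtype=float), grid.shape) * V

    m = fluid
    Amat = sp.coo_matrix(
        (np.concatenate([diag[m]] + vals),
         (np.concatenate([num[m]] + rows),
          np.concatenate([num[m]] + cols))),
        shape=(ncell, ncell)).tocsr()
    b = rhs[m]
    if solver_cache is not None and "lu" in solver_cache:
        lu = solver_cache["lu"]
        M = LinearOperator(Amat.shape, matvec=lu.solve)
        x, info = gmres(Amat, b, M=M, x0=solver_cache.get("x"),
                        rtol=1e-12, atol=0.0, maxiter=100)
        if info != 0:
            lu = splu(Amat.tocsc())
            x = lu.solve(b)
            solver_cache["lu"] = lu
        solver_cache["x"] = x
    else:
        lu = splu(Amat.tocsc())
        x = lu.solve(b)
        if solver_cache is not None:
            solver_cache["lu"] = lu
            solver_cache["x"] = x
    C = np.full(grid.shape, np.nan)
    C[m] = x
    return C
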