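"""Steady creeping-flow field in the channel planform.

The full 3D incompressible Stokes problem in a shallow channel is reduced to
its depth-averaged (Hele-Shaw/Brinkman) form on the planform:

    mu * lap(u_bar) - (12 mu / h^2) * u_bar = grad(p),    div(u_bar) = 0,

where ``u_bar(x, y)`` is the velocity averaged over the depth ``h``.  The
Brinkman drag term represents the parabolic depth profile; the in-plane
Laplacian retains the side-wall boundary layers, so the straight-channel
solution is the classical Brinkman profile (see
:func:`analytic_straight_profile`).  Midplane (z = 0) values are recovered
from the depth-averaged field through the local rectangular-duct series ratio
(:func:`duct_midplane_ratio`).

The solve uses a streamfunction-vorticity-like splitting: with
``u_bar = d(psi)/dy``, ``v_bar = -d(psi)/dx`` continuity is automatic, and
eliminating the pressure leaves the coupled pair

    lap(psi) = q,       mu * lap(q) - (12 mu / h^2) * q = 0,

discretized with second-order finite differences on the boundary-fitted
``(x, eta)`` map and solved by a sparse direct factorization.  Boundary
conditions: uniform inflow upstream, zero-gradient outflow downstream, no-slip
side walls (psi Dirichlet + normal-derivative condition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ChannelGeometry, StructuredGrid2D, build_grid

__all__ = [
    "FluidProperties",
    "FlowConditions",
    "FlowField2D",
    "SolverError",
    "reynolds_number",
    "analytic_straight_profile",
    "duct_midplane_ratio",
    "duct_max_to_mean",
    "solve_depth_averaged_stokes",
    "midplane_velocity",
    "centerline_velocity",
    "transverse_profile",
    "grid_refinement_study",
]


class SolverError(RuntimeError):
    """Raised when the flow solve fails; carries the residual history."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals or []


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian carrier fluid: density (kg/m^3) and dynamic viscosity (Pa s)."""

    rho: float
    mu: float

    def __post_init__(self) -> None:
        if self.rho <= 0.0 or self.mu <= 0.0:
            raise ValueError("require rho > 0 and mu > 0")

    @classmethod
    def dextran40(cls) -> "FluidProperties":
        """Dextran 40 suspending medium at 37 C."""
        return cls(rho=1046.0, mu=4.5e-3)


@dataclass(frozen=True)
class FlowConditions:
    """Imposed flow rate and the quantities derived from it (never stored
    separately, so they cannot drift out of consistency)."""

    Q: float                      # volumetric flow rate, m^3/s
    geom: ChannelGeometry
    fluid: FluidProperties

    def __post_init__(self) -> None:
        if self.Q <= 0.0:
            raise ValueError("require Q > 0")

    @property
    def mean_upstream_velocity(self) -> float:
        return self.Q / (self.geom.w_u * self.geom.h)

    @property
    def reynolds(self) -> float:
        return reynolds_number(self.fluid, self.geom, self.Q)


def reynolds_number(fluid: FluidProperties, geom: ChannelGeometry, Q: float) -> float:
    """Re = rho * <Vz>_u * (w_u/2) / mu = rho * Q / (2 h mu).

    The upstream half-width is the length scale and the upstream mean velocity
    ``Q / (w_u h)`` the velocity scale, so ``w_u`` cancels.
    """
    if geom.h <= 0.0 or fluid.mu <= 0.0:
        raise ValueError("require h > 0 and mu > 0")
    if Q < 0.0:
        raise ValueError("require Q >= 0")
    return fluid.rho * Q / (2.0 * geom.h * fluid.mu)


def analytic_straight_profile(W: float, h: float, Q: float,
                              fluid: FluidProperties | None = None):
    """Depth-averaged Brinkman profile of a straight rectangular section.

    Returns a callable ``ubar(y)`` with

        ubar(y) = A [1 - cosh(sqrt(12) y / h) / cosh(sqrt(12) W / (2h))],

    ``A`` fixed so that the flux ``h * int ubar dy`` equals ``Q`` exactly
    (closed-form normalization).  Independent of viscosity: mu cancels between
    the pressure gradient and the drag.
    """
    if W <= 0.0 or h <= 0.0:
        raise ValueError("require W > 0 and h > 0")
    k = math.sqrt(12.0) / h
    flux_shape = W - (2.0 / k) * math.tanh(k * W / 2.0)
    A = Q / (h * flux_shape)
    cosh_wall = math.cosh(k * W / 2.0)

    def ubar(y):
        y = np.asarray(y, dtype=float)
        out = A * (1.0 - np.cosh(k * y) / cosh_wall)
        return float(out) if out.ndim == 0 else out

    return ubar


# ---------------------------------------------------------------------------
# rectangular-duct Fourier series (midplane conversion)
# ---------------------------------------------------------------------------

def _sech(a: np.ndarray) -> np.ndarray:
    # overflow-safe 1/cosh
    a = np.asarray(a, dtype=float)
    out = np.zeros_like(a)
    small = a < 700.0
    out[small] = 1.0 / np.cosh(a[small])
    return out


def duct_midplane_ratio(w_over_h, nterms: int = 100):
    """Ratio of midplane-centerline to depth-averaged-centerline velocity in a
    developed rectangular duct of width/depth ratio ``w_over_h``.

    Fourier-series duct solution expanded along the depth; tends to 3/2 in the
    wide-slot limit (parabolic depth profile) and to 1 for a deep narrow slot
    (plug-like depth profile).
    """
    alpha = np.atleast_1d(np.asarray(w_over_h, dtype=float))
    if np.any(alpha <= 0.0):
        raise ValueError("require w/h > 0")
    n = np.arange(1, 2 * nterms, 2, dtype=float)
    sgn = np.where(n % 4 == 1, 1.0, -1.0)
    a = 0.5 * np.pi * n[None, :] * alpha[:, None]
    term = 1.0 - _sech(a)
    u_mid = np.sum(sgn / n ** 3 * term, axis=1)
    u_avg = np.sum((2.0 / (np.pi * n * n ** 3)) * term, axis=1)
    r = u_mid / u_avg
    return float(r[0]) if np.isscalar(w_over_h) or np.ndim(w_over_h) == 0 else r


def duct_max_to_mean(W: float, h: float, nterms: int = 100) -> float:
    """Ratio of maximum to cross-section-mean velocity in a developed
    rectangular duct (2.096 for a square section, 1.5 in the slot limit)."""
    if W <= 0.0 or h <= 0.0:
        raise ValueError("require W > 0 and h > 0")
    n = np.arange(1, 2 * nterms, 2, dtype=float)
    sgn = np.where(n % 4 == 1, 1.0, -1.0)
    a = 0.5 * np.pi * n * W / h
    term = 1.0 - _sech(a)
    u_max = np.sum(sgn / n ** 3 * term)
    # cross-section mean: both integrals done analytically
    u_mean = np.sum((2.0 / (np.pi * n * n ** 3))
                    * (1.0 - (2.0 * h / (np.pi * n * W)) * np.tanh(a)))
    return float(u_max / u_mean)


# ---------------------------------------------------------------------------
# finite-difference operators on the boundary-fitted map
# ---------------------------------------------------------------------------

def _fd_weights(x0: float, xs: np.ndarray, order: int) -> np.ndarray:
    """Finite-difference weights for the ``order``-th derivative at ``x0``
    from the nodes ``xs`` (solve of the local Vandermonde moment system)."""
    xs = np.asarray(xs, dtype=float) - x0
    n = xs.size
    V = np.vander(xs, n, increasing=True).T        # V[k, j] = xs[j]**k
    rhs = np.zeros(n)
    rhs[order] = math.factorial(order)
    return np.linalg.solve(V, rhs)


def _diff_ops_1d(x: np.ndarray):
    """First/second derivative matrices on a nonuniform 1D grid.

    Interior rows are 3-point central (second order); end rows are one-sided
    4-point (third order for D1 — the wall no-slip closure and the wall
    velocity reconstruction both use these rows, and their order controls the
    near-wall accuracy of the whole solve).
    """
    n = x.size
    D1 = sp.lil_matrix((n, n))
    D2 = sp.lil_matrix((n, n))
    for i in range(1, n - 1):
        hm = x[i] - x[i - 1]
        hp = x[i + 1] - x[i]
        D1[i, i - 1] = -hp / (hm * (hm + hp))
        D1[i, i] = (hp - hm) / (hm * hp)
        D1[i, i + 1] = hm / (hp * (hm + hp))
        D2[i, i - 1] = 2.0 / (hm * (hm + hp))
        D2[i, i] = -2.0 / (hm * hp)
        D2[i, i + 1] = 2.0 / (hp * (hm + hp))
    m = min(4, n)
    D1[0, :m] = _fd_weights(x[0], x[:m], 1)
    D1[n - 1, n - m:] = _fd_weights(x[-1], x[n - m:], 1)
    D2[0, :m] = _fd_weights(x[0], x[:m], 2)
    D2[n - 1, n - m:] = _fd_weights(x[-1], x[n - m:], 2)
    return D1.tocsr(), D2.tocsr()


def _equilibrated_solve(A: sp.csr_matrix, b: np.ndarray) -> np.ndarray:
    """Direct sparse solve with row/column equilibration.

    The assembled system mixes O(1) Dirichlet rows with O(1/dx^2) operator
    rows and streamfunction/vorticity unknowns of very different magnitudes;
    scaling both sides to unit max-norm keeps the factorization well
    conditioned.
    """
    absA = abs(A)
    r = absA.max(axis=1).toarray().ravel()
    if np.any(r == 0.0):
        raise SolverError("assembly produced an empty equation row")
    Rinv = sp.diags(1.0 / r)
    A1 = (Rinv @ A).tocsc()
    c = abs(A1).max(axis=0).toarray().ravel()
    if np.any(c == 0.0):
        raise SolverError("assembly left an unknown without any equation")
    Cinv = sp.diags(1.0 / c)
    A2 = (A1 @ Cinv).tocsc()
    try:
        lu = spla.splu(A2)
    except RuntimeError as exc:  # singular factorization
        raise SolverError(f"sparse factorization failed: {exc}") from exc
    b2 = b / r
    y = lu.solve(b2)
    # iterative refinement: the factorization of this poorly conditioned
    # operator leaves localized residuals that two cheap passes remove
    for _ in range(2):
        y += lu.solve(b2 - A2 @ y)
    denom = spla.norm(A2, np.inf) * np.linalg.norm(y, np.inf) + np.linalg.norm(b2, np.inf)
    rel = float(np.linalg.norm(A2 @ y - b2, np.inf) / denom) if denom > 0 else 0.0
    return (1.0 / c) * y, rel


@dataclass
class FlowField2D:
    """Depth-averaged planform field on a boundary-fitted grid.

    ``u_bar``/``v_bar``/``p`` are node arrays of shape ``(nx+1, ny+1)``.
    ``r_station`` holds the per-station duct-series midplane conversion
    ratio; midplane values are ``r * u_bar``.
    """

    grid: StructuredGrid2D
    fluid: FluidProperties
    Q: float
    u_bar: np.ndarray
    v_bar: np.ndarray
    p: np.ndarray
    residual: float
    r_station: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.r_station is None:
            self.r_station = duct_midplane_ratio(self.grid.W / self.grid.h)
        self.r_station = np.atleast_1d(self.r_station)

    # Stokes flow is linear in Q: rescaling is exact and cheap.
    def with_flow_rate(self, Q_new: float) -> "FlowField2D":
        s = Q_new / self.Q
        return replace(self, Q=Q_new, u_bar=self.u_bar * s,
                       v_bar=self.v_bar * s, p=self.p * s,
                       r_station=self.r_station.copy())

    # -- midplane sampling -------------------------------------------------
    def _locate(self, x: np.ndarray, y: np.ndarray):
        xs = self.grid.x
        if np.any(x < xs[0] - 1e-15) or np.any(x > xs[-1] + 1e-15):
            raise ValueError("sample point outside the channel (axial)")
        i = np.clip(np.searchsorted(xs, x, side="right") - 1, 0, self.grid.nx - 1)
        tx = (x - xs[i]) / (xs[i + 1] - xs[i])
        W_loc = (1.0 - tx) * self.grid.W[i] + tx * self.grid.W[i + 1]
        eta = 2.0 * y / W_loc
        if np.any(np.abs(eta) > 1.0 + 1e-12):
            raise ValueError("sample point outside the channel (transverse)")
        eta = np.clip(eta, -1.0, 1.0)
        ej = self.grid.eta
        j = np.clip(np.searchsorted(ej, eta, side="right") - 1, 0, self.grid.ny - 1)
        ty = (eta - ej[j]) / (ej[j + 1] - ej[j])
        return i, tx, j, ty

    def sample_midplane(self, x, y):
        """Bilinear sample of the midplane velocity (u, v) at points (x, y)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        i, tx, j, ty = self._locate(x, y)
        r = self.r_station
        U = r[:, None] * self.u_bar
        V = r[:, None] * self.v_bar
        out = []
        for F in (U, V):
            f = ((1 - tx) * ((1 - ty) * F[i, j] + ty * F[i, j + 1])
                 + tx * ((1 - ty) * F[i + 1, j] + ty * F[i + 1, j + 1]))
            out.append(f)
        return out[0], out[1]

    def flux_through_station(self, x: float) -> float:
        """Volume flux through the transverse section at ``x`` (quadrature of
        the depth-averaged axial velocity)."""
        W_loc = float(self.grid.width_interp(x))
        ys = 0.5 * W_loc * self.grid.eta
        xs = self.grid.x
        i = int(np.clip(np.searchsorted(xs, x, side="right") - 1, 0, self.grid.nx - 1))
        tx = (x - xs[i]) / (xs[i + 1] - xs[i])
        ubar = (1 - tx) * self.u_bar[i, :] + tx * self.u_bar[i + 1, :]
        return float(np.trapezoid(ubar, ys) * self.grid.h)

    def export_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame({
            "x_um": self.grid.X.ravel() * 1e6,
            "y_um": self.grid.Y.ravel() * 1e6,
            "u_mps": self.u_bar.ravel(),
            "v_mps": self.v_bar.ravel(),
            "p_Pa": self.p.ravel(),
        })
        df.to_csv(path, index=False)


def solve_depth_averaged_stokes(grid: StructuredGrid2D, fluid: FluidProperties,
                                Q: float, *, tol: float = 1e-8) -> FlowField2D:
    """Solve the depth-averaged Stokes-Brinkman equations on ``grid``.

    Inlet: uniform depth-averaged velocity ``Q / (W_in h)``; outlet:
    zero-gradient; side walls: no slip.  Direct sparse factorization; the
    relative residual of the assembled system is checked against ``tol``.
    """
    if grid.geom is not None and Q > 0:
        Re = reynolds_number(fluid, grid.geom, Q)
        if Re > 1.0:
            warnings.warn(f"Re = {Re:.3g} > 1: creeping-flow model out of range",
                          stacklevel=2)

    nx, ny = grid.nx, grid.ny
    npx, npy = nx + 1, ny + 1
    N = npx * npy
    h = grid.h
    mu = fluid.mu

    Dx1, Dxx1 = _diff_ops_1d(grid.x)
    De1, Dee1 = _diff_ops_1d(grid.eta)
    Ix = sp.identity(npx, format="csr")
    Iy = sp.identity(npy, format="csr")
    Fx = sp.kron(Dx1, Iy, format="csr")
    Fxx = sp.kron(Dxx1, Iy, format="csr")
    Fe = sp.kron(Ix, De1, format="csr")
    Fee = sp.kron(Ix, Dee1, format="csr")
    Fxe = sp.kron(Dx1, De1, format="csr")

    W = grid.W
    g = (Dx1 @ W) / W                 # d(ln W)/dx per station
    gp = Dx1 @ g
    eta = grid.eta
    a_node = (-eta[None, :] * g[:, None]).ravel()
    alpha = (a_node ** 2
             + (4.0 / W[:, None] ** 2 * np.ones((1, npy))).ravel())
    gamma = (-eta[None, :] * (gp[:, None] - g[:, None] ** 2)).ravel()

    dA = sp.diags(a_node)
    Lap = (Fxx + sp.diags(alpha) @ Fee + 2.0 * dA @ Fxe
           + sp.diags(gamma) @ Fe)
    Mx = Fx + dA @ Fe                 # physical d/dx at constant y
    I = sp.identity(N, format="csr")

    jj, ii = np.meshgrid(np.arange(npy), np.arange(npx))
    ii, jj = ii.ravel(), jj.ravel()
    wall = (jj == 0) | (jj == ny)
    inlet = (ii == 0)
    outlet = (ii == nx)
    # psi-block rows
    wall_psi = wall
    inlet_psi = inlet & ~wall
    outlet_psi = outlet & ~wall
    int_psi = ~(wall_psi | inlet_psi | outlet_psi)
    # q-block rows: no-slip rows on walls except the corners, where the
    # inlet profile / outflow condition take precedence
    wall_q = wall & ~inlet & ~outlet
    inlet_q = inlet
    outlet_q = outlet
    int_q = ~(wall_q | inlet_q | outlet_q)

    def rows(mask):
        return sp.diags(mask.astype(float))

    # outlet zero-gradient as a 2-point difference: the outlet column copies
    # its upstream neighbor, so the wall no-slip there is inherited exactly
    shift = sp.lil_matrix((npx, npx))
    shift[nx, nx - 1] = 1.0
    Gout = I - sp.kron(shift.tocsr(), Iy, format="csr")

    A11 = (rows(int_psi) @ Lap + rows(wall_psi | inlet_psi)
           + rows(outlet_psi) @ Gout)
    A12 = -rows(int_psi)
    A21 = rows(wall_q) @ Fe
    A22 = (rows(int_q) @ (mu * Lap - (12.0 * mu / h ** 2) * I)
           + rows(inlet_q) + rows(outlet_q) @ Gout)

    u_in = Q / (W[0] * h)
    psi_wall = np.where(jj == ny, Q / (2.0 * h), -Q / (2.0 * h))
    y_nodes = grid.Y.ravel()
    b1 = np.zeros(N)
    b1[wall_psi] = psi_wall[wall_psi]
    b1[inlet_psi] = u_in * y_nodes[inlet_psi]
    b2 = np.zeros(N)

    A = sp.bmat([[A11, A12], [A21, A22]], format="csr")
    b = np.concatenate([b1, b2])
    s, residual = _equilibrated_solve(A, b)
    if not np.isfinite(residual) or residual > tol:
        raise SolverError(
            f"flow solve residual {residual:.3e} exceeds tolerance {tol:.1e}",
            residuals=[residual])

    psi = s[:N]
    q = s[N:]
    u_bar = ((2.0 / W[:, None]) *
             (Fe @ psi).reshape(npx, npy))
    v_bar = -(Mx @ psi).reshape(npx, npy)

    # pressure diagnostic: integrate the x-momentum balance along the
    # centerline, gauge p = 0 at the outlet (Hele-Shaw pressure is nearly
    # uniform across the width)
    px = (mu * (Lap @ u_bar.ravel()) - (12.0 * mu / h ** 2) * u_bar.ravel())
    jc = ny // 2
    px_line = px.reshape(npx, npy)[:, jc]
    from scipy.integrate import cumulative_trapezoid
    p_line = cumulative_trapezoid(px_line, grid.x, initial=0.0)
    p_line -= p_line[-1]
    p = np.broadcast_to(p_line[:, None], (npx, npy)).copy()

    return FlowField2D(grid=grid, fluid=fluid, Q=Q, u_bar=u_bar, v_bar=v_bar,
                       p=p, residual=residual)


def midplane_velocity(field: FlowField2D, x: float, y: float):
    """Midplane (z = 0) velocity components at a point, via the local
    duct-series conversion ratio applied to the depth-averaged field."""
    u, v = field.sample_midplane(x, y)
    return float(u[0]), float(v[0])


def centerline_velocity(field: FlowField2D, xs) -> np.ndarray:
    """Midplane axial velocity along the centerline at positions ``xs``."""
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    u, _ = field.sample_midplane(xs, np.zeros_like(xs))
    return u


def transverse_profile(field: FlowField2D, x: float, ys) -> np.ndarray:
    """Midplane axial velocity across the width at station ``x``."""
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    u, _ = field.sample_midplane(np.full_like(ys, float(x)), ys)
    return u


def grid_refinement_study(geom: ChannelGeometry, fluid: FluidProperties,
                          Q: float, resolutions, *,
                          window=None, reference: int = -1):
    """Strain rate per grid resolution and relative error vs the reference grid.

    For each ``(nx, ny)`` the full pipeline fit is run: solve the field,
    advect a midplane centerline tracer, fit velocity vs axial position over
    the contraction window.  ``error = 100 |g_i - g_ref| / g_ref``.
    Returns a pandas DataFrame.
    """
    import pandas as pd

    from .analysis import fit_strain_rate, relative_error_percent
    from .particles import ParticleProperties, advect_through_channel

    resolutions = list(resolutions)
    if len(resolutions) < 2:
        raise ValueError("need at least two resolutions")
    if window is None:
        window = (0.0, min(500e-6, geom.L_c))
    particle = ParticleProperties.rbc()
    rates = []
    for nx, ny in resolutions:
        grid = build_grid(geom, nx, ny)
        fld = solve_depth_averaged_stokes(grid, fluid, Q)
        traj = advect_through_channel(fld, fluid, particle,
                                      release=(-100e-6, 0.0),
                                      x_stop=window[1] + 50e-6)
        fit = fit_strain_rate(traj.x, traj.u, window)
        rates.append(fit.slope)
    g_ref = rates[reference]
    err = [relative_error_percent(g, g_ref) for g in rates]
    return pd.DataFrame({
        "nx": [r[0] for r in resolutions],
        "ny": [r[1] for r in resolutions],
        "strain_rate": rates,
        "error_pct": err,
    })
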