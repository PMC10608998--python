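"""Parametric geometry and discretization of a hyperbolic contraction microchannel.

The planform is a straight inlet of width ``w_u``, a hyperbolic contraction of
length ``L_c`` whose width decreases from ``w_u`` to ``w_c`` such that ``1/w``
is affine in the axial coordinate (the profile that makes the depth-averaged
centerline velocity rise linearly, hence a nearly constant extensional strain
rate), an abrupt expansion back to ``w_u``, and a straight outlet.

Coordinates: ``x`` axial with origin at the contraction entrance, ``y``
transverse with origin on the centerline, ``z`` along the depth with origin at
the midplane.  All internal quantities are SI (meters); configuration I/O uses
micrometers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelGeometry",
    "StructuredGrid2D",
    "width_at",
    "hencky_strain",
    "build_grid",
]


@dataclass(frozen=True)
class ChannelGeometry:
    """Hyperbolic contraction planform and depth, in meters.

    Parameters
    ----------
    w_u : upstream/downstream width
    w_c : minimum contraction width
    L_c : contraction length
    h : channel depth
    L_in, L_out : straight inlet/outlet lengths
    """

    w_u: float
    w_c: float
    L_c: float
    h: float
    L_in: float = 500e-6
    L_out: float = 500e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.w_c < self.w_u):
            raise ValueError("require 0 < w_c < w_u")
        if self.L_c <= 0.0 or self.h <= 0.0:
            raise ValueError("require L_c > 0 and h > 0")
        if self.L_in < 0.0 or self.L_out < 0.0:
            raise ValueError("require L_in, L_out >= 0")

    # -- canonical device of the validation study (dimensions in um:
    #    w_u=406, w_c=17, L_c=780, h=60, L_in=L_out=500) --
    @classmethod
    def default(cls) -> "ChannelGeometry":
        return cls(w_u=406e-6, w_c=17e-6, L_c=780e-6, h=60e-6,
                   L_in=500e-6, L_out=500e-6)

    @classmethod
    def from_um(cls, w_u_um: float, w_c_um: float, L_c_um: float, h_um: float,
                L_in_um: float = 500.0, L_out_um: float = 500.0) -> "ChannelGeometry":
        return cls(w_u_um * 1e-6, w_c_um * 1e-6, L_c_um * 1e-6, h_um * 1e-6,
                   L_in_um * 1e-6, L_out_um * 1e-6)

    @property
    def x_min(self) -> float:
        return -self.L_in

    @property
    def x_max(self) -> float:
        return self.L_c + self.L_out

    def planform_area(self) -> float:
        """Analytic area under the width profile (m^2)."""
        straight = self.w_u * (self.L_in + self.L_out)
        contraction = (self.w_u * self.w_c * self.L_c
                       / (self.w_u - self.w_c) * math.log(self.w_u / self.w_c))
        return straight + contraction

    def hencky_strain(self) -> float:
        return hencky_strain(self)


def width_at(geom: ChannelGeometry, x):
    """Local channel width w(x) in meters.

    ``1/w`` is affine in ``x`` inside the contraction; the expansion at
    ``x = L_c`` is an instantaneous step back to ``w_u``.  ``x`` may be a
    scalar or array; values outside ``[-L_in, L_c + L_out]`` raise.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < geom.x_min - 1e-15) or np.any(x > geom.x_max + 1e-15):
        raise ValueError(
            f"x outside channel [{geom.x_min:.6g}, {geom.x_max:.6g}] m")
    xc = np.clip(x, 0.0, geom.L_c)
    w_hyp = (geom.w_u * geom.w_c * geom.L_c
             / (geom.w_c * geom.L_c + (geom.w_u - geom.w_c) * xc))
    w = np.where((x >= 0.0) & (x <= geom.L_c), w_hyp, geom.w_u)
    return float(w) if w.ndim == 0 else w


def hencky_strain(geom: ChannelGeometry) -> float:
    """Total extensional (Hencky) strain ln(w_u / w_c) through the contraction."""
    return math.log(geom.w_u / geom.w_c)


def _x_of_width(geom: ChannelGeometry, w: np.ndarray) -> np.ndarray:
    # inverse of the hyperbola: axial position at which the width equals w
    return geom.w_c * geom.L_c * (geom.w_u / w - 1.0) / (geom.w_u - geom.w_c)


@dataclass
class StructuredGrid2D:
    """Boundary-fitted structured grid on the channel planform.

    The map is a tensor product: axial stations ``x[i]`` (nonuniform) and a
    uniform transverse coordinate ``eta[j] in [-1, 1]`` scaled by the local
    half-width, ``y = eta * W(x) / 2``.  ``W`` is the grid's generating width
    profile: identical to :func:`width_at` except that the abrupt expansion is
    regularized over a short ramp (``expansion_smoothing``) so that the mapping
    metrics remain finite; the ramp is centered on the expansion and
    area-neutral.
    """

    nx: int
    ny: int
    x: np.ndarray          # (nx+1,) axial node stations, m
    eta: np.ndarray        # (ny+1,) uniform in [-1, 1]
    W: np.ndarray          # (nx+1,) generating width at each station, m
    h: float               # depth, m
    geom: ChannelGeometry | None = None
    expansion_smoothing: float = 0.0
    X: np.ndarray = field(init=False)   # (nx+1, ny+1) node x
    Y: np.ndarray = field(init=False)   # (nx+1, ny+1) node y

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ValueError("require nx, ny >= 4")
        if self.ny % 2 != 0:
            raise ValueError("ny must be even so a node row lies on the centerline")
        if np.any(self.W <= 0.0):
            raise ValueError("degenerate zero-width cell in grid")
        if np.any(np.diff(self.x) <= 0.0):
            raise ValueError("axial stations must be strictly increasing")
        self.X = np.broadcast_to(self.x[:, None],
                                 (self.nx + 1, self.ny + 1)).copy()
        self.Y = self.eta[None, :] * self.W[:, None] / 2.0
        # exact centerline row (guards against -0.0 and rounding of eta)
        self.Y[:, self.ny // 2] = 0.0

    @classmethod
    def straight(cls, W: float, h: float, length: float, nx: int, ny: int,
                 x0: float = 0.0, wall_cluster: bool = True) -> "StructuredGrid2D":
        """Straight rectangular channel (validation plumbing)."""
        x = np.linspace(x0, x0 + length, nx + 1)
        return cls(nx=nx, ny=ny, x=x, eta=eta_nodes(ny, wall_cluster),
                   W=np.full(nx + 1, float(W)), h=h)

    def cell_areas(self) -> np.ndarray:
        """Areas of the (nx, ny) quadrilateral cells by the shoelace formula."""
        X, Y = self.X, self.Y
        x1, y1 = X[:-1, :-1], Y[:-1, :-1]
        x2, y2 = X[1:, :-1], Y[1:, :-1]
        x3, y3 = X[1:, 1:], Y[1:, 1:]
        x4, y4 = X[:-1, 1:], Y[:-1, 1:]
        return 0.5 * np.abs((x1 * y2 - x2 * y1) + (x2 * y3 - x3 * y2)
                            + (x3 * y4 - x4 * y3) + (x4 * y1 - x1 * y4))

    def total_area(self) -> float:
        return float(self.cell_areas().sum())

    def width_interp(self, xq):
        """Generating width at arbitrary axial positions (linear between stations)."""
        return np.interp(xq, self.x, self.W)


def eta_nodes(ny: int, wall_cluster: bool = True) -> np.ndarray:
    """Transverse nodes in [-1, 1]; cosine-clustered toward the side walls by
    default so the Brinkman wall layers (thickness ~ h / sqrt(12)) are
    resolved.  ``eta = 0`` is always a node (ny even)."""
    s = np.linspace(-1.0, 1.0, ny + 1)
    return np.sin(0.5 * np.pi * s) if wall_cluster else s


def _grid_width(geom: ChannelGeometry, x: np.ndarray, delta: float) -> np.ndarray:
    """Generating width profile: width_at with the expansion step replaced by a
    cosine ramp on [L_c - delta/2, L_c + delta/2] (area-neutral by symmetry)."""
    w = np.asarray(width_at(geom, x), dtype=float).copy()
    if delta > 0.0:
        x0 = geom.L_c - delta / 2.0
        in_ramp = (x > x0) & (x < x0 + delta)
        if np.any(in_ramp):
            w0 = width_at(geom, x0)
            s = (x[in_ramp] - x0) / delta
            w[in_ramp] = w0 + (geom.w_u - w0) * 0.5 * (1.0 - np.cos(np.pi * s))
    return w


def build_grid(geom: ChannelGeometry, nx: int, ny: int, *,
               cluster: bool = True, wall_cluster: bool = True,
               expansion_smoothing: float = 20e-6) -> StructuredGrid2D:
    """Build a boundary-fitted grid with ``(nx+1) x (ny+1)`` nodes.

    With ``cluster=True`` the contraction stations are spaced uniformly in
    ``log w`` (denser toward the throat, where the width — and hence the cell
    scale — shrinks) and the outlet stations grow geometrically away from the
    expansion so the regularized step is resolved.  ``expansion_smoothing`` is
    the ramp length over which the abrupt expansion is regularized; it is
    clipped to the available outlet length.
    """
    if nx < 4 or ny < 4:
        raise ValueError("require nx, ny >= 4")
    if ny % 2 != 0:
        raise ValueError("ny must be even")
    delta = float(min(expansion_smoothing, 0.8 * geom.L_out)) if geom.L_out > 0 else 0.0

    # split the axial budget between inlet / contraction / outlet
    n_in = max(4, int(round(nx * (0.18 if cluster else geom.L_in
                                  / (geom.L_in + geom.L_c + geom.L_out)))))
    n_out = max(4, int(round(nx * (0.22 if cluster else geom.L_out
                                   / (geom.L_in + geom.L_c + geom.L_out)))))
    if geom.L_in == 0.0:
        n_in = 0
    if geom.L_out == 0.0:
        n_out = 0
    n_con = nx - n_in - n_out
    if n_con < 4:
        raise ValueError("nx too small for the requested segment split")

    xs = []
    if n_in:
        xs.append(np.linspace(-geom.L_in, 0.0, n_in + 1)[:-1])
    x_con_end = geom.L_c - delta / 2.0
    if cluster:
        w_end = width_at(geom, x_con_end)
        ws = np.exp(np.linspace(math.log(geom.w_u), math.log(w_end), n_con + 1))
        xc = _x_of_width(geom, ws)
        xc[0], xc[-1] = 0.0, x_con_end
        xs.append(xc[:-1])
    else:
        xs.append(np.linspace(0.0, x_con_end, n_con + 1)[:-1])
    if n_out:
        if cluster and delta > 0.0:
            # resolve the regularized expansion with its own uniform segment,
            # then grow geometrically toward the outlet
            n_ramp = min(max(4, nx // 24), n_out - 4)
            x_ramp_end = x_con_end + delta
            xr = np.linspace(x_con_end, x_ramp_end, n_ramp + 1)
            n = n_out - n_ramp
            length = geom.x_max - x_ramp_end
            d0 = min(delta / n_ramp, length / n)
            ratio = _geometric_ratio(length, d0, n)
            steps = d0 * ratio ** np.arange(n)
            xo = x_ramp_end + np.cumsum(steps)
            xo[-1] = geom.x_max
            xo = np.concatenate([xr, xo])
        else:
            xo = np.linspace(x_con_end, geom.x_max, n_out + 1)
        xs.append(xo)
    else:
        xs.append(np.array([x_con_end]))
    x = np.concatenate(xs)
    assert x.size == nx + 1

    eta = eta_nodes(ny, wall_cluster)
    W = _grid_width(geom, x, delta)
    return StructuredGrid2D(nx=nx, ny=ny, x=x, eta=eta, W=W, h=geom.h,
                            geom=geom, expansion_smoothing=delta)


def _geometric_ratio(length: float, d0: float, n: int) -> float:
    """Solve d0 * (r^n - 1)/(r - 1) = length for the growth ratio r >= 1."""
    if abs(n * d0 - length) / length < 1e-12:
        return 1.0
    lo, hi = 1.0 + 1e-12, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        tot = d0 * (mid ** n - 1.0) / (mid - 1.0)
        if tot < length:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
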