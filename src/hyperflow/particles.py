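"""Lagrangian discrete-phase tracking of rigid spherical tracers.

Each particle obeys the point-particle force balance

    du_p/dt = (u - u_p) / tau_r + g (rho_p - rho) / rho_p + F / m_p,

with Stokes-drag relaxation time ``tau_r = rho_p d_p^2 / (18 mu)`` (particle
Reynolds number << 1) and ``F = 0`` (no lift, Magnus or wall forces — the
same rigid-sphere simplification as the carrier model).  The drag term is
integrated exactly (exponential scheme), positions by a trapezoidal update.
Because the channel lies horizontally, gravity acts along the depth axis and
only produces a depth-settling offset tracked as a diagnostic; it never feeds
back on the planform motion.

Particle spin relaxes toward half the local fluid vorticity under the
creeping-flow rotational drag ``T = 8 pi mu (d_p/2)^3 Omega`` (time constant
``rho_p d_p^2 / (60 mu)``); it is a diagnostic and does not alter translation.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, replace

import numpy as np

from .flow import FlowField2D, FluidProperties

__all__ = [
    "ParticleProperties",
    "ParticleState",
    "Trajectory",
    "stokes_relaxation_time",
    "rotational_relaxation_time",
    "rotational_torque",
    "step_particle",
    "step_rotation",
    "advect_through_channel",
    "MidplaneSampler",
]

G_ACCEL = 9.81  # m/s^2, along -z (depth axis)


@dataclass(frozen=True)
class ParticleProperties:
    """Rigid spherical tracer: diameter (m) and density (kg/m^3)."""

    d_p: float
    rho_p: float

    def __post_init__(self) -> None:
        if self.d_p <= 0.0 or self.rho_p <= 0.0:
            raise ValueError("require d_p > 0 and rho_p > 0")

    @classmethod
    def rbc(cls) -> "ParticleProperties":
        """Human red blood cell at rest: d_p = 8 um, rho_p = 1080 kg/m^3."""
        return cls(d_p=8e-6, rho_p=1080.0)

    @property
    def mass(self) -> float:
        return self.rho_p * math.pi * self.d_p ** 3 / 6.0

    @property
    def moment_of_inertia(self) -> float:
        return math.pi * self.rho_p * self.d_p ** 5 / 60.0


@dataclass
class ParticleState:
    """Instantaneous Lagrangian state (planform position/velocity, spin, and
    the depth-settling diagnostic)."""

    t: float
    x: float
    y: float
    u: float
    v: float
    omega: float = 0.0
    z_offset: float = 0.0
    exited: bool = False


@dataclass
class Trajectory:
    """Time series of one particle's states."""

    particle_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    omega: np.ndarray
    z_offset: np.ndarray
    exited: bool = False
    truncated: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0.0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "particle_id": self.particle_id,
            "t_s": self.t,
            "x_um": self.x * 1e6,
            "y_um": self.y * 1e6,
            "u_mps": self.u,
            "v_mps": self.v,
            "omega_1_per_s": self.omega,
        })


def stokes_relaxation_time(particle: ParticleProperties,
                           fluid: FluidProperties) -> float:
    """tau_r = rho_p d_p^2 / (18 mu)."""
    if fluid.mu <= 0.0:
        raise ValueError("require mu > 0")
    return particle.rho_p * particle.d_p ** 2 / (18.0 * fluid.mu)


def rotational_relaxation_time(particle: ParticleProperties,
                               fluid: FluidProperties) -> float:
    """tau_rot = rho_p d_p^2 / (60 mu), from I_p and the Stokes rotational drag."""
    if fluid.mu <= 0.0:
        raise ValueError("require mu > 0")
    return particle.rho_p * particle.d_p ** 2 / (60.0 * fluid.mu)


def rotational_torque(particle: ParticleProperties, fluid: FluidProperties,
                      Omega: float) -> float:
    """Creeping-flow torque T = 8 pi mu (d_p/2)^3 Omega on a sphere spinning
    at Omega relative to the local fluid rotation."""
    return 8.0 * math.pi * fluid.mu * (particle.d_p / 2.0) ** 3 * Omega


def settling_terminal_velocity(particle: ParticleProperties,
                               fluid: FluidProperties) -> float:
    """Quasi-steady depth-settling speed tau_r g (rho_p - rho) / rho_p."""
    tau = stokes_relaxation_time(particle, fluid)
    return tau * G_ACCEL * (particle.rho_p - fluid.rho) / particle.rho_p


class MidplaneSampler:
    """Fast scalar bilinear sampler of the midplane velocity and vorticity.

    Pulls the node arrays out of a :class:`FlowField2D` once so the
    per-step cost of the advection loop stays at plain-float arithmetic.
    """

    def __init__(self, field: FlowField2D):
        g = field.grid
        r = field.r_station[:, None]
        self.xs = g.x.tolist()
        self.x0, self.x1 = g.x[0], g.x[-1]
        self.Wn = g.W
        self.U = r * field.u_bar
        self.V = r * field.v_bar
        self.ny = g.ny
        self.etas = g.eta.tolist()
        self.eta_arr = g.eta
        # half the planform curl on the midplane grid (solid-body rate)
        dVdx = np.gradient(self.V, g.x, axis=0)
        dUde = np.gradient(self.U, g.eta, axis=1)
        dUdy = dUde * (2.0 / g.W[:, None])
        self.CURL2 = 0.5 * (dVdx - dUdy)
        self.dx_cells = np.diff(g.x)

    def locate(self, x: float):
        i = bisect_right(self.xs, x) - 1
        if i < 0 or x > self.x1 + 1e-15:
            return None
        if i >= len(self.xs) - 1:
            i = len(self.xs) - 2
        return i

    def sample(self, x: float, y: float):
        """Return (u, v, i) at a point, or None if outside the planform."""
        i = self.locate(x)
        if i is None:
            return None
        tx = (x - self.xs[i]) / (self.xs[i + 1] - self.xs[i])
        W = (1.0 - tx) * self.Wn[i] + tx * self.Wn[i + 1]
        eta = 2.0 * y / W
        if eta > 1.0 or eta < -1.0:
            return None
        j = bisect_right(self.etas, eta) - 1
        if j >= self.ny:
            j = self.ny - 1
        if j < 0:
            j = 0
        ty = (eta - self.etas[j]) / (self.etas[j + 1] - self.etas[j])
        U, V = self.U, self.V
        u = ((1 - tx) * ((1 - ty) * U[i, j] + ty * U[i, j + 1])
             + tx * ((1 - ty) * U[i + 1, j] + ty * U[i + 1, j + 1]))
        v = ((1 - tx) * ((1 - ty) * V[i, j] + ty * V[i, j + 1])
             + tx * ((1 - ty) * V[i + 1, j] + ty * V[i + 1, j + 1]))
        return u, v, i

    def half_curl(self, x: float, y: float) -> float:
        i = self.locate(x)
        if i is None:
            return 0.0
        tx = (x - self.xs[i]) / (self.xs[i + 1] - self.xs[i])
        W = (1.0 - tx) * self.Wn[i] + tx * self.Wn[i + 1]
        eta = max(-1.0, min(1.0, 2.0 * y / W))
        j = min(max(bisect_right(self.etas, eta) - 1, 0), self.ny - 1)
        ty = (eta - self.etas[j]) / (self.etas[j + 1] - self.etas[j])
        C = self.CURL2
        return ((1 - tx) * ((1 - ty) * C[i, j] + ty * C[i, j + 1])
                + tx * ((1 - ty) * C[i + 1, j] + ty * C[i + 1, j + 1]))


def _drag_update(u: float, uf: float, e: float) -> float:
    # exact solution of du/dt = (uf - u)/tau over one step, e = exp(-dt/tau)
    return uf + (u - uf) * e


def step_particle(state: ParticleState, field: FlowField2D,
                  fluid: FluidProperties, particle: ParticleProperties,
                  dt: float) -> ParticleState:
    """Advance translation by one step of the exponential drag scheme."""
    if dt <= 0.0:
        raise ValueError("require dt > 0")
    if state.exited:
        return state
    sampler = field if isinstance(field, MidplaneSampler) else MidplaneSampler(field)
    hit = sampler.sample(state.x, state.y)
    if hit is None:
        return replace(state, exited=True)
    uf, vf, _ = hit
    tau = stokes_relaxation_time(particle, fluid)
    e = math.exp(-dt / tau)
    # predictor with the fluid velocity at the departure point, corrector
    # with its midpoint average (keeps the drag integration exact while the
    # carrier field varies along the step)
    u_new = _drag_update(state.u, uf, e)
    v_new = _drag_update(state.v, vf, e)
    x_new = state.x + 0.5 * dt * (state.u + u_new)
    y_new = state.y + 0.5 * dt * (state.v + v_new)
    hit2 = sampler.sample(x_new, y_new)
    if hit2 is not None:
        ufm = 0.5 * (uf + hit2[0])
        vfm = 0.5 * (vf + hit2[1])
        u_new = _drag_update(state.u, ufm, e)
        v_new = _drag_update(state.v, vfm, e)
        x_new = state.x + 0.5 * dt * (state.u + u_new)
        y_new = state.y + 0.5 * dt * (state.v + v_new)
    z_new = state.z_offset - settling_terminal_velocity(particle, fluid) * dt
    out = replace(state, t=state.t + dt, x=x_new, y=y_new,
                  u=u_new, v=v_new, z_offset=z_new)
    if sampler.sample(x_new, y_new) is None:
        out.exited = True
    return out


def step_rotation(state: ParticleState, field: FlowField2D,
                  fluid: FluidProperties, particle: ParticleProperties,
                  dt: float) -> ParticleState:
    """Relax the spin toward half the local fluid vorticity (diagnostic)."""
    if dt <= 0.0:
        raise ValueError("require dt > 0")
    sampler = field if isinstance(field, MidplaneSampler) else MidplaneSampler(field)
    wf = sampler.half_curl(state.x, state.y)
    tau = rotational_relaxation_time(particle, fluid)
    e = math.exp(-dt / tau)
    return replace(state, omega=wf + (state.omega - wf) * e)


def advect_through_channel(field: FlowField2D, fluid: FluidProperties,
                           particle: ParticleProperties, release,
                           *, dt_policy=None, x_stop: float | None = None,
                           max_time: float = 60.0,
                           particle_id: int = 0) -> Trajectory:
    """Integrate a particle from ``release = (x0, y0)`` until it exits the
    domain, passes ``x_stop``, or ``max_time`` is exceeded (then flagged
    truncated).

    Step control: ``dt = min(0.1 * cell-crossing time, 10 * tau_r)``; a
    custom ``dt_policy(state, dt_default) -> dt`` may shrink it further.
    """
    sampler = MidplaneSampler(field)
    x0, y0 = float(release[0]), float(release[1])
    hit = sampler.sample(x0, y0)
    if hit is None:
        raise ValueError("release point outside the planform")
    uf, vf, _ = hit
    tau = stokes_relaxation_time(particle, fluid)
    tau_rot = rotational_relaxation_time(particle, fluid)
    wsettle = settling_terminal_velocity(particle, fluid)
    if x_stop is None:
        x_stop = sampler.x1

    t = 0.0
    x, y = x0, y0
    u, v = uf, vf                       # released at the local fluid velocity
    omega = sampler.half_curl(x0, y0)
    z = 0.0
    T = [t]; X = [x]; Y = [y]; U = [u]; V = [v]; OM = [omega]; Z = [z]
    exited = False
    truncated = False
    dx_cells = sampler.dx_cells

    while True:
        hit = sampler.sample(x, y)
        if hit is None:
            exited = True
            break
        uf, vf, i = hit
        speed = math.hypot(u, v)
        cell_cross = dx_cells[i] / speed if speed > 0 else 10.0 * tau
        dt = min(0.1 * cell_cross, 10.0 * tau)
        if dt_policy is not None:
            dt = min(dt, float(dt_policy(ParticleState(t, x, y, u, v, omega, z), dt)))
        e = math.exp(-dt / tau)
        u_new = _drag_update(u, uf, e)
        v_new = _drag_update(v, vf, e)
        x_new = x + 0.5 * dt * (u + u_new)
        y_new = y + 0.5 * dt * (v + v_new)
        hit2 = sampler.sample(x_new, y_new)
        if hit2 is not None:
            ufm = 0.5 * (uf + hit2[0])
            vfm = 0.5 * (vf + hit2[1])
            u_new = _drag_update(u, ufm, e)
            v_new = _drag_update(v, vfm, e)
            x_new = x + 0.5 * dt * (u + u_new)
            y_new = y + 0.5 * dt * (v + v_new)
        x, y = x_new, y_new
        u, v = u_new, v_new
        wf = sampler.half_curl(x, y)
        omega = wf + (omega - wf) * math.exp(-dt / tau_rot)
        z -= wsettle * dt
        t += dt
        T.append(t); X.append(x); Y.append(y); U.append(u); V.append(v)
        OM.append(omega); Z.append(z)
        if x >= x_stop:
            # reaching the domain end counts as leaving through the outlet
            exited = x_stop >= sampler.x1
            break
        if t >= max_time:
            truncated = True
            break

    return Trajectory(particle_id=particle_id,
                      t=np.array(T), x=np.array(X), y=np.array(Y),
                      u=np.array(U), v=np.array(V), omega=np.array(OM),
                      z_offset=np.array(Z), exited=exited, truncated=truncated)
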