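"""Tracking velocimetry and strain-rate statistics.

Frame-wise velocities come from finite differences of tracked positions
(the frame-pair estimate manual tracking software reports), the extensional
strain rate from an ordinary least-squares fit of the axial velocity against
axial position over the contraction window — in a hyperbolic contraction the
centerline velocity rises linearly, so the slope du_x/dx is the (nearly
constant) strain rate and R^2 measures how well the device realizes it.
Per-flow-rate means and numerical-vs-experimental relative errors assemble
the comparison report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "StrainRateFit",
    "ComparisonRow",
    "ComparisonReport",
    "finite_difference_velocities",
    "add_velocities",
    "fit_strain_rate",
    "fit_track_strain_rate",
    "mean_strain_rate",
    "relative_error_percent",
    "profile_from_tracks",
    "compare_experiment_numerical",
]


@dataclass(frozen=True)
class StrainRateFit:
    """OLS fit of axial velocity vs axial position.

    slope : strain rate (1/s); intercept : m/s; window : (x_lo, x_hi) in m.
    """

    slope: float
    intercept: float
    r2: float
    window: tuple
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")
        if self.n_points < 3:
            raise ValueError("a fit needs at least 3 points")


def finite_difference_velocities(track: pd.DataFrame):
    """Per-sample velocity components (m/s) of one track.

    Central differences at interior samples, one-sided at the ends.  The
    track frame holds ``t_s, x_um, y_um``; duplicate timestamps are an error.
    Returns ``(u, v)`` arrays.
    """
    t = np.asarray(track["t_s"], dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples to difference")
    if np.any(np.diff(t) <= 0.0):
        raise ValueError("duplicate or non-increasing timestamps in track")
    x = np.asarray(track["x_um"], dtype=float) * 1e-6
    y = np.asarray(track["y_um"], dtype=float) * 1e-6
    u = np.gradient(x, t)
    v = np.gradient(y, t)
    return u, v


def add_velocities(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a multi-track table with ``u_mps, v_mps`` columns."""
    out = []
    for tid, sub in table.groupby("track_id", sort=True):
        sub = sub.sort_values("frame").copy()
        u, v = finite_difference_velocities(sub)
        sub["u_mps"] = u
        sub["v_mps"] = v
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def fit_strain_rate(x, u, window) -> StrainRateFit:
    """OLS of axial velocity ``u`` (m/s) on position ``x`` (m) inside
    ``window = (x_lo, x_hi)`` in meters.  The slope is the strain rate."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    lo, hi = window
    m = (x >= lo) & (x <= hi)
    if m.sum() < 3:
        raise ValueError(f"fewer than 3 samples inside window [{lo}, {hi}] m")
    xs, us = x[m], u[m]
    if np.ptp(xs) == 0.0:
        raise ValueError("all positions identical: slope undefined")
    res = linregress(xs, us)
    return StrainRateFit(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2), window=(float(lo), float(hi)),
                         n_points=int(m.sum()))


def fit_track_strain_rate(track: pd.DataFrame, window) -> StrainRateFit:
    """Velocity-differencing + strain-rate fit of one track (window in m)."""
    u, _ = finite_difference_velocities(track)
    return fit_strain_rate(np.asarray(track["x_um"], dtype=float) * 1e-6,
                           u, window)


def _slope(f) -> float:
    return f.slope if isinstance(f, StrainRateFit) else float(f)


def mean_strain_rate(fits) -> float:
    """Arithmetic mean of fitted slopes (accepts fits or plain values)."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to average")
    return float(np.mean([_slope(f) for f in fits]))


def relative_error_percent(value: float, reference: float) -> float:
    """100 * |value - reference| / reference."""
    if reference == 0.0:
        raise ValueError("zero reference in relative error")
    return 100.0 * abs(value - reference) / reference


def profile_from_tracks(table: pd.DataFrame, station_x_um: float,
                        bin_width_um: float) -> pd.DataFrame:
    """Binned transverse profile of axial velocity at one axial station.

    For every track crossing the station, the crossing's transverse position
    and frame-pair axial velocity are collected, then averaged in y-bins of
    ``bin_width_um``.  Returns columns ``y_center_um, u_mps, n``.
    """
    pts_y, pts_u = [], []
    for _, sub in table.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        x = sub["x_um"].to_numpy(dtype=float)
        y = sub["y_um"].to_numpy(dtype=float)
        t = sub["t_s"].to_numpy(dtype=float)
        for k in np.nonzero((x[:-1] - station_x_um) * (x[1:] - station_x_um) <= 0.0)[0]:
            if x[k + 1] == x[k]:
                continue
            s = (station_x_um - x[k]) / (x[k + 1] - x[k])
            pts_y.append(y[k] + s * (y[k + 1] - y[k]))
            pts_u.append((x[k + 1] - x[k]) * 1e-6 / (t[k + 1] - t[k]))
    if not pts_y:
        warnings.warn(f"no tracks cross the station x = {station_x_um} um",
                      stacklevel=2)
        return pd.DataFrame(columns=["y_center_um", "u_mps", "n"])
    yb = np.floor(np.asarray(pts_y) / bin_width_um).astype(int)
    df = pd.DataFrame({"bin": yb, "u": pts_u})
    g = df.groupby("bin")["u"].agg(["mean", "size"]).reset_index()
    return pd.DataFrame({
        "y_center_um": (g["bin"] + 0.5) * bin_width_um,
        "u_mps": g["mean"],
        "n": g["size"].astype(int),
    }).sort_values("y_center_um", ignore_index=True)


@dataclass
class ComparisonRow:
    flow_rate_mlh: float
    particle_strain_rates: list
    r2_values: list
    mean_exp: float
    numerical: float
    error_pct: float


@dataclass
class ComparisonReport:
    """Per-flow-rate comparison of experimental and numerical strain rates."""

    rows: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "flow_rate_mlh": r.flow_rate_mlh,
            "particle_strain_rates": ";".join(f"{s:.6g}" for s in r.particle_strain_rates),
            "r2": ";".join(f"{v:.6g}" for v in r.r2_values),
            "mean_exp": r.mean_exp,
            "numerical": r.numerical,
            "error_pct": r.error_pct,
        } for r in self.rows])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = [{
            "flow_rate_mlh": r.flow_rate_mlh,
            "particle_strain_rates": list(r.particle_strain_rates),
            "r2": list(r.r2_values),
            "mean_exp": r.mean_exp,
            "numerical": r.numerical,
            "error_pct": r.error_pct,
        } for r in self.rows]
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        return None


def compare_experiment_numerical(exp_fits, num_fits) -> ComparisonReport:
    """Assemble the comparison report from per-flow-rate experimental fits and
    the numerical fit, keyed by flow rate in mL/h.

    ``exp_fits``: mapping Q -> sequence of fits (or slopes); ``num_fits``:
    mapping Q -> fit (or slope).  The relative error references the
    experimental mean.  Rows are sorted by ascending Q.
    """
    if set(exp_fits) != set(num_fits):
        raise ValueError("flow-rate keys of experimental and numerical fits differ")
    rows = []
    for Q in sorted(exp_fits):
        fits = list(exp_fits[Q])
        slopes = [_slope(f) for f in fits]
        r2s = [f.r2 if isinstance(f, StrainRateFit) else float("nan") for f in fits]
        mean_exp = mean_strain_rate(fits)
        num = _slope(num_fits[Q])
        rows.append(ComparisonRow(
            flow_rate_mlh=float(Q),
            particle_strain_rates=slopes,
            r2_values=r2s,
            mean_exp=mean_exp,
            numerical=num,
            error_pct=relative_error_percent(num, mean_exp),
        ))
    return ComparisonReport(rows=rows)
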