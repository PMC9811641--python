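"""Forward models of jet-impact cavity expansion in a capillary bridge.

Three model families, in increasing physical fidelity:

1. *Inertial crater law* (:func:`inertial_profile`): at We >> 1 and Re >> 1
   each axial slice of the cavity opens with a radial impulse set by the jet
   energy flux and then coasts, so the local radius grows as
   ``R(x,t)^2 = a (t - t0(x))`` with ``a = beta D_0 U_0`` and opening time
   ``t0(x) = x / U_c``.  At fixed ``t`` this is a parabola with its apex at
   the cavity front ``H_c(t) = U_c t``.

2. *Per-slice radial momentum balance* (:func:`rayleigh2d_integrate`): the
   cylindrical-slice analogue of the Rayleigh equation,
   ``rho d/dt(R Rdot) = p(t) - gamma/R - 4 mu Rdot / R``, integrated
   numerically.  Under an impulsive driving pressure it reproduces the
   square-root coasting law of model 1, which is used as an oracle test.

3. *Viscous droplet-train superposition* (:func:`viscous_drop_cavity`,
   :func:`superposed_train_profile`): the jet is replaced by an equivalent
   train of droplets of identical volumetric flux; each droplet drives one
   slice of the cavity through model 2 including capillary and viscous
   terms, and successive solutions are time-shifted, offset to the advancing
   front and combined by pointwise maximum.  For viscous targets this yields
   the observed deeper, narrower cavities that the inviscid parabola
   overestimates radially.

The cavity-front speed itself is modelled by :func:`cavity_velocity_model`:
an impedance-matching factor ``sqrt(rho_r)/(1 + sqrt(rho_r))`` (equal to 1/2
for density-matched jet and target) reduced by viscous dissipation in the
target, ``mu_cb U_0^2 / D_0^2`` scale, through ``1/(1 + C_v mu_cb/(rho_0 U_0 D_0))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .materials import JetSpec, Material

__all__ = [
    "CavityTrajectory",
    "DropletTrainSpec",
    "RatioSet",
    "IntegrationError",
    "cavity_front_position",
    "inertial_profile",
    "rayleigh2d_integrate",
    "viscous_drop_cavity",
    "train_from_jet",
    "train_cavity_velocity",
    "superposed_train_profile",
    "cavity_velocity_model",
    "projected_area",
]

N_AXIAL_DEFAULT = 512
ODE_RTOL = 1e-8
ODE_ATOL = 1e-12
EPS_INIT = 1e-3  # initial cavity radius as a fraction of the drop radius


class IntegrationError(RuntimeError):
    """ODE solver failed to converge; message carries solver diagnostics."""


@dataclass(frozen=True)
class RatioSet:
    """Jet-to-target density and viscosity ratios (both > 0)."""

    rho_r: float
    mu_r: float

    def __post_init__(self) -> None:
        if self.rho_r <= 0 or self.mu_r <= 0:
            raise ValueError("density and viscosity ratios must be positive")

    @staticmethod
    def from_materials(jet_liquid: Material, target: Material) -> "RatioSet":
        return RatioSet(
            rho_r=jet_liquid.rho_cb / target.rho_cb,
            mu_r=jet_liquid.mu_cb / target.mu_cb,
        )


@dataclass(frozen=True)
class DropletTrainSpec:
    """Droplet train equivalent to a jet of radius ``r_cyl``.

    ``f`` is the (dimensionless) train frequency parameter: the
    centre-to-centre spacing is ``h_cyl = 2 r_d / f``, so ``f = 1/2`` packs
    the drops into a continuous column and recovers the jet limit.
    Volume equivalence ``(4/3) pi r_d^3 = pi r_cyl^2 h_cyl`` is enforced.
    """

    r_d: float
    U_d: float
    f: float
    h_cyl: float
    r_cyl: float

    def __post_init__(self) -> None:
        if min(self.r_d, self.U_d, self.f, self.h_cyl, self.r_cyl) <= 0:
            raise ValueError("all train parameters must be positive")
        if not math.isclose(self.h_cyl, 2.0 * self.r_d / self.f, rel_tol=1e-12):
            raise ValueError("h_cyl must equal 2 r_d / f")
        v_drop = (4.0 / 3.0) * math.pi * self.r_d**3
        v_cyl = math.pi * self.r_cyl**2 * self.h_cyl
        if not math.isclose(v_drop, v_cyl, rel_tol=1e-12):
            raise ValueError("droplet and equivalent-cylinder volumes must match")

    @property
    def period(self) -> float:
        """Time between successive drop impacts, h_cyl / U_d (s)."""
        return self.h_cyl / self.U_d

    @property
    def volume_flux(self) -> float:
        """Time-averaged volumetric flux of the train (m^3/s)."""
        return (4.0 / 3.0) * math.pi * self.r_d**3 * self.U_d / self.h_cyl


@dataclass
class CavityTrajectory:
    """Time-resolved cavity description on a fixed axial grid.

    ``profiles[i, j]`` is the cavity half-width R(x_j, t_i) in metres;
    ``front[i]`` is the cavity front position H_c(t_i).
    """

    times: np.ndarray
    x: np.ndarray
    profiles: np.ndarray
    front: np.ndarray
    U_c: float
    t0: np.ndarray
    L_max: float
    A_max: float
    H_max: float

    def __post_init__(self) -> None:
        if np.any(self.profiles < 0):
            raise ValueError("cavity radii must be non-negative")
        grow = np.diff(self.front) < -1e-12
        if grow.any() and self.front[np.argmax(grow)] < self.L_max - 1e-12:
            raise ValueError("front must be non-decreasing during expansion")

    def area_series(self) -> np.ndarray:
        """Projected cavity area A(t) = integral of 2 R dx (m^2)."""
        return np.trapezoid(2.0 * self.profiles, self.x, axis=1)

    def to_frame(self):
        """Long-format DataFrame with columns t_s, x_m, R_m."""
        import pandas as pd

        t_col = np.repeat(self.times, self.x.size)
        x_col = np.tile(self.x, self.times.size)
        return pd.DataFrame(
            {"t_s": t_col, "x_m": x_col, "R_m": self.profiles.ravel()}
        )


def cavity_front_position(U_c: float, t: float | np.ndarray) -> float | np.ndarray:
    """Cavity front H_c = U_c t during the linear-growth expansion stage."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = U_c * t
    return float(out) if out.ndim == 0 else out


def crater_growth_coefficient(jet: JetSpec, beta: float = 1.0) -> float:
    """Slope ``a`` of the local growth law R^2 = a (t - t0), a = beta D_0 U_0."""
    return beta * jet.D_0 * jet.U_0


def inertial_profile(
    x: np.ndarray | float,
    t: float,
    jet: JetSpec,
    U_c: Optional[float] = None,
    beta: float = 1.0,
    t0_convention: str = "x_over_Uc",
) -> np.ndarray | float:
    """Inviscid parabolic cavity profile R(x, t).

    R = sqrt(a (t - t0(x))) for x <= H_c(t), zero beyond; ``t0(x) = x/U_c``
    (the only dimensionally consistent opening time; the literal alternative
    ``x/H_c``, which is dimensionless, is refused).
    """
    if t0_convention != "x_over_Uc":
        raise ValueError(
            "only the x/U_c opening-time convention is dimensionally admissible"
        )
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or t < 0:
        raise ValueError("x and t must be non-negative")
    if U_c is None:
        U_c = 0.5 * jet.U_0
    a = crater_growth_coefficient(jet, beta)
    tau = t - (x_arr / U_c if U_c > 0 else np.inf)
    r2 = a * np.clip(tau, 0.0, None)
    out = np.sqrt(r2)
    return float(out) if out.ndim == 0 else out


def _integrate_slice(
    driving_pressure: Callable[[float], float],
    R_init: float,
    Rdot_init: float,
    t_grid: np.ndarray,
    rho: float,
    gamma: float,
    mu: float,
    rtol: float,
    atol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the slice balance; returns (R, Rdot) on t_grid, zero past collapse."""
    floor = 1e-12 * max(R_init, 1.0)

    def rhs(t, y):
        R, Rdot = y
        R = max(R, floor)
        p = driving_pressure(t) - gamma / R - 4.0 * mu * Rdot / R
        return [Rdot, (p / rho - Rdot**2) / R]

    def collapsed(t, y):
        return y[0] - floor

    collapsed.terminal = True
    collapsed.direction = -1

    sol = solve_ivp(
        rhs,
        (float(t_grid[0]), float(t_grid[-1])),
        [R_init, Rdot_init],
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        events=collapsed,
        method="LSODA",
    )
    if not sol.success and sol.status != 1:
        raise IntegrationError(f"slice integration failed: {sol.message}")
    R = np.zeros_like(t_grid)
    Rdot = np.zeros_like(t_grid)
    R[: sol.y.shape[1]] = np.clip(sol.y[0], 0.0, None)
    Rdot[: sol.y.shape[1]] = sol.y[1]
    return R, Rdot


def rayleigh2d_integrate(
    driving_pressure: Callable[[float], float],
    R_init: float,
    Rdot_init: float,
    t_grid: Sequence[float],
    rho: float = 998.0,
    gamma: float = 0.0,
    mu: float = 0.0,
    rtol: float = ODE_RTOL,
    atol: float = ODE_ATOL,
) -> np.ndarray:
    """Integrate the per-slice radial momentum balance on ``t_grid``.

    rho d/dt(R Rdot) = p(t) - gamma / R - 4 mu Rdot / R

    i.e. ``Rddot = ((p - gamma/R - 4 mu Rdot/R)/rho - Rdot^2) / R``.  The
    slice collapses when R reaches zero; past collapse the radius is
    reported as zero.
    """
    if R_init <= 0:
        raise ValueError("initial radius must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    R, _ = _integrate_slice(
        driving_pressure, R_init, Rdot_init, t_grid, rho, gamma, mu, rtol, atol
    )
    return R


def drive_pressure_coefficient(f: float, rho_r: float = 1.0, beta: float = 1.0) -> float:
    """Driving-pressure coefficient C_p of a single drop in the train.

    Chosen so that in the dissipation-free limit the per-slice radial
    impulse of one drop reproduces the jet crater law with coefficient
    ``a = beta D_0 U_0`` of the jet the train is equivalent to:
    C_p = beta f sqrt(2 f / 3) / (2 rho_r).
    """
    return beta * f * math.sqrt(2.0 * f / 3.0) / (2.0 * rho_r)


def viscous_drop_cavity(
    drop: DropletTrainSpec,
    target: Material,
    t_grid: Sequence[float],
    rho_jet: float = 1000.0,
    beta: float = 1.0,
    include_surface_tension: bool = True,
    eps_init: float = EPS_INIT,
) -> np.ndarray:
    """Cavity radius evolution of a single train droplet in a viscous target.

    The drop feeds the slice for ``4 r_d / U_d`` (its length consumed at the
    relative speed ``U_d - U_c = U_d/2``) with a driving pressure
    ``C_p rho_jet U_d^2``; thereafter the slice coasts against capillary and
    viscous stresses.  The feed is a direct momentum injection: the drop's
    dynamic pressure dwarfs both the capillary pressure (above a sub-micron
    radius) and the shear stress in the thin boundary layer, so the
    capillary and viscous terms act in the coasting phase, on the
    established cavity flow.  In the Re -> infinity limit this reduces to
    the inviscid single-drop solution.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if drop.U_d == 0:
        return np.full(t_grid.size, eps_init * drop.r_d)
    c_p = drive_pressure_coefficient(drop.f, rho_jet / target.rho_cb, beta)
    p0 = c_p * rho_jet * drop.U_d**2
    t_feed = 4.0 * drop.r_d / drop.U_d

    def p(t):
        return p0 if 0.0 <= t <= t_feed else 0.0

    gamma = target.gamma_cb if include_surface_tension else 0.0
    feed = t_grid <= t_feed
    feed_grid = np.concatenate([[0.0], t_grid[feed], [t_feed]])
    feed_grid = np.unique(feed_grid)
    R_feed, Rdot_feed = _integrate_slice(
        p, eps_init * drop.r_d, 0.0, feed_grid,
        target.rho_cb, 0.0, 0.0, ODE_RTOL, ODE_ATOL,
    )
    R = np.empty_like(t_grid)
    R[feed] = np.interp(t_grid[feed], feed_grid, R_feed)
    if (~feed).any():
        coast_grid = np.concatenate([[t_feed], t_grid[~feed]])
        if R_feed[-1] <= 0:
            R[~feed] = 0.0
        else:
            R_coast, _ = _integrate_slice(
                p, R_feed[-1], Rdot_feed[-1], coast_grid,
                target.rho_cb, gamma, target.mu_cb, ODE_RTOL, ODE_ATOL,
            )
            R[~feed] = R_coast[1:]
    return R


def train_from_jet(jet: JetSpec, f: float = 0.5) -> DropletTrainSpec:
    """Equivalent droplet train of a jet: equal volume and equal cavity speed.

    Volume equivalence of one drop with its slice of the encapsulating
    cylinder fixes ``r_d = r_cyl sqrt(3/(2f))``; matching the train's cavity
    velocity ``f U_d`` to the jet's ``U_0/2`` fixes ``U_d = U_0/(2f)``.
    """
    if f <= 0:
        raise ValueError("train frequency parameter must be positive")
    r_cyl = jet.D_0 / 2.0
    r_d = r_cyl * math.sqrt(3.0 / (2.0 * f))
    h_cyl = 2.0 * r_d / f
    U_d = jet.U_0 / (2.0 * f)
    return DropletTrainSpec(r_d=r_d, U_d=U_d, f=f, h_cyl=h_cyl, r_cyl=r_cyl)


def train_cavity_velocity(U_d: float, f: float) -> float:
    """Cavity front speed of a droplet train, U_c = f U_d.

    Each drop advances the front at U_d/2 while it is being consumed, which
    is a fraction 2f of the inter-drop period, so the time-averaged front
    speed is f U_d; f = 1/2 recovers the continuous-jet value U_d/2.
    """
    if U_d < 0 or f <= 0:
        raise ValueError("U_d must be non-negative, f positive")
    return f * U_d


def superposed_train_profile(
    train: DropletTrainSpec,
    target: Material,
    t: float,
    rho_jet: float = 1000.0,
    n_x: int = N_AXIAL_DEFAULT,
    n_drops: Optional[int] = None,
    beta: float = 1.0,
    include_surface_tension: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Composite cavity profile of the train at time ``t``.

    Drop ``k`` impacts at ``t_k = k T`` (T the train period) onto the
    instantaneous front and owns the axial band
    ``[k dH, (k+1) dH]`` with ``dH = U_c T = 2 r_d``; its slice radius
    follows the single-drop solution time-shifted by ``t_k``.  Bands are
    combined by pointwise maximum and the profile is cut at the front
    ``H_c(t) = U_c t``.  Returns ``(x, R)`` arrays.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    U_c = train_cavity_velocity(train.U_d, train.f)
    T = train.period
    dH = U_c * T
    H_c = U_c * t
    k_max = int(math.ceil(t / T)) if n_drops is None else n_drops
    k_max = max(k_max, 1)

    # one shared single-drop solution, sampled densely up to t
    tau_grid = np.linspace(0.0, max(t, T), 512)
    R_drop = viscous_drop_cavity(
        train,
        target,
        tau_grid,
        rho_jet=rho_jet,
        beta=beta,
        include_surface_tension=include_surface_tension,
    )

    x = np.linspace(0.0, max(H_c, dH * k_max), n_x)
    R = np.zeros_like(x)
    for k in range(k_max):
        t_k = k * T
        if t_k >= t:
            break
        r_k = float(np.interp(t - t_k, tau_grid, R_drop))
        band = (x >= k * dH) & (x < (k + 1) * dH)
        R[band] = np.maximum(R[band], r_k)
    R[x > H_c] = 0.0
    return x, R


def cavity_velocity_model(
    jet: JetSpec,
    target: Material,
    ratios: Optional[RatioSet] = None,
    c_visc: float = 20.0,
) -> float:
    """Cavity front speed U_c including density mismatch and viscous dissipation.

    U_c = U_0 * sqrt(rho_r)/(1 + sqrt(rho_r)) * 1/(1 + C_v mu_cb/(rho_0 U_0 D_0))

    The first factor is the pressure-balance (impedance-matching) penetration
    speed, equal to 1/2 for matched densities; the second discounts the
    viscous dissipation ``mu_cb U_0^2 / D_0^2`` relative to the jet's dynamic
    pressure, with an order-one constant ``c_visc``.
    """
    if jet.U_0 == 0:
        return 0.0
    rho_r = ratios.rho_r if ratios is not None else jet.rho_0 / target.rho_cb
    s = math.sqrt(rho_r)
    visc_number = target.mu_cb / (jet.rho_0 * jet.U_0 * jet.D_0)
    return jet.U_0 * (s / (1.0 + s)) / (1.0 + c_visc * visc_number)


def projected_area(x: np.ndarray, R: np.ndarray) -> float:
    """Projected (side-view) cavity area, integral of 2 R dx (m^2)."""
    return float(np.trapezoid(2.0 * np.asarray(R), np.asarray(x)))


def inertial_trajectory(
    jet: JetSpec,
    target: Material,
    t_grid: Sequence[float],
    U_c: Optional[float] = None,
    beta: float = 1.0,
    x_max: Optional[float] = None,
    n_x: int = N_AXIAL_DEFAULT,
) -> CavityTrajectory:
    """Sampled :class:`CavityTrajectory` under the inertial crater law."""
    t_grid = np.asarray(t_grid, dtype=float)
    if U_c is None:
        U_c = cavity_velocity_model(jet, target)
    front = cavity_front_position(U_c, t_grid)
    if x_max is None:
        x_max = float(front[-1]) if front[-1] > 0 else jet.D_0
    x = np.linspace(0.0, x_max, n_x)
    profiles = np.vstack([inertial_profile(x, t, jet, U_c, beta) for t in t_grid])
    areas = np.trapezoid(2.0 * profiles, x, axis=1)
    i_max = int(np.argmax(areas))
    return CavityTrajectory(
        times=t_grid,
        x=x,
        profiles=profiles,
        front=np.asarray(front),
        U_c=U_c,
        t0=x / U_c if U_c > 0 else np.full_like(x, np.inf),
        L_max=float(np.max(front)),
        A_max=float(areas[i_max]),
        H_max=float(np.max(front)),
    )
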