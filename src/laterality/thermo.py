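"""Entropy, free energy and the Boltzmann equilibrium of the L/R ratio.

With the composition parameterized as N_L/N = tanh^2(theta), the population
entropy is

    S(theta) = -(sinh^2(theta) ln sinh^2(theta) - cosh^2(theta) ln cosh^2(theta)),

which coincides exactly with the Shannon entropy of the geometric occupation
law W_X.  The free energy of the configuration with ratio X = sinh^2(theta)
is F = X * E_X - S / beta, where E_X is the configuration energy scale and
beta = 1/T (k_B = 1, all quantities dimensionless).  Stationarity dF = 0
gives the Boltzmann form

    -beta E_X = ln tanh^2(theta)  <=>  N_L / N = exp(-beta E_X),

so the balanced population N_L/N = 1/2 (X = 1) occurs exactly at
beta E_X = ln 2.  The boundary compositions N_L/N in {0, 1} are excluded:
they would require T -> 0 or T -> infinity.  beta and E_X enter every
observable only through the product beta * E_X; the API exposes both for
readability but documents the degeneracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import xlogy

__all__ = [
    "ThermoParams",
    "FreeEnergyProfile",
    "entropy",
    "entropy_from_occupations",
    "free_energy",
    "free_energy_gradient",
    "free_energy_curvature",
    "stationarity_solve",
    "temperature_from_ratio",
    "free_energy_profile",
]


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic state (theta, beta, E_X, g) with derived composition.

    ``a = tanh^2(theta)`` is the L-fraction N_L/N and ``ratio = sinh^2(theta)``
    the continuous L/R ratio X; H_X = X * E_X.  Units: k_B = 1.
    """

    theta: float
    beta: float
    e_x: float
    g: float = 1.0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta is restricted to the nonnegative branch")
        if self.beta <= 0:
            raise ValueError("inverse temperature beta must be > 0")

    @property
    def a(self) -> float:
        """L-fraction N_L/N = tanh^2(theta), in [0, 1)."""
        return float(np.tanh(self.theta) ** 2)

    @property
    def ratio(self) -> float:
        """X = N_L/N_R = sinh^2(theta) = a / (1 - a)."""
        return float(np.sinh(self.theta) ** 2)

    @property
    def configuration_energy(self) -> float:
        """H_X = X * E_X."""
        return self.ratio * self.e_x

    @property
    def entropy(self) -> float:
        return entropy(self.theta)

    @property
    def free_energy(self) -> float:
        return free_energy(self.theta, self.beta, self.e_x)


@dataclass(frozen=True)
class FreeEnergyProfile:
    """F and S sampled on a theta grid, with the stationary point attached."""

    theta_grid: np.ndarray = field(repr=False)
    s_values: np.ndarray = field(repr=False)
    f_values: np.ndarray = field(repr=False)
    theta_star: float
    x_star: float

    def __post_init__(self) -> None:
        if not (len(self.theta_grid) == len(self.s_values) == len(self.f_values)):
            raise ValueError("grid and value vectors must have equal length")


def entropy(theta):
    """Population entropy S(theta); 0 at theta = 0 and strictly increasing.

    The theta = 0 limit is handled analytically (x ln x -> 0), not by
    epsilon-shifting.  Accepts scalars or arrays.
    """
    s2 = np.sinh(theta) ** 2
    c2 = 1.0 + s2
    s = -(xlogy(s2, s2) - xlogy(c2, c2))
    return float(s) if np.isscalar(theta) else s


def entropy_from_occupations(theta: float, tail_tol: float = 1e-12) -> tuple[float, float]:
    """Shannon entropy -sum_X W_X ln W_X of the occupation law, truncated.

    Returns ``(value, abs_discrepancy)`` against the closed form; the two
    agree exactly (same algebraic identity), so the discrepancy is a
    consistency diagnostic that should sit at rounding level.
    """
    t2 = np.tanh(theta) ** 2
    if t2 == 0.0:
        return 0.0, abs(entropy(theta))
    # truncate the geometric tail at relative mass tail_tol
    x_max = max(1, int(np.ceil(np.log(tail_tol) / np.log(t2))))
    w = (1.0 - t2) * t2 ** np.arange(x_max + 1)
    val = float(-np.sum(xlogy(w, w)))
    # tail correction: sum_{X>x_max} W ln W is bounded by the residual mass
    return val, abs(val - entropy(theta))


def free_energy(theta, beta: float, e_x: float):
    """F(theta) = sinh^2(theta) * E_X - S(theta) / beta."""
    if beta <= 0:
        raise ValueError("inverse temperature beta must be > 0")
    return np.sinh(theta) ** 2 * e_x - entropy(theta) / beta


def free_energy_gradient(theta, beta: float, e_x: float):
    """dF/dtheta = 2 sinh(theta) cosh(theta) (E_X + ln tanh^2(theta) / beta).

    Vanishes at theta = 0 (the sinh*cosh prefactor kills the log divergence)
    and at the Boltzmann stationary point ln tanh^2(theta*) = -beta E_X.
    """
    theta_arr = np.asarray(theta, dtype=float)
    sc = np.sinh(theta_arr) * np.cosh(theta_arr)
    with np.errstate(divide="ignore"):
        log_t2 = np.where(theta_arr != 0.0, np.log(np.tanh(theta_arr) ** 2), 0.0)
    grad = 2.0 * sc * e_x + 2.0 * sc * log_t2 / beta
    grad = np.where(theta_arr == 0.0, 0.0, grad)
    return float(grad) if np.isscalar(theta) else grad


def free_energy_curvature(theta: float, beta: float, e_x: float, h: float = 1e-5) -> float:
    """d^2F/dtheta^2 by centred differencing of the analytic gradient."""
    return float(
        (free_energy_gradient(theta + h, beta, e_x) - free_energy_gradient(theta - h, beta, e_x))
        / (2.0 * h)
    )


def stationarity_solve(beta: float, e_x: float, g: float = 1.0) -> ThermoParams:
    """Equilibrium theta* from dF = 0: tanh^2(theta*) = exp(-beta E_X).

    The closed form theta* = artanh(exp(-beta E_X / 2)) is cross-validated
    against a numeric root of dF/dtheta on the substitution u = tanh^2(theta)
    (monotone, so bracketing is trivial).  The equilibrium fractions follow
    the Boltzmann factor N_L/N = exp(-beta E_X), with X* strictly between 0
    and infinity.
    """
    be = beta * e_x
    if not np.isfinite(be) or be <= 0:
        raise ValueError(
            "beta * E_X must be positive and finite: N_L/N = 1 would need "
            "beta E_X ~ 0 (T ~ infinity) and N_L/N = 0 would need "
            "beta E_X ~ infinity (T ~ 0); both are excluded"
        )
    u_star = np.exp(-be)
    theta_star = float(np.arctanh(np.sqrt(u_star)))
    # independent numeric root of dF on the substitution v = ln tanh^2(theta):
    # E_X + v / beta = 0, bracketed on v < 0 (log space stays well-conditioned
    # at large beta E_X where u_star underflows toward 0)
    v_num = brentq(lambda v: e_x + v / beta, -2 * be - 1.0, -1e-300, xtol=1e-12)
    if abs(v_num + be) > 1e-9 * max(be, 1.0):  # pragma: no cover
        raise RuntimeError("numeric stationarity root disagrees with the closed form")
    return ThermoParams(theta=theta_star, beta=beta, e_x=e_x, g=g)


def temperature_from_ratio(x: float, e_x: float) -> float:
    """Temperature implied by an observed ratio: T = E_X / ln((1 + X)/X).

    Inverts N_L/N = X/(1+X) = exp(-E_X/T); round-trips with
    ``stationarity_solve``.  T -> infinity as X -> infinity, consistent with
    the exclusion of the all-L composition at finite temperature.
    """
    if x <= 0 or not np.isfinite(x):
        raise ValueError("ratio X must be positive and finite")
    if e_x <= 0:
        raise ValueError("configuration energy E_X must be > 0")
    return float(e_x / np.log((1.0 + x) / x))


def free_energy_profile(
    beta: float, e_x: float, theta_grid: np.ndarray | None = None
) -> FreeEnergyProfile:
    """Sample S and F on a theta grid and attach the stationary point."""
    if theta_grid is None:
        theta_grid = np.linspace(0.0, 2.0, 401)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.ndim != 1 or np.any(np.diff(theta_grid) <= 0):
        raise ValueError("theta_grid must be strictly increasing")
    params = stationarity_solve(beta, e_x)
    return FreeEnergyProfile(
        theta_grid=theta_grid,
        s_values=entropy(theta_grid),
        f_values=free_energy(theta_grid, beta, e_x),
        theta_star=params.theta,
        x_star=params.ratio,
    )
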