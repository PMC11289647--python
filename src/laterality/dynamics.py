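"""Relaxation of the population composition toward the free-energy minimum.

The thermodynamic layer predicts a unique equilibrium ratio X* set by the
Boltzmann condition N_L/N = exp(-beta E_X).  This module supplies the two
simplest dynamics whose fixed point / stationary law is exactly that
prediction, making the re-equilibration claim (a perturbed ratio X' relaxes
back to X) a testable statement:

* ``metropolis`` — a Markov chain on the integer L-count, single-unit flips
  N_L -> N_L +/- 1 accepted with min(1, exp(-beta dF_N)), where
  F_N(N_L) = F(theta(N_L/N)) is the finite-N free energy.  Detailed balance
  makes the stationary distribution proportional to exp(-beta F_N) on the
  interior 1..N-1; the boundary all-R / all-L compositions are excluded
  (infinite-F convention), mirroring the thermodynamic exclusions.
* ``gradient_flow`` — deterministic steepest descent
  dtheta/dt = -eta dF/dtheta, converging to the closed-form theta*.

A pluggable game-theoretic fitness layer f(X) = a(X) + c s(X) (antagonistic
plus c times synergistic interactions) is provided for the evolutionarily
stable strategy account of population-level alignment: ``ess_equilibrium``
locates the fitness-maximizing ratio.  No specific a, s are shipped as
scientific claims; callers supply their own functional forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from .thermo import free_energy, free_energy_gradient

__all__ = [
    "RelaxationConfig",
    "Trajectory",
    "FitnessSpec",
    "HistogramResult",
    "DegenerateFitnessError",
    "finite_free_energy_table",
    "exact_stationary",
    "relax",
    "stationary_histogram",
    "ess_equilibrium",
]


@dataclass(frozen=True)
class RelaxationConfig:
    """Parameters of one relaxation run (seeded, hence fully reproducible)."""

    n: int
    n_left_init: int
    beta: float
    e_x: float
    n_steps: int
    seed: int
    scheme: str = "metropolis"  # or "gradient_flow"
    eta: float | None = None  # gradient-flow step; default beta/8 (see relax)

    def __post_init__(self) -> None:
        if not 0 <= self.n_left_init <= self.n:
            raise ValueError("initial N_L must lie in [0, N]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.scheme not in ("metropolis", "gradient_flow"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n < 3:
            raise ValueError("need N >= 3 so the interior 1..N-1 is nonempty")


@dataclass(frozen=True)
class Trajectory:
    """Time series of the relaxing composition, tagged with its seed."""

    steps: np.ndarray = field(repr=False)
    n_left: np.ndarray = field(repr=False)
    ratio: np.ndarray = field(repr=False)
    f_values: np.ndarray = field(repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = {len(self.steps), len(self.n_left), len(self.ratio), len(self.f_values)}
        if len(lengths) != 1:
            raise ValueError("all trajectory vectors must have equal length")


@dataclass(frozen=True)
class FitnessSpec:
    """Fitness f(X) = a(X) + c s(X) with a user-supplied pair of interactions."""

    antagonistic: Callable[[np.ndarray], np.ndarray]
    synergistic: Callable[[np.ndarray], np.ndarray]
    c: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.c):
            raise ValueError("control parameter c must be finite")

    def fitness(self, x):
        return self.antagonistic(x) + self.c * self.synergistic(x)


@dataclass(frozen=True)
class HistogramResult:
    """Post-burn-in occupancy of N_L against the exact Boltzmann law."""

    n_left_values: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)
    exact_probabilities: np.ndarray = field(repr=False)
    tv_distance: float
    n_samples: int


class DegenerateFitnessError(ValueError):
    """Raised when f(X) is flat on the domain and has no unique maximizer."""


def finite_free_energy_table(n: int, beta: float, e_x: float) -> np.ndarray:
    """F_N(N_L) = F(theta(N_L/N)) for N_L = 0..N; boundaries at +infinity.

    The infinite boundary values encode the exclusion of the all-R and all-L
    compositions from the chain's state space.
    """
    table = np.full(n + 1, np.inf)
    k = np.arange(1, n)
    theta = np.arctanh(np.sqrt(k / n))
    table[1:n] = free_energy(theta, beta, e_x)
    return table


def exact_stationary(n: int, beta: float, e_x: float) -> np.ndarray:
    """Boltzmann law pi(N_L) ~ exp(-beta F_N) on the interior 1..N-1."""
    table = finite_free_energy_table(n, beta, e_x)
    logw = -beta * table[1:n]
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _acceptance_table(n: int, beta: float, e_x: float) -> np.ndarray:
    """acc[k, d] = min(1, exp(-beta (F[k'] - F[k]))) for the move d: 0 down, 1 up."""
    table = finite_free_energy_table(n, beta, e_x)
    acc = np.zeros((n + 1, 2))
    k = np.arange(1, n)
    with np.errstate(over="ignore"):
        acc[1:n, 0] = np.minimum(1.0, np.exp(-beta * (table[k - 1] - table[k])))
        acc[1:n, 1] = np.minimum(1.0, np.exp(-beta * (table[k + 1] - table[k])))
    return acc


def _nudge_boundary(n_left: int, n: int) -> int:
    if n_left == 0 or n_left == n:
        nudged = 1 if n_left == 0 else n - 1
        warnings.warn(
            f"initial N_L = {n_left} is an excluded boundary composition; "
            f"starting the chain at N_L = {nudged}",
            stacklevel=3,
        )
        return nudged
    return n_left


def _run_chain(
    n: int,
    n_left0: int,
    acc: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    path: np.ndarray | None = None,
    counts: np.ndarray | None = None,
    burn_in: int = 0,
) -> int:
    """Single-flip Metropolis kernel; records a path and/or occupancy counts."""
    directions = rng.integers(0, 2, size=n_steps)
    uniforms = rng.random(n_steps)
    state = n_left0
    top = n - 1
    acc_list = acc.tolist()  # python floats: ~3x faster inner loop
    for i in range(n_steps):
        d = directions[i]
        proposal = state + (1 if d else -1)
        if 1 <= proposal <= top and uniforms[i] < acc_list[state][d]:
            state = proposal
        if path is not None:
            path[i + 1] = state
        if counts is not None and i >= burn_in:
            counts[state] += 1
    return state


def relax(config: RelaxationConfig) -> Trajectory:
    """Relax an initial composition toward the equilibrium ratio X*.

    Metropolis runs produce an integer N_L path whose stationary law is the
    Boltzmann distribution exp(-beta F_N); gradient-flow runs descend
    F(theta) deterministically (default step eta = beta/8, which contracts
    at rate 1/2 near the minimum since d2F/dtheta2(theta*) = 4/beta) and
    record the continuous composition N * tanh^2(theta) rounded to a count.
    Runs are bit-reproducible given (config, seed).
    """
    if config.scheme == "metropolis":
        return _relax_metropolis(config)
    return _relax_gradient(config)


def _relax_metropolis(config: RelaxationConfig) -> Trajectory:
    n, n_steps = config.n, config.n_steps
    start = _nudge_boundary(config.n_left_init, n)
    acc = _acceptance_table(n, config.beta, config.e_x)
    table = finite_free_energy_table(n, config.beta, config.e_x)
    path = np.empty(n_steps + 1, dtype=np.int64)
    path[0] = start
    rng = np.random.default_rng(config.seed)
    _run_chain(n, start, acc, n_steps, rng, path=path)
    return Trajectory(
        steps=np.arange(n_steps + 1),
        n_left=path,
        ratio=path / (n - path),
        f_values=table[path],
        seed=config.seed,
    )


def _relax_gradient(config: RelaxationConfig) -> Trajectory:
    n, beta, e_x = config.n, config.beta, config.e_x
    start = _nudge_boundary(config.n_left_init, n)
    theta = float(np.arctanh(np.sqrt(start / n)))
    eta = config.eta if config.eta is not None else beta / 8.0
    thetas = [theta]
    for _ in range(config.n_steps):
        step = eta * free_energy_gradient(theta, beta, e_x)
        step = float(np.clip(step, -0.5, 0.5))  # guard against overshoot at large theta
        theta = max(theta - step, 1e-12)
        thetas.append(theta)
        if abs(step) < 1e-14:
            break
    theta_arr = np.asarray(thetas)
    return Trajectory(
        steps=np.arange(len(thetas)),
        n_left=np.rint(n * np.tanh(theta_arr) ** 2).astype(np.int64),
        ratio=np.sinh(theta_arr) ** 2,
        f_values=free_energy(theta_arr, beta, e_x),
        seed=config.seed,
    )


def stationary_histogram(
    config: RelaxationConfig, n_samples: int, burn_in: int | None = None
) -> HistogramResult:
    """Empirical stationary law of N_L versus exact Boltzmann enumeration.

    Runs the Metropolis chain for ``burn_in + n_samples`` steps (burn-in
    defaults to max(10^4, 10 N)), histograms the post-burn-in states and
    reports the total-variation distance to the exactly enumerable
    distribution ~ exp(-beta F_N) on 1..N-1.
    """
    if config.scheme != "metropolis":
        raise ValueError("stationary_histogram requires the metropolis scheme")
    if n_samples < 10 * config.n:
        warnings.warn(
            f"n_samples = {n_samples} < 10 N; the histogram will be noisy", stacklevel=2
        )
    if burn_in is None:
        burn_in = max(10_000, 10 * config.n)
    n = config.n
    start = _nudge_boundary(config.n_left_init, n)
    acc = _acceptance_table(n, config.beta, config.e_x)
    counts = np.zeros(n + 1, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    _run_chain(n, start, acc, burn_in + n_samples, rng, counts=counts, burn_in=burn_in)
    probs = counts[1:n] / counts.sum()
    exact = exact_stationary(n, config.beta, config.e_x)
    tv = 0.5 * float(np.abs(probs - exact).sum())
    return HistogramResult(
        n_left_values=np.arange(1, n),
        probabilities=probs,
        exact_probabilities=exact,
        tv_distance=tv,
        n_samples=n_samples,
    )


def ess_equilibrium(
    spec: FitnessSpec,
    domain: tuple[float, float],
    n_grid: int = 2001,
    flat_tol: float = 1e-12,
) -> float:
    """Ratio X maximizing the fitness f(X) = a(X) + c s(X) on ``domain``.

    Grid scan followed by bounded local refinement.  A fitness that is flat
    over the whole domain has no unique evolutionarily stable ratio and
    raises ``DegenerateFitnessError``.
    """
    lo, hi = domain
    if not lo < hi:
        raise ValueError("domain must be a nonempty interval (lo, hi)")
    xs = np.linspace(lo, hi, n_grid)
    fs = np.asarray(spec.fitness(xs), dtype=float)
    if not np.all(np.isfinite(fs)):
        raise ValueError("fitness must be finite on the domain")
    if np.ptp(fs) < flat_tol * (1.0 + np.abs(fs).max()):
        raise DegenerateFitnessError("fitness is flat on the domain; no unique maximizer")
    i = int(np.argmax(fs))
    bracket = (xs[max(i - 1, 0)], xs[min(i + 1, n_grid - 1)])
    res = minimize_scalar(
        lambda x: -float(spec.fitness(x)),
        bounds=bracket,
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x) if -res.fun >= fs[i] else float(xs[i])
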