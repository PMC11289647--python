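"""Collective state of a population of N lateralized units.

The population state |ell> lives in the (N+1)-dimensional permutation
symmetric (Dicke) sector of the N-doublet product space: ell units in the
|R> state and N - ell in |L>.  The ratio X = N_L / N_R and the order
parameter M = ell - N/2 = (N_R - N_L)/2 measure the population-level
asymmetry; M != 0 breaks the R<->L exchange symmetry.

Two complementary parameterizations of the composition are used:

* integer counts (N, ell), exact at this layer;
* the angle theta with N_L/N = tanh^2(theta), N_R/N = 1/cosh^2(theta),
  hence X = sinh^2(theta).

The occupation law W_X = (N_R/N) (N_L/N)^X is then a geometric distribution
in the integer index X (number of L-draws before an R-draw), normalized to 1.

Collective ladder operators S+/-, S3 act on the Dicke sector with the usual
spin-j = N/2 matrix elements.  Rescaled by sqrt(N) at fixed M they satisfy
[S+/sqrt(N), S-/sqrt(N)] = 2 S3 / N -> (2M/N) * 1 -> 0, the contraction of
su(2) to the Euclidean algebra e(2) in which S+/- act as the commuting
"translations" N_R -> N_R +/- 1, N_L -> N_L -/+ 1.  The residual of that
limit is exposed as a windowed operator-norm diagnostic that decays as 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "PopulationState",
    "CollectiveOperators",
    "InteractionSpec",
    "InteractionEnergy",
    "make_population_state",
    "asymmetry_measure",
    "collective_operators",
    "occupation_probability",
    "occupation_distribution",
    "theta_from_fractions",
    "contraction_residual",
    "interaction_energy",
]


@dataclass(frozen=True)
class PopulationState:
    """A state in the symmetric (Dicke) sector of N two-state units.

    ``amplitudes[ell]`` is the amplitude on the basis state |ell> with
    ``ell`` units lateralized R.  ``make_population_state`` builds the pure
    |ell> configurations the model works with.
    """

    n: int
    ell: int
    amplitudes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size N must be >= 1")
        if not 0 <= self.ell <= self.n:
            raise ValueError(f"ell must lie in [0, {self.n}], got {self.ell}")
        amp = np.asarray(self.amplitudes, dtype=complex)
        if amp.shape != (self.n + 1,):
            raise ValueError("amplitudes must have length N + 1")
        if abs(np.vdot(amp, amp).real - 1.0) > 1e-10:
            raise ValueError("amplitudes are not normalized")
        object.__setattr__(self, "amplitudes", amp)

    @property
    def n_right(self) -> int:
        return self.ell

    @property
    def n_left(self) -> int:
        return self.n - self.ell

    @property
    def has_ratio(self) -> bool:
        """Whether X = N_L/N_R is defined (requires at least one R unit)."""
        return self.ell > 0

    @property
    def ratio(self) -> float:
        """X = N_L / N_R.  Undefined (raises) when N_R = 0."""
        if not self.has_ratio:
            raise ValueError("X = N_L/N_R is undefined when N_R = 0")
        return self.n_left / self.n_right

    @property
    def asymmetry(self) -> float:
        """Order parameter M = ell - N/2 = (N_R - N_L)/2."""
        return self.ell - self.n / 2


@dataclass(frozen=True)
class CollectiveOperators:
    """S+, S-, S3 on the (N+1)-dim Dicke sector, plus sqrt(N)-scaled variants."""

    n: int
    s_plus: np.ndarray = field(repr=False)
    s_minus: np.ndarray = field(repr=False)
    s_3: np.ndarray = field(repr=False)

    @property
    def s_plus_scaled(self) -> np.ndarray:
        return self.s_plus / np.sqrt(self.n)

    @property
    def s_minus_scaled(self) -> np.ndarray:
        return self.s_minus / np.sqrt(self.n)


@dataclass(frozen=True)
class InteractionSpec:
    """Environment coupling lambda (b* S- + b S+) with a classical amplitude b.

    The environment mode is represented by a c-number amplitude ``b_amp``
    rather than a quantized boson; only the coupling structure and its
    N-scaling enter the model.
    """

    lam: float
    b_amp: complex = 1.0 + 0.0j

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("coupling strength lambda must be >= 0")


class InteractionEnergy(NamedTuple):
    value: float
    coupling_scale: float


def make_population_state(n: int, ell: int) -> PopulationState:
    """The pure Dicke configuration |ell>: ell R-units, N - ell L-units.

    It is the S3 eigenstate with eigenvalue ell - N/2, equal to the
    normalized symmetrization of all C(N, ell) product arrangements.
    """
    if n < 1:
        raise ValueError("population size N must be >= 1")
    if not 0 <= ell <= n:
        raise ValueError(f"ell must lie in [0, {n}], got {ell}")
    amp = np.zeros(n + 1, dtype=complex)
    amp[ell] = 1.0
    return PopulationState(n=n, ell=ell, amplitudes=amp)


def asymmetry_measure(state: PopulationState) -> float:
    """M = <S3> = ell - N/2, cross-checked against M = (1/2) N_R (1 - X)."""
    m = state.asymmetry
    if state.has_ratio:
        alt = 0.5 * state.n_right * (1.0 - state.ratio)
        if abs(m - alt) > 1e-9 * max(1.0, abs(m)):  # pragma: no cover
            raise AssertionError("the two closed forms of M disagree")
    return m


def collective_operators(n: int) -> CollectiveOperators:
    """Dicke-sector matrices with spin j = N/2 elements.

    S+ |ell> = sqrt((N - ell)(ell + 1)) |ell + 1> and S- its transpose;
    S3 |ell> = (ell - N/2) |ell>.
    """
    if n < 1:
        raise ValueError("population size N must be >= 1")
    ell = np.arange(n)
    s_plus = np.zeros((n + 1, n + 1))
    s_plus[ell + 1, ell] = np.sqrt((n - ell) * (ell + 1.0))
    s_3 = np.diag(np.arange(n + 1) - n / 2.0)
    return CollectiveOperators(n=n, s_plus=s_plus, s_minus=s_plus.T.copy(), s_3=s_3)


def occupation_probability(theta: float, x: int) -> float:
    """W_X = (N_R/N)(N_L/N)^X = tanh^(2X)(theta) / cosh^2(theta).

    ``x`` is the integer occupation index (number of L-states drawn per
    R-state); the continuous ratio X(theta) = sinh^2(theta) is a separate
    parameterization reconciled with this one only through theta.
    """
    if x < 0 or int(x) != x:
        raise ValueError("occupation index X must be a nonnegative integer")
    t2 = np.tanh(theta) ** 2
    w = (1.0 - t2) * t2**x if x > 0 else (1.0 - t2)
    return float(w)


def occupation_distribution(theta: float, x_max: int) -> np.ndarray:
    """Vector (W_0, ..., W_{x_max}); sums to 1 geometrically as x_max grows."""
    if x_max < 0:
        raise ValueError("x_max must be >= 0")
    t2 = np.tanh(theta) ** 2
    return (1.0 - t2) * t2 ** np.arange(x_max + 1)


def theta_from_fractions(n_left: float, n: float) -> float:
    """Invert N_L/N = tanh^2(theta) for the nonnegative branch of theta.

    Boundary compositions N_L in {0, N} are rejected: they correspond to
    theta = 0 or theta = infinity, the excluded all-R / all-L equilibria.
    """
    if not 0 < n_left < n:
        raise ValueError(
            "N_L must satisfy 0 < N_L < N: the all-R and all-L compositions "
            "(theta = 0 or infinite) are excluded"
        )
    return float(np.arctanh(np.sqrt(n_left / n)))


def contraction_residual(n: int, ell: int, window: int = 11) -> float:
    """Distance from su(2) to the contracted e(2) commutation structure.

    Operator norm of [S+/sqrt(N), S-/sqrt(N)] - (2M/N) * 1 restricted to a
    ``window`` of Dicke states centred on ``ell`` (M = ell - N/2).  Since the
    exact commutator is 2 S3 / N, the residual on a fixed window is 2*half/N:
    it decays as 1/N at fixed M, the regime where the rescaled ladder
    operators become the commuting translations of e(2).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    if ell - half < 0 or ell + half > n:
        raise ValueError(
            f"window of {window} states around ell={ell} exceeds the Dicke basis 0..{n}"
        )
    ops = collective_operators(n)
    sp, sm = ops.s_plus_scaled, ops.s_minus_scaled
    comm = sp @ sm - sm @ sp
    m = ell - n / 2.0
    resid = comm - (2.0 * m / n) * np.eye(n + 1)
    sl = slice(ell - half, ell + half + 1)
    return float(np.linalg.norm(resid[sl, sl], ord=2))


def interaction_energy(
    spec: InteractionSpec, state: PopulationState, collective: bool = True
) -> InteractionEnergy:
    """Expectation of the environment coupling lambda (b* S- + b S+).

    The N-component coupling is the sum of the per-component couplings
    lambda (b* tau- + b tau+), which on the symmetric sector is exactly the
    collective form, so the expectation value is mode-independent; the
    ``collective`` flag selects the reported effective coupling scale,
    lambda*N in the strong-coupling collective regime versus lambda for a
    single component.
    """
    ops = collective_operators(state.n)
    h = spec.lam * (
        np.conj(spec.b_amp) * ops.s_minus + spec.b_amp * ops.s_plus
    )
    val = np.vdot(state.amplitudes, h @ state.amplitudes)
    if abs(val.imag) > 1e-10:  # pragma: no cover - H is Hermitian
        raise AssertionError("interaction expectation must be real")
    scale = spec.lam * (state.n if collective else 1)
    return InteractionEnergy(value=float(val.real), coupling_scale=float(scale))
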