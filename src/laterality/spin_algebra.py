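"""Exact spin-1/2 algebra for the two-component lateralized system.

A single functional unit (hemisphere, ganglion, appendage pair ...) is a
doublet ``psi = (psi_R, psi_L)`` over the two lateral states R and L, acted
on by the su(2) generators ``tau_i = sigma_i / 2``.  Two coupled units live
in the 4-dimensional product space spanned by (RR, RL, LR, LL) and decompose
into a symmetric triplet (total spin 1) and an antisymmetric singlet (total
spin 0).  Because the interaction energy must be a rotational scalar it can
only involve the invariant ``g * tau1 . tau2``, whose expectation is -3/4 on
the singlet and +1/4 on every triplet member: for g > 0 the antisymmetric
(lateralized) singlet is the unique ground state, with a gap of exactly g.

Conventions
-----------
* Doublet basis order (R, L); R is the tau_3 eigenvector with eigenvalue +1/2.
* Pair basis order (RR, RL, LR, LL).
* Global phases fixed by making the first nonzero amplitude real-positive.
* All checks use an absolute tolerance of 1e-12; everything here is exact
  linear algebra on 2x2 / 4x4 matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATOL",
    "DOUBLET_LABELS",
    "PAIR_LABELS",
    "SpinOperatorSet",
    "SpinState",
    "CoupledPairState",
    "make_operators",
    "coupled_states",
    "exchange_operator",
    "tau_dot_tau",
    "scalar_coupling_expectation",
    "energy_spectrum",
    "energy_gap",
]

ATOL = 1e-12

DOUBLET_LABELS = ("R", "L")
PAIR_LABELS = ("RR", "RL", "LR", "LL")


@dataclass(frozen=True)
class SpinOperatorSet:
    """Pauli matrices, su(2) generators and ladder operators for one doublet.

    ``tau_plus`` maps L to R and ``tau_minus`` maps R to L; they satisfy
    ``[tau_3, tau_pm] = +/- tau_pm`` and ``tau_plus = tau_minus^dagger``.
    """

    sigma_1: np.ndarray
    sigma_2: np.ndarray
    sigma_3: np.ndarray
    tau_1: np.ndarray = field(init=False)
    tau_2: np.ndarray = field(init=False)
    tau_3: np.ndarray = field(init=False)
    tau_plus: np.ndarray = field(init=False)
    tau_minus: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau_1", self.sigma_1 / 2)
        object.__setattr__(self, "tau_2", self.sigma_2 / 2)
        object.__setattr__(self, "tau_3", self.sigma_3 / 2)
        object.__setattr__(self, "tau_plus", self.tau_1 + 1j * self.tau_2)
        object.__setattr__(self, "tau_minus", self.tau_1 - 1j * self.tau_2)

    @property
    def taus(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.tau_1, self.tau_2, self.tau_3)

    def pair_total(self, i: int) -> np.ndarray:
        """Total generator tau_i x 1 + 1 x tau_i on the pair space."""
        t = self.taus[i]
        eye = np.eye(2)
        return np.kron(t, eye) + np.kron(eye, t)


@dataclass(frozen=True)
class SpinState:
    """Normalized complex amplitude vector over a labelled basis."""

    amplitudes: np.ndarray
    basis_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=complex)
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "basis_labels", tuple(self.basis_labels))
        if amp.ndim != 1 or len(self.basis_labels) != amp.size:
            raise ValueError("basis_labels length must equal amplitude vector length")
        if abs(np.vdot(amp, amp).real - 1.0) > 1e-10:
            raise ValueError("state amplitudes are not normalized")

    @property
    def dim(self) -> int:
        return self.amplitudes.size


@dataclass(frozen=True)
class CoupledPairState:
    """One of the four coupled two-unit states with its quantum labels."""

    state: SpinState
    s_tot: int
    s3_tot: int
    symmetry: str  # "symmetric" (triplet) or "antisymmetric" (singlet)

    def __post_init__(self) -> None:
        if self.symmetry not in ("symmetric", "antisymmetric"):
            raise ValueError(f"unknown symmetry tag {self.symmetry!r}")
        if (self.symmetry == "antisymmetric") != (self.s_tot == 0):
            raise ValueError("antisymmetric iff s_tot == 0")

    @property
    def label(self) -> str:
        if self.s_tot == 0:
            return "singlet"
        return f"triplet_{self.s3_tot:+d}" if self.s3_tot else "triplet_0"


def make_operators() -> SpinOperatorSet:
    """Pauli matrices in the (R, L) basis and the derived tau operators."""
    sigma_1 = np.array([[0, 1], [1, 0]], dtype=complex)
    sigma_2 = np.array([[0, -1j], [1j, 0]], dtype=complex)
    sigma_3 = np.array([[1, 0], [0, -1]], dtype=complex)
    return SpinOperatorSet(sigma_1, sigma_2, sigma_3)


def _fix_phase(amp: np.ndarray) -> np.ndarray:
    """Rotate a global phase so the first nonzero amplitude is real-positive."""
    idx = np.flatnonzero(np.abs(amp) > ATOL)
    if idx.size == 0:
        return amp
    lead = amp[idx[0]]
    return amp * (abs(lead) / lead)


def coupled_states() -> list[CoupledPairState]:
    """The three triplet states and the singlet on the (RR, RL, LR, LL) basis.

    Returns four normalized, mutually orthogonal states ordered as
    triplet s3=+1, 0, -1, then the singlet.  The mixed states carry the
    1/sqrt(2) normalization.
    """
    r2 = 1.0 / np.sqrt(2.0)
    specs = [
        (np.array([1, 0, 0, 0], dtype=complex), 1, +1, "symmetric"),
        (np.array([0, r2, r2, 0], dtype=complex), 1, 0, "symmetric"),
        (np.array([0, 0, 0, 1], dtype=complex), 1, -1, "symmetric"),
        (np.array([0, r2, -r2, 0], dtype=complex), 0, 0, "antisymmetric"),
    ]
    return [
        CoupledPairState(SpinState(_fix_phase(a), PAIR_LABELS), s, s3, sym)
        for a, s, s3, sym in specs
    ]


def exchange_operator() -> np.ndarray:
    """The R<->L particle-exchange (swap) operator on the pair basis."""
    p = np.zeros((4, 4))
    p[0, 0] = p[3, 3] = 1.0  # RR, LL fixed
    p[1, 2] = p[2, 1] = 1.0  # RL <-> LR
    return p


def tau_dot_tau() -> np.ndarray:
    """The scalar invariant tau1 . tau2 = sum_i (tau_i x 1)(1 x tau_i) as a 4x4 matrix."""
    ops = make_operators()
    eye = np.eye(2)
    out = np.zeros((4, 4), dtype=complex)
    for t in ops.taus:
        out += np.kron(t, eye) @ np.kron(eye, t)
    return out


def scalar_coupling_expectation(state: CoupledPairState | SpinState) -> float:
    """Expectation of the rotational scalar tau1 . tau2 in a pair state.

    Evaluates to exactly -3/4 on the singlet and +1/4 on each triplet
    member.  Raises ``ValueError`` if the state is not normalized or not
    4-dimensional.
    """
    psi = state.state if isinstance(state, CoupledPairState) else state
    amp = psi.amplitudes
    if amp.size != 4:
        raise ValueError("scalar coupling is defined on the 4-dim pair space")
    norm = np.vdot(amp, amp).real
    if abs(norm - 1.0) > 1e-10:
        raise ValueError(f"state is not normalized (|psi|^2 = {norm})")
    # dividing by the computed norm cancels the rounding of 1/sqrt(2)
    # amplitudes, so the four coupled states evaluate to exact -3/4 / +1/4
    val = np.vdot(amp, tau_dot_tau() @ amp) / norm
    if abs(val.imag) > ATOL:  # pragma: no cover - Hermitian operator
        raise ValueError("expectation of a Hermitian operator must be real")
    return float(val.real)


def energy_spectrum(g: float = 1.0) -> dict[str, float]:
    """Energies E = g <tau1 . tau2> of the four coupled states.

    For g > 0 the singlet is the unique minimum and the triplet-singlet gap
    equals g (so exactly 1 in the dimensionless default).
    """
    if g <= 0:
        raise ValueError("coupling g must be positive (singlet ground-state convention)")
    return {cs.label: g * scalar_coupling_expectation(cs) for cs in coupled_states()}


def energy_gap(g: float = 1.0) -> float:
    """Triplet minus singlet energy: g * (1/4 - (-3/4)) = g."""
    spectrum = energy_spectrum(g)
    triplet = spectrum["triplet_+1"]
    return triplet - spectrum["singlet"]
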