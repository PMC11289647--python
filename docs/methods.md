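# Methods

## Model

The package implements a two-layer model of lateralization in dimensionless
units (k_B = 1, energies in units of the pair coupling).

**Pair energetics.** A lateral functional unit is a doublet over (R, L) with
R the +1/2 eigenvector of τ₃; the pair basis is ordered (RR, RL, LR, LL).
Because the interaction energy must be invariant under the su(2) rotations
generated by the τ_i, it can depend on the two units only through the scalar
g τ̄₁·τ̄₂. On the four coupled states this operator is diagonal with
eigenvalue (s(s+1) − 3/2)/2: −3/4 on the antisymmetric singlet and +1/4 on
the symmetric triplet. The sign convention g > 0 makes the singlet the
ground state, so pair-level asymmetry is energetically forced rather than
statistical; the gap is exactly g. The expectation is computed as a
quadratic form divided by the state's own squared norm, which cancels the
rounding of the 1/√2 amplitudes and returns the eigenvalues exactly in
floating point.

**Population layer.** The collective state of N units with ℓ in R is
represented in the (N+1)-dimensional permutation-symmetric (Dicke) sector,
not the 2^N product space: the model only ever occupies symmetric
superpositions, and the reduced representation is exact for N in the
thousands. The full product space survives solely as a brute-force test
oracle (N ≤ 10), where the symmetric states are built explicitly from
itertools combinations and the collective ladder operators as sums of
single-unit flips. Counts are exact integers at this layer; the continuous
description enters only through θ with N_L/N = tanh²θ.

The occupation index X in W_X = (N_R/N)(N_L/N)^X is treated as a
nonnegative integer (number of L-draws per R-draw), making W a normalized
geometric law; the continuous ratio X(θ) = sinh²θ is a separate
parameterization of the same composition. The two readings are reconciled
only through θ and never silently unified. A consequence worth recording:
the Shannon entropy −Σ_X W_X ln W_X of the geometric law equals the closed
form S(θ) = −(sinh²θ ln sinh²θ − cosh²θ ln cosh²θ) exactly (substitute
1 − u = 1/cosh²θ, u/(1−u) = sinh²θ), so the per-configuration surprisal and
the average entropy agree identically; `entropy_from_occupations` reports
the truncated-sum discrepancy, which sits at rounding level (~1e-11).

**Contraction diagnostic.** The exact commutator [S₊/√N, S₋/√N] = 2S₃/N,
restricted to a window of Dicke states centred on ℓ (default width 11,
configurable), differs from the c-number 2M/N by an operator of norm
2·(window half-width)/N. The diagnostic therefore decays exactly as 1/N at
fixed M — the su(2) → e(2) contraction in which the rescaled ladder
operators become commuting translations N_R → N_R ± 1 while [S₃, S±] = ±S±
is untouched (e(2) keeps three parameters, like su(2)). The environment
coupling λ(b†S₋ + bS₊) treats b as a classical complex amplitude; no mode
dynamics are modelled, only the coupling structure and its λ → λN collective
enhancement, which the matrix elements of S₊ + S₋ near the equatorial Dicke
states exhibit directly (max element ≈ N/2).

## Thermodynamics

F(θ) = sinh²θ·E_X − S(θ)/β. β and E_X enter every observable only through
the product βE_X; both are exposed for readability. E_X is implemented as a
constant configuration-energy scale, independent of X — any X-dependence
would alter the stationarity condition, and none is modelled. The θ = 0
logarithms are handled by the analytic limit x ln x → 0 (scipy's `xlogy`),
never by epsilon-shifting. Stationarity is solved in closed form,
θ* = artanh(e^{−βE_X/2}), and cross-validated at every call against a
Brent root of the gradient on the substitution v = ln tanh²θ, which stays
well-conditioned at large βE_X where tanh²θ* underflows toward 0. Products
βE_X ≤ 0 or infinite are rejected: they correspond to the excluded all-L
(T → ∞) and all-R (T → 0) compositions. d²F/dθ² = 4/β at θ*, so every
admissible equilibrium is a minimum.

## Dynamics

No explicit equation of motion is prescribed by the theory, so the package
supplies the minimal dynamics whose long-run behaviour is exactly the
thermodynamic prediction, making the re-equilibration claim falsifiable:

* **Metropolis.** Single-unit flips N_L → N_L ± 1 accepted with
  min(1, e^{−βΔF_N}), F_N(N_L) = F(θ(N_L/N)). The boundary states
  N_L ∈ {0, N} carry infinite F (excluded equilibria); a boundary start is
  nudged inward with a warning. The kernel satisfies detailed balance, so
  the stationary law is ∝ e^{−βF_N} on 1..N−1 and can be enumerated exactly
  for comparison (total-variation distance is reported). Note that F_N is
  intensive, so the stationary law is broad: the *mode* sits at the
  free-energy minimum while time averages of X carry O(1) spread at
  moderate β.
* **Gradient flow.** dθ/dt = −η dF/dθ, explicit Euler with default step
  η = β/8, which contracts at rate 1/2 near the minimum (curvature 4/β);
  steps are clamped to |Δθ| ≤ 0.5 against overshoot at large θ and θ is
  floored at 1e−12. Converges to θ* to well below 1e−8 from any interior
  start.

One RNG (`numpy.random.default_rng`) per run, seeded from the config;
trajectories carry their seed and identical configs reproduce bit-identical
output.

**Fitness layer.** f(X) = a(X) + c·s(X) with caller-supplied antagonistic
and synergistic terms; no functional forms are shipped as scientific claims
— the built-in "quadratic" family and the test quadratics are worked toys.
The maximizer is located by a 2001-point grid scan plus bounded refinement
(xatol 1e−10); a fitness flat over the domain raises a degenerate-equilibrium
error rather than returning an arbitrary point.

## Test design and problem sizes

Stochastic checks run at sizes where the chain genuinely equilibrates while
keeping the default suite fast: the stationary-histogram comparison uses
N = 50 with 2×10⁶ post-burn-in samples (observed TV ≈ 0.006 against exact
enumeration, asserted < 0.05), and start-independence of the time-averaged
ratio uses N = 50, two starts (N_L = 5 vs 45) × 3 seeds with 3×10⁵ steps
each; at this size the ±1 walk's O(N²) mixing time is a small fraction of
the run, so the overlap criterion tests convergence rather than
autocorrelated noise. The brute-force product-space oracle stops at N = 10
(2¹⁰ amplitudes), the contraction scaling uses N ∈ {20, 40, 80, 160}, and
perturbations are modelled as instantaneous displacements of N_L followed by
free relaxation — no richer perturbation process is specified by the model.

## What passing tests do and do not show

All inputs are model parameters; there is no empirical dataset, and the
generator-free fixtures emulate nothing about measurement noise, finite
sampling of real populations, or biological heterogeneity between units.
Passing tests certify the internal mathematics — exact pair spectra,
operator algebra, closed-form equilibria, convergence of the dynamics to
them — not the biological adequacy of a two-state unit or of a single
scalar coupling. Known limitations: the environment mode is classical (no
dissipative open-system evolution), spin > 1/2 units and more than two
coupled units at the pair level are out of scope, finite-size corrections to
the thermodynamic limit are not modelled, and the Metropolis scheme is one
of many dynamics compatible with the same stationary law.
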