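"""Free-energy minimization fixes the equilibrium L/R ratio.

With N_L/N = tanh^2(theta), the free energy F = X E_X - S/beta is stationary
where ln tanh^2(theta) = -beta E_X, i.e. the minority fraction follows the
Boltzmann factor N_L/N = exp(-beta E_X).  The balanced population (X = 1)
occurs exactly at beta E_X = ln 2; any other value of beta E_X yields an
asymmetric but nonzero split.
"""

import numpy as np

from laterality import entropy, stationarity_solve, temperature_from_ratio

for be in (np.log(2), 1.0, 2.0, 5.0):
    p = stationarity_solve(beta=1.0, e_x=be)
    print(
        f"beta*E_X = {be:.4f}:  theta* = {p.theta:.4f}  N_L/N = {p.a:.5f}  "
        f"X* = {p.ratio:.5f}  S = {entropy(p.theta):.4f}  F = {p.free_energy:+.4f}"
    )

t = temperature_from_ratio(1.0, 1.0)
print(f"\nobserved X = 1 with E_X = 1 implies temperature T = {t:.4f} (= 1/ln 2)")
print("=> equilibrium composition is the Boltzmann distribution over L-states.")
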