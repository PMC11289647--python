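"""Evolutionarily stable ratio from a fitness trade-off f(X) = a(X) + c s(X).

The game-theoretic account of population-level alignment balances an
antagonistic (competitive) term a(X) against a synergistic (cooperative)
term s(X) weighted by a control parameter c.  With toy quadratics peaked at
X = 1 and X = 3, the stable ratio (1 + 3c)/(1 + c) slides from 1 to 3 as
cooperation strengthens: the equilibrium is set by c.
"""

from laterality import FitnessSpec, ess_equilibrium

for c in (0.0, 0.5, 1.0, 2.0, 5.0):
    spec = FitnessSpec(
        antagonistic=lambda x: -((x - 1.0) ** 2),
        synergistic=lambda x: -((x - 3.0) ** 2),
        c=c,
    )
    x_star = ess_equilibrium(spec, (0.0, 10.0))
    print(f"c = {c:3.1f}: stable ratio X* = {x_star:.4f}")
print("=> stronger cooperative pressure shifts the stable L/R ratio.")
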