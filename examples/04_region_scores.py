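"""Region-partitioned von Mises stress percentages.

After a balanced-standing solve, the plantar surface (8 areas on the
ground), the talar trochlea (9 equal-count sets) and the subtalar joint
(3 facets; posterior facet in 4 equal quadrants) are scored: each region's
value is its share of the summed element von Mises stress, in percent.
"""

from pedfem import (FootParams, SolverOptions, build_load_case,
                    generate_foot, solve_equilibrium)
from pedfem.pipeline import score_model

model = generate_foot(FootParams(seed=1, severity=0.7))
lc = build_load_case(model.params.body_weight, model)
result = solve_equilibrium(model, lc, SolverOptions(rtol=1e-3, increments=3))
scores = score_model(model, result)

plantar = scores["plantar"].per_region
print("plantar areas (% of total):")
print("  " + "  ".join(f"{k}:{v:5.2f}" for k, v in sorted(plantar.items())))
print(f"  sum = {sum(plantar.values()):.6f}")
print("talocrural groups:", {k: round(v, 1) for k, v in
                             scores["talocrural"].per_group.items()})
print("posterior subtalar quadrants:",
      {k: round(v, 1) for k, v in scores["post_subtalar"].per_group.items()})
# Area 8 (the heel) dominates in quiet stance; each grouping axis
# (medial+middle+lateral, anterior+middle+posterior) sums to 100.
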