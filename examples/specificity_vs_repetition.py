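"""Specificity p versus repetitions k: reaching a goal at minimum energy.

An organism can recognise a target with a highly specific code (one costly
attempt, like an enzyme's substrate choice) or spray cheap low-specificity
attempts (antibody repertoires, seed dispersal). Both reach the same overall
success probability 1 − (1 − p)^k; the planner picks the cheaper route.
"""

from oildrop import PKQuery, min_repetitions, optimize

print("repetitions needed for 95% overall success:")
for p in (0.1, 0.3, 0.5, 0.9):
    print(f"  p = {p:.1f} -> k = {min_repetitions(p, 0.95)}")

grid = [0.1, 0.3, 0.5, 0.7, 0.9]
for base, spec, label in [
    (5.0, 0.1, "attempts expensive, coding cheap"),
    (0.1, 5.0, "coding expensive, attempts cheap"),
]:
    plan = optimize(PKQuery(p_grid=grid, target_success=0.95,
                            base_cost=base, specificity_cost=spec))
    print(f"{label}: p = {plan.p}, k = {plan.k}, "
          f"achieved = {plan.achieved:.3f}, energy = {plan.energy:.2f}")
print()
print("When each attempt is expensive the planner buys specificity; when")
print("coding is expensive it mass-repeats a low-specificity attempt — the")
print("energy column is k · (base_cost + specificity_cost · bits of coding).")
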