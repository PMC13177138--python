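"""Threshold-inhibition oscillation and disturbance propagation.

Simulates the default single negative-feedback loop (enzyme + receptor with
a delayed inhibition signal), measures its oscillation, checks it against a
"clinical" normal range, then couples two loops through the effector channel
and doubles the upstream production rate to watch the disturbance propagate.
"""

from oildrop import check_range, gen_loop_fixture, measure_oscillation, simulate
from oildrop.feedback import disturbance_experiment

traj = simulate(gen_loop_fixture(1), steps=500)
s = measure_oscillation(traj, "loop1", burn_in=100)
ok = check_range(s, low=0.0, high=10.0)
print(f"single loop: period = {s.period:.1f} steps, amplitude = {s.amplitude:.2f},")
print(f"  concentration stays in [{s.min:.2f}, {s.max:.2f}]; "
      f"within normal range [0, 10]: {ok}")

pairs = disturbance_experiment(
    gen_loop_fixture(2, "effector"), loop="loop1",
    parameter="effector_rate", factor=2.0, steps=500,
)
base, dist = pairs["loop2"]
print(f"two coupled loops, upstream rate doubled:")
print(f"  downstream frequency {base.frequency:.4f} -> {dist.frequency:.4f}")
print()
print("The delayed inhibition turns each loop into a relaxation oscillator;")
print("product concentration cycles around the receptor sensitivity. Leaving")
print("the stated normal range would flag pathology. Speeding up the upstream")
print("effector raises the downstream loop's oscillation frequency.")
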