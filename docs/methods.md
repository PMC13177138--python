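# Methods

## Micelle-likeness analysis

### Model

A chain is reduced to one *effective atom* per residue: the arithmetic mean
of its side-chain heavy atoms, falling back to Cα for glycine or truncated
side chains (a warning is logged rather than an error raised, so partially
modelled structures remain analysable). Intrinsic hydrophobicity H_r comes
from a named residue scale rescaled linearly so the scale's extremes map to
0 and 1; Kyte–Doolittle is the shipped default, and the scale is a
swappable input whose name is recorded in every result. No claim is made
that any particular server's internal scale is reproduced — results are
comparable *within* a scale choice.

The point set is centred and rotated onto its covariance principal axes
(largest variance on x, proper rotation; the per-axis sign ambiguity is
irrelevant because everything downstream depends on squared coordinates).
The Gaussian width per axis is σ = (max |coordinate|)/3, placing the
molecular surface at the 3σ shell where the ideal density effectively
vanishes. The theoretical profile T is the normalized product-of-exponentials
density at each effective atom.

The observed profile O sums (H_i + H_j)·g(r_ij/c) over pairs within the
cutoff c (default 9 Å, a conventional hydrophobic-interaction range), with
the polynomial decay g(u) = 1 − ½(7u² − 9u⁴ + 5u⁶ − u⁸), g(0) = 1,
g(1) = 0. The self term j = i is excluded. A structure with no interacting
pair anywhere is rejected rather than silently normalized.

RD = D(O‖T) / (D(O‖T) + D(O‖R)) with R uniform and divergences in log base
2. The degenerate 0/0 case returns 0. Before any D(O‖·) the reference is
floored at 1e-12 so exact zeros produced by g(1) = 0 or by M-clipping
cannot create spurious infinities; the floor is far below any profile value
that matters at realistic chain lengths.

The inverted profile is TM ∝ max(T) − T and the environment-modified
target is the linear mix M(K) ∝ T + K·(TM − T), clipped at 0 and
renormalized. K = 0 reproduces T exactly and K = 1 reproduces TM. K is
fitted by scanning 0…2 in steps of 0.01 and refining one pass at 0.001
around the optimum, ties toward smaller K; K is unbounded in principle and
a wider grid can be passed explicitly.

Residue flags compare O and T relative to the chain's own largest
deviation: residue i is *deficit* if T_i − O_i > τ and *excess* if
O_i − T_i > τ with τ = threshold_fraction · max|O − T|
(threshold_fraction default 0.5). The relative criterion makes the flags
scale-free; there is no published numeric flagging rule to match, so the
fraction is an explicit, recorded parameter.

### Numerical properties worth knowing

* RD and the fitted K are invariant under rigid motion of the input (the
  orientation step absorbs it); verified to 1e-9.
* Mixing the observed profile toward the target, O(λ) = (1−λ)O + λT,
  monotonically shrinks the numerator divergence D(O(λ)‖T), but **RD
  itself is not monotone along that path**: the mixture can pass closer to
  the uniform reference, shrinking the denominator faster. Measured on
  random profile pairs the interior rise can reach ≈ 0.03. Tests therefore
  assert the numerator's monotonicity and the RD endpoints, not ratio
  monotonicity.
* K recovery: when O is constructed as M(K*), the fit returns K* to within
  the 0.001 refinement step for K* up to 1.5 (beyond K = 1 the clipping
  makes M progressively less sensitive to K, but recovery still holds on
  the default grid).

## Synthetic structures

The generator samples n points (default 200) from a centred anisotropic
Gaussian with σ = (3.5, 2.8, 2.2) Å and assigns hydrophobicity from the
Gaussian density at each point, min–max rescaled — ground truth that is
independent of any residue scale. The axis widths are deliberately
well-separated (unambiguous principal axes) and the cloud deliberately
dense relative to the 9 Å contact cutoff, so the contact-aggregated
observed profile is a low-noise readout of the planted field: the ideal
mode scores RD ≈ 0.05–0.13 across seeds, the inverted mode RD ≈ 0.7, and
planted outliers (h → 1 − h at randomly chosen positions) raise RD
measurably. These fixtures make no claim of physical realism — no bond
lengths, no excluded volume, and a packing density higher than a real
globular protein; they exist to give every engine a known answer.

A caveat that passing tests on these fixtures does *not* establish: RD
sensitivity to a **single** discordant residue. One flip among 200 residues
perturbs the aggregated O profile below its sampling-noise floor and the
resulting RD shift is sign-indefinite; the planted-outlier separation is
asserted at 10 outliers, where the effect dominates noise, and the
eliminate-and-recompute demonstration uses the generator defaults.

Fixtures can be written as minimal poly-alanine PDB files (CA and CB at the
effective point) to exercise the full file-reading path; note that
re-reading assigns hydrophobicity from the residue scale (constant for
poly-ALA), not from the planted field, so round-tripped fixtures test I/O,
not ground-truth recovery.

## Feedback-loop simulator

The update is discrete-time and synchronous. Per step t each loop computes
its effective rate v′ and sensitivity S′ by multiplying the base values by
(1 + gain · C_src/S_src) for every incoming coupling on the matching
channel (effector → rate, receptor → sensitivity); the source concentration
is normalized by the source's own sensitivity so gains are dimensionless,
which is why coupling sources must have S > 0. Activity is then
A(t) = 0 iff the loop's own concentration *delay* steps earlier strictly
exceeded S′ (boundary equality keeps the effector active); before any
history exists the `initial_active` flag decides. Finally
C(t+1) = C(t) + v′·A(t) − decay·C(t), floored at 0. The recorded series is
the state *before* each update, so an uninhibited unit-rate loop reads
exactly 0, 1, 2, ….

The defaults v = 1.0, decay = 0.1, S = 5.0, delay = 3, C0 = 0 give a
sustained relaxation oscillation with period 12 steps and amplitude ≈ 1.5;
with decay > 0 the concentration is bounded by v′_max/decay. The model is
deterministic — the seed argument is recorded for provenance and reserved
for future noise terms. The loop count is capped at three by default
(`allow_large=True` lifts it). This is one explicit realization of a
verbal threshold-inhibition description; no numeric identity with any
external simulator is claimed.

Oscillations are summarised over a post-burn-in window (default 100 steps)
as min/max/amplitude plus the mean interval between successive upward
crossings of the window mean; fewer than two crossings reports period NaN
and frequency 0. Range checking is inclusive on both bounds.

## (p, k) planner

All attempts are independent and identically distributed. `min_repetitions`
uses the closed form ⌈log(1−target)/log(1−p)⌉ and then verifies by direct
evaluation at k and k−1, which removes floating-point boundary errors. The
energy model E = k·(base + spec·b(p)) with b(p) = −log₂(1−p) is a declared
minimal stand-in for an unspecified cost functional: it is linear in both
resources and isolated in one function (`plan_energy`) so a different
functional can be swapped in without touching the optimizer. p = 1 is
rejected there (infinite coding burden under this model). The optimizer
enumerates the p grid, takes the minimal feasible k for each, and breaks
energy ties toward smaller k, then smaller p.

## CLI and reproducibility

Each CLI run writes its data outputs (CSV at 6 significant digits, JSON at
full precision) plus a `manifest.json` with the command, parameters, input
SHA-256 checksums, tool version and a wall-clock timestamp. Re-running
with identical inputs reproduces the data outputs byte for byte; the
manifest differs only in its timestamp. Errors surface as one-line
diagnostics with non-zero exit codes, never tracebacks.

## Problem sizes

Default test and demonstration sizes — 200-residue synthetic structures,
500-step simulations, p grids of a handful of points — were chosen as the
smallest sizes at which every claimed effect is comfortably measurable;
the analysis itself is O(n²) in residues and linear in simulation steps,
and handles ordinary protein chains and much longer runs directly.

## Known limitations

* Single chains only; no complexes, nucleic acids, ligands or structure
  repair. Multi-conformer files use altloc blank/"A" only.
* The intrinsic hydrophobicity scale is an input, not a discovery: RD and
  K values are comparable within a scale, not across scales.
* The feedback model is a discrete abstraction — no continuous-time
  kinetics, no stochasticity, no mechanistic allosteric detail beyond the
  threshold switch.
* The (p, k) energy model is a stated convention, not an estimate of any
  biological energy budget; correlated attempts are out of scope.
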