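"""How micelle-like is a protein's hydrophobicity distribution?

Builds three synthetic 200-residue structures with known ground truth —
an ideal micelle-like core, its inverted (surface-hydrophobic) counterpart,
and an ideal core with 10 planted discordant residues — runs the full
analysis on each, and shows the eliminate-and-recompute step that removes
the planted residues.
"""

from oildrop import (
    SyntheticStructureSpec,
    analyze,
    eliminate_and_recompute,
    gen_structure,
    planted_outliers,
)

for mode, kwargs in [
    ("ideal_micelle", {}),
    ("inverted", {}),
    ("planted_outliers", {"n_outliers": 10}),
]:
    spec = SyntheticStructureSpec(n=200, mode=mode, seed=0, **kwargs)
    model = gen_structure(spec)
    result = analyze(model)
    n_flag = sum(s != "accordant" for s in result.status)
    print(f"{mode:>18}: RD = {result.rd:.3f}  K = {result.k_fit:.3f}  "
          f"flagged residues = {n_flag}")
    if mode == "planted_outliers":
        redo = eliminate_and_recompute(model, planted_outliers(spec))
        print(f"{'after elimination':>18}: RD = {redo.rd:.3f}  "
              f"K = {redo.k_fit:.3f}  (removed {len(redo.eliminated)} residues)")

print()
print("RD = 0 would be a perfect micelle-like hydrophobic core; values near 1")
print("match the unordered uniform reference. K > 0 means the observed")
print("distribution is best explained by a target tilted toward a non-aqueous")
print("(membrane-like) environment. Removing the planted discordant residues")
print("moves RD back toward the ideal-core value.")
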