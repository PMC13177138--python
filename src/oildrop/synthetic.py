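"""Ground-truth fixtures: synthetic structures and feedback-loop networks.

The structure generator samples residue effective points from a centred
anisotropic 3D Gaussian and assigns intrinsic hydrophobicity directly from
the Gaussian density at each point, so the micelle-like ideal (high
hydrophobicity in the core, none at the surface) holds by construction and
independently of any residue scale. Three modes:

* ``ideal_micelle`` — hydrophobicity proportional to the density (low RD);
* ``inverted`` — hydrophobicity proportional to the inverted field, the
  surface-hydrophobic arrangement a membrane environment would favour;
* ``planted_outliers`` — ideal_micelle with ``n_outliers`` residues flipped
  to the opposite extreme (h → 1 − h), giving known discordant positions.

Fixtures can be emitted as minimal poly-alanine PDB files (effective point
written as both CA and CB) so the full file-reading path is exercisable
end to end without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import InputError
from .feedback import DEFAULT_LOOP, CouplingSpec, LoopSpec, SystemSpec
from .structure import ResidueRecord, StructureModel

__all__ = [
    "SyntheticStructureSpec", "gen_structure", "planted_outliers",
    "write_pdb", "gen_loop_fixture",
]

MODES = ("ideal_micelle", "inverted", "planted_outliers")

# Well-separated axis widths (unambiguous principal axes) and a point cloud
# dense relative to the 9 Å contact cutoff, so the contact-aggregated
# observed profile is a low-noise readout of the planted field.
DEFAULT_SIGMA = (3.5, 2.8, 2.2)


@dataclass
class SyntheticStructureSpec:
    """Recipe for one synthetic structure with known ground truth."""

    n: int = 200
    sigma: tuple[float, float, float] = DEFAULT_SIGMA
    mode: str = "ideal_micelle"
    n_outliers: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 3:
            raise InputError("n must be >= 3")
        if len(self.sigma) != 3 or any(s <= 0 for s in self.sigma):
            raise InputError("sigma must be three positive values")
        if self.mode not in MODES:
            raise InputError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 <= self.n_outliers < self.n:
            raise InputError("n_outliers must satisfy 0 <= n_outliers < n")


def _sample(spec: SyntheticStructureSpec):
    """Draw points, hydrophobicities and outlier positions for a spec."""
    rng = np.random.default_rng(spec.seed)
    sigma = np.asarray(spec.sigma, dtype=float)
    pts = rng.normal(0.0, sigma, size=(spec.n, 3))
    density = np.exp(-0.5 * np.sum((pts / sigma) ** 2, axis=1))
    lo, hi = density.min(), density.max()
    if hi == lo:  # pathological tiny-n draw; nudge to avoid a constant field
        h = np.full(spec.n, 0.5)
    else:
        h = (density - lo) / (hi - lo)
    idx = np.array([], dtype=int)
    if spec.mode == "inverted":
        h = 1.0 - h
    elif spec.mode == "planted_outliers":
        idx = np.sort(rng.choice(spec.n, size=spec.n_outliers, replace=False))
        h = h.copy()
        h[idx] = 1.0 - h[idx]
    return pts, h, idx


def planted_outliers(spec: SyntheticStructureSpec) -> list[int]:
    """Ground-truth 0-based positions flipped in ``planted_outliers`` mode."""
    spec.validate()
    return _sample(spec)[2].tolist()


def gen_structure(spec: SyntheticStructureSpec) -> StructureModel:
    """Sample a structure model from the spec; deterministic given (spec, seed)."""
    spec.validate()
    pts, h, _ = _sample(spec)

    residues = [
        ResidueRecord(
            chain_id="A",
            residue_index=i + 1,
            residue_name="ALA",
            effective_point=pts[i],
            intrinsic_h=float(h[i]),
        )
        for i in range(spec.n)
    ]
    return StructureModel(
        residues=residues,
        source_id=f"synthetic:{spec.mode}:n={spec.n}:seed={spec.seed}",
        scale_name="synthetic-gaussian",
    )


def write_pdb(model: StructureModel, path: str) -> None:
    """Write a model as a minimal poly-alanine PDB file.

    Each residue becomes an ALA with CA and CB placed at the effective
    point; the B-factor column carries the intrinsic hydrophobicity scaled
    by 100 (informational only — re-reading assigns hydrophobicity from the
    residue scale, not from B-factors).
    """
    st = gemmi.Structure()
    st.name = "synthetic"
    gm = gemmi.Model("1")
    chain = gemmi.Chain(model.residues[0].chain_id if model.residues else "A")
    for rec in model.residues:
        res = gemmi.Residue()
        res.name = rec.residue_name
        res.seqid = gemmi.SeqId(rec.residue_index, rec.icode or " ")
        for atom_name, element in (("CA", "C"), ("CB", "C")):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*rec.effective_point)
            atom.occ = 1.0
            atom.b_iso = round(100.0 * rec.intrinsic_h, 2)
            res.add_atom(atom)
        chain.add_residue(res)
    gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def gen_loop_fixture(n_loops: int, coupling_mode: str = "none") -> SystemSpec:
    """Default loops chained with unit-gain couplings in the requested mode.

    ``coupling_mode`` is "effector", "receptor" or "none"; loops are named
    loop1..loopN and coupled in a chain loop1→loop2→…
    """
    if not 1 <= n_loops <= 3:
        raise InputError("n_loops must be between 1 and 3")
    if coupling_mode not in ("effector", "receptor", "none"):
        raise InputError(f"unknown coupling_mode {coupling_mode!r}")
    loops = [LoopSpec(name=f"loop{i + 1}", **DEFAULT_LOOP) for i in range(n_loops)]
    couplings = []
    if coupling_mode != "none":
        couplings = [
            CouplingSpec(
                source=f"loop{i + 1}", target=f"loop{i + 2}",
                mode=coupling_mode, gain=1.0,
            )
            for i in range(n_loops - 1)
        ]
    spec = SystemSpec(loops=loops, couplings=couplings)
    spec.validate()
    return spec
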