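"""Protein structure input: per-residue effective atoms and intrinsic hydrophobicity.

A protein chain is reduced to one point per residue (the geometric centre of
its side-chain heavy atoms, Cα for glycine) plus an intrinsic hydrophobicity
value Hr taken from a named residue scale rescaled linearly to [0, 1]. The
reduced representation is what the micelle-likeness engine consumes.

PDB and mmCIF files are read through gemmi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

# Kyte & Doolittle residue hydropathy values (raw, before rescaling).
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

SCALES: dict[str, dict[str, float]] = {"kyte-doolittle": KYTE_DOOLITTLE}

DEFAULT_SCALE = "kyte-doolittle"

# Backbone atoms excluded from the side-chain centroid.
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class ResidueRecord:
    """One residue reduced to an effective point and its hydrophobicity.

    ``residue_index`` keeps the author numbering as read from the file;
    ``icode`` carries the insertion code so the pair stays a unique identity.
    """

    chain_id: str
    residue_index: int
    residue_name: str
    effective_point: np.ndarray
    intrinsic_h: float
    icode: str = ""

    def __post_init__(self) -> None:
        pt = np.asarray(self.effective_point, dtype=float)
        if pt.shape != (3,) or not np.all(np.isfinite(pt)):
            raise InputError(f"effective_point must be a finite 3-vector, got {pt!r}")
        object.__setattr__(self, "effective_point", pt)
        if not 0.0 <= self.intrinsic_h <= 1.0:
            raise InputError(
                f"intrinsic_h must lie in [0, 1], got {self.intrinsic_h!r}"
            )


@dataclass
class StructureModel:
    """Ordered per-residue reduction of one chain, with provenance."""

    residues: list[ResidueRecord]
    source_id: str
    scale_name: str = DEFAULT_SCALE

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def points(self) -> np.ndarray:
        """(n, 3) array of effective-atom coordinates in Å, chain order."""
        return np.array([r.effective_point for r in self.residues], dtype=float)

    @property
    def hydrophobicity(self) -> np.ndarray:
        """(n,) array of intrinsic hydrophobicities in [0, 1], chain order."""
        return np.array([r.intrinsic_h for r in self.residues], dtype=float)

    def subset(self, keep: list[int]) -> "StructureModel":
        """New model with only the residues at the given 0-based positions."""
        return StructureModel(
            residues=[self.residues[i] for i in keep],
            source_id=self.source_id,
            scale_name=self.scale_name,
        )


def effective_atom(atoms: list[tuple[str, np.ndarray]]) -> np.ndarray:
    """Reduce one residue's atoms to a single effective point.

    Returns the arithmetic mean of side-chain heavy atoms; falls back to Cα
    for glycine or truncated residues with no side-chain heavy atom.

    Parameters
    ----------
    atoms
        List of ``(atom_name, xyz)`` pairs; hydrogens (names starting with
        H or D) are ignored.
    """
    ca = None
    side = []
    for name, pos in atoms:
        name = name.strip().upper()
        if name.startswith(("H", "D")):  # hydrogens / deuteriums
            continue
        pos = np.asarray(pos, dtype=float)
        if name == "CA":
            ca = pos
        elif name not in _BACKBONE:
            side.append(pos)
    if side:
        return np.mean(side, axis=0)
    if ca is not None:
        return ca
    raise InputError("residue has no side-chain heavy atom and no CA atom")


def assign_hydrophobicity(
    residue_names: list[str], scale: str | dict[str, float] = DEFAULT_SCALE
) -> np.ndarray:
    """Map residue names to intrinsic hydrophobicities rescaled to [0, 1].

    The rescaling is linear over the *scale table's* extrema, so the scale's
    most hydrophobic residue maps to 1 and the least hydrophobic to 0
    regardless of which residues appear in the input.
    """
    table = SCALES[scale] if isinstance(scale, str) else scale
    vmin = min(table.values())
    vmax = max(table.values())
    if vmax == vmin:
        raise InputError("hydrophobicity scale is constant; cannot rescale")
    out = np.empty(len(residue_names), dtype=float)
    for i, name in enumerate(residue_names):
        if name not in table:
            raise InputError(f"residue code {name!r} not in hydrophobicity scale")
        out[i] = (table[name] - vmin) / (vmax - vmin)
    return out


def read_structure(
    path: str,
    chain: str | None = None,
    scale: str | dict[str, float] = DEFAULT_SCALE,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only standard amino-acid residues of one chain are retained, in file
    order. Alternate locations other than blank or "A" are dropped, so a
    single deterministic conformer is used. Heteroatoms and waters are
    excluded by the standard-residue filter.

    Parameters
    ----------
    path
        PDB or mmCIF file.
    chain
        Chain identifier; default is the first chain that contains standard
        amino-acid residues.
    scale
        Named hydrophobicity scale or an explicit ``{residue: value}`` table.

    Raises
    ------
    FormatError
        If the file cannot be parsed.
    InputError
        If the chain is absent or has fewer than 3 standard residues.
    """
    table = SCALES[scale] if isinstance(scale, str) else scale
    scale_name = scale if isinstance(scale, str) else "custom"
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, SystemError) as exc:
        raise FormatError(f"cannot parse structure file {path!r}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"structure file {path!r} contains no model")
    model = st[0]

    chains = [ch for ch in model if chain is None or ch.name == chain]
    if chain is not None and not chains:
        raise InputError(f"chain {chain!r} not present in {path!r}")

    residues: list[ResidueRecord] = []
    for ch in chains:
        ch_residues: list[ResidueRecord] = []
        for res in ch:
            if res.name not in KYTE_DOOLITTLE:  # standard amino acids only
                continue
            atoms = [
                (atom.name, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                for atom in res
                if atom.altloc in ("", "\x00", "A")
            ]
            if not atoms:
                continue
            try:
                point = effective_atom(atoms)
            except InputError:
                logger.warning(
                    "residue %s %s%s has no usable atoms; skipped",
                    res.name, res.seqid.num, res.seqid.icode.strip(),
                )
                continue
            h = assign_hydrophobicity([res.name], table)[0]
            ch_residues.append(
                ResidueRecord(
                    chain_id=ch.name,
                    residue_index=res.seqid.num,
                    residue_name=res.name,
                    effective_point=point,
                    intrinsic_h=h,
                    icode=res.seqid.icode.strip(),
                )
            )
        if ch_residues:
            residues = ch_residues
            break  # first chain with standard residues (or the requested one)

    if len(residues) < 3:
        raise InputError(
            f"chain has {len(residues)} standard residues; at least 3 required"
        )
    return StructureModel(residues=residues, source_id=str(path), scale_name=scale_name)
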