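"""Shared fixtures: hand-written PDB snippets and small random instances."""

from __future__ import annotations

import numpy as np
import pytest


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz,
    altloc: str = " ",
    element: str | None = None,
) -> str:
    """Format one fixed-column ATOM record."""
    x, y, z = xyz
    if element is None:
        element = name[0]
    padded = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {padded}{altloc}{resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def make_pdb(records: list[tuple], chain: str = "A") -> str:
    """Build a minimal PDB text from (resname, resseq, [(atom, xyz, altloc?)]) tuples."""
    lines = []
    serial = 1
    for resname, resseq, atoms in records:
        for atom in atoms:
            name, xyz = atom[0], atom[1]
            altloc = atom[2] if len(atom) > 2 else " "
            lines.append(pdb_atom_line(serial, name, resname, chain, resseq, xyz, altloc))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_residue_pdb(tmp_path):
    """GLY + ALA + LEU with known side-chain geometry."""
    text = make_pdb(
        [
            ("GLY", 1, [("N", (0.0, 1.0, 0.0)), ("CA", (1.0, 1.0, 1.0)),
                        ("C", (2.0, 1.0, 0.0)), ("O", (2.5, 2.0, 0.0))]),
            ("ALA", 2, [("N", (3.0, 0.0, 0.0)), ("CA", (4.0, 0.0, 0.0)),
                        ("C", (5.0, 0.0, 0.0)), ("O", (5.5, 1.0, 0.0)),
                        ("CB", (4.0, 1.5, 1.0))]),
            ("LEU", 3, [("N", (6.0, 0.0, 0.0)), ("CA", (7.0, 0.0, 0.0)),
                        ("C", (8.0, 0.0, 0.0)), ("O", (8.5, 1.0, 0.0)),
                        ("CB", (7.0, 2.0, 0.0)), ("CG", (7.0, 2.0, 2.0))]),
        ]
    )
    path = tmp_path / "three.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_profile(rng, n: int) -> np.ndarray:
    """A strictly positive normalized profile."""
    v = rng.uniform(0.05, 1.0, n)
    return v / v.sum()
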