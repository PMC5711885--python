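"""Minimal structure container for membrane-slab SASA analysis.

Holds heavy atoms with per-atom radii (a NACCESS-compatible table keyed on
element) and named transmembrane-helix residue ranges, oriented with the
membrane normal along z.  Structures are read from PDB files via
Biopython; hydrogens are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Atom", "StructureModel", "read_pdb", "write_pdb", "ATOM_RADII"]

# van der Waals radii (Angstrom), NACCESS-compatible element defaults.
ATOM_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "H": 1.00,
}
DEFAULT_RADIUS = 1.80


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    xyz: tuple[float, float, float]
    radius: float


@dataclass
class StructureModel:
    """Atoms plus named helix residue ranges; membrane normal is z."""

    atoms: list[Atom]
    helices: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(np.isfinite(a.xyz).all() for a in self.atoms):
            raise ValueError("atom coordinates must be finite")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def residues(self) -> dict[tuple[str, int], list[int]]:
        """Atom indices grouped by (chain, residue number), in order."""
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain, a.res_seq), []).append(i)
        return out

    def helix_residues(self, name: str) -> list[tuple[str, int]]:
        lo, hi = self.helices[name]
        return [key for key in self.residues() if lo <= key[1] <= hi]

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0
                   ) -> "StructureModel":
        moved = [
            Atom(a.name, a.element, a.res_name, a.res_seq, a.chain,
                 (a.xyz[0] + dx, a.xyz[1] + dy, a.xyz[2] + dz), a.radius)
            for a in self.atoms
        ]
        return StructureModel(moved, dict(self.helices))


def read_pdb(path, helices: dict[str, tuple[int, int]] | None = None
             ) -> StructureModel:
    """Load heavy atoms of the first model of a PDB file."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if residue.id[0].strip():  # skip heteroatoms/waters
                continue
            for atom in residue:
                element = (atom.element or atom.get_name()[0]).upper()
                if element == "H":
                    continue
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=element,
                        res_name=residue.get_resname(),
                        res_seq=residue.id[1],
                        chain=chain.id,
                        xyz=tuple(float(c) for c in atom.coord),
                        radius=ATOM_RADII.get(element, DEFAULT_RADIUS),
                    )
                )
    if not atoms:
        raise ValueError(f"no protein atoms found in {path}")
    return StructureModel(atoms, helices or {})


def write_pdb(structure: StructureModel, path) -> None:
    """Write a minimal PDB file (ATOM records only)."""
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms, start=1):
            x, y, z = a.xyz
            fh.write(
                f"ATOM  {i:5d} {a.name:<4s} {a.res_name:>3s} {a.chain:1s}"
                f"{a.res_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")
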