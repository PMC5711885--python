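"""Residual hydrophobic mismatch (RHM) energetics of transmembrane helices.

RHM is the hydrophobic-mismatch penalty left unrelieved by membrane
deformation: hydrophobic residue surface exposed outside the bilayer's
hydrophobic core, or polar residue surface buried within it.  The core is
idealized here as a planar slab [z_lower, z_upper]; each residue's
solvent-accessible surface points are partitioned by z, giving

    hydrophobic residue:  SA_res = accessible area outside the slab
    polar residue:        SA_res = accessible area inside the slab

and the per-helix energy is sigma_res * sum(SA_res) with
sigma_res = 0.0028 kcal/(mol.A^2).  Three residue classes are exempt:
Ser/Thr always (their hydroxyls hydrogen-bond to the helix backbone),
interfacial Trp (favorably accommodated at the headgroup interface), and
Arg/Lys near a slab boundary (snorkeling).  Replicate energies are
summarized by a small-resample bootstrap SD and construct differences by
an unpaired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sasa import SasaResult, compute_sasa
from .structure import StructureModel

__all__ = [
    "MembraneSlab",
    "ResidueExposure",
    "HelixRHM",
    "SIGMA_RES",
    "HYDROPHOBIC_RESIDUES",
    "ALWAYS_EXEMPT",
    "SNORKELING",
    "classify_residue",
    "residue_mismatch_area",
    "helix_rhm_energy",
    "rhm_profile",
    "rhm_from_table",
    "bootstrap_sd",
    "compare_constructs",
]

#: RHM energy per unit mismatch area, kcal/(mol.Angstrom^2).
SIGMA_RES = 0.0028

HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "PRO", "GLY", "CYS"}
)
ALWAYS_EXEMPT = frozenset({"SER", "THR"})
SNORKELING = frozenset({"ARG", "LYS"})
_KNOWN = HYDROPHOBIC_RESIDUES | ALWAYS_EXEMPT | SNORKELING | {
    "ASP", "GLU", "ASN", "GLN", "HIS", "TYR", "TRP",
}


@dataclass(frozen=True)
class MembraneSlab:
    """Planar hydrophobic-core slab, bounds in Angstrom along z."""

    z_lower: float = -15.0
    z_upper: float = 15.0
    headgroup_margin: float = 3.0

    def __post_init__(self) -> None:
        if self.z_lower >= self.z_upper:
            raise ValueError("z_lower must be below z_upper")
        if self.headgroup_margin < 0:
            raise ValueError("headgroup_margin must be nonnegative")

    def near_boundary(self, z: float) -> bool:
        return (
            abs(z - self.z_lower) <= self.headgroup_margin
            or abs(z - self.z_upper) <= self.headgroup_margin
        )

    def contains(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return (z >= self.z_lower) & (z <= self.z_upper)


@dataclass(frozen=True)
class ResidueExposure:
    """Accessible-area bookkeeping for one residue against the slab."""

    chain: str
    res_seq: int
    res_name: str
    residue_class: str       # hydrophobic | polar | exempt
    sa_prot: float           # total accessible area, A^2
    sa_inside: float         # accessible area within the slab, A^2
    sa_outside: float        # accessible area outside the slab, A^2
    sa_res: float            # penalized mismatch area, A^2

    @property
    def sa_mem(self) -> float:
        """Accessible area remaining when the slab occludes the core."""
        return self.sa_outside


def _side_chain_z(structure: StructureModel, atom_idx: Sequence[int]) -> float:
    """z of the side-chain reference: CB if present, else CA, else centroid."""
    names = {structure.atoms[i].name: i for i in atom_idx}
    for ref in ("CB", "CA"):
        if ref in names:
            return structure.atoms[names[ref]].xyz[2]
    return float(np.mean([structure.atoms[i].xyz[2] for i in atom_idx]))


def classify_residue(
    res_name: str,
    side_chain_z: float,
    slab: MembraneSlab,
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES,
) -> str:
    """Assign hydrophobic / polar / exempt for the RHM penalty.

    Ser and Thr are always exempt; Trp is exempt at the interface
    (side chain within ``headgroup_margin`` of a slab boundary); Arg and
    Lys are exempt near a boundary (snorkeling).  Everything else is
    hydrophobic or polar per the residue table; unknown residue names are
    treated as polar with a warning.
    """
    name = res_name.upper()
    if name in ALWAYS_EXEMPT:
        return "exempt"
    if name == "TRP" and slab.near_boundary(side_chain_z):
        return "exempt"
    if name in SNORKELING and slab.near_boundary(side_chain_z):
        return "exempt"
    if name in hydrophobic_set:
        return "hydrophobic"
    if name not in _KNOWN:
        warnings.warn(f"unknown residue {res_name}; treated as polar", stacklevel=2)
    return "polar"


def residue_mismatch_area(residue_class: str, sa_inside: float, sa_outside: float
                          ) -> float:
    """Penalized area: outside-slab for hydrophobic, inside for polar."""
    if residue_class == "hydrophobic":
        return sa_outside
    if residue_class == "polar":
        return sa_inside
    return 0.0


def residue_exposures(
    structure: StructureModel,
    slab: MembraneSlab,
    sasa: SasaResult | None = None,
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES,
    n_points: int = 960,
) -> dict[tuple[str, int], ResidueExposure]:
    """Slab-partitioned exposure of every residue in the structure."""
    if sasa is None:
        sasa = compute_sasa(structure, n_points=n_points)
    out: dict[tuple[str, int], ResidueExposure] = {}
    for key, idx in structure.residues().items():
        inside = outside = total = 0.0
        for i in idx:
            pts = sasa.surface_points[i]
            if pts.size:
                in_mask = slab.contains(pts[:, 2])
                inside += in_mask.sum() * sasa.point_areas[i]
                outside += (~in_mask).sum() * sasa.point_areas[i]
            total += sasa.atom_areas[i]
        res_name = structure.atoms[idx[0]].res_name
        cls = classify_residue(
            res_name, _side_chain_z(structure, idx), slab, hydrophobic_set
        )
        out[key] = ResidueExposure(
            chain=key[0],
            res_seq=key[1],
            res_name=res_name,
            residue_class=cls,
            sa_prot=total,
            sa_inside=inside,
            sa_outside=outside,
            sa_res=residue_mismatch_area(cls, inside, outside),
        )
    return out


@dataclass(frozen=True)
class HelixRHM:
    """RHM energy of one transmembrane helix."""

    name: str
    energy: float                                  # kcal/mol
    contributions: tuple[ResidueExposure, ...]
    sigma_res: float = SIGMA_RES

    @property
    def n_res(self) -> int:
        return len(self.contributions)


def helix_rhm_energy(
    name: str,
    exposures: Sequence[ResidueExposure],
    sigma_res: float = SIGMA_RES,
) -> HelixRHM:
    """Sum sigma_res * SA_res over the helix residues."""
    exposures = tuple(exposures)
    if not exposures:
        warnings.warn(f"helix {name} has no residues; energy 0", stacklevel=2)
    energy = sigma_res * sum(e.sa_res for e in exposures)
    return HelixRHM(name=name, energy=float(energy), contributions=exposures,
                    sigma_res=sigma_res)


def rhm_profile(
    structure: StructureModel,
    slab: MembraneSlab,
    sigma_res: float = SIGMA_RES,
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES,
    n_points: int = 960,
) -> list[HelixRHM]:
    """Per-helix RHM energies; the whole chain is one helix if none defined."""
    helices = structure.helices
    if not helices:
        warnings.warn("no helix ranges defined; treating whole chain as one helix",
                      stacklevel=2)
        seqs = [a.res_seq for a in structure.atoms]
        helices = {"all": (min(seqs), max(seqs))}
    exposures = residue_exposures(structure, slab,
                                  hydrophobic_set=hydrophobic_set,
                                  n_points=n_points)
    out = []
    for hname, (lo, hi) in helices.items():
        members = [e for k, e in exposures.items() if lo <= k[1] <= hi]
        out.append(helix_rhm_energy(hname, members, sigma_res))
    return out


def rhm_from_table(
    table: pd.DataFrame,
    slab: MembraneSlab | None = None,
    sigma_res: float = SIGMA_RES,
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES,
) -> list[HelixRHM]:
    """RHM energies from a precomputed per-residue accessibility table.

    Expected columns: ``helix``, ``res_name``, ``res_seq``, ``sa_prot``
    (protein-only SASA), ``sa_mem`` (SASA with the membrane core treated
    as part of the solute), and optionally ``side_chain_z`` for the
    interfacial exemptions (omitted -> no positional exemption applies).
    Hydrophobic residues are penalized by sa_mem, polar by
    sa_prot - sa_mem (floored at 0).
    """
    required = {"helix", "res_name", "sa_prot", "sa_mem"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"accessibility table missing columns: {sorted(missing)}")
    if slab is None:
        slab = MembraneSlab()
    out = []
    for hname, grp in table.groupby("helix", sort=False):
        exposures = []
        for _, row in grp.iterrows():
            z = float(row["side_chain_z"]) if "side_chain_z" in grp.columns else 0.0
            cls = classify_residue(str(row["res_name"]), z, slab, hydrophobic_set)
            sa_prot = float(row["sa_prot"])
            sa_mem = float(row["sa_mem"])
            if cls == "hydrophobic":
                sa_res = sa_mem
            elif cls == "polar":
                sa_res = max(sa_prot - sa_mem, 0.0)
            else:
                sa_res = 0.0
            exposures.append(
                ResidueExposure(
                    chain=str(row.get("chain", "A")),
                    res_seq=int(row.get("res_seq", 0)),
                    res_name=str(row["res_name"]),
                    residue_class=cls,
                    sa_prot=sa_prot,
                    sa_inside=max(sa_prot - sa_mem, 0.0),
                    sa_outside=sa_mem,
                    sa_res=sa_res,
                )
            )
        out.append(helix_rhm_energy(str(hname), exposures, sigma_res))
    return out


def bootstrap_sd(
    replicate_values: Sequence[float],
    seed: int,
    n_resamples: int = 4,
    subset_size: int = 3,
) -> float:
    """Small-resample bootstrap SD of replicate energies.

    Draws ``n_resamples`` subsets of ``subset_size`` replicates (without
    replacement within a subset), takes each subset's mean, and returns
    the sample SD of those means.
    """
    values = np.asarray(replicate_values, dtype=float)
    if values.size < max(subset_size, 4):
        raise ValueError("need at least 4 replicate values")
    rng = np.random.default_rng(seed)
    means = [
        values[rng.choice(values.size, size=subset_size, replace=False)].mean()
        for _ in range(n_resamples)
    ]
    return float(np.std(means, ddof=1))


def compare_constructs(
    profile_a: Mapping[str, Sequence[float]],
    profile_b: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Per-helix mean RHM difference (b - a) with unpaired t-test p-values."""
    rows = []
    for helix in profile_a:
        if helix not in profile_b:
            continue
        a = np.asarray(profile_a[helix], dtype=float)
        b = np.asarray(profile_b[helix], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"helix {helix}: need >=2 replicates per construct")
        delta = float(b.mean() - a.mean())
        if a.std() == 0 and b.std() == 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            p = float(stats.ttest_ind(a, b).pvalue)
        rows.append({"helix": helix, "delta": delta, "p_value": p,
                     "mean_a": float(a.mean()), "mean_b": float(b.mean())})
    return pd.DataFrame(rows)
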