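"""Solvent-accessible surface area and relative-exposure classification.

SASA is computed with a sphere-sampling (Shrake–Rupley-style)
calculator: each heavy atom is expanded by the solvent probe radius
(default 1.4 Å, a water molecule) and sampled with a deterministic
Fibonacci point set; the accessible area is the unoccluded fraction of
the expanded sphere.  Per-residue areas are sums over the residue's
atoms.

A residue is classified as exposed when its area exceeds 40% of the
area the same residue type shows in an extended Ala-X-Ala tripeptide;
the reference areas are computed once per session by running this same
calculator on internally constructed extended tripeptides
(φ = −120°, ψ = 120°).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = [
    "VDW_RADII",
    "SASAResult",
    "sasa",
    "atom_sasa",
    "relative_exposure",
    "exposure_profile",
    "reference_tripeptide_areas",
]

#: Van der Waals radii (Å), Bondi (1964) set for the elements common in
#: proteins.  User-replaceable via the ``radii`` argument of :func:`sasa`.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


@lru_cache(maxsize=8)
def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom accessible area (Å²) of a bare coordinate/radius set.

    area_k = (unoccluded test points / n_points) · 4π (r_k + probe)².
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    ext = radii + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.empty(len(coords))
    for k in range(len(coords)):
        # any occluder center must lie within the sum of expanded radii
        neighbors = tree.query_ball_point(coords[k], ext[k] + max_ext)
        neighbors = [j for j in neighbors if j != k]
        pts = coords[k] + ext[k] * sphere
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = (d2 < ext[nb][None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[k] = frac * 4.0 * np.pi * ext[k] ** 2
    return areas


@dataclass
class SASAResult:
    """Accessible-surface areas of one structure.

    ``atom_areas`` aligns with the structure's atom order; ``residues``
    is a table indexed by residue label with columns ``res_name``,
    ``area`` (Å²) and, after :func:`relative_exposure`, ``percent`` and
    ``exposed``.
    """

    structure_id: str
    atom_areas: np.ndarray
    residues: pd.DataFrame


def sasa(
    s: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> SASAResult:
    """Accessible surface area of a structure's heavy atoms.

    Parameters
    ----------
    probe_radius : float
        Solvent probe radius in Å (1.4 ≈ water).
    n_points : int
        Test points per atom; the deterministic point set makes results
        reproducible bit-for-bit.
    radii : mapping, optional
        Element → van der Waals radius (Å) overriding :data:`VDW_RADII`.
    """
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    try:
        r = np.array([table[e.upper()] for e in s.element])
    except KeyError as exc:
        raise ValueError(
            f"no van der Waals radius for element {exc.args[0]!r}; pass radii="
        ) from None
    areas = atom_sasa(s.coord, r, probe_radius, n_points)
    labels = [f"{rid}{ic}" for rid, ic in zip(s.res_id, s.ins_code)]
    df = pd.DataFrame({"label": labels, "res_name": s.res_name, "area": areas})
    per_res = df.groupby("label", sort=False).agg(
        res_name=("res_name", "first"), area=("area", "sum")
    )
    per_res.index.name = "residue"
    return SASAResult(structure_id=s.id, atom_areas=areas, residues=per_res)


# ---------------------------------------------------------------------------
# Extended Ala-X-Ala reference areas


def _build_extended_tripeptide(letter: str):
    """Heavy-atom coords/elements/residue ids of an extended Ala-X-Ala peptide.

    Built with rdkit from sequence, embedded (seeded, deterministic) and
    straightened to an extended backbone (φ = −120°, ψ = 120°); ring
    dihedrals (proline φ) are left as embedded.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdMolTransforms

    mol = Chem.MolFromSequence(f"A{letter}A")
    if mol is None:
        raise ValueError(f"cannot build tripeptide for residue letter {letter!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = 1914
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for Ala-{letter}-Ala")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    backbone: dict[tuple[int, str], int] = {}
    for atom in mol.GetAtoms():
        info = atom.GetPDBResidueInfo()
        if info is not None:
            backbone[(info.GetResidueNumber(), info.GetName().strip())] = atom.GetIdx()
    conf = mol.GetConformer()
    for res in (1, 2, 3):
        try:
            if res > 1:  # φ: C(i-1)–N–CA–C
                rdMolTransforms.SetDihedralDeg(
                    conf,
                    backbone[(res - 1, "C")], backbone[(res, "N")],
                    backbone[(res, "CA")], backbone[(res, "C")], -120.0,
                )
            if res < 3:  # ψ: N–CA–C–N(i+1)
                rdMolTransforms.SetDihedralDeg(
                    conf,
                    backbone[(res, "N")], backbone[(res, "CA")],
                    backbone[(res, "C")], backbone[(res + 1, "N")], 120.0,
                )
        except ValueError:
            continue  # dihedral inside a ring (proline)
    coords, elements, res_ids = [], [], []
    pos = conf.GetPositions()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        info = atom.GetPDBResidueInfo()
        coords.append(pos[atom.GetIdx()])
        elements.append(atom.GetSymbol().upper())
        res_ids.append(info.GetResidueNumber() if info else 0)
    return np.asarray(coords), elements, np.asarray(res_ids)


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@lru_cache(maxsize=1)
def reference_tripeptide_areas(
    probe_radius: float = 1.4, n_points: int = 960
) -> dict[str, float]:
    """Area (Å²) of residue X in an extended Ala-X-Ala context, per residue type.

    Computed once per session with the package's own calculator on
    internally built extended tripeptides; keyed by three-letter residue
    name.
    """
    table: dict[str, float] = {}
    for letter, res3 in _ONE_TO_THREE.items():
        coords, elements, res_ids = _build_extended_tripeptide(letter)
        radii = np.array([VDW_RADII[e] for e in elements])
        areas = atom_sasa(coords, radii, probe_radius, n_points)
        table[res3] = float(areas[res_ids == 2].sum())
    return table


def relative_exposure(
    result: SASAResult,
    reference: Mapping[str, float] | None = None,
    threshold_percent: float = 40.0,
) -> pd.DataFrame:
    """Classify residues as exposed from their relative accessible area.

    percent = 100 · area / reference(res_name); exposed iff percent
    strictly exceeds ``threshold_percent``.  A copy of the residue table
    with ``percent`` and ``exposed`` columns is returned (and stored
    back on ``result.residues``).
    """
    if reference is None:
        reference = reference_tripeptide_areas()
    df = result.residues.copy()
    missing = sorted(set(df["res_name"]) - set(reference))
    if missing:
        raise ValueError(f"no reference area for residue type(s): {', '.join(missing)}")
    ref = df["res_name"].map(reference)
    df["percent"] = 100.0 * df["area"] / ref
    df["exposed"] = df["percent"] > threshold_percent
    result.residues = df
    return df


def exposure_profile(per_structure: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean and maximum relative exposure per residue over an ensemble.

    Input tables must carry a ``percent`` column (from
    :func:`relative_exposure`); statistics are taken over the structures
    in which a residue is present.
    """
    stacked = pd.concat(
        [df["percent"] for df in per_structure], axis=1, join="outer"
    )
    return pd.DataFrame(
        {"mean_percent": stacked.mean(axis=1), "max_percent": stacked.max(axis=1)}
    )
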