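"""Structure ingest, nucleotide-state annotation, superposition and RMSD.

Coordinates come from standard PDB files.  Only heavy atoms are kept:
all downstream statistics (probe contacts, solvent exposure, PCA) are
defined on heavy atoms, and crystallographic hydrogen positions are
rarely observed anyway.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "CoordinateSet",
    "read_structure",
    "write_structure",
    "classify_nucleotide_state",
    "extract_calpha",
    "superpose",
    "superpose_ensemble",
    "pairwise_rmsd",
    "DEFAULT_LIGAND_MAP",
]

#: GTP-state codes cover the true nucleotide plus the common
#: non-hydrolysable analogs used for crystallisation.
DEFAULT_LIGAND_MAP: dict[str, str] = {
    "GTP": "GTP",
    "GNP": "GTP",  # GppNHp
    "GSP": "GTP",  # GTP-gamma-S
    "GCP": "GTP",  # GppCp
    "GDP": "GDP",
}

_HYDROGEN = frozenset({"H", "D"})


@dataclass
class Structure:
    """Heavy atoms of one protein chain plus its HET groups.

    Attributes
    ----------
    id : str
        Source identifier, conventionally ``"<entry>_<chain>"``.
    atom_name, element, res_name, chain_id : ndarray of str
    res_id : ndarray of int
        Author-assigned residue numbers, kept verbatim.
    ins_code : ndarray of str
        Insertion codes ('' when absent); together with ``res_id`` they
        identify a residue uniquely within the chain.
    coord : (n_atoms, 3) float ndarray, Å
    b_factor, occupancy : float ndarrays
    """

    id: str
    atom_name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    ins_code: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    b_factor: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"{self.id}: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def het_codes(self) -> set[str]:
        """Residue names of non-polymer (HETATM) groups present."""
        return set(self.res_name[self._hetero_mask()])

    def _hetero_mask(self) -> np.ndarray:
        return ~np.isin(self.res_name, list(_AMINO3))

    def residue_labels(self) -> list[str]:
        """Ordered unique labels ('<resid>' or '<resid><icode>') of polymer residues."""
        mask = ~self._hetero_mask()
        seen: dict[str, None] = {}
        for rid, icode in zip(self.res_id[mask], self.ins_code[mask]):
            seen.setdefault(f"{rid}{icode}", None)
        return list(seen)

    def calpha(self) -> dict[str, np.ndarray]:
        """Map residue label -> Cα coordinate for polymer residues."""
        mask = (self.atom_name == "CA") & (self.element == "C") & ~self._hetero_mask()
        out: dict[str, np.ndarray] = {}
        for i in np.flatnonzero(mask):
            lab = f"{self.res_id[i]}{self.ins_code[i]}"
            out.setdefault(lab, self.coord[i])
        return out

    def one_letter_sequence(self) -> str:
        """One-letter sequence of polymer residues in label order ('X' if unknown)."""
        mask = ~self._hetero_mask()
        seen: dict[str, str] = {}
        for i in np.flatnonzero(mask):
            lab = f"{self.res_id[i]}{self.ins_code[i]}"
            seen.setdefault(lab, _AMINO3.get(self.res_name[i], "X"))
        return "".join(seen.values())

    def to_atom_array(self) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.coord = np.asarray(self.coord, dtype=np.float32)
        arr.atom_name = self.atom_name
        arr.element = self.element
        arr.res_name = self.res_name
        arr.res_id = self.res_id
        arr.ins_code = self.ins_code
        arr.chain_id = self.chain_id
        arr.hetero = self._hetero_mask()
        arr.set_annotation("b_factor", np.asarray(self.b_factor, dtype=np.float64))
        arr.set_annotation("occupancy", np.asarray(self.occupancy, dtype=np.float64))
        return arr


# Standard residues; used to separate polymer from HET records.
_AMINO3: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_structure(pdb_source, chain: str, structure_id: str | None = None) -> Structure:
    """Read one chain's heavy atoms from a PDB file or text stream.

    Alternate locations are resolved to the highest-occupancy copy
    (ties broken by file order).  Hydrogens are dropped.

    Parameters
    ----------
    pdb_source : path, str of PDB text, or text stream
    chain : str
        Chain identifier to extract.
    structure_id : str, optional
        Identifier stored on the result; defaults to ``<stem>_<chain>``.

    Raises
    ------
    ValueError
        If the chain is absent (message lists available chains) or a
        coordinate line cannot be parsed (message carries line number).
    """
    name = "stream"
    if isinstance(pdb_source, (str, Path)) and "\n" not in str(pdb_source):
        name = Path(pdb_source).stem
        pdb_file = pdbio.PDBFile.read(pdb_source)
    elif isinstance(pdb_source, str):
        pdb_file = pdbio.PDBFile.read(io.StringIO(pdb_source))
    else:
        pdb_file = pdbio.PDBFile.read(pdb_source)
    _check_coordinate_lines(pdb_file.lines)
    arr = pdb_file.get_structure(
        model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
    )
    chains = sorted(set(arr.chain_id))
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not found; available chains: {', '.join(chains)}"
        )
    arr = arr[arr.chain_id == chain]
    arr = arr[~np.isin(arr.element, list(_HYDROGEN))]
    return Structure(
        id=structure_id or f"{name}_{chain}",
        atom_name=np.asarray(arr.atom_name),
        element=np.asarray(arr.element),
        res_name=np.asarray(arr.res_name),
        res_id=np.asarray(arr.res_id),
        ins_code=np.asarray(arr.ins_code),
        chain_id=np.asarray(arr.chain_id),
        coord=np.asarray(arr.coord, dtype=float),
        b_factor=np.asarray(arr.b_factor, dtype=float),
        occupancy=np.asarray(arr.occupancy, dtype=float),
    )


def _check_coordinate_lines(lines: Sequence[str]) -> None:
    for i, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(f"unparsable coordinate fields at line {i}: {line!r}")


def write_structure(s: Structure, path) -> None:
    """Write a Structure back to a standard PDB file."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(s.to_atom_array())
    pdb_file.write(path)


def classify_nucleotide_state(
    s: Structure, ligand_map: Mapping[str, str] | None = None
) -> str:
    """Assign a nucleotide state label from the HET groups present.

    Returns one of ``"GTP"``, ``"GDP"``, ``"APO"`` or ``"UNKNOWN"``
    (the last when both GTP-class and GDP-class codes co-occur).
    """
    ligand_map = DEFAULT_LIGAND_MAP if ligand_map is None else ligand_map
    states = {ligand_map[c] for c in s.het_codes if c in ligand_map}
    if not states:
        return "APO"
    if len(states) > 1:
        return "UNKNOWN"
    return states.pop()


@dataclass
class CoordinateSet:
    """Aligned Cα coordinates of an ensemble over a shared residue set.

    Attributes
    ----------
    labels : list of str
        Residue labels common to all members, ordered by residue number.
    coords : (n_structures, n_residues, 3) float ndarray, Å
    states : list of str
        Per-structure nucleotide-state label.
    bfactors : (n_structures, n_residues) float ndarray
    ids : list of str
        Per-structure identifiers.
    """

    labels: list[str]
    coords: np.ndarray
    states: list[str]
    bfactors: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_structures, n_residues, 3)")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("coords second axis must match number of labels")
        if not self.ids:
            self.ids = [f"s{i}" for i in range(self.n_structures)]

    @property
    def n_structures(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def flat(self) -> np.ndarray:
        """Coordinates as an (n_structures, 3·n_residues) matrix."""
        return self.coords.reshape(self.n_structures, -1)


def _label_sort_key(label: str) -> tuple[int, str]:
    digits = "".join(ch for ch in label if ch in "-0123456789")
    icode = label[len(digits):]
    return int(digits), icode


def extract_calpha(
    structures: Sequence[Structure],
    residue_range: tuple[int, int] | None = None,
    states: Sequence[str] | None = None,
) -> CoordinateSet:
    """Build the shared-Cα coordinate matrix of an ensemble.

    The label set is the intersection of residues with a Cα in every
    member, optionally clipped to ``residue_range`` (inclusive bounds on
    the numeric residue id), ordered by residue number.
    """
    if len(structures) < 2:
        raise ValueError("need at least two structures")
    ca_maps = [s.calpha() for s in structures]
    shared = set(ca_maps[0])
    for m in ca_maps[1:]:
        shared &= set(m)
    if residue_range is not None:
        lo, hi = residue_range
        shared = {l for l in shared if lo <= _label_sort_key(l)[0] <= hi}
    if not shared:
        raise ValueError("no residues with Cα common to all structures")
    labels = sorted(shared, key=_label_sort_key)
    coords = np.stack([[m[l] for l in labels] for m in ca_maps])
    if states is None:
        states = ["UNKNOWN"] * len(structures)
    bf = np.zeros((len(structures), len(labels)))
    for k, s in enumerate(structures):
        mask = (s.atom_name == "CA") & (s.element == "C")
        bmap = {
            f"{s.res_id[i]}{s.ins_code[i]}": s.b_factor[i] for i in np.flatnonzero(mask)
        }
        bf[k] = [bmap[l] for l in labels]
    return CoordinateSet(
        labels=labels,
        coords=coords,
        states=list(states),
        bfactors=bf,
        ids=[s.id for s in structures],
    )


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    core: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns the transformed copy of all mobile coordinates and the RMSD
    over the core positions.  The rotation is proper (det = +1); the fit
    is the global optimum of the orthogonal Procrustes problem.

    Parameters
    ----------
    mobile, reference : (n, 3) ndarrays, Å
    core : index array, optional
        Subset of positions used to compute the fit (default: all).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if core is None:
        core = np.arange(len(mobile))
    mob_core = mobile[core]
    ref_core = reference[core]
    if len(mob_core) < 3:
        raise ValueError("need at least 3 core positions")
    mc = mob_core.mean(axis=0)
    rc = ref_core.mean(axis=0)
    a = mob_core - mc
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("degenerate core: positions collinear or coincident")
    rot, _ = Rotation.align_vectors(ref_core - rc, a)
    moved = rot.apply(mobile - mc) + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved[core] - ref_core) ** 2, axis=1))))
    return moved, rmsd


def superpose_ensemble(
    cs: CoordinateSet,
    core: np.ndarray | None = None,
    refine_core: bool = False,
    max_iter: int = 10,
    var_quantile: float = 0.75,
) -> CoordinateSet:
    """Superpose every member onto a converged mean structure.

    All members are first fitted to the first member, then iteratively
    re-fitted to the coordinate-wise mean until the mean stabilises.
    With ``refine_core=True`` the fit core is additionally restricted to
    the lower-variance positions (below ``var_quantile`` of per-residue
    variance), re-selected each iteration — useful when a mobile region
    would otherwise dominate the fit; off by default.
    """
    coords = cs.coords.copy()
    ref = coords[0]
    fit_core = core
    for _ in range(max_iter):
        for k in range(len(coords)):
            coords[k], _ = superpose(coords[k], ref, core=fit_core)
        mean = coords.mean(axis=0)
        if np.max(np.abs(mean - ref)) < 1e-9:
            break
        ref = mean
        if refine_core:
            var = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)
            keep = var <= np.quantile(var, var_quantile)
            fit_core = np.flatnonzero(keep) if core is None else np.intersect1d(
                np.flatnonzero(keep), core
            )
    return CoordinateSet(
        labels=list(cs.labels),
        coords=coords,
        states=list(cs.states),
        bfactors=cs.bfactors.copy(),
        ids=list(cs.ids),
    )


def pairwise_rmsd(cs: CoordinateSet) -> np.ndarray:
    """Symmetric matrix of pairwise RMSDs, each after a fresh optimal fit."""
    n = cs.n_structures
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, r = superpose(cs.coords[j], cs.coords[i])
            out[i, j] = out[j, i] = r
    return out
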