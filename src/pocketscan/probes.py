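"""Fragment-probe poses and residue–probe contact evaluation.

Probe poses come either from an external fragment-mapping tool (as
multi-model PDB files, one small molecule per MODEL) or from the
built-in geometric scan, which marks sheltered near-surface grid points
and clusters them into pseudo-probes.  Either way a residue is scored
as contacted in a structure when any heavy atom of any probe lies
strictly within the contact cutoff (default 5.0 Å) of any heavy atom of
the residue.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure import Structure, _HYDROGEN

__all__ = [
    "Probe",
    "ProbeSet",
    "ContactVector",
    "read_probe_poses",
    "write_probe_poses",
    "geometric_probe_scan",
    "residue_contacts",
]


@dataclass
class Probe:
    """One probe pose: a type label, a cluster id and heavy-atom coordinates."""

    kind: str
    cluster_id: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if len(self.coords) == 0 or not np.all(np.isfinite(self.coords)):
            raise ValueError("probe needs at least one finite heavy-atom coordinate")


@dataclass
class ProbeSet:
    """All probe poses mapped onto one structure."""

    structure_id: str
    probes: list[Probe]

    def __len__(self) -> int:
        return len(self.probes)

    def all_coords(self) -> np.ndarray:
        if not self.probes:
            return np.empty((0, 3))
        return np.vstack([p.coords for p in self.probes])


@dataclass
class ContactVector:
    """Binary per-residue probe-contact indicator for one structure."""

    structure_id: str
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if set(np.unique(self.values)) - {0, 1}:
            raise ValueError("contact values must be binary")
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels length mismatch")


def read_probe_poses(source, structure_id: str) -> ProbeSet:
    """Read a multi-model PDB probe file: one probe per MODEL, heavy atoms only.

    The model number is used as the cluster id; the probe type label is
    the (first) residue name inside the model.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        pdb_file = pdbio.PDBFile.read(source)
    elif isinstance(source, str):
        pdb_file = pdbio.PDBFile.read(io.StringIO(source))
    else:
        pdb_file = pdbio.PDBFile.read(source)
    probes: list[Probe] = []
    for model in range(1, pdb_file.get_model_count() + 1):
        arr = pdb_file.get_structure(model=model)
        arr = arr[~np.isin(arr.element, list(_HYDROGEN))]
        if arr.array_length() == 0:
            continue
        probes.append(
            Probe(
                kind=str(arr.res_name[0]),
                cluster_id=model,
                coords=np.asarray(arr.coord, dtype=float),
            )
        )
    if not probes:
        raise ValueError("no probe heavy atoms found in file")
    return ProbeSet(structure_id=structure_id, probes=probes)


def write_probe_poses(ps: ProbeSet, path) -> None:
    """Write probes as a multi-model PDB file (one MODEL per probe)."""
    lines: list[str] = []
    for m, probe in enumerate(ps.probes, start=1):
        lines.append(f"MODEL     {m:4d}")
        for a, (x, y, z) in enumerate(probe.coords, start=1):
            name = f"C{a}"
            lines.append(
                f"HETATM{a:5d} {name:<4s}{probe.kind[:3].upper():>4s} A{m % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{'C':>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def geometric_probe_scan(
    s: Structure,
    grid_spacing: float = 1.0,
    shell_distance: float = 4.5,
    burial_threshold: int = 45,
    burial_radius: float = 8.0,
    min_component: int = 3,
) -> ProbeSet:
    """Pseudo-probe sites from a sheltered near-surface grid scan.

    A regular grid over the structure's bounding box (padded by the
    shell distance) is filtered to points that (a) lie between 2.5 Å and
    ``shell_distance`` from the nearest protein heavy atom and (b) have
    at least ``burial_threshold`` protein heavy atoms within
    ``burial_radius`` — i.e. near-surface yet sheltered from solvent.
    Retained points are clustered by 6-neighbour grid adjacency;
    components smaller than ``min_component`` points are discarded.
    Deterministic, no randomness.
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    coords = s.coord
    lo = coords.min(axis=0) - shell_distance
    hi = coords.max(axis=0) + shell_distance
    axes = [np.arange(lo[d], hi[d] + grid_spacing / 2, grid_spacing) for d in range(3)]
    shape = tuple(len(a) for a in axes)
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(coords)
    dist, _ = tree.query(grid)
    near = (dist >= 2.5) & (dist <= shell_distance)
    counts = tree.query_ball_point(grid[near], burial_radius, return_length=True)
    keep = np.zeros(len(grid), dtype=bool)
    keep[np.flatnonzero(near)[counts >= burial_threshold]] = True
    mask = keep.reshape(shape)
    labeled, n_comp = ndimage.label(mask)  # default structuring element = 6-neighbour
    probes: list[Probe] = []
    flat_labels = labeled.reshape(-1)
    for c in range(1, n_comp + 1):
        idx = np.flatnonzero(flat_labels == c)
        if len(idx) < min_component:
            continue
        probes.append(Probe(kind="GRID", cluster_id=len(probes) + 1, coords=grid[idx]))
    return ProbeSet(structure_id=s.id, probes=probes)


def residue_contacts(
    s: Structure,
    ps: ProbeSet,
    cutoff: float = 5.0,
    labels: list[str] | None = None,
) -> ContactVector:
    """Binary per-residue contact indicator against all probes of a set.

    A residue scores 1 iff the minimum heavy-atom distance between any
    of its atoms and any probe atom is strictly below ``cutoff``.
    ``labels`` restricts/reorders the output to a shared label set
    (residues absent from the structure score 0).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atom_labels = np.array([f"{r}{i}" for r, i in zip(s.res_id, s.ins_code)])
    polymer = ~s._hetero_mask()
    if labels is None:
        labels = s.residue_labels()
    values = np.zeros(len(labels), dtype=np.uint8)
    probe_coords = ps.all_coords()
    if len(probe_coords):
        tree = cKDTree(probe_coords)
        dmin, _ = tree.query(s.coord)
        index = {lab: k for k, lab in enumerate(labels)}
        for i in np.flatnonzero(polymer):
            if dmin[i] < cutoff:
                k = index.get(atom_labels[i])
                if k is not None:
                    values[k] = 1
    return ContactVector(structure_id=s.id, labels=list(labels), values=values)
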