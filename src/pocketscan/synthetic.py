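"""Synthetic fixtures with the statistical structure the analysis assumes.

Three generators, all deterministic given a seed:

* a two-state Cα ensemble laid on a smooth helix-like curve whose states
  differ along a planted collective mode (localised to a contiguous
  "switch" block, orthogonalised against rigid motions so superposition
  preserves it) plus isotropic Gaussian noise;
* probe poses that occupy a planted pocket with state-dependent
  probability — all-or-none per structure, matching the binary
  per-structure contact datum — plus a direct Bernoulli contact-matrix
  simulator for statistical calibration at scale;
* alignments whose columns are sampled i.i.d. from specified letter
  distributions, with the implied ground-truth entropies returned.

The geometry is deliberately idealised (no side chains, no packing):
these fixtures exercise the statistics and the geometric plumbing, not
protein physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conservation import Alignment
from .occupancy import OccupancyProfile
from .probes import Probe, ProbeSet
from .structure import CoordinateSet, Structure

__all__ = [
    "SyntheticSpec",
    "make_two_state_ensemble",
    "make_probe_sets",
    "simulate_contact_matrices",
    "make_alignment",
    "make_backbone_structure",
    "coordinate_structure",
    "write_synthetic_dataset",
]

# Helix-like backbone: 100° twist and 1.5 Å rise per residue at 2.3 Å
# radius gives the canonical ~3.8 Å Cα-Cα spacing.
_TWIST_DEG = 100.0
_RISE = 1.5
_RADIUS = 2.3


@dataclass
class SyntheticSpec:
    """Parameters of the planted two-state ensemble.

    Defaults are the package's reference study conditions: 200 residues,
    30 structures per state, a 3 Å inter-state displacement along a
    switch-like block (residues 24–40), 0.2 Å isotropic positional
    noise, and a pocket contacted with probability 0.9 in the first
    state and 0.1 in the second.
    """

    n_residues: int = 200
    n_per_state: int = 30
    amplitude: float = 3.0
    sigma: float = 0.2
    mode_block: tuple[int, int] = (24, 40)
    pocket_residues: tuple[int, ...] = (100, 101)
    probe_prob: tuple[float, float] = (0.9, 0.1)
    states: tuple[str, str] = ("GDP", "GTP")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        lo, hi = self.mode_block
        if not 1 <= lo <= hi <= self.n_residues:
            raise ValueError("mode_block must be a 1-based range within the chain")
        if not all(0 <= p <= 1 for p in self.probe_prob):
            raise ValueError("probe probabilities must lie in [0, 1]")
        if not all(1 <= r <= self.n_residues for r in self.pocket_residues):
            raise ValueError("pocket residues must lie within 1..n_residues")

    @classmethod
    def for_mode_recovery(cls, seed: int = 0) -> "SyntheticSpec":
        """Well-powered design for planted-mode (PC1) recovery.

        The angular error of the leading sample eigenvector scales as
        sqrt(3N σ² / (n λ₁)), so recovering the planted direction to a
        cosine above 0.99 needs many more observations than coordinate
        dimensions: 50 residues × 600 structures keeps that error near
        0.005 at the reference noise level (σ = 0.2 Å, amplitude 3 Å).
        """
        return cls(
            n_residues=50,
            n_per_state=300,
            mode_block=(15, 31),
            pocket_residues=(40, 41),
            seed=seed,
        )


def _helix_coords(n: int) -> np.ndarray:
    t = np.arange(n)
    theta = np.deg2rad(_TWIST_DEG) * t
    return np.column_stack(
        [_RADIUS * np.cos(theta), _RADIUS * np.sin(theta), _RISE * t]
    )


def _rigid_modes(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N × 6) of rigid translations and rotations."""
    n = len(coords)
    centered = coords - coords.mean(axis=0)
    modes = []
    for axis in np.eye(3):
        modes.append(np.tile(axis, n))
    for axis in np.eye(3):
        modes.append(np.cross(centered, axis).reshape(-1))
    q, _ = np.linalg.qr(np.column_stack(modes))
    return q


def _planted_mode(coords: np.ndarray, block: tuple[int, int]) -> np.ndarray:
    """Unit 3N mode: radial outward push of the block, rigid motions removed.

    Orthogonalising against the six rigid-body modes of the mean
    geometry makes the planted signal invisible to least-squares
    superposition, so the analysis sees it undistorted.
    """
    n = len(coords)
    lo, hi = block
    d = np.zeros((n, 3))
    axis_xy = coords[:, :2]
    for i in range(lo - 1, hi):
        r = axis_xy[i]
        d[i, :2] = r / np.linalg.norm(r)
    flat = d.reshape(-1)
    rigid = _rigid_modes(coords)
    flat = flat - rigid @ (rigid.T @ flat)
    return flat / np.linalg.norm(flat)


def make_two_state_ensemble(spec: SyntheticSpec) -> tuple[CoordinateSet, dict]:
    """Generate the planted two-state ensemble.

    Returns the CoordinateSet (already in a common frame; no noise in
    the frame itself) and a ground-truth dict with the planted unit
    ``mode`` (3N,), the per-structure ``states`` and the generative
    per-axis noise ``sigma``.
    """
    if spec.amplitude == 0 and spec.sigma == 0:
        raise ValueError("degenerate spec: amplitude and sigma both zero")
    rng = np.random.default_rng(spec.seed)
    base = _helix_coords(spec.n_residues)
    mode = _planted_mode(base, spec.mode_block)
    mode_mat = mode.reshape(spec.n_residues, 3)
    n = spec.n_per_state
    coords = np.empty((2 * n, spec.n_residues, 3))
    states: list[str] = []
    for k in range(2 * n):
        sign = 1.0 if k < n else -1.0
        states.append(spec.states[0] if k < n else spec.states[1])
        noise = rng.normal(0.0, spec.sigma, size=(spec.n_residues, 3))
        coords[k] = base + sign * (spec.amplitude / 2.0) * mode_mat + noise
    bfactors = np.full((2 * n, spec.n_residues), 8.0 * np.pi**2 * spec.sigma**2)
    cs = CoordinateSet(
        labels=[str(i + 1) for i in range(spec.n_residues)],
        coords=coords,
        states=states,
        bfactors=bfactors,
        ids=[f"{states[k]}_{k}" for k in range(2 * n)],
    )
    truth = {"mode": mode, "states": states, "sigma": spec.sigma}
    return cs, truth


def make_backbone_structure(n_residues: int = 200) -> Structure:
    """Idealised backbone (N, CA, C, O per residue) on the helix-like curve.

    A multi-atom-per-residue fixture for surface-area and contact
    plumbing; deterministic, no randomness.
    """
    ca = _helix_coords(n_residues)
    tangent = np.gradient(ca, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    outward = np.zeros_like(ca)
    outward[:, :2] = ca[:, :2] / np.linalg.norm(ca[:, :2], axis=1, keepdims=True)
    names, elements, res_ids, coords = [], [], [], []
    for i in range(n_residues):
        for name, elem, off in (
            ("N", "N", -1.2 * tangent[i]),
            ("CA", "C", np.zeros(3)),
            ("C", "C", 1.2 * tangent[i]),
            ("O", "O", 1.2 * tangent[i] + 1.2 * outward[i]),
        ):
            names.append(name)
            elements.append(elem)
            res_ids.append(i + 1)
            coords.append(ca[i] + off)
    n = len(coords)
    return Structure(
        id=f"backbone{n_residues}",
        atom_name=np.array(names),
        element=np.array(elements),
        res_name=np.array(["ALA"] * n),
        res_id=np.array(res_ids),
        ins_code=np.array([""] * n),
        chain_id=np.array(["A"] * n),
        coord=np.array(coords),
        b_factor=np.zeros(n),
        occupancy=np.ones(n),
    )


def coordinate_structure(cs: CoordinateSet, index: int) -> Structure:
    """View one ensemble member as a Cα-only Structure (residues as ALA)."""
    n = cs.n_residues
    res_ids = np.array([int("".join(c for c in l if c in "-0123456789")) for l in cs.labels])
    return Structure(
        id=cs.ids[index],
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        res_name=np.array(["ALA"] * n),
        res_id=res_ids,
        ins_code=np.array([""] * n),
        chain_id=np.array(["A"] * n),
        coord=cs.coords[index].copy(),
        b_factor=cs.bfactors[index].copy(),
        occupancy=np.ones(n),
    )


# tetrahedral heavy-atom offsets of the 4-atom pseudo-probe (Å)
_PROBE_OFFSETS = 0.8 * np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
) / np.sqrt(3.0)


def make_probe_sets(
    cs: CoordinateSet, spec: SyntheticSpec, seed: int | None = None
) -> tuple[list[ProbeSet], np.ndarray]:
    """Place state-preferential probe poses on each ensemble member.

    For each structure, with its state's probability a 4-atom probe is
    placed at the centroid of the pocket residues, offset 3.5 Å outward
    (away from the structure centroid); otherwise the structure gets an
    empty ProbeSet.  Returns the probe sets and the boolean presence
    vector (the ground truth).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    prob = dict(zip(spec.states, spec.probe_prob))
    pocket_idx = [cs.labels.index(str(r)) for r in spec.pocket_residues]
    sets: list[ProbeSet] = []
    present = np.zeros(cs.n_structures, dtype=bool)
    for k in range(cs.n_structures):
        place = rng.random() < prob[cs.states[k]]
        present[k] = place
        probes: list[Probe] = []
        if place:
            pocket_centroid = cs.coords[k][pocket_idx].mean(axis=0)
            outward = pocket_centroid - cs.coords[k].mean(axis=0)
            outward /= np.linalg.norm(outward)
            center = pocket_centroid + 3.5 * outward
            probes.append(Probe(kind="SYN", cluster_id=1, coords=center + _PROBE_OFFSETS))
        sets.append(ProbeSet(structure_id=cs.ids[k], probes=probes))
    return sets, present


def simulate_contact_matrices(
    n_residues: int = 200,
    n_per_state: int = 30,
    pocket: tuple[int, int] = (60, 79),
    p_pocket: tuple[float, float] = (0.9, 0.1),
    p_null: float = 0.5,
    states: tuple[str, str] = ("GDP", "GTP"),
    seed: int = 0,
) -> tuple[OccupancyProfile, OccupancyProfile, np.ndarray]:
    """Directly simulate per-residue Bernoulli contact matrices.

    Pocket residues (inclusive 1-based block) are contacted with
    state-dependent probability ``p_pocket``; every other residue with
    the state-independent probability ``p_null`` — so false-positive
    rates are measured against a non-degenerate null.  Returns the two
    occupancy profiles and the boolean planted-pocket mask.
    """
    lo, hi = pocket
    if not 1 <= lo <= hi <= n_residues:
        raise ValueError("pocket block must be a 1-based range within the chain")
    rng = np.random.default_rng(seed)
    labels = [str(i + 1) for i in range(n_residues)]
    planted = np.zeros(n_residues, dtype=bool)
    planted[lo - 1 : hi] = True
    profiles = []
    for p_state in p_pocket:
        p = np.where(planted, p_state, p_null)
        mat = (rng.random((n_per_state, n_residues)) < p).astype(np.uint8)
        profiles.append(mat)
    prof_a = OccupancyProfile(
        labels=labels, values=profiles[0].mean(axis=0),
        contact_matrix=profiles[0], state=states[0],
    )
    prof_b = OccupancyProfile(
        labels=labels, values=profiles[1].mean(axis=0),
        contact_matrix=profiles[1], state=states[1],
    )
    return prof_a, prof_b, planted


def make_alignment(
    columns: list[dict[str, float]],
    n_seq: int = 200,
    seed: int = 0,
    gap: str = "-",
) -> tuple[Alignment, pd.DataFrame]:
    """Sample an alignment column-wise from specified letter distributions.

    Each column spec maps letters (amino acids or the gap character) to
    probabilities summing to 1 (±1e-9).  Rows are i.i.d. samples.
    Returns the alignment and a table of the distributions' target
    entropies (bits, both alphabets) together with the realised letter
    frequencies' entropies.
    """
    from .conservation import column_entropy

    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    targets = []
    for j, dist in enumerate(columns):
        letters = list(dist)
        probs = np.array([dist[l] for l in letters], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"column {j} distribution sums to {probs.sum()}, not 1")
        cols.append(rng.choice(letters, size=n_seq, p=probs))
        expanded = "".join(
            l * max(1, round(1e6 * p)) for l, p in zip(letters, probs) if p > 0
        )
        targets.append(
            {
                "target_entropy21": column_entropy(expanded, 21, gap),
                "target_entropy7": column_entropy(expanded, 7, gap),
            }
        )
    rows = ["".join(cols[j][i] for j in range(len(cols))) for i in range(n_seq)]
    aln = Alignment(sequences=[(f"seq{i}", r) for i, r in enumerate(rows)], gap=gap)
    return aln, pd.DataFrame(targets)


def write_synthetic_dataset(outdir, spec: SyntheticSpec) -> dict:
    """Materialise a full synthetic study on disk.

    Writes per-structure PDB files, per-structure probe-pose files, a
    manifest (id, file, chain, state, probe_file), a small alignment in
    FASTA, and a ground-truth JSON.  Returns the manifest as a dict.
    """
    from .probes import write_probe_poses
    from .structure import write_structure

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cs, truth = make_two_state_ensemble(spec)
    probe_sets, present = make_probe_sets(cs, spec)
    rows = []
    for k in range(cs.n_structures):
        s = coordinate_structure(cs, k)
        pdb_path = outdir / f"{cs.ids[k]}.pdb"
        write_structure(s, str(pdb_path))
        probe_path = ""
        if probe_sets[k].probes:
            probe_path = f"{cs.ids[k]}_probes.pdb"
            write_probe_poses(probe_sets[k], outdir / probe_path)
        rows.append(
            {
                "id": cs.ids[k],
                "file": pdb_path.name,
                "chain": "A",
                "state": cs.states[k],
                "probe_file": probe_path,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    aln, _ = make_alignment(
        [
            {"A": 1.0},
            {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"},
            {"D": 0.5, "E": 0.5},
            {"-": 0.35, "A": 0.65},
        ],
        n_seq=100,
        seed=spec.seed,
    )
    with open(outdir / "alignment.fasta", "w") as fh:
        for rid, row in aln.sequences:
            fh.write(f">{rid}\n{row}\n")
    truth_json = {
        "mode": truth["mode"].tolist(),
        "states": truth["states"],
        "sigma": truth["sigma"],
        "pocket_residues": list(spec.pocket_residues),
        "probe_present": present.tolist(),
        "amplitude": spec.amplitude,
        "seed": spec.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth_json))
    return {"manifest": manifest, "coordinate_set": cs, "truth": truth_json}
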