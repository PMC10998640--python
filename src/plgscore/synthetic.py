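"""Synthetic protein pockets, ligands and decoy pose sets.

Generates small but structurally plausible protein-ligand complexes so
the whole pipeline — parsing, featurization, training, evaluation — is
exercisable without external structure databases:

* receptors: residues placed on an ideal alpha-helical curve (rise
  1.5 A, 100 degrees per residue, CA radius 2.3 A, giving consecutive
  CA-CA distances of ~3.8 A) with backbone N, CA, C, O and template side
  chains pointing outward from the helix axis;
* ligands: small heavy-atom topologies from a template set (including a
  six-membered aromatic ring whose 12-fold graph symmetry exercises the
  symmetry-corrected RMSD), positioned against the helix so that every
  heavy atom sits well within contact distance of the pocket;
* decoys: random rigid perturbations (bounded rotation about the ligand
  center plus bounded translation) combined with center-preserving
  per-atom jitter, rescaled by bisection until the symmetry-corrected
  RMSD from the native pose hits a requested target within 0.05 A.

Decoy RMSD targets default to {0, 0.5, 1, 2, 4, 8} A, spanning the
near-native to clearly-misdocked range a docking engine produces, and
native affinities pKd_nat are drawn uniformly from [2, 11] to cover the
realistic span from millimolar to ~10 pM.  Everything is deterministic
under the spec seed, including output file bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Geometry import Point3D
from scipy.spatial.transform import Rotation

from .geometry import automorphisms, symmetry_corrected_rmsd
from .structure_io import (
    Atom,
    LigandPose,
    ProteinStructure,
    Residue,
    _mol_to_topology,
)

__all__ = [
    "FixtureSpec",
    "LIGAND_TEMPLATES",
    "make_toy_protein",
    "make_toy_ligand",
    "write_pdb",
    "write_sdf",
    "perturb_pose_to_rmsd",
    "generate_dataset",
]

DEFAULT_RMSD_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of one synthetic dataset."""

    n_complexes: int = 5
    n_residues: int = 10
    residue_names: tuple[str, ...] | None = None  # None: random draw per complex
    ligand_template: str = "ring6_tail"
    target_rmsds: tuple[float, ...] = DEFAULT_RMSD_GRID
    pkd_range: tuple[float, float] = (2.0, 11.0)
    seed: int = 0

    @property
    def n_poses(self) -> int:
        return len(self.target_rmsds)


# ---------------------------------------------------------------------------
# receptor generation

_HELIX_RISE = 1.5
_HELIX_TWIST = math.radians(100.0)
_HELIX_RADIUS = 2.3

# side-chain atoms in the residue-local frame (out = radial, t = helix tangent)
_SIDE_CHAINS: dict[str, list[tuple[str, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", 1.5, 0.0)],
    "SER": [("CB", 1.5, 0.0), ("OG", 2.9, 0.3)],
    "THR": [("CB", 1.5, 0.0), ("OG1", 2.6, 0.7), ("CG2", 2.6, -0.7)],
    "LEU": [("CB", 1.5, 0.0), ("CG", 2.8, 0.0), ("CD1", 3.9, 0.7), ("CD2", 3.9, -0.7)],
    "ASP": [("CB", 1.5, 0.0), ("CG", 2.8, 0.0), ("OD1", 3.7, 0.7), ("OD2", 3.7, -0.7)],
    "LYS": [("CB", 1.5, 0.0), ("CG", 2.8, 0.0), ("CD", 4.0, 0.0), ("CE", 5.3, 0.0), ("NZ", 6.5, 0.0)],
    "PHE": [
        ("CB", 1.5, 0.0), ("CG", 2.9, 0.0),
        ("CD1", 3.6, 1.2), ("CD2", 3.6, -1.2),
        ("CE1", 5.0, 1.2), ("CE2", 5.0, -1.2),
        ("CZ", 5.7, 0.0),
    ],
}

_TEMPLATE_RESIDUE_POOL = tuple(_SIDE_CHAINS)


def make_toy_protein(
    n_residues: int,
    residue_names: tuple[str, ...] | None = None,
    seed: int | np.random.Generator = 0,
    chain: str = "A",
) -> ProteinStructure:
    """Residues on an ideal helix with backbone + template side chains."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if residue_names is None:
        residue_names = tuple(rng.choice(_TEMPLATE_RESIDUE_POOL, size=n_residues))
    if len(residue_names) != n_residues:
        raise ValueError("residue_names length must equal n_residues")

    residues: list[Residue] = []
    serial = 1
    for i, name in enumerate(residue_names):
        phi = i * _HELIX_TWIST
        ca = np.array(
            [_HELIX_RADIUS * math.cos(phi), _HELIX_RADIUS * math.sin(phi), i * _HELIX_RISE]
        )
        out = np.array([math.cos(phi), math.sin(phi), 0.0])
        # helix tangent at the CA
        t = np.array(
            [-_HELIX_RADIUS * _HELIX_TWIST * math.sin(phi),
             _HELIX_RADIUS * _HELIX_TWIST * math.cos(phi),
             _HELIX_RISE]
        )
        t /= np.linalg.norm(t)
        up = np.cross(out, t)

        atoms = [
            Atom("N", "N", serial, ca - 1.2 * t - 0.5 * out),
            Atom("C", "CA", serial + 1, ca),
            Atom("C", "C", serial + 2, ca + 1.2 * t - 0.5 * out),
            Atom("O", "O", serial + 3, ca + 1.2 * t - 0.5 * out + 1.23 * up),
        ]
        serial += 4
        for atom_name, d_out, d_t in _SIDE_CHAINS[name]:
            coords = ca + d_out * out + d_t * t
            atoms.append(Atom(atom_name[0], atom_name, serial, coords))
            serial += 1
        residues.append(Residue(name=name, chain=chain, seq=i + 1, atoms=atoms))
    return ProteinStructure(residues=residues, source="synthetic", model=1)


def write_pdb(protein: ProteinStructure, path) -> None:
    """Write fixed-width PDB ATOM records (deterministic bytes)."""
    lines = ["MODEL     1"]
    for res in protein.residues:
        for atom in res.atoms:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {atom.serial:5d} {name}{'':1s}{res.name:>3s} {res.chain:1s}"
                f"{res.seq:4d}{res.icode:1s}   "
                f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
            )
    lines += ["ENDMDL", "END", ""]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# ligand generation

def _hexagon(radius: float = 1.39) -> np.ndarray:
    ang = np.arange(6) * math.pi / 3.0
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)


def _template_mol(name: str) -> Chem.Mol:
    mol = Chem.RWMol()
    conf_coords: np.ndarray
    if name == "chain3":
        for sym in ("C", "O", "N"):
            mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(0, 1, Chem.BondType.SINGLE)
        mol.AddBond(1, 2, Chem.BondType.SINGLE)
        conf_coords = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [2.1, 1.2, 0.0]])
    elif name == "branch5":
        for sym in ("C", "C", "N", "O", "C"):
            mol.AddAtom(Chem.Atom(sym))
        for j in (1, 2, 3, 4):
            mol.AddBond(0, j, Chem.BondType.SINGLE)
        conf_coords = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.45, 0.0, 0.0],
                [-0.6, 1.3, 0.0],
                [-0.6, -0.7, 1.15],
                [-0.6, -0.7, -1.15],
            ]
        )
    elif name in ("ring6", "ring6_tail"):
        for _ in range(6):
            a = Chem.Atom("C")
            a.SetIsAromatic(True)
            mol.AddAtom(a)
        for j in range(6):
            b = mol.AddBond(j, (j + 1) % 6, Chem.BondType.AROMATIC) - 1
            mol.GetBondWithIdx(b).SetIsAromatic(True)
        conf_coords = _hexagon()
        if name == "ring6_tail":
            mol.AddAtom(Chem.Atom("C"))
            mol.AddAtom(Chem.Atom("O"))
            mol.AddBond(0, 6, Chem.BondType.SINGLE)
            mol.AddBond(6, 7, Chem.BondType.SINGLE)
            tail = np.array([[2.9, 0.0, 0.6], [3.6, 1.2, 0.6]])
            conf_coords = np.concatenate([conf_coords, tail])
    else:
        raise ValueError(f"unknown ligand template {name!r}")
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    conf = Chem.Conformer(m.GetNumAtoms())
    for i, (x, y, z) in enumerate(conf_coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    m.AddConformer(conf)
    return m


LIGAND_TEMPLATES = ("chain3", "branch5", "ring6", "ring6_tail")


def make_toy_ligand(
    template: str = "ring6", center: np.ndarray | None = None, pose_id: str = "native"
) -> LigandPose:
    """Ligand pose from a named template, optionally recentered."""
    mol = _template_mol(template)
    conf = mol.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    if center is not None:
        coords = coords - coords.mean(axis=0) + np.asarray(center, dtype=float)
    return LigandPose(topology=_mol_to_topology(mol), coords=coords, pose_id=pose_id)


def write_sdf(poses: list[LigandPose], path, template: str) -> None:
    """Write poses as a multi-record SDF sharing one topology."""
    mol = _template_mol(template)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for pose in poses:
        conf = mol.GetConformer()
        for i, (x, y, z) in enumerate(pose.coords):
            conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        mol.SetProp("_Name", pose.pose_id)
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# decoy construction

def perturb_pose_to_rmsd(
    pose: LigandPose,
    target_rmsd: float,
    seed: int | np.random.Generator = 0,
    tol: float = 0.02,
    max_translation: float = 3.0,
    max_angle_deg: float = 60.0,
    pose_id: str | None = None,
) -> LigandPose:
    """Perturb a pose until its symmetry-corrected RMSD hits the target.

    One random rigid motion (rotation about the ligand center, saturating
    at `max_angle_deg`, plus translation saturating at `max_translation`)
    and one center-preserving per-atom jitter draw are scaled by a common
    magnitude found by bisection.  The translation/rotation caps keep the
    decoy inside the pocket, so arbitrarily large targets are reached
    through jitter.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be >= 0")
    if target_rmsd == 0:
        return pose.with_coords(pose.coords.copy(), pose_id or f"{pose.pose_id}_rmsd0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    autos = automorphisms(pose.topology)
    coords0 = pose.coords
    center = pose.center
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    t_dir = rng.normal(size=3)
    t_dir /= np.linalg.norm(t_dir)
    jitter = rng.normal(size=coords0.shape)
    jitter -= jitter.mean(axis=0)

    def candidate(m: float) -> LigandPose:
        angle = math.radians(max_angle_deg) * min(m, 1.0)
        R = Rotation.from_rotvec(angle * axis).as_matrix()
        x = (coords0 - center) @ R.T + center
        x = x + t_dir * min(1.5 * m, max_translation)
        x = x + jitter * (0.5 * m)
        return pose.with_coords(x, pose_id or f"{pose.pose_id}_p")

    def achieved(m: float) -> float:
        return symmetry_corrected_rmsd(candidate(m), pose, autos)

    hi = 1.0
    while achieved(hi) < target_rmsd and hi < 1e4:
        hi *= 2.0
    lo = 0.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val = achieved(mid)
        if abs(val - target_rmsd) <= tol:
            lo = hi = mid
            break
        if val < target_rmsd:
            lo = mid
        else:
            hi = mid
    final = 0.5 * (lo + hi)
    return candidate(final)


# ---------------------------------------------------------------------------
# dataset assembly

def generate_dataset(spec: FixtureSpec, out_dir) -> Path:
    """Emit complexes (receptor PDB, reference SDF, pose SDF) plus a manifest.

    Per complex: a native pose (rmsd_real = 0, pose index 0) and one decoy
    per entry of ``spec.target_rmsds`` beyond the first if it is 0, each
    with its achieved symmetry-corrected RMSD recorded.  pKd_nat is drawn
    once per complex.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for c in range(spec.n_complexes):
        name = f"complex_{c:03d}"
        cdir = out_dir / name
        cdir.mkdir(exist_ok=True)
        n_res = spec.n_residues
        protein = make_toy_protein(n_res, spec.residue_names, seed=rng)
        write_pdb(protein, cdir / "receptor.pdb")

        z_mid = 0.5 * (n_res - 1) * _HELIX_RISE
        lig_center = np.array([_HELIX_RADIUS + 2.2, 0.0, z_mid])
        native = make_toy_ligand(spec.ligand_template, center=lig_center, pose_id=f"{name}:native")
        write_sdf([native], cdir / "ref.sdf", spec.ligand_template)

        autos = automorphisms(native.topology)
        pkd_nat = float(rng.uniform(*spec.pkd_range))
        poses = []
        rmsds = []
        for k, target in enumerate(spec.target_rmsds):
            decoy = perturb_pose_to_rmsd(
                native, target, seed=rng, pose_id=f"{name}:pose{k}"
            )
            poses.append(decoy)
            rmsds.append(symmetry_corrected_rmsd(decoy, native, autos))
        write_sdf(poses, cdir / "poses.sdf", spec.ligand_template)
        for k, rmsd in enumerate(rmsds):
            rows.append(
                {
                    "sample_id": f"{name}_pose{k}",
                    "receptor_path": f"{name}/receptor.pdb",
                    "ref_ligand_path": f"{name}/ref.sdf",
                    "pose_path": f"{name}/poses.sdf",
                    "pose_index": k,
                    "pkd_nat": round(pkd_nat, 4),
                    "rmsd_real": round(rmsd, 4),
                }
            )
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path
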