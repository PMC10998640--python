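"""Receptor/ligand file parsing and tabular manifests.

PDB receptors are read through gemmi, ligand poses (SDF / MOL2) through
RDKit.  Everything downstream of this module works on plain dataclasses
holding NumPy coordinate arrays, so the rest of the package never touches
a file-format library directly.

Conventions fixed here:

* coordinates are Angstrom throughout, no unit conversion anywhere;
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by altloc identifier, so 'A' wins);
* hydrogens are parsed and kept in the ligand topology, but every graph
  and RMSD downstream operates on the heavy-atom view;
* waters and hetero groups are excluded from receptors unless requested.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "LigandAtom",
    "LigandBond",
    "LigandTopology",
    "LigandPose",
    "ManifestRow",
    "DatasetManifest",
    "SkipReport",
    "ParseError",
    "SchemaError",
    "EmptyStructureError",
    "MAIN_CHAIN_ATOMS",
    "read_protein",
    "read_ligand",
    "read_ligand_poses",
    "read_manifest",
    "write_scores",
    "read_scores",
    "SCORE_COLUMNS",
]

MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

SCORE_COLUMNS = ["sample_id", "pose_id", "rmsd_pred", "pkd_pred", "W"]

MANIFEST_COLUMNS = [
    "sample_id",
    "receptor_path",
    "ref_ligand_path",
    "pose_path",
    "pose_index",
    "pkd_nat",
    "rmsd_real",
]


class ParseError(ValueError):
    """Unreadable or structurally invalid input file."""


class SchemaError(ValueError):
    """Tabular input is missing a mandatory column."""


class EmptyStructureError(ParseError):
    """A structure file contained no usable residues/atoms."""


# ---------------------------------------------------------------------------
# receptor model


@dataclass
class Atom:
    element: str
    name: str
    serial: int
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")

    @property
    def is_main_chain(self) -> bool:
        return self.name in MAIN_CHAIN_ATOMS

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name: str
    chain: str
    seq: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq, self.icode)

    @property
    def alpha_carbon(self) -> Atom | None:
        for atom in self.atoms:
            if atom.name == "CA" and not atom.is_hydrogen:
                return atom
        return None

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def main_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_main_chain and not a.is_hydrogen]

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_main_chain and not a.is_hydrogen]


@dataclass
class ProteinStructure:
    residues: list[Residue]
    source: str = ""
    model: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyStructureError(f"{self.source or 'structure'}: no residues")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ParseError(f"{self.source}: duplicate residue identifiers")

    def __len__(self) -> int:
        return len(self.residues)

    def iter_heavy_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.heavy_atoms():
                yield res, atom

    def heavy_coords(self) -> np.ndarray:
        return np.array(
            [a.coords for _, a in self.iter_heavy_atoms()], dtype=float
        ).reshape(-1, 3)


# ---------------------------------------------------------------------------
# ligand model


@dataclass(frozen=True)
class LigandAtom:
    element: str
    aromatic: bool = False
    formal_charge: int = 0


@dataclass(frozen=True)
class LigandBond:
    i: int
    j: int
    order: str  # single | double | triple | aromatic
    in_ring: bool = False
    conjugated: bool = False

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-bond")
        if self.order not in ("single", "double", "triple", "aromatic"):
            raise ValueError(f"unknown bond order {self.order!r}")


@dataclass
class LigandTopology:
    atoms: list[LigandAtom]
    bonds: list[LigandBond]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[frozenset[int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) has out-of-range endpoint")
            key = frozenset((b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond ({b.i},{b.j})")
            seen.add(key)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element not in ("H", "D")]

    @property
    def heavy_elements(self) -> list[str]:
        return [self.atoms[i].element for i in self.heavy_indices]

    def heavy_bonds(self) -> list[LigandBond]:
        remap = {orig: k for k, orig in enumerate(self.heavy_indices)}
        out = []
        for b in self.bonds:
            if b.i in remap and b.j in remap:
                out.append(
                    LigandBond(remap[b.i], remap[b.j], b.order, b.in_ring, b.conjugated)
                )
        return out

    def heavy_bond_keys(self) -> list[tuple[int, int, tuple]]:
        """(i, j, bond-type key) triples over heavy-atom indexing."""
        return [
            (b.i, b.j, (b.order, b.in_ring, b.conjugated)) for b in self.heavy_bonds()
        ]


@dataclass
class LigandPose:
    topology: LigandTopology
    coords: np.ndarray
    pose_id: str = "pose0"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] != len(self.topology.atoms):
            raise ValueError(
                f"{self.pose_id}: {self.coords.shape[0]} coordinates for "
                f"{len(self.topology.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.pose_id}: non-finite coordinates")

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.topology.heavy_indices]

    @property
    def center(self) -> np.ndarray:
        """Geometric center P: unweighted mean of heavy-atom coordinates."""
        return self.heavy_coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray, pose_id: str | None = None) -> "LigandPose":
        return LigandPose(self.topology, coords, pose_id or self.pose_id)


@dataclass(frozen=True)
class SkipReport:
    path: str
    record_index: int
    reason: str


# ---------------------------------------------------------------------------
# receptor parsing


def _resolve_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to lowest altloc."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in raw_atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif (atom.occupancy, _altloc_rank(atom.altloc)) > (
            prev.occupancy,
            _altloc_rank(prev.altloc),
        ):
            by_name[atom.name] = atom
    return [by_name[n] for n in order]


def _altloc_rank(altloc: str) -> float:
    # higher rank wins a tie; '' and 'A' beat 'B', 'C', ...
    if altloc in ("", " ", "A"):
        return 0.0
    return -float(ord(altloc[0]))


def read_protein(
    path: str | os.PathLike,
    model_selector: int | None = None,
    include_hetero: bool = False,
    include_waters: bool = False,
) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    Selects one MODEL (the first by default), resolves altlocs to the
    highest-occupancy conformer, and drops waters/hetero groups unless
    requested.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    if model_selector is None:
        model = st[0]
    else:
        matches = [m for m in st if m.num == model_selector]
        if not matches:
            raise ParseError(f"{path}: no MODEL {model_selector}")
        model = matches[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.is_water() and not include_waters:
                continue
            if res.het_flag == "H" and not res.is_water() and not include_hetero:
                continue
            raw = [
                Atom(
                    element=at.element.name,
                    name=at.name,
                    serial=at.serial,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    altloc=at.altloc if at.altloc else "",
                )
                for at in res
            ]
            residues.append(
                Residue(
                    name=res.name,
                    chain=chain.name,
                    seq=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    atoms=_resolve_altlocs(raw),
                )
            )
    if not residues:
        raise EmptyStructureError(f"{path}: model {model.num} holds no usable residues")
    return ProteinStructure(residues=residues, source=str(path), model=model.num)


# ---------------------------------------------------------------------------
# ligand parsing

_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


def _mol_to_topology(mol: Chem.Mol) -> LigandTopology:
    atoms = [
        LigandAtom(
            element=a.GetSymbol(),
            aromatic=a.GetIsAromatic(),
            formal_charge=a.GetFormalCharge(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = _BOND_ORDER.get(b.GetBondType())
        if order is None:
            # unusual orders (dative etc.) degrade to single
            order = "single"
        bonds.append(
            LigandBond(
                i=b.GetBeginAtomIdx(),
                j=b.GetEndAtomIdx(),
                order=order,
                in_ring=b.IsInRing(),
                conjugated=b.GetIsConjugated(),
            )
        )
    return LigandTopology(atoms=atoms, bonds=bonds)


def _mol_to_pose(mol: Chem.Mol, pose_id: str) -> LigandPose:
    conf = mol.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    return LigandPose(topology=_mol_to_topology(mol), coords=coords, pose_id=pose_id)


def read_ligand_poses(
    path: str | os.PathLike, fmt: str | None = None
) -> tuple[list[LigandPose], list[SkipReport]]:
    """Read all records of an SDF (or a MOL2) file.

    Unparseable records are skipped and reported rather than aborting the
    whole file, mirroring standard practice when digesting docking output.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    poses: list[LigandPose] = []
    skips: list[SkipReport] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for k, mol in enumerate(supplier):
            if mol is None:
                skips.append(SkipReport(str(path), k, "rdkit failed to parse record"))
                continue
            name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            try:
                poses.append(_mol_to_pose(mol, pose_id=name or f"{path.stem}:{k}"))
            except ValueError as exc:
                skips.append(SkipReport(str(path), k, str(exc)))
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=True)
        if mol is None:
            skips.append(SkipReport(str(path), 0, "rdkit failed to parse mol2"))
        else:
            poses.append(_mol_to_pose(mol, pose_id=f"{path.stem}:0"))
    else:
        raise ParseError(f"{path}: unsupported ligand format {fmt!r}")
    if not poses and not skips:
        raise EmptyStructureError(f"{path}: no ligand records")
    return poses, skips


def read_ligand(
    path: str | os.PathLike, fmt: str | None = None, pose_index: int = 0
) -> LigandPose:
    """Read one conformer record of a ligand file."""
    poses, skips = read_ligand_poses(path, fmt=fmt)
    if pose_index >= len(poses):
        detail = f"; {len(skips)} records skipped" if skips else ""
        raise ParseError(
            f"{path}: pose_index {pose_index} out of range ({len(poses)} poses{detail})"
        )
    return poses[pose_index]


# ---------------------------------------------------------------------------
# manifests and score tables


@dataclass
class ManifestRow:
    sample_id: str
    receptor_path: str
    ref_ligand_path: str
    pose_path: str
    pose_index: int = 0
    pkd_nat: float | None = None
    rmsd_real: float | None = None
    resolved: bool = True

    @property
    def has_affinity(self) -> bool:
        return self.pkd_nat is not None and np.isfinite(self.pkd_nat)


@dataclass
class DatasetManifest:
    rows: list[ManifestRow]
    source: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def read_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Load a TSV manifest; relative paths resolve against the manifest directory.

    Rows pointing at missing files are kept but flagged ``resolved=False``
    so callers can decide whether to fail or skip.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in MANIFEST_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest missing mandatory column(s) {missing}")
    base = path.parent
    rows: list[ManifestRow] = []
    for rec in df.to_dict("records"):
        def _resolve(p: str) -> tuple[str, bool]:
            q = Path(p)
            if not q.is_absolute():
                q = base / q
            return str(q), q.exists()

        receptor, ok_r = _resolve(rec["receptor_path"])
        ref, ok_f = _resolve(rec["ref_ligand_path"])
        pose, ok_p = _resolve(rec["pose_path"])
        pkd = rec.get("pkd_nat")
        rmsd = rec.get("rmsd_real")
        rows.append(
            ManifestRow(
                sample_id=str(rec["sample_id"]),
                receptor_path=receptor,
                ref_ligand_path=ref,
                pose_path=pose,
                pose_index=int(rec["pose_index"]),
                pkd_nat=None if pd.isna(pkd) else float(pkd),
                rmsd_real=None if pd.isna(rmsd) else float(rmsd),
                resolved=ok_r and ok_f and ok_p,
            )
        )
    return DatasetManifest(rows=rows, source=str(path))


def write_scores(records: Sequence[dict], path: str | os.PathLike) -> None:
    """Write per-pose predictions as TSV with fixed column order.

    Numeric fields are serialized with 6 decimal places so that a write /
    read cycle is lossless at that precision.
    """
    df = pd.DataFrame(list(records))
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"score records missing column(s) {missing}")
    df = df[SCORE_COLUMNS + [c for c in df.columns if c not in SCORE_COLUMNS]]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scores(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pose_id": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: score table missing column(s) {missing}")
    return df
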