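"""Two-graph featurization of a protein-ligand complex.

A scored pose is represented by two graphs:

* a residue-level **pocket graph**: one node per binding-site residue
  (residues with any atom closer than 8 A to the reference ligand), with
  undirected edges between residues whose minimum inter-atomic distance
  is below 10 A.  Node features describe residue identity, internal
  geometry and position relative to the pocket center; edge features are
  main-chain atom distances.

* an atom-level heterogeneous **interaction graph** over protein heavy
  atoms within 8 A of the reference ligand (V_R) and ligand heavy atoms
  (V_L), with four directed message channels: intra-protein edges below
  5 A (feature: length), intra-ligand covalent-bond edges (features:
  bond order one-hot, ring/conjugation flags, length), and bidirectional
  protein-ligand cross edges below 8 A.  Each cross edge between protein
  atom R (in a residue with alpha carbon Ca) and ligand atom L (ligand
  geometric center P) carries the orientation features

      [sin(phi/2), cos(theta1/2), cos(theta2/2), d(R, L)]

  where theta1 is the angle at R between Ca-R and L-R, theta2 the angle
  at L between P-L and R-L, and phi the signed dihedral Ca-R-L-P.  The
  same 4-vector sits on both edge directions.

All cutoff comparisons are strict ``<``.  The reference defining the
pocket is the co-crystal ligand in ``native_ref`` mode and the scored
pose itself in ``self_ref`` mode.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    angle_at_vertex,
    dihedral,
    distance,
    geometric_center,
)
from .structure_io import LigandPose, ProteinStructure, Residue

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "InteractionGraph",
    "PocketGraph",
    "NoPocketError",
    "select_pocket_residues",
    "ligand_atom_class",
    "protein_atom_class",
    "protein_node_features",
    "ligand_node_features",
    "cross_edge_features",
    "build_interaction_graph",
    "build_pocket_graph",
    "featurize_complex",
    "save_graphs",
    "load_graphs",
    "LIGAND_CLASSES",
    "PROTEIN_CLASSES",
    "STANDARD_RESIDUES",
]


class NoPocketError(ValueError):
    """No residue/atom fell inside the pocket cutoff."""


STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

LIGAND_CLASSES = ("C", "N", "O", "P", "S", "Hal", "DU")
_HALOGENS = frozenset({"F", "Cl", "Br", "I"})

_PROTEIN_ELEMENTS = ("C", "N", "O", "S")

# RES-{MC|SC}-{ELEM} over 20 residues, plus a single OTHER bucket.
PROTEIN_CLASSES: tuple[str, ...] = tuple(
    f"{res}-{loc}-{el}"
    for res in STANDARD_RESIDUES
    for loc in ("MC", "SC")
    for el in _PROTEIN_ELEMENTS
) + ("OTHER",)
_PROTEIN_CLASS_INDEX = {c: k for k, c in enumerate(PROTEIN_CLASSES)}

# side-chain ring atoms carrying the aromatic flag
_AROMATIC_ATOMS = {
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
}

# template formal charges at physiological protonation; the charge of a
# charged group is flagged on each member atom
_CHARGED_ATOMS = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 1.0,
    ("ARG", "NH2"): 1.0,
    ("ASP", "OD1"): -1.0,
    ("ASP", "OD2"): -1.0,
    ("GLU", "OE1"): -1.0,
    ("GLU", "OE2"): -1.0,
}

_BOND_ORDERS = ("single", "double", "triple", "aromatic")


@dataclass(frozen=True)
class FeatureConfig:
    """Cutoffs (A) and modes of the two-graph featurization."""

    pocket_cutoff: float = 8.0        # residue inclusion around the reference
    rec_atom_cutoff: float = 8.0      # V_R atom inclusion around the reference
    rec_rec_cutoff: float = 5.0       # intra-protein edges
    cross_cutoff: float = 8.0         # protein-ligand edges
    pocket_edge_cutoff: float = 10.0  # residue-residue edges
    pocket_mode: str = "native_ref"   # native_ref | self_ref
    degenerate_angle_fill: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "pocket_cutoff",
            "rec_atom_cutoff",
            "rec_rec_cutoff",
            "cross_cutoff",
            "pocket_edge_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pocket_mode not in ("native_ref", "self_ref"):
            raise ValueError(f"unknown pocket_mode {self.pocket_mode!r}")

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class InteractionGraph:
    """Atom-level heterogeneous graph of one pose against the pocket."""

    rec_feats: np.ndarray   # (Nr, 164)
    lig_feats: np.ndarray   # (Nl, 9)
    edges_rr: np.ndarray    # (2, Err) directed, both orientations present
    feats_rr: np.ndarray    # (Err, 1)
    edges_ll: np.ndarray    # (2, Ell) directed, both orientations present
    feats_ll: np.ndarray    # (Ell, 7)
    edges_rl: np.ndarray    # (2, Ec) rows: (rec src, lig dst)
    edges_lr: np.ndarray    # (2, Ec) rows: (lig src, rec dst), mirror order
    feats_cross: np.ndarray  # (Ec, 4) shared by both directions
    rec_labels: list[str]    # protein-atom class label per V_R node
    rec_atom_ids: list[tuple] = field(default_factory=list)  # (chain, seq, icode, atom name)
    lig_atom_ids: list[int] = field(default_factory=list)    # heavy-atom index in the pose
    fingerprint: str = ""

    @property
    def n_rec(self) -> int:
        return self.rec_feats.shape[0]

    @property
    def n_lig(self) -> int:
        return self.lig_feats.shape[0]

    @property
    def n_cross(self) -> int:
        return self.feats_cross.shape[0]


@dataclass
class PocketGraph:
    """Residue-level undirected graph of the binding pocket."""

    node_feats: np.ndarray  # (Np, 29)
    edges: np.ndarray       # (2, Ep) directed, both orientations present
    edge_feats: np.ndarray  # (Ep, 4)
    residue_ids: list[tuple] = field(default_factory=list)
    fingerprint: str = ""

    @property
    def n_nodes(self) -> int:
        return self.node_feats.shape[0]


# ---------------------------------------------------------------------------
# atom classing


def ligand_atom_class(element: str) -> str:
    """7-way ligand element class: C, N, O, P, S, Hal or DU."""
    if element in ("C", "N", "O", "P", "S"):
        return element
    if element in _HALOGENS:
        return "Hal"
    return "DU"


def protein_atom_class(residue_name: str, atom_name: str, element: str) -> tuple[str, int]:
    """Protein atom class ``RES-{MC|SC}-{ELEM}`` and its one-hot index.

    Non-standard residues and elements outside {C, N, O, S} land in the
    OTHER bucket.
    """
    loc = "MC" if atom_name in ("N", "CA", "C", "O", "OXT") else "SC"
    if residue_name in STANDARD_RESIDUES and element in _PROTEIN_ELEMENTS:
        label = f"{residue_name}-{loc}-{element}"
    else:
        label = "OTHER"
    return label, _PROTEIN_CLASS_INDEX[label]


def protein_node_features(atom, residue: Residue) -> np.ndarray:
    """Feature row of a protein heavy-atom node.

    ``[class one-hot (161), aromatic flag, template charge, distance to CA]``.
    Residues without an alpha carbon fall back to distance 0.
    """
    label, idx = protein_atom_class(residue.name, atom.name, atom.element)
    row = np.zeros(len(PROTEIN_CLASSES) + 3)
    row[idx] = 1.0
    if atom.name in _AROMATIC_ATOMS.get(residue.name, ()):
        row[-3] = 1.0
    row[-2] = _CHARGED_ATOMS.get((residue.name, atom.name), 0.0)
    ca = residue.alpha_carbon
    if ca is None:
        logger.debug("residue %s lacks CA; distance feature set to 0", residue.key)
        row[-1] = 0.0
    else:
        row[-1] = distance(atom.coords, ca.coords)
    return row


def ligand_node_features(topology) -> np.ndarray:
    """(Nl, 9) rows ``[class one-hot (7), aromatic flag, formal charge]``."""
    heavy = [topology.atoms[i] for i in topology.heavy_indices]
    rows = np.zeros((len(heavy), len(LIGAND_CLASSES) + 2))
    for k, atom in enumerate(heavy):
        rows[k, LIGAND_CLASSES.index(ligand_atom_class(atom.element))] = 1.0
        rows[k, -2] = 1.0 if atom.aromatic else 0.0
        rows[k, -1] = float(atom.formal_charge)
    return rows


# ---------------------------------------------------------------------------
# pocket selection


def select_pocket_residues(
    protein: ProteinStructure,
    reference_coords: np.ndarray,
    cutoff: float = 8.0,
) -> list[int]:
    """Indices of residues with any heavy atom strictly closer than `cutoff`
    to any reference-ligand atom."""
    ref = np.asarray(reference_coords, dtype=float).reshape(-1, 3)
    if ref.shape[0] == 0:
        raise ValueError("empty reference coordinates")
    selected = []
    for idx, res in enumerate(protein.residues):
        atoms = res.heavy_atoms()
        if not atoms:
            continue
        coords = np.array([a.coords for a in atoms])
        dmin = np.sqrt(((coords[:, None, :] - ref[None, :, :]) ** 2).sum(-1)).min()
        if dmin < cutoff:
            selected.append(idx)
    if not selected:
        raise NoPocketError(f"no residue within {cutoff} A of the reference ligand")
    return selected


# ---------------------------------------------------------------------------
# interaction graph


def cross_edge_features(
    rec_coord: np.ndarray,
    lig_coord: np.ndarray,
    ligand_center: np.ndarray,
    residue_ca: np.ndarray | None,
    fill: float = 0.0,
) -> np.ndarray:
    """Orientation features ``[sin(phi/2), cos(theta1/2), cos(theta2/2), d]``.

    Degenerate frames (missing CA, atom coincident with a reference point,
    collinear torsion frame) fill the affected trigonometric entries with
    `fill`; the distance is always exact.
    """
    d = distance(rec_coord, lig_coord)
    s_phi = c_t1 = c_t2 = fill
    if residue_ca is not None:
        try:
            t1 = angle_at_vertex(residue_ca, rec_coord, lig_coord)
            c_t1 = np.cos(np.radians(t1 / 2.0))
        except DegenerateGeometryError:
            pass
        try:
            phi = dihedral(residue_ca, rec_coord, lig_coord, ligand_center)
            s_phi = np.sin(np.radians(phi / 2.0))
        except DegenerateGeometryError:
            pass
    try:
        t2 = angle_at_vertex(ligand_center, lig_coord, rec_coord)
        c_t2 = np.cos(np.radians(t2 / 2.0))
    except DegenerateGeometryError:
        pass
    return np.array([s_phi, c_t1, c_t2, d])


def _bidirect(edges: list[tuple[int, int]]) -> np.ndarray:
    """Stack (i, j) and (j, i) orientations of an undirected edge list."""
    if not edges:
        return np.zeros((2, 0), dtype=np.intp)
    e = np.asarray(edges, dtype=np.intp).T
    return np.concatenate([e, e[::-1]], axis=1)


def build_interaction_graph(
    protein: ProteinStructure,
    pose: LigandPose,
    reference_coords: np.ndarray,
    config: FeatureConfig | None = None,
) -> InteractionGraph:
    """Assemble the heterogeneous atom graph for one pose.

    V_R is restricted to protein heavy atoms strictly within
    ``rec_atom_cutoff`` of the reference coordinates; in ``self_ref`` mode
    callers pass the pose's own heavy coordinates as the reference.
    """
    config = config or FeatureConfig()
    lig_coords = pose.heavy_coords
    if lig_coords.shape[0] == 0:
        raise ValueError("ligand pose has no heavy atoms")
    ref = np.asarray(reference_coords, dtype=float).reshape(-1, 3)

    rec_atoms: list = []
    rec_res: list[Residue] = []
    for res in protein.residues:
        for atom in res.heavy_atoms():
            dmin = np.sqrt(((ref - atom.coords) ** 2).sum(-1)).min()
            if dmin < config.rec_atom_cutoff:
                rec_atoms.append(atom)
                rec_res.append(res)
    if not rec_atoms:
        raise NoPocketError(
            f"no protein heavy atom within {config.rec_atom_cutoff} A of the reference"
        )
    rec_coords = np.array([a.coords for a in rec_atoms])
    rec_feats = np.array([protein_node_features(a, r) for a, r in zip(rec_atoms, rec_res)])
    rec_labels = [protein_atom_class(r.name, a.name, a.element)[0] for a, r in zip(rec_atoms, rec_res)]
    rec_ids = [(r.chain, r.seq, r.icode, a.name) for a, r in zip(rec_atoms, rec_res)]

    lig_feats = ligand_node_features(pose.topology)

    # intra-protein edges: pairwise distance strictly below rec_rec_cutoff
    diff = rec_coords[:, None, :] - rec_coords[None, :, :]
    dmat_rr = np.sqrt((diff**2).sum(-1))
    iu, ju = np.triu_indices(len(rec_atoms), k=1)
    mask = dmat_rr[iu, ju] < config.rec_rec_cutoff
    rr_pairs = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    edges_rr = _bidirect(rr_pairs)
    feats_rr = dmat_rr[edges_rr[0], edges_rr[1]].reshape(-1, 1) if edges_rr.size else np.zeros((0, 1))

    # intra-ligand edges: one per covalent bond between heavy atoms
    ll_pairs: list[tuple[int, int]] = []
    ll_rows: list[np.ndarray] = []
    for bond in pose.topology.heavy_bonds():
        row = np.zeros(7)
        row[_BOND_ORDERS.index(bond.order)] = 1.0
        row[4] = 1.0 if bond.in_ring else 0.0
        row[5] = 1.0 if bond.conjugated else 0.0
        row[6] = distance(lig_coords[bond.i], lig_coords[bond.j])
        ll_pairs.append((bond.i, bond.j))
        ll_rows.append(row)
    edges_ll = _bidirect(ll_pairs)
    feats_ll = (
        np.concatenate([np.asarray(ll_rows), np.asarray(ll_rows)], axis=0)
        if ll_rows
        else np.zeros((0, 7))
    )

    # cross edges: directed pairs in both orientations with shared features
    center = geometric_center(lig_coords)
    dmat_rl = np.sqrt(((rec_coords[:, None, :] - lig_coords[None, :, :]) ** 2).sum(-1))
    ri, li = np.nonzero(dmat_rl < config.cross_cutoff)
    feats_cross = np.zeros((len(ri), 4))
    for k, (i, j) in enumerate(zip(ri, li)):
        ca = rec_res[i].alpha_carbon
        feats_cross[k] = cross_edge_features(
            rec_coords[i],
            lig_coords[j],
            center,
            None if ca is None else ca.coords,
            fill=config.degenerate_angle_fill,
        )
    edges_rl = np.stack([ri, li]).astype(np.intp) if len(ri) else np.zeros((2, 0), dtype=np.intp)
    edges_lr = edges_rl[::-1].copy()

    return InteractionGraph(
        rec_feats=rec_feats,
        lig_feats=lig_feats,
        edges_rr=edges_rr,
        feats_rr=feats_rr,
        edges_ll=edges_ll,
        feats_ll=feats_ll,
        edges_rl=edges_rl,
        edges_lr=edges_lr,
        feats_cross=feats_cross,
        rec_labels=rec_labels,
        rec_atom_ids=rec_ids,
        lig_atom_ids=list(pose.topology.heavy_indices),
        fingerprint=config.fingerprint(),
    )


# ---------------------------------------------------------------------------
# pocket graph


def _residue_geometry(res: Residue) -> dict[str, np.ndarray | None]:
    out: dict[str, np.ndarray | None] = {}
    for name in ("CA", "N", "C", "O"):
        atom = res.get_atom(name)
        out[name] = None if atom is None or atom.is_hydrogen else atom.coords
    side = res.side_chain_atoms()
    out["SCC"] = None if not side else np.array([a.coords for a in side]).mean(axis=0)
    return out


def build_pocket_graph(
    protein: ProteinStructure,
    pocket_residues: list[int],
    config: FeatureConfig | None = None,
) -> PocketGraph:
    """Residue-level pocket graph.

    Node features (29): residue-type one-hot (20 + OTHER); internal
    distances CA-N, CA-C, CA-O, CA-sidechain-centroid, N-sidechain-centroid,
    C-sidechain-centroid (0 where an atom or the side chain is absent);
    side-chain presence flag; distance from CA to the pocket center (the
    geometric center of all pocket-residue heavy atoms).  Edge features:
    the four main-chain distances CA-CA, N-N, C-C, O-O.
    """
    config = config or FeatureConfig()
    if not pocket_residues:
        raise NoPocketError("empty pocket residue selection")
    residues = [protein.residues[i] for i in pocket_residues]
    all_heavy = np.concatenate(
        [np.array([a.coords for a in r.heavy_atoms()]).reshape(-1, 3) for r in residues]
    )
    pocket_center = geometric_center(all_heavy)

    geoms = [_residue_geometry(r) for r in residues]
    n = len(residues)
    node_feats = np.zeros((n, len(STANDARD_RESIDUES) + 1 + 6 + 1 + 1))
    for k, (res, g) in enumerate(zip(residues, geoms)):
        if res.name in STANDARD_RESIDUES:
            node_feats[k, STANDARD_RESIDUES.index(res.name)] = 1.0
        else:
            node_feats[k, len(STANDARD_RESIDUES)] = 1.0
        pairs = [("CA", "N"), ("CA", "C"), ("CA", "O"), ("CA", "SCC"), ("N", "SCC"), ("C", "SCC")]
        for m, (a, b) in enumerate(pairs):
            if g[a] is not None and g[b] is not None:
                node_feats[k, 21 + m] = distance(g[a], g[b])
        node_feats[k, 27] = 1.0 if g["SCC"] is not None else 0.0
        if g["CA"] is not None:
            node_feats[k, 28] = distance(g["CA"], pocket_center)

    pairs_sel: list[tuple[int, int]] = []
    rows: list[np.ndarray] = []
    coords_per_res = [np.array([a.coords for a in r.heavy_atoms()]) for r in residues]
    for i in range(n):
        for j in range(i + 1, n):
            dmin = np.sqrt(
                ((coords_per_res[i][:, None, :] - coords_per_res[j][None, :, :]) ** 2).sum(-1)
            ).min()
            if dmin < config.pocket_edge_cutoff:
                row = np.zeros(4)
                for m, name in enumerate(("CA", "N", "C", "O")):
                    gi, gj = geoms[i][name], geoms[j][name]
                    if gi is not None and gj is not None:
                        row[m] = distance(gi, gj)
                pairs_sel.append((i, j))
                rows.append(row)
    edges = _bidirect(pairs_sel)
    edge_feats = (
        np.concatenate([np.asarray(rows), np.asarray(rows)], axis=0)
        if rows
        else np.zeros((0, 4))
    )
    return PocketGraph(
        node_feats=node_feats,
        edges=edges,
        edge_feats=edge_feats,
        residue_ids=[r.key for r in residues],
        fingerprint=config.fingerprint(),
    )


# ---------------------------------------------------------------------------
# one-call featurization + serialization


def featurize_complex(
    protein: ProteinStructure,
    pose: LigandPose,
    reference: LigandPose | None,
    config: FeatureConfig | None = None,
) -> tuple[InteractionGraph, PocketGraph]:
    """Featurize one pose; the reference ligand is mandatory in native_ref mode."""
    config = config or FeatureConfig()
    if config.pocket_mode == "native_ref":
        if reference is None:
            raise ValueError("native_ref mode requires a reference ligand")
        ref_coords = reference.heavy_coords
    else:
        ref_coords = pose.heavy_coords
    graph = build_interaction_graph(protein, pose, ref_coords, config)
    pocket_idx = select_pocket_residues(protein, ref_coords, config.pocket_cutoff)
    pocket = build_pocket_graph(protein, pocket_idx, config)
    return graph, pocket


def save_graphs(path, interaction: InteractionGraph, pocket: PocketGraph) -> None:
    """Serialize both graphs to a single ``.npz`` archive (bit-exact round trip)."""
    meta = {
        "fingerprint": interaction.fingerprint,
        "rec_labels": interaction.rec_labels,
        "rec_atom_ids": [list(t) for t in interaction.rec_atom_ids],
        "lig_atom_ids": interaction.lig_atom_ids,
        "residue_ids": [list(t) for t in pocket.residue_ids],
    }
    np.savez(
        path,
        rec_feats=interaction.rec_feats,
        lig_feats=interaction.lig_feats,
        edges_rr=interaction.edges_rr,
        feats_rr=interaction.feats_rr,
        edges_ll=interaction.edges_ll,
        feats_ll=interaction.feats_ll,
        edges_rl=interaction.edges_rl,
        edges_lr=interaction.edges_lr,
        feats_cross=interaction.feats_cross,
        pocket_node_feats=pocket.node_feats,
        pocket_edges=pocket.edges,
        pocket_edge_feats=pocket.edge_feats,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_graphs(path) -> tuple[InteractionGraph, PocketGraph]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        interaction = InteractionGraph(
            rec_feats=z["rec_feats"],
            lig_feats=z["lig_feats"],
            edges_rr=z["edges_rr"],
            feats_rr=z["feats_rr"],
            edges_ll=z["edges_ll"],
            feats_ll=z["feats_ll"],
            edges_rl=z["edges_rl"],
            edges_lr=z["edges_lr"],
            feats_cross=z["feats_cross"],
            rec_labels=list(meta["rec_labels"]),
            rec_atom_ids=[tuple(t) for t in meta["rec_atom_ids"]],
            lig_atom_ids=list(meta["lig_atom_ids"]),
            fingerprint=meta["fingerprint"],
        )
        pocket = PocketGraph(
            node_feats=z["pocket_node_feats"],
            edges=z["pocket_edges"],
            edge_feats=z["pocket_edge_feats"],
            residue_ids=[tuple(t) for t in meta["residue_ids"]],
            fingerprint=meta["fingerprint"],
        )
    return interaction, pocket
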