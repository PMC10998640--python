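"""Exact geometric primitives for pose evaluation.

Distances, angles, signed dihedrals, rigid transforms, and RMSD between
docking poses.  Poses are compared *in the receptor frame* (no
superposition): docking engines emit coordinates in the crystallographic
frame, so deviation from the native pose is meaningful without fitting.
The symmetry-corrected RMSD minimises the naive RMSD over all graph
automorphisms of the ligand topology, so chemically indistinguishable
atom relabelings (e.g. a benzene ring rotated by one position) do not
inflate the deviation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateGeometryError",
    "RigidTransform",
    "AutomorphismSet",
    "distance",
    "angle_at_vertex",
    "dihedral",
    "geometric_center",
    "naive_rmsd",
    "automorphisms",
    "symmetry_corrected_rmsd",
    "AUTOMORPHISM_CAP",
]

#: Upper bound on automorphisms enumerated before falling back to identity.
AUTOMORPHISM_CAP = 10_000


class DegenerateGeometryError(ValueError):
    """Angle or torsion undefined (zero-length arm or collinear axis frame).

    Callers that featurize decide the fallback value; this module only
    signals the condition.
    """


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation ``R``, translation ``t`` in A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation matrix must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) coordinate array (or a single 3-vector)."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def random(rng: np.random.Generator, max_translation: float = 5.0) -> "RigidTransform":
        """Uniformly random rotation (QR-based) with a random translation."""
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        return RigidTransform(R, t)


@dataclass
class AutomorphismSet:
    """Element- and bond-preserving permutations of ligand heavy atoms.

    ``perms`` is an (m, n) integer array; row k maps atom i -> perms[k, i].
    Always contains the identity.  ``capped`` records that the search was
    truncated and only the identity was kept.
    """

    perms: np.ndarray
    capped: bool = False

    def __post_init__(self) -> None:
        self.perms = np.asarray(self.perms, dtype=np.intp)
        if self.perms.ndim != 2:
            raise ValueError("perms must be a 2-D array")

    def __len__(self) -> int:
        return self.perms.shape[0]

    def __iter__(self):
        return iter(self.perms)


def distance(a, b) -> float:
    """Euclidean distance between two points, in A."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def angle_at_vertex(a, v, b) -> float:
    """Angle in degrees, in [0, 180], between arms (a - v) and (b - v)."""
    u = np.asarray(a, dtype=float) - np.asarray(v, dtype=float)
    w = np.asarray(b, dtype=float) - np.asarray(v, dtype=float)
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < 1e-12 or nw < 1e-12:
        raise DegenerateGeometryError("zero-length arm in angle computation")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking down the p2 -> p3 axis, a clockwise
    rotation of the far bond relative to the near bond is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise DegenerateGeometryError("degenerate torsion axis p2 == p3")
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("collinear points leave torsion undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = math.degrees(math.atan2(y, x))
    # map -180 exactly onto +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def geometric_center(coords) -> np.ndarray:
    """Unweighted mean of a non-empty (n, 3) coordinate set."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("geometric center of an empty point set is undefined")
    return coords.reshape(-1, 3).mean(axis=0)


def naive_rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation of matched coordinates, no superposition."""
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.shape[0] == 0:
        raise ValueError("RMSD of zero atoms is undefined")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _topology_graph(topology) -> nx.Graph:
    """Heavy-atom molecular graph with element node labels and bond-type edge labels."""
    g = nx.Graph()
    for i, elem in enumerate(topology.heavy_elements):
        g.add_node(i, element=elem)
    for i, j, key in topology.heavy_bond_keys():
        g.add_edge(i, j, bond=key)
    return g


def automorphisms(topology, cap: int = AUTOMORPHISM_CAP) -> AutomorphismSet:
    """All heavy-atom permutations preserving element labels and the bond multiset.

    Found by VF2 backtracking search of the molecular graph against itself.
    If more than `cap` permutations exist the search is abandoned and only
    the identity is returned (with a logged warning), mirroring common
    practice for pathological topologies.
    """
    n = len(topology.heavy_elements)
    if n == 0:
        raise ValueError("topology has no heavy atoms")
    g = _topology_graph(topology)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g,
        g,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["bond"] == b["bond"],
    )
    perms: list[np.ndarray] = []
    for mapping in matcher.isomorphisms_iter():
        perm = np.empty(n, dtype=np.intp)
        for src, dst in mapping.items():
            perm[src] = dst
        perms.append(perm)
        if len(perms) > cap:
            logger.warning(
                "automorphism count exceeds cap (%d); falling back to identity only", cap
            )
            return AutomorphismSet(np.arange(n, dtype=np.intp)[None, :], capped=True)
    out = np.stack(perms, axis=0)
    # identity-first canonical order for reproducible iteration
    order = np.lexsort(out.T[::-1])
    return AutomorphismSet(out[order])


def enumerate_automorphisms_bruteforce(topology) -> np.ndarray:
    """Exhaustive permutation filter; oracle for small molecules (n <= 8 realistic)."""
    elements = list(topology.heavy_elements)
    n = len(elements)
    bonds = {}
    for i, j, key in topology.heavy_bond_keys():
        bonds[frozenset((i, j))] = key
    hits = []
    for perm in itertools.permutations(range(n)):
        if any(elements[i] != elements[perm[i]] for i in range(n)):
            continue
        ok = True
        for (pair, key) in bonds.items():
            i, j = tuple(pair)
            if bonds.get(frozenset((perm[i], perm[j]))) != key:
                ok = False
                break
        if ok:
            hits.append(perm)
    out = np.asarray(hits, dtype=np.intp)
    order = np.lexsort(out.T[::-1])
    return out[order]


def symmetry_corrected_rmsd(pose_a, pose_b, autos: AutomorphismSet | None = None) -> float:
    """Minimum naive RMSD over ligand-graph automorphisms.

    `pose_a` supplies the topology when `autos` is not given; both poses
    must share it.  Always <= naive_rmsd of the unpermuted atom order.
    """
    ca = np.asarray(pose_a.heavy_coords, dtype=float)
    cb = np.asarray(pose_b.heavy_coords, dtype=float)
    if ca.shape != cb.shape:
        raise ValueError("poses have different heavy-atom counts")
    if autos is None:
        autos = automorphisms(pose_a.topology)
    diffs = ca[autos.perms] - cb[None, :, :]  # (m, n, 3)
    msd = np.mean(np.sum(diffs**2, axis=2), axis=1)
    return float(np.sqrt(msd.min()))
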