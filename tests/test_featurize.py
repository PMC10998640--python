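import math

import numpy as np
import pytest

from plgscore.featurize import (
    FeatureConfig,
    NoPocketError,
    build_interaction_graph,
    build_pocket_graph,
    cross_edge_features,
    featurize_complex,
    ligand_atom_class,
    load_graphs,
    protein_atom_class,
    protein_node_features,
    save_graphs,
    select_pocket_residues,
    LIGAND_CLASSES,
    PROTEIN_CLASSES,
)
from plgscore.geometry import (
    DegenerateGeometryError,
    RigidTransform,
    angle_at_vertex,
    dihedral,
    distance,
)
from plgscore.structure_io import (
    Atom,
    LigandAtom,
    LigandBond,
    LigandPose,
    LigandTopology,
    ProteinStructure,
    Residue,
)
from plgscore.synthetic import make_toy_ligand, make_toy_protein


def residue_at(name, seq, coords_by_atom):
    atoms = [Atom(n[0], n, i + 1, c) for i, (n, c) in enumerate(coords_by_atom.items())]
    return Residue(name=name, chain="A", seq=seq, atoms=atoms)


def simple_protein(distance_of_cb):
    res = residue_at(
        "ALA",
        1,
        {
            "N": (0, 0, 0),
            "CA": (1.45, 0, 0),
            "C": (2.0, 1.4, 0),
            "O": (1.4, 2.4, 0),
            "CB": (distance_of_cb, 0, 0),
        },
    )
    return ProteinStructure(residues=[res], source="mem")


# ---------------------------------------------------------------------------
# classification and node features


@pytest.mark.parametrize(
    "element,expected",
    [("C", "C"), ("N", "N"), ("O", "O"), ("P", "P"), ("S", "S"),
     ("F", "Hal"), ("Cl", "Hal"), ("Br", "Hal"), ("I", "Hal"),
     ("Fe", "DU"), ("B", "DU"), ("Se", "DU")],
)
def test_ligand_atom_class(element, expected):
    assert ligand_atom_class(element) == expected


@pytest.mark.parametrize(
    "res,atom,element,expected",
    [
        ("LYS", "CA", "C", "LYS-MC-C"),
        ("LYS", "NZ", "N", "LYS-SC-N"),
        ("GLY", "O", "O", "GLY-MC-O"),
        ("CYS", "SG", "S", "CYS-SC-S"),
        ("MSE", "SE", "Se", "OTHER"),
        ("ALA", "CB", "Se", "OTHER"),
    ],
)
def test_protein_atom_class(res, atom, element, expected):
    label, idx = protein_atom_class(res, atom, element)
    assert label == expected
    assert PROTEIN_CLASSES[idx] == expected


def test_protein_node_features_lys_nz():
    res = residue_at("LYS", 1, {"CA": (0, 0, 0), "NZ": (3.0, 0, 0)})
    row = protein_node_features(res.get_atom("NZ"), res)
    assert row.shape == (len(PROTEIN_CLASSES) + 3,)
    _, idx = protein_atom_class("LYS", "NZ", "N")
    assert row[idx] == 1.0 and row.sum() == pytest.approx(1.0 + 0.0 + 1.0 + 3.0)
    assert row[-3] == 0.0      # not aromatic
    assert row[-2] == 1.0      # template charge
    assert row[-1] == pytest.approx(3.0)


def test_protein_node_features_gly_ca_and_phe_cz():
    gly = residue_at("GLY", 1, {"CA": (5, 5, 5)})
    row = protein_node_features(gly.get_atom("CA"), gly)
    assert row[-1] == 0.0  # distance of CA to itself
    phe = residue_at("PHE", 2, {"CA": (0, 0, 0), "CZ": (4.2, 0, 0)})
    row = protein_node_features(phe.get_atom("CZ"), phe)
    assert row[-3] == 1.0  # ring atom


def test_protein_node_features_missing_ca_fallback():
    res = residue_at("SER", 1, {"CB": (1, 0, 0), "OG": (2, 0, 0)})
    row = protein_node_features(res.get_atom("OG"), res)
    assert row[-1] == 0.0


# ---------------------------------------------------------------------------
# pocket selection


def test_pocket_selection_boundaries():
    near = residue_at("ALA", 1, {"CA": (7.9, 0, 0)})
    far = residue_at("ALA", 2, {"CA": (8.1, 0, 0)})
    protein = ProteinStructure(residues=[near, far], source="mem")
    ref = np.zeros((1, 3))
    assert select_pocket_residues(protein, ref, 8.0) == [0]
    with pytest.raises(NoPocketError):
        select_pocket_residues(protein, ref - 100.0, 8.0)


def test_self_ref_mode_changes_pocket(toy_protein, toy_ligand):
    moved = toy_ligand.with_coords(toy_ligand.coords + np.array([0, 0, 20.0]))
    ref_native = toy_ligand.heavy_coords
    ref_self = moved.heavy_coords
    native_sel = select_pocket_residues(toy_protein, ref_native, 8.0)
    # brute-force scan confirms the native selection
    for idx, res in enumerate(toy_protein.residues):
        dmin = min(
            distance(a.coords, r)
            for a in res.heavy_atoms()
            for r in ref_native
        )
        assert (dmin < 8.0) == (idx in native_sel)
    try:
        self_sel = select_pocket_residues(toy_protein, ref_self, 8.0)
    except NoPocketError:
        self_sel = []
    assert self_sel != native_sel


# ---------------------------------------------------------------------------
# cross-edge features


def _place_cross_geometry(phi, theta1, theta2, d):
    """Construct Ca, R, L, P realizing the requested internal coordinates."""
    R = np.zeros(3)
    L = np.array([d, 0.0, 0.0])
    ca_dir = np.array(
        [math.cos(math.radians(theta1)), math.sin(math.radians(theta1)), 0.0]
    )
    Ca = R + 2.0 * ca_dir  # angle at R between Ca-R and L-R = theta1
    # P at angle theta2 from R-L around L, rotated by phi about the R-L axis
    base = np.array(
        [-math.cos(math.radians(theta2)), math.sin(math.radians(theta2)), 0.0]
    )
    rot = RigidTransform(
        np.array(
            [
                [1, 0, 0],
                [0, math.cos(math.radians(phi)), -math.sin(math.radians(phi))],
                [0, math.sin(math.radians(phi)), math.cos(math.radians(phi))],
            ]
        ),
        np.zeros(3),
    )
    P = L + 1.5 * rot.apply(base)
    return Ca, R, L, P


@pytest.mark.parametrize(
    "phi,t1,t2,d,expected",
    [
        (180.0, 90.0, 60.0, 3.0, [1.0, math.cos(math.radians(45)), math.cos(math.radians(30)), 3.0]),
        (0.0, 0.0, 0.0, 2.5, None),  # degenerate: collinear frame -> fill 0 for sin term
    ],
)
def test_cross_edge_feature_trig(phi, t1, t2, d, expected):
    if expected is not None:
        Ca, R, L, P = _place_cross_geometry(phi, t1, t2, d)
        got = cross_edge_features(R, L, P, Ca)
        np.testing.assert_allclose(got, expected, atol=1e-7)
    else:
        # theta1 = theta2 = 0 puts Ca, R, L, P collinear: dihedral undefined,
        # its feature takes the fill value 0 while the cosine terms are exact
        Ca = np.array([2.0, 0, 0])
        R = np.zeros(3)
        L = np.array([d, 0, 0])
        P = np.array([1.0, 0, 0])
        got = cross_edge_features(R, L, P, Ca)
        np.testing.assert_allclose(got, [0.0, 1.0, 1.0, d], atol=1e-7)


def test_cross_edge_features_match_oracle(toy_graphs, toy_protein, toy_ligand):
    """Every stored cross-edge 4-vector equals an independent recomputation."""
    graph, _ = toy_graphs
    lig_coords = toy_ligand.heavy_coords
    P = lig_coords.mean(axis=0)
    rec_atoms = []
    for res in toy_protein.residues:
        for atom in res.heavy_atoms():
            rec_atoms.append((res, atom))
    # reconstruct V_R with the same cutoff rule
    ref = lig_coords
    v_r = [
        (res, atom)
        for res, atom in rec_atoms
        if min(distance(atom.coords, c) for c in ref) < 8.0
    ]
    assert len(v_r) == graph.n_rec
    for k in range(graph.n_cross):
        i, j = graph.edges_rl[0, k], graph.edges_rl[1, k]
        res, atom = v_r[i]
        Rc, Lc = atom.coords, lig_coords[j]
        ca = res.alpha_carbon.coords
        d = distance(Rc, Lc)
        try:
            c_t1 = math.cos(math.radians(angle_at_vertex(ca, Rc, Lc) / 2))
        except DegenerateGeometryError:
            c_t1 = 0.0  # the protein atom is the CA itself
        try:
            c_t2 = math.cos(math.radians(angle_at_vertex(P, Lc, Rc) / 2))
        except DegenerateGeometryError:
            c_t2 = 0.0
        try:
            s_phi = math.sin(math.radians(dihedral(ca, Rc, Lc, P) / 2))
        except DegenerateGeometryError:
            s_phi = 0.0
        expect = [s_phi, c_t1, c_t2, d]
        np.testing.assert_allclose(graph.feats_cross[k], expect, atol=1e-10)
        assert -1.0 <= graph.feats_cross[k, 0] <= 1.0
        assert d < 8.0


# ---------------------------------------------------------------------------
# interaction graph construction


def two_atom_protein(positions):
    residues = []
    for k, pos in enumerate(positions):
        residues.append(residue_at("GLY", k + 1, {"CA": pos}))
    return ProteinStructure(residues=residues, source="mem")


def co_pose(at):
    topo = LigandTopology(
        atoms=[LigandAtom("C"), LigandAtom("O")],
        bonds=[LigandBond(0, 1, "single")],
    )
    return LigandPose(topology=topo, coords=np.array(at), pose_id="co")


def test_cross_cutoff_rule():
    protein = two_atom_protein([(0, 0, 0), (0, 30, 0)])
    pose = co_pose([[7.0, 0, 0], [30.0, 30, 30]])
    g = build_interaction_graph(protein, pose, pose.heavy_coords)
    assert g.n_cross == 1
    assert g.edges_rl.shape == (2, 1) and g.edges_lr.shape == (2, 1)
    # mirror property
    assert g.edges_lr[0, 0] == g.edges_rl[1, 0]
    assert g.edges_lr[1, 0] == g.edges_rl[0, 0]


def test_rr_cutoff_rule():
    pose = co_pose([[0.0, 3, 0], [1.4, 3, 0]])
    near = two_atom_protein([(0, 0, 0), (4.0, 0, 0)])
    g = build_interaction_graph(near, pose, pose.heavy_coords)
    assert g.edges_rr.shape[1] == 2  # one undirected edge, both orientations
    far = two_atom_protein([(0, 0, 0), (5.5, 0, 0)])
    g2 = build_interaction_graph(far, pose, pose.heavy_coords)
    assert g2.edges_rr.shape[1] == 0


def brute_force_counts(protein, pose, ref, cfg):
    rec = [
        a.coords
        for res in protein.residues
        for a in res.heavy_atoms()
        if min(np.linalg.norm(ref - a.coords, axis=1)) < cfg.rec_atom_cutoff
    ]
    lig = pose.heavy_coords
    n_rr = sum(
        1
        for i in range(len(rec))
        for j in range(i + 1, len(rec))
        if distance(rec[i], rec[j]) < cfg.rec_rec_cutoff
    )
    n_cross = sum(
        1 for r in rec for l in lig if distance(r, l) < cfg.cross_cutoff
    )
    return len(rec), 2 * n_rr, n_cross


@pytest.mark.parametrize("seed", range(6))
def test_edge_counts_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    protein = make_toy_protein(6, seed=rng)
    pose = make_toy_ligand(
        ["chain3", "branch5", "ring6", "ring6_tail"][seed % 4],
        center=(4.0 + rng.uniform(-1, 1), rng.uniform(-1, 1), 3.8),
    )
    cfg = FeatureConfig()
    g = build_interaction_graph(protein, pose, pose.heavy_coords, cfg)
    n_rec, n_rr, n_cross = brute_force_counts(protein, pose, pose.heavy_coords, cfg)
    assert g.n_rec == n_rec
    assert g.edges_rr.shape[1] == n_rr
    assert g.n_cross == n_cross
    assert g.edges_ll.shape[1] == 2 * len(pose.topology.heavy_bonds())
    # no self edges anywhere
    for e in (g.edges_rr, g.edges_ll):
        assert not np.any(e[0] == e[1])


def test_ligand_bond_edge_features(toy_graphs):
    g, _ = toy_graphs
    assert g.feats_ll.shape[1] == 7
    # one-hot bond order, flags binary, positive lengths
    assert np.all(g.feats_ll[:, :4].sum(axis=1) == 1.0)
    assert set(np.unique(g.feats_ll[:, 4:6])) <= {0.0, 1.0}
    assert np.all(g.feats_ll[:, 6] > 0)


# ---------------------------------------------------------------------------
# pocket graph


def test_pocket_edge_cutoff_rule():
    r1 = residue_at("ALA", 1, {"CA": (0, 0, 0)})
    r2 = residue_at("ALA", 2, {"CA": (9.5, 0, 0)})
    protein = ProteinStructure(residues=[r1, r2], source="mem")
    g = build_pocket_graph(protein, [0, 1])
    assert g.edges.shape[1] == 2
    r3 = residue_at("ALA", 2, {"CA": (10.5, 0, 0)})
    protein2 = ProteinStructure(residues=[r1, r3], source="mem")
    g2 = build_pocket_graph(protein2, [0, 1])
    assert g2.edges.shape[1] == 0


def test_single_residue_pocket_and_glycine():
    gly = residue_at("GLY", 1, {"N": (0, 0, 0), "CA": (1.45, 0, 0), "C": (2, 1.4, 0), "O": (1.4, 2.4, 0)})
    protein = ProteinStructure(residues=[gly], source="mem")
    g = build_pocket_graph(protein, [0])
    assert g.n_nodes == 1 and g.edges.shape[1] == 0
    row = g.node_feats[0]
    # side-chain centroid distances zero-filled with presence flag 0
    assert np.all(row[24:27] == 0.0)
    assert row[27] == 0.0


def test_pocket_node_features_internal_distances(toy_protein, toy_ligand):
    idx = select_pocket_residues(toy_protein, toy_ligand.heavy_coords, 8.0)
    g = build_pocket_graph(toy_protein, idx)
    residues = [toy_protein.residues[i] for i in idx]
    all_heavy = np.concatenate([[a.coords for a in r.heavy_atoms()] for r in residues])
    center = all_heavy.mean(axis=0)
    for k, res in enumerate(residues):
        ca = res.alpha_carbon.coords
        assert g.node_feats[k, 21] == pytest.approx(distance(ca, res.get_atom("N").coords))
        assert g.node_feats[k, 28] == pytest.approx(distance(ca, center))


# ---------------------------------------------------------------------------
# global invariance and serialization


def test_rigid_invariance_of_all_features(toy_protein, toy_ligand):
    rng = np.random.default_rng(99)
    T = RigidTransform.random(rng)

    def move_protein(protein):
        residues = []
        for res in protein.residues:
            atoms = [
                Atom(a.element, a.name, a.serial, T.apply(a.coords), a.occupancy, a.altloc)
                for a in res.atoms
            ]
            residues.append(Residue(res.name, res.chain, res.seq, res.icode, atoms))
        return ProteinStructure(residues=residues, source="moved")

    moved_protein = move_protein(toy_protein)
    moved_ligand = toy_ligand.with_coords(T.apply(toy_ligand.coords))
    g1, p1 = featurize_complex(toy_protein, toy_ligand, toy_ligand)
    g2, p2 = featurize_complex(moved_protein, moved_ligand, moved_ligand)
    np.testing.assert_allclose(g1.rec_feats, g2.rec_feats, atol=1e-6)
    np.testing.assert_allclose(g1.feats_cross, g2.feats_cross, atol=1e-6)
    np.testing.assert_allclose(g1.feats_rr, g2.feats_rr, atol=1e-6)
    np.testing.assert_allclose(g1.feats_ll, g2.feats_ll, atol=1e-6)
    np.testing.assert_allclose(p1.node_feats, p2.node_feats, atol=1e-6)
    np.testing.assert_allclose(p1.edge_feats, p2.edge_feats, atol=1e-6)
    assert np.array_equal(g1.edges_rl, g2.edges_rl)


def test_ligand_permutation_stability(toy_protein, toy_ligand):
    """Reordering ligand atoms permutes node rows consistently."""
    rng = np.random.default_rng(3)
    n = len(toy_ligand.topology.atoms)
    perm = rng.permutation(n)
    inv = np.argsort(perm)
    topo = toy_ligand.topology
    permuted = LigandTopology(
        atoms=[topo.atoms[i] for i in perm],
        bonds=[
            LigandBond(int(inv[b.i]), int(inv[b.j]), b.order, b.in_ring, b.conjugated)
            for b in topo.bonds
        ],
    )
    pose_p = LigandPose(permuted, toy_ligand.coords[perm], "perm")
    g1, _ = featurize_complex(toy_protein, toy_ligand, toy_ligand)
    g2, _ = featurize_complex(toy_protein, pose_p, pose_p)
    np.testing.assert_allclose(g1.lig_feats, g2.lig_feats[inv], atol=1e-12)
    # multiset of cross-edge feature rows is preserved
    rows1 = sorted(map(tuple, np.round(g1.feats_cross, 9)))
    rows2 = sorted(map(tuple, np.round(g2.feats_cross, 9)))
    assert rows1 == rows2


def test_graph_serialization_bit_exact(tmp_path, toy_graphs):
    g, p = toy_graphs
    path = tmp_path / "graphs.npz"
    save_graphs(path, g, p)
    g2, p2 = load_graphs(path)
    for name in ("rec_feats", "lig_feats", "feats_rr", "feats_ll", "feats_cross"):
        assert np.array_equal(getattr(g, name), getattr(g2, name))
    assert np.array_equal(g.edges_rl, g2.edges_rl)
    assert np.array_equal(p.node_feats, p2.node_feats)
    assert np.array_equal(p.edge_feats, p2.edge_feats)
    assert g2.fingerprint == g.fingerprint
    assert g2.rec_labels == g.rec_labels


def test_feature_config_validation():
    with pytest.raises(ValueError):
        FeatureConfig(cross_cutoff=-1)
    with pytest.raises(ValueError):
        FeatureConfig(pocket_mode="bogus")
    assert FeatureConfig().fingerprint() != FeatureConfig(pocket_mode="self_ref").fingerprint()
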