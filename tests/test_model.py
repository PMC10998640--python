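import numpy as np
import pytest

from plgscore.featurize import FeatureConfig, InteractionGraph, PocketGraph
from plgscore.model import (
    EdgeGAT,
    ModelConfig,
    NoContactError,
    ScoringModel,
    Tensor,
    atom_importance,
)
from plgscore.model.network import CROSS_EDGE_DIM, LIG_DIM, POCKET_EDGE_DIM, POCKET_NODE_DIM, REC_DIM
from tests.conftest import SMALL_MODEL


# ---------------------------------------------------------------------------
# EdgeGAT layer


def dense_egat_reference(layer, h_src, h_dst, edges, f_edge):
    """Loop-based dense re-implementation of the attention equations."""
    H, oe, on = layer.heads, layer.out_edge, layer.out_node
    E = edges.shape[1]
    n_dst = h_dst.shape[0]
    f_new = np.zeros((E, H * oe))
    for k in range(E):
        s, d = edges[0, k], edges[1, k]
        f_new[k] = (
            h_src[s] @ layer.fc_ni.weight.data
            + f_edge[k] @ layer.fc_fij.weight.data
            + layer.fc_fij.bias.data
            + h_dst[d] @ layer.fc_nj.weight.data
        )
    e_act = np.maximum(f_new, layer.leaky_slope * f_new).reshape(E, H, oe)
    scores = (e_act * layer.attn.data).sum(-1)  # (E, H)
    alpha = np.zeros((E, H))
    for d in range(n_dst):
        incoming = np.nonzero(edges[1] == d)[0]
        for h in range(H):
            if len(incoming):
                z = np.exp(scores[incoming, h] - scores[incoming, h].max())
                alpha[incoming, h] = z / z.sum()
    msg = np.zeros((E, H, on))
    for k in range(E):
        row = h_src[edges[0, k]] @ layer.fc_node.weight.data + layer.fc_node.bias.data
        msg[k] = row.reshape(H, on)
    h_out = np.zeros((n_dst, H * on))
    for d in range(n_dst):
        incoming = np.nonzero(edges[1] == d)[0]
        if len(incoming):
            h_out[d] = (msg[incoming] * alpha[incoming, :, None]).sum(0).reshape(-1)
        else:
            h_out[d] = h_dst[d] @ layer.fc_self.weight.data + layer.fc_self.bias.data
    return h_out, f_new, alpha


def test_edge_gat_matches_dense_reference(rng):
    layer = EdgeGAT(in_src=6, in_dst=5, in_edge=3, out_node=4, out_edge=4, heads=2, rng=rng)
    h_src = rng.normal(size=(5, 6))
    h_dst = rng.normal(size=(5, 5))
    edges = np.array([[0, 1, 2, 3, 4, 0, 2], [1, 0, 3, 2, 4, 2, 1]])
    f_edge = rng.normal(size=(7, 3))
    got_h, got_f, got_a = layer(Tensor(h_src), Tensor(h_dst), edges, Tensor(f_edge))
    ref_h, ref_f, ref_a = dense_egat_reference(layer, h_src, h_dst, edges, f_edge)
    np.testing.assert_allclose(got_f.data, ref_f, atol=1e-10)
    np.testing.assert_allclose(got_a, ref_a, atol=1e-10)
    np.testing.assert_allclose(got_h.data, ref_h, atol=1e-10)


def test_attention_normalization_and_singleton(rng):
    layer = EdgeGAT(4, 4, 2, 4, 4, 3, rng)
    h = Tensor(rng.normal(size=(6, 4)))
    edges = np.array([[0, 1, 2, 3, 4, 5, 1], [1, 1, 1, 2, 2, 3, 3]])
    f = Tensor(rng.normal(size=(7, 2)))
    _, _, alpha = layer(h, h, edges, f)
    for d in np.unique(edges[1]):
        sums = alpha[edges[1] == d].sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)
    # destination 3 has... two incoming; destination with one incoming edge:
    single_edges = np.array([[2], [0]])
    _, _, a1 = layer(h, h, single_edges, Tensor(rng.normal(size=(1, 2))))
    np.testing.assert_allclose(a1, 1.0, atol=1e-12)


def test_zero_edge_graph_self_update(rng):
    layer = EdgeGAT(4, 4, 2, 4, 4, 2, rng)
    h = Tensor(rng.normal(size=(3, 4)))
    empty = np.zeros((2, 0), dtype=np.intp)
    out1, f1, a1 = layer(h, h, empty, Tensor(np.zeros((0, 2))))
    out2, _, _ = layer(h, h, empty, Tensor(np.zeros((0, 2))))
    assert f1.shape == (0, 8) and a1.shape == (0, 2)
    np.testing.assert_array_equal(out1.data, out2.data)
    expect = h.data @ layer.fc_self.weight.data + layer.fc_self.bias.data
    np.testing.assert_allclose(out1.data, expect, atol=1e-12)


# ---------------------------------------------------------------------------
# decoder contracts


@pytest.fixture(scope="module")
def default_model():
    return ScoringModel(ModelConfig(seed=7))


def test_embedding_and_decoder_dimensions(default_model, toy_graphs):
    pred = default_model.predict(*toy_graphs)
    assert pred.pocket_vec.shape == (1024,)
    assert pred.rec_vec.shape == (1024,)
    assert pred.lig_vec.shape == (1024,)
    assert pred.latent.shape == (3072,)
    assert pred.v_rmsd.shape == (128,)
    assert pred.v_pkd.shape == (128,)
    assert pred.v_pkd_prime.shape == (128,)
    assert np.all(np.isfinite(pred.latent))


def test_decode_zeroed_parameters_closed_form():
    model = ScoringModel(SMALL_MODEL)
    for p in model.parameters():
        p.data = np.zeros_like(p.data)
    out = model.decode(np.random.default_rng(0).normal(size=3 * 1024))
    assert out["W"] == pytest.approx(0.5, abs=1e-12)          # logistic(0)
    assert out["rmsd_pred"] == pytest.approx(np.log(2.0), abs=1e-12)  # softplus(0)
    assert out["pkd_pred"] == pytest.approx(0.0, abs=1e-12)


def test_decode_codomain_on_random_latents(default_model, rng):
    latents = rng.normal(size=(1000, 3072)) * 3.0
    out = default_model.decode_batch(Tensor(latents))
    W = out["W"].data
    rmsd = out["rmsd_pred"].data
    assert np.all((W > 0.0) & (W < 1.0))
    assert np.all(rmsd >= 0.0)
    with pytest.raises(ValueError):
        default_model.decode(np.full(3072, np.nan))
    with pytest.raises(ValueError):
        default_model.decode(np.zeros(17))


# ---------------------------------------------------------------------------
# whole-model contracts


def test_forward_deterministic(small_model, toy_graphs):
    p1 = small_model.predict(*toy_graphs)
    p2 = small_model.predict(*toy_graphs)
    assert p1.rmsd_pred == p2.rmsd_pred
    assert p1.pkd_pred == p2.pkd_pred
    np.testing.assert_array_equal(p1.latent, p2.latent)
    np.testing.assert_array_equal(p1.attention["rl"], p2.attention["rl"])


def permute_interaction(graph, perm_rec, perm_lig):
    inv_r = np.argsort(perm_rec)
    inv_l = np.argsort(perm_lig)
    return InteractionGraph(
        rec_feats=graph.rec_feats[perm_rec],
        lig_feats=graph.lig_feats[perm_lig],
        edges_rr=inv_r[graph.edges_rr],
        feats_rr=graph.feats_rr,
        edges_ll=inv_l[graph.edges_ll],
        feats_ll=graph.feats_ll,
        edges_rl=np.stack([inv_r[graph.edges_rl[0]], inv_l[graph.edges_rl[1]]]),
        edges_lr=np.stack([inv_l[graph.edges_lr[0]], inv_r[graph.edges_lr[1]]]),
        feats_cross=graph.feats_cross,
        rec_labels=[graph.rec_labels[i] for i in perm_rec],
        fingerprint=graph.fingerprint,
    )


def test_node_permutation_invariance(small_model, toy_graphs, rng):
    graph, pocket = toy_graphs
    perm_rec = rng.permutation(graph.n_rec)
    perm_lig = rng.permutation(graph.n_lig)
    permuted = permute_interaction(graph, perm_rec, perm_lig)
    p1 = small_model.predict(graph, pocket)
    p2 = small_model.predict(permuted, pocket)
    np.testing.assert_allclose(p1.rec_vec, p2.rec_vec, atol=1e-5)
    np.testing.assert_allclose(p1.lig_vec, p2.lig_vec, atol=1e-5)
    assert p1.rmsd_pred == pytest.approx(p2.rmsd_pred, abs=1e-6)
    assert p1.pkd_pred == pytest.approx(p2.pkd_pred, abs=1e-6)

    perm_p = rng.permutation(pocket.n_nodes)
    inv_p = np.argsort(perm_p)
    pocket_perm = PocketGraph(
        node_feats=pocket.node_feats[perm_p],
        edges=inv_p[pocket.edges],
        edge_feats=pocket.edge_feats,
        fingerprint=pocket.fingerprint,
    )
    e1 = small_model.encode_pocket(pocket)
    e2 = small_model.encode_pocket(pocket_perm)
    np.testing.assert_allclose(e1, e2, atol=1e-5)


def test_batching_equivalence(small_model, toy_graphs, toy_protein, toy_ligand):
    from plgscore.featurize import featurize_complex

    shifted = toy_ligand.with_coords(toy_ligand.coords + [0.4, -0.2, 0.3], "s1")
    shifted2 = toy_ligand.with_coords(toy_ligand.coords + [-0.5, 0.1, 0.6], "s2")
    graphs = [
        toy_graphs,
        featurize_complex(toy_protein, shifted, toy_ligand),
        featurize_complex(toy_protein, shifted2, toy_ligand),
    ]
    batched = small_model.predict_batch(graphs)
    singles = [small_model.predict(*g) for g in graphs]
    for b, s in zip(batched, singles):
        assert b.rmsd_pred == pytest.approx(s.rmsd_pred, abs=1e-5)
        assert b.pkd_pred == pytest.approx(s.pkd_pred, abs=1e-5)
        assert b.W == pytest.approx(s.W, abs=1e-6)
        np.testing.assert_allclose(b.attention["rl"], s.attention["rl"], atol=1e-8)


def test_no_contact_error(small_model, toy_protein, toy_ligand):
    far = toy_ligand.with_coords(toy_ligand.coords + [50.0, 0, 0], "far")
    with pytest.raises(NoContactError):
        small_model.forward(toy_protein, far, toy_ligand)


def test_checkpoint_round_trip_bit_exact(tmp_path, small_model, toy_graphs):
    path = tmp_path / "model.npz"
    small_model.save(path)
    loaded = ScoringModel.load(path)
    p1 = small_model.predict(*toy_graphs)
    p2 = loaded.predict(*toy_graphs)
    assert p1.rmsd_pred == p2.rmsd_pred
    assert p1.pkd_pred == p2.pkd_pred
    assert p1.W == p2.W
    np.testing.assert_array_equal(p1.latent, p2.latent)


def test_checkpoint_fingerprint_mismatch(tmp_path, small_model):
    path = tmp_path / "model.npz"
    small_model.save(path)
    other = FeatureConfig(pocket_mode="self_ref")
    with pytest.raises(ValueError, match="fingerprint"):
        ScoringModel.load(path, expected_feature_config=other)


def test_seed_reproducibility():
    m1 = ScoringModel(SMALL_MODEL)
    m2 = ScoringModel(SMALL_MODEL)
    for (k1, p1), (k2, p2) in zip(
        sorted(m1.named_parameters().items()), sorted(m2.named_parameters().items())
    ):
        assert k1 == k2
        np.testing.assert_array_equal(p1.data, p2.data)


# ---------------------------------------------------------------------------
# attention-based importance


def minimal_single_edge_graph():
    rec = np.zeros((2, REC_DIM))
    lig = np.zeros((1, LIG_DIM))
    edges_rl = np.array([[1], [0]])
    return InteractionGraph(
        rec_feats=rec,
        lig_feats=lig,
        edges_rr=np.zeros((2, 0), dtype=np.intp),
        feats_rr=np.zeros((0, 1)),
        edges_ll=np.zeros((2, 0), dtype=np.intp),
        feats_ll=np.zeros((0, 7)),
        edges_rl=edges_rl,
        edges_lr=edges_rl[::-1].copy(),
        feats_cross=np.array([[0.1, 0.5, 0.5, 3.0]]),
        rec_labels=["GLY-MC-C", "LYS-SC-N"],
    )


def single_node_pocket():
    return PocketGraph(
        node_feats=np.zeros((1, POCKET_NODE_DIM)),
        edges=np.zeros((2, 0), dtype=np.intp),
        edge_feats=np.zeros((0, POCKET_EDGE_DIM)),
    )


def test_single_cross_edge_importance(small_model):
    graph = minimal_single_edge_graph()
    pred = small_model.predict(graph, single_node_pocket())
    table = atom_importance(pred, graph)
    # a single edge per direction: attention is 1 on each, head-averaged 1
    lys = table[table.atom_class == "LYS-SC-N"]["importance"].iloc[0]
    assert lys == pytest.approx(2.0, abs=1e-10)  # one RL + one LR edge
    assert "GLY-MC-C" not in set(table[table.importance > 0].atom_class)


def test_importance_conserves_attention_mass(small_model, toy_graphs):
    graph, pocket = toy_graphs
    pred = small_model.predict(graph, pocket)
    table = atom_importance(pred, graph)
    total = pred.attention["rl"].mean(axis=1).sum() + pred.attention["lr"].mean(axis=1).sum()
    assert table.importance.sum() == pytest.approx(total, abs=1e-8)


def test_single_node_pocket_embedding(small_model):
    vec = small_model.encode_pocket(single_node_pocket())
    assert vec.shape == (1024,)
    assert np.all(np.isfinite(vec))


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(rounds_interaction=0)
    with pytest.raises(ValueError):
        ModelConfig(node_hidden=30, attention_heads=4)
    with pytest.raises(ValueError):
        ModelConfig(readout="median")
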