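"""Encoder-decoder scoring network.

Two encoder branches built from stacked edge-featured graph-attention
layers embed the pocket graph and the heterogeneous interaction graph
into three 1024-dimensional vectors (pocket, protein atoms, ligand
atoms).  One interaction round applies four attention layers — intra-
protein, ligand-to-protein, intra-ligand, protein-to-ligand — and fuses
the two incoming updates of each node set through batch-normalized
residual addition:

    h_rec <- BN(h_rec,intra) + BN(Linear(h_rec,cross))
    h_lig <- BN(h_lig,intra) + BN(Linear(h_lig,cross))

Two rounds with separate parameters are applied, then per-set mean
readout and affine maps produce the embeddings.  The 3072-dim latent
(concatenation) is decoded by two parallel modules (a gMLP block over
the three 1024-dim tokens followed by two linear layers) into V_RMSD and
V_pkd (128 each).  V_RMSD is mapped into the pKd space as V'_pkd; the
fused vector V'_pkd + V_pkd yields the decay factor
W = sigmoid(Linear(.)) in (0, 1) and the predicted pKd, while
RMSD_pred = softplus(Linear(V_RMSD)) >= 0.

Cross-channel attention weights of the last round are retained for
interpretability (per-atom importance aggregation).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ..featurize import (
    FeatureConfig,
    InteractionGraph,
    PocketGraph,
    LIGAND_CLASSES,
    PROTEIN_CLASSES,
    featurize_complex,
)
from .autodiff import Adam, IndexMap, Parameter, Tensor, concat, segment_sum
from .layers import BatchNorm, EdgeGAT, GMLPBlock, Linear, Module

__all__ = [
    "ModelConfig",
    "Prediction",
    "NoContactError",
    "ScoringModel",
    "atom_importance",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1

REC_DIM = len(PROTEIN_CLASSES) + 3   # class one-hot + aromatic + charge + d(CA)
LIG_DIM = len(LIGAND_CLASSES) + 2    # class one-hot + aromatic + formal charge
POCKET_NODE_DIM = 29
POCKET_EDGE_DIM = 4
RR_EDGE_DIM = 1
LL_EDGE_DIM = 7
CROSS_EDGE_DIM = 4


class NoContactError(ValueError):
    """The pose makes no protein-ligand contact within the cross cutoff."""


@dataclass(frozen=True)
class ModelConfig:
    node_hidden: int = 128          # per-layer node width (heads concatenated)
    edge_hidden: int = 128          # per-layer edge width (heads concatenated)
    attention_heads: int = 4
    rounds_interaction: int = 2
    pocket_embed_dim: int = 1024
    rec_embed_dim: int = 1024
    lig_embed_dim: int = 1024
    decoder_dim: int = 128
    gmlp_ffn: int = 512
    readout: str = "mean"           # mean | sum
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds_interaction < 1:
            raise ValueError("rounds_interaction must be >= 1")
        for name in ("node_hidden", "edge_hidden", "pocket_embed_dim", "decoder_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.node_hidden % self.attention_heads or self.edge_hidden % self.attention_heads:
            raise ValueError("hidden widths must be divisible by attention_heads")
        if self.readout not in ("mean", "sum"):
            raise ValueError(f"unknown readout {self.readout!r}")


@dataclass
class Prediction:
    """Per-pose model output."""

    rmsd_pred: float
    pkd_pred: float
    W: float
    v_rmsd: np.ndarray
    v_pkd: np.ndarray
    v_pkd_prime: np.ndarray
    pocket_vec: np.ndarray
    rec_vec: np.ndarray
    lig_vec: np.ndarray
    attention: dict = field(default_factory=dict)  # {"rl": (E, H), "lr": (E, H)}

    @property
    def latent(self) -> np.ndarray:
        return np.concatenate([self.pocket_vec, self.rec_vec, self.lig_vec])


class _InteractionRound(Module):
    def __init__(self, in_rec, in_lig, e_rr, e_ll, e_cross, cfg: ModelConfig, rng):
        H = cfg.attention_heads
        on = cfg.node_hidden // H
        oe = cfg.edge_hidden // H
        self.gat_rr = EdgeGAT(in_rec, in_rec, e_rr, on, oe, H, rng)
        self.gat_lr = EdgeGAT(in_lig, in_rec, e_cross, on, oe, H, rng)
        self.gat_ll = EdgeGAT(in_lig, in_lig, e_ll, on, oe, H, rng)
        self.gat_rl = EdgeGAT(in_rec, in_lig, e_cross, on, oe, H, rng)
        self.lin_rec = Linear(cfg.node_hidden, cfg.node_hidden, rng)
        self.lin_lig = Linear(cfg.node_hidden, cfg.node_hidden, rng)
        self.bn_rec1 = BatchNorm(cfg.node_hidden)
        self.bn_rec2 = BatchNorm(cfg.node_hidden)
        self.bn_lig1 = BatchNorm(cfg.node_hidden)
        self.bn_lig2 = BatchNorm(cfg.node_hidden)


class _Decoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        d = cfg.pocket_embed_dim
        self.gmlp = GMLPBlock(3, d, cfg.gmlp_ffn, rng)
        self.fc1 = Linear(3 * d, cfg.decoder_dim, rng)
        self.fc2 = Linear(cfg.decoder_dim, cfg.decoder_dim, rng)

    def __call__(self, tokens: Tensor) -> Tensor:
        B = tokens.shape[0]
        y = self.gmlp(tokens).reshape(B, -1)
        return self.fc2(self.fc1(y).elu())


class _Batch:
    """Disjoint union of featurized complexes with per-graph segment ids."""

    def __init__(self, graphs: list[tuple[InteractionGraph, PocketGraph]]):
        self.size = len(graphs)
        for ig, _ in graphs:
            if ig.n_cross == 0:
                raise NoContactError(
                    "pose has no protein-ligand contact within the cross cutoff"
                )
        def _cat_edges(edge_lists, offsets_src, offsets_dst):
            cols = [
                e + np.array([[o_s], [o_d]])
                for e, o_s, o_d in zip(edge_lists, offsets_src, offsets_dst)
                if e.size
            ]
            return np.concatenate(cols, axis=1) if cols else np.zeros((2, 0), dtype=np.intp)

        igs = [g for g, _ in graphs]
        pgs = [p for _, p in graphs]
        rec_off = np.cumsum([0] + [g.n_rec for g in igs])[:-1]
        lig_off = np.cumsum([0] + [g.n_lig for g in igs])[:-1]
        pock_off = np.cumsum([0] + [p.n_nodes for p in pgs])[:-1]

        self.rec_feats = np.concatenate([g.rec_feats for g in igs])
        self.lig_feats = np.concatenate([g.lig_feats for g in igs])
        self.pocket_feats = np.concatenate([p.node_feats for p in pgs])
        self.rec_gid = np.concatenate(
            [np.full(g.n_rec, k) for k, g in enumerate(igs)]
        ).astype(np.intp)
        self.lig_gid = np.concatenate(
            [np.full(g.n_lig, k) for k, g in enumerate(igs)]
        ).astype(np.intp)
        self.pock_gid = np.concatenate(
            [np.full(p.n_nodes, k) for k, p in enumerate(pgs)]
        ).astype(np.intp)

        self.edges_rr = _cat_edges([g.edges_rr for g in igs], rec_off, rec_off)
        self.edges_ll = _cat_edges([g.edges_ll for g in igs], lig_off, lig_off)
        self.edges_rl = _cat_edges([g.edges_rl for g in igs], rec_off, lig_off)
        self.edges_lr = _cat_edges([g.edges_lr for g in igs], lig_off, rec_off)
        self.feats_rr = np.concatenate([g.feats_rr for g in igs])
        self.feats_ll = np.concatenate([g.feats_ll for g in igs])
        self.feats_cross = np.concatenate([g.feats_cross for g in igs])
        self.pocket_edges = _cat_edges([p.edges for p in pgs], pock_off, pock_off)
        self.pocket_edge_feats = np.concatenate([p.edge_feats for p in pgs])
        self.cross_sizes = [g.n_cross for g in igs]

        # precomputed sparse gather/scatter maps (src_map, dst_map) per channel
        n_rec, n_lig, n_pock = len(self.rec_gid), len(self.lig_gid), len(self.pock_gid)
        self.maps_rr = self._edge_maps(self.edges_rr, n_rec, n_rec)
        self.maps_ll = self._edge_maps(self.edges_ll, n_lig, n_lig)
        self.maps_rl = self._edge_maps(self.edges_rl, n_rec, n_lig)
        self.maps_lr = self._edge_maps(self.edges_lr, n_lig, n_rec)
        self.maps_pocket = self._edge_maps(self.pocket_edges, n_pock, n_pock)
        self.rec_readout = IndexMap(self.rec_gid, self.size)
        self.lig_readout = IndexMap(self.lig_gid, self.size)
        self.pock_readout = IndexMap(self.pock_gid, self.size)

    @staticmethod
    def _edge_maps(edges: np.ndarray, n_src: int, n_dst: int):
        if edges.shape[1] == 0:
            return None
        return (IndexMap(edges[0], n_src), IndexMap(edges[1], n_dst))


class ScoringModel(Module):
    """Full pose-scoring network (pocket + interaction encoders, twin decoders)."""

    def __init__(self, config: ModelConfig | None = None,
                 feature_config: FeatureConfig | None = None):
        self.config = config or ModelConfig()
        self.feature_config = feature_config or FeatureConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        H = cfg.attention_heads
        on = cfg.node_hidden // H
        oe = cfg.edge_hidden // H

        self.pocket_gat1 = EdgeGAT(
            POCKET_NODE_DIM, POCKET_NODE_DIM, POCKET_EDGE_DIM, on, oe, H, rng
        )
        self.pocket_gat2 = EdgeGAT(
            cfg.node_hidden, cfg.node_hidden, cfg.edge_hidden, on, oe, H, rng
        )
        self.pocket_out = Linear(cfg.node_hidden, cfg.pocket_embed_dim, rng)

        rounds = []
        for r in range(cfg.rounds_interaction):
            if r == 0:
                rounds.append(
                    _InteractionRound(
                        REC_DIM, LIG_DIM, RR_EDGE_DIM, LL_EDGE_DIM, CROSS_EDGE_DIM, cfg, rng
                    )
                )
            else:
                rounds.append(
                    _InteractionRound(
                        cfg.node_hidden, cfg.node_hidden,
                        cfg.edge_hidden, cfg.edge_hidden, cfg.edge_hidden, cfg, rng,
                    )
                )
        self.rounds = rounds
        self.rec_out = Linear(cfg.node_hidden, cfg.rec_embed_dim, rng)
        self.lig_out = Linear(cfg.node_hidden, cfg.lig_embed_dim, rng)

        self.dec_rmsd = _Decoder(cfg, rng)
        self.dec_pkd = _Decoder(cfg, rng)
        self.lin_vprime = Linear(cfg.decoder_dim, cfg.decoder_dim, rng)
        self.head_w = Linear(cfg.decoder_dim, 1, rng)
        self.head_rmsd = Linear(cfg.decoder_dim, 1, rng)
        self.head_pkd = Linear(cfg.decoder_dim, 1, rng)
        self.set_training(False)

    # -- readout -----------------------------------------------------------

    def _readout(self, h: Tensor, imap: IndexMap, gid: np.ndarray, n_graphs: int) -> Tensor:
        total = segment_sum(h, imap)
        if self.config.readout == "sum":
            return total
        counts = np.bincount(gid, minlength=n_graphs).astype(float).reshape(-1, 1)
        return total * Tensor(1.0 / counts)

    # -- encoders ----------------------------------------------------------

    def _encode_pocket_batch(self, batch: _Batch) -> Tensor:
        h = Tensor(batch.pocket_feats)
        f = Tensor(batch.pocket_edge_feats)
        h1, f1, _ = self.pocket_gat1(h, h, batch.pocket_edges, f, batch.maps_pocket)
        h1 = h1.elu()
        h2, _, _ = self.pocket_gat2(h1, h1, batch.pocket_edges, f1, batch.maps_pocket)
        h2 = h2.elu()
        return self.pocket_out(
            self._readout(h2, batch.pock_readout, batch.pock_gid, batch.size)
        )

    def _encode_interaction_batch(self, batch: _Batch):
        h_rec = Tensor(batch.rec_feats)
        h_lig = Tensor(batch.lig_feats)
        f_rr = Tensor(batch.feats_rr)
        f_ll = Tensor(batch.feats_ll)
        f_rl = Tensor(batch.feats_cross)
        f_lr = Tensor(batch.feats_cross)
        att_rl = att_lr = None
        for rnd in self.rounds:
            h_rec1, f_rr_n, _ = rnd.gat_rr(h_rec, h_rec, batch.edges_rr, f_rr, batch.maps_rr)
            h_rec2, f_lr_n, att_lr = rnd.gat_lr(h_lig, h_rec, batch.edges_lr, f_lr, batch.maps_lr)
            h_lig1, f_ll_n, _ = rnd.gat_ll(h_lig, h_lig, batch.edges_ll, f_ll, batch.maps_ll)
            h_lig2, f_rl_n, att_rl = rnd.gat_rl(h_rec, h_lig, batch.edges_rl, f_rl, batch.maps_rl)
            h_rec = (rnd.bn_rec1(h_rec1) + rnd.bn_rec2(rnd.lin_rec(h_rec2))).elu()
            h_lig = (rnd.bn_lig1(h_lig1) + rnd.bn_lig2(rnd.lin_lig(h_lig2))).elu()
            f_rr, f_lr, f_ll, f_rl = f_rr_n, f_lr_n, f_ll_n, f_rl_n
        rec_vec = self.rec_out(
            self._readout(h_rec, batch.rec_readout, batch.rec_gid, batch.size)
        )
        lig_vec = self.lig_out(
            self._readout(h_lig, batch.lig_readout, batch.lig_gid, batch.size)
        )
        return rec_vec, lig_vec, att_rl, att_lr

    # -- decoder -----------------------------------------------------------

    def decode_batch(self, latent: Tensor) -> dict[str, Tensor]:
        B = latent.shape[0]
        d = self.config.pocket_embed_dim
        tokens = latent.reshape(B, 3, d)
        v_rmsd = self.dec_rmsd(tokens)
        v_pkd = self.dec_pkd(tokens)
        v_prime = self.lin_vprime(v_rmsd)
        fused = v_prime + v_pkd
        return {
            "v_rmsd": v_rmsd,
            "v_pkd": v_pkd,
            "v_pkd_prime": v_prime,
            "W": self.head_w(fused).sigmoid().reshape(B),
            "rmsd_pred": self.head_rmsd(v_rmsd).softplus().reshape(B),
            "pkd_pred": self.head_pkd(fused).reshape(B),
        }

    def decode(self, latent: np.ndarray) -> dict[str, np.ndarray]:
        """Decode one 3072-dim latent vector (evaluation mode)."""
        latent = np.asarray(latent, dtype=float).reshape(1, -1)
        if latent.shape[1] != 3 * self.config.pocket_embed_dim:
            raise ValueError("latent length mismatch")
        if not np.all(np.isfinite(latent)):
            raise ValueError("non-finite latent")
        out = self.decode_batch(Tensor(latent))
        return {k: np.asarray(v.data)[0] for k, v in out.items()}

    # -- forward -----------------------------------------------------------

    def forward_batch(self, graphs: list[tuple[InteractionGraph, PocketGraph]]):
        """Run the full network on a batch; returns dict of Tensors of length B
        plus the raw batch (for attention bookkeeping)."""
        batch = _Batch(graphs)
        pocket_vec = self._encode_pocket_batch(batch)
        rec_vec, lig_vec, att_rl, att_lr = self._encode_interaction_batch(batch)
        latent = concat([pocket_vec, rec_vec, lig_vec], axis=1)
        out = self.decode_batch(latent)
        out["pocket_vec"] = pocket_vec
        out["rec_vec"] = rec_vec
        out["lig_vec"] = lig_vec
        out["_att_rl"] = att_rl
        out["_att_lr"] = att_lr
        out["_batch"] = batch
        return out

    def predict_batch(
        self, graphs: list[tuple[InteractionGraph, PocketGraph]]
    ) -> list[Prediction]:
        out = self.forward_batch(graphs)
        batch = out["_batch"]
        preds = []
        bounds = np.cumsum([0] + batch.cross_sizes)
        for k in range(batch.size):
            sl = slice(bounds[k], bounds[k + 1])
            preds.append(
                Prediction(
                    rmsd_pred=float(out["rmsd_pred"].data[k]),
                    pkd_pred=float(out["pkd_pred"].data[k]),
                    W=float(out["W"].data[k]),
                    v_rmsd=out["v_rmsd"].data[k].copy(),
                    v_pkd=out["v_pkd"].data[k].copy(),
                    v_pkd_prime=out["v_pkd_prime"].data[k].copy(),
                    pocket_vec=out["pocket_vec"].data[k].copy(),
                    rec_vec=out["rec_vec"].data[k].copy(),
                    lig_vec=out["lig_vec"].data[k].copy(),
                    attention={
                        "rl": out["_att_rl"][sl].copy(),
                        "lr": out["_att_lr"][sl].copy(),
                    },
                )
            )
        return preds

    def predict(self, interaction: InteractionGraph, pocket: PocketGraph) -> Prediction:
        return self.predict_batch([(interaction, pocket)])[0]

    def forward(self, protein, pose, reference=None) -> Prediction:
        """Featurize one pose and score it (evaluation mode)."""
        interaction, pocket = featurize_complex(
            protein, pose, reference, self.feature_config
        )
        return self.predict(interaction, pocket)

    def encode_pocket(self, pocket: PocketGraph) -> np.ndarray:
        """Pocket-branch embedding of a single graph (length pocket_embed_dim)."""
        if pocket.n_nodes == 0:
            raise ValueError("empty pocket graph")
        class _P:  # minimal stand-in so _Batch machinery is reusable
            pass
        batch = _P()
        batch.size = 1
        batch.pocket_feats = pocket.node_feats
        batch.pocket_edge_feats = pocket.edge_feats
        batch.pocket_edges = pocket.edges
        batch.pock_gid = np.zeros(pocket.n_nodes, dtype=np.intp)
        batch.maps_pocket = _Batch._edge_maps(pocket.edges, pocket.n_nodes, pocket.n_nodes)
        batch.pock_readout = IndexMap(batch.pock_gid, 1)
        return self._encode_pocket_batch(batch).data[0].copy()

    def encode_interaction(self, interaction: InteractionGraph):
        """(rec_vec, lig_vec, attention) of a single interaction graph."""
        if interaction.n_cross == 0:
            raise NoContactError(
                "pose has no protein-ligand contact within the cross cutoff"
            )
        dummy_pocket = PocketGraph(
            node_feats=np.zeros((1, POCKET_NODE_DIM)),
            edges=np.zeros((2, 0), dtype=np.intp),
            edge_feats=np.zeros((0, POCKET_EDGE_DIM)),
        )
        batch = _Batch([(interaction, dummy_pocket)])
        rec_vec, lig_vec, att_rl, att_lr = self._encode_interaction_batch(batch)
        return (
            rec_vec.data[0].copy(),
            lig_vec.data[0].copy(),
            {"rl": att_rl.copy(), "lr": att_lr.copy()},
        )

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "model_config": asdict(self.config),
            "feature_config": asdict(self.feature_config),
            "feature_fingerprint": self.feature_config.fingerprint(),
        }
        arrays = self.state_arrays()
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path, expected_feature_config: FeatureConfig | None = None) -> "ScoringModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            feature_config = FeatureConfig(**meta["feature_config"])
            if (
                expected_feature_config is not None
                and expected_feature_config.fingerprint() != feature_config.fingerprint()
            ):
                raise ValueError(
                    "checkpoint featurization fingerprint does not match the requested "
                    "feature configuration"
                )
            model = cls(ModelConfig(**meta["model_config"]), feature_config)
            state = {k: z[k] for k in z.files if k != "__meta__"}
        model.load_state_arrays(state)
        model.set_training(False)
        return model


def atom_importance(
    prediction: Prediction, interaction: InteractionGraph
) -> pd.DataFrame:
    """Aggregate cross-edge attention into per-protein-atom-class importance.

    Each protein atom's importance is the head-averaged attention summed
    over all its cross edges (both directions); rows aggregate by protein
    atom class, sorted descending.
    """
    n_rec = interaction.n_rec
    per_atom = np.zeros(n_rec)
    att_rl = prediction.attention["rl"]
    att_lr = prediction.attention["lr"]
    if att_rl.size:
        np.add.at(per_atom, interaction.edges_rl[0], att_rl.mean(axis=1))
    if att_lr.size:
        np.add.at(per_atom, interaction.edges_lr[1], att_lr.mean(axis=1))
    df = pd.DataFrame(
        {"atom_class": interaction.rec_labels, "importance": per_atom}
    )
    out = (
        df.groupby("atom_class", as_index=False)["importance"]
        .sum()
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return out
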