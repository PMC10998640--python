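"""Network building blocks: linear maps, normalization, edge-featured
graph attention and a gMLP block, all on the in-package autodiff engine.

The graph-attention layer follows the edge-featured GAT (EGAT) update:
for a directed edge (j -> i) with source feature h_j, destination
feature h_i and edge feature f_ij,

    f'_ij   = A h_j + B f_ij + C h_i                       (per head)
    e_ij    = LeakyReLU(f'_ij)
    a_ij    = softmax_i( attn . e_ij )    over in-edges of i
    h'_i    = sum_j a_ij * (W h_j)                         (per head)

heads are concatenated.  Destination nodes with no incoming edge receive
an affine self-update instead of the (empty) attention sum.
"""

from __future__ import annotations

import numpy as np

from .autodiff import IndexMap, Parameter, Tensor, concat, gather_rows, segment_sum

__all__ = ["Module", "Linear", "EdgeGAT", "BatchNorm", "LayerNorm", "GMLPBlock"]


def _uniform_fanin(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Lightweight parameter container with recursive traversal."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[full] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for k, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{full}.{k}."))
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            if hasattr(m, "training"):
                m.training = flag

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All persistent arrays (parameters + buffers such as running stats)."""
        out = {k: p.data for k, p in self.named_parameters().items()}
        for name, value in vars(self).items():
            if isinstance(value, Module):
                for k, v in value.state_arrays().items():
                    out.setdefault(f"{name}.{k}", v)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for k, v in item.state_arrays().items():
                            out.setdefault(f"{name}.{i}.{k}", v)
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                out[name] = value
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        params = self.named_parameters()
        for k, p in params.items():
            p.data = np.array(state[k], dtype=np.float64)
        # restore buffers
        def _walk(mod: "Module", pre: str) -> None:
            for name, value in vars(mod).items():
                full = f"{pre}{name}"
                if isinstance(value, Module):
                    _walk(value, f"{full}.")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            _walk(item, f"{full}.{i}.")
                elif isinstance(value, np.ndarray) and name.startswith("running_"):
                    setattr(mod, name, np.array(state[full], dtype=np.float64))

        _walk(self, prefix)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_uniform_fanin(rng, in_dim, (in_dim, out_dim)))
        self.bias = Parameter(_uniform_fanin(rng, in_dim, (out_dim,))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm(Module):
    """1-D batch normalization over rows; eval mode uses running averages."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.training = False

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbias = n / max(n - 1, 1)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data[0] * unbias
            )
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * (
                Tensor((self.running_var + self.eps) ** -0.5)
            )
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class EdgeGAT(Module):
    """Edge-featured multi-head graph attention on a (possibly bipartite)
    directed edge set.

    Returns updated destination-node features (heads concatenated),
    updated edge features (the pre-activation f', heads concatenated) and
    the per-edge per-head attention weights.
    """

    def __init__(
        self,
        in_src: int,
        in_dst: int,
        in_edge: int,
        out_node: int,
        out_edge: int,
        heads: int,
        rng: np.random.Generator,
        leaky_slope: float = 0.2,
    ):
        self.heads = heads
        self.out_node = out_node
        self.out_edge = out_edge
        self.leaky_slope = leaky_slope
        self.fc_ni = Linear(in_src, heads * out_edge, rng, bias=False)
        self.fc_fij = Linear(in_edge, heads * out_edge, rng, bias=True)
        self.fc_nj = Linear(in_dst, heads * out_edge, rng, bias=False)
        self.attn = Parameter(_uniform_fanin(rng, out_edge, (heads, out_edge)))
        self.fc_node = Linear(in_src, heads * out_node, rng, bias=True)
        self.fc_self = Linear(in_dst, heads * out_node, rng, bias=True)

    def __call__(
        self,
        h_src: Tensor,
        h_dst: Tensor,
        edge_index: np.ndarray,
        f_edge: Tensor,
        maps: tuple[IndexMap, IndexMap] | None = None,
    ) -> tuple[Tensor, Tensor, np.ndarray]:
        n_dst = h_dst.shape[0]
        H, oe, on = self.heads, self.out_edge, self.out_node
        if edge_index.shape[1] == 0:
            h_out = self.fc_self(h_dst)
            return h_out, Tensor(np.zeros((0, H * oe))), np.zeros((0, H))

        src, dst = edge_index[0], edge_index[1]
        if maps is None:
            maps = (IndexMap(src, h_src.shape[0]), IndexMap(dst, n_dst))
        src_map, dst_map = maps
        f_new = (
            gather_rows(self.fc_ni(h_src), src_map)
            + self.fc_fij(f_edge)
            + gather_rows(self.fc_nj(h_dst), dst_map)
        )  # (E, H*oe)
        e_act = f_new.leaky_relu(self.leaky_slope).reshape(-1, H, oe)
        scores = (e_act * self.attn).sum(axis=-1)  # (E, H)

        # numerically stable segment softmax over incoming edges of each dst
        shift = np.full((n_dst, H), -np.inf)
        np.maximum.at(shift, dst, scores.data)
        z = (scores - Tensor(shift[dst])).exp()
        denom = segment_sum(z, dst_map)
        alpha = z * (gather_rows(denom, dst_map) ** -1.0)  # (E, H)

        msg = gather_rows(self.fc_node(h_src), src_map).reshape(-1, H, on)
        weighted = (msg * alpha.reshape(-1, H, 1)).reshape(-1, H * on)
        agg = segment_sum(weighted, dst_map)

        indeg = np.bincount(dst, minlength=n_dst)
        if np.any(indeg == 0):
            mask = Tensor((indeg == 0).astype(float).reshape(-1, 1))
            agg = agg + mask * self.fc_self(h_dst)
        return agg, f_new, alpha.data.copy()


class GMLPBlock(Module):
    """gMLP block with a spatial gating unit over a short token axis.

    Input ``(B, T, d)``; channel projection to ``d_ffn``, GELU, split in
    half, spatial (token-mixing) affine map on the layer-normalized gate
    half (weights initialized near zero, bias at one, so the block starts
    close to identity gating), multiply, project back, residual.
    """

    def __init__(self, n_tokens: int, dim: int, d_ffn: int, rng: np.random.Generator):
        assert d_ffn % 2 == 0
        self.n_tokens = n_tokens
        self.dim = dim
        self.d_ffn = d_ffn
        self.norm = LayerNorm(dim)
        self.proj_in = Linear(dim, d_ffn, rng)
        self.sgu_norm = LayerNorm(d_ffn // 2)
        self.spatial_weight = Parameter(rng.uniform(-1e-3, 1e-3, size=(n_tokens, n_tokens)))
        self.spatial_bias = Parameter(np.ones(n_tokens))
        self.proj_out = Linear(d_ffn // 2, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, d = x.shape
        flat = x.reshape(B * T, d)
        u = self.proj_in(self.norm(flat)).gelu()  # (B*T, ffn)
        half = self.d_ffn // 2
        u1 = u[:, :half]
        v = self.sgu_norm(u[:, half:])
        # token mixing: (T, T) @ (T, B*half)
        v_t = v.reshape(B, T, half).transpose(1, 0, 2).reshape(T, B * half)
        s = self.spatial_weight @ v_t + self.spatial_bias.reshape(T, 1)
        s = s.reshape(T, B, half).transpose(1, 0, 2).reshape(B * T, half)
        y = self.proj_out(u1 * s)
        return x + y.reshape(B, T, d)
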