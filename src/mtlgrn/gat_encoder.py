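"""Two-layer multi-head graph-attention encoder mapping (A, X) to gene
embeddings Z.

Layer 1 concatenates K heads, layer 2 averages them; both apply ELU.  For a
head with weight matrix W and additive-attention vector a = [a_l ; a_r], the
raw score for the ordered pair (i, j) is

    att_ij = a_l . (W^T g_i) + a_r . (W^T g_j)

passed through LeakyReLU (slope 0.2) and softmax-normalized over the
neighborhood N_i.  The attention mask is the observed (training) adjacency
plus self-loops; self-loops guarantee every row has a non-empty neighborhood
and keep isolated or test-masked nodes well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, masked_softmax_rows
from .io_formats import GeneGraph


@dataclass
class GatLayerParams:
    """Per-head linear maps W_k (d_in x d_head) and attention vectors split
    into source/destination halves (d_head each)."""

    Ws: list[Tensor]
    a_src: list[Tensor]
    a_dst: list[Tensor]
    mode: str  # "concat" | "average"
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.mode not in ("concat", "average"):
            raise ValueError("mode must be 'concat' or 'average'")
        if not (len(self.Ws) == len(self.a_src) == len(self.a_dst)):
            raise ValueError("per-head parameter lists must align")
        d_in = self.Ws[0].shape[0]
        if any(W.shape[0] != d_in for W in self.Ws):
            raise ValueError("all heads must share the input dimension")

    @property
    def n_heads(self) -> int:
        return len(self.Ws)

    @property
    def out_dim(self) -> int:
        d_head = self.Ws[0].shape[1]
        return d_head * self.n_heads if self.mode == "concat" else d_head

    def parameters(self) -> list[Tensor]:
        return [*self.Ws, *self.a_src, *self.a_dst]


@dataclass
class EmbeddingMatrix:
    """Learned gene embeddings, rows aligned to the graph node order."""

    Z: np.ndarray

    def __post_init__(self):
        if not np.isfinite(self.Z).all():
            raise ValueError("embeddings contain non-finite entries")


def init_gat_layer(d_in: int, d_head: int, n_heads: int, mode: str,
                   rng: np.random.Generator) -> GatLayerParams:
    """Glorot-uniform initialization per head."""
    lim_w = np.sqrt(6.0 / (d_in + d_head))
    lim_a = np.sqrt(6.0 / (d_head + 1))
    Ws, a_src, a_dst = [], [], []
    for _ in range(n_heads):
        Ws.append(Tensor(rng.uniform(-lim_w, lim_w, (d_in, d_head)), requires_grad=True))
        a_src.append(Tensor(rng.uniform(-lim_a, lim_a, (d_head,)), requires_grad=True))
        a_dst.append(Tensor(rng.uniform(-lim_a, lim_a, (d_head,)), requires_grad=True))
    return GatLayerParams(Ws, a_src, a_dst, mode)


def _attention_mask(graph) -> np.ndarray:
    """Boolean neighbor mask: observed edges plus self-loops."""
    adj = graph.adjacency if isinstance(graph, GeneGraph) else np.asarray(graph)
    return (adj != 0) | np.eye(adj.shape[0], dtype=bool)


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def attention_coefficients(layer: GatLayerParams, features, graph) -> list:
    """Per-head row-stochastic attention matrices alpha (n x n Tensors).

    alpha_ij is nonzero only for j in N_i (plus the self-loop) and each row
    sums to 1 over its neighborhood.
    """
    X = _lift(features)
    mask = _attention_mask(graph)
    if X.shape[0] != mask.shape[0]:
        raise ValueError("features are not row-aligned with the graph")
    alphas = []
    for W, al, ar in zip(layer.Ws, layer.a_src, layer.a_dst):
        H = X @ W                                   # n x d_head
        n = X.shape[0]
        e_src = (H @ al).reshape(n, 1)
        e_dst = (H @ ar).reshape(1, n)
        scores = (e_src + e_dst).leaky_relu(layer.leaky_slope)
        alphas.append(masked_softmax_rows(scores, mask))
    return alphas


def gat_layer_forward(layer: GatLayerParams, features, graph) -> Tensor:
    """One GAT layer: neighborhood-weighted sums per head, ELU, then head
    concatenation (layer 1) or averaging (layer 2)."""
    X = _lift(features)
    alphas = attention_coefficients(layer, X, graph)
    if layer.mode == "concat":
        heads = [(alpha @ (X @ W)).elu() for alpha, W in zip(alphas, layer.Ws)]
        return concat(heads, axis=1) if len(heads) > 1 else heads[0]
    acc = None
    for alpha, W in zip(alphas, layer.Ws):
        h = alpha @ (X @ W)
        acc = h if acc is None else acc + h
    return (acc / layer.n_heads).elu()


@dataclass
class GatEncoderParams:
    """The fixed two-layer stack: concatenated heads, then averaged heads."""

    layer1: GatLayerParams
    layer2: GatLayerParams

    def __post_init__(self):
        if self.layer1.mode != "concat" or self.layer2.mode != "average":
            raise ValueError("encoder requires layer1=concat, layer2=average")
        if self.layer2.Ws[0].shape[0] != self.layer1.out_dim:
            raise ValueError("layer widths are inconsistent")

    def parameters(self) -> list[Tensor]:
        return self.layer1.parameters() + self.layer2.parameters()


def init_encoder(d_in: int, d_head: int, n_heads: int, d_z: int,
                 rng: np.random.Generator) -> GatEncoderParams:
    l1 = init_gat_layer(d_in, d_head, n_heads, "concat", rng)
    l2 = init_gat_layer(d_head * n_heads, d_z, n_heads, "average", rng)
    return GatEncoderParams(l1, l2)


def encode_t(params: GatEncoderParams, X, graph) -> Tensor:
    """Differentiable forward pass; returns the embedding Tensor Z."""
    h1 = gat_layer_forward(params.layer1, X, graph)
    return gat_layer_forward(params.layer2, h1, graph)


def encode(params: GatEncoderParams, X, graph) -> EmbeddingMatrix:
    """Z = f(A, X) as a plain numpy matrix."""
    return EmbeddingMatrix(encode_t(params, X, graph).data.copy())
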