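"""Graph layers: spectral convolution (GCN) and attention (GAT, GATv2).

All layers operate on a dense node-feature matrix H (n x d) and a dense
symmetric adjacency A (n x n, optionally edge-weighted, without
self-loops — self-connections are added inside each layer).

GCN propagation:  H' = sigma(D~^{-1/2} A~ D~^{-1/2} H W),  A~ = A + I.

GAT attention logits use the concatenation form
``e_ij = LeakyReLU(a^T [W h_i || W h_j])`` which factorizes into a
source term ``a_src . W h_i`` plus a target term ``a_dst . W h_j``;
GATv2 moves the nonlinearity inside, ``e_ij = a^T LeakyReLU(W_l h_i +
W_r h_j)``, which makes the ranking of neighbors query-dependent
(dynamic attention).  Coefficients are softmax-normalized over each
node's neighborhood, which here always includes the node itself so
isolated nodes remain well-defined.

Edge weights (normalized shared-sample counts) enter the GCN through the
weighted adjacency; for the attention layers they are an optional
additive logit bias.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate

__all__ = ["Linear", "GCNLayer", "GATLayer", "GATv2Layer", "graph_readout"]

_NEG_INF = -1e9


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _activate(x: Tensor, activation: str) -> Tensor:
    if activation == "relu":
        return x.relu()
    if activation == "identity":
        return x
    if activation == "leaky_relu":
        return x.leaky_relu()
    raise ValueError(f"unknown activation {activation!r}")


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Tensor(_glorot(rng, (in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self) -> list[Tensor]:
        return [self.W] + ([self.b] if self.b is not None else [])


class GCNLayer:
    """Symmetrically normalized graph convolution with added self-loops."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str = "relu", bias: bool = True):
        self.lin = Linear(in_dim, out_dim, rng, bias=bias)
        self.activation = activation

    @staticmethod
    def propagation_matrix(adjacency: np.ndarray) -> np.ndarray:
        """D~^{-1/2} (A + I) D~^{-1/2}; weighted adjacencies give weighted degrees."""
        a_tilde = adjacency + np.eye(adjacency.shape[0])
        d = a_tilde.sum(axis=1)
        d_inv_sqrt = 1.0 / np.sqrt(d)  # self-loop guarantees d >= 1
        return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]

    def __call__(self, h: Tensor, adjacency: np.ndarray) -> Tensor:
        p = Tensor(self.propagation_matrix(adjacency))
        return _activate(p @ self.lin(h), self.activation)

    def parameters(self) -> list[Tensor]:
        return self.lin.parameters()


def _neighborhood_mask(adjacency: np.ndarray) -> np.ndarray:
    """0 on edges and self-loops, -inf elsewhere (as an additive mask)."""
    n = adjacency.shape[0]
    connected = (adjacency != 0) | np.eye(n, dtype=bool)
    return np.where(connected, 0.0, _NEG_INF)


class GATLayer:
    """Multi-head static graph attention (concatenation-form logits)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 n_heads: int = 1, concat: bool = True,
                 activation: str = "relu", negative_slope: float = 0.2,
                 edge_bias: bool = False):
        self.n_heads = n_heads
        self.concat = concat
        self.activation = activation
        self.negative_slope = negative_slope
        self.edge_bias = edge_bias
        self.W = [Tensor(_glorot(rng, (in_dim, out_dim)), requires_grad=True)
                  for _ in range(n_heads)]
        # attention vector a of length 2*out_dim, split into source/target halves
        self.a_src = [Tensor(_glorot(rng, (out_dim, 1)), requires_grad=True)
                      for _ in range(n_heads)]
        self.a_dst = [Tensor(_glorot(rng, (out_dim, 1)), requires_grad=True)
                      for _ in range(n_heads)]

    def attention(self, h: Tensor, adjacency: np.ndarray,
                  head: int = 0) -> tuple[Tensor, Tensor]:
        """(logits e, coefficients alpha) for one head, dense n x n."""
        wh = h @ self.W[head]
        src = wh @ self.a_src[head]          # (n, 1)
        dst = wh @ self.a_dst[head]          # (n, 1)
        e = (src + dst.T).leaky_relu(self.negative_slope)
        if self.edge_bias:
            e = e + adjacency
        alpha = (e + _neighborhood_mask(adjacency)).softmax(axis=1)
        return e, alpha

    def __call__(self, h: Tensor, adjacency: np.ndarray) -> Tensor:
        outs = []
        for k in range(self.n_heads):
            _, alpha = self.attention(h, adjacency, head=k)
            outs.append(alpha @ (h @ self.W[k]))
        if self.concat:
            out = concatenate(outs, axis=1)
        else:
            out = outs[0]
            for o in outs[1:]:
                out = out + o
            out = out * (1.0 / self.n_heads)
        return _activate(out, self.activation)

    def parameters(self) -> list[Tensor]:
        return [*self.W, *self.a_src, *self.a_dst]


class GATv2Layer(GATLayer):
    """Dynamic attention: the nonlinearity precedes the attention vector.

    ``e_ij = a^T LeakyReLU(W_l h_i + W_r h_j)`` — because the LeakyReLU
    acts on the joint transform, which neighbor scores highest can differ
    per query node, unlike GAT's globally fixed neighbor ranking.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 n_heads: int = 1, concat: bool = True,
                 activation: str = "relu", negative_slope: float = 0.2,
                 edge_bias: bool = False):
        super().__init__(in_dim, out_dim, rng, n_heads=n_heads, concat=concat,
                         activation=activation, negative_slope=negative_slope,
                         edge_bias=edge_bias)
        # separate left/right transforms = W applied to the concatenation
        self.W_r = [Tensor(_glorot(rng, (in_dim, out_dim)), requires_grad=True)
                    for _ in range(n_heads)]
        self.a = [Tensor(_glorot(rng, (out_dim, 1)), requires_grad=True)
                  for _ in range(n_heads)]

    def attention(self, h: Tensor, adjacency: np.ndarray,
                  head: int = 0) -> tuple[Tensor, Tensor]:
        n = h.shape[0]
        left = h @ self.W[head]              # (n, d)
        right = h @ self.W_r[head]           # (n, d)
        d = left.shape[1]
        joint = (left.reshape(n, 1, d) + right.reshape(1, n, d)) \
            .leaky_relu(self.negative_slope)
        e = (joint.reshape(n * n, d) @ self.a[head]).reshape(n, n)
        if self.edge_bias:
            e = e + adjacency
        alpha = (e + _neighborhood_mask(adjacency)).softmax(axis=1)
        return e, alpha

    def __call__(self, h: Tensor, adjacency: np.ndarray) -> Tensor:
        outs = []
        for k in range(self.n_heads):
            _, alpha = self.attention(h, adjacency, head=k)
            outs.append(alpha @ (h @ self.W[k]))
        if self.concat:
            out = concatenate(outs, axis=1)
        else:
            out = outs[0]
            for o in outs[1:]:
                out = out + o
            out = out * (1.0 / self.n_heads)
        return _activate(out, self.activation)

    def parameters(self) -> list[Tensor]:
        return [*self.W, *self.W_r, *self.a]


def graph_readout(node_embeddings: Tensor, pooling: str = "mean") -> Tensor:
    """Permutation-invariant graph-level embedding from node embeddings."""
    if pooling == "mean":
        return node_embeddings.mean(axis=0)
    if pooling == "sum":
        return node_embeddings.sum(axis=0)
    if pooling == "max":
        return node_embeddings.max(axis=0)
    raise ValueError("pooling must be 'mean', 'sum' or 'max'")
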