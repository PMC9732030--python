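"""Heterogeneous graph construction and the layer-attention graph convolutional model.

The denoised association matrix A* (small molecules x miRNAs) and the two
normalized similarity matrices are assembled into one heterogeneous network
over nm + ns nodes (miRNA block first):

    AH = [[ ~SMR, A*^T ],          G = [[ mu ~SMR, A*^T ],
          [ A*,   ~SSM ]]               [ A*,  mu ~SSM ]]

where ``~S = D^{-1/2} S D^{-1/2}`` normalizes each similarity block and the
penalty factor ``mu`` up-weights within-type edges in the propagation graph
G.  Initial node features are the association pattern itself,
``H(0) = [[0, A*^T], [A*, 0]]``.

The encoder stacks L graph-convolution layers
``H(l+1) = ELU(D^{-1/2} G D^{-1/2} H(l) W(l))`` with edge dropout on the
normalized graph and feature dropout on layer inputs during training.
Trainable attention scalars a_l combine the L layer embeddings into final
miRNA embeddings Hm and SM embeddings Hs, and a bilinear decoder
``A' = sigmoid(Hm W' Hs^T)`` scores every miRNA-SM pair.

Training minimizes a class-weighted binary cross-entropy between A' and the
original binary association matrix over all pairs, with positives up-weighted
by the negative:positive count ratio to counter the extreme sparsity of
known associations.  The whole model is dense numpy; gradients are exact
(hand-derived backpropagation) and optimization uses Adam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_io import AssociationData, RunConfig
from .lrr import IALMConfig, denoise_associations
from .similarity import SimilarityMatrix

logger = logging.getLogger("smmira")


# ---------------------------------------------------------------------------
# graph construction


def _sym_normalize(S: np.ndarray, what: str = "matrix") -> np.ndarray:
    """D^{-1/2} S D^{-1/2} with zero-degree rows/columns mapped to zero."""
    d = S.sum(axis=1)
    if np.any(d == 0):
        logger.warning("%s has %d zero-degree node(s); their normalized rows are zero",
                       what, int((d == 0).sum()))
    inv_sqrt = np.zeros_like(d)
    np.divide(1.0, np.sqrt(d), out=inv_sqrt, where=d > 0)
    return (S * inv_sqrt[:, None]) * inv_sqrt[None, :]


@dataclass
class HeteroGraph:
    AH: np.ndarray        # heterogeneous adjacency, miRNA block first
    G: np.ndarray         # propagation graph (similarity blocks scaled by mu)
    H0: np.ndarray        # initial embeddings [[0, A*^T], [A*, 0]]
    degrees: np.ndarray   # row sums of G
    G_norm: np.ndarray    # D^{-1/2} G D^{-1/2}
    n_mirna: int
    n_sm: int

    @property
    def n_nodes(self) -> int:
        return self.n_mirna + self.n_sm


def build_hetero_graph(A_star: np.ndarray, SSM: SimilarityMatrix,
                       SMR: SimilarityMatrix, mu: float) -> HeteroGraph:
    """Assemble the heterogeneous network, propagation graph and initial features."""
    A_star = np.asarray(A_star, dtype=float)
    ns, nm = A_star.shape
    if SSM.n != ns:
        raise ValueError(f"SM similarity is {SSM.n}x{SSM.n} but A* has {ns} SM rows")
    if SMR.n != nm:
        raise ValueError(f"miRNA similarity is {SMR.n}x{SMR.n} but A* has {nm} miRNA columns")
    if mu <= 0:
        raise ValueError("penalty factor mu must be positive")

    smr_n = _sym_normalize(SMR.S, "miRNA similarity")
    ssm_n = _sym_normalize(SSM.S, "SM similarity")

    AH = np.block([[smr_n, A_star.T], [A_star, ssm_n]])
    G = np.block([[mu * smr_n, A_star.T], [A_star, mu * ssm_n]])
    H0 = np.block([[np.zeros((nm, nm)), A_star.T], [A_star, np.zeros((ns, ns))]])
    degrees = G.sum(axis=1)
    G_norm = _sym_normalize(G, "propagation graph")
    return HeteroGraph(AH=AH, G=G, H0=H0, degrees=degrees, G_norm=G_norm,
                       n_mirna=nm, n_sm=ns)


# ---------------------------------------------------------------------------
# model


@dataclass
class GCNModel:
    """Trainable state: per-layer weights, attention scalars, decoder matrix."""

    W: list[np.ndarray]       # W[0]: (nm+ns) x k, W[l>=1]: k x k
    a: np.ndarray             # L layer-attention scalars
    W_dec: np.ndarray         # k x k bilinear decoder
    dropout_edge: float = 0.6
    dropout_feature: float = 0.4

    @property
    def n_layers(self) -> int:
        return len(self.W)

    @property
    def embed_dim(self) -> int:
        return self.W[0].shape[1]

    def parameters(self) -> dict[str, np.ndarray]:
        params = {f"W{l}": self.W[l] for l in range(self.n_layers)}
        params["a"] = self.a
        params["W_dec"] = self.W_dec
        return params


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_model(n_nodes: int, k: int, L: int, rng: np.random.Generator,
               dropout_edge: float = 0.6, dropout_feature: float = 0.4,
               attn_init: str = "inverse_layer") -> GCNModel:
    """Symmetric-uniform (Glorot) weight init; attention a_l = 1/(l+1) by default."""
    W = [_glorot(rng, n_nodes, k)]
    W += [_glorot(rng, k, k) for _ in range(L - 1)]
    if attn_init == "inverse_layer":
        a = np.array([1.0 / (l + 1) for l in range(1, L + 1)])
    elif attn_init == "uniform":
        a = np.full(L, 1.0 / L)
    else:
        raise ValueError(f"unknown attn_init {attn_init!r}")
    W_dec = _glorot(rng, k, k)
    return GCNModel(W=W, a=a, W_dec=W_dec,
                    dropout_edge=dropout_edge, dropout_feature=dropout_feature)


def _elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def _elu_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))


def _forward(graph: HeteroGraph, model: GCNModel, training: bool,
             rng: np.random.Generator | None):
    """Run the encoder; returns (H_list, per-layer caches for backprop)."""
    if training and rng is None:
        raise ValueError("training forward pass requires an rng")
    H = graph.H0
    H_list: list[np.ndarray] = []
    caches = []
    for l, Wl in enumerate(model.W):
        Gd = graph.G_norm
        feat_scale = None
        if training:
            if model.dropout_edge > 0:
                keep = 1.0 - model.dropout_edge
                Gd = Gd * (rng.random(Gd.shape) < keep) / keep
            if model.dropout_feature > 0:
                keep = 1.0 - model.dropout_feature
                feat_scale = (rng.random(H.shape) < keep) / keep
        Hin = H if feat_scale is None else H * feat_scale
        P = Gd @ Hin
        Z = P @ Wl
        H = _elu(Z)
        if not np.isfinite(H).all():
            raise FloatingPointError(f"non-finite values in GCN layer {l + 1}")
        H_list.append(H)
        caches.append((Gd, feat_scale, P, Z))
    return H_list, caches


def gcn_forward(graph: HeteroGraph, model: GCNModel, training: bool = False,
                seed: int | None = None) -> list[np.ndarray]:
    """Return the L layer embeddings [H(1), ..., H(L)], each (nm+ns) x k.

    With ``training=False`` dropout is disabled and the pass is deterministic;
    with ``training=True`` the dropout masks are drawn from ``seed``.
    """
    rng = np.random.default_rng(seed) if training else None
    H_list, _ = _forward(graph, model, training, rng)
    return H_list


def attention_combine(H_list: list[np.ndarray], a: np.ndarray,
                      n_mirna: int) -> tuple[np.ndarray, np.ndarray]:
    """Weighted sum of layer embeddings, split into (Hm, Hs) blocks."""
    a = np.asarray(a, dtype=float)
    if len(a) != len(H_list):
        raise ValueError(f"{len(a)} attention scalars for {len(H_list)} layers")
    H = sum(al * Hl for al, Hl in zip(a, H_list))
    return H[:n_mirna], H[n_mirna:]


def decode(Hm: np.ndarray, Hs: np.ndarray, W_dec: np.ndarray) -> np.ndarray:
    """Bilinear decoder: sigmoid(Hm W' Hs^T), an nm x ns score matrix in (0, 1)."""
    return expit(Hm @ W_dec @ Hs.T)


# ---------------------------------------------------------------------------
# training


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _loss_and_grads(graph: HeteroGraph, model: GCNModel, target: np.ndarray,
                    w_pos: float, training: bool, rng: np.random.Generator | None):
    """Weighted-BCE loss and exact gradients for all trainable parameters.

    ``target`` is the binary association matrix in miRNA x SM orientation.
    """
    H_list, caches = _forward(graph, model, training, rng)
    nm = graph.n_mirna
    L = model.n_layers

    Hfin = sum(al * Hl for al, Hl in zip(model.a, H_list))
    Hm, Hs = Hfin[:nm], Hfin[nm:]
    Z = Hm @ model.W_dec @ Hs.T
    y = target
    N = Z.size
    # -[w+ y log p + (1-y) log(1-p)] written through softplus for stability
    loss = float(np.sum(w_pos * y * _softplus(-Z) + (1.0 - y) * _softplus(Z)) / N)
    p = expit(Z)
    dZ = (-w_pos * y * (1.0 - p) + (1.0 - y) * p) / N

    dW_dec = Hm.T @ dZ @ Hs
    dHm = dZ @ Hs @ model.W_dec.T
    dHs = dZ.T @ Hm @ model.W_dec
    dHfin = np.vstack([dHm, dHs])

    da = np.array([float(np.sum(dHfin * Hl)) for Hl in H_list])
    dW = [np.zeros_like(Wl) for Wl in model.W]
    # backprop through layers; each layer output receives attention gradient
    g = model.a[L - 1] * dHfin
    for l in range(L - 1, -1, -1):
        Gd, feat_scale, P, Zl = caches[l]
        dZl = g * _elu_grad(Zl)
        dW[l] = P.T @ dZl
        if l > 0:
            dHin = Gd.T @ (dZl @ model.W[l].T)
            if feat_scale is not None:
                dHin = dHin * feat_scale
            g = model.a[l - 1] * dHfin + dHin
    grads = {f"W{l}": dW[l] for l in range(L)}
    grads["a"] = da
    grads["W_dec"] = dW_dec
    return loss, grads


class AdamOptimizer:
    """Adam with the standard (beta1, beta2, eps) = (0.9, 0.999, 1e-8)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_model(data: AssociationData, SSM: SimilarityMatrix, SMR: SimilarityMatrix,
                cfg: RunConfig, ialm_cfg: IALMConfig | None = None,
                log_every: int = 0):
    """Run the full pipeline: denoise, build the graph, train, decode.

    Returns ``(model, A_prime)`` where ``A_prime`` is the reconstructed score
    matrix in miRNA x SM orientation (transpose it for SM x miRNA use).  The
    run is fully reproducible from ``cfg.seed``.
    """
    ialm_cfg = ialm_cfg or IALMConfig(alpha=cfg.lrr_alpha)
    lrr_res = denoise_associations(data, ialm_cfg, side=cfg.lrr_side)
    graph = build_hetero_graph(lrr_res.A_star, SSM, SMR, cfg.graph_penalty)

    rng = np.random.default_rng(cfg.seed)
    model = init_model(graph.n_nodes, cfg.embed_dim, cfg.n_layers, rng,
                       dropout_edge=cfg.dropout_edge,
                       dropout_feature=cfg.dropout_feature,
                       attn_init=cfg.attn_init)

    target = data.A.T  # miRNA x SM, binary
    n_pos = target.sum()
    n_neg = target.size - n_pos
    w_pos = (n_neg / n_pos) if (cfg.loss == "weighted_bce" and n_pos > 0) else 1.0

    params = model.parameters()
    opt = AdamOptimizer(params, lr=cfg.learning_rate)
    for epoch in range(cfg.epochs):
        loss, grads = _loss_and_grads(graph, model, target, w_pos,
                                      training=True, rng=rng)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        opt.step(params, grads)
        if log_every and (epoch % log_every == 0 or epoch == cfg.epochs - 1):
            logger.info("epoch %d loss %.6f", epoch, loss)

    H_list = gcn_forward(graph, model, training=False)
    Hm, Hs = attention_combine(H_list, model.a, graph.n_mirna)
    A_prime = decode(Hm, Hs, model.W_dec)
    return model, A_prime
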