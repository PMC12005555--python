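"""Graph-attention network predicting interaction parameters from a
contact map.

The network embeds node eigenvector features, applies edge-conditioned
dynamic-attention message passing (attention scores computed after the
nonlinearity, in the style of GATv2) interleaved with MLPs, and decodes
the latent node embedding Z with two heads: a bilinear epigenetic head
``L_hat_100 = Z W Z^T`` upsampled 2x to 50 kb, and a genomic-distance
head mapping the flattened embedding to the diagonals of a Toeplitz
``T_hat``.  The full forward pass is run on +X and -X and summed, making
the prediction exactly invariant to eigenvector sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..preprocess import ContactMap, coarsen_2x
from ..simulator import InteractionParams
from .autodiff import Adam, Tensor
from .graph import GraphInput, N_NODE_EIGVECS, build_graph, signed_log_transform

__all__ = [
    "GNNConfig",
    "PredictionOutput",
    "init_weights",
    "forward",
    "sign_invariant_forward",
    "train",
    "predict_params",
    "save_weights",
    "load_weights",
]


@dataclass
class GNNConfig:
    """Architecture and training hyperparameters (desk-scale defaults)."""

    n_message_layers: int = 2
    hidden_dim: int = 32
    n_attention_heads: int = 2
    mlp_hidden_dims: list[int] = field(default_factory=lambda: [64])
    k_node_eigvecs: int = N_NODE_EIGVECS
    learning_rate: float = 1e-3
    batch_size: int = 1
    n_epochs: int = 100
    seed: int = 0
    leaky_slope: float = 0.01
    n_nodes: int = 32  # fixed by the flattened-Z distance head

    def __post_init__(self) -> None:
        for name in ("n_message_layers", "hidden_dim", "n_attention_heads",
                     "k_node_eigvecs", "batch_size", "n_epochs", "n_nodes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.hidden_dim % self.n_attention_heads:
            raise ValueError("hidden_dim must be divisible by n_attention_heads")


@dataclass
class PredictionOutput:
    """Predicted interaction matrices at 50 kb: ``U_hat = L_hat + T_hat``."""

    L_hat: np.ndarray
    T_hat: np.ndarray

    @property
    def U_hat(self) -> np.ndarray:
        return self.L_hat + self.T_hat

    def as_params(self) -> InteractionParams:
        return InteractionParams(0.5 * (self.L_hat + self.L_hat.T), self.T_hat)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=shape)


def init_weights(config: GNNConfig) -> dict[str, Tensor]:
    """Initialize all learnable parameters (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    d = config.hidden_dim
    dh = d // config.n_attention_heads
    w: dict[str, Tensor] = {}

    def par(name: str, shape, zero=False):
        w[name] = Tensor(np.zeros(shape) if zero else _glorot(rng, shape), requires_grad=True)

    # sign-symmetrized per-column embedding: each eigenvector column is
    # passed through phi(v) + phi(-v) before columns are mixed, making
    # the whole network exactly invariant to per-column sign flips
    par("embed_W1", (1, config.k_node_eigvecs, d))
    par("embed_W2", (1, config.k_node_eigvecs, d))
    par("embed_mix_W", (d, d))
    par("embed_b", (1, d), zero=True)
    for layer in range(config.n_message_layers):
        for head in range(config.n_attention_heads):
            p = f"l{layer}_h{head}_"
            par(p + "Ws", (d, dh))
            par(p + "Wt", (d, dh))
            par(p + "We", (2, dh))
            par(p + "a", (1, 1, dh))
            par(p + "Wv", (d, dh))
            # value-side edge projection: lets contact magnitudes reach
            # the node embedding directly, not only through attention
            par(p + "Wev", (2, dh))
        dims = [d] + list(config.mlp_hidden_dims) + [d]
        for li, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            par(f"l{layer}_mlp{li}_W", (din, dout))
            par(f"l{layer}_mlp{li}_b", (1, dout), zero=True)
    par("bilinear_W", (d, d))
    w["bilinear_gain"] = Tensor(np.ones(1), requires_grad=True)
    n_flat = config.n_nodes * d
    dims = [n_flat] + list(config.mlp_hidden_dims) + [2 * config.n_nodes]
    for li, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
        par(f"thead_mlp{li}_W", (din, dout))
        par(f"thead_mlp{li}_b", (1, dout), zero=True)
    return w


def _mlp(x: Tensor, weights: dict[str, Tensor], prefix: str, n_layers: int, slope: float) -> Tensor:
    for li in range(n_layers):
        x = x @ weights[f"{prefix}{li}_W"] + weights[f"{prefix}{li}_b"]
        if li < n_layers - 1:
            x = x.leaky_relu(slope)
    return x


def _embed(graph: GraphInput, X: np.ndarray, weights: dict[str, Tensor], config: GNNConfig) -> Tensor:
    """Initial node embedding, exactly even in each eigenvector column.

    phi(v_c) mixes nodes through the (row-normalized) adjacency before
    the nonlinearity, so phi(v) + phi(-v) keeps relative-sign structure
    (e.g. |v_i + v_j| vs |v_i - v_j|) while being even per column.
    """
    A = graph.adjacency
    deg = A.sum(axis=1, keepdims=True)
    S = A / np.where(deg > 0, deg, 1.0)
    X = X * np.sqrt(X.shape[0])  # unit-norm eigvec entries -> O(1) scale
    V = X[:, :, None]  # (n, k, 1)
    # column-wise products keep sign flips bitwise-exact (a blocked GEMM
    # on the full matrix rounds columns differently when others change)
    SV = np.stack([S @ X[:, c] for c in range(X.shape[1])], axis=1)[:, :, None]
    pre = Tensor(V) * weights["embed_W1"] + Tensor(SV) * weights["embed_W2"]  # (n, k, d)
    sym = pre.leaky_relu(config.leaky_slope) + (-pre).leaky_relu(config.leaky_slope)
    h = sym.sum(axis=1)  # (n, d)
    return h @ weights["embed_mix_W"] + weights["embed_b"]


def _encode(graph: GraphInput, X: np.ndarray, weights: dict[str, Tensor], config: GNNConfig) -> Tensor:
    """Node features -> latent embedding Z via attention message passing."""
    A = graph.adjacency.astype(bool)
    E = graph.edge_features
    slope = config.leaky_slope
    n_mlp = len(config.mlp_hidden_dims) + 1
    h = _embed(graph, X, weights, config)
    for layer in range(config.n_message_layers):
        head_outs = []
        for head in range(config.n_attention_heads):
            p = f"l{layer}_h{head}_"
            s = h @ weights[p + "Ws"]  # (n, dh)
            t = h @ weights[p + "Wt"]
            e = Tensor.edge_project(E, weights[p + "We"])  # (n, n, dh)
            n, dh = s.shape
            pre = s.reshape(n, 1, dh) + t.reshape(1, n, dh) + e
            scores = (pre.leaky_relu(slope) * weights[p + "a"]).sum(axis=2)
            alpha = scores.masked_softmax(A, axis=1)  # (n, n)
            node_msg = alpha @ (h @ weights[p + "Wv"])
            ev = Tensor.edge_project(E, weights[p + "Wev"])  # (n, n, dh)
            edge_msg = (alpha.reshape(n, n, 1) * ev).sum(axis=1)
            head_outs.append(node_msg + edge_msg)
        msg = Tensor.concat(head_outs, axis=1)  # (n, d)
        h = _mlp(msg.leaky_relu(slope), weights, f"l{layer}_mlp", n_mlp, slope)
    return h


def _decode(Z: Tensor, weights: dict[str, Tensor], config: GNNConfig) -> tuple[Tensor, Tensor]:
    """Latent embedding -> (L_hat at 50 kb, T_hat at 50 kb) as Tensors."""
    n = Z.shape[0]
    W = weights["bilinear_W"]
    Wsym = (W + W.T) * 0.5  # symmetrized so L_hat is symmetric
    L100 = (Z @ Wsym @ Z.T) * weights["bilinear_gain"].reshape(1, 1)
    L_hat = L100.upsample2()
    n_mlp = len(config.mlp_hidden_dims) + 1
    flat = Z.reshape(1, n * Z.shape[1])
    t_vals = _mlp(flat, weights, "thead_mlp", n_mlp, config.leaky_slope)  # (1, 2n)
    T_hat = t_vals.reshape(2 * n).toeplitz_from_diags()
    return L_hat, T_hat


def _forward_tensors(
    graph: GraphInput, weights: dict[str, Tensor], config: GNNConfig, sign: float
) -> tuple[Tensor, Tensor]:
    Z = _encode(graph, sign * graph.node_features, weights, config)
    return _decode(Z, weights, config)


def forward(graph: GraphInput, weights: dict[str, Tensor], config: GNNConfig) -> PredictionOutput:
    """Single forward pass (no sign symmetrization)."""
    _check_graph(graph, config)
    L_hat, T_hat = _forward_tensors(graph, weights, config, +1.0)
    return PredictionOutput(L_hat=L_hat.data.copy(), T_hat=T_hat.data.copy())


def _sign_invariant_tensors(
    graph: GraphInput, weights: dict[str, Tensor], config: GNNConfig
) -> tuple[Tensor, Tensor]:
    Lp, Tp = _forward_tensors(graph, weights, config, +1.0)
    Lm, Tm = _forward_tensors(graph, weights, config, -1.0)
    return Lp + Lm, Tp + Tm


def sign_invariant_forward(
    graph: GraphInput, weights: dict[str, Tensor], config: GNNConfig
) -> PredictionOutput:
    """Run on +X and -X and sum, removing eigenvector sign ambiguity."""
    _check_graph(graph, config)
    L_hat, T_hat = _sign_invariant_tensors(graph, weights, config)
    return PredictionOutput(L_hat=L_hat.data.copy(), T_hat=T_hat.data.copy())


def _check_graph(graph: GraphInput, config: GNNConfig) -> None:
    if graph.node_features.shape[1] != config.k_node_eigvecs:
        raise ValueError(
            f"expected {config.k_node_eigvecs} node-feature columns, "
            f"got {graph.node_features.shape[1]}"
        )
    if graph.n != config.n_nodes:
        raise ValueError(
            f"graph has {graph.n} nodes but the model was configured for "
            f"{config.n_nodes} (the flattened-embedding distance head fixes m)"
        )


# ---------------------------------------------------------------------------
# Training


def _pair_loss(graph: GraphInput, U_dagger: np.ndarray, weights, config) -> Tensor:
    L_hat, T_hat = _sign_invariant_tensors(graph, weights, config)
    U_hat = L_hat + T_hat
    diff = U_hat.signed_log() - Tensor(U_dagger)
    return (diff * diff).mean()


def train(
    dataset,
    config: GNNConfig,
    validation_fraction: float = 0.1,
    patience: int | None = None,
    verbose: bool = False,
):
    """Train on (H, U) pairs; returns (weights, history dict).

    Graphs are built from the 2x-coarsened contact map of each pair; the
    loss is the MSE between signed-log transforms of the true and
    predicted U.  The split into train/validation is by sample index at
    a fixed seed; per-epoch losses are recorded for both.
    """
    if not dataset:
        raise ValueError("empty dataset")
    m = dataset[0].H.m
    if any(p.H.m != m for p in dataset):
        raise ValueError("all training pairs must share m")
    graphs = [build_graph(coarsen_2x(p.H)) for p in dataset]
    targets = [signed_log_transform(p.params.U) for p in dataset]

    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    order = rng.permutation(n)
    n_val = int(round(validation_fraction * n)) if n > 1 else 0
    val_idx = order[:n_val]
    train_idx = order[n_val:]

    weights = init_weights(config)
    opt = Adam(weights, lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = None
    bad_epochs = 0

    for epoch in range(config.n_epochs):
        perm = rng.permutation(len(train_idx))
        total = 0.0
        for bstart in range(0, len(perm), config.batch_size):
            batch = [train_idx[i] for i in perm[bstart : bstart + config.batch_size]]
            opt.zero_grad()
            loss_val = 0.0
            for idx in batch:
                loss = _pair_loss(graphs[idx], targets[idx], weights, config) * (1.0 / len(batch))
                loss.backward()
                loss_val += float(loss.data)
            opt.step()
            total += loss_val * len(batch)
        history["train_loss"].append(total / max(len(train_idx), 1))

        if n_val:
            val = np.mean(
                [float(_pair_loss(graphs[i], targets[i], weights, config).data) for i in val_idx]
            )
        else:
            val = history["train_loss"][-1]
        history["val_loss"].append(float(val))
        if verbose:
            print(f"epoch {epoch}: train {history['train_loss'][-1]:.4f} val {val:.4f}")
        if patience is not None:
            if val < best_val - 1e-6:
                best_val = val
                best_weights = {k: Tensor(p.data.copy(), requires_grad=True) for k, p in weights.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > patience:
                    weights = best_weights or weights
                    break
    return weights, history


def predict_params(H_exp: ContactMap, weights: dict[str, Tensor], config: GNNConfig) -> PredictionOutput:
    """50 kb map -> coarsen 2x -> build graph -> sign-invariant forward."""
    graph = build_graph(coarsen_2x(H_exp))
    return sign_invariant_forward(graph, weights, config)


def save_weights(weights: dict[str, Tensor], config: GNNConfig, path: str | Path) -> None:
    arrays = {k: p.data for k, p in weights.items()}
    np.savez_compressed(
        path,
        __config__=np.array(
            [
                config.n_message_layers,
                config.hidden_dim,
                config.n_attention_heads,
                config.k_node_eigvecs,
                config.n_nodes,
            ]
        ),
        __mlp_dims__=np.array(config.mlp_hidden_dims),
        **arrays,
    )


def load_weights(path: str | Path) -> tuple[dict[str, Tensor], GNNConfig]:
    with np.load(path) as z:
        cfgv = z["__config__"]
        config = GNNConfig(
            n_message_layers=int(cfgv[0]),
            hidden_dim=int(cfgv[1]),
            n_attention_heads=int(cfgv[2]),
            k_node_eigvecs=int(cfgv[3]),
            n_nodes=int(cfgv[4]),
            mlp_hidden_dims=[int(x) for x in z["__mlp_dims__"]],
        )
        weights = {
            k: Tensor(np.asarray(z[k]), requires_grad=True)
            for k in z.files
            if not k.startswith("__")
        }
    return weights, config
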