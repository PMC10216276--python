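"""Classical feature branches: cell-line 1-D CNN and drug GCN.

Both branches map their input to a 128-dimensional embedding and are fused
by concatenation into the 256-vector consumed by the prediction head:

* **Cell branch** — a 735-long binary genomic-mutation vector passes through
  three blocks of (1-D convolution -> ReLU -> non-overlapping max-pool),
  is flattened, and a fully connected layer produces 128 outputs. Channel
  plan (32, 64, 96), kernel width 8, pool width 3 by default; all
  configurable.
* **Drug branch** — a molecular graph passes through three graph-convolution
  layers (symmetric-normalized propagation with self-loops, Kipf-Welling
  style) with channel plan 78 -> 78 -> 156 -> 312, each followed by ReLU;
  global max pooling over nodes collapses the node dimension; then dense
  layers 312 -> 1024 (ReLU) -> 128.

Everything is plain NumPy. Each encoder exposes ``forward`` returning
``(output, cache)`` and ``backward`` consuming the upstream gradient plus
the cache, returning parameter gradients — the training loop in
:mod:`qdinn.pipeline` stitches these into full back-propagation.

The drug embedding is invariant under simultaneous permutation of the
graph's node order (normalized graph convolution is equivariant and max
pooling is permutation-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemgraph import MolecularGraph, N_ATOM_FEATURES

__all__ = [
    "CellLineProfile",
    "CellEncoderConfig",
    "DrugEncoderConfig",
    "CellLineEncoder",
    "DrugEncoder",
    "normalized_adjacency",
    "gcn_layer_forward",
    "fuse",
    "EMBED_DIM",
    "CELL_PROFILE_DIM",
]

#: Per-branch embedding width.
EMBED_DIM = 128
#: Length of the binary genomic-mutation vector describing a cell line.
CELL_PROFILE_DIM = 735


@dataclass
class CellLineProfile:
    """A tumor cell line as a binary genomic-mutation indicator vector."""

    mutations: np.ndarray
    cell_id: str = ""

    def validate(self) -> None:
        m = np.asarray(self.mutations)
        if m.shape != (CELL_PROFILE_DIM,):
            raise ValueError(
                f"mutations must have shape ({CELL_PROFILE_DIM},), got {m.shape}"
            )
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mutation entries must be 0 or 1")


def _profile_array(profile) -> np.ndarray:
    if isinstance(profile, CellLineProfile):
        return np.asarray(profile.mutations, dtype=float)
    return np.asarray(profile, dtype=float)


# ---------------------------------------------------------------------------
# layer primitives (forward + backward)
# ---------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


def _conv1d_forward(x, w, b):
    # x: (B, C_in, L); w: (C_out, C_in, K); valid convolution, stride 1.
    # im2col so the contraction runs through BLAS.
    c_out, c_in, k = w.shape
    windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
    out_len = windows.shape[2]
    col = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(
        -1, c_in * k
    )  # (B*out_len, C_in*K)
    y = col @ w.reshape(c_out, c_in * k).T + b
    y = y.reshape(x.shape[0], out_len, c_out).transpose(0, 2, 1)
    return y, col


def _conv1d_backward(dy, col, w, in_len):
    c_out, c_in, k = w.shape
    batch, _, out_len = dy.shape
    dy_col = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(-1, c_out)
    dw = (dy_col.T @ col).reshape(c_out, c_in, k)
    db = dy_col.sum(axis=0)
    dcol = (dy_col @ w.reshape(c_out, c_in * k)).reshape(
        batch, out_len, c_in, k
    )
    dx = np.zeros((batch, c_in, in_len))
    for j in range(k):
        dx[:, :, j:j + out_len] += dcol[:, :, :, j].transpose(0, 2, 1)
    return dx, dw, db


def _maxpool1d_forward(x, width):
    # non-overlapping pooling; a trailing remainder shorter than the window
    # is dropped
    n_windows = x.shape[2] // width
    xr = x[:, :, : n_windows * width].reshape(x.shape[0], x.shape[1], n_windows, width)
    idx = xr.argmax(axis=3)
    y = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
    return y, (idx, x.shape[2])


def _maxpool1d_backward(dy, cache, width):
    idx, in_len = cache
    batch, ch, n_windows = dy.shape
    dx = np.zeros((batch, ch, in_len))
    b_ix, c_ix, w_ix = np.indices((batch, ch, n_windows), sparse=True)
    dx[b_ix, c_ix, w_ix * width + idx] = dy
    return dx


# ---------------------------------------------------------------------------
# graph convolution
# ---------------------------------------------------------------------------

def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops.

    ``A_hat = D^{-1/2} (A + I) D^{-1/2}`` where ``D`` is the degree matrix
    of ``A + I``; every degree is >= 1, so the inverse root always exists.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a_loop = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_loop.sum(axis=1))
    return a_loop * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer_forward(
    node_features: np.ndarray,
    adjacency: np.ndarray,
    layer_weights: np.ndarray,
) -> np.ndarray:
    """One graph-convolution layer: ``ReLU(A_hat @ X @ W)``."""
    x = np.asarray(node_features, dtype=float)
    w = np.asarray(layer_weights, dtype=float)
    if x.shape[1] != w.shape[0]:
        raise ValueError(
            f"feature dim {x.shape[1]} does not match weight rows {w.shape[0]}"
        )
    if adjacency.shape[0] != x.shape[0]:
        raise ValueError("adjacency and node_features disagree on node count")
    return _relu(normalized_adjacency(adjacency) @ x @ w)


def _graph_norm_adj(graph: MolecularGraph) -> np.ndarray:
    # cached per graph: the topology is fixed while weights train
    if graph._norm_adj_cache is None:
        graph._norm_adj_cache = normalized_adjacency(graph.adjacency)
    return graph._norm_adj_cache


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellEncoderConfig:
    """Shape of the cell-line CNN branch (defaults mirror the reference
    drug-response CNN lineage; every value is overridable)."""

    n_features: int = CELL_PROFILE_DIM
    channels: tuple[int, ...] = (32, 64, 96)
    kernel: int = 8
    pool: int = 3
    embed_dim: int = EMBED_DIM
    dropout: float = 0.0


@dataclass(frozen=True)
class DrugEncoderConfig:
    """Shape of the drug GCN branch: GCN channel plan then two dense
    layers; the last GCN width equals the first dense input (312)."""

    gcn_channels: tuple[int, ...] = (N_ATOM_FEATURES, N_ATOM_FEATURES, 156, 312)
    fc_hidden: int = 1024
    embed_dim: int = EMBED_DIM
    dropout: float = 0.0


def _he(rng, fan_in, shape):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _linear_init(rng, fan_in, shape):
    return rng.normal(0.0, np.sqrt(1.0 / fan_in), size=shape)


def _dropout_forward(x, rate, rng):
    if rate <= 0.0 or rng is None:
        return x, None
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


class CellLineEncoder:
    """Three (conv -> ReLU -> max-pool) blocks, flatten, dense to 128."""

    def __init__(self, config: CellEncoderConfig, rng: np.random.Generator):
        self.config = config
        c = config
        self.params: dict[str, np.ndarray] = {}
        in_ch, length = 1, c.n_features
        for i, out_ch in enumerate(c.channels, start=1):
            fan_in = in_ch * c.kernel
            self.params[f"conv{i}_W"] = _he(rng, fan_in, (out_ch, in_ch, c.kernel))
            self.params[f"conv{i}_b"] = np.zeros(out_ch)
            length = (length - c.kernel + 1) // c.pool
            in_ch = out_ch
        if length < 1:
            raise ValueError("input too short for the configured conv stack")
        self.flat_dim = in_ch * length
        self.params["fc_W"] = _linear_init(rng, self.flat_dim, (self.flat_dim, c.embed_dim))
        self.params["fc_b"] = np.zeros(c.embed_dim)

    def forward(self, profiles: np.ndarray, rng: np.random.Generator | None = None):
        """Encode a batch of mutation vectors.

        ``profiles`` is (B, 735); returns ``(embeddings (B, 128), cache)``.
        ``rng`` is only consulted when dropout is configured.
        """
        x = np.atleast_2d(_profile_array(profiles))
        if x.shape[1] != self.config.n_features:
            raise ValueError(
                f"expected profiles of length {self.config.n_features}, "
                f"got {x.shape[1]}"
            )
        h = x[:, None, :]  # (B, 1, L)
        cache: dict = {"conv": []}
        for i in range(1, len(self.config.channels) + 1):
            w, b = self.params[f"conv{i}_W"], self.params[f"conv{i}_b"]
            pre, windows = _conv1d_forward(h, w, b)
            act = _relu(pre)
            pooled, pool_cache = _maxpool1d_forward(act, self.config.pool)
            cache["conv"].append((windows, pre, pool_cache, h.shape[2]))
            h = pooled
        flat = h.reshape(h.shape[0], -1)
        flat_d, mask = _dropout_forward(flat, self.config.dropout, rng)
        out = flat_d @ self.params["fc_W"] + self.params["fc_b"]
        cache["flat"] = flat_d
        cache["flat_shape"] = h.shape
        cache["drop_mask"] = mask
        return out, cache

    def backward(self, d_out: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Parameter gradients for an upstream gradient ``d_out`` (B, 128)."""
        grads = {
            "fc_W": cache["flat"].T @ d_out,
            "fc_b": d_out.sum(axis=0),
        }
        d_flat = d_out @ self.params["fc_W"].T
        if cache["drop_mask"] is not None:
            d_flat = d_flat * cache["drop_mask"]
        dh = d_flat.reshape(cache["flat_shape"])
        for i in range(len(self.config.channels), 0, -1):
            windows, pre, pool_cache, in_len = cache["conv"][i - 1]
            d_act = _maxpool1d_backward(dh, pool_cache, self.config.pool)
            d_pre = d_act * (pre > 0)
            dh, dw, db = _conv1d_backward(
                d_pre, windows, self.params[f"conv{i}_W"], in_len
            )
            grads[f"conv{i}_W"] = dw
            grads[f"conv{i}_b"] = db
        return grads


class DrugEncoder:
    """Three GCN layers, global max pool, dense 312 -> 1024 -> 128."""

    def __init__(self, config: DrugEncoderConfig, rng: np.random.Generator):
        self.config = config
        ch = config.gcn_channels
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(ch) - 1):
            self.params[f"gcn{i + 1}_W"] = _he(rng, ch[i], (ch[i], ch[i + 1]))
        self.params["fc1_W"] = _he(rng, ch[-1], (ch[-1], config.fc_hidden))
        self.params["fc1_b"] = np.zeros(config.fc_hidden)
        self.params["fc2_W"] = _linear_init(
            rng, config.fc_hidden, (config.fc_hidden, config.embed_dim)
        )
        self.params["fc2_b"] = np.zeros(config.embed_dim)

    @property
    def n_gcn_layers(self) -> int:
        return len(self.config.gcn_channels) - 1

    def forward(self, graph: MolecularGraph, rng: np.random.Generator | None = None):
        """Encode one molecular graph into a 128-vector; returns (y, cache)."""
        if graph.n_atoms < 1:
            raise ValueError("cannot encode an empty graph")
        a_hat = _graph_norm_adj(graph)
        h = graph.node_features
        cache: dict = {"gcn": [], "a_hat": a_hat}
        for i in range(1, self.n_gcn_layers + 1):
            ax = a_hat @ h
            pre = ax @ self.params[f"gcn{i}_W"]
            cache["gcn"].append((ax, pre))
            h = _relu(pre)
        pool_idx = h.argmax(axis=0)
        pooled = h[pool_idx, np.arange(h.shape[1])]
        cache["pool_idx"] = pool_idx
        cache["n_atoms"] = h.shape[0]
        pre_fc1 = pooled @ self.params["fc1_W"] + self.params["fc1_b"]
        hid = _relu(pre_fc1)
        hid_d, mask = _dropout_forward(hid, self.config.dropout, rng)
        out = hid_d @ self.params["fc2_W"] + self.params["fc2_b"]
        cache.update(pooled=pooled, pre_fc1=pre_fc1, hid=hid_d, drop_mask=mask)
        return out, cache

    def backward(self, d_out: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Parameter gradients for one graph; ``d_out`` has shape (128,)."""
        grads = {
            "fc2_W": np.outer(cache["hid"], d_out),
            "fc2_b": d_out,
        }
        d_hid = d_out @ self.params["fc2_W"].T
        if cache["drop_mask"] is not None:
            d_hid = d_hid * cache["drop_mask"]
        d_pre1 = d_hid * (cache["pre_fc1"] > 0)
        grads["fc1_W"] = np.outer(cache["pooled"], d_pre1)
        grads["fc1_b"] = d_pre1
        d_pooled = d_pre1 @ self.params["fc1_W"].T
        n_out = d_pooled.shape[0]
        dh = np.zeros((cache["n_atoms"], n_out))
        dh[cache["pool_idx"], np.arange(n_out)] = d_pooled
        a_hat = cache["a_hat"]
        for i in range(self.n_gcn_layers, 0, -1):
            ax, pre = cache["gcn"][i - 1]
            d_pre = dh * (pre > 0)
            grads[f"gcn{i}_W"] = ax.T @ d_pre
            if i > 1:
                dh = a_hat @ (d_pre @ self.params[f"gcn{i}_W"].T)
        return grads


def fuse(cell_embedding: np.ndarray, drug_embedding: np.ndarray) -> np.ndarray:
    """Concatenate the branch embeddings, drug block first (fixed order)."""
    cell = np.asarray(cell_embedding, dtype=float)
    drug = np.asarray(drug_embedding, dtype=float)
    if cell.shape[-1] != EMBED_DIM or drug.shape[-1] != EMBED_DIM:
        raise ValueError(
            f"both embeddings must have length {EMBED_DIM}, got "
            f"{cell.shape[-1]} and {drug.shape[-1]}"
        )
    return np.concatenate([drug, cell], axis=-1)
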