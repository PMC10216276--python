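"""Full drug-response models: hybrid quantum head vs. classical head.

Both variants share an identical classical trunk — the cell-line CNN and the
drug GCN of :mod:`qdinn.encoders`, fused into a 256-vector — and differ only
in the head that maps the fused vector to a predicted normalized IC50:

* ``hybrid``  — the quantum depth-infused layer (1320 trainable rotation
  angles) followed by the affine readout (2 scalars);
* ``classical`` — two dense layers 256 -> 8 (ReLU) -> 1. The first layer has
  256*8 + 8 = 2056 parameters, the second 9.

Raw IC50 values (any positive dose scale) are squashed into (0, 1) with the
logistic-like map ``norm(y) = 1 / (1 + y**0.1)``; training minimizes mean
squared error on the normalized scale. The map is strictly decreasing, so
*larger* normalized values mean *more potent* drugs, and it satisfies
``norm(y) + norm(1/y) = 1``.

Construction is fully seeded: the trunk is drawn from one seed stream and the
head from another, so a hybrid and a classical model built with the same seed
start from bit-identical trunks — the controlled comparison used by the
training-set-size experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemgraph import MolecularGraph
from .encoders import (
    CellEncoderConfig,
    CellLineEncoder,
    DrugEncoder,
    DrugEncoderConfig,
    EMBED_DIM,
    _profile_array,
    fuse,
)
from .quantum import CircuitGeometry, QDILayer, QDIParams

__all__ = [
    "ResponseRecord",
    "DrugResponseModel",
    "normalize_ic50",
    "denormalize_ic50",
    "mse",
    "save_checkpoint",
    "load_checkpoint",
]

_FUSED_DIM = 2 * EMBED_DIM
_CLASSICAL_HIDDEN = 8


def normalize_ic50(y):
    """Map raw IC50 ``y > 0`` to (0, 1): ``norm(y) = 1 / (1 + y**0.1)``."""
    arr = np.asarray(y, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("IC50 must be a finite positive number greater than zero")
    out = 1.0 / (1.0 + arr ** 0.1)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def denormalize_ic50(v):
    """Exact inverse of :func:`normalize_ic50`: ``y = (1/v - 1)**10``."""
    arr = np.asarray(v, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("normalized IC50 must lie strictly inside (0, 1)")
    out = (1.0 / arr - 1.0) ** 10
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def mse(predictions, targets) -> float:
    """Mean squared error ``(1/N) * sum_i (O_i - Y_i)**2``."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("mse requires at least one sample")
    return float(np.mean((p - t) ** 2))


@dataclass
class ResponseRecord:
    """One supervised example: a (drug, cell line) pair with its IC50."""

    drug_id: str
    cell_id: str
    ic50_raw: float
    ic50_norm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.ic50_raw <= 0 or not np.isfinite(self.ic50_raw):
            raise ValueError(
                f"ic50_raw must be positive and finite, got {self.ic50_raw} "
                f"for ({self.drug_id}, {self.cell_id})"
            )
        if self.ic50_norm is None:
            self.ic50_norm = normalize_ic50(self.ic50_raw)


class DrugResponseModel:
    """Trunk + head, with batched forward/backward for training.

    Parameters live in ``self.params`` — a flat dict of named NumPy arrays
    (scalars as 0-d arrays) that the optimizer updates in place.
    """

    KINDS = ("hybrid", "classical")

    def __init__(
        self,
        kind: str = "hybrid",
        seed: int = 0,
        geometry: CircuitGeometry | None = None,
        cell_config: CellEncoderConfig | None = None,
        drug_config: DrugEncoderConfig | None = None,
    ):
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {kind!r}")
        self.kind = kind
        self.seed = seed
        trunk_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        head_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        self.cell_encoder = CellLineEncoder(
            cell_config or CellEncoderConfig(), trunk_rng
        )
        self.drug_encoder = DrugEncoder(
            drug_config or DrugEncoderConfig(), trunk_rng
        )
        if self.cell_encoder.config.embed_dim != EMBED_DIM:
            raise ValueError("cell embedding width must be 128")
        self.params: dict[str, np.ndarray] = {}
        for name, arr in self.cell_encoder.params.items():
            self.params[f"cell.{name}"] = arr
        for name, arr in self.drug_encoder.params.items():
            self.params[f"drug.{name}"] = arr
        if kind == "hybrid":
            self.geometry = geometry if geometry is not None else CircuitGeometry()
            if self.geometry.n_features != _FUSED_DIM:
                raise ValueError(
                    f"circuit consumes {self.geometry.n_features} features "
                    f"but the fused embedding has {_FUSED_DIM}"
                )
            self.qdi = QDILayer(self.geometry)
            qp = QDIParams.initialize(self.geometry, head_rng)
            # scalars as 0-d arrays so the optimizer can update them in place
            self.qparams = QDIParams(
                qp.theta_initial, qp.theta_blocks,
                np.array(1.0), np.array(0.0),
            )
            self.params["head.theta_initial"] = self.qparams.theta_initial
            self.params["head.theta_blocks"] = self.qparams.theta_blocks
            self.params["head.out_scale"] = self.qparams.out_scale
            self.params["head.out_shift"] = self.qparams.out_shift
        else:
            self.geometry = None
            self.params["head.W1"] = head_rng.normal(
                0.0, np.sqrt(2.0 / _FUSED_DIM), size=(_FUSED_DIM, _CLASSICAL_HIDDEN)
            )
            self.params["head.b1"] = np.zeros(_CLASSICAL_HIDDEN)
            self.params["head.W2"] = head_rng.normal(
                0.0, np.sqrt(1.0 / _CLASSICAL_HIDDEN), size=(_CLASSICAL_HIDDEN, 1)
            )
            self.params["head.b2"] = np.zeros(1)

    # -- forward / backward ---------------------------------------------

    def forward_batch(self, graphs, profiles):
        """Predictions for a batch of (graph, profile) pairs.

        ``graphs`` is a sequence of :class:`MolecularGraph` (repeats are
        encoded once and reused); ``profiles`` is (B, 735). Returns
        ``(predictions (B,), cache)``.
        """
        profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
        batch = profiles.shape[0]
        if len(graphs) != batch:
            raise ValueError("graphs and profiles disagree on batch size")
        cell_out, cell_cache = self.cell_encoder.forward(profiles)
        unique: dict[int, int] = {}
        graph_list: list[MolecularGraph] = []
        sample_to_unique = np.empty(batch, dtype=int)
        for i, graph in enumerate(graphs):
            key = id(graph)
            if key not in unique:
                unique[key] = len(graph_list)
                graph_list.append(graph)
            sample_to_unique[i] = unique[key]
        drug_embs = np.empty((len(graph_list), EMBED_DIM))
        drug_caches = []
        for u, graph in enumerate(graph_list):
            emb, dcache = self.drug_encoder.forward(graph)
            drug_embs[u] = emb
            drug_caches.append(dcache)
        drug_out = drug_embs[sample_to_unique]
        fused = fuse(cell_out, drug_out)
        cache = {
            "cell_cache": cell_cache,
            "drug_caches": drug_caches,
            "sample_to_unique": sample_to_unique,
            "n_unique": len(graph_list),
            "fused": fused,
        }
        if self.kind == "hybrid":
            raw, state = self.qdi.forward(fused, self.qparams, return_state=True)
            raw = np.atleast_1d(raw)
            preds = float(self.qparams.out_scale) * raw + float(
                self.qparams.out_shift
            )
            cache.update(raw=raw, final_state=np.atleast_2d(state))
        else:
            pre1 = fused @ self.params["head.W1"] + self.params["head.b1"]
            h1 = np.maximum(pre1, 0.0)
            preds = (h1 @ self.params["head.W2"] + self.params["head.b2"])[:, 0]
            cache.update(pre1=pre1, h1=h1)
        return preds, cache

    def backward_batch(self, d_preds, cache) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter.

        ``d_preds`` is dLoss/dPrediction per sample, shape (B,).
        """
        d_preds = np.asarray(d_preds, dtype=float)
        fused = cache["fused"]
        grads: dict[str, np.ndarray] = {}
        if self.kind == "hybrid":
            raw = cache["raw"]
            qgrads = self.qdi.gradient(
                fused, self.qparams, final_state=cache["final_state"]
            )
            scale = float(self.qparams.out_scale)
            d_raw = d_preds * scale
            grads["head.out_scale"] = np.array(np.dot(d_preds, raw))
            grads["head.out_shift"] = np.array(d_preds.sum())
            grads["head.theta_initial"] = np.einsum(
                "b,blq->lq", d_raw, qgrads["theta_initial"]
            )
            grads["head.theta_blocks"] = np.einsum(
                "b,bnlq->nlq", d_raw, qgrads["theta_blocks"]
            )
            d_fused = d_raw[:, None] * qgrads["features"]
        else:
            h1, pre1 = cache["h1"], cache["pre1"]
            d_out = d_preds[:, None]
            grads["head.W2"] = h1.T @ d_out
            grads["head.b2"] = d_out.sum(axis=0)
            d_h1 = (d_out @ self.params["head.W2"].T) * (pre1 > 0)
            grads["head.W1"] = fused.T @ d_h1
            grads["head.b1"] = d_h1.sum(axis=0)
            d_fused = d_h1 @ self.params["head.W1"].T
        d_drug = d_fused[:, :EMBED_DIM]
        d_cell = d_fused[:, EMBED_DIM:]
        for name, g in self.cell_encoder.backward(d_cell, cache["cell_cache"]).items():
            grads[f"cell.{name}"] = g
        s2u = cache["sample_to_unique"]
        drug_grads: dict[str, np.ndarray] | None = None
        for u in range(cache["n_unique"]):
            upstream = d_drug[s2u == u].sum(axis=0)
            g = self.drug_encoder.backward(upstream, cache["drug_caches"][u])
            if drug_grads is None:
                drug_grads = g
            else:
                for name in g:
                    drug_grads[name] += g[name]
        for name, g in (drug_grads or {}).items():
            grads[f"drug.{name}"] = g
        return grads

    def predict(self, graph: MolecularGraph, profile) -> float:
        """Predicted normalized IC50 for a single (drug, cell line) pair."""
        preds, _ = self.forward_batch([graph], _profile_array(profile)[None, :])
        return float(preds[0])

    # -- bookkeeping -----------------------------------------------------

    def count_head_parameters(self):
        """Per-layer head parameter counts and their total."""
        if self.kind == "hybrid":
            counts = {
                "rotation_angles": self.qparams.n_rotation_angles,
                "readout_affine": 2,
            }
        else:
            counts = {
                "dense1": int(
                    self.params["head.W1"].size + self.params["head.b1"].size
                ),
                "dense2": int(
                    self.params["head.W2"].size + self.params["head.b2"].size
                ),
            }
        return counts, sum(counts.values())

    def count_trunk_parameters(self) -> int:
        return int(
            sum(
                v.size
                for k, v in self.params.items()
                if k.startswith(("cell.", "drug."))
            )
        )


def save_checkpoint(model: DrugResponseModel, path) -> None:
    """Write all parameters as a named-array archive plus a text manifest.

    The manifest (``<path>.manifest.txt``) lists ``name shape dtype`` per
    line, with the model kind on the first line.
    """
    arrays = {k: np.asarray(v) for k, v in model.params.items()}
    np.savez(path, **arrays)
    base = str(path)
    if base.endswith(".npz"):
        base = base[:-4]
    with open(base + ".manifest.txt", "w") as fh:
        fh.write(f"kind {model.kind}\n")
        for k in sorted(arrays):
            fh.write(f"{k} {list(arrays[k].shape)} {arrays[k].dtype}\n")


def load_checkpoint(model: DrugResponseModel, path) -> DrugResponseModel:
    """Load parameters saved by :func:`save_checkpoint` into ``model``.

    Shapes must match the model's architecture exactly.
    """
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
        names = set(data.files)
        expected = set(model.params)
        if names != expected:
            missing = expected - names
            extra = names - expected
            raise ValueError(
                f"checkpoint mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        for k in expected:
            arr = data[k]
            if arr.shape != np.asarray(model.params[k]).shape:
                raise ValueError(
                    f"shape mismatch for {k}: checkpoint {arr.shape} vs "
                    f"model {np.asarray(model.params[k]).shape}"
                )
            model.params[k][...] = arr
    return model
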