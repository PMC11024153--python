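"""Encoder/predictor model F = g . w with deterministic NumPy numerics.

The reference encoder is a GIN-style message-passing network (3 layers by
default, mean-pooling readout, edge-feature embeddings added to neighbour
messages) followed by a single affine predictor head.  Batch normalization
and dropout are deliberately absent so forward passes and gradients are
deterministic and batch-size robust, which the principal-gradient machinery
relies on.

Forward and reverse passes are written directly in NumPy: the reverse pass
is hand-derived and checked against central finite differences in the test
suite.  A trivial "bag-of-atoms" encoder (mean of atom embeddings) is also
provided for fast tests.

Parameter initialization draws every tensor from its own seeded stream, in
registration order, so that two configs that agree on the encoder produce
byte-identical extractor parameters regardless of the predictor width.
This is what makes principal gradients comparable across datasets with
different numbers of subtasks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import (
    MolecularGraph,
    NUM_ATOM_TYPES,
    NUM_BOND_DIRECTIONS,
    NUM_BOND_TYPES,
    NUM_CHIRALITY_TAGS,
    TaskSpec,
)
from .errors import ConfigurationError, DataError, NumericError

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ModelConfig:
    encoder: str = "gin"  # "gin" | "bag"
    encoder_depth: int = 3
    hidden_width: int = 64
    readout: str = "mean"
    predictor_out: int = 1
    init_seed: int = 0

    def __post_init__(self):
        if self.encoder not in ("gin", "bag"):
            raise ConfigurationError(f"unknown encoder {self.encoder!r}")
        if self.readout != "mean":
            raise ConfigurationError("only mean readout is supported")
        if self.encoder_depth < 1 or self.hidden_width < 1 or self.predictor_out < 1:
            raise ConfigurationError("depth, width and predictor_out must be positive")

    def with_predictor_out(self, n: int) -> "ModelConfig":
        return replace(self, predictor_out=n)


def _param_specs(config: ModelConfig):
    """Ordered (name, shape, init_bound, group) registration list.

    The order defines the flattening used for gradient vectors; extractor
    parameters always precede predictor parameters.
    """
    d = config.hidden_width
    specs = [
        ("atom_embed.z", (NUM_ATOM_TYPES, d), 1.0 / np.sqrt(d), "extractor"),
        ("atom_embed.chirality", (NUM_CHIRALITY_TAGS, d), 1.0 / np.sqrt(d), "extractor"),
    ]
    if config.encoder == "gin":
        for layer in range(config.encoder_depth):
            specs += [
                (f"gin{layer}.bond_embed.type", (NUM_BOND_TYPES, d), 1.0 / np.sqrt(d), "extractor"),
                (f"gin{layer}.bond_embed.direction", (NUM_BOND_DIRECTIONS, d), 1.0 / np.sqrt(d), "extractor"),
                (f"gin{layer}.mlp.W1", (d, d), 1.0 / np.sqrt(d), "extractor"),
                (f"gin{layer}.mlp.b1", (d,), 1.0 / np.sqrt(d), "extractor"),
                (f"gin{layer}.mlp.W2", (d, d), 1.0 / np.sqrt(d), "extractor"),
                (f"gin{layer}.mlp.b2", (d,), 1.0 / np.sqrt(d), "extractor"),
            ]
    specs += [
        ("predictor.W", (d, config.predictor_out), 1.0 / np.sqrt(d), "predictor"),
        ("predictor.b", (config.predictor_out,), 1.0 / np.sqrt(d), "predictor"),
    ]
    return specs


@dataclass
class ModelState:
    """Named parameter tensors split into feature extractor g and predictor w."""

    config: ModelConfig
    params: dict[str, np.ndarray]

    @property
    def extractor_names(self) -> list[str]:
        return [n for n, _, _, g in _param_specs(self.config) if g == "extractor"]

    @property
    def predictor_names(self) -> list[str]:
        return [n for n, _, _, g in _param_specs(self.config) if g == "predictor"]

    def copy(self) -> "ModelState":
        return ModelState(self.config, {k: v.copy() for k, v in self.params.items()})

    def extractor_size(self) -> int:
        return sum(self.params[n].size for n in self.extractor_names)


def init_model(config: ModelConfig) -> ModelState:
    """Seeded fan-in-uniform initialization, one stream per parameter.

    Streams are indexed by registration order, and extractor parameters are
    registered first, so the extractor is bit-identical across configs that
    differ only in ``predictor_out``.
    """
    base = config.init_seed % _SEED_MOD
    params: dict[str, np.ndarray] = {}
    for idx, (name, shape, bound, _group) in enumerate(_param_specs(config)):
        rng = np.random.default_rng(np.random.SeedSequence([base, idx]))
        if name.endswith((".b1", ".b2")) or name == "predictor.b":
            params[name] = np.zeros(shape, dtype=np.float64)
        else:
            params[name] = rng.uniform(-bound, bound, size=shape)
    return ModelState(config=config, params=params)


@dataclass
class GraphBatch:
    """A disjoint union of molecular graphs plus per-graph labels/masks."""

    node_features: np.ndarray  # (N, 2)
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_features: np.ndarray  # (E, 2)
    graph_id: np.ndarray  # (N,)
    n_graphs: int
    node_counts: np.ndarray  # (n_graphs,)
    labels: np.ndarray  # (n_graphs, n_subtasks)
    observed: np.ndarray  # bool, same shape


def make_batch(graphs: list[MolecularGraph], labels, observed) -> GraphBatch:
    if not graphs:
        raise DataError("empty batch")
    node_feat = np.concatenate([g.node_features for g in graphs])
    counts = np.array([g.n_nodes for g in graphs], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    src = np.concatenate([g.edge_src + off for g, off in zip(graphs, offsets)]) \
        if any(g.n_arcs for g in graphs) else np.empty(0, dtype=np.int64)
    dst = np.concatenate([g.edge_dst + off for g, off in zip(graphs, offsets)]) \
        if any(g.n_arcs for g in graphs) else np.empty(0, dtype=np.int64)
    efeat = np.concatenate([g.edge_features for g in graphs]) \
        if any(g.n_arcs for g in graphs) else np.empty((0, 2), dtype=np.int64)
    gid = np.repeat(np.arange(len(graphs)), counts)
    labels = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    observed = np.atleast_2d(np.asarray(observed, dtype=bool))
    return GraphBatch(node_feat, src, dst, efeat, gid, len(graphs), counts, labels, observed)


def _forward(state: ModelState, batch: GraphBatch):
    """Forward pass; returns (logits, cache) where cache feeds the backward."""
    p = state.params
    cfg = state.config
    h = p["atom_embed.z"][batch.node_features[:, 0]] + \
        p["atom_embed.chirality"][batch.node_features[:, 1]]
    cache = {"h0": h}
    layers = []
    if cfg.encoder == "gin":
        for layer in range(cfg.encoder_depth):
            last = layer == cfg.encoder_depth - 1
            bt = p[f"gin{layer}.bond_embed.type"][batch.edge_features[:, 0]]
            bd = p[f"gin{layer}.bond_embed.direction"][batch.edge_features[:, 1]]
            msg = h[batch.edge_src] + bt + bd
            agg = h.copy()
            np.add.at(agg, batch.edge_dst, msg)
            u1 = agg @ p[f"gin{layer}.mlp.W1"] + p[f"gin{layer}.mlp.b1"]
            r = np.maximum(u1, 0.0)
            pre = r @ p[f"gin{layer}.mlp.W2"] + p[f"gin{layer}.mlp.b2"]
            h_out = pre if last else np.maximum(pre, 0.0)
            layers.append({"agg": agg, "u1": u1, "r": r, "pre": pre, "last": last})
            h = h_out
    cache["layers"] = layers
    pooled = np.zeros((batch.n_graphs, h.shape[1]))
    np.add.at(pooled, batch.graph_id, h)
    pooled /= batch.node_counts[:, None]
    logits = pooled @ p["predictor.W"] + p["predictor.b"]
    cache["pooled"] = pooled
    return logits, cache


def _loss_and_dlogits(logits, labels, observed, task_type):
    mask = observed
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise DataError("batch has zero observed labels; caller should drop it")
    if task_type == "classification":
        z, y = logits, labels
        cell = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
        dlog = (1.0 / (1.0 + np.exp(-z)) - y) / n_obs
    else:
        diff = logits - labels
        absd = np.abs(diff)
        cell = np.where(absd < 1.0, 0.5 * diff**2, absd - 0.5)
        dlog = np.clip(diff, -1.0, 1.0) / n_obs
    loss = float((cell * mask).sum() / n_obs)
    return loss, dlog * mask


def forward_loss(state: ModelState, batch: GraphBatch, task: TaskSpec) -> float:
    """Mean loss over observed label cells: logistic cross-entropy for
    classification, smooth-L1 (beta=1) for regression."""
    logits, _ = _forward(state, batch)
    loss, _ = _loss_and_dlogits(logits, batch.labels, batch.observed, task.task_type)
    return loss


def loss_and_gradients(state: ModelState, batch: GraphBatch, task: TaskSpec):
    """Loss plus gradients for every parameter (extractor and predictor)."""
    p = state.params
    cfg = state.config
    logits, cache = _forward(state, batch)
    loss, dlogits = _loss_and_dlogits(logits, batch.labels, batch.observed, task.task_type)
    grads = {name: np.zeros_like(arr) for name, arr in p.items()}
    pooled = cache["pooled"]
    grads["predictor.W"] = pooled.T @ dlogits
    grads["predictor.b"] = dlogits.sum(axis=0)
    dpooled = dlogits @ p["predictor.W"].T
    dh = dpooled[batch.graph_id] / batch.node_counts[batch.graph_id][:, None]
    if cfg.encoder == "gin":
        for layer in reversed(range(cfg.encoder_depth)):
            c = cache["layers"][layer]
            dpre = dh if c["last"] else dh * (c["pre"] > 0)
            grads[f"gin{layer}.mlp.W2"] = c["r"].T @ dpre
            grads[f"gin{layer}.mlp.b2"] = dpre.sum(axis=0)
            dr = dpre @ p[f"gin{layer}.mlp.W2"].T
            du1 = dr * (c["u1"] > 0)
            grads[f"gin{layer}.mlp.W1"] = c["agg"].T @ du1
            grads[f"gin{layer}.mlp.b1"] = du1.sum(axis=0)
            dagg = du1 @ p[f"gin{layer}.mlp.W1"].T
            dh = dagg.copy()
            if batch.edge_src.size:
                dmsg = dagg[batch.edge_dst]
                np.add.at(dh, batch.edge_src, dmsg)
                np.add.at(grads[f"gin{layer}.bond_embed.type"], batch.edge_features[:, 0], dmsg)
                np.add.at(grads[f"gin{layer}.bond_embed.direction"], batch.edge_features[:, 1], dmsg)
    np.add.at(grads["atom_embed.z"], batch.node_features[:, 0], dh)
    np.add.at(grads["atom_embed.chirality"], batch.node_features[:, 1], dh)
    return loss, grads


def extractor_gradient(state: ModelState, batch: GraphBatch, task: TaskSpec) -> np.ndarray:
    """Flat gradient of the batch loss w.r.t. extractor parameters only.

    Flattening order is the registration order of the extractor tensors
    (row-major within each tensor), so vectors computed under a shared
    :class:`ModelConfig` align entry-by-entry across datasets.
    """
    _, grads = loss_and_gradients(state, batch, task)
    flat = np.concatenate([grads[n].ravel() for n in state.extractor_names])
    if not np.all(np.isfinite(flat)):
        raise NumericError(
            f"non-finite extractor gradient on batch of {batch.n_graphs} graphs"
        )
    return flat
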