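"""GO-specificity embeddings from edge-type classification on the typed DAG.

A two-layer GraphSAGE-style network with max-pooling neighbor aggregation
(120-dimensional in and out by default, batch normalization after each
activation) feeds a single-hidden-layer perceptron that classifies an
ordered vertex pair — the concatenation ``[h_u ; h_v]`` — into one of the
four edge types ``is_a``, ``part_of``, ``parent_is_a``, ``parent_part_of``.
Training on masked edges forces the node vectors to encode where a term
sits in the hierarchy; the final-layer vectors are then exported as
specificity embeddings for downstream fusion.

Message passing runs over the full graph each step (desk scale); the loss
is mini-batched over edge samples.  All dense math lives in ``goaqc._nn``.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from . import _nn
from .errors import TermNotFoundError, TrainingError
from .ontology import EDGE_TYPES, GODag

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; defaults follow the study's fine-tuning setup."""

    epochs: int = 5
    batch_size: int = 16
    warmup_steps: int = 300
    weight_decay: float = 0.01
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size <= 0 or self.warmup_steps < 0:
            raise ValueError("invalid training configuration")


@dataclass(frozen=True)
class EdgeSample:
    u: str
    v: str
    edge_type: str
    split: str  # "train" | "test"


def build_edge_dataset(
    dag: GODag, train_fraction: float = 0.74, rng: np.random.Generator | None = None
) -> list[EdgeSample]:
    """Assign every typed edge (reversals included) to exactly one split."""
    if not (0.0 <= train_fraction <= 1.0):
        raise ValueError("train_fraction must lie in [0, 1]")
    rng = rng or np.random.default_rng(0)
    edges = list(dag.edges)
    present = {e.edge_type for e in edges}
    for t in EDGE_TYPES:
        if t not in present:
            warnings.warn(f"edge type {t!r} absent from the graph", stacklevel=2)
    order = rng.permutation(len(edges))
    n_train = int(round(train_fraction * len(edges)))
    out = []
    for rank, j in enumerate(order):
        e = edges[j]
        out.append(EdgeSample(e.child_id, e.parent_id, e.edge_type,
                              "train" if rank < n_train else "test"))
    return out


# ---------------------------------------------------------------------------
# node feature providers
# ---------------------------------------------------------------------------

def ngram_name_features(dag: GODag, d: int = 120) -> dict[str, np.ndarray]:
    """Hashed bag of character 3-grams of the term name, L2-normalized."""
    table: dict[str, np.ndarray] = {}
    for tid, term in dag.terms.items():
        vec = np.zeros(d)
        text = f"#{term.name.lower()}#"
        for i in range(len(text) - 2):
            vec[zlib.crc32(text[i : i + 3].encode()) % d] += 1.0
        norm = np.linalg.norm(vec)
        table[tid] = vec / norm if norm else vec
    return table


def structural_features(dag: GODag, d: int = 120) -> dict[str, np.ndarray]:
    """[depth, fan-in (children), fan-out (parents)] tiled to dimension d.

    Slot 0 of each vector is the BFS depth from the nearest root.
    """
    depths = dag.depths()
    base = {}
    for tid in dag.terms:
        base[tid] = np.array(
            [float(depths.get(tid, 0)),
             float(len(dag.direct_children(tid))),
             float(len(dag.direct_parents(tid)))]
        )
    table = {}
    for tid, b in base.items():
        reps = int(np.ceil(d / 3))
        table[tid] = np.tile(b, reps)[:d]
    return table


def zero_features(dag: GODag, d: int = 120) -> dict[str, np.ndarray]:
    """Degenerate all-zero provider; the no-information control."""
    return {tid: np.zeros(d) for tid in dag.terms}


def project_features(table: dict[str, np.ndarray], d: int, seed: int = 0) -> dict[str, np.ndarray]:
    """Fixed-seed random projection to dimension d (for wide encoder outputs)."""
    src_d = len(next(iter(table.values())))
    proj = np.random.default_rng(seed).normal(0.0, 1.0 / np.sqrt(d), size=(src_d, d))
    return {tid: v @ proj for tid, v in table.items()}


_PROVIDERS = {
    "ngram": ngram_name_features,
    "structural": structural_features,
    "zero": zero_features,
}


def init_node_features(dag: GODag, provider, d: int = 120) -> dict[str, np.ndarray]:
    """Build one d-vector per vertex from a named or callable provider."""
    fn = _PROVIDERS[provider] if isinstance(provider, str) else provider
    try:
        table = fn(dag, d)
    except Exception as exc:
        raise TrainingError(f"feature provider failed: {exc}") from exc
    for tid in dag.terms:
        if tid not in table:
            raise TrainingError(f"feature provider produced no vector for term {tid}")
        if len(table[tid]) != d:
            raise TrainingError(f"feature vector for term {tid} has dimension "
                                f"{len(table[tid])} != {d}")
    return table


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class _SageLayer:
    """h_u = BN(ReLU(W_s x_u + W_n · maxpool_{v∈N(u)} ReLU(W_p x_v)))."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.pool = _nn.Linear(d_in, d_out, rng)
        self.self_lin = _nn.Linear(d_in, d_out, rng)
        self.neigh_lin = _nn.Linear(d_out, d_out, rng)
        self.norm = _nn.BatchNorm(d_out)
        self._cache: tuple | None = None

    def params(self) -> list[_nn.Param]:
        return (self.pool.params() + self.self_lin.params()
                + self.neigh_lin.params() + self.norm.params())

    def forward(self, x: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
        n, d_out = x.shape[0], self.pool.W.value.shape[1]
        zpre = self.pool.forward(x)
        z = np.maximum(zpre, 0.0)
        pooled = np.full((n, d_out), -np.inf)
        np.maximum.at(pooled, dst, z[src])
        isolated = ~np.isfinite(pooled)
        pooled[isolated] = 0.0
        s = self.self_lin.forward(x) + self.neigh_lin.forward(pooled)
        h = np.maximum(s, 0.0)
        out = self.norm.forward(h)
        self._cache = (zpre, z, pooled, isolated, s, src, dst)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        zpre, z, pooled, isolated, s, src, dst = self._cache
        dh = self.norm.backward(dout)
        ds = dh * (s > 0)
        dx = self.self_lin.backward(ds)
        dpooled = self.neigh_lin.backward(ds)
        dpooled = np.where(isolated, 0.0, dpooled)
        # max-pool backward: split gradient uniformly across tying maxima
        hit = (z[src] == pooled[dst]) & ~isolated[dst]
        counts = np.zeros_like(pooled)
        np.add.at(counts, dst, hit.astype(float))
        share = np.divide(dpooled, counts, out=np.zeros_like(dpooled), where=counts > 0)
        dz = np.zeros_like(z)
        np.add.at(dz, src, share[dst] * hit)
        dx += self.pool.backward(dz * (zpre > 0))
        return dx


class GnnModel:
    """Two SAGE layers plus an edge-type head over ordered endpoint pairs."""

    def __init__(self, dag: GODag, features: dict[str, np.ndarray],
                 cfg: TrainingConfig, d: int | None = None):
        self.node_ids = dag.term_ids()
        self.index = {tid: i for i, tid in enumerate(self.node_ids)}
        self.d = d or len(next(iter(features.values())))
        self.cfg = cfg
        self.x = np.stack([np.asarray(features[tid], dtype=float) for tid in self.node_ids])
        # message-passing edges: every typed edge (reversals included) carries
        # one directed message, so neighborhoods are effectively bidirectional
        self.msg_src = np.array([self.index[e.child_id] for e in dag.edges], dtype=int)
        self.msg_dst = np.array([self.index[e.parent_id] for e in dag.edges], dtype=int)
        rng = np.random.default_rng(cfg.seed)
        self.layers = [_SageLayer(self.d, self.d, rng), _SageLayer(self.d, self.d, rng)]
        self.head = _nn.mlp(2 * self.d, 2 * self.d, len(EDGE_TYPES), rng)
        self.edge_types = EDGE_TYPES
        self.trained = False
        self.loss_history: list[float] = []

    def params(self) -> list[_nn.Param]:
        return [p for layer in self.layers for p in layer.params()] + self.head.params()

    def node_embeddings(self) -> np.ndarray:
        h = self.x
        for layer in self.layers:
            h = layer.forward(h, self.msg_src, self.msg_dst)
        return h

    def _pair_logits(self, h: np.ndarray, ui: np.ndarray, vi: np.ndarray) -> np.ndarray:
        return self.head.forward(np.concatenate([h[ui], h[vi]], axis=1))


def train_edge_classifier(
    dag: GODag,
    features: dict[str, np.ndarray],
    edges: list[EdgeSample],
    cfg: TrainingConfig,
) -> GnnModel:
    """Fit the edge-type classifier on the train split of ``edges``."""
    model = GnnModel(dag, features, cfg)
    train = [e for e in edges if e.split == "train"]
    if cfg.epochs == 0:
        warnings.warn("epochs=0: returning an untrained model", stacklevel=2)
        return model
    if not train:
        raise TrainingError("empty training split")
    ui = np.array([model.index[e.u] for e in train])
    vi = np.array([model.index[e.v] for e in train])
    yi = np.array([EDGE_TYPES.index(e.edge_type) for e in train])

    rng = np.random.default_rng(cfg.seed + 1)
    opt = _nn.AdamW(model.params(), lr=cfg.learning_rate,
                    warmup_steps=cfg.warmup_steps, weight_decay=cfg.weight_decay)
    n = len(train)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            opt.zero_grad()
            h = model.x
            for layer in model.layers:
                h = layer.forward(h, model.msg_src, model.msg_dst)
            logits = model._pair_logits(h, ui[sel], vi[sel])
            loss, dlogits = _nn.softmax_xent(logits, yi[sel])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            dcat = model.head.backward(dlogits)
            dh = np.zeros_like(h)
            np.add.at(dh, ui[sel], dcat[:, : model.d])
            np.add.at(dh, vi[sel], dcat[:, model.d :])
            for layer in reversed(model.layers):
                dh = layer.backward(dh)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.loss_history.append(epoch_loss / max(n_batches, 1))
        logger.info("gnn epoch %d: loss %.4f", epoch, model.loss_history[-1])
    model.trained = True
    return model


def classify_edge(model: GnnModel, u: str, v: str) -> tuple[str, np.ndarray]:
    """Predicted type and 4-way probability vector for the ordered pair (u, v)."""
    for t in (u, v):
        if t not in model.index:
            raise TermNotFoundError(t)
    h = model.node_embeddings()
    logits = model._pair_logits(h, np.array([model.index[u]]), np.array([model.index[v]]))
    probs = _nn.softmax(logits)[0]
    return model.edge_types[int(np.argmax(probs))], probs


def predict_edge_types(model: GnnModel, samples: list[EdgeSample]) -> list[str]:
    h = model.node_embeddings()
    ui = np.array([model.index[e.u] for e in samples])
    vi = np.array([model.index[e.v] for e in samples])
    logits = model._pair_logits(h, ui, vi)
    return [model.edge_types[int(k)] for k in np.argmax(logits, axis=1)]


def extract_embeddings(model: GnnModel, dag: GODag) -> dict[str, np.ndarray]:
    """Final-layer node vectors, one per vertex, deterministic for a fixed model."""
    h = model.node_embeddings()
    return {tid: h[model.index[tid]].copy() for tid in dag.term_ids()}


def write_embeddings_tsv(table: dict[str, np.ndarray], handle) -> None:
    for tid in sorted(table):
        handle.write(tid + "\t" + "\t".join(f"{v:.6g}" for v in table[tid]) + "\n")


def save_model(model: GnnModel, path: str) -> None:
    """Checkpoint as JSON: weights plus a sidecar of dims/seed/edge order."""
    payload = {
        "sidecar": {
            "d": model.d,
            "seed": model.cfg.seed,
            "edge_types": list(model.edge_types),
            "trained": model.trained,
        },
        "node_ids": model.node_ids,
        "x": model.x.tolist(),
        "msg_src": model.msg_src.tolist(),
        "msg_dst": model.msg_dst.tolist(),
        "params": [p.value.tolist() for p in model.params()],
        "cfg": model.cfg.__dict__,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str, dag: GODag) -> GnnModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = TrainingConfig(**payload["cfg"])
    features = {tid: np.asarray(row, dtype=float)
                for tid, row in zip(payload["node_ids"], payload["x"])}
    model = GnnModel(dag, features, cfg, d=payload["sidecar"]["d"])
    for p, stored in zip(model.params(), payload["params"]):
        p.value[...] = np.asarray(stored, dtype=float)
    model.trained = payload["sidecar"]["trained"]
    return model
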