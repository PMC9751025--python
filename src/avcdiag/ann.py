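"""Small feed-forward diagnostic network trained with resilient backpropagation.

Architecture: markers → H hidden units (ReLU) → 2 output units (softmax over
normal/disease), fit by minimizing the summed cross-entropy against one-hot
labels. Optimization is Rprop+ — per-parameter adaptive step sizes with
weight backtracking on gradient sign changes — which is insensitive to the
gradient's magnitude and converges quickly on small tabular problems like
the 35-sample binary gene-score table.

After training, each marker's "gene weight" is the maximum of its H
input→hidden weights; the per-sample linear score is the dot product of the
binary gene scores with these gene weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genescore import GeneScoreTable
from .io_preprocess import DISEASE, NORMAL

# canonical Rprop+ step-size schedule
ETA_PLUS = 1.2
ETA_MINUS = 0.5
DELTA0 = 0.1
DELTA_MIN = 1e-6
DELTA_MAX = 50.0

CLASSES = (NORMAL, DISEASE)


@dataclass
class AnnModel:
    """Weights of the markers → H → 2 network plus training metadata."""

    W1: np.ndarray  # markers × H
    b1: np.ndarray  # H
    W2: np.ndarray  # H × 2
    b2: np.ndarray  # 2
    markers: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        p, h = self.W1.shape
        if self.b1.shape != (h,) or self.W2.shape != (h, 2) or self.b2.shape != (2,):
            raise ValueError("inconsistent weight shapes")
        if not all(
            np.all(np.isfinite(a)) for a in (self.W1, self.b1, self.W2, self.b2)
        ):
            raise ValueError("weights must be finite")

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[1]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(model: AnnModel, x: np.ndarray) -> np.ndarray:
    """Per-sample (p_normal, p_disease); rows sum to 1."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.W1.shape[0]:
        raise ValueError(
            f"marker count mismatch: model {model.W1.shape[0]}, input {x.shape[1]}"
        )
    hidden = np.maximum(x @ model.W1 + model.b1, 0.0)
    return _softmax(hidden @ model.W2 + model.b2)


def _loss_and_grads(params, shapes, x, onehot):
    W1, b1, W2, b2 = _unflatten(params, shapes)
    pre = x @ W1 + b1
    hid = np.maximum(pre, 0.0)
    logits = hid @ W2 + b2
    prob = _softmax(logits)
    # summed cross-entropy; clip only for the loss value, not the gradient
    loss = -np.sum(onehot * np.log(np.clip(prob, 1e-300, None)))
    dlogits = prob - onehot
    gW2 = hid.T @ dlogits
    gb2 = dlogits.sum(axis=0)
    dhid = dlogits @ W2.T
    dhid[pre <= 0] = 0.0
    gW1 = x.T @ dhid
    gb1 = dhid.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1.ravel(), gW2.ravel(), gb2.ravel()])
    return loss, grad, prob


def _unflatten(params, shapes):
    out, i = [], 0
    for shp in shapes:
        n = int(np.prod(shp))
        out.append(params[i : i + n].reshape(shp))
        i += n
    return out


def train(
    t: GeneScoreTable,
    labels,
    H: int = 5,
    seed: int = 0,
    stop_threshold: float = 0.01,
    max_steps: int = 100_000,
) -> AnnModel:
    """Fit the H-hidden-unit network to a gene-score table with Rprop+.

    Initial weights are uniform(−0.5, 0.5) from ``seed``; training stops when
    the largest absolute partial derivative of the summed cross-entropy drops
    below ``stop_threshold`` or after ``max_steps`` updates. The loss
    trajectory is kept in ``model.meta['history']``.
    """
    labels = np.asarray(labels)
    x = t.values
    if x.shape[0] < 4:
        raise ValueError("need at least 4 samples to train")
    if set(labels) - set(CLASSES):
        raise ValueError(f"labels must be in {CLASSES}")
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")
    onehot = np.zeros((len(labels), 2))
    onehot[labels == NORMAL, 0] = 1.0
    onehot[labels == DISEASE, 1] = 1.0

    p = x.shape[1]
    shapes = [(p, H), (H,), (H, 2), (2,)]
    n_params = sum(int(np.prod(s)) for s in shapes)
    rng = np.random.default_rng(seed)
    params = rng.uniform(-0.5, 0.5, size=n_params)

    delta = np.full(n_params, DELTA0)
    grad_prev = np.zeros(n_params)
    step_prev = np.zeros(n_params)
    history = []
    stop_reason = "max_steps"
    steps = 0
    for steps in range(1, max_steps + 1):
        loss, grad, _ = _loss_and_grads(params, shapes, x, onehot)
        history.append(loss)
        if np.max(np.abs(grad)) < stop_threshold:
            stop_reason = "gradient_threshold"
            steps -= 1
            break
        sign = grad_prev * grad
        inc, dec = sign > 0, sign < 0
        delta[inc] = np.minimum(delta[inc] * ETA_PLUS, DELTA_MAX)
        delta[dec] = np.maximum(delta[dec] * ETA_MINUS, DELTA_MIN)
        step = -np.sign(grad) * delta
        # backtracking: revert parameters whose gradient changed sign
        step[dec] = -step_prev[dec]
        params = params + step
        grad_eff = grad.copy()
        grad_eff[dec] = 0.0  # skip the adaptation on the next step
        grad_prev, step_prev = grad_eff, step

    final_loss, grad, prob = _loss_and_grads(params, shapes, x, onehot)
    W1, b1, W2, b2 = (a.copy() for a in _unflatten(params, shapes))
    accuracy = float(np.mean(np.argmax(prob, axis=1) == np.argmax(onehot, axis=1)))
    return AnnModel(
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        markers=t.marker_ids,
        meta={
            "seed": seed,
            "steps": steps,
            "final_loss": float(final_loss),
            "stop_reason": stop_reason,
            "training_accuracy": accuracy,
            "history": [float(v) for v in history],
        },
    )


def extract_gene_weights(model: AnnModel) -> pd.Series:
    """Per-marker gene weight: the maximum of its input→hidden weights.

    Hidden biases and the output layer are excluded — only the hidden-layer
    block of weights contributes.
    """
    return pd.Series(model.W1.max(axis=1), index=model.markers, name="gene_weight")


def diagnostic_values(model: AnnModel, t: GeneScoreTable) -> pd.DataFrame:
    """Output-node values and predicted class for every sample in the table."""
    if list(t.marker_ids) != list(model.markers):
        raise ValueError(
            f"marker mismatch: model {model.markers}, table {t.marker_ids}"
        )
    prob = forward(model, t.values)
    pred = np.where(prob[:, 1] > prob[:, 0], DISEASE, NORMAL)
    return pd.DataFrame(
        {
            "p_normal": prob[:, 0],
            "p_disease": prob[:, 1],
            "predicted": pred,
        },
        index=t.sample_ids,
    )


def linear_score(gene_weights: pd.Series, t: GeneScoreTable) -> pd.Series:
    """Per-sample Σ gene_score × gene_weight."""
    if set(gene_weights.index) != set(t.marker_ids):
        raise ValueError("marker sets of weights and score table differ")
    w = gene_weights.reindex(t.marker_ids).to_numpy()
    return pd.Series(t.values @ w, index=t.sample_ids, name="linear_score")


_MODEL_KEYS = ("W1", "b1", "W2", "b2", "markers")


def save_model(model: AnnModel, path) -> None:
    """Serialize to JSON with full float precision (bit-exact round trip)."""
    payload = {
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
        "markers": list(model.markers),
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> AnnModel:
    with open(path) as fh:
        payload = json.load(fh)
    for key in _MODEL_KEYS:
        if key not in payload:
            raise ValueError(f"model file missing key {key!r}: {path}")
    return AnnModel(
        W1=np.array(payload["W1"]),
        b1=np.array(payload["b1"]),
        W2=np.array(payload["W2"]),
        b2=np.array(payload["b2"]),
        markers=list(payload["markers"]),
        meta=payload.get("meta", {}),
    )
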