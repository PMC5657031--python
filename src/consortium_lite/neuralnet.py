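"""Decentralized training of a multilayer perceptron by gradient averaging.

One mini-batch = one training sample per site.  Every round each site draws
its next sample from its own shuffled order, computes the exact
backpropagated gradient of the cross-entropy loss, and uploads it; the
master averages the gradients (one vote per site, matching the one sample
each contributed) and broadcasts the average; every site applies the same
update W ← W − η·∇Q̄ to its weight replica.  Because the initialization is
broadcast once and every subsequent update is identical, all site replicas
stay bit-for-bit synchronized, and the trajectory equals centralized
mini-batch SGD whose batches are assembled from the same one-sample-per-site
groups in the same order.

Hidden activation is the logistic sigmoid by default (ReLU available); the
output layer is softmax with cross-entropy loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import pairwise_sum
from .federation import ConsortiumState, RoundTranscript, SiteDataset, run_decentralized

__all__ = [
    "MLPWeights",
    "init_mlp",
    "forward_backward",
    "fit_decentralized_mlp",
    "DecentralizedMLPClassifier",
]


@dataclass
class MLPWeights:
    """Per-layer (weight matrix, bias vector) pairs; shapes chain correctly."""

    layers: list  # [(W: (out, in), b: (out,)), ...]
    architecture: list
    init_seed: int = 0

    def copy(self) -> "MLPWeights":
        return MLPWeights(
            layers=[(W.copy(), b.copy()) for W, b in self.layers],
            architecture=list(self.architecture),
            init_seed=self.init_seed,
        )

    def flat(self) -> np.ndarray:
        return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in self.layers])


def init_mlp(layer_sizes: list, seed: int = 0) -> MLPWeights:
    """Scaled-Gaussian initialization, Var = 1/fan_in; biases start at zero."""
    if len(layer_sizes) < 2:
        raise ValueError("need at least input and output layer sizes")
    if any(s < 1 for s in layer_sizes):
        raise ValueError("zero-size layer")
    rng = np.random.default_rng(seed)
    layers = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        W = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_out, fan_in))
        layers.append((W, np.zeros(fan_out)))
    return MLPWeights(layers=layers, architecture=list(layer_sizes), init_seed=seed)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def forward_backward(
    weights: MLPWeights, x: np.ndarray, y_onehot: np.ndarray, activation: str = "logistic"
) -> tuple[float, list]:
    """Loss and exact gradient for one sample (softmax output, cross-entropy).

    Returns (Q, [(dW, db), ...]) with gradient entries shaped like the weights.
    """
    x = np.asarray(x, dtype=float).ravel()
    y_onehot = np.asarray(y_onehot, dtype=float).ravel()
    if x.shape[0] != weights.architecture[0]:
        raise ValueError("sample dimension does not match input layer")
    acts = [x]
    pre = []
    a = x
    for li, (W, b) in enumerate(weights.layers):
        z = W @ a + b
        if not np.all(np.isfinite(z)):
            raise FloatingPointError("non-finite activations in forward pass")
        pre.append(z)
        if li == len(weights.layers) - 1:
            a = _softmax(z)
        elif activation == "logistic":
            a = _sigmoid(z)
        elif activation == "relu":
            a = np.maximum(z, 0.0)
        else:
            raise ValueError(f"unknown activation {activation!r}")
        acts.append(a)
    probs = acts[-1]
    loss = float(-(y_onehot * np.log(np.maximum(probs, 1e-300))).sum())
    # softmax + cross-entropy: output-layer error = predicted - target
    delta = probs - y_onehot
    grads = [None] * len(weights.layers)
    for li in range(len(weights.layers) - 1, -1, -1):
        grads[li] = (np.outer(delta, acts[li]), delta.copy())
        if li > 0:
            W, _ = weights.layers[li]
            back = W.T @ delta
            if activation == "logistic":
                h = acts[li]
                delta = back * h * (1.0 - h)
            else:
                delta = back * (pre[li - 1] > 0)
    return loss, grads


class _MlpComputation:
    def __init__(self, architecture, learning_rate, epochs, activation, seed):
        self.architecture = architecture
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.activation = activation
        self.seed = seed
        self.site_state: dict[str, dict] = {}
        self.replicas: dict[str, MLPWeights] = {}

    def init_master(self, consortium, rng):
        w0 = init_mlp(self.architecture, seed=self.seed)
        self.replicas = {s.site_id: w0.copy() for s in consortium.sites}
        rounds_per_epoch = max(s.n for s in consortium.sites)
        state = {
            "weights": w0.copy(),  # master bookkeeping only; sites hold replicas
            "round": 0,
            "total_rounds": rounds_per_epoch * self.epochs,
            "loss_history": [],
        }
        return state, {"round": 0.0}

    def _next_sample(self, site, rng):
        st = self.site_state.get(site.site_id)
        if st is None:
            st = {"order": rng.permutation(site.n), "pos": 0}
            self.site_state[site.site_id] = st
        if st["pos"] >= len(st["order"]):
            st["order"] = rng.permutation(site.n)  # smaller sites recycle, reshuffled
            st["pos"] = 0
        idx = st["order"][st["pos"]]
        st["pos"] += 1
        return idx

    def local_step(self, site, broadcast, rng):
        weights = self.replicas[site.site_id]
        idx = self._next_sample(site, rng)
        x = site.X[idx]
        label = int(site.y[idx])
        onehot = np.zeros(self.architecture[-1])
        onehot[label] = 1.0
        loss, grads = forward_backward(weights, x, onehot, self.activation)
        payload = {"loss": loss}
        for li, (dW, db) in enumerate(grads):
            payload[f"dW{li}"] = dW
            payload[f"db{li}"] = db
        return payload

    def aggregate(self, uploads, state, rng):
        n_sites = len(uploads)
        ordered = sorted(uploads)
        mean_grads = []
        for li in range(len(self.architecture) - 1):
            dW = pairwise_sum([uploads[sid][f"dW{li}"] for sid in ordered]) / n_sites
            db = pairwise_sum([uploads[sid][f"db{li}"] for sid in ordered]) / n_sites
            mean_grads.append((dW, db))
        mean_loss = float(pairwise_sum([uploads[sid]["loss"] for sid in ordered])) / n_sites
        if not np.isfinite(mean_loss):
            raise FloatingPointError(
                f"training diverged (loss non-finite); try a learning rate below "
                f"{self.learning_rate:g}"
            )
        # every site applies the broadcast average to its own replica
        eta = self.learning_rate
        for sid in self.replicas:
            rep = self.replicas[sid]
            rep.layers = [
                (W - eta * dW, b - eta * db)
                for (W, b), (dW, db) in zip(rep.layers, mean_grads)
            ]
        state["weights"] = next(iter(self.replicas.values())).copy()
        state["loss_history"].append(mean_loss)
        state["round"] += 1
        stop = state["round"] >= state["total_rounds"]
        return state, {"round": float(state["round"]), "mean_loss": mean_loss}, stop


def fit_decentralized_mlp(
    consortium: ConsortiumState,
    architecture: list,
    learning_rate: float = 0.1,
    epochs: int = 1,
    activation: str = "logistic",
    seed: Optional[int] = None,
    record_payloads: bool = True,
) -> tuple[MLPWeights, list, RoundTranscript]:
    """Train an MLP across sites; one sample per site per round.

    An epoch is one pass of the largest site; smaller sites cycle through
    reshuffled orders.  Returns (weights, per-round mean loss, transcript).
    The weight replicas at all sites are asserted identical at the end.
    """
    seed = consortium.master_seed if seed is None else seed
    comp = _MlpComputation(architecture, learning_rate, epochs, activation, seed)
    rounds = max(s.n for s in consortium.sites) * epochs
    state, transcript = run_decentralized(
        comp, consortium, max_rounds=rounds, record_payloads=record_payloads
    )
    flats = [rep.flat() for rep in comp.replicas.values()]
    for f in flats[1:]:
        if not np.array_equal(f, flats[0]):
            raise AssertionError("site weight replicas desynchronized")
    return state["weights"], state["loss_history"], transcript


class DecentralizedMLPClassifier(ClassifierMixin, BaseEstimator):
    """Softmax MLP trained by decentralized per-round gradient averaging."""

    def __init__(
        self,
        hidden_layer_sizes: tuple = (16,),
        learning_rate: float = 0.1,
        epochs: int = 5,
        activation: str = "logistic",
        random_state: int = 0,
        record_transcript: bool = False,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.activation = activation
        self.random_state = random_state
        self.record_transcript = record_transcript

    def fit(self, X, y, sites=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if sites is None:
            sites = np.zeros(X.shape[0], dtype=int)
        sites = np.asarray(sites)
        labels = sorted(set(sites.tolist()), key=str)
        width = max(2, max(len(str(lab)) for lab in labels))
        names = [f"f{j}" for j in range(X.shape[1])]
        datasets = [
            SiteDataset(
                site_id=f"site-{str(lab):0>{width}}",
                X=X[sites == lab],
                feature_names=list(names),
                y=y_idx[sites == lab].astype(float),
                y_name="label",
            )
            for lab in labels
        ]
        consortium = ConsortiumState(sites=datasets, master_seed=self.random_state)
        architecture = [X.shape[1], *self.hidden_layer_sizes, len(self.classes_)]
        weights, losses, transcript = fit_decentralized_mlp(
            consortium,
            architecture,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            activation=self.activation,
            record_payloads=self.record_transcript,
        )
        self.weights_ = weights
        self.loss_history_ = losses
        self.transcript_ = transcript
        self.n_features_in_ = X.shape[1]
        return self

    def _forward(self, X):
        A = np.atleast_2d(np.asarray(X, dtype=float))
        for li, (W, b) in enumerate(self.weights_.layers):
            Z = A @ W.T + b
            if li == len(self.weights_.layers) - 1:
                Z -= Z.max(axis=1, keepdims=True)
                E = np.exp(Z)
                A = E / E.sum(axis=1, keepdims=True)
            elif self.activation == "logistic":
                A = _sigmoid(Z)
            else:
                A = np.maximum(Z, 0.0)
        return A

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        return self._forward(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
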