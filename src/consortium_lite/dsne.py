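"""Decentralized t-SNE (dSNE) anchored on a shared public reference set.

Every site holds private high-dimensional points X_p; a public reference set
X_s is available to all sites.  Each site builds one affinity matrix over its
union X_p ∪ X_s, so the shared points' affinities differ per site by design —
that coupling is what lets local embedding information flow across sites.
Per round the master broadcasts the shared embedding Y_s; each site takes one
gradient step on its union embedding, applies the local part to its private
Y_p, and uploads only the gradient of the shared part; the master averages
the shared gradients (one unweighted vote per site) and updates Y_s with the
classic momentum/gain schedule.  Y_s is therefore identical at every site
after each broadcast and serves as the common frame of reference, while the
private Y_p never leave their sites.

The centralized optimizer (:func:`fit_centralized_tsne`) shares every kernel
and the update rule, so a single site holding no private points reproduces it
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from ._utils import pairwise_sum
from .federation import ConsortiumState, RoundTranscript, SiteDataset, run_decentralized

__all__ = [
    "AffinityMatrix",
    "EmbeddingState",
    "conditional_affinities",
    "tsne_gradient",
    "kl_divergence",
    "fit_centralized_tsne",
    "fit_dsne",
    "DecentralizedTSNE",
]

MACHINE_EPS = 1e-12


@dataclass
class AffinityMatrix:
    """Symmetrized pairwise probabilities with entropy-calibrated bandwidths."""

    P: np.ndarray
    perplexity: float
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.P < 0):
            raise ValueError("affinities must be nonnegative")
        if abs(self.P.sum() - 1.0) > 1e-8:
            raise ValueError("affinities must sum to 1")


@dataclass
class EmbeddingState:
    """Shared and per-site 2-D coordinates plus optimizer buffers."""

    Y_s: np.ndarray
    Y_p: dict = field(default_factory=dict)
    iteration: int = 0
    gains: dict = field(default_factory=dict)
    velocity: dict = field(default_factory=dict)
    kl_history: dict = field(default_factory=dict)


def _squared_distances(X: np.ndarray) -> np.ndarray:
    s = (X**2).sum(axis=1)
    d = s[:, None] + s[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def conditional_affinities(X: np.ndarray, perplexity: float) -> AffinityMatrix:
    """Gaussian conditional affinities with per-point bandwidths.

    Each point's precision is set by bisection so the conditional
    distribution's entropy matches log2(perplexity) bits; the conditionals
    are then symmetrized, p_ij = (p_{j|i} + p_{i|j}) / (2n).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 0 < perplexity < n:
        raise ValueError(f"perplexity must lie in (0, n_points={n})")
    D = _squared_distances(X)
    target = np.log(perplexity)  # entropy target in nats
    P = np.zeros((n, n))
    sigmas = np.empty(n)
    for i in range(n):
        d_i = np.delete(D[i], i)
        beta, lo, hi = 1.0, 0.0, np.inf
        bracketed = False
        for it in range(100):
            w = np.exp(-d_i * beta)
            sw = w.sum()
            if sw <= 0:
                h = 0.0
            else:
                p = w / sw
                nz = p > 0
                h = float(-(p[nz] * np.log(p[nz])).sum())
            diff = h - target
            if abs(diff) < 1e-7:
                bracketed = True
                break
            if diff > 0:  # entropy too high -> narrow the kernel
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else 0.5 * (beta + hi)
            else:
                hi = beta
                beta = beta / 2.0 if lo == 0.0 else 0.5 * (beta + lo)
            if it == 49 and (lo == 0.0 or not np.isfinite(hi)):
                raise RuntimeError(
                    f"perplexity bisection failed to bracket for point {i}"
                )
        if not bracketed and abs(diff) > 1e-5:
            raise RuntimeError(f"perplexity bisection did not converge for point {i}")
        sigmas[i] = np.sqrt(0.5 / beta)
        w = np.exp(-d_i * beta)
        row = np.zeros(n)
        row[np.arange(n) != i] = w / w.sum()
        P[i] = row
    P = (P + P.T) / (2.0 * n)
    return AffinityMatrix(P=P, perplexity=float(perplexity), sigmas=sigmas)


def _student_t_kernel(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    num = 1.0 / (1.0 + _squared_distances(Y))
    np.fill_diagonal(num, 0.0)
    Q = num / max(num.sum(), MACHINE_EPS)
    return num, Q


def tsne_gradient(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """KL gradient with the Student-t low-dimensional kernel.

    grad_i = 4 Σ_j (p_ij − q_ij) (y_i − y_j) / (1 + ||y_i − y_j||²).
    Coincident points contribute zero (their difference vector vanishes).
    """
    P = np.asarray(P, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    num, Q = _student_t_kernel(Y)
    W = (P - Q) * num
    return 4.0 * ((np.diag(W.sum(axis=1)) - W) @ Y)


def kl_divergence(P: np.ndarray, Y: np.ndarray) -> float:
    _, Q = _student_t_kernel(Y)
    mask = P > 0
    return float((P[mask] * np.log(P[mask] / np.maximum(Q[mask], MACHINE_EPS))).sum())


@dataclass
class _Optimizer:
    """Momentum + adaptive-gain updates with the classic t-SNE schedule."""

    n_points: int
    learning_rate: float = 100.0
    momentum_start: float = 0.5
    momentum_final: float = 0.8
    momentum_switch: int = 250
    adaptive_gains: bool = True

    def __post_init__(self) -> None:
        self.gains = np.ones((self.n_points, 2))
        self.velocity = np.zeros((self.n_points, 2))

    def momentum(self, iteration: int) -> float:
        return self.momentum_start if iteration < self.momentum_switch else self.momentum_final

    def step(self, Y: np.ndarray, grad: np.ndarray, iteration: int) -> np.ndarray:
        if self.n_points == 0:
            return Y
        if self.adaptive_gains:
            same_sign = np.sign(grad) == np.sign(self.velocity)
            self.gains[~same_sign] += 0.2
            self.gains[same_sign] *= 0.8
            np.clip(self.gains, 0.01, None, out=self.gains)
        self.velocity = self.momentum(iteration) * self.velocity - (
            self.learning_rate * self.gains * grad
        )
        Y = Y + self.velocity
        if not np.all(np.isfinite(Y)):
            raise FloatingPointError("non-finite embedding update")
        return Y


@dataclass
class _Schedule:
    perplexity: float = 30.0
    n_iter: int = 1000
    learning_rate: float = 100.0
    early_exaggeration: float = 4.0
    exaggeration_iter: int = 100
    momentum_start: float = 0.5
    momentum_final: float = 0.8
    momentum_switch: int = 250
    adaptive_gains: bool = True

    def exaggeration(self, iteration: int) -> float:
        return self.early_exaggeration if iteration < self.exaggeration_iter else 1.0

    def optimizer(self, n_points: int) -> _Optimizer:
        return _Optimizer(
            n_points=n_points,
            learning_rate=self.learning_rate,
            momentum_start=self.momentum_start,
            momentum_final=self.momentum_final,
            momentum_switch=self.momentum_switch,
            adaptive_gains=self.adaptive_gains,
        )


def fit_centralized_tsne(
    X: np.ndarray,
    perplexity: float = 30.0,
    n_iter: int = 1000,
    learning_rate: float = 100.0,
    seed: int = 0,
    schedule: Optional[_Schedule] = None,
) -> np.ndarray:
    """Reference single-machine t-SNE (the pooled baseline for dSNE)."""
    sched = schedule or _Schedule(
        perplexity=perplexity, n_iter=n_iter, learning_rate=learning_rate
    )
    P = conditional_affinities(X, sched.perplexity).P
    rng = np.random.default_rng(seed)
    Y = rng.normal(0.0, 1e-4, size=(X.shape[0], 2))
    opt = sched.optimizer(X.shape[0])
    for j in range(sched.n_iter):
        grad = tsne_gradient(P * sched.exaggeration(j), Y)
        Y = opt.step(Y, grad, j)
    return Y


class _DsneComputation:
    def __init__(self, X_s: np.ndarray, sched: _Schedule, track_kl: bool):
        self.X_s = X_s
        self.sched = sched
        self.track_kl = track_kl
        self.site_state: dict[str, dict] = {}
        self.kl_history: dict[str, list] = {}

    def init_master(self, consortium, rng):
        n_s = self.X_s.shape[0]
        Y_s = rng.normal(0.0, 1e-4, size=(n_s, 2))
        state = {"Y_s": Y_s, "opt": self.sched.optimizer(n_s), "iter": 0}
        return state, {"Y_s": Y_s, "iteration": 0.0}

    def _site(self, site, rng):
        st = self.site_state.get(site.site_id)
        if st is None:
            X_p = site.X if site.n_local else np.empty((0, self.X_s.shape[1]))
            union = np.vstack([X_p, self.X_s])
            if union.shape[0] <= self.sched.perplexity:
                raise ValueError(
                    f"site {site.site_id!r}: union has {union.shape[0]} points, "
                    f"needs more than perplexity={self.sched.perplexity}"
                )
            st = {
                "P": conditional_affinities(union, self.sched.perplexity).P,
                "n_p": X_p.shape[0],
                "Y_p": rng.normal(0.0, 1e-4, size=(X_p.shape[0], 2)),
                "opt": self.sched.optimizer(X_p.shape[0]),
            }
            self.site_state[site.site_id] = st
        return st

    def local_step(self, site, broadcast, rng):
        st = self._site(site, rng)
        j = int(broadcast["iteration"])
        Y_s = np.asarray(broadcast["Y_s"])
        Y_union = np.vstack([st["Y_p"], Y_s])
        P_eff = st["P"] * self.sched.exaggeration(j)
        grad = tsne_gradient(P_eff, Y_union)
        n_p = st["n_p"]
        if n_p:
            st["Y_p"] = st["opt"].step(st["Y_p"], grad[:n_p], j)
        if self.track_kl:
            self.kl_history.setdefault(site.site_id, []).append(
                kl_divergence(st["P"], Y_union)
            )
        return {"grad_shared": grad[n_p:]}

    def aggregate(self, uploads, state, rng):
        grads = [uploads[sid]["grad_shared"] for sid in sorted(uploads)]
        mean_grad = pairwise_sum(grads) / len(grads)
        j = state["iter"]
        state["Y_s"] = state["opt"].step(state["Y_s"], mean_grad, j)
        state["iter"] = j + 1
        stop = state["iter"] >= self.sched.n_iter
        return state, {"Y_s": state["Y_s"], "iteration": float(state["iter"])}, stop


class _DsneSite(SiteDataset):
    """SiteDataset that may legitimately hold zero private rows."""

    def __post_init__(self):  # allow empty X_p; skip base row-count check
        self.X = np.asarray(self.X, dtype=float).reshape(-1, len(self.feature_names))
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite site data")
        if not self.feature_types:
            self.feature_types = ["numeric"] * len(self.feature_names)

    @property
    def n_local(self) -> int:
        return self.X.shape[0]


def _as_dsne_site(site) -> "_DsneSite":
    if isinstance(site, _DsneSite):
        return site
    return _DsneSite(
        site_id=site.site_id,
        X=site.X,
        feature_names=list(site.feature_names),
        feature_types=list(site.feature_types),
    )


def fit_dsne(
    consortium: ConsortiumState,
    X_shared: np.ndarray,
    perplexity: float = 30.0,
    n_iter: int = 1000,
    learning_rate: float = 100.0,
    schedule: Optional[_Schedule] = None,
    track_kl: bool = False,
    record_payloads: bool = True,
) -> tuple[EmbeddingState, RoundTranscript]:
    """Multi-shot decentralized t-SNE over a consortium plus shared reference."""
    X_shared = np.atleast_2d(np.asarray(X_shared, dtype=float))
    if X_shared.shape[0] == 0:
        raise ValueError("reference required: shared dataset X_s is empty")
    sched = schedule or _Schedule(
        perplexity=perplexity, n_iter=n_iter, learning_rate=learning_rate
    )
    dsne_consortium = ConsortiumState(
        sites=[_as_dsne_site(s) for s in consortium.sites],
        master_seed=consortium.master_seed,
        config=consortium.config,
        name=consortium.name,
    )
    comp = _DsneComputation(X_shared, sched, track_kl)
    state, transcript = run_decentralized(
        comp, dsne_consortium, max_rounds=sched.n_iter, record_payloads=record_payloads
    )
    embedding = EmbeddingState(
        Y_s=state["Y_s"],
        Y_p={sid: st["Y_p"] for sid, st in comp.site_state.items()},
        iteration=state["iter"],
        gains={sid: st["opt"].gains for sid, st in comp.site_state.items()},
        velocity={sid: st["opt"].velocity for sid, st in comp.site_state.items()},
        kl_history=comp.kl_history,
    )
    return embedding, transcript


class DecentralizedTSNE(BaseEstimator):
    """2-D embedding of multi-site data through a shared public reference.

    ``fit_transform(X, sites=..., shared=...)`` takes per-row site labels and
    a Boolean mask marking the public reference rows; private rows are
    embedded at their sites, reference rows by the master, and the stacked
    embedding is returned in the original row order.
    """

    def __init__(
        self,
        perplexity: float = 30.0,
        n_iter: int = 1000,
        learning_rate: float = 100.0,
        early_exaggeration: float = 4.0,
        random_state: int = 0,
        record_transcript: bool = False,
    ):
        self.perplexity = perplexity
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.early_exaggeration = early_exaggeration
        self.random_state = random_state
        self.record_transcript = record_transcript

    def fit_transform(self, X, sites=None, shared=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if shared is None:
            # no reference designated: run the centralized optimizer
            Y = fit_centralized_tsne(
                X,
                perplexity=self.perplexity,
                n_iter=self.n_iter,
                learning_rate=self.learning_rate,
                seed=self.random_state,
            )
            self.embedding_ = Y
            return Y
        shared = np.asarray(shared, dtype=bool)
        if sites is None:
            sites = np.zeros(n, dtype=int)
        sites = np.asarray(sites)
        names = [f"x{j}" for j in range(X.shape[1])]
        labels = sorted(set(sites[~shared].tolist()), key=str)
        width = max(2, max(len(str(lab)) for lab in labels))
        site_objs, index_of = [], {}
        for lab in labels:
            mask = (~shared) & (sites == lab)
            sid = f"site-{str(lab):0>{width}}"
            index_of[sid] = np.where(mask)[0]
            site_objs.append(
                _DsneSite(site_id=sid, X=X[mask], feature_names=list(names))
            )
        consortium = ConsortiumState(sites=site_objs, master_seed=self.random_state)
        sched = _Schedule(
            perplexity=self.perplexity,
            n_iter=self.n_iter,
            learning_rate=self.learning_rate,
            early_exaggeration=self.early_exaggeration,
        )
        state, transcript = fit_dsne(
            consortium,
            X[shared],
            schedule=sched,
            record_payloads=self.record_transcript,
        )
        Y = np.empty((n, 2))
        Y[shared] = state.Y_s
        for sid, idx in index_of.items():
            Y[idx] = state.Y_p[sid]
        self.embedding_ = Y
        self.shared_embedding_ = state.Y_s
        self.state_ = state
        self.transcript_ = transcript
        return Y
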