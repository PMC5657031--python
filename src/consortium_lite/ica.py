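"""Decentralized joint ICA (Infomax) with one global unmixing matrix.

Temporal concatenation of datasets — the pooled joint-ICA construction — is
performed implicitly: all sites share a single unmixing matrix W and bias b,
and because the Infomax natural gradient is a sum over samples, summing the
per-site gradients at the master reproduces the pooled gradient exactly.

Per round the master broadcasts (W, b); each site forms its source estimate
Z_p = W X_p + b·1' and the sigmoid transform Y_p, then uploads the local
natural-gradient pieces

    G_p = (N_p·I + (1 − 2Y_p)·Z_p') · W        h_p = Σ_t (1 − 2Y_p)

together with N_p and its contribution to the entropy objective.  The master
sums, normalizes by the global sample count, and takes a step of size ρ,
halving ρ (with rollback) whenever the aggregated entropy decreases, so the
accepted objective history is non-decreasing.

Whitening is decentralized-global by default: sites upload their second
moments, the master eigendecomposes the pooled covariance and broadcasts one
whitening transform — required for exact pooled-equivalence.  Site-local
whitening is available as the degraded variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .federation import (
    ConsortiumState,
    RoundTranscript,
    SiteDataset,
    aggregate_sum,
    run_decentralized,
)

__all__ = [
    "UnmixingState",
    "local_infomax_gradient",
    "fit_djica",
    "amari_index",
    "DecentralizedJointICA",
]


@dataclass
class UnmixingState:
    """Global unmixing matrix, bias, and the training trace."""

    W: np.ndarray
    b: np.ndarray
    iteration: int
    rho: float
    converged: bool
    objective_history: list
    whitening: Optional[np.ndarray] = None
    mean: Optional[np.ndarray] = None

    @property
    def effective_unmixing(self) -> np.ndarray:
        """W composed with the whitening transform (acts on raw channels)."""
        return self.W @ self.whitening if self.whitening is not None else self.W


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def local_infomax_gradient(
    W: np.ndarray, b: np.ndarray, X_p: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Site-local Infomax natural gradient for (W, b) on channels x samples data.

    Z_p = W X_p + b·1', Y_p = sigmoid(Z_p);
    G_p = (N_p·I + (1 − 2Y_p)·Z_p')·W,  h_p = row-sums of (1 − 2Y_p).
    Additive over any split of the samples.
    """
    X_p = np.atleast_2d(np.asarray(X_p, dtype=float))
    n_p = X_p.shape[1]
    Z = W @ X_p + b[:, None]
    if not np.all(np.isfinite(Z)):
        raise FloatingPointError("non-finite source estimate Z")
    U = 1.0 - 2.0 * _sigmoid(Z)
    G = (n_p * np.eye(W.shape[0]) + U @ Z.T) @ W
    h = U.sum(axis=1)
    return G, h, n_p


def _entropy_contribution(W: np.ndarray, b: np.ndarray, X_p: np.ndarray) -> float:
    """Σ_t Σ_i log y'(z) = Σ log(y(1−y)); the log|det W| term is added at master."""
    Z = W @ X_p + b[:, None]
    Y = _sigmoid(Z)
    return float(np.log(np.maximum(Y * (1.0 - Y), 1e-300)).sum())


class _WhiteningComputation:
    def init_master(self, consortium, rng):
        return {}, {"phase": 0.0}

    def local_step(self, site, broadcast, rng):
        X = site.X.T  # channels x samples
        return {"sum_x": X.sum(axis=1), "outer": X @ X.T, "n": float(X.shape[1])}

    def aggregate(self, uploads, state, rng):
        n = float(aggregate_sum(uploads, "n"))
        mean = aggregate_sum(uploads, "sum_x") / n
        cov = aggregate_sum(uploads, "outer") / n - np.outer(mean, mean)
        state.update(n=n, mean=mean, cov=cov)
        return state, {"done": 1.0}, True


def _whitening_from_cov(cov: np.ndarray, n_components: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_components]
    vals, vecs = vals[order], vecs[:, order]
    return (vecs / np.sqrt(np.maximum(vals, 1e-12))).T


class _InfomaxComputation:
    def __init__(self, n_components, rho0, max_iterations, tolerance, whiten):
        self.n_components = n_components
        self.rho0 = rho0
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.whiten = whiten
        self.site_white: dict[str, np.ndarray] = {}

    # ----- whitening bookkeeping (site-local storage, never transmitted) ----
    def set_global_whitening(self, mean, V):
        self.global_mean = mean
        self.global_V = V

    def _whitened(self, site):
        Xw = self.site_white.get(site.site_id)
        if Xw is None:
            X = site.X.T
            if self.whiten == "global":
                Xw = self.global_V @ (X - self.global_mean[:, None])
            else:  # site-local PCA whitening (degraded variant)
                mean = X.mean(axis=1)
                cov = np.cov(X, bias=True)
                V = _whitening_from_cov(np.atleast_2d(cov), self.n_components)
                Xw = V @ (X - mean[:, None])
            self.site_white[site.site_id] = Xw
        return Xw

    def init_master(self, consortium, rng):
        m = self.n_components
        state = {
            "W": np.eye(m),
            "b": np.zeros(m),
            "rho": self.rho0,
            "iter": 0,
            "history": [],
            "prev": None,  # (W, b, G, h, objective) at last accepted iterate
            "converged": False,
        }
        return state, {"W": state["W"], "b": state["b"]}

    def local_step(self, site, broadcast, rng):
        Xw = self._whitened(site)
        W = np.asarray(broadcast["W"])
        b = np.asarray(broadcast["b"])
        G, h, n_p = local_infomax_gradient(W, b, Xw)
        return {
            "G": G,
            "h": h,
            "n": float(n_p),
            "entropy": _entropy_contribution(W, b, Xw),
        }

    def aggregate(self, uploads, state, rng):
        W, b = state["W"], state["b"]
        if np.linalg.cond(W) > 1e8:
            raise FloatingPointError("degenerate unmixing: condition number > 1e8")
        G = aggregate_sum(uploads, "G")
        h = aggregate_sum(uploads, "h")
        n = float(aggregate_sum(uploads, "n"))
        sign, logdet = np.linalg.slogdet(W)
        objective = logdet + float(aggregate_sum(uploads, "entropy")) / n
        state["iter"] += 1
        prev = state["prev"]
        if prev is None or objective >= prev[4]:
            state["history"].append(objective)
            dW = state["rho"] * G / n
            if float(np.linalg.norm(dW)) < self.tolerance:
                state["converged"] = True
                return state, {"W": W, "b": b}, True
            state["prev"] = (W.copy(), b.copy(), G, h, objective)
            state["W"] = W + dW
            state["b"] = b + state["rho"] * h / n
        else:
            # entropy decreased: halve the step and retry from the accepted iterate
            state["rho"] *= 0.5
            W0, b0, G0, h0, _ = prev
            state["W"] = W0 + state["rho"] * G0 / n
            state["b"] = b0 + state["rho"] * h0 / n
        stop = state["iter"] >= self.max_iterations
        if stop and state["prev"] is not None:
            state["W"], state["b"] = state["prev"][0], state["prev"][1]
        return state, {"W": state["W"], "b": state["b"]}, stop


def fit_djica(
    consortium: ConsortiumState,
    n_components: Optional[int] = None,
    rho: float = 0.1,
    max_iterations: int = 400,
    tolerance: float = 1e-7,
    whiten: str = "global",
    record_payloads: bool = True,
) -> tuple[UnmixingState, RoundTranscript]:
    """Decentralized Infomax joint ICA over a consortium of mixture sites.

    Site tables hold samples x channels; ``whiten`` is "global"
    (decentralized pooled whitening, exact pooled-equivalence) or "local".
    """
    n_channels = consortium.sites[0].X.shape[1]
    m = n_components or n_channels
    comp = _InfomaxComputation(m, rho, max_iterations, tolerance, whiten)
    mean = V = None
    if whiten == "global":
        wstate, white_transcript = run_decentralized(
            _WhiteningComputation(), consortium, max_rounds=1, record_payloads=record_payloads
        )
        mean = wstate["mean"]
        V = _whitening_from_cov(wstate["cov"], m)
        comp.set_global_whitening(mean, V)
    elif whiten != "local":
        raise ValueError("whiten must be 'global' or 'local'")
    state, transcript = run_decentralized(
        comp, consortium, max_rounds=max_iterations + 1, record_payloads=record_payloads
    )
    if whiten == "global":
        transcript.rounds = white_transcript.rounds + transcript.rounds
    result = UnmixingState(
        W=state["W"],
        b=state["b"],
        iteration=state["iter"],
        rho=state["rho"],
        converged=state["converged"],
        objective_history=state["history"],
        whitening=V,
        mean=mean,
    )
    return result, transcript


def amari_index(W_est: np.ndarray, A_true: np.ndarray) -> float:
    """Moreau-Amari separation index of P = W_est·A_true, normalized to [0, 1].

    Zero iff P is a scaled permutation; 1 for maximal row/column confusion.
    """
    P = np.abs(np.asarray(W_est, dtype=float) @ np.asarray(A_true, dtype=float))
    m = P.shape[0]
    if P.shape[0] != P.shape[1]:
        raise ValueError("amari_index needs square matrices")
    row_max = P.max(axis=1)
    col_max = P.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("zero row or column in the permutation product")
    rows = (P / row_max[:, None]).sum(axis=1) - 1.0
    cols = (P / col_max[None, :]).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * m * (m - 1)))


class DecentralizedJointICA(BaseEstimator):
    """Infomax ICA fitted across sites that share one global unmixing matrix.

    ``fit(X, sites=...)`` takes samples x channels with per-row site labels.
    ``components_`` maps raw channels to sources (whitening folded in);
    ``transform`` returns source estimates.
    """

    def __init__(
        self,
        n_components: Optional[int] = None,
        rho: float = 0.1,
        max_iterations: int = 400,
        tolerance: float = 1e-7,
        whiten: str = "global",
        random_state: int = 0,
        record_transcript: bool = False,
    ):
        self.n_components = n_components
        self.rho = rho
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.whiten = whiten
        self.random_state = random_state
        self.record_transcript = record_transcript

    def fit(self, X, sites=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if sites is None:
            sites = np.zeros(X.shape[0], dtype=int)
        sites = np.asarray(sites)
        labels = sorted(set(sites.tolist()), key=str)
        width = max(2, max(len(str(lab)) for lab in labels))
        names = [f"ch{j}" for j in range(X.shape[1])]
        datasets = [
            SiteDataset(
                site_id=f"site-{str(lab):0>{width}}",
                X=X[sites == lab],
                feature_names=list(names),
            )
            for lab in labels
        ]
        consortium = ConsortiumState(sites=datasets, master_seed=self.random_state)
        state, transcript = fit_djica(
            consortium,
            n_components=self.n_components,
            rho=self.rho,
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            whiten=self.whiten,
            record_payloads=self.record_transcript,
        )
        self.state_ = state
        self.transcript_ = transcript
        self.unmixing_ = state.W
        self.bias_ = state.b
        self.mean_ = state.mean
        self.components_ = state.effective_unmixing
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        centered = X - (self.mean_ if self.mean_ is not None else 0.0)
        return (self.components_ @ centered.T + self.bias_[:, None]).T

    def fit_transform(self, X, sites=None):
        return self.fit(X, sites=sites).transform(X)
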