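"""Decentralized IVA with a multivariate-Laplace source prior (IVA-L).

K datasets (e.g. subjects) are distributed over sites; dataset k has its own
unmixing matrix W_k, and the n-th sources of all datasets form one source
component vector (SCV), modeled as dependent within the vector and
independent across vectors.  The objective is

    J = Σ_n (1/T) Σ_t sqrt( Σ_k s_n^[k](t)² )  −  Σ_k log|det W_k|

which splits into per-dataset pieces plus a coupling term that depends only
on the cross-dataset **matrix of norms** C[n, t] = Σ_k s_n^[k](t)².  Each
round the sites upload their additive contributions (C_p, d_p); the master
forms C and the global cost and broadcasts C back; sites apply the
multivariate-Laplace score φ_n(t) = s_n(t)/sqrt(C[n,t]) in a relative
(natural) gradient

    G_k = (I − (1/T) Σ_t φ(t) s(t)') W_k

and upload only the gradient norms, from which the master sets one global
step size α — kept while the cost decreases, halved with rollback when it
does not.  Dataset placement across sites changes only who transmits what,
never the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._utils import pairwise_sum
from .federation import ConsortiumState, RoundTranscript, run_decentralized
from .ica import amari_index

__all__ = [
    "IvaSite",
    "IvaState",
    "scv_norm_summaries",
    "local_relative_gradient",
    "fit_diva",
    "joint_isi",
    "DecentralizedIVA",
]

NORM_FLOOR = 1e-8  # floor under sqrt(C) in the score, against division blow-ups


@dataclass
class IvaSite:
    """A site holding a disjoint subset of the K datasets (channels x samples)."""

    site_id: str
    datasets: dict  # dataset index k -> array (m, T)

    def __post_init__(self) -> None:
        ts = {np.asarray(X).shape[1] for X in self.datasets.values()}
        if len(ts) > 1:
            raise ValueError(
                f"site {self.site_id!r}: datasets have mismatched sample counts {sorted(ts)}"
            )
        self.datasets = {int(k): np.asarray(X, dtype=float) for k, X in self.datasets.items()}

    @property
    def n(self) -> int:
        return next(iter(self.datasets.values())).shape[1]

    def raw_arrays(self) -> list[np.ndarray]:
        return [X.T for X in self.datasets.values()]  # observations x channels


@dataclass
class IvaState:
    """Per-dataset unmixing matrices and the aggregated training trace."""

    W: dict  # dataset index -> unmixing matrix (whitened basis)
    whitening: dict  # dataset index -> whitening transform
    C: np.ndarray
    cost_history: list = field(default_factory=list)
    alpha: float = 0.0
    iteration: int = 0
    converged: bool = False

    def effective_unmixing(self, k: int) -> np.ndarray:
        return self.W[k] @ self.whitening[k]


def scv_norm_summaries(W_set: dict, X_set: dict) -> tuple[np.ndarray, float]:
    """Additive site summaries (C_p, d_p) for the site's datasets.

    C_p[n, t] = Σ_{k at site} s_n^[k](t)² with s^[k] = W_k x^[k];
    d_p = −Σ_{k at site} log|det W_k| (the site's determinant contribution;
    the sqrt coupling term needs the global C and is completed at the master).
    """
    if set(W_set) != set(X_set):
        raise ValueError("W_set and X_set must cover the same dataset indices")
    keys = sorted(X_set)
    ts = {np.asarray(X_set[k]).shape[1] for k in keys}
    if len(ts) != 1:
        raise ValueError(f"mismatched sample counts across datasets: {sorted(ts)}")
    sq = []
    d_p = 0.0
    for k in keys:
        s = W_set[k] @ X_set[k]
        sq.append(s**2)
        d_p -= float(np.linalg.slogdet(W_set[k])[1])
    return pairwise_sum(sq), d_p


def local_relative_gradient(W_k: np.ndarray, X_k: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Relative gradient of the Laplace IVA cost for one dataset.

    φ_n(t) = s_n(t)/sqrt(C[n,t]) (floored), G_k = (I − (1/T)·φ s') W_k.
    With K = 1 the score reduces to the sign-like s/|s| of single-dataset
    Laplace ICA.
    """
    s = W_k @ X_k
    T = s.shape[1]
    phi = s / np.sqrt(np.maximum(C, NORM_FLOOR**2))
    if not np.all(np.isfinite(phi)):
        raise FloatingPointError("non-finite score in relative gradient")
    return (np.eye(W_k.shape[0]) - (phi @ s.T) / T) @ W_k


def _laplace_coupling(C: np.ndarray) -> float:
    T = C.shape[1]
    return float(np.sqrt(np.maximum(C, 0.0)).sum() / T)


class _DivaComputation:
    """Two-phase rounds: S (summaries/cost) then G (gradients/step)."""

    def __init__(self, alpha0, max_iterations, tolerance):
        self.alpha0 = alpha0
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.site_W: dict[str, dict] = {}  # site-local: current W_k per dataset
        self.site_white: dict[str, dict] = {}
        self.site_Xw: dict[str, dict] = {}
        self.site_best: dict[str, dict] = {}  # last accepted (W_k, G_k)

    def _prepare(self, site):
        if site.site_id in self.site_W:
            return
        Ws, Vs, Xw = {}, {}, {}
        for k, X in site.datasets.items():
            mean = X.mean(axis=1, keepdims=True)
            cov = np.atleast_2d(np.cov(X, bias=True))
            vals, vecs = np.linalg.eigh(cov)
            order = np.argsort(vals)[::-1]
            vals, vecs = vals[order], vecs[:, order]
            V = (vecs / np.sqrt(np.maximum(vals, 1e-12))).T
            Vs[k] = V
            Xw[k] = V @ (X - mean)
            Ws[k] = np.eye(X.shape[0])
        self.site_W[site.site_id] = Ws
        self.site_white[site.site_id] = Vs
        self.site_Xw[site.site_id] = Xw
        self.site_best[site.site_id] = {}

    def init_master(self, consortium, rng):
        state = {
            "phase": 0,  # 0 = expect summaries, 1 = expect gradient norms
            "alpha": self.alpha0,
            "best_cost": None,
            "halvings": 0,
            "history": [],
            "iter": 0,
            "converged": False,
            "C": None,
        }
        return state, {"phase": 0.0, "action": 0.0, "alpha": self.alpha0}

    def local_step(self, site, broadcast, rng):
        self._prepare(site)
        Ws = self.site_W[site.site_id]
        Xw = self.site_Xw[site.site_id]
        phase = broadcast["phase"]
        if phase == 0.0:
            action = broadcast["action"]
            if action == 2.0:  # rollback: revert to accepted W, retry smaller step
                alpha = float(broadcast["alpha"])
                best = self.site_best[site.site_id]
                for k in Ws:
                    W0, G0 = best[k]
                    Ws[k] = W0 + alpha * G0
            C_p, d_p = scv_norm_summaries(Ws, Xw)
            return {"C_p": C_p, "d_p": d_p}
        # gradient phase: the broadcast C corresponds to the just-accepted W
        C = np.asarray(broadcast["C"])
        alpha = float(broadcast["alpha"])
        norms = []
        best = self.site_best[site.site_id]
        for k in sorted(Ws):
            G = local_relative_gradient(Ws[k], Xw[k], C)
            best[k] = (Ws[k].copy(), G)
            norms.append([float(np.linalg.norm(G) ** 2), float(np.linalg.norm(Ws[k]) ** 2)])
            Ws[k] = Ws[k] + alpha * G  # trial step, evaluated next S round
        return {"grad_w_norms_sq": np.asarray(norms)}

    def aggregate(self, uploads, state, rng):
        ordered = sorted(uploads)
        if state["phase"] == 0:
            C = pairwise_sum([uploads[sid]["C_p"] for sid in ordered])
            d = float(pairwise_sum([uploads[sid]["d_p"] for sid in ordered]))
            cost = _laplace_coupling(C) + d
            if state["best_cost"] is None or cost <= state["best_cost"]:
                state.update(best_cost=cost, halvings=0, C=C, phase=1)
                state["history"].append(cost)
                return state, {"phase": 1.0, "C": C, "alpha": state["alpha"]}, False
            state["halvings"] += 1
            if state["halvings"] > 20:
                raise FloatingPointError(
                    "no descent direction: cost increased after 20 step halvings"
                )
            state["alpha"] *= 0.5
            if state["alpha"] < 1e-6:
                state["converged"] = True
                # have sites restore the accepted weights before stopping
                return state, {"phase": 0.0, "action": 2.0, "alpha": 0.0}, True
            return state, {"phase": 0.0, "action": 2.0, "alpha": state["alpha"]}, False
        # gradient phase results
        ratios = np.concatenate([uploads[sid]["grad_w_norms_sq"] for sid in ordered])
        max_ratio = float(np.sqrt((ratios[:, 0] / ratios[:, 1]).max()))
        state["iter"] += 1
        state["phase"] = 0
        if max_ratio < self.tolerance:
            state["converged"] = True
            # undo the trial step the sites just took
            return state, {"phase": 0.0, "action": 2.0, "alpha": 0.0}, True
        stop = state["iter"] >= self.max_iterations
        return state, {"phase": 0.0, "action": 1.0, "alpha": state["alpha"]}, stop


def fit_diva(
    datasets: Sequence[np.ndarray],
    site_assignment: Optional[Sequence[int]] = None,
    max_iterations: int = 512,
    alpha0: float = 0.1,
    tolerance: float = 1e-5,
    seed: int = 0,
    record_payloads: bool = True,
) -> tuple[IvaState, RoundTranscript]:
    """Decentralized IVA-L over datasets spread across sites.

    ``datasets`` are channels x samples mixtures; ``site_assignment[k]``
    names the site holding dataset k (default: one site per dataset).  Each
    dataset is whitened locally; W_k starts at identity in the whitened
    basis.  Returns the fitted state (unmixing per dataset, non-increasing
    cost history, final step size) and the communication transcript.
    """
    K = len(datasets)
    if K < 2:
        raise ValueError("IVA needs K >= 2 datasets")
    if site_assignment is None:
        site_assignment = list(range(K))
    groups: dict[str, dict] = {}
    for k, lab in enumerate(site_assignment):
        groups.setdefault(f"site-{str(lab):0>2}", {})[k] = datasets[k]
    consortium = ConsortiumState(
        sites=[IvaSite(site_id=sid, datasets=d) for sid, d in groups.items()],
        master_seed=seed,
    )
    comp = _DivaComputation(alpha0, max_iterations, tolerance)
    state, transcript = run_decentralized(
        comp,
        consortium,
        max_rounds=2 * max_iterations + 64,
        record_payloads=record_payloads,
    )
    # collect site-local results (stored at the sites, per the protocol)
    W_all, V_all = {}, {}
    for sid in comp.site_W:
        best = comp.site_best[sid]
        for k, W in comp.site_W[sid].items():
            W_all[k] = best[k][0] if k in best else W
        V_all.update(comp.site_white[sid])
    result = IvaState(
        W=W_all,
        whitening=V_all,
        C=state["C"],
        cost_history=state["history"],
        alpha=state["alpha"],
        iteration=state["iter"],
        converged=state["converged"],
    )
    return result, transcript


def joint_isi(W_set: Sequence[np.ndarray], A_set: Sequence[np.ndarray]) -> float:
    """Joint intersymbol interference across datasets, in [0, 1].

    P̄ = (1/K) Σ_k |W_k A_k| scored with the Amari row/column confusion;
    zero iff all datasets share one common scaled permutation.
    """
    if len(W_set) != len(A_set) or not W_set:
        raise ValueError("need equally many unmixing and mixing matrices")
    P = pairwise_sum([np.abs(np.asarray(W) @ np.asarray(A)) for W, A in zip(W_set, A_set)])
    P /= len(W_set)
    return amari_index(P, np.eye(P.shape[0]))


class DecentralizedIVA(BaseEstimator):
    """IVA-L across distributed datasets; scikit-learn-style wrapper.

    ``fit(datasets, site_assignment=...)`` takes a list of channels x samples
    mixtures.  Fitted attributes: ``unmixing_`` (list, whitening folded in),
    ``cost_history_``, ``sources_``.
    """

    def __init__(
        self,
        max_iterations: int = 512,
        alpha0: float = 0.1,
        tolerance: float = 1e-5,
        random_state: int = 0,
        record_transcript: bool = False,
    ):
        self.max_iterations = max_iterations
        self.alpha0 = alpha0
        self.tolerance = tolerance
        self.random_state = random_state
        self.record_transcript = record_transcript

    def fit(self, datasets, site_assignment=None):
        state, transcript = fit_diva(
            datasets,
            site_assignment=site_assignment,
            max_iterations=self.max_iterations,
            alpha0=self.alpha0,
            tolerance=self.tolerance,
            seed=self.random_state,
            record_payloads=self.record_transcript,
        )
        self.state_ = state
        self.transcript_ = transcript
        K = len(datasets)
        self.unmixing_ = [state.effective_unmixing(k) for k in range(K)]
        self.cost_history_ = state.cost_history
        self.sources_ = [
            self.unmixing_[k] @ (datasets[k] - np.mean(datasets[k], axis=1, keepdims=True))
            for k in range(K)
        ]
        return self
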