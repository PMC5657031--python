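"""Decentralized ridge regression over a simulated consortium.

Two modes, mirroring the meta- vs mega-analysis distinction:

* **multi-shot** — iterative decentralized gradient descent.  Each round the
  master broadcasts the current coefficient vector; every site returns the
  gradient of its local residual sum of squares and its local objective; the
  master sums the gradients (sums, not averages, so unequal site sizes cannot
  bias the estimate), adds the ridge penalty term once, normalizes by the
  global sample count and takes a step.  The iterate sequence is bit-for-bit
  the one centralized gradient descent on the physically pooled data would
  produce: the mega-analysis claim, made exact.
* **single-shot** — each site solves its local closed-form ridge problem once
  and the master returns the sample-size-weighted average of the local
  coefficient vectors (a meta-analytic combination; generally differs from
  the pooled solution on heterogeneous splits).

Covariates and response are standardized internally using decentralized
global moments (raw FreeSurfer volumes sit near 5e4, which would make
unscaled gradient descent numerically hopeless); reported coefficients are
de-standardized.  The intercept is never penalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import check_finite
from .federation import (
    ConsortiumState,
    DivergenceError,
    RoundTranscript,
    SiteDataset,
    aggregate_sum,
    run_decentralized,
)

__all__ = [
    "DesignMatrix",
    "RidgeConfig",
    "FitResult",
    "build_design",
    "local_objective_gradient",
    "closed_form_oracle",
    "fit_multishot",
    "fit_singleshot",
    "DecentralizedRidge",
]


@dataclass
class DesignMatrix:
    """Observation-by-coefficient matrix; first column is the intercept."""

    values: np.ndarray
    coefficient_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in design matrix")
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("first design column must be the all-ones intercept")
        if len(self.coefficient_names) != self.values.shape[1]:
            raise ValueError("coefficient_names length mismatch")

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class RidgeConfig:
    """Hyperparameters for the iterative (multi-shot) fit.

    ``lam`` = 0 gives a standard unregularized regression.  The default
    iteration cap of 25 matches the platform's multi-shot default; the step
    size applies on the standardized scale and is halved whenever the global
    objective increases, which keeps the accepted objective history
    non-increasing.
    """

    lam: float = 0.0
    learning_rate: float = 0.25
    max_iterations: int = 25
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.learning_rate <= 0 or self.max_iterations < 1 or self.tolerance <= 0:
            raise ValueError("learning_rate, max_iterations, tolerance must be positive")


@dataclass
class FitResult:
    """Fitted coefficients on the raw (de-standardized) scale."""

    w: np.ndarray
    coefficient_names: list[str]
    objective_history: list[float]
    iterations_used: int
    converged: bool
    lam: float = 0.0
    mode: str = "multishot"

    def as_dict(self) -> dict:
        return dict(zip(self.coefficient_names, self.w.tolist()))


def build_design(site: SiteDataset) -> tuple[DesignMatrix, np.ndarray]:
    """Intercept-augmented design and response for one site (Booleans as 0/1)."""
    if site.y is None:
        raise ValueError(f"site {site.site_id!r} has no response variable")
    values = np.column_stack([np.ones(site.n), site.X])
    names = ["intercept"] + list(site.feature_names)
    return DesignMatrix(values, names), site.y


def local_objective_gradient(
    design: DesignMatrix, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, float, int]:
    """Site-local gradient and objective of the residual sum of squares.

    gradient = -2 X'(y - Xw) over the site's rows only; the ridge penalty is
    applied once at the master, never per site.  Returns (gradient, ||y-Xw||^2,
    local sample count).
    """
    check_finite("w", w)
    X = design.values
    if w.shape[0] != X.shape[1]:
        raise ValueError("w length does not match design columns")
    resid = y - X @ w
    return -2.0 * X.T @ resid, float(resid @ resid), X.shape[0]


def closed_form_oracle(design: DesignMatrix, y: np.ndarray, lam: float = 0.0) -> np.ndarray:
    """Pooled closed-form ridge solution (X'X + lam*J) b = X'y, J sparing the intercept."""
    X = design.values
    k = X.shape[1]
    J = np.eye(k)
    J[0, 0] = 0.0
    G = X.T @ X + lam * J
    if np.linalg.matrix_rank(G) < k:
        raise np.linalg.LinAlgError("singular penalized normal equations")
    return np.linalg.solve(G, X.T @ y)


# Standardization moments are computed in two decentralized passes (means
# first, then squared deviations about the broadcast means): the one-pass
# E[x^2]-E[x]^2 form loses digits on raw volumes near 5e4.


def _standardize(site: SiteDataset, moments: dict) -> tuple[np.ndarray, np.ndarray]:
    Xs = (site.X - moments["mean_x"]) / moments["std_x"]
    ys = (site.y - moments["mean_y"]) / moments["std_y"]
    return np.column_stack([np.ones(site.n), Xs]), ys


def _destandardize(w_std: np.ndarray, moments: dict) -> np.ndarray:
    sy, my = moments["std_y"], moments["mean_y"]
    sx, mx = moments["std_x"], moments["mean_x"]
    beta = np.empty_like(w_std)
    beta[1:] = sy * w_std[1:] / sx
    beta[0] = my + sy * w_std[0] - float(beta[1:] @ mx)
    return beta


class _MultishotComputation:
    """Round state machine: one moments round, then gradient-descent rounds."""

    def __init__(self, config: RidgeConfig):
        self.config = config

    def init_master(self, consortium, rng):
        k = consortium.sites[0].X.shape[1] + 1
        state = {
            "phase": 0,
            "k": k,
            "lr": self.config.learning_rate,
            "w": np.zeros(k),
            "history": [],
            "iterations": 0,
            "converged": False,
            "prev": None,  # (w, grad, objective) of last accepted iterate
            "moments": None,
        }
        return state, {"phase": 0.0}

    def local_step(self, site, broadcast, rng):
        if broadcast["phase"] == 0.0:
            return {
                "n": float(site.n),
                "sum_x": site.X.sum(axis=0),
                "sum_y": float(site.y.sum()),
            }
        if broadcast["phase"] == 0.5:
            dx = site.X - np.asarray(broadcast["mean_x"])
            dy = site.y - float(broadcast["mean_y"])
            return {"ss_x": (dx**2).sum(axis=0), "ss_y": float((dy**2).sum())}
        moments = {
            "mean_x": np.asarray(broadcast["mean_x"]),
            "std_x": np.asarray(broadcast["std_x"]),
            "mean_y": float(broadcast["mean_y"]),
            "std_y": float(broadcast["std_y"]),
        }
        Xs, ys = _standardize(site, moments)
        w = np.asarray(broadcast["w"])
        resid = ys - Xs @ w
        return {
            "grad": -2.0 * Xs.T @ resid,
            "objective": float(resid @ resid),
            "n": float(site.n),
        }

    def aggregate(self, uploads, state, rng):
        cfg = self.config
        if state["phase"] == 0:
            n = float(aggregate_sum(uploads, "n"))
            state["moments"] = {
                "n": n,
                "mean_x": aggregate_sum(uploads, "sum_x") / n,
                "mean_y": float(aggregate_sum(uploads, "sum_y")) / n,
            }
            state["phase"] = 0.5
            m = state["moments"]
            return (
                state,
                {"phase": 0.5, "mean_x": m["mean_x"], "mean_y": m["mean_y"]},
                False,
            )
        if state["phase"] == 0.5:
            m = state["moments"]
            std_x = np.sqrt(aggregate_sum(uploads, "ss_x") / m["n"])
            std_x[std_x == 0.0] = 1.0  # constant covariate: leave unscaled
            m["std_x"] = std_x
            m["std_y"] = float(np.sqrt(aggregate_sum(uploads, "ss_y") / m["n"])) or 1.0
            state["phase"] = 1
            return state, self._broadcast(state), False

        n_global = state["moments"]["n"]
        w = state["w"]
        w_pen = w.copy()
        w_pen[0] = 0.0  # the intercept is never penalized
        grad = (aggregate_sum(uploads, "grad") + 2.0 * cfg.lam * w_pen) / n_global
        objective = float(aggregate_sum(uploads, "objective")) + cfg.lam * float(
            w_pen @ w_pen
        )
        if not np.isfinite(objective):
            raise DivergenceError(
                f"objective diverged at learning_rate={state['lr']:g}; use a smaller step"
            )
        state["iterations"] += 1
        prev = state["prev"]
        # relative slack keeps the accept/reject branch stable under the
        # ~1e-16 summation-order noise that different site splits introduce
        if prev is None or objective <= prev[2] * (1.0 + 1e-12):
            state["history"].append(objective)
            state["prev"] = (w.copy(), grad.copy(), objective)
            gnorm = float(np.linalg.norm(grad))
            if gnorm < cfg.tolerance:
                state["converged"] = True
                return state, self._broadcast(state), True
            state["w"] = w - state["lr"] * grad
        else:
            # Backtracking: the trial step increased the global objective —
            # halve the step and retry from the last accepted iterate.
            state["lr"] *= 0.5
            w_acc, g_acc, _ = prev
            state["w"] = w_acc - state["lr"] * g_acc
        stop = state["iterations"] >= cfg.max_iterations
        if stop:
            state["w"] = state["prev"][0] if state["prev"] is not None else state["w"]
        return state, self._broadcast(state), stop

    def _broadcast(self, state):
        m = state["moments"]
        return {
            "phase": 1.0,
            "w": state["w"].copy(),
            "mean_x": m["mean_x"],
            "std_x": m["std_x"],
            "mean_y": m["mean_y"],
            "std_y": m["std_y"],
        }


def fit_multishot(
    consortium: ConsortiumState,
    config: Optional[RidgeConfig] = None,
    record_payloads: bool = True,
) -> tuple[FitResult, RoundTranscript]:
    """Iterative decentralized ridge fit; equals pooled gradient descent."""
    config = config or RidgeConfig(**consortium.config.get("ridge", {}))
    comp = _MultishotComputation(config)
    state, transcript = run_decentralized(
        comp, consortium, max_rounds=config.max_iterations + 3, record_payloads=record_payloads
    )
    w_std = state["prev"][0] if state["prev"] is not None else state["w"]
    beta = _destandardize(w_std, state["moments"])
    names = ["intercept"] + list(consortium.sites[0].feature_names)
    result = FitResult(
        w=beta,
        coefficient_names=names,
        objective_history=list(state["history"]),
        iterations_used=state["iterations"],
        converged=state["converged"],
        lam=config.lam,
        mode="multishot",
    )
    return result, transcript


class _SingleshotComputation:
    def __init__(self, lam: float):
        self.lam = lam

    def init_master(self, consortium, rng):
        return {}, {"phase": 0.0}

    def local_step(self, site, broadcast, rng):
        design, y = build_design(site)
        try:
            beta = closed_form_oracle(design, y, self.lam)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular local system at site {site.site_id!r}"
            ) from exc
        return {"beta": beta, "n": float(site.n)}

    def aggregate(self, uploads, state, rng):
        from ._utils import pairwise_sum

        n = float(aggregate_sum(uploads, "n"))
        beta = (
            pairwise_sum(
                [uploads[sid]["beta"] * uploads[sid]["n"] for sid in sorted(uploads)]
            )
            / n
        )
        state["beta"] = beta
        return state, {"beta": beta}, True


def fit_singleshot(
    consortium: ConsortiumState, lam: float = 0.0, record_payloads: bool = True
) -> tuple[FitResult, RoundTranscript]:
    """One-round meta-analytic combination: N_p-weighted average of local fits."""
    state, transcript = run_decentralized(
        _SingleshotComputation(lam), consortium, max_rounds=1, record_payloads=record_payloads
    )
    names = ["intercept"] + list(consortium.sites[0].feature_names)
    result = FitResult(
        w=state["beta"],
        coefficient_names=names,
        objective_history=[],
        iterations_used=1,
        converged=True,
        lam=lam,
        mode="singleshot",
    )
    return result, transcript


class DecentralizedRidge(RegressorMixin, BaseEstimator):
    """Ridge regression fitted across simulated sites without pooling rows.

    Parameters follow scikit-learn conventions: ``alpha`` is the ridge
    penalty (0 = ordinary least squares), ``mode`` selects the iterative
    mega-analysis ("multishot") or the one-round meta-analysis
    ("singleshot").  ``fit`` accepts an optional per-row ``sites`` label
    array; omitted, all rows form a single site (and the fit equals a
    centralized one).
    """

    def __init__(
        self,
        alpha: float = 0.0,
        mode: str = "multishot",
        learning_rate: float = 0.25,
        max_iterations: int = 25,
        tolerance: float = 1e-6,
        random_state: int = 0,
        record_transcript: bool = True,
    ):
        self.alpha = alpha
        self.mode = mode
        self.learning_rate = learning_rate
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.random_state = random_state
        self.record_transcript = record_transcript

    def _make_consortium(self, X, y, sites) -> ConsortiumState:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        names = [f"x{j}" for j in range(X.shape[1])]
        if sites is None:
            sites = np.zeros(X.shape[0], dtype=int)
        sites = np.asarray(sites)
        labels = sorted(set(sites.tolist()), key=str)
        width = max(2, max(len(str(s)) for s in labels))
        datasets = []
        for lab in labels:
            mask = sites == lab
            datasets.append(
                SiteDataset(
                    site_id=f"site-{str(lab):0>{width}}",
                    X=X[mask],
                    feature_names=list(names),
                    y=y[mask],
                    y_name="y",
                )
            )
        return ConsortiumState(sites=datasets, master_seed=self.random_state)

    def fit(self, X, y, sites=None):
        consortium = self._make_consortium(X, y, sites)
        result, transcript = self._fit_consortium(consortium)
        self.result_ = result
        self.transcript_ = transcript
        self.coef_ = result.w[1:]
        self.intercept_ = float(result.w[0])
        self.n_iter_ = result.iterations_used
        self.converged_ = result.converged
        self.objective_history_ = result.objective_history
        self.n_features_in_ = consortium.sites[0].X.shape[1]
        return self

    def _fit_consortium(self, consortium: ConsortiumState):
        if self.mode == "multishot":
            config = RidgeConfig(
                lam=self.alpha,
                learning_rate=self.learning_rate,
                max_iterations=self.max_iterations,
                tolerance=self.tolerance,
            )
            return fit_multishot(consortium, config, record_payloads=self.record_transcript)
        if self.mode == "singleshot":
            return fit_singleshot(consortium, self.alpha, record_payloads=self.record_transcript)
        raise ValueError(f"unknown mode {self.mode!r}; use 'multishot' or 'singleshot'")

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef_ + self.intercept_
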