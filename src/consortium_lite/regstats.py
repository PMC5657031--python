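"""Decentralized inference for the fitted regression: R², t-values, p-values.

Goodness of fit and per-coefficient significance are computed without any
site revealing subject-level rows:

* **R²** takes exactly two rounds.  Sites first upload their local response
  mean and sample size; the master broadcasts the global mean; sites then
  upload their local total sum of squares (about the global mean) and sum of
  squared errors, and the master forms R² = 1 − ΣSSE_p / ΣSST_p.
* **t-values** take one round.  Sites upload their uncentered Gram matrix
  G_p = X_p'X_p (intercept column included), SSE_p and N_p.  Aggregating the
  Gram matrices reconstructs the pooled X'X exactly — which is why the Gram
  form is used rather than a centered covariance, whose aggregation could not
  recover the intercept's standard error.  The master forms
  MSE = ΣSSE_p/(N−k) and t_j = β_j / sqrt(MSE·[G⁻¹]_jj).
* **p-values** are two-tailed Student-t tail probabilities, p = 2·(1 −
  F_t(|t|; N−k)).

For λ > 0 the same OLS formulas are applied to the ridge coefficients and the
report flags them as approximate under regularization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .federation import (
    ConsortiumState,
    RoundTranscript,
    SiteDataset,
    aggregate_sum,
    run_decentralized,
)
from .regression import FitResult, build_design, closed_form_oracle

__all__ = [
    "decentralized_r_squared",
    "decentralized_t_stats",
    "t_to_pvalue",
    "TStats",
    "RegressionReport",
    "build_report",
]


class _R2Computation:
    def __init__(self, w: np.ndarray):
        self.w = np.asarray(w, dtype=float)

    def init_master(self, consortium, rng):
        return {"phase": 0}, {"phase": 0.0}

    def local_step(self, site, broadcast, rng):
        if broadcast["phase"] == 0.0:
            return {"ybar": float(site.y.mean()), "n": float(site.n)}
        design, y = build_design(site)
        ybar = float(broadcast["ybar_global"])
        resid = y - design.values @ self.w
        return {
            "sst": float(((y - ybar) ** 2).sum()),
            "sse": float((resid**2).sum()),
        }

    def aggregate(self, uploads, state, rng):
        if state["phase"] == 0:
            n = float(aggregate_sum(uploads, "n"))
            ybar = (
                sum(uploads[sid]["ybar"] * uploads[sid]["n"] for sid in sorted(uploads))
                / n
            )
            state.update(phase=1, ybar=ybar, n=n)
            return state, {"phase": 1.0, "ybar_global": ybar}, False
        sst = float(aggregate_sum(uploads, "sst"))
        sse = float(aggregate_sum(uploads, "sse"))
        if sst == 0.0:
            raise ValueError("degenerate response: total sum of squares is zero")
        state["r2"] = 1.0 - sse / sst
        state["per_site"] = {
            sid: (1.0 - uploads[sid]["sse"] / uploads[sid]["sst"])
            if uploads[sid]["sst"] > 0
            else float("nan")
            for sid in uploads
        }
        return state, {"r2": state["r2"]}, True


def decentralized_r_squared(
    consortium: ConsortiumState, w: np.ndarray, record_payloads: bool = True
) -> tuple[float, dict, RoundTranscript]:
    """Global and per-site R² for coefficients ``w`` in exactly two rounds.

    Per-site values use the site's own SSE/SST about the *global* response
    mean, i.e. how well the global model explains each site's data.
    """
    state, transcript = run_decentralized(
        _R2Computation(w), consortium, max_rounds=2, record_payloads=record_payloads
    )
    return state["r2"], state["per_site"], transcript


@dataclass
class TStats:
    t: np.ndarray
    se: np.ndarray
    mse: float
    df: int
    coefficient_names: list[str]

    @property
    def p(self) -> np.ndarray:
        return t_to_pvalue(self.t, self.df)


class _TStatsComputation:
    def __init__(self, w: np.ndarray):
        self.w = np.asarray(w, dtype=float)

    def init_master(self, consortium, rng):
        names = ["intercept"] + list(consortium.sites[0].feature_names)
        return {"names": names}, {"phase": 0.0}

    def local_step(self, site, broadcast, rng):
        design, y = build_design(site)
        X = design.values
        resid = y - X @ self.w
        return {"gram": X.T @ X, "sse": float(resid @ resid), "n": float(site.n)}

    def aggregate(self, uploads, state, rng):
        G = aggregate_sum(uploads, "gram")
        sse = float(aggregate_sum(uploads, "sse"))
        n = float(aggregate_sum(uploads, "n"))
        k = G.shape[0]
        df = int(n - k)
        if df <= 0:
            raise ValueError(f"degrees of freedom N-k = {df} must be positive")
        if np.linalg.matrix_rank(G) < k:
            _, r = np.linalg.qr(G)
            bad = [state["names"][j] for j in range(k) if abs(r[j, j]) < 1e-10 * abs(r[0, 0])]
            raise np.linalg.LinAlgError(
                f"aggregated Gram matrix is singular; collinear coefficients: {bad}"
            )
        G_inv = np.linalg.inv(G)
        mse = sse / df
        se = np.sqrt(mse * np.diag(G_inv))
        state.update(t=self.w / se, se=se, mse=mse, df=df)
        return state, {"t": state["t"]}, True


def decentralized_t_stats(
    consortium: ConsortiumState, w: np.ndarray, record_payloads: bool = True
) -> tuple[TStats, RoundTranscript]:
    """Per-coefficient t statistics from aggregated Gram matrices (one round)."""
    state, transcript = run_decentralized(
        _TStatsComputation(w), consortium, max_rounds=1, record_payloads=record_payloads
    )
    result = TStats(
        t=state["t"],
        se=state["se"],
        mse=state["mse"],
        df=state["df"],
        coefficient_names=state["names"],
    )
    return result, transcript


def t_to_pvalue(t, df: int):
    """Two-tailed Student-t p-value, p = 2 (1 - F(|t|; df)); monotone in |t|."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return 2.0 * stats.t.sf(np.abs(t), df)


@dataclass
class RegressionReport:
    """Global + per-site coefficient/R²/t/p table.

    The global block carries the decentralized statistics for the consortium
    fit; each per-site block re-fits the same model on that site's data alone
    and reports its purely local statistics, so heterogeneous sites are
    visible at a glance.  Sites with too few rows (N_p <= k) get an
    "insufficient data" marker instead of a local block.
    """

    consortium_name: str
    dependent_variable: str
    lam: float
    global_stats: dict
    per_site: dict = field(default_factory=dict)
    approximate_inference: bool = False  # OLS formulas applied to a ridge fit

    def to_json(self) -> str:
        return json.dumps(
            {
                "consortium_name": self.consortium_name,
                "dependent_variable": self.dependent_variable,
                "lambda": self.lam,
                "approximate_inference": self.approximate_inference,
                "global": self.global_stats,
                "per_site": self.per_site,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, doc: str) -> "RegressionReport":
        d = json.loads(doc)
        return cls(
            consortium_name=d["consortium_name"],
            dependent_variable=d["dependent_variable"],
            lam=d["lambda"],
            global_stats=d["global"],
            per_site=d["per_site"],
            approximate_inference=d["approximate_inference"],
        )

    def to_text(self) -> str:
        lines = [
            f"Consortium: {self.consortium_name}",
            f"Dependent variable: {self.dependent_variable}    lambda = {self.lam:g}"
            + ("    [t/p approximate under regularization]" if self.approximate_inference else ""),
            "",
        ]

        def block(title: str, stats_: dict) -> None:
            lines.append(title)
            if "message" in stats_:
                lines.append(f"  {stats_['message']}")
                lines.append("")
                return
            lines.append(
                f"  R^2 = {stats_['r_squared']:.6f}    df = {stats_['degrees_of_freedom']}"
            )
            lines.append(f"  {'coefficient':<24}{'beta':>16}{'t':>12}{'p':>14}")
            for name, b, t, p in zip(
                stats_["coefficient_names"], stats_["beta"], stats_["t"], stats_["p"]
            ):
                lines.append(f"  {name:<24}{b:>16.4f}{t:>12.4f}{p:>14.4e}")
            lines.append("")

        block("Global", self.global_stats)
        for sid in sorted(self.per_site):
            block(f"Site {sid}", self.per_site[sid])
        return "\n".join(lines)


def _local_block(site: SiteDataset, lam: float) -> dict:
    design, y = build_design(site)
    k = design.k
    if site.n <= k:
        return {"message": f"insufficient data (N={site.n} <= k={k})"}
    beta = closed_form_oracle(design, y, lam)
    X = design.values
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    df = site.n - k
    mse = sse / df
    se = np.sqrt(mse * np.diag(np.linalg.inv(X.T @ X)))
    t = beta / se
    return {
        "coefficient_names": design.coefficient_names,
        "beta": beta.tolist(),
        "r_squared": (1.0 - sse / sst) if sst > 0 else float("nan"),
        "t": t.tolist(),
        "p": t_to_pvalue(t, df).tolist(),
        "degrees_of_freedom": df,
    }


def build_report(
    consortium: ConsortiumState,
    fit: FitResult,
    lam: Optional[float] = None,
    dependent_variable: Optional[str] = None,
    record_payloads: bool = True,
) -> RegressionReport:
    """Assemble the global + per-site statistics table for a fitted model."""
    lam = fit.lam if lam is None else lam
    r2, _, _ = decentralized_r_squared(consortium, fit.w, record_payloads=record_payloads)
    tstats, _ = decentralized_t_stats(consortium, fit.w, record_payloads=record_payloads)
    global_stats = {
        "coefficient_names": list(fit.coefficient_names),
        "beta": fit.w.tolist(),
        "r_squared": r2,
        "t": tstats.t.tolist(),
        "p": tstats.p.tolist(),
        "standard_errors": tstats.se.tolist(),
        "degrees_of_freedom": tstats.df,
        "converged": fit.converged,
        "iterations_used": fit.iterations_used,
    }
    per_site = {s.site_id: _local_block(s, lam) for s in consortium.sites}
    dep = dependent_variable or consortium.sites[0].y_name or "response"
    return RegressionReport(
        consortium_name=consortium.name,
        dependent_variable=dep,
        lam=lam,
        global_stats=global_stats,
        per_site=per_site,
        approximate_inference=lam > 0,
    )
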