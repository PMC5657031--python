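"""JSON computation schemas, a linear pipeline manager, and model expansion.

A *computation schema* declares a step's typed inputs and outputs; a
*pipeline* chains local (per-site preprocessing) and decentralized steps, the
input of a later step wired to the output of an earlier one or bound by the
user.  The manager type-checks the wiring before anything runs, executes
steps in order, caches intermediates by content hash, and stores the final
outputs.  Containerized execution is replaced by an in-process plugin
registry keyed by schema name + version; the schema format itself is
preserved.

:func:`expand_models` implements the combination expansion used for
many-models studies: one regression model per (dependent variable, nonempty
subset of independent variables), singleton subsets first.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .federation import ConsortiumState, SiteDataset
from .regression import RidgeConfig, fit_multishot, fit_singleshot
from .regstats import build_report

__all__ = [
    "TYPE_VOCABULARY",
    "validate_schema",
    "PipelineStep",
    "PipelineSpec",
    "PipelineRun",
    "run_pipeline",
    "expand_models",
    "ModelSpec",
    "zscore_local",
    "REGISTRY",
    "load_consortium",
]

TYPE_VOCABULARY = ("number", "boolean", "string", "matrix_csv", "column_selector")

_REQUIRED_FIELDS = ("name", "version", "mode", "inputs", "outputs")


def validate_schema(document: dict) -> list[str]:
    """Check a computation schema; returns violations with JSON-path locations."""
    violations = []
    if not isinstance(document, dict):
        return ["/: schema must be a JSON object"]
    for f in _REQUIRED_FIELDS:
        if f not in document:
            violations.append(f"/{f}: required field missing")
    if document.get("mode") not in ("local", "decentralized", None):
        violations.append("/mode: must be 'local' or 'decentralized'")
    for section in ("inputs", "outputs"):
        items = document.get(section, [])
        if not isinstance(items, list):
            violations.append(f"/{section}: must be a list")
            continue
        seen = set()
        for i, item in enumerate(items):
            name = item.get("name")
            if not name:
                violations.append(f"/{section}/{i}/name: required field missing")
            elif name in seen:
                violations.append(f"/{section}/{i}/name: duplicate name {name!r}")
            else:
                seen.add(name)
            typ = item.get("type")
            if typ not in TYPE_VOCABULARY:
                violations.append(
                    f"/{section}/{i}/type: {typ!r} not in allowed types {TYPE_VOCABULARY}"
                )
    return violations


# --------------------------------------------------------------------------
# step registry


@dataclass
class StepImpl:
    schema: dict
    fn: Callable
    executions: int = 0

    def run(self, consortium: ConsortiumState, inputs: dict):
        self.executions += 1
        return self.fn(consortium, inputs)


REGISTRY: dict[str, StepImpl] = {}


def register_step(schema: dict, fn: Callable) -> None:
    problems = validate_schema(schema)
    if problems:
        raise ValueError(f"invalid schema for {schema.get('name')!r}: {problems}")
    REGISTRY[f"{schema['name']}@{schema['version']}"] = StepImpl(schema=schema, fn=fn)


def zscore_local(consortium: ConsortiumState, columns: Optional[Sequence[str]] = None) -> ConsortiumState:
    """Site-local z-scoring of numeric covariate columns (a preprocessing step)."""
    new_sites = []
    for site in consortium.sites:
        X = site.X.copy()
        for j, (name, typ) in enumerate(zip(site.feature_names, site.feature_types)):
            if typ != "numeric" or (columns is not None and name not in columns):
                continue
            sd = X[:, j].std()
            X[:, j] = (X[:, j] - X[:, j].mean()) / (sd if sd > 0 else 1.0)
        new_sites.append(
            SiteDataset(
                site_id=site.site_id,
                X=X,
                feature_names=list(site.feature_names),
                feature_types=list(site.feature_types),
                y=site.y,
                y_name=site.y_name,
            )
        )
    return ConsortiumState(
        sites=new_sites,
        master_seed=consortium.master_seed,
        config=consortium.config,
        name=consortium.name,
    )


def _zscore_fn(consortium, inputs):
    cols = inputs.get("columns")
    return zscore_local(consortium, cols), {"data": "consortium"}


def _ridge_fn(consortium, inputs):
    lam = float(inputs.get("lambda", 0.0))
    mode = inputs.get("mode", "multishot")
    if mode == "multishot":
        config = RidgeConfig(
            lam=lam,
            learning_rate=float(inputs.get("learning_rate", 0.25)),
            max_iterations=int(inputs.get("max_iterations", 25)),
            tolerance=float(inputs.get("tolerance", 1e-6)),
        )
        fit, _ = fit_multishot(consortium, config)
    elif mode == "singleshot":
        fit, _ = fit_singleshot(consortium, lam)
    else:
        raise ValueError(f"unknown regression mode {mode!r}")
    report = build_report(consortium, fit, lam=lam)
    return consortium, {"report": report.to_json(), "coefficients": fit.w.tolist()}


register_step(
    {
        "name": "zscore",
        "version": "1.0",
        "mode": "local",
        "inputs": [{"name": "columns", "type": "column_selector", "required": False}],
        "outputs": [{"name": "data", "type": "matrix_csv"}],
    },
    _zscore_fn,
)
register_step(
    {
        "name": "ridge_regression",
        "version": "1.0",
        "mode": "decentralized",
        "inputs": [
            {"name": "lambda", "type": "number", "required": True},
            {"name": "mode", "type": "string", "required": False},
            {"name": "max_iterations", "type": "number", "required": False},
            {"name": "learning_rate", "type": "number", "required": False},
            {"name": "tolerance", "type": "number", "required": False},
        ],
        "outputs": [
            {"name": "report", "type": "string"},
            {"name": "coefficients", "type": "matrix_csv"},
        ],
    },
    _ridge_fn,
)


# --------------------------------------------------------------------------
# pipeline manager


@dataclass
class PipelineStep:
    computation: str  # registry key "name@version"
    bindings: dict = field(default_factory=dict)  # input name -> value or {"from_step", "output"}
    controller: dict = field(default_factory=dict)  # max_iterations, convergence flag


@dataclass
class PipelineSpec:
    steps: list

    @classmethod
    def from_json(cls, doc: str) -> "PipelineSpec":
        d = json.loads(doc)
        return cls(
            steps=[
                PipelineStep(
                    computation=s["computation"],
                    bindings=s.get("bindings", {}),
                    controller=s.get("controller", {}),
                )
                for s in d["steps"]
            ]
        )


@dataclass
class PipelineRun:
    outputs: dict  # final step's outputs
    intermediates: list  # per-step output dicts
    cache_hits: list


class PipelineWiringError(ValueError):
    pass


def _check_wiring(spec: PipelineSpec) -> None:
    produced: list[dict] = []
    for i, step in enumerate(spec.steps):
        impl = REGISTRY.get(step.computation)
        if impl is None:
            raise PipelineWiringError(f"step {i}: unknown computation {step.computation!r}")
        input_types = {inp["name"]: inp["type"] for inp in impl.schema["inputs"]}
        for inp in impl.schema["inputs"]:
            if inp.get("required") and inp["name"] not in step.bindings:
                raise PipelineWiringError(
                    f"step {i}: required input {inp['name']!r} is unbound"
                )
        for name, binding in step.bindings.items():
            if name not in input_types:
                raise PipelineWiringError(
                    f"step {i}: binding for unknown input {name!r}"
                )
            if isinstance(binding, dict) and "from_step" in binding:
                src = binding["from_step"]
                if not 0 <= src < i:
                    raise PipelineWiringError(
                        f"step {i}: from_step {src} is not an earlier step"
                    )
                out_types = produced[src]
                out_name = binding["output"]
                if out_name not in out_types:
                    raise PipelineWiringError(
                        f"step {i}: step {src} has no output {out_name!r}"
                    )
                if out_types[out_name] != input_types[name]:
                    raise PipelineWiringError(
                        f"step {i}: type mismatch wiring {out_name!r} "
                        f"({out_types[out_name]}) into {name!r} ({input_types[name]})"
                    )
        produced.append({o["name"]: o["type"] for o in impl.schema["outputs"]})


def _consortium_digest(consortium: ConsortiumState) -> str:
    h = hashlib.sha256()
    for site in consortium.sites:
        h.update(site.site_id.encode())
        h.update(np.ascontiguousarray(site.X).tobytes())
        if site.y is not None:
            h.update(np.ascontiguousarray(site.y).tobytes())
    h.update(str(consortium.master_seed).encode())
    return h.hexdigest()


def run_pipeline(
    spec: PipelineSpec,
    consortium: ConsortiumState,
    cache: Optional[dict] = None,
) -> PipelineRun:
    """Execute a validated linear pipeline over a consortium.

    Local-mode steps transform each site's data in place (never crossing
    sites); decentralized steps run the corresponding consortium computation.
    Step outputs are cached by content hash of (computation, bindings,
    controller, input-data digest): re-running with unchanged inputs replays
    the cached outputs without recomputation.
    """
    _check_wiring(spec)
    cache = cache if cache is not None else {}
    intermediates: list[dict] = []
    cache_hits = []
    current = consortium
    for i, step in enumerate(spec.steps):
        impl = REGISTRY[step.computation]
        inputs = {}
        for name, binding in step.bindings.items():
            if isinstance(binding, dict) and "from_step" in binding:
                inputs[name] = intermediates[binding["from_step"]][binding["output"]]
            else:
                inputs[name] = binding
        inputs.update(step.controller)
        key = hashlib.sha256(
            json.dumps(
                [step.computation, sorted(inputs.items(), key=lambda kv: kv[0])],
                default=str,
                sort_keys=True,
            ).encode()
            + _consortium_digest(current).encode()
        ).hexdigest()
        if key in cache:
            current, outputs = cache[key]
            cache_hits.append(i)
        else:
            current, outputs = impl.run(current, inputs)
            cache[key] = (current, outputs)
        intermediates.append(outputs)
    return PipelineRun(
        outputs=intermediates[-1] if intermediates else {},
        intermediates=intermediates,
        cache_hits=cache_hits,
    )


# --------------------------------------------------------------------------
# model combination expansion


@dataclass(frozen=True)
class ModelSpec:
    dependent: str
    independents: tuple


def expand_models(
    dependent_variables: Sequence[str], independent_variables: Sequence[str]
) -> list[ModelSpec]:
    """One model per (dependent, nonempty independent subset).

    Subsets are enumerated singletons first, then larger subsets in input
    order, separately for each dependent variable; the count is
    n_dep * (2**n_indep - 1).
    """
    deps = list(dependent_variables)
    indeps = list(independent_variables)
    if not deps or not indeps:
        raise ValueError("both variable lists must be nonempty")
    if len(set(deps)) != len(deps) or len(set(indeps)) != len(indeps):
        raise ValueError("duplicate variable names")
    models = []
    for dep in deps:
        for size in range(1, len(indeps) + 1):
            for combo in itertools.combinations(indeps, size):
                models.append(ModelSpec(dependent=dep, independents=combo))
    return models


def load_consortium(config_path, response: Optional[str] = None) -> ConsortiumState:
    """Build a ConsortiumState from a consortium config JSON.

    Expected structure: {"consortium_name": str, "computation": str,
    "sites": [{"site_id": str, "data_csv": path}], "hyperparameters": {...},
    "seed": int}.  ``response`` (or hyperparameters["roi"]) selects the
    dependent-variable column in each site's CSV.
    """
    from .synthdata import read_freesurfer_csv

    with open(config_path) as fh:
        cfg = json.load(fh)
    hyper = cfg.get("hyperparameters", {})
    roi = response or hyper.get("roi")
    sites = [
        read_freesurfer_csv(s["data_csv"], response=roi, site_id=s["site_id"])
        for s in cfg["sites"]
    ]
    return ConsortiumState(
        sites=sites,
        master_seed=int(cfg.get("seed", 0)),
        config=hyper,
        name=cfg.get("consortium_name", "consortium"),
    )
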