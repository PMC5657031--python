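"""Master/site topology and synchronous round-based message passing.

Every decentralized algorithm in this package runs on the same simulated
consortium: an ordered set of sites, each owning a private dataset, plus one
data-free master (aggregator).  Communication happens in synchronous rounds —
the master broadcasts shared state, every site computes on its local data and
uploads only aggregate quantities, the master combines the uploads — and every
round is recorded in a :class:`RoundTranscript`, the auditable record of
exactly what left each site.

The transcript is the privacy enforcement surface: :func:`audit_transcript`
asserts that no uploaded payload is (or even has the shape of) a slice of any
site's raw subject-level data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional, Protocol, Sequence

import numpy as np

from ._utils import derive_site_seed, pairwise_sum

__all__ = [
    "SiteDataset",
    "ConsortiumState",
    "Round",
    "RoundTranscript",
    "Computation",
    "ComputationError",
    "DivergenceError",
    "run_decentralized",
    "split_pooled",
    "audit_transcript",
    "assert_transcript_private",
]

COLUMN_TYPES = ("numeric", "boolean")


@dataclass
class SiteDataset:
    """One site's private table: observations x features, optional response.

    All sites in a consortium must share identical column names, order and
    types; rows are subjects and never leave the site.
    """

    site_id: str
    X: np.ndarray
    feature_names: list[str]
    feature_types: list[str] = field(default_factory=list)
    y: Optional[np.ndarray] = None
    y_name: Optional[str] = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] < 1:
            raise ValueError(f"site {self.site_id!r}: needs at least one row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError(f"site {self.site_id!r}: missing/non-finite values in X")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError(
                f"site {self.site_id!r}: {len(self.feature_names)} feature names "
                f"for {self.X.shape[1]} columns"
            )
        if not self.feature_types:
            self.feature_types = ["numeric"] * self.X.shape[1]
        for t in self.feature_types:
            if t not in COLUMN_TYPES:
                raise ValueError(f"unknown column type {t!r}; allowed: {COLUMN_TYPES}")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float).ravel()
            if self.y.shape[0] != self.X.shape[0]:
                raise ValueError(f"site {self.site_id!r}: y length != row count")
            if not np.all(np.isfinite(self.y)):
                raise ValueError(f"site {self.site_id!r}: missing values in y")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def raw_arrays(self) -> list[np.ndarray]:
        """Subject-level arrays that must never appear in a transcript."""
        out = [self.X]
        if self.y is not None:
            out.append(self.y.reshape(-1, 1))
        return out


class SiteLike(Protocol):
    site_id: str

    def raw_arrays(self) -> list[np.ndarray]: ...


@dataclass
class ConsortiumState:
    """A named group of sites jointly running one decentralized analysis."""

    sites: list[Any]
    master_seed: int = 0
    config: dict = field(default_factory=dict)
    name: str = "consortium"

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("a consortium needs at least one site")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate site_ids: {sorted(ids)}")
        # Reproducibility contract: iteration is always in ascending site_id order.
        self.sites = sorted(self.sites, key=lambda s: s.site_id)
        self._check_schema()

    def _check_schema(self) -> None:
        datasets = [s for s in self.sites if isinstance(s, SiteDataset)]
        if len(datasets) < 2:
            return
        ref = datasets[0]
        for s in datasets[1:]:
            if s.feature_names != ref.feature_names or s.feature_types != ref.feature_types:
                raise ValueError(
                    f"site {s.site_id!r} column schema differs from {ref.site_id!r}"
                )

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def n_global(self) -> int:
        return sum(s.n for s in self.sites)

    def site_rng(self, site_index: int) -> np.random.Generator:
        return np.random.default_rng(derive_site_seed(self.master_seed, site_index))


@dataclass
class Round:
    iteration: int
    uploads: dict  # site_id -> {payload name -> array/scalar}
    broadcast: dict  # {payload name -> array/scalar}


@dataclass
class RoundTranscript:
    """Ordered log of site->master and master->site payloads per iteration."""

    rounds: list[Round] = field(default_factory=list)
    payloads_recorded: bool = True

    def __len__(self) -> int:
        return len(self.rounds)

    def to_json(self) -> str:
        def conv(obj):
            out = {}
            for k, v in obj.items():
                a = np.asarray(v)
                out[k] = a.tolist() if a.ndim else float(a)
            return out

        doc = {
            "payloads_recorded": self.payloads_recorded,
            "rounds": [
                {
                    "iteration": r.iteration,
                    "uploads": {sid: conv(p) for sid, p in sorted(r.uploads.items())},
                    "broadcast": conv(r.broadcast),
                }
                for r in self.rounds
            ],
        }
        return json.dumps(doc, sort_keys=True)

    def iter_uploads(self):
        for r in self.rounds:
            for sid, payloads in r.uploads.items():
                for name, value in payloads.items():
                    yield r.iteration, sid, name, value


class ComputationError(RuntimeError):
    """A site or master callback failed; carries the round index."""


class DivergenceError(RuntimeError):
    """A master aggregate became non-finite."""


class Computation(Protocol):
    """Callback bundle run by :func:`run_decentralized`.

    ``init_master`` returns the initial model state and first broadcast;
    ``local_step`` is a pure function of (site data, broadcast, site rng) and
    returns the site's uploads; ``aggregate`` combines uploads into the next
    state/broadcast and decides whether to stop.
    """

    def init_master(self, consortium: ConsortiumState, rng: np.random.Generator): ...

    def local_step(self, site, broadcast: dict, rng: np.random.Generator) -> dict: ...

    def aggregate(self, uploads: dict, state, rng: np.random.Generator): ...


def run_decentralized(
    computation: Computation,
    consortium: ConsortiumState,
    max_rounds: int,
    record_payloads: bool = True,
):
    """Execute synchronous rounds until the computation stops or max_rounds.

    Per round: master broadcast -> local compute at every site in ascending
    site_id order -> aggregation -> stop test.  With a fixed master_seed the
    transcript and final state are bit-identical across repeated runs.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    master_rng = np.random.default_rng(consortium.master_seed)
    site_rngs = [consortium.site_rng(i) for i in range(len(consortium.sites))]
    transcript = RoundTranscript(payloads_recorded=record_payloads)

    state, broadcast = computation.init_master(consortium, master_rng)
    for j in range(max_rounds):
        uploads: dict[str, dict] = {}
        try:
            for site, rng in zip(consortium.sites, site_rngs):
                uploads[site.site_id] = computation.local_step(site, broadcast, rng)
            state, broadcast, stop = computation.aggregate(uploads, state, master_rng)
        except (ComputationError, DivergenceError):
            raise
        except Exception as exc:  # noqa: BLE001 - wrap with round context
            raise ComputationError(f"callback failed in round {j}: {exc}") from exc
        for name, value in broadcast.items():
            arr = np.asarray(value, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise DivergenceError(
                    f"divergence: non-finite aggregate {name!r} in round {j}"
                )
        if record_payloads:
            transcript.rounds.append(
                Round(iteration=j, uploads=uploads, broadcast=dict(broadcast))
            )
        else:
            shapes = {
                sid: {k: list(np.shape(v)) for k, v in p.items()}
                for sid, p in uploads.items()
            }
            transcript.rounds.append(Round(iteration=j, uploads=shapes, broadcast={}))
        if stop:
            break
    return state, transcript


def aggregate_sum(uploads: dict, name: str):
    """Sum one named payload over sites, pairwise, in ascending site_id order."""
    return pairwise_sum([uploads[sid][name] for sid in sorted(uploads)])


def split_pooled(
    pooled: SiteDataset,
    n_sites: int,
    proportions: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> list[SiteDataset]:
    """Randomly partition one pooled dataset into ``n_sites`` disjoint sites.

    Supports the split-invariance experiments: any decentralized run over the
    returned sites must reproduce the pooled analysis.
    """
    n = pooled.n
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_sites > n:
        raise ValueError(f"cannot split {n} rows over {n_sites} sites")
    if proportions is not None:
        proportions = np.asarray(proportions, dtype=float)
        if len(proportions) != n_sites:
            raise ValueError("proportions length must equal n_sites")
        if np.any(proportions < 0) or abs(proportions.sum() - 1.0) > 1e-8:
            raise ValueError("proportions must be nonnegative and sum to 1")
        sizes = np.floor(proportions * n).astype(int)
        # largest-remainder completion
        rem = proportions * n - sizes
        for i in np.argsort(-rem)[: n - sizes.sum()]:
            sizes[i] += 1
    else:
        sizes = np.full(n_sites, n // n_sites, dtype=int)
        sizes[: n % n_sites] += 1
    if np.any(sizes == 0):
        raise ValueError("a site would receive zero rows")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    out, start = [], 0
    width = max(2, len(str(n_sites - 1)))
    for i, size in enumerate(sizes):
        idx = np.sort(order[start : start + size])
        start += size
        out.append(
            SiteDataset(
                site_id=f"{pooled.site_id}-{i:0{width}d}",
                X=pooled.X[idx],
                feature_names=list(pooled.feature_names),
                feature_types=list(pooled.feature_types),
                y=None if pooled.y is None else pooled.y[idx],
                y_name=pooled.y_name,
            )
        )
    return out


def _row_slice_match(payload: np.ndarray, raw: np.ndarray) -> bool:
    """True if payload equals a contiguous row-slice of raw (or its transpose)."""
    for cand in (payload, payload.T):
        r, c = cand.shape
        if c != raw.shape[1] or r > raw.shape[0]:
            continue
        for start in range(raw.shape[0] - r + 1):
            if np.array_equal(cand, raw[start : start + r]):
                return True
    return False


def audit_transcript(transcript: RoundTranscript, consortium: ConsortiumState) -> list[str]:
    """Structural privacy audit of every uploaded payload.

    Flags (a) any 2-D upload whose shape equals the uploading site's raw
    (row count x feature count), and (b) any upload equal to a contiguous
    row-slice of the site's raw subject-level data (single raw rows included).
    Returns a list of human-readable violations; empty means the transcript
    contains only aggregates.
    """
    if not transcript.payloads_recorded:
        raise ValueError("cannot audit a transcript recorded without payloads")
    raw_by_site = {s.site_id: s.raw_arrays() for s in consortium.sites}
    violations = []
    for iteration, sid, name, value in transcript.iter_uploads():
        arr = np.asarray(value, dtype=float)
        for raw in raw_by_site.get(sid, []):
            raw2 = np.atleast_2d(np.asarray(raw, dtype=float))
            if arr.ndim == 2 and arr.shape == raw2.shape:
                violations.append(
                    f"round {iteration}, site {sid}, payload {name!r}: shape "
                    f"{arr.shape} equals the site's raw data shape"
                )
            cand = arr.reshape(1, -1) if arr.ndim == 1 else arr
            if cand.ndim == 2 and cand.size and _row_slice_match(cand, raw2):
                violations.append(
                    f"round {iteration}, site {sid}, payload {name!r}: equals a "
                    f"row-slice of the site's raw data"
                )
    return violations


def assert_transcript_private(transcript: RoundTranscript, consortium: ConsortiumState) -> None:
    violations = audit_transcript(transcript, consortium)
    if violations:
        raise AssertionError("privacy audit failed:\n" + "\n".join(violations))
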