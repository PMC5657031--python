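"""Multi-site synthetic data with the structure each algorithm assumes.

Five generators cover the study conditions used throughout the package:

* :func:`simulate_freesurfer_volumes` — tabular regression data shaped like a
  FreeSurfer aseg ROI-volume table (subject_id, age, isControl, one ROI
  column), with per-subject random effect sizes and noise scales drawn from
  fixed intervals around a known intercept.
* :func:`simulate_gaussian_clusters` — labeled isotropic Gaussian blobs for
  embedding/cluster-recovery experiments.
* :func:`simulate_ica_mixtures` — linear mixtures of super-Gaussian sources
  (Laplace or GARCH-style variance-modulated Gaussian) shared across sites
  through one global mixing matrix.
* :func:`simulate_iva_scv_datasets` — several datasets whose corresponding
  sources are correlated across datasets (source component vectors) but
  independent across components, each dataset with its own mixing matrix.
* :func:`simulate_labeled_features` — Gaussian class-conditional feature
  vectors with identical class distributions at every site, for classifier
  training.

Every generator takes a seed and is exactly reproducible; ground truth
(mixing matrices, sources, labels, generating coefficients) is always
returned so recovery metrics need no external reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import derive_site_seed
from .federation import SiteDataset

__all__ = [
    "GeneratorSpec",
    "simulate_freesurfer_volumes",
    "simulate_gaussian_clusters",
    "simulate_ica_mixtures",
    "simulate_iva_scv_datasets",
    "simulate_labeled_features",
    "write_freesurfer_csv",
    "read_freesurfer_csv",
]

DEFAULT_ROI = "Right-Cerebellum-Cortex"
DEFAULT_INTERCEPT = 48466.3
DEFAULT_AGE_EFFECT = (-300.0, -100.0)
DEFAULT_GROUP_EFFECT = (500.0, 1000.0)
DEFAULT_NOISE_SCALE = (1800.0, 2200.0)
ADULT_AGE_RANGE = (18.0, 65.0)

# First-order variance recursion h_t = w + a*x_{t-1}^2 + b*h_{t-1} with
# (a, b) = (0.1, 0.8) and w = 1 - a - b, giving unit unconditional variance.
GARCH_ALPHA = 0.1
GARCH_BETA = 0.8


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic dataset."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    KINDS = (
        "freesurfer_volumes",
        "gaussian_clusters",
        "ica_mixtures",
        "iva_scv",
        "labeled_features",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; allowed {self.KINDS}")
        for k, v in self.parameters.items():
            arr = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"parameter {k!r} is not finite")

    def generate(self):
        fn = {
            "freesurfer_volumes": simulate_freesurfer_volumes,
            "gaussian_clusters": simulate_gaussian_clusters,
            "ica_mixtures": simulate_ica_mixtures,
            "iva_scv": simulate_iva_scv_datasets,
            "labeled_features": simulate_labeled_features,
        }[self.kind]
        return fn(seed=self.seed, **self.parameters)


def _check_interval(name: str, interval) -> tuple[float, float]:
    lo, hi = float(interval[0]), float(interval[1])
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError(f"{name} must be finite")
    if lo > hi:
        raise ValueError(f"{name} is inverted: ({lo}, {hi})")
    return lo, hi


def simulate_freesurfer_volumes(
    n_subjects: int,
    intercept: float = DEFAULT_INTERCEPT,
    age_effect_range: Sequence[float] = DEFAULT_AGE_EFFECT,
    group_effect_range: Sequence[float] = DEFAULT_GROUP_EFFECT,
    noise_scale_range: Sequence[float] = DEFAULT_NOISE_SCALE,
    roi_name: str = DEFAULT_ROI,
    per_subject_effects: bool = True,
    seed: int = 0,
) -> SiteDataset:
    """Simulate an aseg-style ROI volume table around a known linear model.

    Each subject i gets ``roi_volume_i = intercept + b1_i*age_i + b2_i*g_i +
    s_i*eps_i`` where the age effect b1, the group (isControl) effect b2 and
    the noise scale s are drawn uniformly from the given ranges — per subject
    by default, or once per simulation with ``per_subject_effects=False``.
    Age is uniform over the adult range [18, 65]; isControl is a balanced
    Boolean.  The population regression therefore targets the interval
    midpoints while the intercept stays at the fixed constant.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    a_lo, a_hi = _check_interval("age_effect_range", age_effect_range)
    g_lo, g_hi = _check_interval("group_effect_range", group_effect_range)
    s_lo, s_hi = _check_interval("noise_scale_range", noise_scale_range)
    if s_lo < 0:
        raise ValueError("noise scale cannot be negative")

    rng = np.random.default_rng(seed)
    age = rng.uniform(*ADULT_AGE_RANGE, size=n_subjects)
    group = np.zeros(n_subjects)
    group[rng.permutation(n_subjects)[: n_subjects // 2]] = 1.0
    size = n_subjects if per_subject_effects else 1
    b1 = rng.uniform(a_lo, a_hi, size=size)
    b2 = rng.uniform(g_lo, g_hi, size=size)
    sd = rng.uniform(s_lo, s_hi, size=size)
    eps = rng.standard_normal(n_subjects)
    volume = intercept + b1 * age + b2 * group + sd * eps
    return SiteDataset(
        site_id="pooled",
        X=np.column_stack([age, group]),
        feature_names=["age", "isControl"],
        feature_types=["numeric", "boolean"],
        y=volume,
        y_name=roi_name,
    )


def simulate_gaussian_clusters(
    n_clusters: int,
    dim: int,
    n_per_cluster: int,
    separation: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian blobs whose centers are >= separation s.d. apart.

    Returns (points, labels).  Centers are drawn on a sphere of radius chosen
    so every pairwise center distance meets the separation requirement
    (resampled if necessary), with unit within-cluster standard deviation.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if dim < 2:
        raise ValueError("dim must be >= 2 (2-D embedding target)")
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    for _ in range(200):
        # centers uniform in a box wide enough that the separation is feasible
        radius = separation * max(1.0, n_clusters ** (1.0 / min(dim, 3)))
        centers = rng.uniform(-radius, radius, size=(n_clusters, dim))
        if n_clusters == 1:
            break
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        if d[np.triu_indices(n_clusters, 1)].min() >= separation:
            break
    else:
        raise RuntimeError("could not place cluster centers at the requested separation")
    points = np.concatenate(
        [c + rng.standard_normal((n_per_cluster, dim)) for c in centers]
    )
    labels = np.repeat(np.arange(n_clusters), n_per_cluster)
    return points, labels


def _garch_series(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance series with GARCH(1,1)-style conditional variance."""
    omega = 1.0 - GARCH_ALPHA - GARCH_BETA
    h = 1.0
    x = np.empty(n)
    eps = rng.standard_normal(n)
    prev = 0.0
    for t in range(n):
        h = omega + GARCH_ALPHA * prev**2 + GARCH_BETA * h
        x[t] = np.sqrt(h) * eps[t]
        prev = x[t]
    return x


def _draw_sources(kind: str, m: int, n: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "laplace":
        return rng.laplace(scale=1.0 / np.sqrt(2.0), size=(m, n))
    if kind == "garch_like":
        return np.vstack([_garch_series(n, rng) for _ in range(m)])
    raise ValueError(f"unknown source_kind {kind!r}")


def _well_conditioned_matrix(
    m: int, rng: np.random.Generator, max_cond: float = 20.0, retries: int = 50
) -> np.ndarray:
    for _ in range(retries):
        a = rng.standard_normal((m, m))
        if np.linalg.cond(a) < max_cond:
            return a
    raise RuntimeError(f"could not sample a mixing matrix with condition < {max_cond}")


def simulate_ica_mixtures(
    n_sources: int,
    n_samples_per_site: int,
    n_sites: int,
    source_kind: str = "laplace",
    mixing_matrix: Optional[np.ndarray] = None,
    seed: int = 0,
) -> tuple[list[SiteDataset], np.ndarray, np.ndarray]:
    """Linearly mixed super-Gaussian sources shared across sites.

    One global square mixing matrix A (condition number < 20) mixes
    independent source segments at every site: X_p = A S_p.  Returns
    (sites, A, pooled sources).  Site rows are samples, columns channels.
    ``mixing_matrix`` overrides the sampled A (e.g. identity for tests).

    The pooled source matrix is drawn from a single stream and sliced into
    contiguous per-site segments, so splitting the same total sample count
    over a different number of sites leaves the concatenated data identical
    (generation commutes with site-splitting).
    """
    rng = np.random.default_rng(seed)
    A = _well_conditioned_matrix(n_sources, rng) if mixing_matrix is None else np.asarray(
        mixing_matrix, dtype=float
    )
    if A.shape != (n_sources, n_sources):
        raise ValueError("mixing matrix must be square n_sources x n_sources")
    n_total = n_samples_per_site * n_sites
    source_rng = np.random.default_rng(derive_site_seed(seed + 1, 0))
    S = _draw_sources(source_kind, n_sources, n_total, source_rng)
    names = [f"ch{c}" for c in range(n_sources)]
    sites = []
    for p in range(n_sites):
        S_p = S[:, p * n_samples_per_site : (p + 1) * n_samples_per_site]
        sites.append(
            SiteDataset(site_id=f"site-{p:02d}", X=(A @ S_p).T, feature_names=list(names))
        )
    return sites, A, S


def simulate_iva_scv_datasets(
    n_datasets: int,
    n_sources: int,
    n_samples: int,
    cross_dataset_correlation: float = 0.7,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Correlated source-component-vector datasets for IVA.

    The n-th source across the K datasets shares a common GARCH-style
    variance driver and a common Gaussian factor with loading
    sqrt(correlation), so corresponding sources correlate about the requested
    level while distinct sources stay uncorrelated.  Each dataset is mixed by
    its own well-conditioned A^[k].  Returns (mixtures X^[k] of shape
    sources x samples, mixing matrices A^[k], sources of shape
    K x sources x samples).
    """
    if n_datasets < 2:
        raise ValueError("IVA needs K >= 2 datasets")
    rho = float(cross_dataset_correlation)
    if not 0.0 <= rho < 1.0:
        raise ValueError("cross_dataset_correlation must be in [0, 1)")
    rng = np.random.default_rng(seed)
    S = np.empty((n_datasets, n_sources, n_samples))
    for n in range(n_sources):
        common = rng.standard_normal(n_samples)
        sigma = np.abs(_garch_series(n_samples, rng)) + 0.25  # shared variance driver
        sigma /= np.sqrt(np.mean(sigma**2))
        for k in range(n_datasets):
            g = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal(n_samples)
            S[k, n] = sigma * g
    A = [_well_conditioned_matrix(n_sources, rng) for _ in range(n_datasets)]
    X = [A[k] @ S[k] for k in range(n_datasets)]
    return X, A, S


def simulate_labeled_features(
    n_per_site: int,
    n_sites: int,
    n_features: int,
    n_classes: int = 2,
    class_separation: float = 2.0,
    seed: int = 0,
) -> list[SiteDataset]:
    """Gaussian class-conditional feature vectors, identical across sites.

    Class c has mean ``class_separation * m_c`` with unit isotropic noise,
    where the unit-norm direction m_c is shared by all sites; sites differ
    only by sampling.  Labels are stored in ``y``.  As with the mixture
    generator, the pooled sample is drawn from one stream and sliced
    contiguously per site, so total sample count alone determines the pooled
    data regardless of the site count.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((n_classes, n_features))
    means /= np.linalg.norm(means, axis=1, keepdims=True)
    means *= class_separation
    n_total = n_per_site * n_sites
    sample_rng = np.random.default_rng(derive_site_seed(seed + 1, 0))
    labels = sample_rng.integers(0, n_classes, size=n_total)
    X = means[labels] + sample_rng.standard_normal((n_total, n_features))
    names = [f"f{j}" for j in range(n_features)]
    sites = []
    for p in range(n_sites):
        sl = slice(p * n_per_site, (p + 1) * n_per_site)
        sites.append(
            SiteDataset(
                site_id=f"site-{p:02d}",
                X=X[sl],
                feature_names=list(names),
                y=labels[sl].astype(float),
                y_name="label",
            )
        )
    return sites


def write_freesurfer_csv(site: SiteDataset, path) -> None:
    """Write a site table as FreeSurfer-style CSV (Booleans as True/False)."""
    df = pd.DataFrame({"subject_id": [f"subj{i:05d}" for i in range(site.n)]})
    for j, (name, typ) in enumerate(zip(site.feature_names, site.feature_types)):
        col = site.X[:, j]
        df[name] = col.astype(bool) if typ == "boolean" else col
    if site.y is not None:
        df[site.y_name or "response"] = site.y
    df.to_csv(path, index=False)


def read_freesurfer_csv(path, response: Optional[str] = None, site_id: Optional[str] = None) -> SiteDataset:
    """Read a FreeSurfer-style CSV into a SiteDataset.

    Boolean columns (literal True/False) are encoded 0/1; ``response`` names
    the dependent-variable column (e.g. an ROI volume).
    """
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values after ingestion")
    sid = site_id or Path(path).stem
    id_col = df.columns[0]
    feats, names, types = [], [], []
    y = None
    for col in df.columns[1:]:
        if response is not None and col == response:
            y = df[col].to_numpy(dtype=float)
            continue
        if df[col].dtype == bool:
            feats.append(df[col].to_numpy(dtype=float))
            types.append("boolean")
        else:
            feats.append(pd.to_numeric(df[col]).to_numpy(dtype=float))
            types.append("numeric")
        names.append(col)
    del id_col
    return SiteDataset(
        site_id=sid,
        X=np.column_stack(feats),
        feature_names=names,
        feature_types=types,
        y=y,
        y_name=response,
    )
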