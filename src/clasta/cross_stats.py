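"""Cross-channel distance statistics.

The test statistic of the randomization test is the area under the empirical
cumulative distribution function (ecdf) of cross-channel nearest-neighbor
distances,

    g = integral_0^{r_max} cdf(r) dr ,

which for a step ecdf has the closed form
``r_max - mean_i(min(r_i, r_max))``.  Two statistic variants are supported:
the mean distance to the k nearest neighbors (k-NN), and the per-point
cross-type Ripley statistic L_cross(r*) = sqrt(K_i / pi) with
K_i = (area / n_ref) * (# reference points within r* of query point i),
without edge correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, InsufficientDataError
from .localizations import LocalizationSet


@dataclass(frozen=True)
class EmpiricalCdf:
    """Right-continuous empirical cdf stored as its sorted sample."""

    sorted_values: np.ndarray

    def __post_init__(self) -> None:
        v = np.sort(np.asarray(self.sorted_values, dtype=float).ravel())
        if v.size == 0:
            raise InsufficientDataError("empirical cdf needs at least one value")
        if not np.all(np.isfinite(v)):
            raise ValueError("cdf values must be finite")
        object.__setattr__(self, "sorted_values", v)

    @property
    def n(self) -> int:
        return self.sorted_values.size

    def __call__(self, r) -> np.ndarray | float:
        """cdf(r) = (# values <= r) / n, vectorized over r."""
        counts = np.searchsorted(self.sorted_values, np.asarray(r, dtype=float), side="right")
        out = counts / self.n
        return float(out) if np.isscalar(r) or np.ndim(r) == 0 else out


@dataclass(frozen=True)
class StatisticConfig:
    """Choice of summary statistic for the randomization test.

    Parameters
    ----------
    kind : {"nn", "knn", "lcross"}
        Nearest neighbor, mean of k nearest neighbors, or L_cross(r*).
    k : int
        Neighbor count for ``knn`` (typical values 3, 5, 10); 1 for ``nn``.
    r_star : float
        Disc radius in nm for ``lcross`` (default 50 nm).
    r_max : float or "auto"
        Upper integration limit for the test statistic; "auto" uses the
        maximum statistic value occurring anywhere in the analysis, making
        the test parameter-free.
    """

    kind: str = "nn"
    k: int = 1
    r_star: float = 50.0
    r_max: float | str = "auto"

    def __post_init__(self) -> None:
        if self.kind not in ("nn", "knn", "lcross"):
            raise ConfigurationError(f"unknown statistic kind {self.kind!r}")
        if self.k < 1:
            raise ConfigurationError("k must be a positive integer")
        if self.kind == "nn" and self.k != 1:
            raise ConfigurationError("kind='nn' implies k=1; use kind='knn' for k>1")
        if self.r_star <= 0:
            raise ConfigurationError("r_star must be positive")
        if self.r_max != "auto" and not (np.isfinite(self.r_max) and self.r_max > 0):
            raise ConfigurationError("r_max must be 'auto' or a positive number")


def cross_nn_distances(
    query: LocalizationSet, reference: LocalizationSet, k: int = 1
) -> np.ndarray:
    """Distance from each query localization to its nearest reference
    localization (k=1), or the mean of the k smallest such distances (k>1).

    Uses the plain (non-toroidal) Euclidean metric.
    """
    if len(query) == 0:
        raise InsufficientDataError("query channel is empty")
    if len(reference) < k:
        raise InsufficientDataError(
            f"reference channel has {len(reference)} record(s), need at least k={k}"
        )
    tree = cKDTree(reference.xy)
    return _nn_from_tree(query.xy, tree, k)


def _nn_from_tree(query_xy: np.ndarray, reference_tree: cKDTree, k: int) -> np.ndarray:
    d, _ = reference_tree.query(query_xy, k=k, workers=-1)
    if k > 1:
        d = d.mean(axis=1)
    return np.asarray(d, dtype=float).ravel()


def empirical_cdf(values) -> EmpiricalCdf:
    """Build the right-continuous ecdf of a non-empty sample."""
    return EmpiricalCdf(np.asarray(values, dtype=float))


def cdf_integral(cdf: EmpiricalCdf, r_max: float) -> float:
    """Exact integral of the step ecdf over [0, r_max].

    Equals ``r_max - mean_i(min(v_i, r_max))``; lies in [0, r_max].
    """
    if not (np.isfinite(r_max) and r_max > 0):
        raise ValueError("r_max must be positive and finite")
    return float(r_max - np.minimum(cdf.sorted_values, r_max).mean())


def lcross_values(
    query: LocalizationSet,
    reference: LocalizationSet,
    r_star: float = 50.0,
    area: float | None = None,
) -> np.ndarray:
    """Per-query-point L_cross(r*) values (nm), without edge correction.

    ``area`` defaults to the query set's ROI area (nm^2).
    """
    if len(reference) == 0:
        raise InsufficientDataError("reference channel is empty")
    if len(query) == 0:
        raise InsufficientDataError("query channel is empty")
    if area is None:
        area = query.roi.area
    if area <= 0:
        raise ValueError("area must be positive")
    tree = cKDTree(reference.xy)
    return _lcross_from_tree(query.xy, tree, len(reference), r_star, area)


def _lcross_from_tree(
    query_xy: np.ndarray, reference_tree: cKDTree, n_reference: int,
    r_star: float, area: float,
) -> np.ndarray:
    counts = reference_tree.query_ball_point(
        query_xy, r_star, workers=-1, return_length=True
    )
    k_hat = area / n_reference * np.asarray(counts, dtype=float)
    return np.sqrt(k_hat / np.pi)


def statistic_values(
    query_xy: np.ndarray,
    reference_tree: cKDTree,
    n_reference: int,
    config: StatisticConfig,
    area: float,
) -> np.ndarray:
    """One statistic value per query point for a prebuilt reference tree.

    Internal fast path shared by the observed data and the randomized
    controls, so the reference tree is built only once per test.
    """
    if config.kind in ("nn", "knn"):
        k = 1 if config.kind == "nn" else config.k
        if n_reference < k:
            raise InsufficientDataError(
                f"reference channel has {n_reference} record(s), need at least k={k}"
            )
        return _nn_from_tree(query_xy, reference_tree, k)
    return _lcross_from_tree(query_xy, reference_tree, n_reference, config.r_star, area)
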