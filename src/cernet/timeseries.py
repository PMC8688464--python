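"""Soft clustering of three-timepoint expression profiles.

The monocyte-to-macrophage differentiation series is reduced to per-gene
timepoint means, screened by a standard-deviation filter, standardized to
zero mean and unit SD per gene, and soft-clustered with fuzzy c-means.
Cluster centroids are then classified into qualitative trend shapes
(monotone up/down, rise-fall, fall-rise), and genes are assigned to trend
classes via their maximum cluster membership.

Order of operations: the SD filter runs on the raw timepoint means,
*before* standardization — after standardization every profile has SD 1
and the filter could no longer remove anything, which would defeat its
purpose of discarding genes with essentially flat expression.

Fuzzy c-means minimizes
``J = sum_i sum_j u_ij^m ||x_i - c_j||^2`` subject to rows of the
membership matrix ``u`` summing to 1, by the classical alternating updates.
The fuzzifier ``m`` controls softness (m -> 1 approaches hard k-means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FuzzyClustering",
    "profile_means",
    "sd_filter",
    "standardize",
    "estimate_fuzzifier",
    "fuzzy_cmeans",
    "classify_trends",
    "cluster_gene_sets",
]

TREND_LABELS = ("rise-fall", "fall-rise", "up", "down")


@dataclass
class FuzzyClustering:
    """Fuzzy c-means result.

    ``membership`` is genes x clusters (rows sum to 1); ``centroids`` is
    clusters x timepoints; ``objective`` the value of J after each
    iteration; ``row_sum_error`` the largest deviation of any membership
    row sum from 1 seen at any iteration.
    """

    membership: pd.DataFrame
    centroids: pd.DataFrame
    m: float
    objective: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    row_sum_error: float = 0.0

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def hard_labels(self) -> pd.Series:
        """Argmax-membership cluster per gene."""
        return self.membership.idxmax(axis=1)


def profile_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean expression at each timepoint.

    Timepoint order follows first appearance in the sample metadata (so a
    0h/3h/20h design keeps its chronological order rather than a
    lexicographic one).
    """
    tp = matrix.samples.loc[matrix.values.columns, "timepoint"]
    order = list(dict.fromkeys(tp))
    out = pd.DataFrame(index=matrix.values.index, columns=order, dtype=float)
    for label in order:
        cols = tp.index[tp == label]
        out[label] = matrix.values[cols].mean(axis=1)
    out.index.name = matrix.values.index.name
    return out


def sd_filter(profiles: pd.DataFrame, min_sd: float = 0.05) -> pd.DataFrame:
    """Keep genes whose SD across timepoint means is >= ``min_sd``.

    The SD is the population SD (ddof=0) of the raw (pre-standardization)
    timepoint means; the bound is inclusive.
    """
    if min_sd < 0:
        raise ValueError("min_sd must be >= 0")
    sd = profiles.std(axis=1, ddof=0)
    return profiles.loc[sd >= min_sd]


def standardize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene zero mean, unit SD (ddof=0).

    Raises if any gene has zero SD — such genes must be removed by
    :func:`sd_filter` first.
    """
    mu = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = list(profiles.index[sd == 0][:5])
        raise ValueError(f"zero-SD profiles reached standardize: {bad!r}")
    return profiles.sub(mu, axis=0).div(sd, axis=0)


def estimate_fuzzifier(
    profiles: pd.DataFrame,
    coefficient: float = 2.0,
    override: float | None = None,
    clamp: tuple[float, float] = (1.05, 4.0),
) -> float:
    """Data-size heuristic for the fuzzifier m.

    ``m = 1 + coefficient * (1/D + 1/sqrt(G))`` for G genes in D
    dimensions, clamped to ``clamp``: fewer genes (or dimensions) call for
    a softer partition. An explicit ``override`` is returned unchanged.
    """
    if override is not None:
        if override <= 1:
            raise ValueError("fuzzifier must be > 1")
        return float(override)
    g, d = profiles.shape
    m = 1.0 + coefficient * (1.0 / d + 1.0 / np.sqrt(g))
    return float(min(max(m, clamp[0]), clamp[1]))


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = 10,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> FuzzyClustering:
    """Fuzzy c-means on standardized profiles.

    Centroids are initialized from ``c`` distinct gene rows chosen by the
    seeded generator; the alternating membership/centroid updates run until
    the largest membership change falls below ``tol`` or ``max_iter`` is
    reached (non-convergence returns the best state with
    ``converged=False`` rather than raising). A gene coinciding exactly
    with one or more centroids gets full membership in the first of them.
    """
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzzifier must be > 1")
    x = profiles.to_numpy(float)
    n = x.shape[0]
    if n <= c:
        raise ValueError(f"need more genes ({n}) than clusters ({c})")
    rng = np.random.default_rng(seed)
    centroids = x[rng.choice(n, size=c, replace=False)].copy()

    exponent = 1.0 / (m - 1.0)
    u = np.zeros((n, c))
    objective: list[float] = []
    row_err = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = cdist(x, centroids, "sqeuclidean")
        coincident = d2 <= 1e-300
        with np.errstate(divide="ignore"):
            inv = d2 ** (-exponent)
        u_new = np.empty_like(d2)
        regular = ~coincident.any(axis=1)
        u_new[regular] = inv[regular] / inv[regular].sum(axis=1, keepdims=True)
        for i in np.flatnonzero(~regular):
            u_new[i] = 0.0
            u_new[i, np.argmax(coincident[i])] = 1.0
        row_err = max(row_err, float(np.abs(u_new.sum(axis=1) - 1.0).max()))

        um = u_new**m
        weights = um.sum(axis=0)
        for j in range(c):
            if weights[j] > 0:
                centroids[j] = um[:, j] @ x / weights[j]
        d2_new = cdist(x, centroids, "sqeuclidean")
        objective.append(float((um * d2_new).sum()))

        delta = np.abs(u_new - u).max()
        u = u_new
        if it > 1 and delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("fuzzy_cmeans: no convergence in %d iterations", max_iter)

    cluster_ids = [f"cluster{j + 1}" for j in range(c)]
    return FuzzyClustering(
        membership=pd.DataFrame(u, index=profiles.index, columns=cluster_ids),
        centroids=pd.DataFrame(
            centroids, index=cluster_ids, columns=profiles.columns
        ),
        m=float(m),
        objective=objective,
        converged=converged,
        n_iter=it,
        row_sum_error=row_err,
    )


def classify_trends(clustering: FuzzyClustering) -> dict[str, str]:
    """Qualitative shape of each centroid over the three timepoints.

    For a centroid (a, b, c): ``rise-fall`` if the middle point is the
    strict maximum, ``fall-rise`` if it is the strict minimum, otherwise
    monotone ``up``/``down`` by comparing the endpoints (ties at the middle
    point fall through to the endpoint comparison).
    """
    if clustering.centroids.shape[1] != 3:
        raise ValueError("trend classification assumes 3 timepoints")
    labels: dict[str, str] = {}
    for cid, (a, b, c3) in clustering.centroids.iterrows():
        if b > a and b > c3:
            labels[cid] = "rise-fall"
        elif b < a and b < c3:
            labels[cid] = "fall-rise"
        elif a < c3:
            labels[cid] = "up"
        else:
            labels[cid] = "down"
    return labels


def cluster_gene_sets(
    clustering: FuzzyClustering,
    trend_labels: Mapping[str, str] | None = None,
    membership_threshold: float = 0.5,
) -> dict[str, list[str]]:
    """Gene lists per trend class from thresholded hard assignments.

    A gene joins its argmax-membership cluster only if that membership is
    at least ``membership_threshold``; each trend class's list is the union
    of the genes of all clusters carrying that label, sorted.
    """
    if trend_labels is None:
        trend_labels = classify_trends(clustering)
    out: dict[str, list[str]] = {lab: [] for lab in TREND_LABELS}
    best = clustering.membership.idxmax(axis=1)
    peak = clustering.membership.max(axis=1)
    for gene in clustering.membership.index:
        if peak[gene] >= membership_threshold:
            out[trend_labels[best[gene]]].append(gene)
    return {lab: sorted(genes) for lab, genes in out.items()}


def intersect_gene_lists(
    a: Iterable[str], b: Iterable[str]
) -> list[str]:
    """Sorted exact-id intersection of two gene lists."""
    return sorted(set(a) & set(b))
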