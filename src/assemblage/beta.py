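"""Beta diversity: Bray-Curtis, Hellinger transform, NMDS and ANOSIM."""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .distance import DistanceMatrix
from .otu import OtuTable

__all__ = [
    "bray_curtis",
    "hellinger_transform",
    "nmds",
    "anosim",
    "OrdinationResult",
    "AnosimResult",
]


def bray_curtis(table: OtuTable, transform: str = "none") -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    ``transform`` is applied to counts first: ``none``, ``sqrt`` or
    ``relative`` (per-sample relative abundance).  On evenly rarefied tables
    ``none`` and ``relative`` coincide.
    """
    totals = table.sample_totals()
    empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if empty:
        raise ValueError(f"all-zero samples: {empty}")
    x = table.counts.astype(float)
    if transform == "none":
        pass
    elif transform == "sqrt":
        x = np.sqrt(x)
    elif transform == "relative":
        x = x / totals[:, None]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return DistanceMatrix(squareform(pdist(x, metric="braycurtis")),
                          list(table.sample_ids))


def hellinger_transform(table: OtuTable) -> pd.DataFrame:
    """Square root of per-sample relative abundance.

    Euclidean distance between transformed rows equals the Hellinger
    distance between the samples' abundance profiles.
    """
    totals = table.sample_totals()
    empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if empty:
        raise ValueError(f"empty samples: {empty}")
    vals = np.sqrt(table.counts / totals[:, None])
    return pd.DataFrame(vals, index=list(table.sample_ids), columns=list(table.otu_ids))


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x k, centered
    stress: float            # Kruskal stress-1
    k: int
    converged: bool
    seed: int | None
    n_restarts: int
    labels: tuple[str, ...]
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.coordinates, index=list(self.labels), columns=cols)


def _stress1(dissim: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against target dissimilarities."""
    d = pdist(coords)
    order = np.argsort(dissim, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(d.size), d[order])
    denom = float((d ** 2).sum())
    if denom == 0.0:
        return 0.0
    return math.sqrt(float(((d - dhat) ** 2).sum()) / denom)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 50,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric multidimensional scaling with best-of-restarts selection.

    Reports Kruskal stress-1 (monotone regression of embedding distances on
    the input dissimilarities) for the lowest-stress solution; coordinates
    are mean-centered.  An all-equal input matrix is flagged as degenerate.
    """
    if dm.n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} samples, got {dm.n}")
    cond = dm.condensed()
    degenerate = bool(np.allclose(cond, cond[0]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MDS(
            n_components=k,
            metric=False,
            dissimilarity="precomputed",
            n_init=n_restarts,
            random_state=seed,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
        )
        coords = model.fit_transform(dm.values)
    coords = coords - coords.mean(axis=0)
    stress = _stress1(cond, coords)
    return OrdinationResult(
        coordinates=coords,
        stress=stress,
        k=k,
        converged=model.n_iter_ < max_iter,
        seed=seed,
        n_restarts=n_restarts,
        labels=dm.labels,
        degenerate=degenerate,
    )


@dataclass
class AnosimResult:
    global_r: float
    p_value: float
    n_permutations: int
    seed: int | None
    exact: bool = False


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    dm: DistanceMatrix,
    grouping: Mapping[str, str],
    n_permutations: int = 999,
    seed: int | None = 0,
    exact: bool = False,
) -> AnosimResult:
    """Analysis of similarities on ranked dissimilarities.

    ``R = (mean_between_rank - mean_within_rank) / (M / 2)`` with
    ``M = n(n-1)/2``; the p-value is the one-sided upper tail over label
    permutations.  ``exact=True`` enumerates all label permutations (small n
    only) and the identity permutation is included in the count.
    """
    labels = [grouping[s] for s in dm.labels]
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    n = dm.n
    labels = np.asarray(labels)
    cond_ranks = rankdata(dm.condensed())
    iu = np.triu_indices(n, k=1)

    def within_mask(lab: np.ndarray) -> np.ndarray:
        return lab[iu[0]] == lab[iu[1]]

    r_obs = _anosim_r(cond_ranks, within_mask(labels))
    if exact:
        total = 0
        hits = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if _anosim_r(cond_ranks, within_mask(labels[list(perm)])) >= r_obs - 1e-12:
                hits += 1
        return AnosimResult(r_obs, hits / total, total, seed, exact=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _anosim_r(cond_ranks, within_mask(labels[perm])) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return AnosimResult(r_obs, p, n_permutations, seed)
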