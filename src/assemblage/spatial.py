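"""Spatial statistics: geographic/environmental distances, Mantel tests,
distance-decay summaries and PCNM spatial eigenfunctions."""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .distance import DistanceMatrix
from .metadata import SampleMetadata

__all__ = [
    "EARTH_RADIUS_KM",
    "geographic_distance",
    "env_distance",
    "mantel",
    "partial_mantel",
    "distance_decay",
    "pcnm",
    "MantelResult",
    "PcnmBasis",
]

EARTH_RADIUS_KM = 6371.0088


def geographic_distance(metadata: SampleMetadata) -> DistanceMatrix:
    """Great-circle (haversine) distance matrix in kilometres."""
    lon = np.radians(metadata.frame["longitude"].to_numpy())
    lat = np.radians(metadata.frame["latitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, metadata.sample_ids)


def env_distance(
    metadata: SampleMetadata,
    variables: list[str] | None = None,
    standardize: bool = True,
    no_sqrt: tuple[str, ...] = ("pH",),
) -> DistanceMatrix:
    """Euclidean distance over environmental variables.

    All variables except those named in ``no_sqrt`` (pH by default) are
    square-root transformed first; ``standardize`` z-scores each variable
    afterwards (variables carry incommensurable units).
    """
    env = metadata.env_table(variables)
    if env.isna().any().any():
        bad = [(s, v) for v in env.columns for s in env.index[env[v].isna()]]
        raise ValueError(f"missing environmental values: {bad[:5]}")
    x = env.copy()
    for col in x.columns:
        if col in no_sqrt:
            continue
        if (x[col] < 0).any():
            sample = x.index[x[col] < 0][0]
            raise ValueError(
                f"negative value for {col!r} at sample {sample!r}; cannot sqrt"
            )
        x[col] = np.sqrt(x[col])
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd = sd.replace(0.0, 1.0)  # constant columns contribute zero distance
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, metadata.sample_ids)


# -- Mantel machinery -----------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    tail: str
    method: str
    seed: int | None
    exact: bool = False
    orientation: str | None = None

    def to_dict(self) -> dict:
        return {
            "r": self.r, "p_value": self.p_value,
            "n_permutations": self.n_permutations, "tail": self.tail,
            "method": self.method, "seed": self.seed, "exact": self.exact,
            "orientation": self.orientation,
        }


def _prep(dm: DistanceMatrix, method: str) -> np.ndarray:
    """Square matrix of (rank-)transformed values, zero diagonal kept."""
    vals = dm.values
    if method == "spearman":
        cond = rankdata(squareform(vals, checks=False))
        return squareform(cond)
    return vals


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a ** 2).sum()) * float((b ** 2).sum()))
    if denom == 0.0:
        return float("nan")
    return float((a * b).sum() / denom)


def _tail_hit(r_perm: float, r_obs: float, tail: str) -> bool:
    eps = 1e-12
    if tail == "upper":
        return r_perm >= r_obs - eps
    if tail == "lower":
        return r_perm <= r_obs + eps
    return abs(r_perm) >= abs(r_obs) - eps


def mantel(
    dmA: DistanceMatrix,
    dmB: DistanceMatrix,
    method: str = "spearman",
    n_permutations: int = 999,
    tail: str = "upper",
    seed: int | None = 0,
    exact: bool = False,
) -> MantelResult:
    """Mantel test: correlation of off-diagonal entries of two distance
    matrices with a permutation p-value.

    Rows/columns of ``dmB`` are permuted simultaneously.  ``exact=True``
    enumerates all n! permutations (identity included in the count) — only
    sensible for very small n.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if tail not in ("upper", "lower", "two"):
        raise ValueError(f"unknown tail {tail!r}")
    if set(dmA.labels) != set(dmB.labels):
        raise ValueError("label mismatch between matrices")
    dmB = dmB.reorder(list(dmA.labels))
    n = dmA.n
    if n < 4:
        raise ValueError("need at least 4 samples")
    a = squareform(_prep(dmA, method), checks=False)
    sq_b = _prep(dmB, method)
    r_obs = _corr(a, squareform(sq_b, checks=False))
    if math.isnan(r_obs):
        warnings.warn("zero variance in a distance matrix; Mantel r undefined")
        return MantelResult(float("nan"), float("nan"), 0, tail, method, seed, exact)
    if exact:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            perm = list(perm)
            r_p = _corr(a, squareform(sq_b[np.ix_(perm, perm)], checks=False))
            if _tail_hit(r_p, r_obs, tail):
                hits += 1
        return MantelResult(r_obs, hits / total, total, tail, method, seed, exact=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_p = _corr(a, squareform(sq_b[np.ix_(perm, perm)], checks=False))
        if _tail_hit(r_p, r_obs, tail):
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return MantelResult(r_obs, p, n_permutations, tail, method, seed)


def _partial_r(ab: float, ac: float, bc: float) -> float:
    return (ab - ac * bc) / math.sqrt((1 - ac ** 2) * (1 - bc ** 2))


def partial_mantel(
    dmA: DistanceMatrix,
    dmB: DistanceMatrix,
    dmC: DistanceMatrix,
    method: str = "spearman",
    n_permutations: int = 999,
    tail: str = "upper",
    seed: int | None = 0,
) -> MantelResult:
    """Partial Mantel test of A vs B conditioned on C.

    Uses the first-order partial correlation of the off-diagonal vectors and
    the simple permutation scheme: rows/columns of ``dmB`` are permuted while
    A and C stay fixed.
    """
    if set(dmA.labels) != set(dmB.labels) or set(dmA.labels) != set(dmC.labels):
        raise ValueError("label mismatch between matrices")
    dmB = dmB.reorder(list(dmA.labels))
    dmC = dmC.reorder(list(dmA.labels))
    n = dmA.n
    a = squareform(_prep(dmA, method), checks=False)
    sq_b = _prep(dmB, method)
    c = squareform(_prep(dmC, method), checks=False)
    b = squareform(sq_b, checks=False)
    r_ac = _corr(a, c)
    r_bc = _corr(b, c)
    if abs(r_ac) >= 1.0 - 1e-12 or abs(r_bc) >= 1.0 - 1e-12:
        # conditioning on A itself: numerator vanishes too -> r is 0 by
        # construction; anything else is genuinely degenerate
        if abs(_corr(a, b) - r_ac * r_bc) < 1e-9:
            return MantelResult(0.0, 1.0, 0, tail, method, seed)
        raise ValueError("degenerate conditioning: |r_AC| or |r_BC| = 1")
    r_obs = _partial_r(_corr(a, b), r_ac, r_bc)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        bp = squareform(sq_b[np.ix_(perm, perm)], checks=False)
        r_bc_p = _corr(bp, c)
        if abs(r_bc_p) >= 1.0 - 1e-12:
            continue
        r_p = _partial_r(_corr(a, bp), r_ac, r_bc_p)
        if _tail_hit(r_p, r_obs, tail):
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return MantelResult(r_obs, p, n_permutations, tail, method, seed)


@dataclass
class DistanceDecayResult:
    mantel: MantelResult
    slope: float        # OLS slope of similarity vs geographic distance
    intercept: float
    orientation: str = "similarity_vs_distance"


def distance_decay(
    community_dm: DistanceMatrix,
    geo_dm: DistanceMatrix,
    method: str = "spearman",
    n_permutations: int = 999,
    seed: int | None = 0,
    tail: str = "lower",
) -> DistanceDecayResult:
    """Distance decay of community similarity with geographic distance.

    ``community_dm`` holds dissimilarities; similarity is taken as
    ``1 - dissimilarity``.  A negative Mantel r means similarity decays with
    distance (tested on the lower tail by default); an OLS slope of
    similarity on distance is reported as a descriptive effect size.
    """
    geo_dm = geo_dm.reorder(list(community_dm.labels))
    sim_vals = 1.0 - community_dm.values
    np.fill_diagonal(sim_vals, 0.0)
    sim = squareform(sim_vals, checks=False)
    geo = geo_dm.condensed()
    if np.allclose(sim, sim[0]):
        warnings.warn("community similarity has zero variance; r undefined")
        res = MantelResult(float("nan"), float("nan"), 0, tail, method, seed,
                           orientation="similarity_vs_distance")
        return DistanceDecayResult(res, float("nan"), float("nan"))
    res = _mantel_vectors(sim, geo, list(community_dm.labels), method,
                          n_permutations, tail, seed)
    res.orientation = "similarity_vs_distance"
    slope, intercept = np.polyfit(geo, sim, 1)
    return DistanceDecayResult(res, float(slope), float(intercept))


def _mantel_vectors(a_vec, b_vec, labels, method, n_permutations, tail, seed):
    """Mantel permutation test on pre-extracted condensed vectors."""
    n = len(labels)
    if method == "spearman":
        a_vec = rankdata(a_vec)
        b_vec = rankdata(b_vec)
    sq_a = squareform(a_vec)
    r_obs = _corr(a_vec, b_vec)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_p = _corr(squareform(sq_a[np.ix_(perm, perm)], checks=False), b_vec)
        if _tail_hit(r_p, r_obs, tail):
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return MantelResult(r_obs, p, n_permutations, tail, method, seed)


# -- PCNM ----------------------------------------------------------------

@dataclass
class PcnmBasis:
    """Positive spatial eigenfunctions of a truncated distance matrix."""

    eigenvectors: np.ndarray   # sites x q, orthonormal
    eigenvalues: np.ndarray    # positive, descending
    truncation_distance: float
    labels: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCNM{i + 1}" for i in range(self.eigenvectors.shape[1])]
        return pd.DataFrame(self.eigenvectors, index=list(self.labels), columns=cols)


def pcnm(geo_dm: DistanceMatrix, rel_threshold: float = 1e-9) -> PcnmBasis:
    """Principal coordinates of neighbour matrices.

    The truncation distance ``t`` is the longest edge of the minimum
    spanning tree of the site distance matrix; distances above ``t`` are
    replaced by ``4t``, the result is Gower-centered (``-D²/2``) and
    eigen-decomposed; only eigenvectors with eigenvalue above
    ``rel_threshold`` times the largest are retained (orthonormal, ordered
    by descending eigenvalue).
    """
    n = geo_dm.n
    if n < 3:
        raise ValueError("need at least 3 sites")
    d = geo_dm.values.copy()
    off = squareform(d, checks=False)
    if np.all(off == 0):
        raise ValueError("all distances are zero")
    mst = minimum_spanning_tree(d).toarray()
    t = float(mst.max())
    d[d > t] = 4.0 * t
    np.fill_diagonal(d, 0.0)
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > rel_threshold * vals[0]
    return PcnmBasis(vecs[:, keep], vals[keep], t, geo_dm.labels)
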