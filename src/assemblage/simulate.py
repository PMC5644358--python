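"""Synthetic metacommunities with known neutral or niche structure, plus a
24-site two-habitat study-layout emulator.

Neutral local communities are drawn from the stationary law of the fitted
neutral model: per-site composition ``x ~ Dirichlet(N m p)`` (whose margins
are ``Beta(Nmp, Nm(1-p))``), then ``counts ~ Multinomial(N, x)``.  The niche
simulator reweights the regional pool by Gaussian environmental tolerance,
with a weight exponent ``w`` interpolating between pure neutral mass effects
(``w=0``) and pure environmental filtering (``w=1``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import logser

from .metadata import SampleMetadata
from .otu import OtuTable

__all__ = [
    "simulate_metacommunity",
    "simulate_neutral_communities",
    "simulate_niche_communities",
    "simulate_study_layout",
    "spatial_gradient",
    "simulate_dataset",
    "two_habitat_dataset",
    "SyntheticDataset",
]

#: printed habitat contrasts used by the study-layout emulator
HABITAT_ENV = {
    "water": {
        "temperature": (28.1, 30.2),   # uniform range, degC
        "salinity": 26.4,              # mean, psu
        "pH": 9.35,
        "TN": 0.57,                    # mg/L
        "TP": 0.018,                   # mg/L
    },
    "sediment": {
        "temperature": (31.5, 33.9),
        "salinity": 25.0,
        "pH": 7.97,
        "TN": 3.07,
        "TP": 0.112,
    },
}


def simulate_metacommunity(
    n_species: int,
    distribution: str = "lognormal",
    seed: int | None = 0,
    mu: float = 0.0,
    sigma: float = 1.0,
    theta: float = 0.999,
) -> np.ndarray:
    """Regional relative-abundance vector ``p`` (sums to 1).

    ``lognormal(mu, sigma)`` draws independent lognormal abundances
    (``sigma=0`` gives a uniform vector); ``logseries`` draws abundances
    from a log-series with shape parameter ``theta`` in (0, 1).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "lognormal":
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        vals = np.exp(mu + sigma * rng.standard_normal(n_species))
    elif distribution == "logseries":
        if not (0.0 < theta < 1.0):
            raise ValueError("logseries shape parameter must lie in (0, 1)")
        vals = logser.rvs(theta, size=n_species, random_state=rng).astype(float)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return vals / vals.sum()


def _table(counts: np.ndarray, prefix: str = "S") -> OtuTable:
    sample_ids = [f"{prefix}{i + 1}" for i in range(counts.shape[0])]
    otu_ids = [f"OTU_{j + 1}" for j in range(counts.shape[1])]
    return OtuTable(counts, sample_ids, otu_ids)


def simulate_neutral_communities(
    p: np.ndarray,
    m: float,
    N: int,
    n_sites: int,
    seed: int | None = 0,
    sample_prefix: str = "S",
) -> OtuTable:
    """Neutral local communities at the model's stationary distribution."""
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("p must sum to 1")
    if np.any(p <= 0):
        raise ValueError("p must be strictly positive")
    if not (0.0 < m):
        raise ValueError("m must be positive")
    if N < 1 or n_sites < 1:
        raise ValueError("N and n_sites must be positive")
    rng = np.random.default_rng(seed)
    alpha = N * m * p
    counts = np.empty((n_sites, p.size), dtype=np.int64)
    for i in range(n_sites):
        x = rng.dirichlet(alpha)
        # guard against numerically zeroed simplex draws at tiny alpha
        s = x.sum()
        x = x / s if s > 0 else p
        counts[i] = rng.multinomial(N, x)
    return _table(counts, sample_prefix)


def simulate_niche_communities(
    p: np.ndarray,
    env: np.ndarray,
    optima: np.ndarray,
    niche_breadth,
    w: float,
    N: int,
    seed: int | None = 0,
    sample_prefix: str = "S",
) -> OtuTable:
    """Environmentally filtered communities along a gradient.

    Per site, species weights are ``p_j * g_j(env)^w`` with Gaussian
    tolerance ``g_j = exp(-(env - optimum_j)^2 / (2 breadth_j^2))``; counts
    are multinomial at depth ``N``.  ``w=0`` reduces to sampling the
    regional pool directly.
    """
    p = np.asarray(p, dtype=float)
    env = np.asarray(env, dtype=float)
    optima = np.asarray(optima, dtype=float)
    breadth = np.broadcast_to(np.asarray(niche_breadth, dtype=float), p.shape)
    if optima.shape != p.shape:
        raise ValueError("optima must have one entry per species")
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    counts = np.empty((env.size, p.size), dtype=np.int64)
    for i, e in enumerate(env):
        log_g = -((e - optima) ** 2) / (2.0 * breadth ** 2)
        weights = p * np.exp(w * log_g)
        total = weights.sum()
        if total <= 0:
            raise ValueError(f"zero total weight at site index {i}")
        counts[i] = rng.multinomial(N, weights / total)
    return _table(counts, sample_prefix)


def spatial_gradient(
    coords: np.ndarray,
    autocorr_range_km: float,
    seed: int | None = 0,
    nugget: float = 1e-6,
) -> np.ndarray:
    """Spatially autocorrelated standard-normal field over site coordinates.

    Gaussian-kernel covariance ``exp(-d^2 / (2 range^2))``; ``coords`` is an
    (n, 2) array already in kilometre-scale units (or lon/lat for small
    extents, where degrees are near-affine in km).
    """
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    cov = np.exp(-d ** 2 / (2.0 * autocorr_range_km ** 2))
    cov[np.diag_indices_from(cov)] += nugget
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(coords.shape[0])


def simulate_ibd_communities(
    coords: np.ndarray,
    n_species: int = 100,
    N: int = 1000,
    autocorr_range: float = 10.0,
    effect: float = 1.5,
    seed: int | None = 0,
) -> OtuTable:
    """Communities whose similarity decays with distance (isolation by
    distance emulation).

    Each species' log-weight across sites is an independent spatially
    autocorrelated field scaled by ``effect``; ``autocorr_range=0`` (or
    ``effect=0``) gives spatially unstructured communities.
    """
    coords = np.asarray(coords, dtype=float)
    n_sites = coords.shape[0]
    rng = np.random.default_rng(seed)
    if autocorr_range > 0:
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        cov = np.exp(-d ** 2 / (2.0 * autocorr_range ** 2))
        cov[np.diag_indices_from(cov)] += 1e-6
        chol = np.linalg.cholesky(cov)
        fields = chol @ rng.standard_normal((n_sites, n_species))
    else:
        fields = rng.standard_normal((n_sites, n_species))
    weights = np.exp(effect * fields)
    weights /= weights.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(N, w) for w in weights])
    return _table(counts)


def simulate_study_layout(seed: int | None = 0) -> SampleMetadata:
    """24 sites around a ~10 km ring: 12 water and 12 sediment samples in 4
    stations of 3 replicates per habitat, with environmental variables drawn
    inside each habitat's printed range (uniform for temperature, small
    jitter around the habitat means otherwise)."""
    rng = np.random.default_rng(seed)
    center_lon, center_lat = 118.10, 24.48
    radius_deg = 0.045  # ~5 km
    km_per_deg = 111.195
    rows = []
    station_angles = {
        "water": np.deg2rad([0.0, 90.0, 180.0, 270.0]),
        "sediment": np.deg2rad([45.0, 135.0, 225.0, 315.0]),
    }
    station_names = {"water": ["N", "E", "S", "W"], "sediment": ["A", "B", "C", "D"]}
    for habitat in ("water", "sediment"):
        spec = HABITAT_ENV[habitat]
        for ang, st in zip(station_angles[habitat], station_names[habitat]):
            for rep in range(3):
                jitter = rng.normal(0.0, 0.3 / km_per_deg, size=2)  # ~300 m
                lon = center_lon + radius_deg * np.cos(ang) + jitter[0]
                lat = center_lat + radius_deg * np.sin(ang) + jitter[1]
                t_lo, t_hi = spec["temperature"]
                rows.append({
                    "sample_id": f"{st}{rep + 1}",
                    "habitat": habitat,
                    "longitude": lon,
                    "latitude": lat,
                    "temperature": rng.uniform(t_lo, t_hi),
                    "salinity": spec["salinity"] * (1 + rng.normal(0, 0.02)),
                    "pH": spec["pH"] + rng.normal(0, 0.05),
                    "TN": max(spec["TN"] * (1 + rng.normal(0, 0.10)), 1e-4),
                    "TP": max(spec["TP"] * (1 + rng.normal(0, 0.10)), 1e-5),
                })
    frame = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(frame)


@dataclass
class SyntheticDataset:
    """A simulated study: table + metadata + the generating truth."""

    table: OtuTable
    metadata: SampleMetadata
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        from pathlib import Path
        from .otu import write_otu_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_otu_table(self.table, outdir / "otu_table.tsv")
        self.metadata.write(outdir / "metadata.csv")
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in self.truth.items()}
        (outdir / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1))


def simulate_dataset(
    n_species: int = 2000,
    m: float = 0.1,
    N: int = 5000,
    w: float = 0.0,
    env_variable: str = "temperature",
    niche_breadth: float = 1.0,
    metadata: SampleMetadata | None = None,
    seed: int | None = 0,
    sigma: float = 2.0,
) -> SyntheticDataset:
    """Two-habitat study emulation with tunable neutral/niche balance.

    ``w=0`` draws each site from the neutral stationary law with immigration
    ``m``; ``w>0`` mixes in Gaussian environmental filtering along
    ``env_variable`` (species optima spread over the observed range).
    """
    rng = np.random.default_rng(seed)
    if metadata is None:
        metadata = simulate_study_layout(int(rng.integers(2 ** 31)))
    p = simulate_metacommunity(n_species, "lognormal", int(rng.integers(2 ** 31)),
                               sigma=sigma)
    env = metadata.frame[env_variable].to_numpy(dtype=float)
    lo, hi = env.min(), env.max()
    span = hi - lo if hi > lo else 1.0
    optima = rng.uniform(lo - 0.1 * span, hi + 0.1 * span, size=n_species)
    n_sites = len(metadata.sample_ids)
    if w == 0.0:
        table = simulate_neutral_communities(p, m, N, n_sites,
                                             int(rng.integers(2 ** 31)))
    else:
        neutral = simulate_neutral_communities(p, m, N, n_sites,
                                               int(rng.integers(2 ** 31)))
        # environmental filtering acts on the locally arriving pool
        counts = np.empty_like(neutral.counts)
        rng2 = np.random.default_rng(int(rng.integers(2 ** 31)))
        breadth = np.full(n_species, niche_breadth * span)
        for i in range(n_sites):
            local = neutral.counts[i] / N
            log_g = -((env[i] - optima) ** 2) / (2.0 * breadth ** 2)
            weights = np.where(local > 0, local * np.exp(w * log_g), 0.0)
            weights_sum = weights.sum()
            if weights_sum <= 0:
                weights, weights_sum = local, 1.0
            counts[i] = rng2.multinomial(N, weights / weights_sum)
        table = OtuTable(counts, list(neutral.sample_ids), list(neutral.otu_ids))
    table = OtuTable(table.counts, metadata.sample_ids, table.otu_ids)
    truth = {
        "p": p, "m": m, "N": N, "w": w, "Nm": N * m,
        "env_variable": env_variable, "optima": optima,
        "seed": seed, "n_species": n_species,
    }
    return SyntheticDataset(table, metadata, truth)


def two_habitat_dataset(
    n_species_per_habitat: int = 1000,
    m: float = 0.1,
    N: int = 5000,
    n_sites_per_habitat: int = 12,
    seed: int | None = 0,
) -> SyntheticDataset:
    """Two habitats with disjoint metacommunities sharing one OTU namespace.

    Water sites draw from species ``1..S``; sediment sites from species
    ``S+1..2S``.  Merging the habitats breaks the single-metacommunity
    assumption of the neutral model by construction.
    """
    if n_sites_per_habitat > 12:
        raise ValueError("the study layout has 12 sites per habitat")
    rng = np.random.default_rng(seed)
    metadata = simulate_study_layout(int(rng.integers(2 ** 31)))
    s = n_species_per_habitat
    p1 = simulate_metacommunity(s, "lognormal", int(rng.integers(2 ** 31)), sigma=2.0)
    p2 = simulate_metacommunity(s, "lognormal", int(rng.integers(2 ** 31)), sigma=2.0)
    t1 = simulate_neutral_communities(p1, m, N, n_sites_per_habitat,
                                      int(rng.integers(2 ** 31)))
    t2 = simulate_neutral_communities(p2, m, N, n_sites_per_habitat,
                                      int(rng.integers(2 ** 31)))
    counts = np.zeros((2 * n_sites_per_habitat, 2 * s), dtype=np.int64)
    counts[:n_sites_per_habitat, :s] = t1.counts
    counts[n_sites_per_habitat:, s:] = t2.counts
    water = [sid for sid, h in metadata.habitat.items()
             if h == "water"][:n_sites_per_habitat]
    sediment = [sid for sid, h in metadata.habitat.items()
                if h == "sediment"][:n_sites_per_habitat]
    sample_ids = water + sediment
    otu_ids = [f"OTU_{j + 1}" for j in range(2 * s)]
    table = OtuTable(counts, sample_ids, otu_ids)
    truth = {"m": m, "N": N, "Nm": N * m, "p_water": p1, "p_sediment": p2,
             "water_samples": water, "sediment_samples": sediment, "seed": seed}
    return SyntheticDataset(table, metadata.select(sample_ids), truth)
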