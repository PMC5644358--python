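"""Sloan-style neutral community model: occurrence frequency vs regional
mean relative abundance.

The model predicts, for an OTU at regional mean relative abundance ``p`` in
local communities of ``N`` individuals coupled to the region with
immigration ``m``, an occurrence frequency of ``1 - BetaCDF(d; Nm p,
Nm (1 - p))`` where ``d`` is the detection limit (one read, ``1/N``).  The
single free parameter ``Nm`` is fitted by least squares; goodness of fit is
a non-linear R² about the mean observed frequency and may be negative when
the data do not follow the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import beta as beta_dist

from .otu import OtuTable

__all__ = [
    "NcmInput",
    "NcmFit",
    "occurrence_frequency",
    "ncm_predict",
    "presence_probability",
    "fit_ncm",
]

LOG_NM_BOUNDS = (0.0, np.log(1e8))
WILSON_Z = 1.959963984540054  # two-sided 95%


@dataclass
class NcmInput:
    """Per-OTU regional abundance and occurrence frequency at equal depth."""

    otu_ids: list[str]
    p: np.ndarray          # mean relative abundance, sums to 1
    f_obs: np.ndarray      # fraction of samples where the OTU is present
    N: int                 # reads per sample (post-rarefaction)
    n_samples: int

    @property
    def d(self) -> float:
        return 1.0 / self.N


def occurrence_frequency(table: OtuTable) -> NcmInput:
    """Build model input from an evenly rarefied table.

    Errors if sample depths differ (rarefy first); OTUs with zero total
    count are excluded.
    """
    totals = table.sample_totals()
    if len(set(totals.tolist())) != 1:
        raise ValueError(
            "sample depths are unequal; rarefy to a common depth before "
            "fitting the neutral model"
        )
    n = int(totals[0])
    if n == 0:
        raise ValueError("empty samples")
    keep = table.otu_totals() > 0
    counts = table.counts[:, keep]
    otu_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    p = counts.mean(axis=0) / n
    f_obs = (counts > 0).mean(axis=0)
    return NcmInput(otu_ids, p, f_obs, n, table.n_samples)


def ncm_predict(p, Nm: float, d: float):
    """Predicted occurrence frequency ``1 - BetaCDF(d; Nm p, Nm (1 - p))``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie in (0, 1)")
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not (0.0 < d < 1.0):
        raise ValueError("detection limit must lie in (0, 1)")
    out = beta_dist.sf(d, Nm * p, Nm * (1.0 - p))
    return float(out) if out.ndim == 0 else out


def presence_probability(p, Nm: float, N: int):
    """Exact detection probability under the stationary generative model.

    With local composition ``x ~ Beta(Nm p, Nm (1 - p))`` and counts drawn
    multinomially at depth ``N``, an OTU is detected with probability
    ``1 - E[(1 - x)^N] = 1 - B(a, b + N) / B(a, b)``.  :func:`ncm_predict`
    is the Sloan threshold approximation ``P(x > 1/N)`` of this quantity.
    """
    p = np.asarray(p, dtype=float)
    a = Nm * p
    b = Nm * (1.0 - p)
    log_e = gammaln(b + N) + gammaln(a + b) - gammaln(a + b + N) - gammaln(b)
    out = 1.0 - np.exp(log_e)
    return float(out) if out.ndim == 0 else out


@dataclass
class NcmFit:
    Nm: float
    m: float
    N: int
    d: float
    r2: float
    n_otus: int
    n_samples: int
    per_otu: pd.DataFrame   # otu_id, p, f_obs, f_pred, ci_low, ci_high, partition
    at_bound: bool = False

    def partition_counts(self) -> dict[str, int]:
        vc = self.per_otu["partition"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("above", "neutral", "below")}

    def summary(self) -> dict:
        out = {
            "Nm": self.Nm, "m": self.m, "N": self.N, "d": self.d,
            "r2": self.r2, "n_otus": self.n_otus, "n_samples": self.n_samples,
            "at_bound": self.at_bound,
        }
        out.update({f"n_{k}": v for k, v in self.partition_counts().items()})
        return out


def _wilson_interval(phat: np.ndarray, n: int, z: float = WILSON_Z):
    denom = 1.0 + z ** 2 / n
    center = (phat + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


def fit_ncm(inp: NcmInput, grid_size: int = 200) -> NcmFit:
    """Least-squares fit of ``Nm`` on a log grid refined by bounded scalar
    optimization; deterministic.

    The 95% bands are Wilson binomial intervals of the predicted frequency
    at ``n_samples`` trials; OTUs are partitioned as above/neutral/below the
    bands.
    """
    if len(inp.otu_ids) < 10:
        raise ValueError("need at least 10 OTUs to fit the model")
    p = np.clip(inp.p, 1e-300, 1.0 - 1e-12)
    f_obs = np.asarray(inp.f_obs, dtype=float)
    d = inp.d

    def sse(log_nm: float) -> float:
        pred = beta_dist.sf(d, np.exp(log_nm) * p, np.exp(log_nm) * (1.0 - p))
        return float(((f_obs - pred) ** 2).sum())

    grid = np.linspace(LOG_NM_BOUNDS[0], LOG_NM_BOUNDS[1], grid_size)
    grid_sse = np.array([sse(g) for g in grid])
    k = int(np.argmin(grid_sse))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_size - 1)]
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    best_log = res.x if res.fun <= grid_sse[k] else grid[k]
    nm = float(np.exp(best_log))
    at_bound = bool(best_log <= LOG_NM_BOUNDS[0] + 1e-6
                    or best_log >= LOG_NM_BOUNDS[1] - 1e-6)
    if at_bound:
        warnings.warn(f"Nm optimizer at bound (Nm={nm:.3g})")
    f_pred = beta_dist.sf(d, nm * p, nm * (1.0 - p))
    sse_best = float(((f_obs - f_pred) ** 2).sum())
    ss_tot = float(((f_obs - f_obs.mean()) ** 2).sum())
    r2 = 1.0 - sse_best / ss_tot if ss_tot > 0 else float("nan")
    ci_low, ci_high = _wilson_interval(f_pred, inp.n_samples)
    partition = np.where(f_obs > ci_high, "above",
                         np.where(f_obs < ci_low, "below", "neutral"))
    per_otu = pd.DataFrame({
        "otu_id": inp.otu_ids,
        "p": inp.p,
        "f_obs": f_obs,
        "f_pred": f_pred,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "partition": partition,
    })
    return NcmFit(nm, nm / inp.N, inp.N, d, r2, len(inp.otu_ids),
                  inp.n_samples, per_otu, at_bound)
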