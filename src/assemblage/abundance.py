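"""Abundance-category classification of OTUs and rarity-cutoff robustness.

OTUs are assigned to six categories by their per-sample relative abundance
against a rare threshold (default 0.01%) and an abundant threshold (default
1%): abundant (AT), rare (RT), moderate (MT), conditionally rare (CRT),
conditionally abundant (CAT) and conditionally rare-and-abundant (CRAT).
Absence (count 0) is treated as below the rare threshold.

The truncation analysis (``multicola``) measures how much the multivariate
structure of the data set depends on its rarest OTU types: it removes an
increasing fraction of the rarest types and correlates the truncated
Bray-Curtis matrix with the original one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _procrustes
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .otu import OtuTable

__all__ = [
    "CATEGORIES",
    "CategoryAssignment",
    "relative_abundance",
    "classify_otus",
    "combine_dominant",
    "multicola",
    "DEFAULT_FRACTIONS",
]

CATEGORIES = ("AT", "RT", "MT", "CRT", "CAT", "CRAT")

#: default truncation grid, 0 to 0.9 in steps of 0.05
DEFAULT_FRACTIONS = tuple(round(0.05 * i, 2) for i in range(19))


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances (rows sum to 1)."""
    totals = table.sample_totals()
    empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if empty:
        raise ValueError(f"empty samples: {empty}")
    rel = table.counts / totals[:, None]
    return pd.DataFrame(rel, index=list(table.sample_ids), columns=list(table.otu_ids))


@dataclass
class CategoryAssignment:
    """Mapping of each OTU to exactly one abundance category."""

    labels: pd.Series  # otu_id -> category
    rare_thresh: float
    abund_thresh: float

    def counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {cat: int(vc.get(cat, 0)) for cat in CATEGORIES}

    def otus_in(self, *categories: str) -> list[str]:
        mask = self.labels.isin(categories)
        return self.labels.index[mask].tolist()

    def write(self, path) -> None:
        out = self.labels.rename("category").to_frame()
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")


def classify_otus(
    table: OtuTable,
    rare_thresh: float = 1e-4,
    abund_thresh: float = 1e-2,
) -> CategoryAssignment:
    """Assign every OTU to one of the six abundance categories.

    Decision rules on each OTU's per-sample relative abundance:

    * AT   — >= ``abund_thresh`` in all samples
    * RT   — <  ``rare_thresh`` in all samples
    * MT   — in ``[rare_thresh, abund_thresh)`` in all samples
    * CAT  — >= ``rare_thresh`` in all samples and >= ``abund_thresh`` in
      some (but not all)
    * CRT  — < ``abund_thresh`` in all samples and < ``rare_thresh`` in some
      (but not all)
    * CRAT — < ``rare_thresh`` in some samples and >= ``abund_thresh`` in
      others
    """
    if not (0.0 < rare_thresh < abund_thresh <= 1.0):
        raise ValueError(
            f"need 0 < rare_thresh < abund_thresh <= 1, got "
            f"{rare_thresh} / {abund_thresh}"
        )
    rel = relative_abundance(table).to_numpy()
    lo = rel.min(axis=0)
    hi = rel.max(axis=0)
    labels = np.empty(table.n_otus, dtype=object)
    at = lo >= abund_thresh
    rt = hi < rare_thresh
    mt = (lo >= rare_thresh) & (hi < abund_thresh)
    cat = (lo >= rare_thresh) & (hi >= abund_thresh) & ~at
    crt = (hi < abund_thresh) & (lo < rare_thresh) & ~rt
    crat = (lo < rare_thresh) & (hi >= abund_thresh)
    for mask, name in ((at, "AT"), (rt, "RT"), (mt, "MT"),
                       (cat, "CAT"), (crt, "CRT"), (crat, "CRAT")):
        labels[mask] = name
    assert not (labels == None).any()  # noqa: E711 — six predicates partition
    series = pd.Series(labels, index=pd.Index(table.otu_ids, name="otu_id"))
    return CategoryAssignment(series, rare_thresh, abund_thresh)


def combine_dominant(assignment: CategoryAssignment) -> list[str]:
    """The dominant-taxa set: union of AT, CAT and CRAT."""
    return assignment.otus_in("AT", "CAT", "CRAT")


# -- truncation robustness ------------------------------------------------

@dataclass
class MulticolaProfile:
    """Structure-correlation profile across rarity truncation levels."""

    table: pd.DataFrame  # columns: fraction, n_removed, spearman[, procrustes_m2]
    comparator: str
    direction: str
    flagged: list[float] = field(default_factory=list)  # fractions with empty samples

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _rank_otus(table: OtuTable, direction: str) -> np.ndarray:
    """Column order for truncation: rarest-first (ties broken by OTU id)."""
    totals = table.otu_totals()
    order = sorted(range(table.n_otus), key=lambda j: (totals[j], table.otu_ids[j]))
    if direction == "remove_abundant":
        order = order[::-1]
    return np.asarray(order)


def _nmds_coords(values: np.ndarray, seed: int) -> np.ndarray:
    from .beta import nmds  # local import to avoid cycle at module load
    from .distance import DistanceMatrix

    dm = DistanceMatrix(values, [str(i) for i in range(values.shape[0])])
    return nmds(dm, k=2, n_restarts=8, seed=seed).coordinates


def multicola(
    table: OtuTable,
    fractions=DEFAULT_FRACTIONS,
    comparator: str = "matrix_spearman",
    seed: int = 0,
    direction: str = "remove_rare",
) -> MulticolaProfile:
    """Correlate the Bray-Curtis structure of rarity-truncated tables with
    the full table across a grid of truncation fractions.

    For each fraction ``f`` the ``ceil(f * n_otus)`` rarest OTU types (by
    total count, ties broken by id) are removed.  ``comparator`` is either
    ``matrix_spearman`` (Spearman correlation of the off-diagonal entries of
    the two Bray-Curtis matrices) or ``procrustes`` (both Spearman and the
    Procrustes m² between 2-D NMDS ordinations).  Truncations that empty a
    sample are reported as NaN and flagged, never silently skipped.
    """
    fractions = sorted(float(f) for f in fractions)
    if any(f < 0 or f >= 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1)")
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if comparator not in ("matrix_spearman", "procrustes"):
        raise ValueError(f"unknown comparator {comparator!r}")
    if direction not in ("remove_rare", "remove_abundant"):
        raise ValueError(f"unknown direction {direction!r}")

    order = _rank_otus(table, direction)
    base_bc = pdist(table.counts.astype(float), metric="braycurtis")
    base_coords = None
    rows = []
    flagged: list[float] = []
    for f in fractions:
        n_removed = math.ceil(f * table.n_otus)
        keep = np.sort(order[n_removed:])
        sub = table.counts[:, keep].astype(float)
        row: dict = {"fraction": f, "n_removed": n_removed}
        if sub.shape[1] == 0 or (sub.sum(axis=1) == 0).any():
            row["spearman"] = np.nan
            if comparator == "procrustes":
                row["procrustes_m2"] = np.nan
            flagged.append(f)
            rows.append(row)
            continue
        trunc_bc = pdist(sub, metric="braycurtis")
        if np.allclose(trunc_bc, base_bc):
            rho = 1.0  # removed OTUs carried no signal (e.g. all-zero types)
        else:
            rho = float(spearmanr(base_bc, trunc_bc).statistic)
        row["spearman"] = rho
        if comparator == "procrustes":
            if base_coords is None:
                from scipy.spatial.distance import squareform
                base_coords = _nmds_coords(squareform(base_bc), seed)
            from scipy.spatial.distance import squareform
            trunc_coords = _nmds_coords(squareform(trunc_bc), seed)
            _, _, m2 = _procrustes(base_coords, trunc_coords)
            row["procrustes_m2"] = float(m2)
        rows.append(row)
    return MulticolaProfile(pd.DataFrame(rows), comparator, direction, flagged)
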