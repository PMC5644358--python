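"""OTU count tables: TSV I/O, rarefaction, alpha diversity and rarefaction curves.

The on-disk dialect is a tab-separated table with samples in rows (header row
of OTU ids, first column of sample ids).  The transposed, QIIME-classic style
layout (OTUs in rows, optional trailing ``taxonomy`` column) is accepted via
``orientation="otus"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "read_otu_table",
    "write_otu_table",
    "rarefy",
    "alpha_diversity",
    "rarefaction_curve",
    "shared_otu_counts",
    "aggregate_taxonomy",
]


@dataclass
class OtuTable:
    """Integer count matrix of samples x OTUs with identifiers.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_samples, n_otus)``.
    sample_ids, otu_ids
        Unique identifiers for rows and columns.
    taxonomy
        Optional lineage string per OTU (semicolon-delimited ranks).
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x OTUs)")
        if counts.dtype.kind == "f":
            if not np.all(counts == np.floor(counts)):
                bad = np.argwhere(counts != np.floor(counts))[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        elif counts.dtype.kind not in "iu":
            raise ValueError(f"counts must be integer, got dtype {counts.dtype}")
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        self.counts = counts
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if len(self.sample_ids) != counts.shape[0]:
            raise ValueError("sample_ids length does not match counts rows")
        if len(self.otu_ids) != counts.shape[1]:
            raise ValueError("otu_ids length does not match counts columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU identifiers")
        if self.taxonomy is not None and len(self.taxonomy) != counts.shape[1]:
            raise ValueError("taxonomy length does not match number of OTUs")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    # -- subsetting ------------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        rows = [idx[s] for s in sample_ids]
        return OtuTable(self.counts[rows], list(sample_ids), list(self.otu_ids),
                        None if self.taxonomy is None else list(self.taxonomy))

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        missing = [o for o in otu_ids if o not in idx]
        if missing:
            raise KeyError(f"unknown OTUs: {missing[:5]}")
        cols = [idx[o] for o in otu_ids]
        tax = None if self.taxonomy is None else [self.taxonomy[c] for c in cols]
        return OtuTable(self.counts[:, cols], list(self.sample_ids), list(otu_ids), tax)

    def drop_empty_otus(self) -> "OtuTable":
        """Drop OTUs with zero total count, logging how many were removed."""
        keep = self.otu_totals() > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d OTUs with zero total count", n_dropped)
        tax = None if self.taxonomy is None else [t for t, k in zip(self.taxonomy, keep) if k]
        return OtuTable(self.counts[:, keep],
                        list(self.sample_ids),
                        [o for o, k in zip(self.otu_ids, keep) if k],
                        tax)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.otu_ids == other.otu_ids
                and np.array_equal(self.counts, other.counts)
                and self.taxonomy == other.taxonomy)


# -- I/O -----------------------------------------------------------------

def read_otu_table(path, orientation: str = "samples") -> OtuTable:
    """Read a tab-separated OTU table.

    ``orientation="samples"``: samples in rows, OTU ids in the header.
    ``orientation="otus"``: OTUs in rows (QIIME-classic), sample ids in the
    header, optional trailing ``taxonomy`` column.
    """
    if orientation not in ("samples", "otus"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate identifiers in {path}")
    taxonomy = None
    if orientation == "otus":
        if df.columns[-1].lower() == "taxonomy":
            taxonomy = df.iloc[:, -1].fillna("").tolist()
            df = df.iloc[:, :-1]
        df = df.T
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        try:
            vals = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in column {col!r} of {path}") from exc
        if not np.all(vals == np.floor(vals)):
            row = df.index[np.flatnonzero(vals != np.floor(vals))[0]]
            raise ValueError(f"non-integer count at row {row!r}, column {col!r} of {path}")
        counts[:, j] = vals.astype(np.int64)
    table = OtuTable(counts, df.index.tolist(), df.columns.tolist(), taxonomy)
    logger.info("read OTU table: %d samples, %d OTUs, %d reads",
                table.n_samples, table.n_otus, int(table.counts.sum()))
    return table


def write_otu_table(table: OtuTable, path, orientation: str = "samples") -> None:
    """Write a table in the dialect :func:`read_otu_table` accepts."""
    if orientation not in ("samples", "otus"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = table.to_frame()
    if orientation == "samples":
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
    else:
        out = df.T
        out.index.name = "otu_id"
        if table.taxonomy is not None:
            out = out.assign(taxonomy=table.taxonomy)
        out.to_csv(path, sep="\t")


# -- rarefaction ---------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples shallower than ``depth`` are an error; the caller must drop them
    explicitly before rarefying.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    totals = table.sample_totals()
    shallow = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if shallow:
        raise ValueError(
            f"samples shallower than depth {depth}: {shallow} — drop them "
            "explicitly before rarefying"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        if totals[i] == depth:
            out[i] = table.counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return OtuTable(out, list(table.sample_ids), list(table.otu_ids),
                    None if table.taxonomy is None else list(table.taxonomy))


# -- alpha diversity -----------------------------------------------------

def _chao1(counts: np.ndarray) -> float:
    # bias-corrected form: well-defined at F2 = 0
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _ace(counts: np.ndarray, rare_cutoff: int = 10) -> float:
    present = counts[counts > 0]
    rare = present[present <= rare_cutoff]
    s_abund = int((present > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return float("nan")  # all rare taxa are singletons; estimator undefined
    freqs = np.bincount(rare, minlength=rare_cutoff + 1)
    i = np.arange(rare_cutoff + 1)
    sum_iif = float((i * (i - 1) * freqs).sum())
    gamma2 = max(s_rare / c_ace * sum_iif / (n_rare * (n_rare - 1.0)) - 1.0, 0.0) \
        if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample alpha diversity.

    Columns: ``s_obs``, ``chao1``, ``ace``, ``shannon`` (nats), ``pielou``,
    ``simpson_1_minus_d``, ``goods_coverage``.  Pielou evenness is reported
    as missing for single-OTU samples.
    """
    totals = table.sample_totals()
    empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if empty:
        raise ValueError(f"empty samples: {empty}")
    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        n = totals[i]
        present = c[c > 0]
        s_obs = present.size
        p = present / n
        shannon = float(-(p * np.log(p)).sum())
        pielou = shannon / np.log(s_obs) if s_obs > 1 else np.nan
        simpson = float(1.0 - (p ** 2).sum())
        f1 = int((c == 1).sum())
        rows.append({
            "s_obs": s_obs,
            "chao1": _chao1(c),
            "ace": _ace(c),
            "shannon": shannon,
            "pielou": pielou,
            "simpson_1_minus_d": simpson,
            "goods_coverage": 1.0 - f1 / n,
        })
    return pd.DataFrame(rows, index=list(table.sample_ids))


def rarefaction_curve(
    table: OtuTable,
    depths: Iterable[int],
    mode: str = "analytic",
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected richness per (sample, depth).

    Analytic mode evaluates the hypergeometric expectation
    ``E[S(d)] = sum_j (1 - C(N - c_j, d) / C(N, d))`` exactly; Monte-Carlo
    mode averages observed richness over ``reps`` rarefactions.
    """
    depths = [int(d) for d in depths]
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    if sorted(depths) != depths:
        raise ValueError("depths must be increasing")
    totals = table.sample_totals()
    too_deep = [(s, d) for s, t in zip(table.sample_ids, totals)
                for d in depths if d > t]
    if too_deep:
        raise ValueError(f"depth exceeds sample total for: {too_deep[:5]}")
    out = np.empty((len(depths), table.n_samples))
    if mode == "analytic":
        for i in range(table.n_samples):
            c = table.counts[i]
            c = c[c > 0]
            n = totals[i]
            for k, d in enumerate(depths):
                # log C(N-c, d) - log C(N, d), zero probability when N-c < d
                nc = n - c
                ok = nc >= d
                logp = np.full(c.shape, -np.inf)
                logp[ok] = (
                    gammaln(nc[ok] + 1) - gammaln(d + 1) - gammaln(nc[ok] - d + 1)
                    - (gammaln(n + 1) - gammaln(d + 1) - gammaln(n - d + 1))
                )
                out[k, i] = float((1.0 - np.exp(logp)).sum())
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        for i in range(table.n_samples):
            c = table.counts[i]
            for k, d in enumerate(depths):
                rich = [
                    int((rng.multivariate_hypergeometric(c, d) > 0).sum())
                    for _ in range(reps)
                ]
                out[k, i] = float(np.mean(rich))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(out, index=depths, columns=list(table.sample_ids))


# -- presence bookkeeping ------------------------------------------------

def shared_otu_counts(table: OtuTable, grouping: Mapping[str, str]) -> dict:
    """Venn-style membership counts of OTUs across sample groups.

    ``grouping`` maps sample id -> group label.  Returns per-group unique
    counts, the count shared by all groups, and counts per group combination.
    """
    unknown = [s for s in grouping if s not in table.sample_ids]
    if unknown:
        raise KeyError(f"unknown samples in grouping: {unknown}")
    groups = sorted(set(grouping.values()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sample_idx = {s: i for i, s in enumerate(table.sample_ids)}
    presence = {}
    for g in groups:
        rows = [sample_idx[s] for s, lab in grouping.items() if lab == g]
        presence[g] = table.counts[rows].sum(axis=0) > 0
    membership: dict[tuple[str, ...], int] = {}
    any_present = np.zeros(table.n_otus, dtype=bool)
    for g in groups:
        any_present |= presence[g]
    stack = np.vstack([presence[g] for g in groups])
    for j in np.flatnonzero(any_present):
        combo = tuple(g for gi, g in enumerate(groups) if stack[gi, j])
        membership[combo] = membership.get(combo, 0) + 1
    unique = {g: membership.get((g,), 0) for g in groups}
    return {
        "groups": groups,
        "unique": unique,
        "shared_all": membership.get(tuple(groups), 0),
        "combinations": membership,
        "total": int(any_present.sum()),
    }


def aggregate_taxonomy(table: OtuTable, rank: int) -> dict[str, pd.DataFrame]:
    """Per-sample sequence-abundance and OTU-richness shares at a lineage rank.

    Lineages are semicolon-delimited; lineages shallower than ``rank`` (or
    missing entirely) are binned as ``"unclassified"``.  Returns
    ``{"abundance": DataFrame, "richness": DataFrame}`` (groups x samples),
    each column summing to 1.
    """
    if table.taxonomy is None:
        logger.warning("no taxonomy present; all OTUs binned as 'unclassified'")
        labels = ["unclassified"] * table.n_otus
    else:
        labels = []
        for lineage in table.taxonomy:
            parts = [p.strip() for p in str(lineage).split(";") if p.strip()]
            labels.append(parts[rank] if rank < len(parts) else "unclassified")
    groups = sorted(set(labels))
    gidx = {g: k for k, g in enumerate(groups)}
    abund = np.zeros((len(groups), table.n_samples))
    rich = np.zeros((len(groups), table.n_samples))
    for j, lab in enumerate(labels):
        abund[gidx[lab]] += table.counts[:, j]
        rich[gidx[lab]] += table.counts[:, j] > 0
    totals = table.sample_totals().astype(float)
    s_obs = (table.counts > 0).sum(axis=1).astype(float)
    return {
        "abundance": pd.DataFrame(abund / totals, index=groups,
                                  columns=list(table.sample_ids)),
        "richness": pd.DataFrame(rich / s_obs, index=groups,
                                 columns=list(table.sample_ids)),
    }
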