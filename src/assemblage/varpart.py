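"""Redundancy analysis, VIF filtering, forward selection and two-component
variation partitioning with permutation tests.

All explained-variance fractions are Ezekiel-adjusted R²:
``adjR2 = 1 - (1 - R2) (n - 1) / (n - p - 1)``.  Permutation tests permute
rows of the (possibly residualized) response freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "rda",
    "adjusted_r2",
    "vif_filter",
    "forward_select",
    "varpart2",
    "RdaResult",
    "VifReport",
    "ForwardSelectionResult",
    "VarpartResult",
]


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def _proj_basis(xc: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of centered X."""
    q, r = np.linalg.qr(xc)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _r2_from_basis(q: np.ndarray, yc: np.ndarray, ss_total: float) -> float:
    if ss_total == 0.0:
        return 0.0
    return float(((q.T @ yc) ** 2).sum()) / ss_total


def _r2(yc: np.ndarray, xc: np.ndarray, ss_total: float | None = None) -> float:
    """Fraction of total variance of centered Y captured by projection on
    the column space of centered X."""
    if ss_total is None:
        ss_total = float((yc ** 2).sum())
    return _r2_from_basis(_proj_basis(xc), yc, ss_total)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment; may be negative."""
    if n - p - 1 <= 0:
        raise ValueError(f"too few samples (n={n}) for {p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(_center(x))
    if rank < x.shape[1]:
        # identify offending columns via QR pivoting on the correlation
        q, r = np.linalg.qr(_center(x))
        diag = np.abs(np.diag(r))
        bad = [names[j] for j in range(x.shape[1])
               if diag[j] <= 1e-10 * max(1.0, diag.max())]
        raise ValueError(f"predictor matrix is rank deficient; collinear columns: {bad}")


@dataclass
class RdaResult:
    r2: float
    adj_r2: float
    n: int
    p: int
    p_value: float | None
    n_permutations: int
    seed: int | None


def rda(
    Y,
    X,
    n_permutations: int = 999,
    seed: int | None = 0,
    permute: bool = True,
) -> RdaResult:
    """Redundancy analysis of (Hellinger-transformed) community data on a
    predictor matrix; R² from the multivariate least-squares projection."""
    y = _as_matrix(Y)
    x = _as_matrix(X)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(x.shape[1])]
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError("Y and X have different numbers of rows")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    _check_rank(x, names)
    yc = _center(y)
    q = _proj_basis(_center(x))
    ss = float((yc ** 2).sum())
    r2 = _r2_from_basis(q, yc, ss)
    adj = adjusted_r2(r2, n, p)
    p_value = None
    if permute and n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if _r2_from_basis(q, yc[perm], ss) >= r2 - 1e-12:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)
    return RdaResult(r2, adj, n, p, p_value, n_permutations if permute else 0, seed)


@dataclass
class VifReport:
    removed: list[str]          # in removal order
    vifs: dict[str, float]      # final VIFs of retained variables
    threshold: float


def _vif_values(x: np.ndarray) -> np.ndarray:
    n, p = x.shape
    out = np.empty(p)
    for j in range(p):
        others = np.delete(x, j, axis=1)
        xc = _center(others)
        yj = _center(x[:, [j]])
        ss = float((yj ** 2).sum())
        if ss == 0.0:
            out[j] = 1.0
            continue
        r2 = _r2(yj, xc, ss)
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(X: pd.DataFrame, threshold: float = 10.0) -> tuple[pd.DataFrame, VifReport]:
    """Iteratively drop the highest-VIF predictor until all VIF <= threshold.

    Ties are broken by column order (the earlier column is kept).
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one predictor")
    cols = list(X.columns)
    removed: list[str] = []
    while len(cols) > 1:
        vifs = _vif_values(X[cols].to_numpy(dtype=float))
        worst = int(np.argmax(vifs))
        # argmax takes the first maximum -> drop the LATER of tied duplicates
        tied = np.flatnonzero(np.isclose(vifs, vifs[worst], rtol=1e-9) | (np.isinf(vifs) & np.isinf(vifs[worst])))
        worst = int(tied[-1])
        if vifs[worst] <= threshold:
            break
        removed.append(cols.pop(worst))
    final = _vif_values(X[cols].to_numpy(dtype=float)) if len(cols) > 1 else np.array([1.0])
    report = VifReport(removed, {c: float(v) for c, v in zip(cols, final)}, threshold)
    return X[cols], report


@dataclass
class ForwardSelectionResult:
    selected: list[str]
    steps: list[dict] = field(default_factory=list)  # per-step adjR2 and p
    stopping_reason: str = "exhausted"
    global_adj_r2: float = float("nan")
    global_p: float | None = None

    @property
    def adj_r2(self) -> float:
        return self.steps[-1]["adj_r2"] if self.steps else 0.0


def forward_select(
    Y,
    X: pd.DataFrame,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> ForwardSelectionResult:
    """Forward selection of predictors with the two Blanchet stopping rules.

    The global model must pass a permutation test at ``alpha`` first; at each
    step the candidate maximizing the model adjR² is added if its partial
    contribution is significant at ``alpha`` AND the cumulative adjR² does
    not exceed the global model's adjR².
    """
    y = _as_matrix(Y)
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    global_fit = rda(Y, X, n_permutations=n_permutations,
                     seed=None if seed is None else int(rng.integers(2 ** 31)))
    result = ForwardSelectionResult([], [], "exhausted",
                                    global_fit.adj_r2, global_fit.p_value)
    if global_fit.p_value is not None and global_fit.p_value > alpha:
        result.stopping_reason = "global_pretest_failed"
        return result
    yc = _center(y)
    remaining = list(X.columns)
    selected: list[str] = []
    r2_selected = 0.0
    while remaining:
        best = None
        for cand in remaining:
            cols = selected + [cand]
            xc = _center(X[cols].to_numpy(dtype=float))
            r2 = _r2(yc, xc)
            adj = adjusted_r2(r2, n, len(cols))
            if best is None or adj > best[2]:
                best = (cand, r2, adj)
        cand, r2_cand, adj_cand = best
        if adj_cand > global_fit.adj_r2 + 1e-12:
            result.stopping_reason = "global_adjR2"
            break
        # permutation test of the partial contribution of `cand`
        q_full = _proj_basis(_center(X[selected + [cand]].to_numpy(dtype=float)))
        stat = r2_cand - r2_selected
        q_sel = _proj_basis(_center(X[selected].to_numpy(dtype=float))) if selected else None
        ss = float((yc ** 2).sum())
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            yp = yc[perm]
            r2_full_p = _r2_from_basis(q_full, yp, ss)
            r2_sel_p = _r2_from_basis(q_sel, yp, ss) if q_sel is not None else 0.0
            if r2_full_p - r2_sel_p >= stat - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
        if p > alpha:
            result.stopping_reason = "alpha"
            break
        selected.append(cand)
        remaining.remove(cand)
        r2_selected = r2_cand
        result.steps.append({"variable": cand, "r2": r2_cand,
                             "adj_r2": adj_cand, "p": p})
    result.selected = selected
    if not remaining and result.stopping_reason not in ("alpha", "global_adjR2"):
        result.stopping_reason = "exhausted"
    return result


@dataclass
class VarpartResult:
    """Adjusted-R² decomposition [pure env | shared | pure spatial | residual].

    The shared fraction is not independently testable and carries no p-value.
    Negative fractions are reported as-is, never clamped.
    """

    pure_env: float
    shared: float
    pure_spatial: float
    residual: float
    p_pure_env: float | None
    p_pure_spatial: float | None
    p_env_marginal: float | None
    p_spatial_marginal: float | None
    adj_env: float          # ab: adjR2 of Y ~ X_env
    adj_spatial: float      # bc: adjR2 of Y ~ X_spat
    adj_full: float         # abc
    n: int
    seed: int | None

    def fractions(self) -> dict[str, float]:
        return {"pure_env": self.pure_env, "shared": self.shared,
                "pure_spatial": self.pure_spatial, "residual": self.residual}

    def to_dict(self) -> dict:
        out = self.fractions()
        out.update({
            "p_pure_env": self.p_pure_env,
            "p_pure_spatial": self.p_pure_spatial,
            "p_env_marginal": self.p_env_marginal,
            "p_spatial_marginal": self.p_spatial_marginal,
            "adj_env": self.adj_env, "adj_spatial": self.adj_spatial,
            "adj_full": self.adj_full, "n": self.n,
        })
        return out

    def to_table(self) -> pd.DataFrame:
        rows = [
            ("Environment", self.pure_env, self.p_pure_env),
            ("Spatial", self.pure_spatial, self.p_pure_spatial),
            ("Shared", self.shared, None),
            ("Residual", self.residual, None),
        ]
        return pd.DataFrame(rows, columns=["component", "adj_r2", "p"])


def _residualize(y: np.ndarray, xc: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(xc)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return y - q @ (q.T @ y)


def _partial_perm_p(yc, x_test, x_cond, n_permutations, rng) -> float:
    """Permutation p for the partial effect of x_test given x_cond, by
    residualizing response and test predictors on the conditioning set."""
    y_res = _residualize(yc, x_cond)
    x_res = _residualize(x_test, x_cond)
    ss = float((y_res ** 2).sum())
    q = _proj_basis(x_res)
    stat = _r2_from_basis(q, y_res, ss)
    hits = 0
    n = yc.shape[0]
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = y_res[perm]
        if _r2_from_basis(q, yp, float((yp ** 2).sum())) >= stat - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def varpart2(
    Y,
    X_env: pd.DataFrame,
    X_spat: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> VarpartResult:
    """Two-component variation partitioning of Y between environmental and
    spatial predictor sets.

    ``a = abc - bc`` (pure env), ``c = abc - ab`` (pure spatial),
    ``b = ab + bc - abc`` (shared), ``d = 1 - abc`` (residual), all on the
    adjusted-R² scale; p-values for the pure fractions come from partial
    RDAs residualized on the other set.
    """
    y = _as_matrix(Y)
    n = y.shape[0]
    if X_env.shape[1] == 0 or X_spat.shape[1] == 0:
        raise ValueError("both predictor sets must be non-empty")
    xe = X_env.to_numpy(dtype=float)
    xs = X_spat.to_numpy(dtype=float)
    both = np.hstack([xe, xs])
    names = list(X_env.columns) + list(X_spat.columns)
    # shared columns between the two sets are legitimate; only check the
    # combined rank when the sets are disjoint as variable lists
    if len(set(names)) == len(names):
        _check_rank(both, names)
    rng = np.random.default_rng(seed)
    sub = None if seed is None else int(rng.integers(2 ** 31))
    fit_env = rda(Y, X_env, n_permutations=n_permutations, seed=sub)
    sub = None if seed is None else int(rng.integers(2 ** 31))
    fit_spat = rda(Y, X_spat, n_permutations=n_permutations, seed=sub)
    yc = _center(y)
    xc_both = _center(both)
    q, r = np.linalg.qr(xc_both)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    rank_both = int(keep.sum())
    r2_full = _r2(yc, xc_both)
    adj_full = adjusted_r2(r2_full, n, rank_both)
    ab, bc = fit_env.adj_r2, fit_spat.adj_r2
    a = adj_full - bc
    c = adj_full - ab
    b = ab + bc - adj_full
    d = 1.0 - adj_full
    xce = _center(xe)
    xcs = _center(xs)
    p_a = _partial_perm_p(yc, xce, xcs, n_permutations, rng)
    p_c = _partial_perm_p(yc, xcs, xce, n_permutations, rng)
    return VarpartResult(
        pure_env=a, shared=b, pure_spatial=c, residual=d,
        p_pure_env=p_a, p_pure_spatial=p_c,
        p_env_marginal=fit_env.p_value, p_spatial_marginal=fit_spat.p_value,
        adj_env=ab, adj_spatial=bc, adj_full=adj_full, n=n, seed=seed,
    )
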