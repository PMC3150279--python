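"""Distance-based redundancy analysis with permutation inference.

Regression of a genetic distance matrix on sets of environmental
predictors: the distance matrix is Gower-centred, predictor sets are fitted
by projection (McArdle-Anderson direct approach, no eigen-decomposition or
correction of negative eigenvalues), and significance comes from
simultaneous permutation of the rows and columns of the distance matrix
(marginal tests) or of the residual matrix under the reduced model
(sequential forward selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PredictorTable", "DbrdaResult", "gower_center", "marginal_test",
    "forward_selection",
]


@dataclass
class PredictorTable:
    """Per-location predictor variables grouped into named sets.

    ``data`` has one row per location; ``sets`` maps a set name (e.g.
    ``"subregion"``) to its column list.  Binary one-hot sets must row-sum
    to 1 within the set.
    """

    data: pd.DataFrame
    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, cols in self.sets.items():
            missing = [c for c in cols if c not in self.data.columns]
            if missing:
                raise ValueError(f"set {name!r} references missing columns {missing}")
        if self.data.isna().any().any():
            raise ValueError("predictor table contains missing values")

    def matrix(self, set_name: str) -> np.ndarray:
        return self.data[self.sets[set_name]].to_numpy(dtype=float)


@dataclass
class DbrdaResult:
    marginal: pd.DataFrame                       # set, pseudo_F, P, pct_var
    selection: pd.DataFrame | None = None        # forward-selection path
    set_correlations: pd.DataFrame | None = None


def gower_center(D: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 J D^2 J.

    ``D`` is a symmetric distance matrix with zero diagonal; J is the
    centring projector I - 11'/n.  Row sums of G are zero, and for
    Euclidean D, G is the centred Gram matrix of the underlying points.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat_matrix(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of centred X; returns rank."""
    Xc = X - X.mean(axis=0)
    q, r = np.linalg.qr(Xc)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def _pseudo_f(G: np.ndarray, H: np.ndarray, m: int) -> tuple[float, float, float]:
    """(F, explained trace, residual trace) for hat matrix H of rank m."""
    n = G.shape[0]
    tr_fit = float(np.einsum("ij,ji->", H, G @ H))
    I_H = np.eye(n) - H
    tr_res = float(np.einsum("ij,ji->", I_H, G @ I_H))
    df_res = n - m - 1
    if df_res <= 0 or tr_res <= 0:
        return np.inf, tr_fit, tr_res
    return (tr_fit / m) / (tr_res / df_res), tr_fit, tr_res


def marginal_test(G: np.ndarray, X: np.ndarray, n_perm: int = 9999,
                  rng: np.random.Generator | None = None) -> dict:
    """Permutation test of one predictor set against the centred matrix G.

    pseudo-F = [tr(HGH)/m] / [tr((I-H)G(I-H))/(n-m-1)] with H the hat
    matrix of the centred predictors (intercept implicit); %var =
    100 tr(HGH)/tr(G).  P is obtained by simultaneously permuting the rows
    and columns of the distance matrix (equivalently of G), add-one
    corrected.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = rng or np.random.default_rng()
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("predictor rows must match distance-matrix size")
    H, m = _hat_matrix(X)
    if m == 0:
        raise ValueError("predictor set is constant after centring")
    f_obs, tr_fit, _ = _pseudo_f(G, H, m)
    tr_g = float(np.trace(G))
    pct = 100.0 * tr_fit / tr_g if tr_g > 0 else np.nan
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_p, _, _ = _pseudo_f(G[np.ix_(perm, perm)], H, m)
        if f_p >= f_obs - 1e-12:
            hits += 1
    return {"pseudo_F": float(f_obs), "p_value": (1 + hits) / (n_perm + 1),
            "pct_var": float(pct), "rank": m}


def _set_correlations(table: PredictorTable) -> pd.DataFrame:
    """Pairwise RV-style correlation between predictor sets (collinearity check)."""
    names = list(table.sets)
    k = len(names)
    out = np.eye(k)
    cent = {}
    for nm in names:
        X = table.matrix(nm)
        cent[nm] = X - X.mean(axis=0)
    for a in range(k):
        for b in range(a + 1, k):
            Xa, Xb = cent[names[a]], cent[names[b]]
            Sab = Xa.T @ Xb
            num = float(np.sum(Sab * Sab))
            den = np.sqrt(float(np.sum((Xa.T @ Xa) ** 2)) *
                          float(np.sum((Xb.T @ Xb) ** 2)))
            out[a, b] = out[b, a] = num / den if den > 0 else np.nan
    return pd.DataFrame(out, index=names, columns=names)


def forward_selection(G: np.ndarray, table: PredictorTable,
                      n_perm: int = 9999,
                      rng: np.random.Generator | None = None,
                      stop_alpha: float | None = None) -> DbrdaResult:
    """Marginal tests plus sequential forward selection over predictor sets.

    At each step the candidate set with the largest conditional pseudo-F is
    added; its conditional P comes from permuting the residual matrix under
    the reduced model (the model containing the already-selected sets).
    Selection stops when no remaining candidate reaches ``stop_alpha``
    (``None`` = report-all: every set is eventually entered).
    """
    rng = rng or np.random.default_rng()
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    names = list(table.sets)
    if len(names) < 2:
        raise ValueError("forward selection needs at least two predictor sets")
    tr_g = float(np.trace(G))

    marg_rows = []
    for nm in names:
        res = marginal_test(G, table.matrix(nm), n_perm, rng)
        marg_rows.append({"set": nm, "pseudo_F": res["pseudo_F"],
                          "P": res["p_value"], "pct_var": res["pct_var"]})
    marginal = pd.DataFrame(marg_rows)

    selected: list[str] = []
    sel_rows = []
    remaining = list(names)
    X_sel = np.empty((n, 0))
    while remaining:
        H0, m0 = (np.zeros((n, n)), 0) if not selected else _hat_matrix(X_sel)
        G_res = (np.eye(n) - H0) @ G @ (np.eye(n) - H0)
        best = None
        for nm in remaining:
            Xf = np.hstack([X_sel, table.matrix(nm)])
            Hf, mf = _hat_matrix(Xf)
            mc = mf - m0
            if mc == 0:
                f_c, tr_fit_f = 0.0, float(np.einsum("ij,ji->", Hf, G @ Hf))
            else:
                delta = Hf - H0
                tr_cond = float(np.einsum("ij,ji->", delta, G @ delta))
                I_Hf = np.eye(n) - Hf
                tr_res = float(np.einsum("ij,ji->", I_Hf, G @ I_Hf))
                df_res = n - mf - 1
                f_c = np.inf if (df_res <= 0 or tr_res <= 0) else \
                    (tr_cond / mc) / (tr_res / df_res)
                tr_fit_f = float(np.einsum("ij,ji->", Hf, G @ Hf))
            if best is None or f_c > best[1]:
                best = (nm, f_c, tr_fit_f, mc)
        nm, f_obs, tr_fit_f, mc = best
        # conditional permutation P: permute residual matrix under reduced model
        hits = 0
        if mc > 0 and np.isfinite(f_obs):
            Xf = np.hstack([X_sel, table.matrix(nm)])
            Hf, mf = _hat_matrix(Xf)
            delta = Hf - H0
            I_Hf = np.eye(n) - Hf
            for _ in range(n_perm):
                perm = rng.permutation(n)
                Gp = G_res[np.ix_(perm, perm)]
                tr_c = float(np.einsum("ij,ji->", delta, Gp @ delta))
                tr_r = float(np.einsum("ij,ji->", I_Hf, Gp @ I_Hf))
                df_res = n - mf - 1
                f_p = np.inf if (df_res <= 0 or tr_r <= 0) else \
                    (tr_c / mc) / (tr_r / df_res)
                if f_p >= f_obs - 1e-12:
                    hits += 1
            p_cond = (1 + hits) / (n_perm + 1)
        else:
            p_cond = 1.0
        if stop_alpha is not None and p_cond > stop_alpha:
            break
        selected.append(nm)
        remaining.remove(nm)
        X_sel = np.hstack([X_sel, table.matrix(nm)])
        sel_rows.append({"set": nm, "cond_pseudo_F": f_obs, "P": p_cond,
                         "cum_pct_var": 100.0 * tr_fit_f / tr_g if tr_g > 0 else np.nan})
    return DbrdaResult(marginal=marginal,
                       selection=pd.DataFrame(sel_rows),
                       set_correlations=_set_correlations(table))
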