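"""Environmental drivers: Mantel / partial Mantel tests and Pearson
correlations of network topology against environmental variables.

Mantel statistics correlate the off-diagonal entries of two distance
matrices; significance comes from permuting the row/column order of the
second matrix (one-sided, positive association — the ecological
convention — with the plus-one estimator, 999 permutations by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .diversity import DistanceMatrix
from .errors import ValidationError


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    partialled_variable: str | None = None


def _check_match(*mats: DistanceMatrix):
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValidationError("distance matrices have mismatched samples")


def _offdiag(m: DistanceMatrix) -> np.ndarray:
    return m.condensed()


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValidationError("constant distance matrix")
    return (v - v.mean()) / sd


def _perm_offdiag(data: np.ndarray, perms: np.ndarray,
                  iu0: np.ndarray, iu1: np.ndarray) -> np.ndarray:
    """Off-diagonal vectors of data[p][:, p] for each permutation p."""
    return data[perms[:, iu0], perms[:, iu1]]


def mantel(d_a: DistanceMatrix, d_b: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None,
           alternative: str = "greater") -> MantelResult:
    """Mantel test: Pearson r of the two off-diagonal vectors."""
    _check_match(d_a, d_b)
    a = _standardize(_offdiag(d_a))
    b = _standardize(_offdiag(d_b))
    m = len(a)
    r_obs = float(a @ b / m)
    n = d_a.n
    iu0, iu1 = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    b_perm = _perm_offdiag(d_b.data, perms, iu0, iu1)
    b_perm = (b_perm - b_perm.mean(axis=1, keepdims=True)) \
        / b_perm.std(axis=1, keepdims=True)
    r_perm = b_perm @ a / m
    if alternative == "greater":
        exceed = np.sum(r_perm >= r_obs)
    elif alternative == "two-sided":
        exceed = np.sum(np.abs(r_perm) >= abs(r_obs))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    p = (1.0 + exceed) / (n_perm + 1.0)
    return MantelResult(r_obs, float(p), n_perm)


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    numer = r_ab - r_ac * r_bc
    denom = (1 - r_ac ** 2) * (1 - r_bc ** 2)
    if denom <= 0:
        # self-partialling limit (B == C): the numerator vanishes too and
        # the partial correlation is 0 analytically
        if abs(numer) < 1e-12:
            return 0.0
        raise ValidationError(
            "partial correlation undefined: the controlled matrix is "
            "perfectly correlated with an input")
    return numer / np.sqrt(denom)


def partial_mantel(d_a: DistanceMatrix, d_b: DistanceMatrix,
                   d_c: DistanceMatrix, n_perm: int = 999,
                   seed: int | None = None,
                   alternative: str = "greater") -> MantelResult:
    """Partial Mantel test of A vs B controlling C.

    r_AB.C = (r_AB - r_AC r_BC) / sqrt((1-r_AC^2)(1-r_BC^2)); the
    permutation scheme permutes the rows/columns of B.
    """
    _check_match(d_a, d_b, d_c)
    a = _standardize(_offdiag(d_a))
    b = _standardize(_offdiag(d_b))
    c = _standardize(_offdiag(d_c))
    m = len(a)
    r_ab = float(a @ b / m)
    r_ac = float(a @ c / m)
    r_bc = float(b @ c / m)
    r_obs = float(_partial_r(r_ab, r_ac, r_bc))
    n = d_a.n
    iu0, iu1 = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    b_perm = _perm_offdiag(d_b.data, perms, iu0, iu1)
    b_perm = (b_perm - b_perm.mean(axis=1, keepdims=True)) \
        / b_perm.std(axis=1, keepdims=True)
    r_ab_p = b_perm @ a / m
    r_bc_p = b_perm @ c / m
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt((1 - r_ac ** 2) * (1 - r_bc_p ** 2))
        r_perm = (r_ab_p - r_ac * r_bc_p) / denom
    r_perm = r_perm[np.isfinite(r_perm)]
    if alternative == "greater":
        exceed = np.sum(r_perm >= r_obs)
    elif alternative == "two-sided":
        exceed = np.sum(np.abs(r_perm) >= abs(r_obs))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    p = (1.0 + exceed) / (n_perm + 1.0)
    return MantelResult(r_obs, float(p), n_perm)


def euclidean_distance(values: np.ndarray, ids: list[str],
                       standardize: bool = True) -> DistanceMatrix:
    """Euclidean distances between samples, on standardized variables by
    default (the usual environmental-distance choice)."""
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform
    return DistanceMatrix(squareform(pdist(x)), list(ids))


def mantel_report(d_comm: DistanceMatrix, env, n_perm: int = 999,
                  seed: int | None = None, partial: bool = True) -> pd.DataFrame:
    """(Partial) Mantel of community distance vs each environmental
    variable's distance, controlling the remaining variables jointly."""
    df = env.to_dataframe().loc[d_comm.ids]
    rows = []
    rng = np.random.default_rng(seed)
    for var in df.columns:
        d_var = euclidean_distance(df[var].to_numpy(), list(df.index))
        s = int(rng.integers(2 ** 31 - 1))
        if partial and df.shape[1] > 1:
            rest = df.drop(columns=var).to_numpy()
            d_rest = euclidean_distance(rest, list(df.index))
            res = partial_mantel(d_comm, d_var, d_rest, n_perm=n_perm, seed=s)
            res.partialled_variable = "all other variables"
        else:
            res = mantel(d_comm, d_var, n_perm=n_perm, seed=s)
        rows.append({"variable": var, "r": res.r, "p": res.p,
                     "n_permutations": res.n_permutations,
                     "partialled": res.partialled_variable or ""})
    return pd.DataFrame(rows)


def env_topology_correlation(env_df: pd.DataFrame,
                             metrics_df: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (with two-sided p and significance stars) between each
    topology metric and each environmental variable across networks.

    Rows of both frames are networks/units (>= 3 required); constant
    columns yield missing entries.
    """
    if len(env_df) != len(metrics_df):
        raise ValidationError("env and metrics tables must align by row")
    if len(env_df) < 3:
        raise ValidationError("need at least 3 networks/units")
    rows = []
    for metric in metrics_df.columns:
        y = pd.to_numeric(metrics_df[metric], errors="coerce").to_numpy(float)
        for var in env_df.columns:
            x = pd.to_numeric(env_df[var], errors="coerce").to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = pearsonr(x[ok], y[ok])
            stars = ""
            if np.isfinite(p):
                stars = "**" if p <= 0.01 else ("*" if p <= 0.05 else "")
            rows.append({"metric": metric, "variable": var,
                         "r": r, "p": p, "significance": stars})
    return pd.DataFrame(rows)
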