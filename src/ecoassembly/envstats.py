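"""Environmental heterogeneity, Mantel tests and distance regressions.

The heterogeneity index of a group of samples (a season) is the mean
pairwise Euclidean distance between their environmental vectors.
Variables are z-scored across *all* samples before distances are taken
(default), so mixed units (degrees C, psu, mg/L) contribute comparably
while between-group spread differences are preserved.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .otu import EnvTable

__all__ = [
    "euclidean_matrix",
    "heterogeneity_index",
    "mantel_test",
    "distance_regression",
]


def _env_values(
    env: EnvTable | pd.DataFrame,
    standardize: bool,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    df = env.data if isinstance(env, EnvTable) else env
    df = df.drop(columns=[c for c in exclude if c in df.columns])
    if df.isna().any().any():
        raise ValueError("missing environmental values; impute or drop first")
    if standardize:
        sd = df.std(ddof=0)
        flat = sd.index[sd == 0].tolist()
        if flat:
            warnings.warn(f"dropping zero-variance variable(s) under standardization: {flat}")
            df = df.drop(columns=flat)
            sd = sd.drop(flat)
        df = (df - df.mean()) / sd
    return df


def euclidean_matrix(
    env: EnvTable | pd.DataFrame,
    standardize: bool = True,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Pairwise Euclidean distance over environmental variables.

    ``exclude`` drops variables (e.g. dissolved oxygen when it is
    collinear with temperature) before computing distances.
    """
    df = _env_values(env, standardize, exclude)
    mat = squareform(pdist(df.to_numpy(float)))
    return pd.DataFrame(mat, index=df.index, columns=df.index)


def heterogeneity_index(
    env: EnvTable,
    grouping: pd.Series | None = None,
    standardize: bool = True,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Mean pairwise environmental distance within each group.

    H(group) = mean of the off-diagonal upper-triangle Euclidean
    distances between the group's samples; H = 0 iff all rows in the
    group are identical.  ``grouping`` defaults to the "season" column of
    the environment table's grouping frame.
    """
    if grouping is None:
        if "season" not in env.grouping.columns:
            raise ValueError("no grouping given and no 'season' column present")
        grouping = env.grouping["season"]
    dist = euclidean_matrix(env, standardize=standardize, exclude=exclude)
    rows = []
    for group, ids in pd.Series(grouping).groupby(pd.Series(grouping)).groups.items():
        ids = list(ids)
        if len(ids) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        sub = dist.loc[ids, ids].to_numpy()
        iu = np.triu_indices(len(ids), k=1)
        rows.append({"group": group, "H": float(sub[iu].mean()), "n_samples": len(ids),
                     "n_pairs": len(iu[0])})
    return pd.DataFrame(rows).set_index("group")


def _upper(mat: pd.DataFrame) -> np.ndarray:
    arr = mat.to_numpy(float)
    iu = np.triu_indices(arr.shape[0], k=1)
    return arr[iu]


def mantel_test(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper triangles; significance
    comes from jointly permuting rows and columns of ``d2``:
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1), one-sided.
    """
    if list(d1.index) != list(d2.index):
        raise ValueError("distance matrices must share ids in the same order")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    x = _upper(d1)
    arr2 = d2.to_numpy(float)
    y = _upper(d2)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance vector; Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = arr2.shape[0]
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = arr2[np.ix_(perm, perm)][iu]
        if np.corrcoef(x, y_perm)[0, 1] >= r_obs:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


def distance_regression(dx: pd.DataFrame, dy: pd.DataFrame) -> tuple[float, float, float]:
    """OLS of dy's upper triangle on dx's: (slope, intercept, R^2).

    Distance pairs are not independent observations, so the R^2 is
    descriptive only; test significance with :func:`mantel_test`.
    """
    if list(dx.index) != list(dy.index):
        raise ValueError("distance matrices must share ids in the same order")
    x, y = _upper(dx), _upper(dy)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
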