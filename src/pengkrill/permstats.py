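"""Feature standardisation and one-way PERMANOVA (Euclidean distances).

PERMANOVA partitions the total sum of squared pairwise distances into
between- and within-group components and tests the pseudo-F ratio

    F = ((SS_total − SS_within) / (a − 1)) / (SS_within / (N − a))

against its permutation distribution under unrestricted row-label shuffles.
With Euclidean distances on a single z-scored variable the pseudo-F is
algebraically identical to the classic one-way ANOVA F, which provides an
exact external oracle. The p-value uses the (1 + count) / (1 + n_perm)
convention, so p is never 0 and its resolution is 1 / (n_perm + 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist


def standardize(table, columns=None):
    """z-score columns (sample sd, ddof=1); zero-variance columns are rejected."""
    df = table.copy()
    if columns is None:
        columns = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    for c in columns:
        sd = df[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {c!r} has zero variance; cannot standardize")
        df[c] = (df[c] - df[c].mean()) / sd
    return df


@dataclass
class PermanovaResult:
    pseudo_f: float
    df_between: int
    df_within: int
    p_value: float
    n_perm: int
    seed: int | None


def _group_codes(groups):
    codes, uniques = pd.factorize(np.asarray(groups))
    if len(uniques) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [str(uniques[i]) for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"every group needs >= 2 rows; too small: {small}")
    return codes, counts


def permanova_one_way(X, groups, n_perm=999, seed=None):
    """One-way PERMANOVA on Euclidean distances between the rows of ``X``.

    ``X`` is an (N × p) array or DataFrame of (typically standardized)
    features; ``groups`` the per-row labels. Permutations shuffle the labels
    freely; the permutation count excludes the observed labelling.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes, counts = _group_codes(groups)
    n = len(codes)
    a = len(counts)
    if X.shape[0] != n:
        raise ValueError("X rows and group labels disagree")

    d2 = squareform(pdist(X, metric="sqeuclidean"))
    ss_total = d2.sum() / (2.0 * n)

    def ss_within(cds):
        s = 0.0
        for g in range(a):
            m = cds == g
            s += d2[np.ix_(m, m)].sum() / (2.0 * counts[g])
        return s

    ssw = ss_within(codes)
    df_b, df_w = a - 1, n - a
    if ssw <= 0:
        f_obs = np.inf
        p = 1.0 / (n_perm + 1.0)
        return PermanovaResult(f_obs, df_b, df_w, p, n_perm, seed)
    f_obs = ((ss_total - ssw) / df_b) / (ssw / df_w)

    if n_perm <= 0:
        return PermanovaResult(float(f_obs), df_b, df_w, 1.0, 0, seed)

    rng = np.random.default_rng(seed)
    # batched permutations: one n×n_perm indicator matmul per group
    perm_codes = np.empty((n, n_perm), dtype=np.int8)
    for k in range(n_perm):
        perm_codes[:, k] = rng.permutation(codes)
    ssw_perm = np.zeros(n_perm)
    for g in range(a):
        m = (perm_codes == g).astype(float)        # n × n_perm
        ssw_perm += np.einsum("ik,ik->k", m, d2 @ m) / (2.0 * counts[g])
    ssw_perm = np.where(ssw_perm <= 0, np.finfo(float).tiny, ssw_perm)
    f_perm = ((ss_total - ssw_perm) / df_b) / (ssw_perm / df_w)
    count = int((f_perm >= f_obs * (1.0 - 1e-12)).sum())
    p = (1.0 + count) / (1.0 + n_perm)
    return PermanovaResult(float(f_obs), df_b, df_w, float(p), n_perm, seed)


def permanova_table(df, features, group_col="season", n_perm=999, seed=None,
                    per_variable=True, standardized=True):
    """Season contrasts for a metrics table.

    Runs one univariate PERMANOVA per feature (the default, matching
    per-variable F_{1,N−2} reporting) or a single joint multivariate test.
    Features are z-scored across all rows first unless ``standardized=False``.
    """
    work = df[[*features, group_col]].dropna().reset_index(drop=True)
    if standardized:
        work = standardize(work, features)
    groups = work[group_col].to_numpy()
    rows = []
    if per_variable:
        for i, f in enumerate(features):
            sub_seed = None if seed is None else seed + 7919 * i
            r = permanova_one_way(work[[f]], groups, n_perm, sub_seed)
            rows.append({"feature_set": f, "pseudo_F": r.pseudo_f, "df1": r.df_between,
                         "df2": r.df_within, "p": r.p_value, "n_perm": r.n_perm,
                         "seed": sub_seed})
    else:
        r = permanova_one_way(work[features], groups, n_perm, seed)
        rows.append({"feature_set": "+".join(features), "pseudo_F": r.pseudo_f,
                     "df1": r.df_between, "df2": r.df_within, "p": r.p_value,
                     "n_perm": r.n_perm, "seed": seed})
    return pd.DataFrame(rows)
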