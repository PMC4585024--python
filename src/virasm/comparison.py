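"""Assembly-to-ideal distances, clustering, and association analyses.

Coverage-like species profiles are compared with Bray-Curtis distances
and fragmentation profiles with Hellinger distances; assemblies are then
hierarchically clustered (average linkage) with plain bootstrap support
obtained by resampling profile columns. Three association methods link
the assembly-statistics panel to an alpha-diversity response: Spearman
correlation with Benjamini-Hochberg correction, an L1-regularized
(lasso) Gaussian linear model with cross-validated penalty, and
random-forest permutation importance (%IncMSE on held-out folds). A
predictor supported by at least two of the three is consensus-flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import braycurtis as _braycurtis, squareform
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

Q_THRESHOLD = 0.05


# ---------------------------------------------------------------- distances

def bray_curtis(x, y) -> float:
    """Sum |x_i - y_i| / sum (x_i + y_i) on non-negative abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    if x.sum() + y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


def hellinger_distance(x, y) -> float:
    """Euclidean distance between square-rooted, total-normalized vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("Hellinger undefined for an all-zero vector")
    return float(np.linalg.norm(np.sqrt(x / x.sum()) - np.sqrt(y / y.sum())))


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundance vectors must be non-negative")


_METRICS = {"braycurtis": bray_curtis, "hellinger": hellinger_distance}


def profile_matrix(
    spectra_by_assembly: dict[str, pd.DataFrame], column: str = "coverage"
) -> pd.DataFrame:
    """Assemblies x species matrix of one spectrum column, zero-filled for
    species absent from an assembly."""
    series = {name: df[column] for name, df in spectra_by_assembly.items()}
    return pd.DataFrame(series).T.fillna(0.0).sort_index(axis=1)


def distance_matrix(profiles: pd.DataFrame, metric: str = "braycurtis") -> pd.DataFrame:
    """All-pairs distance matrix between profile rows."""
    fn = _METRICS[metric]
    n = len(profiles)
    d = np.zeros((n, n))
    vals = profiles.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(vals[i], vals[j])
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def correlation_distance_matrix(stats_table: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between assemblies' standardized statistic
    vectors (rows = assemblies, columns = statistics)."""
    z = (stats_table - stats_table.mean()) / stats_table.std(ddof=0).replace(0, 1.0)
    d = 1.0 - np.corrcoef(z.to_numpy(dtype=float))
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=stats_table.index, columns=stats_table.index)


# --------------------------------------------------------------- clustering

@dataclass
class HClusterResult:
    labels: list[str]
    linkage: np.ndarray
    newick: str
    support: dict[frozenset, float]  # leaf set -> bootstrap probability


def _leaf_sets(Z: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Leaf-label sets of every internal node of a linkage tree."""
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = set()
    for k, (a, b, _, _) in enumerate(Z):
        s = members[int(a)] | members[int(b)]
        members[n + k] = s
        out.add(s)
    return out


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def hcluster(
    profiles: pd.DataFrame,
    metric: str = "braycurtis",
    linkage_method: str = "average",
    n_boot: int = 100,
    seed: int | None = None,
) -> HClusterResult:
    """Average-linkage clustering of assemblies with bootstrap support.

    Support (BP) of an internal node is the fraction of ``n_boot``
    replicates -- profile columns resampled with replacement -- whose
    tree contains the same leaf set. Deterministic per seed.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two assemblies to cluster")
    labels = [str(i) for i in profiles.index]
    dm = distance_matrix(profiles, metric)
    Z = hierarchy.linkage(squareform(dm.to_numpy(), checks=False), method=linkage_method)
    nodes = _leaf_sets(Z, labels)
    hits = dict.fromkeys(nodes, 0)
    rng = np.random.default_rng(seed)
    ncol = profiles.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, ncol, size=ncol)
        rep = profiles.iloc[:, cols]
        try:
            dmb = distance_matrix(rep, metric)
        except ValueError:  # an all-zero resample; skip silently
            continue
        Zb = hierarchy.linkage(squareform(dmb.to_numpy(), checks=False), method=linkage_method)
        for s in _leaf_sets(Zb, labels):
            if s in hits:
                hits[s] += 1
    support = {s: hits[s] / n_boot for s in nodes}
    return HClusterResult(labels=labels, linkage=Z, newick=_to_newick(Z, labels), support=support)


def hcluster_from_distances(dm: pd.DataFrame, linkage_method: str = "average") -> HClusterResult:
    """Clustering straight from a distance matrix (no bootstrap support)."""
    arr = dm.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    labels = [str(i) for i in dm.index]
    Z = hierarchy.linkage(squareform(arr, checks=False), method=linkage_method)
    return HClusterResult(labels=labels, linkage=Z, newick=_to_newick(Z, labels), support={})


# ---------------------------------------------------------------- statistics

def kruskal_wallis_bh(groups: dict[str, list]) -> pd.DataFrame:
    """Kruskal-Wallis H per comparison with BH-adjusted q over the family.

    ``groups`` maps a comparison name to its list of group value arrays.
    """
    rows = []
    for name, gs in groups.items():
        if len(gs) < 2 or any(len(g) < 2 for g in gs):
            raise ValueError(f"comparison {name!r} needs >= 2 groups of >= 2 values")
        h, p = stats.kruskal(*gs)
        rows.append({"comparison": name, "H": float(h), "p": float(p)})
    df = pd.DataFrame(rows).set_index("comparison")
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def spearman_matrix(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho among statistics with BH q per pair.

    Returns a long table (stat_a, stat_b, rho, p, q, significant);
    constant columns yield NaN rho and are flagged non-significant.
    """
    if len(stats_table) < 3:
        raise ValueError("need >= 3 assemblies for rank correlations")
    cols = list(stats_table.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x, y = stats_table[a], stats_table[b]
            if x.nunique() < 2 or y.nunique() < 2:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(x, y)
            rows.append({"stat_a": a, "stat_b": b, "rho": rho, "p": p})
    df = pd.DataFrame(rows)
    finite = df["p"].notna()
    q = np.full(len(df), np.nan)
    if finite.any():
        q[finite.to_numpy()] = bh_adjust(df.loc[finite, "p"])
    df["q"] = q
    df["significant"] = df["q"] < Q_THRESHOLD
    return df


# ---------------------------------------------------------------- association

def _rf_incmse(
    X: np.ndarray, y: np.ndarray, seed: int, n_trees: int, n_splits: int, n_repeats: int
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out permutation importance: % increase in out-of-fold MSE when
    one predictor is permuted, averaged over folds and repeats. Returns
    (%IncMSE, z) per predictor, z = mean / SE over fold x repeat draws."""
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    base_var = y.var() or 1.0
    deltas: list[list[float]] = [[] for _ in range(X.shape[1])]
    for train, test in kf.split(X):
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
        rf.fit(X[train], y[train])
        err0 = np.mean((rf.predict(X[test]) - y[test]) ** 2)
        for j in range(X.shape[1]):
            for _ in range(n_repeats):
                Xp = X[test].copy()
                Xp[:, j] = Xp[rng.permutation(len(test)), j]
                err = np.mean((rf.predict(Xp) - y[test]) ** 2)
                deltas[j].append((err - err0) / base_var * 100.0)
    means = np.array([np.mean(d) for d in deltas])
    ses = np.array([np.std(d, ddof=1) / np.sqrt(len(d)) if len(d) > 1 else np.inf for d in deltas])
    z = np.divide(means, ses, out=np.zeros_like(means), where=ses > 0)
    return means, z


def association_analysis(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int | None = None,
    n_trees: int = 300,
    rf_z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Three-method association of assembly statistics with a diversity
    response.

    Per predictor: Spearman rho/p/BH-q (support: q < 0.05); lasso-GLM
    nonzero coefficient at the cross-validated penalty (standardized
    predictors, Gaussian response); random-forest %IncMSE on held-out
    folds (support: importance z above ``rf_z_threshold``). Consensus =
    supported by >= 2 of the 3 methods.
    """
    if len(X) < 10:
        raise ValueError("need >= 10 assemblies for the association analysis")
    X = X.astype(float)
    y = y.astype(float).loc[X.index]
    seed = 0 if seed is None else int(seed)

    rho_p = [stats.spearmanr(X[c], y) if X[c].nunique() > 1 else (np.nan, np.nan) for c in X.columns]
    rho = np.array([r for r, _ in rho_p])
    pvals = np.array([p for _, p in rho_p])
    q = np.full(len(pvals), np.nan)
    fin = np.isfinite(pvals)
    if fin.any():
        q[fin] = bh_adjust(pvals[fin])
    sc_flag = (q < Q_THRESHOLD) & fin

    sd = X.std(ddof=0).replace(0, 1.0)
    Xz = ((X - X.mean()) / sd).to_numpy()
    yv = y.to_numpy()
    n_splits = min(5, len(X))
    lasso = LassoCV(cv=KFold(n_splits=n_splits, shuffle=True, random_state=seed), random_state=seed)
    lasso.fit(Xz, yv)
    glm_flag = np.abs(lasso.coef_) > 1e-10

    incmse, z = _rf_incmse(Xz, yv, seed=seed, n_trees=n_trees, n_splits=n_splits, n_repeats=5)
    rf_flag = z > rf_z_threshold

    flags = sc_flag.astype(int) + glm_flag.astype(int) + rf_flag.astype(int)
    return pd.DataFrame(
        {
            "rho": rho,
            "p": pvals,
            "q": q,
            "spearman_selected": sc_flag,
            "glm_selected": glm_flag,
            "rf_incmse": incmse,
            "rf_z": z,
            "rf_selected": rf_flag,
            "consensus": flags >= 2,
        },
        index=X.columns,
    )


def distance_to_ideal(
    profiles: pd.DataFrame,
    ideal_id: str,
    metric: str = "braycurtis",
    groups: dict[str, str] | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Distance of every assembly's profile to the ideal profile.

    Optionally compares the distances across assembler groups with a
    Kruskal-Wallis test (``groups`` maps assembly id -> group label).
    """
    if ideal_id not in profiles.index:
        raise ValueError(f"ideal row {ideal_id!r} missing from profiles")
    fn = _METRICS[metric]
    ideal = profiles.loc[ideal_id].to_numpy(dtype=float)
    d = {
        str(idx): fn(row.to_numpy(dtype=float), ideal)
        for idx, row in profiles.iterrows()
        if idx != ideal_id
    }
    dser = pd.Series(d, name=f"{metric}_to_ideal")
    kw = None
    if groups:
        by_group: dict[str, list[float]] = {}
        for aid, val in dser.items():
            if aid in groups:
                by_group.setdefault(groups[aid], []).append(val)
        if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
            kw = kruskal_wallis_bh({"distance_to_ideal": list(by_group.values())})
    return dser, kw
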