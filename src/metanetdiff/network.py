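"""Differential (DiffCoEx) and preserved (SimCoEx) correlation-network analysis.

Given per-condition Pearson correlation matrices C and C' over the same
features, the *difference matrix* is large where correlations change between
conditions and the *constancy matrix* where they are strong and concordant
in both::

    d_ij = ( 1/2 |sign(c) c^2 - sign(c') c'^2| )^(beta/2)
    k_ij = ( 1/2 |sign(c) c^2 + sign(c') c'^2| )^(beta/2)

with an even soft-thresholding power beta (default 6) suppressing weak
edges. Either matrix is smoothed by the topological overlap measure (TOM),
converted to a dissimilarity and clustered by average-linkage hierarchical
clustering with a silhouette-guided cut; module significance comes from a
condition-label permutation test on the module dispersion statistic
(root-mean-square within-module d_ij). A paired sign-flip permutation test
compares the overall correlation level between conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .data import FeatureMatrix, align_design
from .exceptions import (AlignmentError, ConfigError, DataError,
                         InsufficientDataError)
from .qc import quantile_normalize

#: WGCNA-style module colour palette, assigned by decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)


@dataclass
class ConditionAdjacency:
    """Signed Pearson correlation matrix of one condition's samples."""

    condition: str
    corr: pd.DataFrame
    n_samples: int

    def __post_init__(self) -> None:
        if not self.corr.index.equals(self.corr.columns):
            raise AlignmentError("correlation matrix must be square over features")


@dataclass
class PairTransform:
    """A difference or constancy matrix derived from two conditions."""

    matrix: pd.DataFrame
    beta_soft: int
    conditions: tuple[str, str]
    kind: str                    # 'difference' | 'constancy'


@dataclass
class ModuleAssignment:
    """Feature -> module colour ('grey' = unassigned) plus module sizes."""

    labels: pd.Series
    sizes: dict[str, int]

    def members(self, color: str) -> pd.Index:
        return self.labels.index[self.labels == color]

    @property
    def module_colors(self) -> list[str]:
        return [c for c in self.sizes if c != "grey"]


# ---------------------------------------------------------------------------
# condition correlation matrices
# ---------------------------------------------------------------------------

def condition_correlations(m: FeatureMatrix, design: pd.DataFrame,
                           split_by: str = "diet",
                           quantile_norm: bool = False,
                           ) -> dict[str, ConditionAdjacency]:
    """Per-level Pearson correlation matrices over an identical feature set.

    ``quantile_norm=True`` quantile-normalizes each level's sample columns
    before correlating (used for age comparisons, where distributional shifts
    between ages would otherwise masquerade as correlation changes).
    """
    d = align_design(m, design)
    if split_by not in d.columns:
        raise ConfigError(f"unknown design factor {split_by!r}")
    out: dict[str, ConditionAdjacency] = {}
    for level, rows in d.groupby(split_by, sort=True):
        if len(rows) < 4:
            raise InsufficientDataError(
                f"level {level!r} of {split_by!r} has {len(rows)} samples (< 4)")
        sub = m.subset_samples(rows["sample_id"])
        if quantile_norm:
            sub = quantile_normalize(sub)
        X = sub.values.to_numpy(dtype=float)
        if np.isnan(X).any():
            raise DataError("correlation matrices require a complete matrix")
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(X)
        C = np.nan_to_num(C, nan=0.0)          # constant features correlate 0
        np.fill_diagonal(C, 1.0)
        corr = pd.DataFrame(C, index=m.feature_ids, columns=m.feature_ids)
        out[str(level)] = ConditionAdjacency(condition=str(level), corr=corr,
                                             n_samples=len(rows))
    return out


def _check_pair(a: ConditionAdjacency, b: ConditionAdjacency, beta_soft: int) -> None:
    if not a.corr.index.equals(b.corr.index):
        raise AlignmentError("condition adjacencies cover different feature sets")
    if beta_soft < 2 or beta_soft % 2 != 0:
        raise ConfigError("beta_soft must be a positive even integer")


def _signed_square(C: np.ndarray) -> np.ndarray:
    return np.sign(C) * C * C


def difference_matrix(a: ConditionAdjacency, b: ConditionAdjacency,
                      beta_soft: int = 6) -> PairTransform:
    """DiffCoEx difference matrix: large where correlations change between
    conditions (in magnitude or sign); zero when the networks are identical."""
    _check_pair(a, b, beta_soft)
    D = (0.5 * np.abs(_signed_square(a.corr.to_numpy())
                      - _signed_square(b.corr.to_numpy()))) ** (beta_soft / 2)
    return PairTransform(matrix=pd.DataFrame(D, index=a.corr.index,
                                             columns=a.corr.columns),
                         beta_soft=beta_soft,
                         conditions=(a.condition, b.condition), kind="difference")


def constancy_matrix(a: ConditionAdjacency, b: ConditionAdjacency,
                     beta_soft: int = 6, method: str = "min-concordant"
                     ) -> PairTransform:
    """SimCoEx constancy matrix: large only for pairs strongly correlated with
    concordant sign in both conditions.

    ``method='min-concordant'`` (default) uses min(|c|, |c'|)^2 for
    sign-agreeing pairs and 0 otherwise, so a pair strong in only one
    condition carries no constancy signal. ``'signed-sum'`` mirrors the
    difference matrix with a sum in place of the difference; it is the exact
    algebraic mirror but assigns half-strength constancy to condition-specific
    pairs. Both agree on sign-flipped and on equally-correlated pairs.
    """
    _check_pair(a, b, beta_soft)
    Ca, Cb = a.corr.to_numpy(), b.corr.to_numpy()
    if method == "min-concordant":
        agree = np.sign(Ca) == np.sign(Cb)
        K = np.where(agree, np.minimum(np.abs(Ca), np.abs(Cb)) ** 2, 0.0) \
            ** (beta_soft / 2)
    elif method == "signed-sum":
        K = (0.5 * np.abs(_signed_square(Ca) + _signed_square(Cb))) ** (beta_soft / 2)
    else:
        raise ConfigError(f"unknown constancy method {method!r}")
    return PairTransform(matrix=pd.DataFrame(K, index=a.corr.index,
                                             columns=a.corr.columns),
                         beta_soft=beta_soft,
                         conditions=(a.condition, b.condition), kind="constancy")


# ---------------------------------------------------------------------------
# topological overlap and clustering
# ---------------------------------------------------------------------------

def topological_overlap(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Unsigned topological overlap matrix of a [0, 1] adjacency.

    t_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), diagonal 1.
    """
    is_df = isinstance(adj, pd.DataFrame)
    A = adj.to_numpy(dtype=float).copy() if is_df else np.array(adj, dtype=float)
    if (A < 0).any():
        raise DataError("TOM requires non-negative adjacency")
    if A.max(initial=0.0) > 1.0 + 1e-9:
        raise DataError("TOM requires adjacency entries <= 1")
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    T = num / den
    np.fill_diagonal(T, 1.0)
    if is_df:
        return pd.DataFrame(T, index=adj.index, columns=adj.columns)
    return T


def tom_dissimilarity(transform: PairTransform) -> pd.DataFrame:
    """1 - TOM of a difference/constancy matrix (the clustering input)."""
    return 1.0 - topological_overlap(transform.matrix)


def cluster_modules(dissim: pd.DataFrame, min_size: int = 10,
                    sil_min: float = 0.05, max_heights: int = 80
                    ) -> ModuleAssignment:
    """Average-linkage clustering with a silhouette-guided height cut.

    The tree is cut at a grid of candidate merge heights. At each cut,
    clusters of size >= ``min_size`` (and at most half of all features) are
    scored by a cluster-level silhouette, (b - a) / max(a, b), where a is
    the mean within-cluster dissimilarity and b the mean dissimilarity of
    members to non-members, both on the dissimilarity affinely rescaled to
    [0, 1] (TOM dissimilarities of sparse difference matrices occupy a
    narrow band near 1, which would otherwise crush the contrast). Clusters
    scoring at least ``sil_min`` are accepted; the cut maximizing the
    size-weighted sum of accepted scores wins — weighting by size prefers a
    complete module over its tighter core. Everything else is 'grey'.
    Colours follow the WGCNA palette by decreasing module size.
    """
    if not dissim.index.equals(dissim.columns):
        raise AlignmentError("dissimilarity must be square over features")
    ids = dissim.index
    n = len(ids)
    grey = pd.Series(["grey"] * n, index=ids, name="module")
    if n < max(min_size, 3):
        return ModuleAssignment(labels=grey, sizes={"grey": n})

    D = dissim.to_numpy(dtype=float).copy()
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    off = D[np.triu_indices(n, k=1)]
    lo, hi = off.min(), off.max()
    if hi - lo < 1e-12:                     # featureless landscape: no modules
        return ModuleAssignment(labels=grey, sizes={"grey": n})
    R = (D - lo) / (hi - lo)
    np.fill_diagonal(R, 0.0)
    row_tot = R.sum(axis=1)

    Z = linkage(squareform(D, checks=False), method="average")
    merge_h = np.unique(Z[:, 2])
    if len(merge_h) > max_heights:          # thin the grid, keep the extremes
        idx = np.unique(np.linspace(0, len(merge_h) - 1, max_heights).astype(int))
        merge_h = merge_h[idx]
    cuts = (merge_h[:-1] + merge_h[1:]) / 2.0 if len(merge_h) > 1 else merge_h

    best_score, best_labels = 0.0, None
    seen: set[bytes] = set()
    for h in cuts:
        flat = fcluster(Z, t=h, criterion="distance")
        key = flat.tobytes()
        if key in seen:
            continue
        seen.add(key)
        accepted: dict[int, float] = {}
        for c, size in zip(*np.unique(flat, return_counts=True)):
            if size < min_size or size > n // 2:
                continue
            mask = flat == c
            sub = R[mask]
            within_sum = sub[:, mask].sum()
            within = within_sum / (size * (size - 1))
            between = (row_tot[mask].sum() - within_sum) / (size * (n - size))
            s = (between - within) / max(within, between, 1e-300)
            if s >= sil_min:
                accepted[c] = s
        score = sum(s * (flat == c).sum() for c, s in accepted.items())
        if score > best_score:
            best_score = score
            lab = np.array(["grey"] * n, dtype=object)
            order = sorted(accepted, key=lambda c: -(flat == c).sum())
            for color, c in zip(MODULE_COLORS, order):
                lab[flat == c] = color
            best_labels = lab
    if best_labels is None:
        return ModuleAssignment(labels=grey, sizes={"grey": n})
    labels = pd.Series(best_labels, index=ids, name="module")
    return ModuleAssignment(labels=labels, sizes=labels.value_counts().to_dict())


def filter_modules_by_dispersion(modules: ModuleAssignment,
                                 dispersion: pd.DataFrame,
                                 alpha: float = 0.05) -> ModuleAssignment:
    """Demote modules whose dispersion permutation p exceeds ``alpha`` to grey.

    The DiffCoEx workflow validates candidate modules by condition-label
    permutation; a module whose differential dispersion is compatible with
    the permutation null is sampling-noise structure, not a differential
    module.
    """
    keep = set(dispersion.loc[dispersion["p"] <= alpha, "module"])
    labels = modules.labels.where(modules.labels.isin(keep), "grey")
    return ModuleAssignment(labels=labels, sizes=labels.value_counts().to_dict())


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------

def _module_dispersion(Xa: np.ndarray, Xb: np.ndarray, beta_soft: int) -> float:
    """RMS difference-matrix entry over a module's off-diagonal pairs."""
    with np.errstate(invalid="ignore"):
        Ca = np.corrcoef(Xa)
        Cb = np.corrcoef(Xb)
    Ca = np.nan_to_num(Ca, nan=0.0)
    Cb = np.nan_to_num(Cb, nan=0.0)
    D = (0.5 * np.abs(_signed_square(Ca) - _signed_square(Cb))) ** (beta_soft / 2)
    iu = np.triu_indices(D.shape[0], k=1)
    return float(np.sqrt((D[iu] ** 2).mean()))


def module_dispersion_test(m_a: pd.DataFrame, m_b: pd.DataFrame,
                           modules: ModuleAssignment, beta_soft: int = 6,
                           n_perm: int = 1000, seed: int | None = None
                           ) -> pd.DataFrame:
    """Condition-permutation test of each module's differential dispersion.

    ``m_a``/``m_b`` are the per-condition data matrices (features x samples,
    same feature index as the module assignment). The observed statistic per
    module is sqrt(mean d_ij^2) over in-module pairs; the null redraws the
    condition split of the pooled samples ``n_perm`` times.
    p = (1 + #{null >= obs}) / (1 + n_perm).
    """
    if n_perm < 10:
        raise ConfigError("n_perm must be >= 10")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation floor")
    if not m_a.index.equals(m_b.index):
        raise AlignmentError("condition matrices cover different features")
    rng = np.random.default_rng(seed)
    colors = [c for c in modules.module_colors if modules.sizes.get(c, 0) >= 2]
    rows = []
    pooled_cols = m_a.shape[1] + m_b.shape[1]
    n_a = m_a.shape[1]
    for color in colors:
        members = modules.members(color)
        sub_a = m_a.loc[members].to_numpy(dtype=float)
        sub_b = m_b.loc[members].to_numpy(dtype=float)
        obs = _module_dispersion(sub_a, sub_b, beta_soft)
        pooled = np.concatenate([sub_a, sub_b], axis=1)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled_cols)
            null = _module_dispersion(pooled[:, perm[:n_a]],
                                      pooled[:, perm[n_a:]], beta_soft)
            if null >= obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        rows.append({"module": color, "size": len(members),
                     "dispersion": obs, "p": p})
    return pd.DataFrame(rows, columns=["module", "size", "dispersion", "p"])


def _mean_offdiag_corr(X: np.ndarray) -> float:
    C = np.nan_to_num(np.corrcoef(X), nan=0.0)
    n = C.shape[0]
    return float((C.sum() - np.trace(C)) / (n * (n - 1)))


def correlation_shift_test(a: ConditionAdjacency, b: ConditionAdjacency,
                           feature_subset=None, n_perm: int = 2000,
                           seed: int | None = None,
                           samples_a: pd.DataFrame | None = None,
                           samples_b: pd.DataFrame | None = None,
                           ) -> tuple[float, float, float]:
    """Mean off-diagonal correlation per condition and a permutation p-value.

    The statistic is the difference of mean off-diagonal correlations. When
    the per-condition sample matrices (features x samples) are supplied, the
    null redraws the condition split of the pooled samples — the exact
    exchangeable null for two independent sample groups. Without sample
    data, the null sign-flips the per-feature mean correlation differences;
    that fallback ignores the dependence between features and is
    anticonservative, so treat its p descriptively.
    """
    _check_pair(a, b, 2)
    Ca, Cb = a.corr, b.corr
    if feature_subset is not None:
        ids = pd.Index(feature_subset)
        if len(ids) < 3:
            raise InsufficientDataError("feature subset must have >= 3 features")
        Ca = Ca.loc[ids, ids]
        Cb = Cb.loc[ids, ids]
        if samples_a is not None:
            samples_a = samples_a.loc[ids]
            samples_b = samples_b.loc[ids]
    A = Ca.to_numpy(dtype=float)
    B = Cb.to_numpy(dtype=float)
    p_feat = A.shape[0]
    u_a = (A.sum(axis=1) - 1.0) / (p_feat - 1)
    u_b = (B.sum(axis=1) - 1.0) / (p_feat - 1)
    mean_a, mean_b = float(u_a.mean()), float(u_b.mean())
    t_obs = mean_a - mean_b
    rng = np.random.default_rng(seed)

    if samples_a is not None and samples_b is not None:
        Xa = samples_a.to_numpy(dtype=float)
        Xb = samples_b.to_numpy(dtype=float)
        pooled = np.concatenate([Xa, Xb], axis=1)
        n_a, n_tot = Xa.shape[1], pooled.shape[1]
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n_tot)
            t_null = (_mean_offdiag_corr(pooled[:, perm[:n_a]])
                      - _mean_offdiag_corr(pooled[:, perm[n_a:]]))
            if abs(t_null) >= abs(t_obs):
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
    else:
        diff = u_a - u_b
        signs = rng.choice([-1.0, 1.0], size=(n_perm, p_feat))
        t_null = (signs * diff[None, :]).mean(axis=1)
        p = (1 + int((np.abs(t_null) >= abs(t_obs)).sum())) / (1 + n_perm)
    return mean_a, mean_b, float(p)


# ---------------------------------------------------------------------------
# feature selection for the module analyses
# ---------------------------------------------------------------------------

def _corr_pvalues(C: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of each pairwise correlation (t with n-2 df)."""
    r = np.clip(C, -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 1.0)
    return p


def differential_feature_selection(a: ConditionAdjacency, b: ConditionAdjacency,
                                   alpha: float = 0.01
                                   ) -> tuple[pd.Index, pd.Index]:
    """Split features into 'differential' and 'similar' correlation classes.

    A feature is *differential* when it has at least one partner whose
    correlation is significant (two-sided, level ``alpha``) in exactly one
    condition and no partner significant in both; *similar* when it has at
    least one partner significant in both conditions with the same sign.
    """
    _check_pair(a, b, 2)
    Ca, Cb = a.corr.to_numpy(), b.corr.to_numpy()
    sig_a = _corr_pvalues(Ca, a.n_samples) < alpha
    sig_b = _corr_pvalues(Cb, b.n_samples) < alpha
    both = sig_a & sig_b
    one = sig_a ^ sig_b
    same_sign_both = both & (np.sign(Ca) == np.sign(Cb))
    ids = a.corr.index
    differential = ids[one.any(axis=1) & ~both.any(axis=1)]
    similar = ids[same_sign_both.any(axis=1)]
    return differential, similar


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def edge_list(a: ConditionAdjacency, b: ConditionAdjacency,
              threshold: float = 0.5) -> pd.DataFrame:
    """Edges with |r| above ``threshold`` in either condition (for rendering)."""
    _check_pair(a, b, 2)
    Ca, Cb = a.corr.to_numpy(), b.corr.to_numpy()
    iu, ju = np.triu_indices(Ca.shape[0], k=1)
    keep = (np.abs(Ca[iu, ju]) > threshold) | (np.abs(Cb[iu, ju]) > threshold)
    ids = a.corr.index
    return pd.DataFrame({
        "feature_i": ids[iu[keep]],
        "feature_j": ids[ju[keep]],
        f"r_{a.condition}": Ca[iu[keep], ju[keep]],
        f"r_{b.condition}": Cb[iu[keep], ju[keep]],
    })


def write_graphml(edges: pd.DataFrame, path) -> None:
    """Write an edge list (as produced by :func:`edge_list`) as GraphML."""
    import networkx as nx
    g = nx.Graph()
    r_cols = [c for c in edges.columns if c.startswith("r_")]
    for _, row in edges.iterrows():
        g.add_edge(row["feature_i"], row["feature_j"],
                   **{c: float(row[c]) for c in r_cols})
    nx.write_graphml(g, path)
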