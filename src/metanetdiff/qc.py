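"""Preprocessing chain: log transform, outlier samples, SNR and missingness
filters, technical-replicate collapse, imputation, centering, quantile
normalization.

The chain mirrors standard untargeted-LC-MS practice: intensities are
log2-transformed; aberrant samples are flagged by standardized network
connectivity (a sample whose correlation to all other samples is unusually
low has strongly negative Z_k); features whose mean is less than 20x their
technical-replicate noise are dropped; technical replicates are averaged;
features missing in more than 10% of biological samples are dropped and the
remainder imputed; features are mean-centred (not rescaled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FeatureMatrix, align_design
from .exceptions import (ConfigError, DataError, InsufficientDataError,
                         UnimputableError)


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def log_transform(m: FeatureMatrix, base: float = 2.0,
                  pseudocount: float = 1.0) -> FeatureMatrix:
    """log(x + pseudocount) on the intensity scale. Missing cells stay missing."""
    if m.scale != "raw":
        raise DataError(f"log_transform expects raw intensities, got scale={m.scale!r}")
    if (m.values < 0).any().any():
        raise DataError("negative intensities")
    out = np.log(m.values + pseudocount) / np.log(base)
    return m.with_values(out, scale="log")


def unlog(m: FeatureMatrix, base: float = 2.0, pseudocount: float = 1.0) -> FeatureMatrix:
    """Inverse of :func:`log_transform`."""
    if m.scale != "log":
        raise DataError("unlog expects a log-scale matrix")
    out = np.power(base, m.values) - pseudocount
    return m.with_values(out, scale="raw")


# ---------------------------------------------------------------------------
# outlier samples
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Standardized sample-network connectivity and the flagged samples."""

    z_k: pd.Series
    flagged: list[str]
    threshold: float


def detect_outlier_samples(m: FeatureMatrix, z_cut: float = -3.0) -> OutlierReport:
    """Flag samples with standardized network connectivity ``Z_k < z_cut``.

    Sample adjacency is ``(1 + cor(s_i, s_j)) / 2`` over features complete in
    all samples; connectivity ``k_i`` sums the off-diagonal adjacencies and is
    standardized across samples. If the connectivities are constant (all
    samples identical) nothing is flagged.
    """
    if m.scale != "log":
        raise DataError("detect_outlier_samples expects log-scale values")
    if m.n_samples < 3:
        raise InsufficientDataError("need at least 3 samples")
    complete = m.values.dropna(axis=0)
    if len(complete) < 2:
        raise InsufficientDataError("need >= 2 complete features")
    corr = np.corrcoef(complete.to_numpy().T)
    corr = np.nan_to_num(corr, nan=0.0)        # constant samples contribute 0
    adj = (1.0 + corr) / 2.0
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    sd = k.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        z = np.zeros_like(k)
    else:
        z = (k - k.mean()) / sd
    z_k = pd.Series(z, index=m.sample_ids, name="Z_k")
    flagged = list(z_k.index[z_k < z_cut])
    return OutlierReport(z_k=z_k, flagged=flagged, threshold=z_cut)


def drop_samples(m: FeatureMatrix, sample_ids) -> FeatureMatrix:
    keep = [s for s in m.sample_ids if s not in set(sample_ids)]
    return m.subset_samples(keep)


# ---------------------------------------------------------------------------
# SNR filter
# ---------------------------------------------------------------------------

@dataclass
class FeatureQCStats:
    """Per-feature QC statistics (all input features, including removed ones)."""

    table: pd.DataFrame   # mean, sigma_tech, snr, missing_frac

    def removed(self, threshold: float) -> pd.Index:
        snr = self.table["snr"]
        return self.table.index[snr < threshold]


def snr_filter(m: FeatureMatrix, design: pd.DataFrame, threshold: float = 20.0,
               sigma_mode: str = "mean") -> tuple[FeatureMatrix, FeatureQCStats]:
    """Remove features whose signal-to-noise ratio falls below ``threshold``.

    SNR_i = mean_i / sigma_tech_i where sigma_tech_i aggregates the standard
    deviation among each biological sample's technical replicates —
    ``sigma_mode='mean'`` averages the per-sample sds, ``'pooled'`` pools the
    within-sample variances. Noiseless features (sigma_tech = 0) are kept.
    """
    if sigma_mode not in ("mean", "pooled"):
        raise ConfigError(f"unknown sigma_mode {sigma_mode!r}")
    d = align_design(m, design)
    groups = d.groupby("bio_id")["sample_id"].agg(list)
    if (groups.str.len() < 2).all():
        raise ConfigError("no technical replicates in design")

    X = m.values
    sds, variances, counts = [], [], []
    for cols in groups:
        sub = X[cols]
        n_obs = sub.notna().sum(axis=1)
        sd = sub.std(axis=1, ddof=1)          # NaN where < 2 observed
        sds.append(sd)
        variances.append(sd**2 * (n_obs - 1))
        counts.append((n_obs - 1).clip(lower=0))
    sd_mat = pd.concat(sds, axis=1)
    if sigma_mode == "mean":
        sigma_tech = sd_mat.mean(axis=1)
    else:
        num = pd.concat(variances, axis=1).sum(axis=1)
        den = pd.concat(counts, axis=1).sum(axis=1)
        sigma_tech = np.sqrt(num / den.replace(0, np.nan))

    mean = X.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = mean / sigma_tech
    snr = snr.where(sigma_tech > 0, np.inf)     # noiseless -> keep
    snr = snr.where(sigma_tech.notna(), np.inf)

    stats = FeatureQCStats(pd.DataFrame({
        "mean": mean,
        "sigma_tech": sigma_tech,
        "snr": snr,
        "missing_frac": X.isna().mean(axis=1),
    }))
    keep = stats.table.index[~(snr < threshold)]
    return m.subset_features(keep), stats


# ---------------------------------------------------------------------------
# technical-replicate collapse
# ---------------------------------------------------------------------------

def collapse_tech_reps(m: FeatureMatrix, design: pd.DataFrame) -> FeatureMatrix:
    """Average technical replicates; one column per biological sample.

    Missing cells are ignored in the mean; a collapsed cell is missing only
    when every technical replicate was missing.
    """
    d = align_design(m, design)
    groups = d.groupby("bio_id", sort=False)["sample_id"].agg(list)
    cols = {bio: m.values[cols].mean(axis=1) for bio, cols in groups.items()}
    out = pd.DataFrame(cols)
    return m.with_values(out)


# ---------------------------------------------------------------------------
# missingness filter / imputation / centering
# ---------------------------------------------------------------------------

def missingness_filter(m: FeatureMatrix, max_frac: float = 0.10) -> FeatureMatrix:
    """Drop features missing in more than ``max_frac`` of samples."""
    frac = m.missing_fraction()
    return m.subset_features(m.feature_ids[frac <= max_frac])


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope/intercept of y on x (assumes len >= 2, non-constant handled)."""
    mx, my = x.mean(), y.mean()
    sxx = ((x - mx) ** 2).sum()
    if sxx == 0:
        return 0.0, my
    b = ((x - mx) * (y - my)).sum() / sxx
    return b, my - b * mx


def impute(m: FeatureMatrix, method: str = "knn", k: int = 10,
           seed: int = 0, tol: float = 1e-6, max_iter: int = 25) -> FeatureMatrix:
    """Fill missing cells.

    ``knn``: for each missing cell, the |r|-weighted mean of predictions from
    the k features most correlated with the target, each neighbour's value
    mapped through the fitted neighbour->target regression line.
    ``em_regression``: initialise with feature means, then iterate regression
    of each incomplete feature on its k best correlates until the largest
    imputed-value change drops below ``tol``.
    """
    if method not in ("knn", "em_regression"):
        raise ConfigError(f"unknown imputation method {method!r}")
    X = m.values.to_numpy(dtype=float).copy()
    if not np.isnan(X).any():
        return m.copy()
    if np.isnan(X).all(axis=0).any():
        raise UnimputableError("a sample has no observed values")
    if np.isnan(X).all(axis=1).any():
        raise UnimputableError("a feature has no observed values")

    obs = ~np.isnan(X)
    df = pd.DataFrame(X.T)                     # samples x features
    corr = df.corr(min_periods=3).to_numpy()   # pairwise-complete correlations
    np.fill_diagonal(corr, np.nan)

    incomplete = np.where(~obs.all(axis=1))[0]

    if method == "knn":
        out = X.copy()
        for i in incomplete:
            c = np.abs(corr[i])
            order = np.argsort(np.nan_to_num(c, nan=-1.0))[::-1]
            for j in np.where(~obs[i])[0]:
                preds, weights = [], []
                for nb in order:
                    if len(preds) >= k or np.isnan(corr[i, nb]) or c[nb] <= 0:
                        break
                    if not obs[nb, j]:
                        continue
                    shared = obs[i] & obs[nb]
                    if shared.sum() < 3:
                        continue
                    b, a = _fit_line(X[nb, shared], X[i, shared])
                    preds.append(a + b * X[nb, j])
                    weights.append(c[nb])
                if preds:
                    out[i, j] = np.average(preds, weights=weights)
                else:                          # no usable neighbour: feature mean
                    out[i, j] = np.nanmean(X[i])
        X = out
    else:  # em_regression
        filled = X.copy()
        row_means = np.nanmean(X, axis=1)
        for i in incomplete:
            filled[i, ~obs[i]] = row_means[i]
        for _ in range(max_iter):
            delta = 0.0
            for i in incomplete:
                c = np.abs(np.nan_to_num(corr[i], nan=0.0))
                nbs = np.argsort(c)[::-1][:k]
                nbs = nbs[c[nbs] > 0]
                if len(nbs) == 0:
                    continue
                A = np.column_stack([np.ones(X.shape[1]), filled[nbs].T])
                train = obs[i]
                coef, *_ = np.linalg.lstsq(A[train], X[i, train], rcond=None)
                pred = A[~train] @ coef
                delta = max(delta, np.max(np.abs(pred - filled[i, ~train]), initial=0.0))
                filled[i, ~train] = pred
            if delta < tol:
                break
        X = filled

    values = pd.DataFrame(X, index=m.feature_ids, columns=m.sample_ids)
    return m.with_values(values)


def center_features(m: FeatureMatrix) -> FeatureMatrix:
    """Subtract each feature's mean; variance unchanged, no rescaling."""
    out = m.values.sub(m.values.mean(axis=1), axis=0)
    return m.with_values(out, scale="centered")


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(m: FeatureMatrix) -> FeatureMatrix:
    """Force every sample to share the mean empirical distribution.

    Each sample's sorted values are replaced by the across-sample mean of
    order statistics; tied values receive the mean of their tied ranks.
    """
    if m.values.isna().any().any():
        raise DataError("quantile_normalize requires a complete matrix")
    X = m.values
    n = X.shape[0]
    sorted_means = np.sort(X.to_numpy(), axis=0).mean(axis=1)
    ranks = X.rank(axis=0, method="average")
    out = pd.DataFrame(
        np.interp(ranks.to_numpy(), np.arange(1, n + 1), sorted_means),
        index=X.index, columns=X.columns)
    return m.with_values(out)
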