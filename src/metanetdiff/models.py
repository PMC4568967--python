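"""Per-feature univariate effect models and the diet-reverses-age analysis.

Each metabolomic feature is modelled as ``y = mu + beta * x`` where x codes
diet (AL=0, DR=1) or age (days), so beta > 0 means the feature increases
under DR or with age. P-values across features are controlled by
Benjamini-Hochberg FDR. The reversal analysis plots the diet slope against
the age slope: features significant for both whose slopes have opposite
signs sit in the "reversal" quadrants (DR pushes the metabolite back toward
its young level); same-sign features sit in "exacerbation" quadrants.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureMatrix, align_design
from .exceptions import (AlignmentError, ConfoundingError, DataError,
                         DegeneratePredictorError, InsufficientDataError)

DIET_CODES = {"AL": 0.0, "DR": 1.0}


@dataclass
class EffectRecord:
    """Fitted simple linear model for one feature and one predictor."""

    feature_id: str
    predictor: str
    intercept: float
    beta: float
    p: float
    q: float | None
    n: int


# ---------------------------------------------------------------------------
# OLS per feature
# ---------------------------------------------------------------------------

def _ols_1d(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, int]:
    """Closed-form OLS of y on x: (intercept, beta, two-sided p for beta=0, n)."""
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 3:
        raise InsufficientDataError("need >= 3 complete pairs")
    mx, my = x.mean(), y.mean()
    sxx = ((x - mx) ** 2).sum()
    if sxx == 0:
        raise DegeneratePredictorError("predictor is constant")
    sxy = ((x - mx) * (y - my)).sum()
    beta = sxy / sxx
    mu = my - beta * mx
    rss = ((y - mu - beta * x) ** 2).sum()
    if rss <= 0:
        # perfect fit: flat y -> no effect; sloped y -> infinitely significant
        p = 1.0 if beta == 0 else 0.0
    else:
        se = np.sqrt(rss / (n - 2) / sxx)
        t = beta / se
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(mu), float(beta), float(p), n


def fit_feature_effect(y, x, feature_id: str = "", predictor: str = "") -> EffectRecord:
    """OLS fit of one feature on one predictor with a t-test on the slope."""
    mu, beta, p, n = _ols_1d(np.asarray(y, float), np.asarray(x, float))
    return EffectRecord(feature_id=feature_id, predictor=predictor,
                        intercept=mu, beta=beta, p=p, q=None, n=n)


def fit_effects(m: FeatureMatrix, x, predictor: str = "x") -> pd.DataFrame:
    """Vectorised per-feature OLS over the whole matrix.

    Returns a DataFrame (index feature_id) with intercept, beta, p, n.
    Features with missing cells fall back to the per-feature path.
    """
    x = np.asarray(x, float)
    if len(x) != m.n_samples:
        raise AlignmentError("predictor length != number of samples")
    if len(np.unique(x[~np.isnan(x)])) < 2:
        raise DegeneratePredictorError("predictor is constant")
    Y = m.values.to_numpy(dtype=float)
    complete = ~np.isnan(Y).any(axis=1)

    out = pd.DataFrame(index=m.feature_ids,
                       columns=["intercept", "beta", "p", "n"], dtype=float)
    if complete.any():
        Yc = Y[complete]
        n = len(x)
        mx = x.mean()
        xc = x - mx
        sxx = (xc ** 2).sum()
        my = Yc.mean(axis=1)
        beta = (Yc - my[:, None]) @ xc / sxx
        mu = my - beta * mx
        rss = ((Yc - mu[:, None] - beta[:, None] * x[None, :]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / (n - 2) / sxx)
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = np.where(rss <= 1e-300,
                     np.where(beta == 0, 1.0, 0.0),
                     2.0 * stats.t.sf(np.abs(t), df=n - 2))
        out.loc[m.feature_ids[complete], "intercept"] = mu
        out.loc[m.feature_ids[complete], "beta"] = beta
        out.loc[m.feature_ids[complete], "p"] = p
        out.loc[m.feature_ids[complete], "n"] = n
    for fid in m.feature_ids[~complete]:
        rec = fit_feature_effect(m.values.loc[fid].to_numpy(), x, fid, predictor)
        out.loc[fid] = [rec.intercept, rec.beta, rec.p, rec.n]
    out["predictor"] = predictor
    return out


def diet_codes(design: pd.DataFrame) -> np.ndarray:
    return design["diet"].map(DIET_CODES).to_numpy(float)


def fit_diet_effects(m: FeatureMatrix, design: pd.DataFrame,
                     age: float | None = None) -> pd.DataFrame:
    """Diet effect (AL=0 vs DR=1) per feature, optionally at a single age."""
    d = align_design(m, design)
    sub = m
    if age is not None:
        keep = d.index[d["age"] == age]
        sub = m.subset_samples(d.loc[keep, "sample_id"])
        d = d.loc[keep]
    return fit_effects(sub, diet_codes(d), predictor="diet")


def fit_age_effects(m: FeatureMatrix, design: pd.DataFrame,
                    diet: str | None = "AL",
                    ages: tuple[float, float] | None = None) -> pd.DataFrame:
    """Age effect (per day) per feature, by default the 10-vs-40-day contrast on AL."""
    d = align_design(m, design)
    keep = np.ones(len(d), dtype=bool)
    if diet is not None:
        keep &= (d["diet"] == diet).to_numpy()
    if ages is not None:
        keep &= d["age"].isin(ages).to_numpy()
    sub = m.subset_samples(d.loc[keep, "sample_id"])
    return fit_effects(sub, d.loc[keep, "age"].to_numpy(float), predictor="age")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags (q <= fdr)."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise DataError("p-values outside [0, 1]")
    from statsmodels.stats.multitest import multipletests
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, q <= fdr


# ---------------------------------------------------------------------------
# batch adjustment (parametric empirical-Bayes location/scale, ComBat)
# ---------------------------------------------------------------------------

def batch_adjust(m: FeatureMatrix, batch, covariates: pd.DataFrame | None = None,
                 eb: bool = True) -> FeatureMatrix:
    """Remove batch location/scale effects while preserving covariate effects.

    ``batch`` is a per-sample label sequence aligned with the matrix columns;
    ``covariates`` (optional) are biological factors whose effects must be
    preserved through the adjustment.

    With ``eb=True`` (default) this is parametric empirical-Bayes ComBat
    (delegated to scanpy; matches the reference R implementation): per-batch
    location/scale estimates are shrunk toward across-feature priors, which
    stabilises small batches but deliberately leaves a shrinkage fraction of
    each feature's estimated batch offset in place. With ``eb=False`` the
    unshrunk estimates are removed outright (limma-style exact location/scale
    adjustment), which equalises per-feature batch means exactly.
    """
    batch = pd.Series(list(batch), index=m.sample_ids).astype(str)
    counts = batch.value_counts()
    if len(counts) == 1:
        return m.copy()
    if (counts < 2).any():
        raise InsufficientDataError("every batch needs >= 2 samples")
    obs = pd.DataFrame({"batch": batch})
    cov_keys: list[str] = []
    if covariates is not None:
        cov = covariates.copy()
        cov.index = m.sample_ids
        # encode categoricals as k-1 numeric dummies (numeric covariates pass
        # through the EB standardization untouched by the batch coding)
        numeric = pd.get_dummies(cov, drop_first=True).astype(float)
        for col in numeric.columns:
            obs[str(col)] = numeric[col].to_numpy()
            cov_keys.append(str(col))
        # full-rank check of [batch dummies | covariates]
        dm = np.column_stack([pd.get_dummies(batch).to_numpy(float),
                              numeric.to_numpy()])
        if np.linalg.matrix_rank(dm) < dm.shape[1]:
            raise ConfoundingError("batch confounded with covariates")

    if eb:
        import anndata

        adata = anndata.AnnData(X=m.values.to_numpy(dtype=float).T, obs=obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import scanpy as sc
            sc.pp.combat(adata, key="batch", covariates=cov_keys or None)
        X_adj = np.asarray(adata.X).T
    else:
        X_adj = _exact_location_scale_adjust(
            m.values.to_numpy(dtype=float), batch,
            obs[cov_keys].to_numpy(dtype=float) if cov_keys else None)
    values = pd.DataFrame(X_adj, index=m.feature_ids, columns=m.sample_ids)
    return m.with_values(values)


def _exact_location_scale_adjust(X: np.ndarray, batch: pd.Series,
                                 C: np.ndarray | None) -> np.ndarray:
    """Unshrunk ComBat: remove OLS batch locations and equalise batch scales.

    X is features x samples. The design is [batch one-hots | covariates];
    each feature's fitted per-batch intercept is replaced by the
    sample-size-weighted grand intercept and within-batch residual sds are
    rescaled to the pooled sd.
    """
    levels = pd.unique(batch)
    B = np.column_stack([(batch == lv).to_numpy(float) for lv in levels])
    n_batches = B.sum(axis=0)
    M = B if C is None else np.column_stack([B, C])
    coef, *_ = np.linalg.lstsq(M, X.T, rcond=None)      # (nb+q) x features
    fit = (M @ coef).T
    var_pooled = ((X - fit) ** 2).mean(axis=1, keepdims=True)
    var_pooled[var_pooled == 0] = 1.0
    grand = (n_batches / len(batch)) @ coef[:len(levels)]
    stand_mean = grand[:, None] + (0 if C is None else (C @ coef[len(levels):]).T)
    s = (X - stand_mean) / np.sqrt(var_pooled)
    for j, lv in enumerate(levels):
        sel = B[:, j] == 1.0
        gamma = (coef[j] - grand)[:, None] / np.sqrt(var_pooled)
        sd = (s[:, sel] - gamma).std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        s[:, sel] = (s[:, sel] - gamma) / sd
    return s * np.sqrt(var_pooled) + stand_mean


# ---------------------------------------------------------------------------
# reversal quadrant analysis
# ---------------------------------------------------------------------------

@dataclass
class ReversalTable:
    """Per-feature quadrant classification and the quadrant summary counts."""

    table: pd.DataFrame           # beta_diet, beta_age, q_diet, q_age, sig_class, quadrant
    counts: dict[str, int]        # reversal / exacerbation among doubly-significant
    fdr: float


def reversal_classification(diet_effects: pd.DataFrame, age_effects: pd.DataFrame,
                            fdr: float = 0.025) -> ReversalTable:
    """Classify features by the signs of their diet and age slopes.

    Both effect tables are BH-adjusted marginally at ``fdr``. A feature
    significant for both predictors is a *reversal* when the slopes have
    opposite signs and an *exacerbation* when they agree; features
    significant for only one predictor get class 'diet-only'/'age-only' and
    quadrant 'none'.
    """
    if not diet_effects.index.equals(age_effects.index):
        if set(diet_effects.index) != set(age_effects.index):
            raise AlignmentError("diet and age effects cover different features")
        age_effects = age_effects.loc[diet_effects.index]
    q_diet, sig_diet = bh_adjust(diet_effects["p"].to_numpy(), fdr)
    q_age, sig_age = bh_adjust(age_effects["p"].to_numpy(), fdr)
    bd = diet_effects["beta"].to_numpy(float)
    ba = age_effects["beta"].to_numpy(float)

    sig_class = np.select(
        [sig_diet & sig_age, sig_diet, sig_age],
        ["both", "diet-only", "age-only"], default="none")
    prod = np.sign(bd) * np.sign(ba)
    quadrant = np.select(
        [(sig_class == "both") & (prod < 0), (sig_class == "both") & (prod > 0)],
        ["reversal", "exacerbation"], default="none")

    table = pd.DataFrame({
        "beta_diet": bd, "beta_age": ba,
        "q_diet": q_diet, "q_age": q_age,
        "sig_class": sig_class, "quadrant": quadrant,
    }, index=diet_effects.index)
    counts = {
        "reversal": int((quadrant == "reversal").sum()),
        "exacerbation": int((quadrant == "exacerbation").sum()),
        "both_significant": int((sig_class == "both").sum()),
    }
    return ReversalTable(table=table, counts=counts, fdr=fdr)


# ---------------------------------------------------------------------------
# Venn region counts
# ---------------------------------------------------------------------------

def tissue_overlap_counts(sig_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive Venn-region counts for >= 2 named feature-id sets.

    Key ``(A,)`` counts features only in A; ``(A, B)`` features in exactly
    A and B; and so on.
    """
    if len(sig_sets) < 2:
        raise DataError("need at least 2 sets")
    names = sorted(sig_sets)
    out: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(set(sig_sets[n]) for n in combo))
            outside = set.union(*(set(sig_sets[n]) for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            out[combo] = len(inside - outside)
    return out


# ---------------------------------------------------------------------------
# PCA scores
# ---------------------------------------------------------------------------

def pca_scores(m: FeatureMatrix, n_components: int = 2
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the leading principal components of the feature space."""
    if m.values.isna().any().any():
        raise DataError("PCA requires a complete matrix")
    from sklearn.decomposition import PCA
    X = m.values.to_numpy(dtype=float).T     # samples x features
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        warnings.warn(f"n_components={n_components} exceeds rank; using {max_rank}")
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=m.sample_ids, columns=cols),
            pca.explained_variance_ratio_)
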