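"""Diet-dependent pairwise correlation screening.

Looks for pairs of metabolites whose *mean* levels are diet-invariant but
whose correlation with each other differs between AL and DR. The primary
statistic is the ANCOVA slope-heterogeneity F: regress one feature on the
other with diet-specific intercepts and slopes and F-test the diet x slope
interaction with df (1, n - 4). A Fisher r-to-z difference test is provided
as a descriptive cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureMatrix, align_design
from .exceptions import DegeneratePredictorError, InsufficientDataError

from .models import bh_adjust, diet_codes, fit_effects


# ---------------------------------------------------------------------------
# single-pair ANCOVA
# ---------------------------------------------------------------------------

def _group_sums(x: np.ndarray, y: np.ndarray, g: np.ndarray):
    """Per-group centred sums of squares/cross-products."""
    out = []
    for level in (0.0, 1.0):
        sel = g == level
        xs, ys = x[sel], y[sel]
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        out.append(((xs * xs).sum(), (ys * ys).sum(), (xs * ys).sum(), sel.sum()))
    return out


def pair_ancova(yi, yj, diet) -> tuple[float, tuple[int, int], float]:
    """Slope-heterogeneity F for a feature pair across the two diets.

    The higher-variance feature is used as the covariate (x) and the other
    as the response; ties break toward ``yi`` as covariate. Returns
    ``(F, (1, n - 4), p)``.
    """
    yi = np.asarray(yi, float)
    yj = np.asarray(yj, float)
    diet = np.asarray(diet)
    if np.isnan(yi).any() or np.isnan(yj).any():
        raise InsufficientDataError("missing values not allowed in pair_ancova")
    g = np.asarray([1.0 if d in ("DR", 1, 1.0, True) else 0.0 for d in diet])
    if min((g == 0).sum(), (g == 1).sum()) < 3:
        raise InsufficientDataError("need >= 3 samples per diet")
    # orientation: larger variance -> covariate
    if np.var(yj) > np.var(yi):
        x, y = yj, yi
    else:
        x, y = yi, yj
    n = len(x)
    sums = _group_sums(x, y, g)
    if any(s[0] == 0 for s in sums):
        raise DegeneratePredictorError("covariate constant within a diet")
    rss_full = sum(syy - sxy**2 / sxx for sxx, syy, sxy, _ in sums)
    sxx_t = sum(s[0] for s in sums)
    syy_t = sum(s[1] for s in sums)
    sxy_t = sum(s[2] for s in sums)
    rss_red = syy_t - sxy_t**2 / sxx_t
    df2 = n - 4
    num = max(rss_red - rss_full, 0.0)
    if rss_full <= 1e-300:
        F = 0.0 if num <= 1e-300 else np.inf
    else:
        F = num / (rss_full / df2)
    p = float(stats.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
    return float(F), (1, df2), p


def fisher_z_difference(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z two-sample correlation difference test: (z, p)."""
    z1 = np.arctanh(np.clip(r1, -0.999999, 0.999999))
    z2 = np.arctanh(np.clip(r2, -0.999999, 0.999999))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# matrix-wide screen
# ---------------------------------------------------------------------------

@dataclass
class PairCorrScreen:
    """Result of the differential-pair screen."""

    pairs: pd.DataFrame        # i, j, r_AL, r_DR, F, df2, p, q, gate_p_i, gate_p_j
    gate_passed: pd.Index      # features whose diet-effect p exceeded the gate
    n_tested: int


def _condition_stats(X: np.ndarray, sel: np.ndarray):
    """Gram matrix and diagonal of centred data for one diet."""
    Xc = X[:, sel] - X[:, sel].mean(axis=1, keepdims=True)
    S = Xc @ Xc.T
    return S, np.diag(S).copy(), sel.sum()


def screen_differential_pairs(m: FeatureMatrix, design: pd.DataFrame,
                              mean_gate_alpha: float = 0.05, fdr: float = 0.05,
                              min_abs_corr_diff: float | None = None,
                              max_pairs: int | None = None,
                              seed: int | None = None) -> PairCorrScreen:
    """Screen all mean-invariant feature pairs for diet-dependent correlation.

    Candidate features must have diet-effect p > ``mean_gate_alpha``
    (unadjusted, per the mean-invariance requirement). Every candidate pair
    is tested with the vectorised ANCOVA interaction F; BH-FDR is applied
    across tested pairs. ``min_abs_corr_diff`` optionally pre-filters pairs
    by |r_AL - r_DR| and ``max_pairs`` subsamples candidates (seeded); both
    trade completeness for speed and skew the FDR calibration, so they are
    off by default.
    """
    d = align_design(m, design)
    g = diet_codes(d)
    gate = fit_effects(m, g, predictor="diet")
    passed = gate.index[gate["p"] > mean_gate_alpha]
    if len(passed) < 2:
        return PairCorrScreen(pairs=_empty_pairs(), gate_passed=passed, n_tested=0)

    sub = m.subset_features(passed)
    X = sub.values.to_numpy(dtype=float)
    n = X.shape[1]
    df2 = n - 4

    S_al, sxx_al, n_al = _condition_stats(X, g == 0.0)
    S_dr, sxx_dr, n_dr = _condition_stats(X, g == 1.0)
    if min(n_al, n_dr) < 3:
        raise InsufficientDataError("need >= 3 samples per diet")

    with np.errstate(divide="ignore", invalid="ignore"):
        r_al = S_al / np.sqrt(np.outer(sxx_al, sxx_al))
        r_dr = S_dr / np.sqrt(np.outer(sxx_dr, sxx_dr))

        # F for response j / covariate i (row i = covariate):
        def f_matrix(Scov_al, Scov_dr):
            rss_full = (Scov_al["syy"] - Scov_al["sxy"]**2 / Scov_al["sxx"]
                        + Scov_dr["syy"] - Scov_dr["sxy"]**2 / Scov_dr["sxx"])
            sxx_t = Scov_al["sxx"] + Scov_dr["sxx"]
            sxy_t = Scov_al["sxy"] + Scov_dr["sxy"]
            syy_t = Scov_al["syy"] + Scov_dr["syy"]
            rss_red = syy_t - sxy_t**2 / sxx_t
            return np.clip(rss_red - rss_full, 0.0, None) / (rss_full / df2)

        # covariate i (rows), response j (cols)
        F_ij = f_matrix(
            {"sxx": sxx_al[:, None], "syy": sxx_al[None, :], "sxy": S_al},
            {"sxx": sxx_dr[:, None], "syy": sxx_dr[None, :], "sxy": S_dr})

    # orientation: covariate = larger total variance; tie -> lower index covariate
    var_tot = X.var(axis=1)
    iu, ju = np.triu_indices(len(passed), k=1)
    cov_is_i = var_tot[iu] > var_tot[ju]
    ties = var_tot[iu] == var_tot[ju]
    cov_is_i |= ties                                  # id tie-break: i is covariate
    F = np.where(cov_is_i, F_ij[iu, ju], F_ij[ju, iu])

    pairs = pd.DataFrame({
        "i": passed[iu], "j": passed[ju],
        "r_AL": r_al[iu, ju], "r_DR": r_dr[iu, ju],
        "F": F, "df2": df2,
        "gate_p_i": gate.loc[passed[iu], "p"].to_numpy(),
        "gate_p_j": gate.loc[passed[ju], "p"].to_numpy(),
    })

    if min_abs_corr_diff is not None:
        pairs = pairs[(pairs["r_AL"] - pairs["r_DR"]).abs() >= min_abs_corr_diff]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        pairs = pairs.iloc[np.sort(rng.choice(len(pairs), max_pairs, replace=False))]

    pairs = pairs.copy()
    pairs["p"] = stats.f.sf(pairs["F"], 1, df2)
    if len(pairs):
        q, _ = bh_adjust(pairs["p"].to_numpy(), fdr)
        pairs["q"] = q
        pairs = pairs.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    else:
        pairs["q"] = np.array([], dtype=float)
    return PairCorrScreen(pairs=pairs, gate_passed=passed, n_tested=len(pairs))


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=["i", "j", "r_AL", "r_DR", "F", "df2",
                                 "gate_p_i", "gate_p_j", "p", "q"])
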