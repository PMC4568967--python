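"""Putative metabolite annotation by m/z matching and metabolite-set enrichment.

Untargeted LC-MS features carry no identity; an observed m/z is matched to a
reference metabolite's neutral monoisotopic mass M through a set of adducts
(e.g. M+H at +1.007276 Da) within a ppm tolerance, keeping every candidate.
Feature lists (diet-responsive features, network modules) are then tested for
over-representation of named metabolite sets with the hypergeometric
upper-tail test, after collapsing many-to-many feature/metabolite matches to
unique metabolites. A cross-condition frequency table summarises in how many
tissue/age analyses each set was enriched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DataError

#: default adduct mass offsets (Da) mapping neutral mass M to observed m/z
DEFAULT_ADDUCTS = {
    "M+H": 1.007276,
    "M+Na": 22.989218,
    "M+K": 38.963158,
    "M-H": -1.007276,
    "M+": -0.000549,      # electron loss
}


# ---------------------------------------------------------------------------
# reference I/O
# ---------------------------------------------------------------------------

def read_reference(path: str | Path) -> pd.DataFrame:
    """Read a metabolite reference TSV with columns metabolite, monoisotopic_mass."""
    ref = pd.read_csv(path, sep="\t")
    required = {"metabolite", "monoisotopic_mass"}
    if not required <= set(ref.columns):
        raise DataError(f"reference must have columns {sorted(required)}")
    return ref


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read pathway sets in GMT format (name, description, members...)."""
    from gseapy.parser import read_gmt as _read_gmt
    return {name: list(members) for name, members in _read_gmt(str(path)).items()}


# ---------------------------------------------------------------------------
# m/z annotation
# ---------------------------------------------------------------------------

def annotate_mz(features: pd.DataFrame, reference: pd.DataFrame,
                adducts: dict[str, float] | None = None,
                ppm: float = 10.0) -> pd.DataFrame:
    """Match feature m/z values to reference metabolites through adducts.

    Parameters
    ----------
    features
        DataFrame indexed by feature_id with an ``mz`` column (Da).
    reference
        DataFrame with ``metabolite`` and ``monoisotopic_mass`` columns.
    adducts
        Mapping adduct name -> mass offset added to the neutral mass.
    ppm
        Relative tolerance: a match requires |mz - expected| <= ppm * 1e-6 *
        expected.

    Returns
    -------
    DataFrame with one row per (feature, metabolite, adduct) candidate and
    the signed ppm error; ambiguous matches are all retained.
    """
    if reference.empty:
        raise ConfigError("empty metabolite reference")
    if (reference["monoisotopic_mass"] <= 0).any():
        raise DataError("monoisotopic masses must be positive")
    adducts = DEFAULT_ADDUCTS if adducts is None else adducts

    mz = features["mz"].to_numpy(dtype=float)
    fids = features.index.to_numpy()
    rows = []
    tol = ppm * 1e-6
    for adduct, offset in adducts.items():
        expected = reference["monoisotopic_mass"].to_numpy(dtype=float) + offset
        valid = expected > 0
        exp_sorted_idx = np.argsort(expected[valid])
        exp_sorted = expected[valid][exp_sorted_idx]
        met_sorted = reference["metabolite"].to_numpy()[valid][exp_sorted_idx]
        # expected mass window containing matches for each observed m/z
        lo = np.searchsorted(exp_sorted, mz / (1.0 + tol), side="left")
        hi = np.searchsorted(exp_sorted, mz / (1.0 - tol), side="right")
        for f_idx in np.where(hi > lo)[0]:
            for r_idx in range(lo[f_idx], hi[f_idx]):
                err = (mz[f_idx] - exp_sorted[r_idx]) / exp_sorted[r_idx] * 1e6
                if abs(err) <= ppm:
                    rows.append((fids[f_idx], met_sorted[r_idx], adduct, err))
    out = pd.DataFrame(rows, columns=["feature_id", "metabolite", "adduct",
                                      "ppm_error"])
    return out.sort_values(["feature_id", "metabolite", "adduct"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# hypergeometric set enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus the universe bookkeeping."""

    table: pd.DataFrame          # set, overlap, set_size, query_size, universe, p, q
    n_universe_metabolites: int
    n_query_metabolites: int


def _features_to_metabolites(feature_ids, annotation: pd.DataFrame) -> set[str]:
    sel = annotation["feature_id"].isin(set(feature_ids))
    return set(annotation.loc[sel, "metabolite"])


def set_enrichment(query, annotation: pd.DataFrame,
                   sets: dict[str, list[str]], universe,
                   fdr: float = 0.05) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of metabolite sets in a query list.

    ``query`` and ``universe`` are feature-id collections (query must be a
    subset of the universe); features collapse to unique metabolites through
    ``annotation`` before counting, so a metabolite matched by several
    features counts once. p = P(X >= overlap) with X hypergeometric on the
    metabolite universe; BH-FDR across sets.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise DataError("empty universe")
    if not query <= universe:
        raise DataError("query must be a subset of the universe")
    uni_mets = _features_to_metabolites(universe, annotation)
    qry_mets = _features_to_metabolites(query, annotation)
    N, n = len(uni_mets), len(qry_mets)
    if N == 0:
        raise DataError("no annotated features in the universe")

    rows = []
    for name, members in sets.items():
        in_uni = set(members) & uni_mets
        K = len(in_uni)
        k = len(in_uni & qry_mets)
        # P(X >= k); k = 0 is certain, so p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N, "p": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                        "query_size", "universe_size", "p"])
    if len(table):
        from .models import bh_adjust
        q, _ = bh_adjust(table["p"].to_numpy(), fdr)
        table["q"] = q
        table = table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        table["q"] = np.array([], dtype=float)
    return EnrichmentResult(table=table, n_universe_metabolites=N,
                            n_query_metabolites=n)


# ---------------------------------------------------------------------------
# cross-condition frequency summary
# ---------------------------------------------------------------------------

def summarize_frequency(per_condition: dict[str, list[str] | set[str]]
                        ) -> pd.DataFrame:
    """Cross-condition enrichment frequency table.

    ``per_condition`` maps a condition label (e.g. 'Thorax10') to the set
    names enriched there. Returns a DataFrame with one row per set enriched
    anywhere, an 'X' mark per condition column, and a Frequency column,
    sorted by decreasing frequency then set name. Sets enriched nowhere are
    omitted.
    """
    conditions = list(per_condition)
    all_sets = sorted({s for names in per_condition.values() for s in names})
    rows = []
    for s in all_sets:
        marks = {c: ("X" if s in set(per_condition[c]) else "") for c in conditions}
        freq = sum(1 for c in conditions if marks[c] == "X")
        rows.append({"set": s, **marks, "Frequency": freq})
    out = pd.DataFrame(rows, columns=["set"] + conditions + ["Frequency"])
    return out.sort_values(["Frequency", "set"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)
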