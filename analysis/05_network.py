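"""Differential (DiffCoEx) and preserved (SimCoEx) correlation-network
analysis of the clean matrix.

Splits features into diet-differential and diet-similar correlation classes,
clusters the difference matrix of the differential set and the constancy
matrix of the similar set (TOM -> average linkage -> silhouette-guided cut),
permutation-tests module dispersion, and tests the global correlation shift
between DR and AL and between young and old within each diet.
"""

from pathlib import Path

import pandas as pd

from metanetdiff import models, network
from metanetdiff.data import FeatureMatrix

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    qcdir = ROOT / "results" / "qc"
    clean = FeatureMatrix.from_tsv(qcdir / "clean.tsv", scale="centered")
    bd = pd.read_csv(qcdir / "bio_metadata.tsv", sep="\t")
    outdir = ROOT / "results" / "network"
    outdir.mkdir(parents=True, exist_ok=True)

    # batch structure induces correlation between every feature pair; remove
    # it (preserving diet and age) before any correlation-network inference
    meta_all = bd.set_index("sample_id").loc[clean.sample_ids]
    clean = models.batch_adjust(clean, meta_all.batch, meta_all[["diet", "age"]])

    by_diet = network.condition_correlations(clean, bd, "diet")
    al, dr = by_diet["AL"], by_diet["DR"]
    diff_ids, sim_ids = network.differential_feature_selection(al, dr, alpha=0.01)
    print(f"diet-differential features: {len(diff_ids)}; "
          f"diet-similar: {len(sim_ids)}")

    meta = bd.set_index("sample_id")
    cols_al = [s for s in clean.sample_ids if meta.loc[s, "diet"] == "AL"]
    cols_dr = [s for s in clean.sample_ids if meta.loc[s, "diet"] == "DR"]

    if len(diff_ids) >= 10:
        sub = clean.subset_features(diff_ids)
        adj = network.condition_correlations(sub, bd, "diet")
        D = network.difference_matrix(adj["AL"], adj["DR"], beta_soft=6)
        mods = network.cluster_modules(network.tom_dissimilarity(D), min_size=10)
        disp = network.module_dispersion_test(
            sub.values[cols_al], sub.values[cols_dr], mods,
            beta_soft=6, n_perm=1000, seed=SEED)
        mods = network.filter_modules_by_dispersion(mods, disp)
        mods.labels.to_csv(outdir / "diffcoex_modules.tsv", sep="\t")
        disp.to_csv(outdir / "diffcoex_dispersion.tsv", sep="\t", index=False)
        print(f"DiffCoEx modules (dispersion-validated): "
              f"{ {c: mods.sizes[c] for c in mods.module_colors} }")

    if len(sim_ids) >= 10:
        sub = clean.subset_features(sim_ids)
        adj = network.condition_correlations(sub, bd, "diet")
        K = network.constancy_matrix(adj["AL"], adj["DR"], beta_soft=6)
        mods = network.cluster_modules(network.tom_dissimilarity(K), min_size=10)
        mods.labels.to_csv(outdir / "simcoex_modules.tsv", sep="\t")
        print(f"SimCoEx modules: { {c: mods.sizes[c] for c in mods.module_colors} }")

    subset = diff_ids if len(diff_ids) >= 3 else None
    mean_dr, mean_al, p = network.correlation_shift_test(
        dr, al, feature_subset=subset, seed=SEED,
        samples_a=clean.values[cols_dr], samples_b=clean.values[cols_al])
    rows = [{"comparison": "DR_vs_AL", "mean_corr_DR": mean_dr,
             "mean_corr_AL": mean_al, "p": p}]
    print(f"mean correlation DR {mean_dr:.3f} vs AL {mean_al:.3f} (p = {p:.3g})")

    ages = sorted(bd.age.unique())
    for diet in ("DR", "AL"):
        sel = bd[(bd.diet == diet) & bd.age.isin((min(ages), max(ages)))]
        sub = clean.subset_samples([s for s in clean.sample_ids
                                    if s in set(sel.sample_id)])
        by_age = network.condition_correlations(sub, sel, "age", quantile_norm=True)
        young, old = by_age[str(min(ages))], by_age[str(max(ages))]
        cols_y = [s for s in sub.sample_ids if meta.loc[s, "age"] == min(ages)]
        cols_o = [s for s in sub.sample_ids if meta.loc[s, "age"] == max(ages)]
        mo, my, p = network.correlation_shift_test(
            old, young, seed=SEED,
            samples_a=sub.values[cols_o], samples_b=sub.values[cols_y])
        rows.append({"comparison": f"{diet}_old_vs_young", "mean_corr_old": mo,
                     "mean_corr_young": my, "p": p})
        print(f"{diet}: mean correlation young {my:.3f} -> old {mo:.3f} (p = {p:.3g})")
    pd.DataFrame(rows).to_csv(outdir / "correlation_summary.tsv",
                              sep="\t", index=False)

    edges = network.edge_list(dr, al, threshold=0.5)
    strongest = edges.reindex(
        edges[["r_DR", "r_AL"]].abs().max(axis=1)
        .sort_values(ascending=False).index)
    strongest.head(2000).to_csv(outdir / "edges.tsv", sep="\t", index=False)
    network.write_graphml(strongest.head(2000), outdir / "edges.graphml")
    print(f"{len(edges)} edges with |r| > 0.5 (strongest 2000 exported)")


if __name__ == "__main__":
    main()
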