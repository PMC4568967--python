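"""Metabolite-set enrichment of diet-responsive feature lists.

Features are annotated by matching m/z to reference monoisotopic masses
through standard adducts at 10 ppm; per-age increased/decreased lists are
tested against the pathway sets with the hypergeometric upper tail; the
cross-condition frequency table counts in how many condition analyses each
set is enriched (q <= 0.05).
"""

from pathlib import Path

import pandas as pd

from metanetdiff import enrich, models
from metanetdiff.data import FeatureMatrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    qcdir = ROOT / "results" / "qc"
    clean = FeatureMatrix.from_tsv(qcdir / "clean.tsv", scale="centered")
    bd = pd.read_csv(qcdir / "bio_metadata.tsv", sep="\t")
    sim = ROOT / "results" / "sim"
    reference = enrich.read_reference(sim / "metabolite_reference.tsv")
    sets = enrich.read_gmt(sim / "pathways.gmt")

    annotation = enrich.annotate_mz(clean.features, reference, ppm=10.0)
    print(f"annotated {annotation.feature_id.nunique()} of {clean.n_features} "
          f"features ({len(annotation)} candidate matches)")

    tissue = bd.tissue.iloc[0].capitalize()
    per_condition, tables = {}, []
    condition_fits = [(a, models.fit_diet_effects(clean, bd, age=a))
                      for a in sorted(bd.age.unique())]
    condition_fits.append(("All", models.fit_diet_effects(clean, bd)))
    for age, eff in condition_fits:
        q, sig = models.bh_adjust(eff.p.to_numpy(), 0.05)
        for direction, mask in (("decreased", sig & (eff.beta < 0)),
                                ("increased", sig & (eff.beta > 0))):
            label = f"{tissue}{age}_{direction}"
            res = enrich.set_enrichment(eff.index[mask], annotation, sets,
                                        clean.feature_ids, fdr=0.05)
            tables.append(res.table.assign(condition=label))
            per_condition[label] = list(
                res.table.loc[res.table.q <= 0.05, "set"])

    outdir = ROOT / "results" / "enrich"
    outdir.mkdir(parents=True, exist_ok=True)
    pd.concat(tables).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    freq = enrich.summarize_frequency(per_condition)
    freq.to_csv(outdir / "enrichment_frequency.tsv", sep="\t", index=False)

    print("conditions with enriched sets:",
          {k: v for k, v in per_condition.items() if v})
    if len(freq):
        print("frequency table (top rows):")
        print(freq.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
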