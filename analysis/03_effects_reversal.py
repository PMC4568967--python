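"""Per-feature diet and age effects, and the diet-reverses-age quadrant plot
data.

Fits y = mu + beta*x per feature (diet coded AL=0/DR=1 at the oldest age;
age in days on AL between the youngest and oldest ages) after ComBat batch
adjustment, classifies features into reversal/exacerbation quadrants at
FDR 0.025, counts per-age diet-responsive features at P < 0.01 for the Venn
comparison, and writes PCA sample scores.
"""

from pathlib import Path

import pandas as pd

from metanetdiff import models
from metanetdiff.data import FeatureMatrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    qcdir = ROOT / "results" / "qc"
    clean = FeatureMatrix.from_tsv(qcdir / "clean.tsv", scale="centered")
    bd = pd.read_csv(qcdir / "bio_metadata.tsv", sep="\t")
    ages = sorted(bd.age.unique())

    meta = bd.set_index("sample_id").loc[clean.sample_ids]
    adjusted = models.batch_adjust(clean, meta.batch, meta[["diet", "age"]])

    diet_eff = models.fit_diet_effects(adjusted, bd, age=max(ages))
    age_eff = models.fit_age_effects(adjusted, bd, diet="AL",
                                     ages=(min(ages), max(ages)))
    rev = models.reversal_classification(diet_eff, age_eff, fdr=0.025)

    venn_sets = {}
    for a in ages:
        eff = models.fit_diet_effects(adjusted, bd, age=a)
        venn_sets[f"age{a}"] = set(eff.index[eff.p < 0.01])
    venn = models.tissue_overlap_counts(venn_sets)
    scores, evr = models.pca_scores(adjusted, n_components=2)

    outdir = ROOT / "results" / "models"
    outdir.mkdir(parents=True, exist_ok=True)
    rev.table.to_csv(outdir / "reversal.tsv", sep="\t")
    pd.DataFrame([{"region": "+".join(k), "count": v} for k, v in venn.items()]) \
        .to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)
    scores.join(meta[["diet", "age"]]).to_csv(outdir / "pca_scores.tsv", sep="\t")

    c = rev.counts
    print(f"diet-responsive at P<0.01 per age: "
          f"{ {k: len(v) for k, v in venn_sets.items()} }")
    print(f"doubly-significant features (FDR 0.025): {c['both_significant']}; "
          f"reversal {c['reversal']} vs exacerbation {c['exacerbation']}")
    print(f"PC1/PC2 explained variance: {evr[0]:.2f} / {evr[1]:.2f}")


if __name__ == "__main__":
    main()
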