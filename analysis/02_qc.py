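"""Quality control of the simulated feature table.

Chain: log2 transform -> connectivity-based outlier samples (Z_k < -3) ->
SNR >= 20 filter against technical-replicate noise -> technical-replicate
collapse -> <= 10% missingness filter -> kNN imputation -> mean-centring.
Writes results/qc/clean.tsv plus a per-feature QC report.
"""

from pathlib import Path

import pandas as pd

from metanetdiff import qc
from metanetdiff.data import FeatureMatrix, bio_design

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    sim = ROOT / "results" / "sim"
    raw = FeatureMatrix.from_tsv(sim / "feature_table.tsv")
    design = pd.read_csv(sim / "sample_metadata.tsv", sep="\t")

    logged = qc.log_transform(raw)
    outliers = qc.detect_outlier_samples(logged, z_cut=-3.0)
    logged = qc.drop_samples(logged, outliers.flagged)
    design_kept = design[design.sample_id.isin(logged.sample_ids)]
    kept, stats = qc.snr_filter(logged, design_kept, threshold=20.0)
    collapsed = qc.collapse_tech_reps(kept, design_kept)
    filtered = qc.missingness_filter(collapsed, max_frac=0.10)
    imputed = qc.impute(filtered, method="knn", k=10, seed=SEED)
    clean = qc.center_features(imputed)

    outdir = ROOT / "results" / "qc"
    outdir.mkdir(parents=True, exist_ok=True)
    clean.to_tsv(outdir / "clean.tsv")
    bio_design(design_kept).to_csv(outdir / "bio_metadata.tsv", sep="\t", index=False)
    report = stats.table.copy()
    report["removed_snr"] = report.index.isin(stats.removed(20.0))
    report["removed_missing"] = (~report.index.isin(filtered.feature_ids)
                                 & ~report["removed_snr"])
    report.to_csv(outdir / "qc_report.tsv", sep="\t")

    print(f"outlier samples flagged: {len(outliers.flagged)} "
          f"(min Z_k = {outliers.z_k.min():.2f})")
    print(f"SNR filter: {raw.n_features} -> {kept.n_features} features")
    print(f"missingness filter: {collapsed.n_features} -> {filtered.n_features}")
    print(f"clean matrix: {clean.n_features} features x {clean.n_samples} "
          f"biological samples -> {outdir / 'clean.tsv'}")


if __name__ == "__main__":
    main()
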