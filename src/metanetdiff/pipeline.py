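"""End-to-end orchestration: synthetic data -> QC -> effect models ->
differential pairs -> correlation networks -> enrichment, with a manifest.

Every stage logs features/samples in and out into a JSON manifest so the
bookkeeping (features_out of one stage == features_in of the next) can be
audited, and a single global seed fans out to fixed per-stage offsets so
stages are independently re-runnable and the whole replay is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import FeatureMatrix, bio_design
from .exceptions import ConfigError, DataError
from . import enrich, models, network, paircorr, qc, synth

#: fixed per-stage seed offsets (keeps stages independently re-runnable)
STAGE_SEEDS = {"synth": 0, "qc": 11, "models": 23, "paircorr": 37,
               "network": 53, "enrich": 71}


@dataclass
class PipelineConfig:
    """All thresholds and paths of the replay, with study defaults.

    QC: SNR >= 20, <= 10% missing, outlier cut Z_k < -3, kNN imputation.
    Models: Venn lists at raw P < 0.01, reversal quadrants at FDR 0.025,
    everything else at FDR 0.05. Networks: soft power 6, minimum module size
    10, 1000 condition permutations.
    """

    outdir: str = "results/pipeline"
    feature_table: str | None = None
    metadata: str | None = None
    reference: str | None = None
    sets: str | None = None
    simulate: bool = True
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    # qc
    snr: float = 20.0
    max_missing: float = 0.10
    zcut: float = -3.0
    impute_method: str = "knn"
    impute_k: int = 10
    log_base: float = 2.0
    pseudocount: float = 1.0
    # models
    venn_p: float = 0.01
    reversal_fdr: float = 0.025
    default_fdr: float = 0.05
    # paircorr
    mean_gate: float = 0.05
    max_pairs: int | None = None
    # network
    beta_soft: int = 6
    min_module: int = 10
    n_perm: int = 1000
    corr_alpha: float = 0.01
    max_network_features: int = 600
    edge_threshold: float = 0.5
    # enrichment
    ppm: float = 10.0
    enrich_q: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing <= 1):
            raise ConfigError("max_missing outside [0, 1]")
        for name in ("venn_p", "reversal_fdr", "default_fdr", "mean_gate",
                     "enrich_q", "corr_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name}={v} outside (0, 1)")
        if isinstance(self.synth, dict):
            ms = self.synth.pop("module_specs", None)
            cfg = synth.SynthConfig(**self.synth)
            if ms is not None:
                cfg = cfg.replace(module_specs=tuple(
                    synth.ModuleSpec(**m) if isinstance(m, dict) else m for m in ms))
            self.synth = cfg

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + STAGE_SEEDS[stage]) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["synth"]["module_specs"] = [dataclasses.asdict(m)
                                      for m in self.synth.module_specs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class PipelineResult:
    """Everything run_full produced, for programmatic use."""

    manifest: dict
    clean: FeatureMatrix
    design: pd.DataFrame
    truth: synth.GroundTruth | None
    diet_effects: pd.DataFrame
    age_effects: pd.DataFrame
    reversal: models.ReversalTable
    pair_screen: paircorr.PairCorrScreen
    diff_modules: network.ModuleAssignment | None
    sim_modules: network.ModuleAssignment | None
    dispersion: pd.DataFrame | None
    enrichment: dict[str, enrich.EnrichmentResult]
    frequency: pd.DataFrame


def _stage(manifest: dict, name: str, f_in: int, s_in: int,
           f_out: int, s_out: int, **params) -> None:
    manifest["stages"].append({
        "stage": name, "features_in": f_in, "samples_in": s_in,
        "features_out": f_out, "samples_out": s_out, "params": params,
    })


def run_full(config: PipelineConfig) -> PipelineResult:
    """Execute the full replay and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }

    # ---- stage 1: synthetic data (or load) --------------------------------
    truth = None
    if config.simulate:
        scfg = config.synth.replace(seed=config.stage_seed("synth"))
        design = synth.make_design(scfg)
        raw, truth = synth.simulate_features(design, scfg)
        synth.write_simulation(outdir / "sim", design, raw, truth)
        reference, sets = synth.simulate_reference(raw, truth, scfg)
        reference.to_csv(outdir / "sim" / "metabolite_reference.tsv",
                         sep="\t", index=False)
        synth.write_gmt(sets, outdir / "sim" / "pathways.gmt")
    else:
        if not (config.feature_table and config.metadata):
            raise ConfigError("feature_table and metadata required without --simulate")
        raw = FeatureMatrix.from_tsv(config.feature_table)
        design = pd.read_csv(config.metadata, sep="\t")
        if config.reference is None or config.sets is None:
            raise ConfigError("reference and sets required without --simulate")
        reference = enrich.read_reference(config.reference)
        sets = enrich.read_gmt(config.sets)
    _stage(manifest, "synth", raw.n_features, raw.n_samples,
           raw.n_features, raw.n_samples, simulate=config.simulate)

    # ---- stage 2: QC -------------------------------------------------------
    f_in, s_in = raw.n_features, raw.n_samples
    logged = qc.log_transform(raw, base=config.log_base,
                              pseudocount=config.pseudocount)
    outliers = qc.detect_outlier_samples(logged, z_cut=config.zcut)
    flagged_bio = set(design.set_index("sample_id").loc[outliers.flagged, "bio_id"]) \
        if outliers.flagged else set()
    drop_cols = design.loc[design["bio_id"].isin(flagged_bio), "sample_id"]
    logged = qc.drop_samples(logged, drop_cols)
    snr_kept, snr_stats = qc.snr_filter(logged, design, threshold=config.snr)
    collapsed = qc.collapse_tech_reps(snr_kept, design)
    bdesign = bio_design(design)
    bdesign = bdesign[bdesign["sample_id"].isin(collapsed.sample_ids)].reset_index(drop=True)
    filtered = qc.missingness_filter(collapsed, max_frac=config.max_missing)
    imputed = qc.impute(filtered, method=config.impute_method, k=config.impute_k,
                        seed=config.stage_seed("qc"))
    clean = qc.center_features(imputed)
    if clean.n_features == 0:
        raise DataError("QC removed every feature; nothing to model")
    clean.to_tsv(outdir / "clean.tsv")
    report = snr_stats.table.copy()
    report["removed_snr"] = report.index.isin(snr_stats.removed(config.snr))
    report["removed_missing"] = ~report.index.isin(filtered.feature_ids) & \
        ~report["removed_snr"]
    report.to_csv(outdir / "qc_report.tsv", sep="\t")
    pd.DataFrame({"Z_k": outliers.z_k,
                  "flagged": outliers.z_k.index.isin(outliers.flagged)}
                 ).to_csv(outdir / "qc_outliers.tsv", sep="\t")
    _stage(manifest, "qc", f_in, s_in, clean.n_features, clean.n_samples,
           snr=config.snr, max_missing=config.max_missing, zcut=config.zcut,
           impute=config.impute_method, n_outlier_samples=len(flagged_bio))

    # ---- stage 3: effect models -------------------------------------------
    ages = sorted(bdesign["age"].unique())
    adjusted = clean
    if bdesign["batch"].nunique() > 1:
        covars = bdesign.set_index("sample_id").loc[clean.sample_ids,
                                                    ["diet", "age"]]
        adjusted = models.batch_adjust(clean, bdesign.set_index("sample_id")
                                       .loc[clean.sample_ids, "batch"], covars)
    diet_effects = models.fit_diet_effects(adjusted, bdesign, age=max(ages))
    if len(ages) > 1:
        age_effects = models.fit_age_effects(adjusted, bdesign, diet="AL",
                                             ages=(min(ages), max(ages)))
    else:
        age_effects = diet_effects.copy()
    reversal = models.reversal_classification(diet_effects, age_effects,
                                              fdr=config.reversal_fdr)
    reversal.table.to_csv(outdir / "reversal.tsv", sep="\t")

    per_age_effects = {a: models.fit_diet_effects(adjusted, bdesign, age=a)
                       for a in ages}
    venn_sets = {f"age{a}": set(e.index[e["p"] < config.venn_p])
                 for a, e in per_age_effects.items()}
    effects_long = pd.concat(
        [e.assign(age=a) for a, e in per_age_effects.items()])
    effects_long["q"] = np.concatenate(
        [models.bh_adjust(e["p"].to_numpy(), config.default_fdr)[0]
         for e in per_age_effects.values()])
    effects_long.to_csv(outdir / "effects.tsv", sep="\t")
    if len(venn_sets) >= 2:
        venn = models.tissue_overlap_counts(venn_sets)
        pd.DataFrame([{"region": "+".join(k), "count": v}
                      for k, v in venn.items()]
                     ).to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)
    scores, evr = models.pca_scores(adjusted, n_components=2)
    scores.assign(explained_1=evr[0], explained_2=evr[-1]) \
        .to_csv(outdir / "pca_scores.tsv", sep="\t")
    _stage(manifest, "models", clean.n_features, clean.n_samples,
           clean.n_features, clean.n_samples,
           venn_p=config.venn_p, reversal_fdr=config.reversal_fdr,
           n_reversal=reversal.counts["reversal"],
           n_exacerbation=reversal.counts["exacerbation"])

    # ---- stage 4: differential pairs --------------------------------------
    screen = paircorr.screen_differential_pairs(
        adjusted, bdesign, mean_gate_alpha=config.mean_gate,
        fdr=config.default_fdr, max_pairs=config.max_pairs,
        seed=config.stage_seed("paircorr"))
    screen.pairs.head(5000).to_csv(outdir / "paircorr.tsv", sep="\t", index=False)
    _stage(manifest, "paircorr", clean.n_features, clean.n_samples,
           clean.n_features, clean.n_samples,
           mean_gate=config.mean_gate, n_gate_passed=len(screen.gate_passed),
           n_tested=screen.n_tested,
           n_flagged=int((screen.pairs["q"] <= config.default_fdr).sum())
           if len(screen.pairs) else 0)

    # ---- stage 5: networks --------------------------------------------------
    rng = np.random.default_rng(config.stage_seed("network"))
    net_matrix = adjusted
    if net_matrix.n_features > config.max_network_features:
        keep = np.sort(rng.choice(net_matrix.n_features,
                                  config.max_network_features, replace=False))
        net_matrix = net_matrix.subset_features(net_matrix.feature_ids[keep])
    by_diet = network.condition_correlations(net_matrix, bdesign, "diet")
    al, dr = by_diet["AL"], by_diet["DR"]
    diff_ids, sim_ids = network.differential_feature_selection(
        al, dr, alpha=config.corr_alpha)

    diff_modules = sim_modules = None
    dispersion = None
    d_bd = bdesign.set_index("sample_id").loc[net_matrix.sample_ids]
    cols_al = d_bd.index[d_bd["diet"] == "AL"]
    cols_dr = d_bd.index[d_bd["diet"] == "DR"]
    if len(diff_ids) >= config.min_module:
        sub = net_matrix.subset_features(diff_ids)
        sub_by_diet = network.condition_correlations(sub, bdesign, "diet")
        D = network.difference_matrix(sub_by_diet["AL"], sub_by_diet["DR"],
                                      beta_soft=config.beta_soft)
        diff_modules = network.cluster_modules(network.tom_dissimilarity(D),
                                               min_size=config.min_module)
        dispersion = network.module_dispersion_test(
            sub.values[list(cols_al)], sub.values[list(cols_dr)], diff_modules,
            beta_soft=config.beta_soft, n_perm=config.n_perm,
            seed=config.stage_seed("network"))
        dispersion.to_csv(outdir / "diffcoex_dispersion.tsv", sep="\t", index=False)
        diff_modules.labels.to_csv(outdir / "diffcoex_modules.tsv", sep="\t")
    if len(sim_ids) >= config.min_module:
        sub = net_matrix.subset_features(sim_ids)
        sub_by_diet = network.condition_correlations(sub, bdesign, "diet")
        K = network.constancy_matrix(sub_by_diet["AL"], sub_by_diet["DR"],
                                     beta_soft=config.beta_soft)
        sim_modules = network.cluster_modules(network.tom_dissimilarity(K),
                                              min_size=config.min_module)
        sim_modules.labels.to_csv(outdir / "simcoex_modules.tsv", sep="\t")

    shift = network.correlation_shift_test(
        dr, al, feature_subset=diff_ids if len(diff_ids) >= 3 else None,
        seed=config.stage_seed("network"),
        samples_a=net_matrix.values[list(cols_dr)],
        samples_b=net_matrix.values[list(cols_al)])
    corr_summary = [{"comparison": "DR_vs_AL", "mean_corr_a": shift[0],
                     "mean_corr_b": shift[1], "p": shift[2]}]

    # age trajectories within each diet (quantile-normalized, min vs max age)
    if len(ages) > 1:
        for diet in ("DR", "AL"):
            sub_design = bdesign[(bdesign["diet"] == diet)
                                 & bdesign["age"].isin((min(ages), max(ages)))]
            sub = net_matrix.subset_samples(
                [s for s in net_matrix.sample_ids
                 if s in set(sub_design["sample_id"])])
            by_age = network.condition_correlations(sub, sub_design, "age",
                                                    quantile_norm=True)
            young, old = by_age[str(min(ages))], by_age[str(max(ages))]
            sd2 = sub_design.set_index("sample_id")
            cols_y = [s for s in sub.sample_ids if sd2.loc[s, "age"] == min(ages)]
            cols_o = [s for s in sub.sample_ids if sd2.loc[s, "age"] == max(ages)]
            s = network.correlation_shift_test(
                old, young, seed=config.stage_seed("network"),
                samples_a=sub.values[cols_o], samples_b=sub.values[cols_y])
            corr_summary.append({"comparison": f"{diet}_age{max(ages)}_vs_age{min(ages)}",
                                 "mean_corr_a": s[0], "mean_corr_b": s[1],
                                 "p": s[2]})
    pd.DataFrame(corr_summary).to_csv(outdir / "correlation_summary.tsv",
                                      sep="\t", index=False)
    edges = network.edge_list(dr, al, threshold=config.edge_threshold)
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    network.write_graphml(edges, outdir / "edges.graphml")
    _stage(manifest, "network", clean.n_features, clean.n_samples,
           clean.n_features, clean.n_samples,
           beta_soft=config.beta_soft, min_module=config.min_module,
           n_perm=config.n_perm, n_network_features=net_matrix.n_features,
           n_differential=len(diff_ids), n_similar=len(sim_ids),
           n_diff_modules=len(diff_modules.module_colors) if diff_modules else 0,
           n_sim_modules=len(sim_modules.module_colors) if sim_modules else 0)

    # ---- stage 6: enrichment ------------------------------------------------
    annotation = enrich.annotate_mz(clean.features, reference, ppm=config.ppm)
    universe = clean.feature_ids
    enrichment: dict[str, enrich.EnrichmentResult] = {}
    per_condition: dict[str, list[str]] = {}
    tissue = bdesign["tissue"].iloc[0].capitalize()
    for a, eff in per_age_effects.items():
        q, sig = models.bh_adjust(eff["p"].to_numpy(), config.default_fdr)
        for direction, mask in (("decreased", sig & (eff["beta"] < 0)),
                                ("increased", sig & (eff["beta"] > 0))):
            label = f"{tissue}{a}_{direction}"
            res = enrich.set_enrichment(eff.index[mask], annotation, sets,
                                        universe, fdr=config.enrich_q)
            enrichment[label] = res
            per_condition[label] = list(
                res.table.loc[res.table["q"] <= config.enrich_q, "set"])
    if diff_modules is not None:
        for color in diff_modules.module_colors:
            label = f"diffcoex_{color}"
            res = enrich.set_enrichment(diff_modules.members(color), annotation,
                                        sets, universe, fdr=config.enrich_q)
            enrichment[label] = res
    pd.concat([r.table.assign(condition=c) for c, r in enrichment.items()]) \
        .to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    frequency = enrich.summarize_frequency(per_condition)
    frequency.to_csv(outdir / "enrichment_frequency.tsv", sep="\t", index=False)
    _stage(manifest, "enrich", clean.n_features, clean.n_samples,
           clean.n_features, clean.n_samples,
           ppm=config.ppm, q=config.enrich_q,
           n_annotated=annotation["feature_id"].nunique(),
           n_conditions=len(per_condition))

    # ---- stage 7: manifest ---------------------------------------------------
    _stage(manifest, "manifest", clean.n_features, clean.n_samples,
           clean.n_features, clean.n_samples)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(
        manifest=manifest, clean=clean, design=bdesign, truth=truth,
        diet_effects=diet_effects, age_effects=age_effects, reversal=reversal,
        pair_screen=screen, diff_modules=diff_modules, sim_modules=sim_modules,
        dispersion=dispersion, enrichment=enrichment, frequency=frequency)
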