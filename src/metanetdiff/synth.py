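"""Seeded synthetic LC-MS metabolome generator emulating a DR/aging fly study.

The generator reproduces the *design* of the experiment the package analyses:
two diets (ad libitum ``AL`` vs dietary restriction ``DR``), sampling ages in
days, one or more tissues, six biological replicates per design cell each
measured as several technical replicates, batch structure, missing values,
low signal-to-noise features, per-feature diet and age effects (with a
controllable fraction of "reversal" features whose diet effect opposes their
age effect), and condition-specific correlated modules built from latent
factors. Ground truth is recorded for every planted structure so recovery can
be tested end to end.

Log2-scale generative model for feature *i* in biological sample *s*::

    y_is = base_i + beta_diet_i * [diet_s == DR] + beta_age_i * age_s
           + gamma_{i, batch_s} + module term + N(0, sigma_bio^2)

A module of size *m* with latent correlation *r* contributes
``sign * sqrt(r_eff) * sigma_bio * z_s + sqrt(1 - r_eff) * sigma_bio * eps``
to its member features in conditions where it is active (``z_s`` shared
across the module, ``eps`` idiosyncratic), giving expected pairwise Pearson
correlation ``r_eff`` within the module. Technical replicates add
``N(0, sigma_tech^2)`` noise (inflated for planted low-SNR features) and the
matrix is exponentiated back to the intensity scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureMatrix, validate_design
from .exceptions import ConfigError

#: printed m/z ranges of the two chromatography columns (Da)
MZ_RANGES = {
    "AE": (86.0605321, 1738.34568),
    "C18": (85.0279778, 1976.50254),
}

MODULE_PATTERNS = ("DR-only", "AL-only", "both-same-sign", "both-opposite-sign")


@dataclass(frozen=True)
class ModuleSpec:
    """One planted correlation module.

    ``pattern`` says in which diet condition the module's latent factor is
    active; ``r`` is the expected within-module pairwise correlation where
    active. ``both-opposite-sign`` flips the loading sign of half the member
    features in AL relative to DR, so cross-half pairs reverse correlation
    sign between diets.
    """

    size: int
    pattern: str
    r: float
    name: str | None = None

    def __post_init__(self) -> None:
        if self.pattern not in MODULE_PATTERNS:
            raise ConfigError(f"unknown module pattern {self.pattern!r}")
        if not (-1.0 < self.r < 1.0):
            raise ConfigError("module correlation r must lie in (-1, 1)")
        if self.size < 2:
            raise ConfigError("module size must be >= 2")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 2 diets x 3 ages x 6 biological
    replicates x 3 technical replicates, a few thousand features, mild MCAR
    missingness and a handful of planted condition-specific modules.
    """

    n_features: int = 2000
    n_bio_reps: int = 6
    n_tech_reps: int = 3
    diets: tuple[str, ...] = ("AL", "DR")
    ages: tuple[int, ...] = (10, 20, 40)
    tissues: tuple[str, ...] = ("thorax",)
    n_batches: int = 2
    frac_diet_affected: float = 0.15
    frac_age_affected: float = 0.15
    frac_reversal: float = 0.7
    effect_size_sd: float = 1.0
    module_specs: tuple[ModuleSpec, ...] = (
        ModuleSpec(40, "DR-only", 0.7),
        ModuleSpec(40, "both-same-sign", 0.7),
        ModuleSpec(30, "AL-only", 0.6),
        ModuleSpec(30, "both-opposite-sign", 0.6),
    )
    corr_age_trend: float = 0.0   # +: r grows with age under DR, shrinks under AL
    frac_missing: float = 0.05
    frac_low_snr: float = 0.05
    batch_shift_sd: float = 0.3
    n_outlier_samples: int = 0
    outlier_sd: float = 5.0
    baseline_range: tuple[float, float] = (10.0, 20.0)   # log2 intensity units
    sigma_bio: float = 0.5
    sigma_tech: float = 0.1
    sigma_tech_low_snr: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        # YAML round trips deliver lists; normalise the tuple-typed fields
        for name in ("diets", "ages", "tissues", "baseline_range",
                     "module_specs"):
            v = getattr(self, name)
            if isinstance(v, list):
                if name == "module_specs":
                    v = [ModuleSpec(**s) if isinstance(s, dict) else s
                         for s in v]
                object.__setattr__(self, name, tuple(v))
        for name in ("frac_diet_affected", "frac_age_affected", "frac_reversal",
                     "frac_missing", "frac_low_snr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not self.diets or not self.ages or not self.tissues:
            raise ConfigError("diets, ages and tissues must be non-empty")
        if self.n_features < 1 or self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ConfigError("counts must be positive")
        if self.n_batches < 1:
            raise ConfigError("need at least one batch")
        if sum(m.size for m in self.module_specs) > self.n_features:
            raise ConfigError("module sizes exceed n_features")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted truth: per-feature effects/modules and per-sample batch/outlier flags."""

    features: pd.DataFrame   # index feature_id: beta_diet, beta_age, module, low_snr
    samples: pd.DataFrame    # index bio sample id: batch, planted_outlier

    def module_members(self, name: str) -> pd.Index:
        return self.features.index[self.features["module"] == name]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def make_design(config: SynthConfig) -> pd.DataFrame:
    """Full-factorial design table: diets x ages x tissues x bio reps x tech reps.

    Batches are assigned round-robin over biological replicates, so every
    design cell is balanced across batches. Deterministic (no randomness).
    """
    rows = []
    for tissue in config.tissues:
        for diet in config.diets:
            for age in config.ages:
                for b in range(1, config.n_bio_reps + 1):
                    batch = (b - 1) % config.n_batches + 1
                    bio_id = f"{tissue}_{diet}_d{age}_r{b}"
                    for t in range(1, config.n_tech_reps + 1):
                        rows.append({
                            "sample_id": f"{bio_id}_t{t}",
                            "bio_id": bio_id,
                            "diet": diet,
                            "age": age,
                            "tissue": tissue,
                            "batch": batch,
                            "bio_rep": b,
                            "tech_rep": t,
                        })
    return validate_design(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# feature simulation
# ---------------------------------------------------------------------------

def _effective_r(spec: ModuleSpec, diet: str, age: float, config: SynthConfig) -> float:
    """Within-module correlation in one (diet, age) cell, with optional age trend."""
    active = (
        spec.pattern in ("both-same-sign", "both-opposite-sign")
        or (spec.pattern == "DR-only" and diet == "DR")
        or (spec.pattern == "AL-only" and diet == "AL")
    )
    if not active:
        return 0.0
    r = spec.r
    if config.corr_age_trend != 0.0 and len(config.ages) > 1:
        lo, hi = min(config.ages), max(config.ages)
        z = (age - (lo + hi) / 2.0) / (hi - lo)        # in [-1/2, 1/2]
        direction = 1.0 if diet == "DR" else -1.0
        r = r + 2.0 * config.corr_age_trend * direction * z
    return float(np.clip(r, 0.0, 0.95))


def simulate_features(design: pd.DataFrame, config: SynthConfig
                      ) -> tuple[FeatureMatrix, GroundTruth]:
    """Simulate the feature table for ``design`` and record the planted truth.

    Returns the raw-intensity-scale feature matrix (technical-replicate
    columns matching ``design.sample_id``) and a :class:`GroundTruth`.
    Bit-identical for identical (design, config).
    """
    validate_design(design)
    rng = np.random.default_rng(config.seed)
    p = config.n_features
    feature_ids = pd.Index([f"F{i:05d}" for i in range(p)], name="feature_id")

    bio = design.drop_duplicates("bio_id").reset_index(drop=True)
    n_bio = len(bio)
    ages = bio["age"].to_numpy(float)
    is_dr = (bio["diet"] == "DR").to_numpy(float)
    batches = bio["batch"].to_numpy()

    # --- per-feature effects ------------------------------------------------
    base = rng.uniform(*config.baseline_range, size=p)
    beta_diet = np.zeros(p)
    beta_age = np.zeros(p)

    n_d = int(round(config.frac_diet_affected * p))
    n_a = int(round(config.frac_age_affected * p))
    diet_idx = rng.choice(p, size=n_d, replace=False)
    age_idx = rng.choice(p, size=n_a, replace=False)
    beta_diet[diet_idx] = rng.normal(0.0, config.effect_size_sd, size=n_d)
    age_span = max(config.ages) - min(config.ages)
    if age_span > 0:
        beta_age[age_idx] = rng.normal(0.0, config.effect_size_sd, size=n_a) / age_span

    # impose the reversal fraction on doubly-affected features: a reversal
    # feature's diet slope opposes its age slope in sign
    both = np.intersect1d(diet_idx, age_idx)
    if len(both) and age_span > 0:
        rev_mask = rng.random(len(both)) < config.frac_reversal
        sign_age = np.sign(beta_age[both])
        want = np.where(rev_mask, -sign_age, sign_age)
        beta_diet[both] = want * np.abs(beta_diet[both])

    # --- module membership (drawn from unaffected features so that planted
    # correlation structure is not confounded with mean shifts) -------------
    module_label = np.array([""] * p, dtype=object)
    affected = set(diet_idx) | set(age_idx)
    free = np.array([i for i in range(p) if i not in affected])
    needed = sum(m.size for m in config.module_specs)
    pool = free if len(free) >= needed else np.arange(p)
    pool = rng.permutation(pool)
    cursor = 0
    module_info: list[tuple[ModuleSpec, np.ndarray, np.ndarray]] = []
    for k, spec in enumerate(config.module_specs):
        members = np.sort(pool[cursor:cursor + spec.size])
        cursor += spec.size
        name = spec.name or f"M{k + 1}_{spec.pattern}"
        module_label[members] = name
        # loading signs: for 'both-opposite-sign', half the members flip in AL
        flip = np.zeros(spec.size, dtype=bool)
        if spec.pattern == "both-opposite-sign":
            flip[: spec.size // 2] = True
        module_info.append((spec, members, flip))

    low_snr = rng.random(p) < config.frac_low_snr

    # --- biological-sample values -------------------------------------------
    # batch effect: a per-batch location shift common to all features
    batch_shift = rng.normal(0.0, config.batch_shift_sd, size=config.n_batches + 1)

    y = (base[:, None]
         + beta_diet[:, None] * is_dr[None, :]
         + beta_age[:, None] * ages[None, :]
         + batch_shift[batches][None, :])

    noise = rng.normal(0.0, 1.0, size=(p, n_bio))        # unit noise, scaled below
    scale = np.full((p, n_bio), 1.0)                     # sqrt(1 - r_eff) per cell
    for spec, members, flip in module_info:
        z = rng.normal(0.0, 1.0, size=n_bio)             # shared latent factor
        r_eff = np.array([
            _effective_r(spec, d, a, config)
            for d, a in zip(bio["diet"], bio["age"])
        ])
        sign = np.ones((len(members), n_bio))
        if spec.pattern == "both-opposite-sign":
            sign[np.ix_(flip, is_dr == 0)] = -1.0
        y[members] += (sign * np.sqrt(r_eff)[None, :] * z[None, :]
                       * config.sigma_bio)
        scale[members] = np.sqrt(1.0 - r_eff)[None, :]
    y += config.sigma_bio * scale * noise

    # --- planted outlier samples --------------------------------------------
    outlier_flag = np.zeros(n_bio, dtype=bool)
    if config.n_outlier_samples > 0:
        out_idx = rng.choice(n_bio, size=config.n_outlier_samples, replace=False)
        outlier_flag[out_idx] = True
        y[:, out_idx] += rng.normal(0.0, config.outlier_sd * config.sigma_bio,
                                    size=(p, len(out_idx)))

    # --- technical replicates + MCAR ------------------------------------------
    sigma_tech = np.where(low_snr, config.sigma_tech_low_snr, config.sigma_tech)
    tech_cols = design["sample_id"].tolist()
    bio_pos = {b: i for i, b in enumerate(bio["bio_id"])}
    col_bio = np.array([bio_pos[b] for b in design["bio_id"]])
    tech = y[:, col_bio] + rng.normal(0.0, 1.0, size=(p, len(col_bio))) * sigma_tech[:, None]

    miss = rng.random((p, n_bio)) < config.frac_missing   # bio-level dropout
    tech[miss[:, col_bio]] = np.nan

    intensities = np.exp2(tech)

    # --- feature keys ----------------------------------------------------------
    column_id = np.where(np.arange(p) % 2 == 0, "AE", "C18")
    mz = np.empty(p)
    for col, (lo, hi) in MZ_RANGES.items():
        sel = column_id == col
        mz[sel] = rng.uniform(lo, hi, size=sel.sum())
    rt = rng.uniform(10.0, 600.0, size=p)

    features = pd.DataFrame({"mz": mz, "rt": rt, "column_id": column_id},
                            index=feature_ids)
    values = pd.DataFrame(intensities, index=feature_ids, columns=tech_cols)
    matrix = FeatureMatrix(values=values, features=features, scale="raw")

    truth = GroundTruth(
        features=pd.DataFrame({
            "beta_diet": beta_diet,
            "beta_age": beta_age,
            "module": module_label,
            "low_snr": low_snr,
        }, index=feature_ids),
        samples=pd.DataFrame({
            "batch": batches,
            "planted_outlier": outlier_flag,
        }, index=pd.Index(bio["bio_id"], name="sample_id")),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# synthetic annotation resources (for the enrichment stage)
# ---------------------------------------------------------------------------

def simulate_reference(matrix: FeatureMatrix, truth: GroundTruth,
                       config: SynthConfig, frac_annotated: float = 0.3,
                       n_background_sets: int = 8, set_size: int = 20,
                       ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Synthetic metabolite reference + pathway sets aligned to the feature m/z.

    A fraction of features is declared annotatable; each gets one synthetic
    metabolite whose monoisotopic mass back-calculates from the feature's m/z
    through the M+H adduct, so annotate_mz recovers the mapping. Pathways:
    one planted set of diet-affected metabolites ("planted_diet_response"),
    plus random background sets.
    """
    rng = np.random.default_rng(config.seed + 104729)
    proton = 1.007276
    ids = matrix.feature_ids
    n_annot = max(2, int(round(frac_annotated * len(ids))))
    # bias annotation toward diet-affected features so the planted pathway is
    # coverable; the matrix may already be QC-filtered, so intersect
    affected = truth.features.index[truth.features["beta_diet"] != 0.0]
    affected = affected.intersection(ids)
    keep_aff = pd.Index(rng.choice(affected, size=min(len(affected), n_annot // 3),
                                   replace=False))
    rest_pool = ids.difference(keep_aff)
    keep_rest = pd.Index(rng.choice(rest_pool, size=n_annot - len(keep_aff),
                                    replace=False))
    annotated = keep_aff.union(keep_rest)

    ref = pd.DataFrame({
        "metabolite": [f"met_{fid}" for fid in annotated],
        "monoisotopic_mass": matrix.features.loc[annotated, "mz"].to_numpy() - proton,
    })

    sets: dict[str, list[str]] = {}
    planted = [f"met_{fid}" for fid in keep_aff]
    if len(planted) >= 5:
        sets["planted_diet_response"] = sorted(planted[:max(5, min(30, len(planted)))])
    met_pool = ref["metabolite"].tolist()
    for k in range(n_background_sets):
        members = rng.choice(met_pool, size=min(set_size, len(met_pool)), replace=False)
        sets[f"background_set_{k + 1}"] = sorted(members)
    return ref, sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    """Write pathway sets in GMT format (name, description, members...)."""
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def write_simulation(outdir: str | Path, design: pd.DataFrame,
                     matrix: FeatureMatrix, truth: GroundTruth) -> dict[str, Path]:
    """Write feature table, metadata and ground truth TSVs; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "feature_table.tsv",
        "design": outdir / "sample_metadata.tsv",
        "truth_features": outdir / "ground_truth_features.tsv",
        "truth_samples": outdir / "ground_truth_samples.tsv",
    }
    matrix.to_tsv(paths["features"])
    design.to_csv(paths["design"], sep="\t", index=False)
    truth.features.to_csv(paths["truth_features"], sep="\t")
    truth.samples.to_csv(paths["truth_samples"], sep="\t")
    return paths
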