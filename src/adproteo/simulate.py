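"""Synthetic three-layer cohort generator with ground truth.

Emulates the statistical structure the downstream analysis assumes: log-normal
intensities with feature baselines around 2^20, additive group effects on the
log2 scale that attenuate across brain regions, covariate-driven confounding,
abundance-dependent (MNAR) dropout, phosphopeptides riding on their parent
protein's abundance, and paired endogenous/chemically-labelled (d0/d3) acetyl
channels whose ratio equals a known occupancy.

Every generator is fully determined by ``SimulationConfig.seed``; independent
substreams are derived per layer so the layers can be generated in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .datamodel import (
    REGIONS,
    DataModelError,
    FeatureAnnotation,
    GeneSetCollection,
    IntensityMatrix,
    SampleTable,
)

#: default attenuation of the AD effect across the region sequence HP -> PRC,
#: producing monotone fold-change trajectories
DEFAULT_REGION_EFFECTS = {"HP": 1.0, "CA1": 0.66, "EC": 0.5, "PRC": 0.25}


@dataclass
class SimulationConfig:
    # cohort design
    n_ad_brains: int = 11
    n_control_brains: int = 12
    regions: tuple[str, ...] = REGIONS
    # layer sizes
    n_proteins: int = 2000
    n_phospho: int = 3000
    n_acetyl_sites: int = 220
    # effect structure
    frac_de: float = 0.05
    effect_log2fc: float = 1.5
    sd_noise: float = 0.5
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    region_effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_REGION_EFFECTS))
    # covariate confounding (log2-abundance slope per SD of the covariate)
    covariate_effects: Mapping[str, float] = field(default_factory=lambda: {"sex": 0.0, "age": 0.0, "pmi": 0.0})
    frac_confounded: float = 0.02
    # covariate distributions (age in years, PMI in hours)
    age_mean: float = 75.0
    age_sd: float = 8.0
    age_group_shift: float = 6.0
    pmi_mean: float = 6.0
    pmi_sd: float = 2.0
    # missingness
    missing_rate: float = 0.10
    mnar_strength: float = 4.0
    # phospho layer
    tech_reps_phospho: int = 2
    phospho_offset_mean: float = -2.0
    phospho_offset_sd: float = 1.0
    phospho_noise_sd: float = 0.3
    phospho_rep_noise_sd: float = 0.2
    # acetyl layer
    acetyl_noise: float = 0.1
    acetyl_occupancy_shift: float = 0.25
    acetyl_occupancy_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_de", "frac_confounded", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataModelError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_proteins", "n_phospho", "n_acetyl_sites", "tech_reps_phospho"):
            if getattr(self, name) < 1:
                raise DataModelError(f"{name} must be positive")
        if self.n_ad_brains < 1 or self.n_control_brains < 1:
            raise DataModelError("both disease groups need at least one brain")
        if self.mnar_strength < 0:
            raise DataModelError("mnar_strength must be >= 0")
        missing_regions = set(self.regions) - set(self.region_effects)
        if missing_regions:
            raise DataModelError(f"region_effects missing entries for {sorted(missing_regions)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = list(self.regions)
        d["region_effects"] = dict(self.region_effects)
        d["covariate_effects"] = dict(self.covariate_effects)
        d["acetyl_occupancy_range"] = list(self.acetyl_occupancy_range)
        return d


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    de_features: dict[str, float] = field(default_factory=dict)  # feature id -> signed log2FC (HP scale)
    confounded_features: dict[str, dict[str, float]] = field(default_factory=dict)
    true_stoichiometry: pd.DataFrame | None = None  # site_key x {AD, control}
    stoich_de: dict[str, float] = field(default_factory=dict)  # site_key -> occupancy(AD) - occupancy(control)
    protein_latent: pd.DataFrame | None = None  # pre-dropout log2 surface, for dependent layers


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def simulate_cohort(config: SimulationConfig) -> SampleTable:
    """One sample per brain per region; covariates drawn at the brain level."""
    rng = _rng(config, 1)
    brains = [f"AD{i + 1:02d}" for i in range(config.n_ad_brains)] + [
        f"CT{i + 1:02d}" for i in range(config.n_control_brains)
    ]
    groups = ["AD"] * config.n_ad_brains + ["control"] * config.n_control_brains
    sex = rng.choice(["M", "F"], size=len(brains))
    shift = np.where(np.asarray(groups) == "AD", config.age_group_shift, 0.0)
    age = np.clip(rng.normal(config.age_mean + shift, config.age_sd), 40.0, None)
    pmi = np.clip(rng.normal(config.pmi_mean, config.pmi_sd, size=len(brains)), 0.5, None)
    rows = []
    for b, g, sx, a, p in zip(brains, groups, sex, age, pmi):
        for region in config.regions:
            rows.append(
                {
                    "sample_id": f"{b}_{region}",
                    "brain_id": b,
                    "region": region,
                    "group": g,
                    "sex": sx,
                    "age": round(float(a), 1),
                    "pmi": round(float(p), 1),
                    "tech_rep": 1,
                }
            )
    return SampleTable(pd.DataFrame(rows))


def expand_replicates(cohort: SampleTable, n_reps: int) -> SampleTable:
    """Technical-replicate sample table (ids suffixed ``_r<k>``)."""
    if n_reps == 1:
        return cohort
    frames = []
    for r in range(1, n_reps + 1):
        f = cohort.frame.copy()
        f["sample_id"] = f["sample_id"] + f"_r{r}"
        f["tech_rep"] = r
        frames.append(f)
    return SampleTable(pd.concat(frames, ignore_index=True))


def _covariate_design(cohort: SampleTable) -> pd.DataFrame:
    """Standardized covariates per sample (sex centred 0/1, age/pmi z-scored)."""
    f = cohort.frame
    design = pd.DataFrame(index=f["sample_id"])
    sex = (f["sex"] == "M").astype(float).to_numpy()
    design["sex"] = sex - sex.mean()
    for col in ("age", "pmi"):
        x = f[col].to_numpy(float)
        sd = x.std()
        design[col] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return design


def _apply_dropout(latent: np.ndarray, rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """MNAR mask: dropout probability is logistic in the latent log2 abundance.

    The logistic intercept is solved numerically so the expected overall
    missing fraction equals ``missing_rate`` at every steepness: increasing
    ``mnar_strength`` concentrates the same total dropout in low-abundance
    cells instead of adding more.
    """
    if config.missing_rate <= 0.0:
        return np.zeros_like(latent, dtype=bool)
    if config.missing_rate >= 1.0:
        return np.ones_like(latent, dtype=bool)
    z = (latent - latent.mean()) / (latent.std() or 1.0)
    s = config.mnar_strength
    if s == 0.0:
        p = np.full_like(latent, config.missing_rate)
    else:
        intercept = brentq(
            lambda a: expit(a - s * z).mean() - config.missing_rate, -200.0, 200.0, xtol=1e-10
        )
        p = expit(intercept - s * z)
    return rng.random(latent.shape) < p


def simulate_protein_matrix(cohort: SampleTable, config: SimulationConfig) -> tuple[IntensityMatrix, GroundTruth]:
    """Raw-scale protein matrix with spiked group effects and MNAR dropout."""
    rng = _rng(config, 2)
    features = [f"PROT{i + 1:05d}" for i in range(config.n_proteins)]
    f = cohort.frame
    is_ad = (f["group"] == "AD").to_numpy(float)
    mult = f["region"].map(config.region_effects).to_numpy(float)
    design = _covariate_design(cohort)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_proteins)
    order = rng.permutation(config.n_proteins)
    n_de = int(round(config.frac_de * config.n_proteins))
    de_idx = order[:n_de]
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effect = np.zeros(config.n_proteins)
    effect[de_idx] = signs * config.effect_log2fc

    any_cov = any(v != 0 for v in config.covariate_effects.values())
    n_conf = int(round(config.frac_confounded * config.n_proteins)) if any_cov else 0
    conf_idx = order[n_de : n_de + n_conf]
    cov_term = np.zeros((config.n_proteins, len(cohort)))
    if n_conf:
        per_sample = sum(
            slope * design[cov].to_numpy() for cov, slope in config.covariate_effects.items() if slope != 0
        )
        cov_term[conf_idx] = per_sample

    latent = (
        baseline[:, None]
        + effect[:, None] * (is_ad * mult)[None, :]
        + cov_term
        + rng.normal(0.0, config.sd_noise, size=(config.n_proteins, len(cohort)))
    )
    mask = _apply_dropout(latent, rng, config)
    values = np.power(2.0, latent)
    values[mask] = np.nan
    frame = pd.DataFrame(values, index=features, columns=f["sample_id"].tolist())

    truth = GroundTruth(
        de_features={features[i]: float(effect[i]) for i in de_idx},
        confounded_features={
            features[i]: {c: s for c, s in config.covariate_effects.items() if s != 0} for i in conf_idx
        },
        protein_latent=pd.DataFrame(latent, index=features, columns=frame.columns),
    )
    return IntensityMatrix(frame, layer="protein", scale="raw"), truth


def simulate_phospho_layer(
    protein_matrix: IntensityMatrix, truth: GroundTruth, config: SimulationConfig
) -> tuple[IntensityMatrix, FeatureAnnotation]:
    """Phosphopeptides as parent-protein log2 abundance plus a site offset.

    Site-specific group effects are added on top of whatever the parent
    protein already does, so phospho-level change can differ from
    protein-level change; technical replicates resample the same latent value
    with replicate noise.  Site effects are recorded in ``truth.de_features``.
    """
    if config.n_phospho < 1:
        raise DataModelError("n_phospho must be >= 1")
    if truth.protein_latent is None:
        raise DataModelError("ground truth lacks the latent protein surface")
    rng = _rng(config, 3)
    latent_prot = truth.protein_latent
    n_prot, n_samples = latent_prot.shape
    sample_ids = list(latent_prot.columns)

    parent = rng.integers(0, n_prot, size=config.n_phospho)
    offset = rng.normal(config.phospho_offset_mean, config.phospho_offset_sd, size=config.n_phospho)
    order = rng.permutation(config.n_phospho)
    n_de = int(round(config.frac_de * config.n_phospho))
    de_idx = order[:n_de]
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effect = np.zeros(config.n_phospho)
    effect[de_idx] = signs * config.effect_log2fc

    # region/group structure read off the sample ids of the protein matrix
    sid_frame = pd.DataFrame({"sample_id": sample_ids})
    parts = sid_frame["sample_id"].str.rsplit("_", n=1, expand=True)
    region = parts[1].to_numpy()
    is_ad = sid_frame["sample_id"].str.startswith("AD").to_numpy(float)
    mult = pd.Series(region).map(config.region_effects).to_numpy(float)

    site_latent = (
        latent_prot.to_numpy()[parent]
        + offset[:, None]
        + effect[:, None] * (is_ad * mult)[None, :]
        + rng.normal(0.0, config.phospho_noise_sd, size=(config.n_phospho, n_samples))
    )

    reps = config.tech_reps_phospho
    blocks, columns = [], []
    for r in range(1, reps + 1):
        obs = site_latent + (
            rng.normal(0.0, config.phospho_rep_noise_sd, size=site_latent.shape) if reps > 1 else 0.0
        )
        blocks.append(obs)
        columns.extend(sample_ids if reps == 1 else [f"{s}_r{r}" for s in sample_ids])
    latent_all = np.hstack(blocks)
    mask = _apply_dropout(latent_all, rng, config)
    values = np.power(2.0, latent_all)
    values[mask] = np.nan

    features = [f"PHOS{i + 1:05d}" for i in range(config.n_phospho)]
    frame = pd.DataFrame(values, index=features, columns=columns)
    annotation = FeatureAnnotation(
        pd.DataFrame(
            {
                "feature_id": features,
                "protein_accession": [latent_prot.index[p] for p in parent],
                "peptide_sequence": ["" for _ in features],
                "ptm_sites": [f"S{(i % 900) + 10}" for i in range(config.n_phospho)],
                "acetyl_channel": ["" for _ in features],
                "site_key": ["" for _ in features],
            }
        )
    )
    truth.de_features.update({features[i]: float(effect[i]) for i in de_idx})
    return IntensityMatrix(frame, layer="phosphopeptide", scale="raw"), annotation


def simulate_acetyl_layer(
    cohort: SampleTable,
    config: SimulationConfig,
    *,
    occupancies: np.ndarray | None = None,
) -> tuple[IntensityMatrix, FeatureAnnotation, GroundTruth]:
    """Paired d0/d3 channels with known per-group occupancy.

    ``d0 = occupancy * T * e`` and ``d3 = (1 - occupancy) * T * e'`` with
    multiplicative log-normal noise; a channel whose true share is zero is
    missing, never zero.  ``occupancies`` optionally fixes the control-group
    occupancy per site (otherwise drawn uniformly in ``acetyl_occupancy_range``).
    """
    rng = _rng(config, 4)
    n = config.n_acetyl_sites
    sites = [f"ACK{i + 1:04d}" for i in range(n)]
    lo, hi = config.acetyl_occupancy_range
    occ_control = np.asarray(occupancies, float) if occupancies is not None else rng.uniform(lo, hi, size=n)
    if occ_control.shape != (n,):
        raise DataModelError("occupancies must have one value per acetyl site")
    if ((occ_control < 0) | (occ_control > 1)).any():
        raise DataModelError("occupancies must lie in [0, 1]")

    n_de = int(round(config.frac_de * n))
    de_idx = rng.permutation(n)[:n_de]
    signs = rng.choice([-1.0, 1.0], size=n_de)
    occ_ad = occ_control.copy()
    occ_ad[de_idx] = np.clip(occ_ad[de_idx] + signs * config.acetyl_occupancy_shift, 0.01, 0.99)

    f = cohort.frame
    is_ad = (f["group"] == "AD").to_numpy()
    occ = np.where(is_ad[None, :], occ_ad[:, None], occ_control[:, None])

    site_base = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    total = np.power(2.0, site_base[:, None] + rng.normal(0.0, config.sd_noise, size=(n, len(cohort))))
    noise0 = np.exp(rng.normal(0.0, config.acetyl_noise, size=total.shape)) if config.acetyl_noise > 0 else 1.0
    noise3 = np.exp(rng.normal(0.0, config.acetyl_noise, size=total.shape)) if config.acetyl_noise > 0 else 1.0
    d0 = occ * total * noise0
    d3 = (1.0 - occ) * total * noise3
    d0[occ == 0.0] = np.nan
    d3[occ == 1.0] = np.nan
    if config.missing_rate > 0:
        d0[rng.random(d0.shape) < config.missing_rate] = np.nan
        d3[rng.random(d3.shape) < config.missing_rate] = np.nan

    features = [f"{s}_d0" for s in sites] + [f"{s}_d3" for s in sites]
    values = pd.DataFrame(np.vstack([d0, d3]), index=features, columns=f["sample_id"].tolist())
    annotation = FeatureAnnotation(
        pd.DataFrame(
            {
                "feature_id": features,
                "protein_accession": ["" for _ in features],
                "peptide_sequence": ["" for _ in features],
                "ptm_sites": [f"K{(i % n) + 5}" for i in range(2 * n)],
                "acetyl_channel": ["d0"] * n + ["d3"] * n,
                "site_key": sites + sites,
            }
        )
    )
    truth = GroundTruth(
        true_stoichiometry=pd.DataFrame({"AD": occ_ad, "control": occ_control}, index=sites),
        stoich_de={sites[i]: float(occ_ad[i] - occ_control[i]) for i in de_idx},
    )
    return IntensityMatrix(values, layer="acetyl", scale="raw"), annotation, truth


def simulate_gene_sets(
    universe: list[str], n_sets: int = 25, min_size: int = 15, max_size: int = 40, seed: int = 0
) -> GeneSetCollection:
    """Random gene sets over a feature universe (for enrichment testing)."""
    rng = np.random.default_rng([int(seed) % (2**31), 5])
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        members = list(rng.choice(universe, size=min(size, len(universe)), replace=False))
        sets[f"SET{k + 1:03d}"] = members
    return GeneSetCollection(sets)


def sample_accession_list(universe: list[str], n: int, seed: int = 0) -> list[str]:
    rng = np.random.default_rng([int(seed) % (2**31), 6])
    return sorted(rng.choice(universe, size=min(n, len(universe)), replace=False))


def simulate_study(config: SimulationConfig) -> dict:
    """Generate the complete three-layer study in one call.

    Returns a dict with cohort/replicate sample tables, the three raw
    matrices, annotations and ground truth.
    """
    cohort = simulate_cohort(config)
    protein, truth = simulate_protein_matrix(cohort, config)
    phospho, phospho_annotation = simulate_phospho_layer(protein, truth, config)
    phospho_samples = expand_replicates(cohort, config.tech_reps_phospho)
    acetyl, acetyl_annotation, acetyl_truth = simulate_acetyl_layer(cohort, config)
    truth.true_stoichiometry = acetyl_truth.true_stoichiometry
    truth.stoich_de = acetyl_truth.stoich_de
    return {
        "config": config,
        "cohort": cohort,
        "phospho_samples": phospho_samples,
        "protein": protein,
        "phospho": phospho,
        "phospho_annotation": phospho_annotation,
        "acetyl": acetyl,
        "acetyl_annotation": acetyl_annotation,
        "truth": truth,
    }
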