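"""Synthetic urine-metabolomics cohorts with known ground truth.

The generator emulates the statistical structure of a quantitative
spot-urine NMR cohort: ~44 log-normally distributed metabolites whose
abundances span several orders of magnitude (urea and creatinine dominate
the concentration sum), correlated metabolite clusters, a shared per-sample
dilution factor multiplying every concentration, sex effects on selected
metabolites (creatinine as a muscle-mass proxy), and clinical outcomes (BMI
and mean arterial pressure) generated as linear combinations of
standardized log physiological concentrations — so the true SD-unit effect
sizes are known exactly and every downstream estimate can be checked
against stored truth.

Model, per sample i and metabolite j with cluster k(j):

    log c_ij = mu_j + beta_sex_j * sex_i
               + sigma_j * (sqrt(rho) * F_{i,k(j)} + sqrt(1-rho) * u_ij)
               + nu * e_ij
    x_ij     = c_ij * d_i,          log d_i ~ N(0, dilution_log_sd^2)

where F are shared cluster factors, u and e independent standard normals,
rho = ``within_cluster_corr``, sigma_j = ``biological_log_sd``, and
nu = ``noise_log_sd`` (uncorrelated measurement noise). Outcomes are
y = Z beta + eps with Z the column-standardized log c and eps scaled so
Var(y) is approximately 1, making the configured betas SD-unit effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import ConfigurationError, MetaboliteTable

#: Metabolites that can serve as internal standards; always present.
REFERENCE_METABOLITES = ("creatinine", "glucose", "urea", "pseudouridine")

#: Default 44-metabolite panel of an NMR spot-urine platform, with a
#: coarse metabolic-class annotation.
DEFAULT_METABOLITE_CLASSES: dict[str, str] = {
    "alanine": "amino acids",
    "glycine": "amino acids",
    "glutamine": "amino acids",
    "histidine": "amino acids",
    "threonine": "amino acids",
    "tyrosine": "amino acids",
    "valine": "amino acids",
    "leucine": "amino acids",
    "isoleucine": "amino acids",
    "creatine": "amino acid metabolism",
    "creatinine": "amino acid metabolism",
    "urea": "amino acid metabolism",
    "taurine": "amino acid metabolism",
    "3-aminoisobutyrate": "amino acid metabolism",
    "3-hydroxyisobutyrate": "amino acid metabolism",
    "3-hydroxyisovalerate": "amino acid metabolism",
    "glucose": "carbohydrate metabolism",
    "lactate": "carbohydrate metabolism",
    "citrate": "carbohydrate metabolism",
    "cis-aconitate": "carbohydrate metabolism",
    "glucuronate": "carbohydrate metabolism",
    "pyruvate": "carbohydrate metabolism",
    "pseudouridine": "nucleotide metabolism",
    "uracil": "nucleotide metabolism",
    "hypoxanthine": "nucleotide metabolism",
    "trigonelline": "nicotinate and nicotinamide metabolism",
    "N1-methylnicotinamide": "nicotinate and nicotinamide metabolism",
    "2-PY": "nicotinate and nicotinamide metabolism",
    "hippurate": "microbial metabolism",
    "3-hydroxyhippurate": "microbial metabolism",
    "4-hydroxyhippurate": "microbial metabolism",
    "HPHPA": "microbial metabolism",
    "4-hydroxyphenylacetate": "microbial metabolism",
    "indoxyl sulfate": "microbial metabolism",
    "acetate": "microbial metabolism",
    "formate": "microbial metabolism",
    "2-hydroxyisobutyrate": "histone modifications",
    "3-methylhistidine": "dietary",
    "2-furoylglycine": "dietary",
    "arabinose": "dietary",
    "sucrose": "dietary",
    "xylose": "dietary",
    "TMAO": "miscellaneous",
    "dimethylamine": "miscellaneous",
}

DEFAULT_METABOLITES: tuple[str, ...] = tuple(DEFAULT_METABOLITE_CLASSES)

#: Default planted SD-unit outcome effects. Effect metabolites sit in
#: different clusters (see cluster assignment below), so the marginal
#: SD-unit association of each equals its configured beta. Signs echo
#: well-replicated epidemiological directions (branched-chain amino acids
#: and lactate up with adiposity; glycine and hippurate down; citrate and
#: formate down with blood pressure).
DEFAULT_OUTCOME_EFFECTS: dict[str, dict[str, float]] = {
    "BMI": {
        "valine": 0.30,
        "tyrosine": 0.25,
        "lactate": 0.20,
        "glycine": -0.20,
        "hippurate": -0.25,
        "2-PY": 0.15,
    },
    "MAP": {
        "alanine": 0.25,
        "TMAO": 0.20,
        "citrate": -0.25,
        "formate": -0.20,
        "glucuronate": 0.15,
        "4-hydroxyhippurate": -0.15,
    },
}

#: Default sex effects on the log-concentration scale (sex coded 0 = female,
#: 1 = male). Creatinine tracks muscle mass; 3-methylhistidine tracks meat
#: intake and muscle protein turnover.
DEFAULT_SEX_EFFECTS: dict[str, float] = {
    "creatinine": 0.35,
    "3-methylhistidine": 0.20,
    "urea": 0.10,
}


def _default_log_means(names: tuple[str, ...]) -> pd.Series:
    """Abundance means on the natural-log mmol/L scale, spanning >3 orders
    of magnitude, with urea and creatinine dominant."""
    n = len(names)
    mu = pd.Series(np.linspace(-5.5, -0.5, n), index=names)
    overrides = {
        "urea": np.log(250.0),        # ~250 mmol/L, dominates the sum
        "creatinine": np.log(10.0),   # ~10 mmol/L
        "glucose": np.log(0.3),
        "hippurate": np.log(1.5),
        "citrate": np.log(1.8),
        "glycine": np.log(0.9),
        "pseudouridine": np.log(0.03),
    }
    for name, value in overrides.items():
        if name in mu.index:
            mu[name] = value
    return mu


def _default_biological_sd(names: tuple[str, ...]) -> pd.Series:
    """Per-metabolite biological SD of log concentration. Pseudouridine
    (whole-body RNA turnover) gets the smallest variance; dietary
    metabolites the largest."""
    sd = pd.Series(0.6, index=names)
    for name in names:
        if DEFAULT_METABOLITE_CLASSES.get(name) == "dietary":
            sd[name] = 0.8
    if "pseudouridine" in sd.index:
        sd["pseudouridine"] = 0.25
    if "creatinine" in sd.index:
        sd["creatinine"] = 0.45
    if "urea" in sd.index:
        sd["urea"] = 0.5
    return sd


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    All SDs are on the natural-log concentration scale. ``outcome_effects``
    maps outcome name -> {metabolite: SD-unit beta}. ``glucose_tail_prob``
    adds a heavy right tail to glucose (a ``glucose_tail_shift`` log-unit
    bump in that fraction of samples), emulating saturated tubular
    reabsorption spilling glucose into urine.
    """

    n_samples: int = 500
    n_metabolites: int = 44
    metabolite_names: tuple[str, ...] | None = None
    abundance_log_means: pd.Series | None = None
    biological_log_sd: pd.Series | float | None = None
    within_cluster_corr: float = 0.5
    n_clusters: int = 8
    dilution_log_sd: float = 0.6
    sex_effect: dict[str, float] | None = None
    outcome_effects: dict[str, dict[str, float]] | None = None
    noise_log_sd: float = 0.1
    male_fraction: float = 0.5
    glucose_tail_prob: float = 0.08
    glucose_tail_shift: float = 1.2
    seed: int = 0

    def resolve(self) -> "GeneratorConfig":
        """Fill defaults and validate; returns self for chaining."""
        if self.metabolite_names is None:
            if self.n_metabolites > len(DEFAULT_METABOLITES):
                raise ConfigurationError(
                    f"n_metabolites > {len(DEFAULT_METABOLITES)} requires explicit names"
                )
            names = list(DEFAULT_METABOLITES[: self.n_metabolites])
            for ref in REFERENCE_METABOLITES:
                if ref not in names:
                    names[-(1 + REFERENCE_METABOLITES.index(ref))] = ref
            self.metabolite_names = tuple(names)
        else:
            self.metabolite_names = tuple(self.metabolite_names)
        names = self.metabolite_names
        if len(names) != self.n_metabolites:
            raise ConfigurationError(
                f"{len(names)} metabolite names for n_metabolites={self.n_metabolites}"
            )
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate metabolite names")
        missing = [m for m in REFERENCE_METABOLITES if m not in names]
        if missing:
            raise ConfigurationError(f"reference metabolites missing: {missing}")
        if self.abundance_log_means is None:
            self.abundance_log_means = _default_log_means(names)
        else:
            self.abundance_log_means = pd.Series(self.abundance_log_means).reindex(names)
            if self.abundance_log_means.isna().any():
                raise ConfigurationError("abundance_log_means must cover every metabolite")
        if self.biological_log_sd is None:
            self.biological_log_sd = _default_biological_sd(names)
        elif np.isscalar(self.biological_log_sd):
            self.biological_log_sd = pd.Series(float(self.biological_log_sd), index=names)
        else:
            self.biological_log_sd = pd.Series(self.biological_log_sd).reindex(names)
            if self.biological_log_sd.isna().any():
                raise ConfigurationError("biological_log_sd must cover every metabolite")
        if self.sex_effect is None:
            self.sex_effect = {m: b for m, b in DEFAULT_SEX_EFFECTS.items() if m in names}
        if self.outcome_effects is None:
            self.outcome_effects = {
                out: {m: b for m, b in eff.items() if m in names}
                for out, eff in DEFAULT_OUTCOME_EFFECTS.items()
            }
        for sd_name in ("dilution_log_sd", "noise_log_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigurationError(f"{sd_name} must be >= 0")
        if (self.biological_log_sd < 0).any():
            raise ConfigurationError("biological_log_sd must be >= 0")
        if not 0.0 <= self.within_cluster_corr <= 1.0:
            raise ConfigurationError("within_cluster_corr must be in [0, 1]")
        if not 1 <= self.n_clusters <= self.n_metabolites:
            raise ConfigurationError("need 1 <= n_clusters <= n_metabolites")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        unknown = [
            m for eff in self.outcome_effects.values() for m in eff if m not in names
        ] + [m for m in self.sex_effect if m not in names]
        if unknown:
            raise ConfigurationError(f"effects reference unknown metabolites: {unknown}")
        return self

    def cluster_assignment(self) -> dict[str, int]:
        """Deterministic round-robin metabolite -> cluster id (0-based);
        consecutive panel entries land in different clusters."""
        self.resolve()
        return {m: i % self.n_clusters for i, m in enumerate(self.metabolite_names)}


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside a generated cohort."""

    dilution_factors: pd.Series
    physiological_matrix: pd.DataFrame
    true_effects: dict[str, dict[str, float]]
    cluster_assignment: dict[str, int]
    seed: int


def compute_map(sbp, dbp):
    """Mean arterial pressure, (SBP + 2 x DBP) / 3, in mmHg.

    Accepts scalars or arrays; requires SBP >= DBP > 0.
    """
    sbp_arr = np.asarray(sbp, dtype=float)
    dbp_arr = np.asarray(dbp, dtype=float)
    if (dbp_arr <= 0).any() or (sbp_arr <= 0).any():
        raise ValueError("blood pressures must be positive")
    if (dbp_arr > sbp_arr).any():
        raise ValueError("diastolic pressure exceeds systolic pressure")
    result = (sbp_arr + 2.0 * dbp_arr) / 3.0
    return result if result.ndim else float(result)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[MetaboliteTable, pd.DataFrame, SyntheticTruth]:
    """Generate one cohort: observed concentrations, covariates, and truth.

    Returns ``(table, covariates, truth)`` where ``table`` holds the
    dilution-confounded observed matrix x_ij = c_ij * d_i, ``covariates``
    has columns sex (0/1), BMI, SBP, DBP, MAP, and ``truth`` stores the
    dilution factors, the pre-dilution physiological matrix and the planted
    effects. Deterministic given ``config.seed``; independent sub-streams
    are spawned per component so adding a component never perturbs others.
    """
    config.resolve()
    n, p = config.n_samples, config.n_metabolites
    names = list(config.metabolite_names)
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_sex, rng_bio, rng_noise, rng_gluc, rng_out, rng_dil = (
        np.random.default_rng(s) for s in streams
    )

    sex = rng_sex.binomial(1, config.male_fraction, size=n)

    clusters = config.cluster_assignment()
    cluster_idx = np.array([clusters[m] for m in names])
    rho = config.within_cluster_corr
    factors = rng_bio.standard_normal((n, config.n_clusters))
    idio = rng_bio.standard_normal((n, p))
    sigma = config.biological_log_sd.to_numpy()
    mu = config.abundance_log_means.to_numpy()
    beta_sex = np.array([config.sex_effect.get(m, 0.0) for m in names])

    log_c = (
        mu
        + np.outer(sex, beta_sex)
        + sigma * (np.sqrt(rho) * factors[:, cluster_idx] + np.sqrt(1.0 - rho) * idio)
    )
    if config.noise_log_sd > 0:
        log_c = log_c + config.noise_log_sd * rng_noise.standard_normal((n, p))
    if config.glucose_tail_prob > 0 and "glucose" in names:
        spill = rng_gluc.random(n) < config.glucose_tail_prob
        log_c[:, names.index("glucose")] += config.glucose_tail_shift * spill

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    physiological = pd.DataFrame(np.exp(log_c), index=sample_ids, columns=names)

    covariates = _generate_covariates(config, physiological, sex, rng_out)

    log_d = rng_dil.normal(0.0, config.dilution_log_sd, size=n)
    dilution = pd.Series(np.exp(log_d), index=sample_ids, name="dilution_factor")
    observed = physiological.mul(dilution, axis=0)

    table = MetaboliteTable(observed, classes={
        m: DEFAULT_METABOLITE_CLASSES.get(m, "miscellaneous") for m in names
    })
    truth = SyntheticTruth(
        dilution_factors=dilution,
        physiological_matrix=physiological,
        true_effects={k: dict(v) for k, v in config.outcome_effects.items()},
        cluster_assignment=clusters,
        seed=config.seed,
    )
    return table, covariates, truth


def _generate_covariates(config, physiological, sex, rng) -> pd.DataFrame:
    """Outcomes as linear combinations of standardized log concentrations.

    The residual SD is set from the sample covariance of the effect
    metabolites so each outcome has variance ~1 on the latent scale; the
    latent score is then mapped to clinical units by a fixed affine
    transform (irrelevant to SD-unit betas).
    """
    n = len(physiological)
    log_c = np.log(physiological.to_numpy())
    if n > 2:
        sd = log_c.std(axis=0, ddof=1)
        sd = np.where(sd < 1e-12, 1.0, sd)  # constant metabolite -> z = 0
        z = (log_c - log_c.mean(axis=0)) / sd
    else:  # too few samples to standardize; outcomes are pure noise
        z = np.zeros_like(log_c)
    z_frame = pd.DataFrame(z, columns=physiological.columns, index=physiological.index)

    latents = {}
    for outcome, effects in config.outcome_effects.items():
        beta = pd.Series(effects, dtype=float)
        if len(beta) and n > 2:
            zb = z_frame[beta.index].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(zb, rowvar=False).reshape(len(beta), len(beta))
            corr = np.nan_to_num(corr)  # constant metabolites explain nothing
            explained = float(beta.to_numpy() @ corr @ beta.to_numpy())
        else:
            explained = float((beta ** 2).sum())
        resid_sd = np.sqrt(max(1.0 - explained, 0.05))
        score = np.zeros(n)
        if len(beta):
            score = z_frame[beta.index].to_numpy() @ beta.to_numpy()
        latents[outcome] = score + resid_sd * rng.standard_normal(n)

    bmi = 26.0 + 4.0 * latents.get("BMI", rng.standard_normal(n))
    map_latent = latents.get("MAP", rng.standard_normal(n))
    mean_map = 93.0 + 8.0 * map_latent
    pulse = np.clip(40.0 + 8.0 * rng.standard_normal(n), 10.0, None)
    sbp = mean_map + 2.0 / 3.0 * pulse
    dbp = mean_map - pulse / 3.0
    return pd.DataFrame(
        {
            "sex": sex,
            "BMI": bmi,
            "SBP": sbp,
            "DBP": dbp,
            "MAP": compute_map(sbp, dbp),
        },
        index=physiological.index,
    )
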