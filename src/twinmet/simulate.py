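"""Synthetic twin-cohort and urinary-metabolome generator.

The generator produces the study conditions the analysis pipeline assumes:

* aggression liability with an ACE twin structure (additive-genetic,
  common-environment and unique-environment variance fractions), scored on
  the T scale (``T = 10 z + 50``);
* selection of concordant-low, concordant-high and discordant twin pairs by
  T-score thresholds, a reserved set of low-scoring control pairs for the
  validation phase, and clinically referred cases drawn from the upper tail
  of the same liability distribution;
* a raw feature matrix in which every measurement is multiplicatively
  diluted as ``beta_m * (d_i - d_w) * excretion``, with per-subject urine
  density ``d_i``, so that control-anchored density normalization can
  recover the underlying excretion exactly;
* pooled-QC replicate vectors with per-feature target RSD and
  limit-of-detection censoring.

Ground truth (the associated feature set, true effects and dilution slopes)
is returned alongside the data so every downstream stage is testable.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .containers import FeatureMatrix, CohortError

__all__ = [
    "simulate_ace_phenotypes",
    "assign_selection_groups",
    "simulate_cohort",
    "simulate_metabolome",
    "simulate_qc_and_censor",
    "simulate_dataset",
    "default_feature_metadata",
    "dilute",
]

# Metabolites the neurotransmitter ratios are built from; they head the
# amines / organic-acids panels so they survive any reasonable panel size.
NAMED_AMINES = (
    "L-tryptophan", "5-hydroxy-L-tryptophan", "serotonin",
    "L-phenylalanine", "L-tyrosine", "3-methoxytyramine",
    "L-glutamine", "L-glutamic acid", "GABA",
)
NAMED_ORGANIC_ACIDS = ("homovanillic acid", "succinic acid")
NAMED_OTHER = ("creatinine", "oxidized DNA/RNA", "neopterin",
               "substance P", "C-peptide")


def _check_fractions(a2: float, c2: float, e2: float) -> None:
    for name, value in (("a2", a2), ("c2", c2), ("e2", e2)):
        if value < 0:
            raise ValueError(f"variance fraction {name} must be >= 0, got {value}")
    if abs(a2 + c2 + e2 - 1.0) > 1e-12:
        raise ValueError("a2 + c2 + e2 must sum to 1")


def _draw_pair_liabilities(rng: np.random.Generator, n: int, is_mz: np.ndarray,
                           a2: float, c2: float, e2: float) -> np.ndarray:
    """Draw (n, 2) liabilities under the ACE model.

    MZ pairs share the full additive-genetic component; DZ pairs share half
    of the additive-genetic variance, so within-pair covariances are
    ``a2 + c2`` (MZ) and ``a2/2 + c2`` (DZ), with unit total variance.
    """
    a_shared = rng.normal(0.0, 1.0, size=n)
    a_own = rng.normal(0.0, 1.0, size=(n, 2))
    c = rng.normal(0.0, math.sqrt(c2), size=n) if c2 > 0 else np.zeros(n)
    e = rng.normal(0.0, math.sqrt(e2), size=(n, 2)) if e2 > 0 else np.zeros((n, 2))
    sd_a = math.sqrt(a2)
    # MZ: identical genomes; DZ: half shared, half segregating independently
    shared_w = np.where(is_mz, sd_a, sd_a * math.sqrt(0.5))[:, None]
    own_w = np.where(is_mz, 0.0, sd_a * math.sqrt(0.5))[:, None]
    return shared_w * a_shared[:, None] + own_w * a_own + c[:, None] + e


def simulate_ace_phenotypes(n_mz: int, n_dz: int, a2: float, c2: float, e2: float,
                            seed: Optional[int] = None,
                            rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate paired twin phenotypes under the ACE generative model.

    Returns one row per twin (``2 * (n_mz + n_dz)`` rows) with columns
    ``family_id``, ``zygosity``, ``member`` and ``phenotype``.  Phenotypes
    have unit total variance in expectation; the expected within-pair
    correlations are ``a2 + c2`` for MZ and ``a2/2 + c2`` for DZ pairs.
    """
    if n_mz <= 0 or n_dz <= 0:
        raise ValueError("pair counts must be positive")
    _check_fractions(a2, c2, e2)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = n_mz + n_dz
    is_mz = np.arange(n) < n_mz
    liab = _draw_pair_liabilities(rng, n, is_mz, a2, c2, e2)
    fam = np.repeat([f"F{i:05d}" for i in range(n)], 2)
    return pd.DataFrame({
        "family_id": fam,
        "zygosity": np.repeat(np.where(is_mz, "MZ", "DZ"), 2),
        "member": np.tile([1, 2], n),
        "phenotype": liab.reshape(-1),
    })


def assign_selection_groups(phenotypes: pd.DataFrame, high_threshold: float = 65.0,
                            low_threshold: float = 55.0,
                            t_column: str = "t_score") -> pd.Series:
    """Label twin pairs by concordance/discordance of their T-scores.

    Both members at or above ``high_threshold`` gives ``concordant_high``,
    both at or below ``low_threshold`` gives ``concordant_low``, one of each
    gives ``discordant`` (per-member labels ``discordant_high`` /
    ``discordant_low``); every other pair is ``unlabeled`` and excluded from
    the analysis sets.
    """
    if low_threshold >= high_threshold:
        raise ValueError("low_threshold must be below high_threshold")
    sizes = phenotypes.groupby("family_id").size()
    bad = sizes[sizes != 2]
    if len(bad):
        raise CohortError(f"unpaired subjects in families: {list(bad.index)}")
    t = phenotypes[t_column].to_numpy(float)
    fam = phenotypes["family_id"].to_numpy()
    order = np.argsort(fam, kind="stable")
    labels = np.empty(len(phenotypes), dtype=object)
    t1, t2 = t[order[0::2]], t[order[1::2]]
    hi1, hi2 = t1 >= high_threshold, t2 >= high_threshold
    lo1, lo2 = t1 <= low_threshold, t2 <= low_threshold
    pair_label = np.where(
        hi1 & hi2, "concordant_high",
        np.where(lo1 & lo2, "concordant_low",
                 np.where((hi1 & lo2) | (hi2 & lo1), "discordant", "unlabeled")),
    )
    lab1 = pair_label.astype(object).copy()
    lab2 = pair_label.astype(object).copy()
    disc = pair_label == "discordant"
    lab1[disc] = np.where(hi1[disc], "discordant_high", "discordant_low")
    lab2[disc] = np.where(hi2[disc], "discordant_high", "discordant_low")
    labels[order[0::2]] = lab1
    labels[order[1::2]] = lab2
    return pd.Series(labels, index=phenotypes.index, name="group")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Generate the selected twin cohort plus clinical cases.

    Twin pairs are drawn from the ACE liability model and screened against
    the T-score selection thresholds until the per-group pair quotas are
    filled (a rejection sampler, mirroring selection from a larger register).
    Concordant-low pairs beyond the discovery quota are labeled ``control``
    and reserved for the validation phase.  Cases are drawn from the upper
    tail of the same liability scale (T approximately N(66, 11)).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    need = {
        "concordant_low": config.n_concordant_low_pairs + config.n_control_pairs,
        "concordant_high": config.n_concordant_high_pairs,
        "discordant": config.n_discordant_pairs,
    }
    kept: dict[str, list[tuple[np.ndarray, bool]]] = {k: [] for k in need}
    chunk = 20000
    for _ in range(500):
        if all(len(kept[k]) >= need[k] for k in need):
            break
        is_mz = rng.random(chunk) < config.mz_fraction
        liab = _draw_pair_liabilities(rng, chunk, is_mz, config.a2, config.c2, config.e2)
        t = 10.0 * liab + 50.0
        hi = t >= config.high_t
        lo = t <= config.low_t
        both_hi = hi.all(axis=1)
        both_lo = lo.all(axis=1)
        disc = (hi[:, 0] & lo[:, 1]) | (hi[:, 1] & lo[:, 0])
        for key, mask in (("concordant_high", both_hi), ("concordant_low", both_lo),
                          ("discordant", disc)):
            short = need[key] - len(kept[key])
            if short > 0:
                idx = np.flatnonzero(mask)[:short]
                kept[key].extend((liab[i], bool(is_mz[i])) for i in idx)
    shortfall = {k: need[k] - len(kept[k]) for k in need if len(kept[k]) < need[k]}
    if shortfall:
        raise RuntimeError(f"could not fill pair quotas: short by {shortfall}")

    rows = []
    fam_counter = 0

    def add_pair(liab: np.ndarray, mz: bool, groups: tuple[str, str]) -> None:
        nonlocal fam_counter
        fam = f"F{fam_counter:04d}"
        fam_counter += 1
        age = rng.uniform(*config.ages)
        if mz:
            sexes = [rng.choice(["F", "M"])] * 2
        else:
            sexes = list(rng.choice(["F", "M"], size=2))
        for member in (0, 1):
            z = liab[member]
            rows.append({
                "subject_id": f"{fam}_{member + 1}",
                "family_id": fam,
                "zygosity": "MZ" if mz else "DZ",
                "role": f"twin{member + 1}",
                "sex": sexes[member],
                "age": age,
                "aggression_score": max(0.0, 4.5 + 2.2 * z + rng.normal(0.0, 2.0)),
                "t_score": 10.0 * z + 50.0,
                "group": groups[member],
                "density": rng.uniform(*config.density_range),
            })

    low_pairs = kept["concordant_low"]
    for i, (liab, mz) in enumerate(low_pairs):
        group = "concordant_low" if i < config.n_concordant_low_pairs else "control"
        add_pair(liab, mz, (group, group))
    for liab, mz in kept["concordant_high"]:
        add_pair(liab, mz, ("concordant_high", "concordant_high"))
    for liab, mz in kept["discordant"]:
        g1 = "discordant_high" if 10 * liab[0] + 50 >= config.high_t else "discordant_low"
        g2 = "discordant_low" if g1 == "discordant_high" else "discordant_high"
        add_pair(liab, mz, (g1, g2))

    for i in range(config.n_clinical):
        z = rng.normal(1.6, 1.1)
        rows.append({
            "subject_id": f"C{i:03d}",
            "family_id": f"CF{i:03d}",
            "zygosity": "NA",
            "role": "case",
            "sex": "F" if rng.random() < config.case_female_fraction else "M",
            "age": rng.uniform(*config.ages),
            "aggression_score": max(0.0, 4.5 + 2.2 * z + rng.normal(0.0, 2.0)),
            "t_score": 10.0 * z + 50.0,
            "group": "case",
            "density": rng.uniform(*config.density_range),
        })

    cohort = pd.DataFrame(rows)
    z_all = (cohort["t_score"].to_numpy() - 50.0) / 10.0
    cohort["excl_chronic"] = rng.random(len(cohort)) < config.rate_chronic
    base = config.rate_medication
    logit = math.log(base / (1 - base)) + config.medication_liability_slope * z_all
    cohort["excl_medication"] = rng.random(len(cohort)) < _logistic(logit)
    cohort["excl_vitamins"] = rng.random(len(cohort)) < config.rate_vitamins
    return cohort


def default_feature_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Feature ids and panel assignments for the simulated platforms."""
    def build(named: tuple, n: int, prefix: str) -> list[str]:
        names = list(named[:n])
        names += [f"{prefix}_{i:02d}" for i in range(len(names) + 1, n + 1)]
        return names

    amines = build(NAMED_AMINES, config.n_amines, "amine")
    oas = build(NAMED_ORGANIC_ACIDS, config.n_organic_acids, "organic_acid")
    other = build(NAMED_OTHER, config.n_other, "biomarker")
    return pd.DataFrame({
        "panel": (["amines"] * len(amines) + ["organic_acids"] * len(oas)
                  + ["other"] * len(other)),
    }, index=pd.Index(amines + oas + other, name="feature_id"))


def dilute(excretion, beta_m, density, d_w: float = 1.0):
    """Measured response ratio under multiplicative urine dilution.

    ``measured = beta_m * (d_i - d_w) * excretion`` — the generative formula
    the density normalization inverts.
    """
    return np.asarray(beta_m) * (np.asarray(density) - d_w) * np.asarray(excretion)


def simulate_metabolome(cohort: pd.DataFrame, config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[FeatureMatrix, dict]:
    """Generate the raw feature matrix for a labeled cohort.

    Log-excretion per feature is baseline + aggression effect (for the
    associated subset) + sex/age terms + family random effect + noise; the
    measured value multiplies excretion by ``beta_m * (d_i - d_w)``.
    Returns the raw :class:`FeatureMatrix` and a ground-truth record.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    dens = cohort["density"].to_numpy(float)
    if (dens <= config.d_w).any():
        bad = cohort.loc[dens <= config.d_w, "subject_id"].tolist()
        raise ValueError(
            f"density must exceed d_w={config.d_w} for all subjects; offending: {bad}"
        )
    meta = default_feature_metadata(config)
    n_feat = len(meta)
    n_sub = len(cohort)

    log_baseline = rng.uniform(-1.0, 3.0, size=n_feat)
    beta_m = rng.uniform(0.5, 2.0, size=n_feat)
    if config.qc_rsd_targets is not None:
        rsd_targets = np.asarray(config.qc_rsd_targets, float)
    else:
        rsd_targets = rng.uniform(*config.qc_rsd_range, size=n_feat)
        # the targeted neurotransmitter assays are precise; keep the ratio
        # constituents reliably below the removal threshold
        named = set(NAMED_AMINES) | set(NAMED_ORGANIC_ACIDS)
        named_idx = [i for i, f in enumerate(meta.index) if f in named]
        if named_idx:
            lo = config.qc_rsd_range[0]
            rsd_targets[named_idx] = rng.uniform(lo, min(12.0, lo + 9.0),
                                                 size=len(named_idx))
    assoc_idx = np.sort(rng.choice(n_feat, size=config.n_true_assoc, replace=False))
    effects = np.zeros(n_feat)
    if config.n_true_assoc:
        signs = rng.choice([-1.0, 1.0], size=config.n_true_assoc)
        # effect_size_sd is the standardized (per biological-SD) outcome shift
        # for the high-vs-low status contrast; concordant selection at the
        # default thresholds separates the groups by about two liability SDs,
        # so the per-liability-SD slope is half that, scaled to the log noise.
        effects[assoc_idx] = signs * config.effect_size_sd * config.log_noise_sd / 2.0
    s_sex = rng.normal(0.0, config.sex_age_effect_sd, size=n_feat)
    s_age = rng.normal(0.0, config.sex_age_effect_sd, size=n_feat)

    z = (cohort["t_score"].to_numpy(float) - 50.0) / 10.0
    female = (cohort["sex"] == "F").to_numpy(float)
    age_std = (cohort["age"].to_numpy(float) - np.mean(config.ages)) / 2.0

    fam_codes, fam_index = pd.factorize(cohort["family_id"])
    sd_fam = config.log_noise_sd * math.sqrt(config.family_effect_share)
    sd_eps = config.log_noise_sd * math.sqrt(1.0 - config.family_effect_share)
    u_fam = (rng.normal(0.0, sd_fam, size=(len(fam_index), n_feat))
             if sd_fam > 0 else np.zeros((len(fam_index), n_feat)))
    eps = (rng.normal(0.0, sd_eps, size=(n_sub, n_feat))
           if sd_eps > 0 else np.zeros((n_sub, n_feat)))

    log_exc = (log_baseline[None, :]
               + z[:, None] * effects[None, :]
               + female[:, None] * s_sex[None, :]
               + age_std[:, None] * s_age[None, :]
               + u_fam[fam_codes, :] + eps)
    if config.confounder_effect:
        fam_mean_z = pd.Series(z).groupby(fam_codes).transform("mean").to_numpy()
        log_exc = log_exc + config.confounder_effect * fam_mean_z[:, None]
    if config.exclusion_shift:
        flagged = cohort["excl_medication"].to_numpy(bool)
        log_exc = log_exc + config.exclusion_shift * flagged[:, None]

    measured = dilute(np.exp(log_exc), beta_m[None, :], dens[:, None], config.d_w)
    if config.measurement_noise:
        sigma = np.sqrt(np.log1p((rsd_targets / 100.0) ** 2))
        measured = measured * np.exp(rng.normal(0.0, 1.0, size=(n_sub, n_feat))
                                     * sigma[None, :])

    meta = meta.copy()
    meta["qc_rsd_target"] = rsd_targets
    meta["lod"] = np.nan
    values = pd.DataFrame(measured, index=pd.Index(cohort["subject_id"], name="subject_id"),
                          columns=meta.index)
    truth = {
        "associated_features": [meta.index[i] for i in assoc_idx],
        "effects": dict(zip(meta.index, effects.tolist())),
        "beta_m": dict(zip(meta.index, beta_m.tolist())),
        "log_baseline": dict(zip(meta.index, log_baseline.tolist())),
        "qc_rsd_target": dict(zip(meta.index, rsd_targets.tolist())),
        "config": config.to_dict(),
    }
    return FeatureMatrix(values=values, feature_meta=meta, stage="raw"), truth


def simulate_qc_and_censor(matrix: FeatureMatrix, config: SimulationConfig,
                           rng: Optional[np.random.Generator] = None) -> FeatureMatrix:
    """Attach pooled-QC replicate vectors and apply LOD censoring.

    QC replicates are lognormal around the pooled (median) level with the
    per-feature target RSD.  Values strictly below the ``lod_quantile`` of
    each feature's distribution are flagged below-LOD and masked; the limit
    itself is recorded for a ``lod_known_fraction`` subset of features and
    left unknown (NaN) for the rest.
    """
    matrix.require_stage("raw", op="simulate_qc_and_censor")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    rsd = matrix.feature_meta["qc_rsd_target"].to_numpy(float)
    if (rsd < 0).any():
        raise ValueError("qc_rsd_targets must be non-negative")
    vals = matrix.values.to_numpy(float)
    center = np.median(vals, axis=0)
    sigma = np.sqrt(np.log1p((rsd / 100.0) ** 2))
    reps = center[None, :] * np.exp(
        rng.normal(0.0, 1.0, size=(config.n_qc_replicates, len(rsd))) * sigma[None, :]
        - 0.5 * sigma[None, :] ** 2
    )
    qc = pd.DataFrame(reps, columns=matrix.values.columns)

    out = matrix.copy_with()
    out.qc_replicates = qc
    if config.lod_quantile > 0:
        lod = np.quantile(vals, config.lod_quantile, axis=0)
        below = vals < lod[None, :]
        known = rng.random(len(lod)) < config.lod_known_fraction
        out.feature_meta["lod"] = np.where(known, lod, np.nan)
        out.below_lod = pd.DataFrame(below, index=matrix.values.index,
                                     columns=matrix.values.columns)
        masked = out.values.to_numpy(float)
        masked[below] = np.nan
        out.values = pd.DataFrame(masked, index=matrix.values.index,
                                  columns=matrix.values.columns)
    return out


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[pd.DataFrame, FeatureMatrix, dict]:
    """End-to-end generation: cohort, censored raw matrix and ground truth."""
    rng = np.random.default_rng(config.seed)
    cohort = simulate_cohort(config, rng=rng)
    matrix, truth = simulate_metabolome(cohort, config, rng=rng)
    matrix = simulate_qc_and_censor(matrix, config, rng=rng)
    return cohort, matrix, truth
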