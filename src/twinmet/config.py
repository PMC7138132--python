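"""Configuration objects for simulation and the association cascade."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

#: Canonical panel names, in reporting order.
PANELS = ("amines", "organic_acids", "other")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic twin-cohort metabolome generator.

    The defaults emulate the study design the analysis pipeline expects:
    a twin cohort enriched for aggression-concordant and -discordant pairs
    (302 concordant-low, 182 concordant-high and 189 discordant complete
    pairs, plus 92 low-scoring control pairs reserved for validation), 183
    clinically referred high-aggression cases, and 89 metabolomics features
    across three panels (64 amines, 20 organic acids, 5 other biomarkers).

    Aggression liability follows an ACE twin model with a2/c2/e2 =
    0.63/0.14/0.23.  Urinary measurements are multiplicatively diluted in
    proportion to ``beta_m * (density - 1)`` so the control-anchored density
    normalization is exactly recoverable.
    """

    # --- cohort composition (complete pairs) ---
    n_concordant_low_pairs: int = 302
    n_concordant_high_pairs: int = 182
    n_discordant_pairs: int = 189
    n_control_pairs: int = 92          # concordant-low pairs reserved for validation
    n_clinical: int = 183
    mz_fraction: float = 0.8           # intentional MZ oversampling
    case_female_fraction: float = 0.257

    # --- selection thresholds on the T-score scale (T = 10 z + 50) ---
    high_t: float = 65.0
    low_t: float = 55.0

    # --- ACE structure of the aggression liability ---
    a2: float = 0.63
    c2: float = 0.14
    e2: float = 0.23

    # --- feature panels ---
    n_amines: int = 64
    n_organic_acids: int = 20
    n_other: int = 5

    # --- aggression effects on metabolite excretion ---
    n_true_assoc: int = 6
    effect_size_sd: float = 0.30       # standardized high-vs-low outcome shift

    # --- nuisance structure ---
    sex_age_effect_sd: float = 0.10
    log_noise_sd: float = 0.30         # total biological SD on the log scale
    family_effect_share: float = 0.10  # fraction of log-scale variance shared per family
    confounder_effect: float = 0.0     # family-level shift per family-mean liability SD
    exclusion_shift: float = 0.0       # log-scale shift for flagged (e.g. medicated) subjects

    # --- urine dilution ---
    density_range: tuple[float, float] = (1.005, 1.035)
    d_w: float = 1.0                   # density of pure water

    # --- measurement layer ---
    lod_quantile: float = 0.05
    lod_known_fraction: float = 0.5
    n_qc_replicates: int = 30
    qc_rsd_range: tuple[float, float] = (3.0, 19.0)
    qc_rsd_targets: Optional[list[float]] = None   # overrides qc_rsd_range if given
    measurement_noise: bool = True     # per-sample technical noise at the QC RSD level

    # --- exclusion-flag base rates (per subject) ---
    rate_chronic: float = 0.018
    rate_medication: float = 0.036
    rate_vitamins: float = 0.050
    medication_liability_slope: float = 1.0  # log-odds increase per liability SD

    ages: tuple[float, float] = (6.0, 13.0)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {"a2": self.a2, "c2": self.c2, "e2": self.e2}
        for name, value in fracs.items():
            if value < 0:
                raise ValueError(f"variance fraction {name} must be >= 0, got {value}")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-12:
            raise ValueError("a2 + c2 + e2 must sum to 1")
        for name in (
            "n_concordant_low_pairs", "n_concordant_high_pairs", "n_discordant_pairs",
            "n_control_pairs", "n_clinical", "n_amines", "n_organic_acids", "n_other",
            "n_true_assoc",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_true_assoc > self.n_features:
            raise ValueError("n_true_assoc cannot exceed the total feature count")
        if self.density_range[0] <= 1.0:
            raise ValueError("density_range lower bound must exceed 1.0 (pure water)")
        if self.density_range[1] <= self.density_range[0]:
            raise ValueError("density_range must be increasing")
        if not (0.0 <= self.lod_quantile < 1.0):
            raise ValueError("lod_quantile must lie in [0, 1)")
        if self.low_t >= self.high_t:
            raise ValueError("low_t must be below high_t")
        if self.qc_rsd_targets is not None:
            if len(self.qc_rsd_targets) != self.n_features:
                raise ValueError("qc_rsd_targets must have one entry per feature")
            if any(t < 0 for t in self.qc_rsd_targets):
                raise ValueError("qc_rsd_targets must be non-negative")

    @property
    def n_features(self) -> int:
        return self.n_amines + self.n_organic_acids + self.n_other

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CascadeConfig:
    """Settings for the three-phase discovery/replication/validation cascade."""

    top_fraction: float = 0.25
    #: explicit per-panel selection counts; take precedence over top_fraction.
    per_panel_counts: Optional[dict[str, int]] = field(
        default_factory=lambda: {"amines": 16, "organic_acids": 5, "other": 2}
    )
    n_top_ratios: int = 3
    k_validation: int = 5
    fdr_level: float = 0.05
    congruence_required: bool = True
    #: declared FDR family sizes per phase, for bookkeeping/provenance.
    test_registry: dict[str, int] = field(
        default_factory=lambda: {
            "discovery_features": 89, "discovery_ratios": 7,
            "replication_features": 23, "replication_ratios": 3,
            "validation_features": 5,
        }
    )
    #: cohort groups whose subjects anchor the density models.
    density_control_groups: tuple[str, ...] = ("concordant_low", "control")
    rsdqc_threshold: float = 20.0
    verification_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.top_fraction < 1.0):
            raise ValueError("top_fraction must lie in (0, 1)")
        if self.k_validation < 1:
            raise ValueError("k_validation must be >= 1")
        if not (0.0 < self.fdr_level < 1.0):
            raise ValueError("fdr_level must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def load_yaml_config(path) -> dict:
    """Load a YAML run configuration into a plain dictionary."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def simulation_config_from_yaml(path) -> SimulationConfig:
    raw = load_yaml_config(path)
    for key in ("density_range", "qc_rsd_range", "ages"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def cascade_config_from_yaml(path) -> CascadeConfig:
    raw = load_yaml_config(path)
    if "density_control_groups" in raw and raw["density_control_groups"] is not None:
        raw["density_control_groups"] = tuple(raw["density_control_groups"])
    return CascadeConfig(**raw)
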