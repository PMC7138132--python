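"""In-memory containers shared across the pipeline.

The cohort is a plain :class:`pandas.DataFrame` with a documented column
schema (see ``docs/data_dictionary.md``); :func:`validate_cohort` enforces
it.  Metabolomics data travel as a :class:`FeatureMatrix`, a thin wrapper
around a subjects-by-features DataFrame that carries panel metadata, QC
replicates, below-LOD bookkeeping and — crucially — a ``stage`` marker used
to enforce the fixed preprocessing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

ZYGOSITIES = ("MZ", "DZ", "NA")
ROLES = ("twin1", "twin2", "case")
SEXES = ("F", "M")
GROUPS = (
    "concordant_low", "concordant_high",
    "discordant_low", "discordant_high",
    "case", "control", "unlabeled",
)

COHORT_COLUMNS = [
    "subject_id", "family_id", "zygosity", "role", "sex", "age",
    "aggression_score", "t_score", "group", "density",
    "excl_chronic", "excl_medication", "excl_vitamins",
]

#: preprocessing stages, in mandatory order.
STAGES = ("raw", "imputed", "percent_median", "normalized", "int")


class PipelineOrderError(RuntimeError):
    """Raised when a preprocessing step is applied out of order."""


class CohortError(ValueError):
    """Raised when a cohort table violates its schema or pair structure."""


@dataclass
class FeatureMatrix:
    """Subjects x features measurement matrix with metadata.

    Attributes
    ----------
    values : DataFrame
        Measured values, indexed by subject id, one column per feature.
        Cells flagged below the limit of detection are NaN until imputed.
    feature_meta : DataFrame
        Indexed by feature id, columns ``panel`` (amines / organic_acids /
        other), ``lod`` (limit of detection on the raw scale; NaN when the
        limit is unknown) and optionally ``qc_rsd_target``.
    qc_replicates : DataFrame or None
        Pooled-QC replicate measurements, one column per feature.
    below_lod : DataFrame
        Boolean mask, aligned with ``values``.
    n_imputed : Series
        Per-feature count of below-LOD imputations performed.
    stage : str
        Current preprocessing stage; see :data:`STAGES`.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    qc_replicates: Optional[pd.DataFrame] = None
    below_lod: Optional[pd.DataFrame] = None
    n_imputed: Optional[pd.Series] = None
    stage: str = "raw"
    caution_features: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.feature_meta.index.equals(self.values.columns):
            self.feature_meta = self.feature_meta.reindex(self.values.columns)
        if self.feature_meta["panel"].isna().any():
            missing = self.feature_meta.index[self.feature_meta["panel"].isna()]
            raise ValueError(f"features without panel metadata: {list(missing)}")
        if self.below_lod is None:
            self.below_lod = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.n_imputed is None:
            self.n_imputed = pd.Series(0, index=self.values.columns, dtype=int)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    def panel_of(self, feature: str) -> str:
        return str(self.feature_meta.loc[feature, "panel"])

    def require_stage(self, *allowed: str, op: str = "operation") -> None:
        if self.stage not in allowed:
            raise PipelineOrderError(
                f"{op} requires stage in {allowed}, but matrix is at "
                f"stage {self.stage!r}; the preprocessing order is "
                f"{' -> '.join(STAGES)}"
            )

    def copy_with(self, *, values: Optional[pd.DataFrame] = None,
                  stage: Optional[str] = None, **kwargs) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values.copy() if values is None else values,
            feature_meta=self.feature_meta.copy(),
            qc_replicates=None if self.qc_replicates is None else self.qc_replicates.copy(),
            below_lod=self.below_lod.copy(),
            n_imputed=self.n_imputed.copy(),
            stage=self.stage if stage is None else stage,
            caution_features=kwargs.get("caution_features", self.caution_features),
        )


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate cohort schema, vocabularies and twin-pair integrity."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortError(f"cohort table is missing required columns: {missing}")
    if cohort["subject_id"].duplicated().any():
        dupes = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortError(f"duplicated subject ids: {dupes}")
    for col, vocab in (("zygosity", ZYGOSITIES), ("role", ROLES),
                       ("sex", SEXES), ("group", GROUPS)):
        bad = ~cohort[col].isin(vocab)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortError(
                f"unknown {col} label {cohort[col].iloc[row]!r} at row {row}"
            )
    twins = cohort[cohort["role"] != "case"]
    sizes = twins.groupby("family_id").size()
    over = sizes[sizes > 2]
    if len(over):
        raise CohortError(f"families with more than two twins: {list(over.index)}")
    # discordant pairs must contain exactly one low and one high member
    disc = twins[twins["group"].str.startswith("discordant")]
    for fam, members in disc.groupby("family_id"):
        labels = sorted(members["group"])
        if labels != ["discordant_high", "discordant_low"]:
            raise CohortError(
                f"discordant family {fam!r} must have exactly one high and one "
                f"low member, got {labels}"
            )
    # non-discordant twin pairs must share a group label
    for fam, members in twins[~twins["group"].str.startswith("discordant")].groupby("family_id"):
        if members["group"].nunique() > 1:
            raise CohortError(
                f"family {fam!r} mixes group labels {sorted(set(members['group']))}"
            )
    return cohort
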