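"""Three-phase association cascade for twin metabolomics.

Phase 1 (discovery) contrasts concordant-high against concordant-low twins
with family-clustered GEE models (sex and age as covariates), applying
Benjamini-Hochberg FDR separately to the biomarker and ratio families.
Phase 2 (replication) takes the top 25% most strongly associated outcomes
into discordant twin pairs: sex/age are regressed out and the high-minus-low
within-pair residual differences are tested with paired t-tests — a contrast
immune to any family-level confounder.  Phase 3 (validation) compares
clinically referred cases against reserved low-scoring twin controls for the
top congruent-direction biomarkers and the top congruent ratio.  Sensitivity
re-analysis repeats the within-pair tests after excluding flagged subjects
(chronic condition, medication, vitamin use).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import CascadeConfig
from .containers import FeatureMatrix, validate_cohort
from .gee import gee_many
from .preprocess import run_preprocessing, inverse_normal_transform
from .ratios import default_ratio_definitions, compute_ratios

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust", "residualize", "within_pair_test", "run_discovery",
    "select_top_fraction", "run_replication", "select_for_validation",
    "run_validation", "sensitivity_rerun", "CascadeReport", "run_cascade",
    "CascadeAnalysis",
]

DISCOVERY_GROUPS = ("concordant_low", "concordant_high")
REPLICATION_GROUPS = ("discordant_low", "discordant_high")
VALIDATION_GROUPS = ("case", "control")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "sex": (cohort["sex"] == "F").astype(float).to_numpy(),
        "age": cohort["age"].to_numpy(float),
    }, index=cohort.index)


def residualize(outcome, sex, age) -> np.ndarray:
    """Least-squares residuals of an outcome on intercept + sex + age."""
    y = np.asarray(outcome, float)
    if y.size < 3:
        raise ValueError("at least 3 subjects are required to residualize")
    X = np.column_stack([np.ones_like(y), np.asarray(sex, float),
                         np.asarray(age, float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates in residualization")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def within_pair_test(residuals: pd.Series, cohort: pd.DataFrame) -> dict:
    """Paired t-test of high-minus-low residual differences.

    ``residuals`` is indexed by subject id; only discordant pairs with both
    members non-missing contribute (dropped pairs are logged).  Returns
    ``mean_diff``, ``t``, ``df``, ``p`` and ``n_pairs``.
    """
    disc = cohort[cohort["group"].isin(REPLICATION_GROUPS)]
    diffs = []
    dropped = 0
    for fam, members in disc.groupby("family_id"):
        hi = members.loc[members["group"] == "discordant_high", "subject_id"]
        lo = members.loc[members["group"] == "discordant_low", "subject_id"]
        if len(hi) != 1 or len(lo) != 1:
            raise ValueError(f"discordant family {fam!r} lacks a high/low pair")
        r_hi = residuals.get(hi.iloc[0], np.nan)
        r_lo = residuals.get(lo.iloc[0], np.nan)
        if np.isfinite(r_hi) and np.isfinite(r_lo):
            diffs.append(r_hi - r_lo)
        else:
            dropped += 1
    if len(diffs) < 2:
        raise ValueError("fewer than 2 usable discordant pairs")
    if dropped:
        logger.info("within_pair_test: dropped %d incomplete pairs", dropped)
    d = np.asarray(diffs)
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else math.inf * np.sign(mean)
        p = 1.0 if mean == 0.0 else np.nextafter(0, 1)
    else:
        t = mean / (sd / math.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return {"mean_diff": mean, "t": float(t), "df": n - 1,
            "p": max(p, np.nextafter(0, 1)), "n_pairs": n}


def _gee_phase(outcomes: pd.DataFrame, cohort: pd.DataFrame, status: np.ndarray,
               phase: str, panels: Optional[pd.Series] = None) -> pd.DataFrame:
    records = gee_many(outcomes, status, _covariates(cohort),
                       cohort["family_id"].to_numpy())
    records["fdr_p"] = bh_adjust(records["p"].to_numpy())
    records["phase"] = phase
    if panels is not None:
        records.insert(0, "panel", panels.reindex(records.index))
    return records


def run_discovery(features: pd.DataFrame, ratios: pd.DataFrame,
                  cohort: pd.DataFrame, config: CascadeConfig
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-family GEE discovery in concordant-low vs -high twins.

    Features and ratios are INT-scale outcomes indexed by subject id.
    FDR families: all biomarkers together, all ratios together.
    """
    sub = cohort[cohort["group"].isin(DISCOVERY_GROUPS)].reset_index(drop=True)
    if sub.empty:
        raise ValueError("empty discovery analysis set")
    status = (sub["group"] == "concordant_high").to_numpy(float)
    ids = sub["subject_id"]
    panels = getattr(features, "attrs", {}).get("panels")
    feat = _gee_phase(features.loc[ids], sub, status, "discovery", panels)
    rat = _gee_phase(ratios.loc[ids], sub, status, "discovery")
    return feat, rat


def select_top_fraction(records: pd.DataFrame, config: CascadeConfig,
                        n_override: Optional[int] = None) -> list[str]:
    """Select the most strongly associated outcomes from discovery.

    Ranking is by ascending p with deterministic tie-breaks (|beta|
    descending, then id).  With ``per_panel_counts`` configured (and a
    ``panel`` column present) the stated per-panel counts take precedence
    over the global ``ceil(top_fraction * m)`` rule; ``n_override`` forces a
    single global count (used for the ratio family).
    """
    if records.empty:
        raise ValueError("no records to select from")
    ordered = records.copy()
    ordered["_absbeta"] = -ordered["beta"].abs()
    ordered = ordered.reset_index()
    id_col = ordered.columns[0]
    ordered = ordered.sort_values(["p", "_absbeta", id_col], kind="stable")
    if n_override is not None:
        return ordered[id_col].head(n_override).tolist()
    if config.per_panel_counts and "panel" in ordered.columns:
        selected: list[str] = []
        for panel, count in config.per_panel_counts.items():
            pool = ordered[ordered["panel"] == panel]
            if count > len(pool):
                raise ValueError(
                    f"per-panel count {count} exceeds panel {panel!r} size {len(pool)}"
                )
            selected.extend(pool[id_col].head(count).tolist())
        return selected
    m = len(ordered)
    k = math.ceil(config.top_fraction * m)
    return ordered[id_col].head(k).tolist()


def run_replication(features: pd.DataFrame, ratios: pd.DataFrame,
                    cohort: pd.DataFrame, selected_features: list[str],
                    selected_ratios: list[str], config: CascadeConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-pair paired t-tests on sex/age-residualized outcomes."""
    sub = cohort[cohort["group"].isin(REPLICATION_GROUPS)].reset_index(drop=True)
    if sub.empty:
        raise ValueError("empty replication analysis set")
    ids = sub["subject_id"]

    def run_family(outcomes: pd.DataFrame, names: list[str]) -> pd.DataFrame:
        if not names:
            return pd.DataFrame(
                columns=["mean_diff", "t", "df", "p", "n_pairs", "fdr_p", "phase"],
                index=pd.Index([], name="id"))
        recs = []
        for name in names:
            y = outcomes.loc[ids, name].to_numpy(float)
            ok = np.isfinite(y)
            resid = np.full(y.shape, np.nan)
            resid[ok] = residualize(y[ok], (sub["sex"] == "F").to_numpy(float)[ok],
                                    sub["age"].to_numpy(float)[ok])
            r = within_pair_test(pd.Series(resid, index=ids.to_numpy()), sub)
            r["id"] = name
            recs.append(r)
        df = pd.DataFrame(recs).set_index("id")
        df["fdr_p"] = bh_adjust(df["p"].to_numpy())
        df["phase"] = "replication"
        return df

    feat = run_family(features, selected_features)
    rat = run_family(ratios, selected_ratios)
    return feat, rat


def select_for_validation(discovery: pd.DataFrame, replication: pd.DataFrame,
                          config: CascadeConfig,
                          k: Optional[int] = None) -> tuple[list[str], pd.DataFrame]:
    """Forward congruent-direction outcomes into validation.

    Congruence means the discovery GEE beta and the replication within-pair
    mean difference share their sign.  Among congruent outcomes the best
    ``k`` (default ``config.k_validation``) by discovery p are selected.
    Returns the candidate ids and a bookkeeping frame with congruence flags.
    """
    k = config.k_validation if k is None else k
    rep = replication.reindex(discovery.index.intersection(replication.index))
    book = pd.DataFrame({
        "discovery_beta": discovery.loc[rep.index, "beta"],
        "discovery_p": discovery.loc[rep.index, "p"],
        "mean_diff": rep["mean_diff"],
    })
    book["congruent"] = (np.sign(book["discovery_beta"])
                         == np.sign(book["mean_diff"])) & (book["mean_diff"] != 0)
    if config.congruence_required:
        pool = book[book["congruent"]]
    else:
        pool = book
    pool = pool.sort_values(
        ["discovery_p", "discovery_beta"],
        key=lambda s: -s.abs() if s.name == "discovery_beta" else s,
        kind="stable",
    )
    if len(pool) < k:
        warnings.warn(
            f"only {len(pool)} congruent candidates available for {k} slots",
            stacklevel=2,
        )
    selected = pool.index[:k].tolist()
    book["selected"] = book.index.isin(selected)
    return selected, book


def run_validation(features: pd.DataFrame, ratios: pd.DataFrame,
                   cohort: pd.DataFrame, candidate_features: list[str],
                   candidate_ratio: Optional[str], config: CascadeConfig
                   ) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Case-control GEE validation of the forwarded candidates.

    BH adjustment spans the candidate biomarkers; the single ratio is
    reported unadjusted.
    """
    sub = cohort[cohort["group"].isin(VALIDATION_GROUPS)].reset_index(drop=True)
    if sub.empty:
        raise ValueError("empty validation analysis set")
    absent = [f for f in candidate_features if f not in features.columns]
    if absent:
        raise ValueError(f"candidates absent from the validation matrix: {absent}")
    status = (sub["group"] == "case").to_numpy(float)
    ids = sub["subject_id"]
    feat = _gee_phase(features.loc[ids, candidate_features], sub, status, "validation")
    rat = None
    if candidate_ratio is not None:
        rat = _gee_phase(ratios.loc[ids, [candidate_ratio]], sub, status, "validation")
        rat["fdr_p"] = rat["p"]  # single pre-registered ratio: unadjusted
    return feat, rat


EXCLUSION_FLAGS = ("excl_chronic", "excl_medication", "excl_vitamins")


def sensitivity_rerun(features: pd.DataFrame, ratios: pd.DataFrame,
                      cohort: pd.DataFrame, candidate_features: list[str],
                      candidate_ratio: Optional[str], config: CascadeConfig,
                      flags: tuple[str, ...] = EXCLUSION_FLAGS,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat within-pair tests per exclusion scenario.

    Each scenario drops every discordant pair containing a flagged twin and
    re-runs the paired tests for the validation candidates.  BH adjustment
    pools the feature records across scenarios (and likewise the ratio
    records), matching a declared family of scenarios x candidates tests.
    """
    disc = cohort[cohort["group"].isin(REPLICATION_GROUPS)]
    feat_recs, ratio_recs = [], []
    for flag in flags:
        if flag not in cohort.columns:
            raise ValueError(f"unknown exclusion flag {flag!r}")
        flagged_fams = set(disc.loc[disc[flag].astype(bool), "family_id"])
        keep = cohort[~cohort["family_id"].isin(flagged_fams)
                      | ~cohort["group"].isin(REPLICATION_GROUPS)]
        remaining = keep[keep["group"].isin(REPLICATION_GROUPS)]
        if remaining["family_id"].nunique() < 2:
            raise ValueError(f"no discordant pairs remain after {flag!r} exclusions")
        feat, rat = run_replication(
            features, ratios, keep, candidate_features,
            [candidate_ratio] if candidate_ratio else [], config,
        )
        feat = feat.assign(scenario=flag, n_excluded=int(disc[flag].astype(bool).sum()))
        feat_recs.append(feat)
        if candidate_ratio:
            ratio_recs.append(rat.assign(scenario=flag))
    feat_all = pd.concat(feat_recs)
    feat_all["fdr_p"] = bh_adjust(feat_all["p"].to_numpy())
    feat_all["phase"] = "sensitivity"
    if ratio_recs:
        rat_all = pd.concat(ratio_recs)
        rat_all["fdr_p"] = bh_adjust(rat_all["p"].to_numpy())
        rat_all["phase"] = "sensitivity"
    else:
        rat_all = pd.DataFrame()
    return feat_all, rat_all


def _frame_to_records(df: Optional[pd.DataFrame]) -> list:
    if df is None or len(df) == 0:
        return []
    out = df.reset_index().replace({np.nan: None})
    return out.to_dict(orient="records")


@dataclass
class CascadeReport:
    """Full provenance-carrying result of one cascade run."""

    discovery_features: pd.DataFrame
    discovery_ratios: pd.DataFrame
    selected_features: list[str]
    selected_ratios: list[str]
    replication_features: pd.DataFrame
    replication_ratios: pd.DataFrame
    candidate_book: pd.DataFrame
    ratio_book: pd.DataFrame
    candidate_features: list[str]
    candidate_ratio: Optional[str]
    validation_features: pd.DataFrame
    validation_ratio: Optional[pd.DataFrame]
    sensitivity_features: pd.DataFrame
    sensitivity_ratios: pd.DataFrame
    qc: Optional[pd.DataFrame] = None
    verification: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "discovery": {
                "features": _frame_to_records(self.discovery_features),
                "ratios": _frame_to_records(self.discovery_ratios),
            },
            "selection": {
                "features": list(self.selected_features),
                "ratios": list(self.selected_ratios),
            },
            "replication": {
                "features": _frame_to_records(self.replication_features),
                "ratios": _frame_to_records(self.replication_ratios),
            },
            "validation_candidates": {
                "features": list(self.candidate_features),
                "ratio": self.candidate_ratio,
                "feature_book": _frame_to_records(self.candidate_book),
                "ratio_book": _frame_to_records(self.ratio_book),
            },
            "validation": {
                "features": _frame_to_records(self.validation_features),
                "ratio": _frame_to_records(self.validation_ratio),
            },
            "sensitivity": {
                "features": _frame_to_records(self.sensitivity_features),
                "ratios": _frame_to_records(self.sensitivity_ratios),
            },
            "qc": _frame_to_records(self.qc),
            "verification": _frame_to_records(self.verification),
        }

    def report_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, allow_nan=False)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def _check_disjoint_phases(cohort: pd.DataFrame) -> None:
    phases = {
        "discovery": DISCOVERY_GROUPS,
        "replication": REPLICATION_GROUPS,
        "validation": VALIDATION_GROUPS,
    }
    fam_phase: dict[str, str] = {}
    for phase, groups in phases.items():
        fams = set(cohort.loc[cohort["group"].isin(groups), "family_id"])
        for fam in fams:
            if fam_phase.get(fam, phase) != phase:
                raise ValueError(
                    f"family {fam!r} appears in both {fam_phase[fam]} and {phase}; "
                    "the three analysis sets must be independent"
                )
            fam_phase[fam] = phase


def run_cascade(cohort: pd.DataFrame, matrix: FeatureMatrix,
                config: Optional[CascadeConfig] = None,
                ratio_definitions=None, seed: Optional[int] = None
                ) -> CascadeReport:
    """Preprocess the raw matrix and execute all three phases in order."""
    config = config or CascadeConfig()
    validate_cohort(cohort)
    _check_disjoint_phases(cohort)

    densities = pd.Series(cohort["density"].to_numpy(float),
                          index=cohort["subject_id"].to_numpy())
    control_mask = pd.Series(
        cohort["group"].isin(config.density_control_groups).to_numpy(),
        index=cohort["subject_id"].to_numpy(),
    )
    prep = run_preprocessing(
        matrix, densities, control_mask,
        rsdqc_threshold=config.rsdqc_threshold,
        tolerance=config.verification_tolerance,
    )
    definitions = ratio_definitions or default_ratio_definitions()
    ratio_raw, ratio_report = compute_ratios(prep["normalized"], definitions)
    int_features = prep["int"].values
    int_features.attrs["panels"] = prep["int"].feature_meta["panel"]
    int_ratios = pd.DataFrame(
        {c: inverse_normal_transform(ratio_raw[c]) for c in ratio_raw.columns},
        index=ratio_raw.index,
    )

    disc_feat, disc_rat = run_discovery(int_features, int_ratios, cohort, config)
    selected_features = select_top_fraction(disc_feat, config)
    selected_ratios = select_top_fraction(disc_rat, config,
                                          n_override=config.n_top_ratios)
    rep_feat, rep_rat = run_replication(int_features, int_ratios, cohort,
                                        selected_features, selected_ratios, config)
    candidate_features, book = select_for_validation(disc_feat, rep_feat, config)
    ratio_candidates, ratio_book = select_for_validation(disc_rat, rep_rat, config, k=1)
    candidate_ratio = ratio_candidates[0] if ratio_candidates else None
    val_feat, val_rat = run_validation(int_features, int_ratios, cohort,
                                       candidate_features, candidate_ratio, config)
    sens_feat, sens_rat = sensitivity_rerun(int_features, int_ratios, cohort,
                                            candidate_features, candidate_ratio,
                                            config)

    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode("utf-8")
    ).hexdigest()
    provenance = {
        "seed": seed,
        "config": config.to_dict(),
        "config_hash": config_hash,
        "n_subjects": int(len(cohort)),
        "n_features": int(len(prep["int"].values.columns)),
        "n_ratios": int(len(int_ratios.columns)),
        "exclusion_counts": {
            flag: int(cohort[flag].astype(bool).sum()) for flag in EXCLUSION_FLAGS
        },
        "caution_features": list(prep["filtered"].caution_features),
        "ratio_missing": ratio_report["n_missing"].to_dict(),
    }
    return CascadeReport(
        discovery_features=disc_feat, discovery_ratios=disc_rat,
        selected_features=selected_features, selected_ratios=selected_ratios,
        replication_features=rep_feat, replication_ratios=rep_rat,
        candidate_book=book, ratio_book=ratio_book,
        candidate_features=candidate_features, candidate_ratio=candidate_ratio,
        validation_features=val_feat, validation_ratio=val_rat,
        sensitivity_features=sens_feat, sensitivity_ratios=sens_rat,
        qc=prep["qc"], verification=prep["verification"],
        provenance=provenance,
    )


class CascadeAnalysis:
    """Estimator-style wrapper: configure once, ``fit`` on cohort + matrix.

    After fitting, the phase tables are available as ``discovery_``,
    ``replication_``, ``validation_`` and the full :class:`CascadeReport`
    as ``report_``.
    """

    def __init__(self, config: Optional[CascadeConfig] = None,
                 ratio_definitions=None, seed: Optional[int] = None):
        self.config = config or CascadeConfig()
        self.ratio_definitions = ratio_definitions
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config,
                "ratio_definitions": self.ratio_definitions, "seed": self.seed}

    def set_params(self, **params) -> "CascadeAnalysis":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, cohort: pd.DataFrame, matrix: FeatureMatrix) -> "CascadeAnalysis":
        self.report_ = run_cascade(cohort, matrix, self.config,
                                   self.ratio_definitions, seed=self.seed)
        self.discovery_ = self.report_.discovery_features
        self.replication_ = self.report_.replication_features
        self.validation_ = self.report_.validation_features
        return self
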