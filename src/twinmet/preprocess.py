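"""Metabolomics preprocessing chain.

The order is fixed and enforced through the matrix ``stage`` marker:

    below-LOD imputation -> percent-of-median scaling -> density-model
    fit/apply -> verification -> inverse normal rank transform (INT)

Dilution correction divides each measured concentration by
``beta_m * (d_i - d_w)``, where ``beta_m`` is the least-squares slope of the
concentration on ``(d_i - d_w)`` fitted in a designated control group, and
``d_w = 1`` is the density of pure water.  Concentrations are expressed as a
percentage of their per-feature median before the fit; densities stay on the
raw specific-gravity scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix, PipelineOrderError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureQC", "compute_rsdqc", "compute_qc_table", "filter_features",
    "impute_below_lod", "to_percent_of_median", "percent_of_median_matrix",
    "fit_density_models", "apply_density_normalization",
    "verify_density_effect_removed", "inverse_normal_transform",
    "int_transform_matrix", "DensityNormalizer", "run_preprocessing",
]

#: smallest admissible dilution slope; below this the division is unstable.
BETA_FLOOR = 1e-8


@dataclass
class FeatureQC:
    """Per-feature measurement reproducibility summary.

    ``rsdqc`` is 100 * (sample SD / mean) of the pooled-QC replicates.
    Status reflects reporting guidance: ``pass`` up to 15%, ``caution`` for
    15-30% (interpret with care), ``fail`` above 30% or for degenerate QC.
    Removal from analysis is a separate, stricter rule applied by
    :func:`filter_features` (strictly above 20% by default).
    """

    feature_id: str
    rsdqc: float
    status: str
    reason: str = ""


def compute_rsdqc(replicates, feature_id: str = "") -> FeatureQC:
    """RSDqc of a QC replicate vector, with interpretability status."""
    x = np.asarray(replicates, float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("at least 2 QC replicates are required")
    mean = x.mean()
    if mean <= 0:
        return FeatureQC(feature_id, float("nan"), "fail", "degenerate QC")
    rsd = 100.0 * x.std(ddof=1) / mean
    if rsd <= 15.0:
        status = "pass"
    elif rsd <= 30.0:
        status = "caution"
    else:
        status = "fail"
    return FeatureQC(feature_id, float(rsd), status)


def compute_qc_table(matrix: FeatureMatrix) -> pd.DataFrame:
    """RSDqc per feature from the matrix's QC replicate vectors."""
    if matrix.qc_replicates is None:
        raise ValueError("matrix carries no QC replicates")
    records = [compute_rsdqc(matrix.qc_replicates[f], f) for f in matrix.feature_ids]
    return pd.DataFrame(
        {"rsdqc": [r.rsdqc for r in records],
         "status": [r.status for r in records],
         "reason": [r.reason for r in records]},
        index=pd.Index([r.feature_id for r in records], name="feature_id"),
    )


def filter_features(matrix: FeatureMatrix, qc: pd.DataFrame,
                    threshold: float = 20.0) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Remove features with RSDqc strictly above ``threshold``.

    Features kept despite a ``caution`` status are flagged on the returned
    matrix (``caution_features``) so downstream reports can carry the flag.
    """
    missing = [f for f in matrix.feature_ids if f not in qc.index]
    if missing:
        raise ValueError(f"QC table does not cover features: {missing}")
    rsd = qc.loc[matrix.feature_ids, "rsdqc"]
    removed = rsd.index[(rsd > threshold) | rsd.isna()].tolist()
    kept = [f for f in matrix.feature_ids if f not in removed]
    if not kept:
        warnings.warn("all features removed by the RSDqc filter", stacklevel=2)
    caution = tuple(
        f for f in kept if qc.loc[f, "status"] == "caution"
    )
    report = qc.loc[matrix.feature_ids].copy()
    report["removed"] = report.index.isin(removed)
    out = FeatureMatrix(
        values=matrix.values[kept].copy(),
        feature_meta=matrix.feature_meta.loc[kept].copy(),
        qc_replicates=None if matrix.qc_replicates is None
        else matrix.qc_replicates[kept].copy(),
        below_lod=matrix.below_lod[kept].copy(),
        n_imputed=matrix.n_imputed.loc[kept].copy(),
        stage=matrix.stage,
        caution_features=caution,
    )
    return out, report


def impute_below_lod(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace below-LOD cells by half the detection limit.

    When the limit is unknown for a feature, half of the lowest observed
    (above-LOD) level is used instead.  A feature that is entirely censored
    with an unknown limit cannot be imputed and raises.
    """
    matrix.require_stage("raw", op="impute_below_lod")
    out = matrix.copy_with(stage="imputed")
    vals = out.values.to_numpy(float)
    below = out.below_lod.to_numpy(bool)
    lods = out.feature_meta["lod"].to_numpy(float)
    n_imp = np.zeros(vals.shape[1], dtype=int)
    for j, feature in enumerate(out.values.columns):
        mask = below[:, j]
        if not mask.any():
            continue
        if np.isfinite(lods[j]):
            fill = lods[j] / 2.0
        else:
            observed = vals[~mask, j]
            observed = observed[np.isfinite(observed)]
            if observed.size == 0:
                raise ValueError(
                    f"feature {feature!r} is entirely below an unknown LOD; "
                    "imputation is undefined"
                )
            fill = observed.min() / 2.0
        vals[mask, j] = fill
        n_imp[j] = int(mask.sum())
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    out.n_imputed = pd.Series(n_imp, index=out.values.columns)
    return out


def to_percent_of_median(values) -> np.ndarray:
    """Express a value vector as a percentage of its median."""
    x = np.asarray(values, float)
    med = np.nanmedian(x)
    if not np.isfinite(med) or med <= 0:
        raise ValueError(f"median must be positive to scale, got {med}")
    return 100.0 * x / med


def percent_of_median_matrix(matrix: FeatureMatrix) -> FeatureMatrix:
    """Percent-of-median scaling of every feature column."""
    matrix.require_stage("imputed", op="percent_of_median")
    out = matrix.copy_with(stage="percent_median")
    scaled = {f: to_percent_of_median(out.values[f]) for f in out.values.columns}
    out.values = pd.DataFrame(scaled, index=out.values.index)[out.values.columns]
    return out


def fit_density_models(matrix: FeatureMatrix, densities: pd.Series,
                       control_mask, d_w: float = 1.0,
                       outlier_sd: float = 2.5) -> pd.DataFrame:
    """Fit per-feature dilution slopes ``beta_m`` in the control group.

    For each feature, control values deviating more than ``outlier_sd`` SDs
    from the control mean are replaced by that mean, then the least-squares
    slope of the value on ``(d_i - d_w)`` (with intercept) is recorded.
    """
    matrix.require_stage("percent_median", "imputed", op="fit_density_models")
    dens = pd.Series(densities).reindex(matrix.values.index)
    if dens.isna().any():
        raise ValueError("densities missing for some subjects")
    if (dens <= d_w).any():
        bad = dens.index[dens <= d_w].tolist()
        raise ValueError(f"density must exceed d_w={d_w}; offending subjects: {bad}")
    mask = np.asarray(
        control_mask.reindex(matrix.values.index)
        if isinstance(control_mask, pd.Series) else control_mask,
        bool,
    )
    if mask.sum() < 3:
        raise ValueError("at least 3 control subjects are required to fit density models")
    x = dens.to_numpy(float)[mask] - d_w
    if np.ptp(x) == 0:
        raise ValueError("zero density variance in the control group")
    records = []
    for feature in matrix.values.columns:
        y = matrix.values[feature].to_numpy(float)[mask]
        ok = np.isfinite(y)
        y_use, x_use = y[ok].copy(), x[ok]
        if y_use.size < 3:
            raise ValueError(f"fewer than 3 usable controls for feature {feature!r}")
        mu, sd = y_use.mean(), y_use.std(ddof=1)
        n_out = 0
        if sd > 0:
            out_mask = np.abs(y_use - mu) > outlier_sd * sd
            n_out = int(out_mask.sum())
            y_use[out_mask] = mu
        X = np.column_stack([np.ones_like(x_use), x_use])
        coef, *_ = np.linalg.lstsq(X, y_use, rcond=None)
        records.append({
            "feature_id": feature,
            "beta_m": float(coef[1]),
            "intercept": float(coef[0]),
            "n_used": int(y_use.size),
            "n_outliers_imputed": n_out,
        })
    return pd.DataFrame(records).set_index("feature_id")


def apply_density_normalization(matrix: FeatureMatrix, densities: pd.Series,
                                models: pd.DataFrame, d_w: float = 1.0,
                                beta_floor: float = BETA_FLOOR) -> FeatureMatrix:
    """Divide every cell by ``beta_m * (d_i - d_w)``.

    Features whose fitted slope is at or below ``beta_floor`` (no usable
    positive dilution signal) are scaled by ``(d_i - d_w)`` alone and
    flagged in the returned matrix's ``feature_meta['beta_guard']``.
    """
    matrix.require_stage("percent_median", "imputed", op="apply_density_normalization")
    dens = pd.Series(densities).reindex(matrix.values.index)
    if (dens <= d_w).any():
        bad = dens.index[dens <= d_w].tolist()
        raise ValueError(
            f"dilution undefined: density <= d_w={d_w} for subjects {bad}"
        )
    missing = [f for f in matrix.values.columns if f not in models.index]
    if missing:
        raise ValueError(f"density models missing for features: {missing}")
    out = matrix.copy_with(stage="normalized")
    dx = dens.to_numpy(float) - d_w
    beta = models.loc[out.values.columns, "beta_m"].to_numpy(float)
    guarded = ~(beta > beta_floor)
    scale = np.where(guarded, 1.0, beta)[None, :] * dx[:, None]
    out.values = pd.DataFrame(out.values.to_numpy(float) / scale,
                              index=out.values.index, columns=out.values.columns)
    out.feature_meta["beta_guard"] = guarded
    if guarded.any():
        flagged = list(out.values.columns[guarded])
        logger.warning("beta_m guard triggered for %d features: %s",
                       len(flagged), flagged)
    return out


def verify_density_effect_removed(norm_matrix: FeatureMatrix, densities: pd.Series,
                                  window_sd: float = 3.0,
                                  tolerance: float = 0.05) -> pd.DataFrame:
    """Check that density no longer predicts the normalized values.

    Using points within ``window_sd`` SDs of each feature's mean, the
    residual slope of the normalized value on density is recorded
    (``post_slope``), together with the fraction of variance density still
    explains (``post_r2``).  A feature is ``verified`` when that fraction is
    at most ``tolerance``; for noiseless data the slope cancels exactly.
    """
    norm_matrix.require_stage("normalized", op="verify_density_effect_removed")
    dens = pd.Series(densities).reindex(norm_matrix.values.index).to_numpy(float)
    records = []
    for feature in norm_matrix.values.columns:
        y = norm_matrix.values[feature].to_numpy(float)
        ok = np.isfinite(y)
        y_ok, d_ok = y[ok], dens[ok]
        mu, sd = y_ok.mean(), y_ok.std(ddof=1) if y_ok.size > 1 else 0.0
        win = np.abs(y_ok - mu) <= window_sd * sd if sd > 0 else np.ones_like(y_ok, bool)
        yw, dw_ = y_ok[win], d_ok[win]
        if yw.size < 3 or np.ptp(dw_) == 0:
            records.append({"feature_id": feature, "post_slope": np.nan,
                            "post_r2": np.nan, "verified": False})
            continue
        sd_w = yw.std(ddof=1)
        if sd_w <= 1e-10 * max(1.0, abs(yw.mean())):
            # (numerically) constant feature: density explains nothing
            records.append({"feature_id": feature, "post_slope": 0.0,
                            "post_r2": 0.0, "verified": True})
            continue
        X = np.column_stack([np.ones_like(dw_), dw_ - dw_.mean()])
        coef, *_ = np.linalg.lstsq(X, yw, rcond=None)
        fitted = X @ coef
        ss_tot = float(np.sum((yw - yw.mean()) ** 2))
        ss_mod = float(np.sum((fitted - yw.mean()) ** 2))
        r2 = ss_mod / ss_tot if ss_tot > 0 else 0.0
        records.append({
            "feature_id": feature,
            "post_slope": float(coef[1]),
            "post_r2": r2,
            "verified": bool(r2 <= tolerance),
        })
    return pd.DataFrame(records).set_index("feature_id")


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps ranks ``r`` (average rank for ties) to standard-normal quantiles
    ``Phi^-1((r - 3/8) / (n + 1/4))``.  Missing values stay missing; the
    output is monotone in the input.
    """
    x = np.asarray(values, float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("at least 2 non-missing values are required for INT")
    xv = x[ok]
    if np.ptp(xv) == 0:
        raise ValueError("all values identical; ranks are undefined for inference")
    ranks = stats.rankdata(xv, method="average")
    out[ok] = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def int_transform_matrix(matrix: FeatureMatrix, offset: float = 0.375) -> FeatureMatrix:
    """Apply the inverse normal transform to every feature column."""
    matrix.require_stage("normalized", op="inverse normal transform")
    out = matrix.copy_with(stage="int")
    cols = {f: inverse_normal_transform(out.values[f], offset=offset)
            for f in out.values.columns}
    out.values = pd.DataFrame(cols, index=out.values.index)[out.values.columns]
    return out


class DensityNormalizer:
    """Control-anchored urine-dilution correction, transformer style.

    Fit estimates per-feature dilution slopes ``beta_m`` from a control
    subset by regressing each (percent-of-median) concentration on
    ``(d_i - d_w)``; transform divides every cell by ``beta_m (d_i - d_w)``.

    Parameters
    ----------
    d_w : float
        Reference density of pure water.
    outlier_sd : float
        Control values further than this many SDs from the feature mean are
        replaced by the mean before the fit.
    beta_floor : float
        Slopes at or below this are treated as missing dilution signal; the
        feature is scaled by ``(d_i - d_w)`` alone and flagged.
    tolerance : float
        Verification bound on the variance fraction density may still
        explain after normalization.

    Attributes
    ----------
    models_ : DataFrame
        Per-feature ``beta_m``, intercept and fitting diagnostics.
    verification_ : DataFrame
        Residual slope / variance fraction and verified flag per feature
        (populated by :meth:`verify`).
    """

    def __init__(self, d_w: float = 1.0, outlier_sd: float = 2.5,
                 beta_floor: float = BETA_FLOOR, tolerance: float = 0.05,
                 window_sd: float = 3.0):
        self.d_w = d_w
        self.outlier_sd = outlier_sd
        self.beta_floor = beta_floor
        self.tolerance = tolerance
        self.window_sd = window_sd

    def get_params(self, deep: bool = True) -> dict:
        return {"d_w": self.d_w, "outlier_sd": self.outlier_sd,
                "beta_floor": self.beta_floor, "tolerance": self.tolerance,
                "window_sd": self.window_sd}

    def set_params(self, **params) -> "DensityNormalizer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, matrix: FeatureMatrix, densities: pd.Series,
            control_mask) -> "DensityNormalizer":
        self.models_ = fit_density_models(
            matrix, densities, control_mask, d_w=self.d_w,
            outlier_sd=self.outlier_sd,
        )
        return self

    def transform(self, matrix: FeatureMatrix, densities: pd.Series) -> FeatureMatrix:
        if not hasattr(self, "models_"):
            raise RuntimeError("DensityNormalizer must be fitted before transform")
        return apply_density_normalization(
            matrix, densities, self.models_, d_w=self.d_w,
            beta_floor=self.beta_floor,
        )

    def fit_transform(self, matrix: FeatureMatrix, densities: pd.Series,
                      control_mask) -> FeatureMatrix:
        return self.fit(matrix, densities, control_mask).transform(matrix, densities)

    def verify(self, norm_matrix: FeatureMatrix, densities: pd.Series) -> pd.DataFrame:
        self.verification_ = verify_density_effect_removed(
            norm_matrix, densities, window_sd=self.window_sd,
            tolerance=self.tolerance,
        )
        merged = self.models_.join(self.verification_)
        self.models_ = merged
        return self.verification_


def run_preprocessing(matrix: FeatureMatrix, densities: pd.Series, control_mask,
                      rsdqc_threshold: float = 20.0, d_w: float = 1.0,
                      outlier_sd: float = 2.5, tolerance: float = 0.05,
                      ) -> dict:
    """Run the full chain and return every intermediate product.

    Returns a dict with keys ``qc``, ``filtered``, ``imputed``, ``scaled``,
    ``normalizer``, ``normalized``, ``verification`` and ``int``.
    """
    qc = compute_qc_table(matrix)
    filtered, qc_report = filter_features(matrix, qc, threshold=rsdqc_threshold)
    imputed = impute_below_lod(filtered)
    scaled = percent_of_median_matrix(imputed)
    mask = (control_mask.reindex(scaled.values.index)
            if isinstance(control_mask, pd.Series) else control_mask)
    normalizer = DensityNormalizer(d_w=d_w, outlier_sd=outlier_sd, tolerance=tolerance)
    normalized = normalizer.fit_transform(scaled, densities, mask)
    verification = normalizer.verify(normalized, densities)
    int_matrix = int_transform_matrix(normalized)
    return {
        "qc": qc_report, "filtered": filtered, "imputed": imputed,
        "scaled": scaled, "normalizer": normalizer, "normalized": normalized,
        "verification": verification, "int": int_matrix,
    }
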