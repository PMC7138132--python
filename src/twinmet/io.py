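"""Readers, writers and report serialization.

All tabular interchange is RFC-4180 CSV/TSV with a header row, UTF-8.
Cohort and feature-matrix readers validate schema and pair integrity on
load.  Cascade reports are written as per-phase TSV tables (p-values to 3
significant digits, effects to 2 decimals) plus a machine-readable JSON
report at full precision with a provenance block.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, validate_cohort, CohortError
from .cascade import CascadeReport

__all__ = [
    "read_cohort", "write_cohort", "write_feature_matrix", "read_feature_matrix",
    "write_report", "validate_report_dict", "write_ace_estimate",
]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    ``NA`` is a legitimate zygosity label (clinical cases), so only empty
    cells are treated as missing.
    """
    cohort = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in ("excl_chronic", "excl_medication", "excl_vitamins"):
        if col in cohort.columns:
            cohort[col] = cohort[col].astype(bool)
    return validate_cohort(cohort)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    validate_cohort(cohort)
    cohort.to_csv(path, index=False)


def write_feature_matrix(matrix: FeatureMatrix, out_dir, prefix: str = "features") -> dict:
    """Write values, metadata and QC replicates; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": out / f"{prefix}_matrix.csv",
        "meta": out / f"{prefix}_metadata.csv",
    }
    matrix.values.to_csv(paths["values"])
    meta = matrix.feature_meta.copy()
    meta["n_imputed"] = matrix.n_imputed
    meta.to_csv(paths["meta"])
    if matrix.qc_replicates is not None:
        paths["qc"] = out / f"{prefix}_qc_replicates.csv"
        matrix.qc_replicates.to_csv(paths["qc"], index=False)
    if matrix.below_lod is not None and matrix.below_lod.any().any():
        paths["below_lod"] = out / f"{prefix}_below_lod.csv"
        matrix.below_lod.astype(int).to_csv(paths["below_lod"])
    return paths


def read_feature_matrix(values_path, meta_path, qc_path=None,
                        below_lod_path=None, stage: str = "raw") -> FeatureMatrix:
    values = pd.read_csv(values_path, index_col=0)
    meta = pd.read_csv(meta_path, index_col=0)
    if "panel" not in meta.columns:
        raise CohortError("feature metadata must carry a 'panel' column")
    qc = pd.read_csv(qc_path) if qc_path else None
    below = (pd.read_csv(below_lod_path, index_col=0).astype(bool)
             if below_lod_path else None)
    n_imputed = meta["n_imputed"] if "n_imputed" in meta.columns else None
    return FeatureMatrix(values=values, feature_meta=meta, qc_replicates=qc,
                         below_lod=below, n_imputed=n_imputed, stage=stage)


def _fmt(value, kind: str) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return "NA"
    if kind == "p":
        return f"{value:.3g}"
    if kind == "effect":
        return f"{value:.2f}"
    if kind == "int":
        return str(int(value))
    return str(value)


_PHASE_COLUMNS = {
    "gee": [("panel", "str"), ("n", "int"), ("beta", "effect"), ("se", "effect"),
            ("p", "p"), ("fdr_p", "p")],
    "paired": [("n_pairs", "int"), ("mean_diff", "effect"), ("t", "effect"),
               ("df", "int"), ("p", "p"), ("fdr_p", "p")],
}


def _write_phase_tsv(df: Optional[pd.DataFrame], path: Path, kind: str,
                     extra: tuple[str, ...] = ()) -> None:
    spec = [c for c in _PHASE_COLUMNS[kind] if df is not None and c[0] in df.columns]
    spec += [(c, "str") for c in extra if df is not None and c in df.columns]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        header = ["id"] + [name for name, _ in spec]
        fh.write("\t".join(header) + "\n")
        if df is None or len(df) == 0:
            return
        for idx, row in df.iterrows():
            cells = [str(idx)] + [_fmt(row[name], kind_) for name, kind_ in spec]
            fh.write("\t".join(cells) + "\n")


def write_report(report: CascadeReport, out_dir) -> dict:
    """Write per-phase TSV tables plus the full JSON report.

    Output is deterministic: fixed column order, fixed number formatting,
    sorted JSON keys — two runs with the same seed and configuration
    produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = [
        ("discovery_features.tsv", report.discovery_features, "gee", ()),
        ("discovery_ratios.tsv", report.discovery_ratios, "gee", ()),
        ("replication_features.tsv", report.replication_features, "paired", ()),
        ("replication_ratios.tsv", report.replication_ratios, "paired", ()),
        ("validation_features.tsv", report.validation_features, "gee", ()),
        ("validation_ratio.tsv", report.validation_ratio, "gee", ()),
        ("sensitivity_features.tsv", report.sensitivity_features, "paired",
         ("scenario",)),
        ("sensitivity_ratios.tsv", report.sensitivity_ratios, "paired",
         ("scenario",)),
    ]
    for name, df, kind, extra in tables:
        path = out / name
        _write_phase_tsv(df, path, kind, extra)
        paths[name] = path
    json_path = out / "cascade_report.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, sort_keys=True, indent=1)
        fh.write("\n")
    paths["json"] = json_path
    return paths


def _load_schema() -> dict:
    with resources.files("twinmet").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report_dict(data: dict) -> None:
    """Structural validation of a serialized cascade report.

    Checks the shipped schema's required keys and basic types without an
    external JSON-Schema engine.
    """
    schema = _load_schema()

    def check(node, spec, path="$"):
        required = spec.get("required", [])
        props = spec.get("properties", {})
        if spec.get("type") == "object":
            if not isinstance(node, dict):
                raise ValueError(f"{path}: expected object")
            for key in required:
                if key not in node:
                    raise ValueError(f"{path}: missing required key {key!r}")
            for key, sub in props.items():
                if key in node and node[key] is not None:
                    check(node[key], sub, f"{path}.{key}")
        elif spec.get("type") == "array":
            if not isinstance(node, list):
                raise ValueError(f"{path}: expected array")

    check(data, schema)


def write_ace_estimate(estimate, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(estimate.to_dict(), fh, sort_keys=True, indent=1)
        fh.write("\n")
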