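"""Neurotransmitter anabolism/catabolism ratios.

Ratios of precursor to product (synthesis) or transmitter to degradation
product proxy the flux through the serotonergic, dopaminergic and GABAergic
pathways.  They are formed on density-normalized concentrations (before the
inverse normal transform, whose output can be non-positive) and are
INT-transformed separately for association analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureMatrix

__all__ = ["RatioDefinition", "default_ratio_definitions", "compute_ratios",
           "ratios_to_yaml", "ratios_from_yaml"]

PATHWAYS = ("serotonergic", "dopaminergic", "GABAergic")
DIRECTIONS = ("anabolism", "catabolism")


@dataclass(frozen=True)
class RatioDefinition:
    """A named numerator/denominator metabolite pair with pathway labels."""

    name: str
    numerator: str
    denominator: str
    pathway: str
    direction: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError(
                f"ratio {self.name!r}: numerator and denominator must differ"
            )
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


def default_ratio_definitions() -> tuple[RatioDefinition, ...]:
    """The seven standard neurotransmitter ratios.

    Serotonergic anabolism: L-tryptophan:5HTP and 5HTP:serotonin.
    Dopaminergic anabolism: L-phenylalanine:L-tyrosine; catabolism: 3MT:HVA.
    GABA synthesis: L-glutamine:L-glutamic acid and L-glutamic acid:GABA;
    GABA degradation: GABA:succinic acid.
    """
    return (
        RatioDefinition("L-tryptophan:5HTP", "L-tryptophan",
                        "5-hydroxy-L-tryptophan", "serotonergic", "anabolism"),
        RatioDefinition("5HTP:serotonin", "5-hydroxy-L-tryptophan",
                        "serotonin", "serotonergic", "anabolism"),
        RatioDefinition("L-phenylalanine:L-tyrosine", "L-phenylalanine",
                        "L-tyrosine", "dopaminergic", "anabolism"),
        RatioDefinition("3MT:HVA", "3-methoxytyramine",
                        "homovanillic acid", "dopaminergic", "catabolism"),
        RatioDefinition("L-glutamine:L-glutamic acid", "L-glutamine",
                        "L-glutamic acid", "GABAergic", "anabolism"),
        RatioDefinition("L-glutamic acid:GABA", "L-glutamic acid",
                        "GABA", "GABAergic", "anabolism"),
        RatioDefinition("GABA:succinic acid", "GABA",
                        "succinic acid", "GABAergic", "catabolism"),
    )


def compute_ratios(matrix: FeatureMatrix,
                   definitions: tuple[RatioDefinition, ...] | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject ratios on the density-normalized (pre-INT) scale.

    Non-positive or missing denominators yield a missing ratio (never an
    infinity).  Returns the ratio matrix and a per-ratio report with the
    count of unusable denominators.
    """
    if definitions is None:
        definitions = default_ratio_definitions()
    matrix.require_stage("normalized", op="compute_ratios")
    needed = sorted({d.numerator for d in definitions}
                    | {d.denominator for d in definitions})
    absent = [f for f in needed if f not in matrix.values.columns]
    if absent:
        raise ValueError(f"ratio metabolites absent from the matrix: {absent}")
    out = {}
    report = []
    for d in definitions:
        num = matrix.values[d.numerator].to_numpy(float)
        den = matrix.values[d.denominator].to_numpy(float)
        bad = ~np.isfinite(den) | (den <= 0) | ~np.isfinite(num)
        ratio = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
        out[d.name] = ratio
        report.append({"ratio": d.name, "pathway": d.pathway,
                       "direction": d.direction, "n_missing": int(bad.sum())})
    ratio_df = pd.DataFrame(out, index=matrix.values.index)
    return ratio_df, pd.DataFrame(report).set_index("ratio")


def ratios_to_yaml(definitions, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump([asdict(d) for d in definitions], fh, sort_keys=False)


def ratios_from_yaml(path) -> tuple[RatioDefinition, ...]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return tuple(RatioDefinition(**d) for d in raw)
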