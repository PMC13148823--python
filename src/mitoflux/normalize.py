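"""Flux normalization: wet weight, total protein, and mitochondrial content.

Respirometry (and H2O2 emission) rates are expressed three ways:

* per mg wet weight — what the instrument yields directly;
* per µg total protein — dividing by the group-mean Bradford factor
  (µg protein per mg wet weight), removing density/hydration differences;
* per mitochondrial content — dividing the total-protein-normalized rate by
  the group mitochondrial enrichment factor (MEF), the summed MitoCarta-
  flagged protein abundance over total proteome abundance.

MEF normalization asks whether a flux difference survives after accounting
for how much mitochondrial protein the tissue contains, i.e. whether the
change is intrinsic to the mitochondria rather than a content effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import validate_annotation
from .omics import AbundanceMatrix

__all__ = [
    "NormalizationFactors",
    "compute_mef",
    "protein_factor",
    "apply_normalization",
    "calibrate_h2o2",
]

SCHEMES = ("wet_weight", "total_protein", "mef")

UNITS = {
    "wet_weight": "pmol_s-1_mg-1",
    "total_protein": "pmol_s-1_ug-1",
    "mef": "pmol_s-1_ug-1_mef-1",
}


@dataclass
class NormalizationFactors:
    """Per-group normalization factors.

    ``protein_ug_per_mg``: group-mean µg total protein per mg wet weight;
    ``mef``: group mitochondrial enrichment factor in [0, 1];
    ``mef_per_sample``: optional per-sample MEF values for audit.
    """

    protein_ug_per_mg: dict[str, float] = field(default_factory=dict)
    mef: dict[str, float] = field(default_factory=dict)
    mef_per_sample: pd.Series | None = None

    def validate(self) -> "NormalizationFactors":
        for g, v in self.protein_ug_per_mg.items():
            if not v > 0:
                raise ValueError(f"protein_ug_per_mg[{g}] must be > 0")
        for g, v in self.mef.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mef[{g}]={v} outside [0, 1]")
        return self


def compute_mef(
    abundance: AbundanceMatrix, annotation: pd.DataFrame
) -> tuple[dict[str, float], pd.Series]:
    """Mitochondrial enrichment factor per group (and per sample).

    Per sample: summed abundance of mitochondrial features over summed
    abundance of all features (missing values contribute zero).  The group
    MEF is the mean over its samples.
    """
    if abundance.layer != "protein":
        raise ValueError("MEF is defined on the protein layer")
    validate_annotation(annotation)
    mito_ids = set(annotation.loc[annotation["is_mito"].astype(bool), "feature_id"])
    vals = abundance.values.fillna(0.0)
    total = vals.sum(axis=0)
    if (total <= 0).any():
        bad = list(total.index[total <= 0])[:5]
        raise ValueError(f"zero total abundance for samples {bad}")
    mito_mask = vals.index.isin(mito_ids)
    per_sample = vals.loc[mito_mask].sum(axis=0) / total
    per_sample.name = "mef"
    group_mef = {
        g: float(per_sample[abundance.sample_ids(g)].mean())
        for g in abundance.group_names
    }
    return group_mef, per_sample


def protein_factor(bradford_table: pd.DataFrame) -> dict[str, float]:
    """Group-mean µg protein per mg wet weight from a Bradford table.

    Expects columns sample_id, group, wet_mg, protein_ug; the per-sample
    ratio protein_ug / wet_mg is averaged within group.
    """
    need = {"sample_id", "group", "wet_mg", "protein_ug"}
    if not need <= set(bradford_table.columns):
        raise ValueError(f"bradford table missing columns {sorted(need - set(bradford_table.columns))}")
    if (bradford_table["wet_mg"] <= 0).any():
        raise ValueError("wet_mg must be positive")
    if (bradford_table["protein_ug"] < 0).any():
        raise ValueError("protein_ug must be non-negative")
    ratio = bradford_table["protein_ug"] / bradford_table["wet_mg"]
    return ratio.groupby(bradford_table["group"]).mean().to_dict()


def apply_normalization(
    state_table: pd.DataFrame,
    scheme: str,
    factors: NormalizationFactors | None = None,
) -> pd.DataFrame:
    """Re-express a flux state table under a normalization scheme.

    ``wet_weight`` passes per-mg values through unchanged; ``total_protein``
    divides by the sample group's protein factor (per µg protein); ``mef``
    further divides the total-protein value by the group MEF.  The output
    records the scheme and units.  Normalization is a positive per-group
    scalar, so within-group sample ranking is scheme-invariant.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme '{scheme}' (choose from {SCHEMES})")
    out = state_table.copy()
    if scheme == "wet_weight":
        out["scheme"] = scheme
        out["units"] = UNITS[scheme]
        return out
    if factors is None:
        raise ValueError(f"scheme '{scheme}' requires NormalizationFactors")
    factors.validate()
    groups = out["group"].unique()
    missing = [g for g in groups if g not in factors.protein_ug_per_mg]
    if missing:
        raise ValueError(f"missing protein factor for groups {missing}")
    denom = out["group"].map(factors.protein_ug_per_mg)
    if scheme == "mef":
        missing = [g for g in groups if g not in factors.mef]
        if missing:
            raise ValueError(f"missing MEF for groups {missing}")
        zero = [g for g in groups if factors.mef[g] == 0]
        if zero:
            raise ValueError(f"MEF of zero for groups {zero}")
        denom = denom * out["group"].map(factors.mef)
    out["jo2"] = out["jo2"] / denom
    out["scheme"] = scheme
    out["units"] = UNITS[scheme]
    return out


def calibrate_h2o2(
    fluorescence_table: pd.DataFrame,
    standard_curve_table: pd.DataFrame,
    volume_ml: float = 1.0,
    amount_col: str = "amount_mg",
    state: str = "S",
) -> pd.DataFrame:
    """Convert Amplex Red fluorescence time courses to H2O2 emission rates.

    The standard curve (columns ``conc_uM``, ``fluorescence_au``, >= 2
    distinct concentrations) is fit by linear least squares
    AU = a + b * [H2O2]; each sample's fluorescence drift (AU/s, OLS slope
    over its time course) becomes a concentration slope (µM/s) via 1/b, and

        rate = conc_slope * volume_ml * 1000 / amount   (pmol s-1 mg-1).

    ``fluorescence_table`` needs columns sample_id, group, time_s,
    fluorescence_au and a per-sample amount column.  Returns a flux state
    table (analyte H2O2) compatible with :func:`apply_normalization`.
    """
    need = {"conc_uM", "fluorescence_au"}
    if not need <= set(standard_curve_table.columns):
        raise ValueError("standard curve needs columns conc_uM, fluorescence_au")
    conc = standard_curve_table["conc_uM"].to_numpy(dtype=float)
    au = standard_curve_table["fluorescence_au"].to_numpy(dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("standard curve needs >= 2 distinct concentrations")
    b, a = np.polyfit(conc, au, 1)
    if b == 0:
        raise ValueError("singular calibration: fluorescence does not depend on concentration")
    rows = []
    for (sample, group), df in fluorescence_table.groupby(["sample_id", "group"], sort=False):
        t = df["time_s"].to_numpy(dtype=float)
        y = df["fluorescence_au"].to_numpy(dtype=float)
        if len(t) < 3:
            raise ValueError(f"sample {sample}: need >= 3 fluorescence points")
        au_slope = np.polyfit(t, y, 1)[0]
        conc_slope = au_slope / b  # µM/s
        amount = float(df[amount_col].iloc[0])
        rate = conc_slope * volume_ml * 1000.0 / amount
        rows.append(
            {
                "sample_id": sample,
                "group": group,
                "state": state,
                "jo2": float(rate),
                "analyte": "H2O2",
                "units": "pmol_s-1_mg-1",
            }
        )
    return pd.DataFrame(rows)
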