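"""Synthetic study generator: every pipeline input with known ground truth.

Emulates the structure of a benign-vs-tumor bioenergetics study: SUIT
respirometry traces (linear O2 decline per state plus Gaussian sensor
noise, two technical replicates per biological sample), a label-free
proteome with mitochondrial content shifts and Bernoulli detection dropout,
a TPM transcriptome with per-complex OXPHOS shifts, a Bradford total-protein
table, and the percent-based cell-type tables feeding the OXPHOS mRNA
Index.  All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import (
    COMPLEX_LABELS,
    OXPHOS_COMPLEX_GENES,
    builtin_fixture_annotation,
)
from .config import GeneratorConfig, GroupConfig
from .omics import AbundanceMatrix, TPM_TOTAL
from .respiro import PROTOCOLS, RespirometryTrace, protocol_states

__all__ = [
    "simulate_respirometry",
    "simulate_proteome",
    "simulate_transcriptome",
    "simulate_celltype_tables",
    "simulate_bradford",
    "bradford_from_proteome",
    "central_contrast_config",
    "fixture_annotation_for",
    "ProteomeSim",
]

# Default cell-type universe: the six IF-harmonized major types with their
# single-cell reference-atlas proportions and immunopositive tissue areas.
DEFAULT_CELLTYPES: dict[str, dict] = {
    "epithelial":   {"scref": 0.35, "benign_pct": 40.0, "tumor_pct": 60.0},
    "mesenchymal":  {"scref": 0.25, "benign_pct": 25.0, "tumor_pct": 15.0},
    "myeloid":      {"scref": 0.15, "benign_pct": 10.0, "tumor_pct": 10.0},
    "T":            {"scref": 0.15, "benign_pct": 10.0, "tumor_pct": 8.0},
    "endothelial":  {"scref": 0.07, "benign_pct": 8.0,  "tumor_pct": 5.0},
    "plasmablasts": {"scref": 0.03, "benign_pct": 2.0,  "tumor_pct": 1.0},
}


def _rng(config: GeneratorConfig, seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-(config, seed, stream) generator."""
    return np.random.default_rng(
        np.random.SeedSequence([abs(int(config.seed)), abs(int(seed)), stream])
    )


def _state_flux(group: GroupConfig, state: str, protocol: str) -> float:
    """Ground-truth flux for a composite state, pmol O2 s-1 mg-1."""
    cc = group.cc_response_fraction
    ref = "PMDGS"
    j_ref = group.true_jo2.get(ref, 0.0)
    j_max = j_ref * (1.0 + cc) if cc is not None else j_ref
    if state in group.true_jo2:
        return group.true_jo2[state]
    if state == "PMDGSC":
        return j_max
    if state == "OMY":
        return (1.0 - group.coupling_fraction) * j_max
    if state in ("AMA", "AMA_ROT", "ROT"):
        return group.residual_fraction * j_max
    raise KeyError(f"no ground-truth flux for state '{state}' in group {group.name}")


def simulate_respirometry(
    config: GeneratorConfig, protocol: str, seed: int = 0
) -> list[RespirometryTrace]:
    """Simulate SUIT traces for every group.

    Each biological sample yields ``config.n_technical_replicates`` traces.
    O2 starts at ``o2_start_uM`` and, within each state segment, declines
    linearly with slope -JO2 * amount / (1000 * chamber_volume_ml) µM/s plus
    i.i.d. Gaussian noise of sd ``noise_sd``.  Per-sample biological
    variability multiplies the whole flux ladder by a lognormal factor with
    CV ``biological_cv`` (shared across technical replicates).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol '{protocol}' (choose from {sorted(PROTOCOLS)})")
    config.validate()
    traces: list[RespirometryTrace] = []
    dur, dt = config.state_duration_s, config.dt_s
    for gi, (gname, group) in enumerate(sorted(config.groups.items())):
        rng = _rng(config, seed, 100 + gi)
        states = protocol_states(protocol, with_cc=group.cc_response_fraction is not None)
        labels = list(PROTOCOLS[protocol])
        if group.cc_response_fraction is not None:
            labels.insert(labels.index("S") + 1 if "S" in labels else len(labels), "CC")
        n_states = len(states)
        t = np.arange(0.0, n_states * dur, dt)
        seg_of_point = np.minimum((t // dur).astype(int), n_states - 1)
        for i in range(group.n_samples):
            bio = (
                rng.lognormal(mean=-0.5 * np.log1p(group.biological_cv**2),
                              sigma=np.sqrt(np.log1p(group.biological_cv**2)))
                if group.biological_cv > 0 else 1.0
            )
            fluxes = np.array([_state_flux(group, s, protocol) for s in states]) * bio
            slopes = -fluxes * group.amount_mg / (1000.0 * config.chamber_volume_ml)
            # integrate the piecewise-constant slope to the O2 curve
            incr = slopes[seg_of_point] * dt
            o2_clean = config.o2_start_uM + np.concatenate([[0.0], np.cumsum(incr[:-1])])
            events = [(float((k + 1) * dur), lab) for k, lab in enumerate(labels)]
            for r in range(config.n_technical_replicates):
                noise = (
                    rng.normal(0.0, group.noise_sd, size=o2_clean.shape)
                    if group.noise_sd > 0 else 0.0
                )
                traces.append(
                    RespirometryTrace(
                        sample_id=f"{gname}_{i + 1:02d}",
                        group=gname,
                        replicate_id=r + 1,
                        time_s=t.copy(),
                        o2_uM=o2_clean + noise,
                        events=list(events),
                        chamber_volume_ml=config.chamber_volume_ml,
                        amount=group.amount_mg,
                        amount_units="mg_wet_weight",
                        protocol=protocol,
                    )
                )
    return traces


def fixture_annotation_for(n_features: int, frac_mito: float) -> pd.DataFrame:
    """Fixture annotation sized to a simulated proteome.

    The OXPHOS subunit block is included whole when the mitochondrial slot
    count allows (>= 84 genes), otherwise truncated; remaining mitochondrial
    slots become complex-less mito filler and the rest non-mito background.
    """
    n_mito = int(round(n_features * frac_mito))
    n_oxphos = sum(len(v) for v in OXPHOS_COMPLEX_GENES.values())
    if n_mito >= n_oxphos:
        ann = builtin_fixture_annotation(
            n_extra_mito=n_mito - n_oxphos, n_background=n_features - n_mito
        )
    else:
        full = builtin_fixture_annotation(n_extra_mito=0, n_background=0)
        ann = pd.concat(
            [full.iloc[:n_mito],
             builtin_fixture_annotation(0, n_features - n_mito).iloc[n_oxphos:]],
            ignore_index=True,
        )
    return ann


@dataclass
class ProteomeSim:
    abundance: AbundanceMatrix
    annotation: pd.DataFrame
    truth: pd.DataFrame  # feature_id, is_mito, true_log2fc


def simulate_proteome(config: GeneratorConfig, seed: int = 0) -> ProteomeSim:
    """Simulate the label-free proteome.

    Log-normal intensities; tumor-group mitochondrial features are scaled by
    ``content_scale`` and shifted by ``mito_log2fc`` (log2).  Detection
    dropout is abundance-independent Bernoulli per feature x sample,
    producing the unique/shared detection structure.  The ground-truth
    per-feature log2 effect is returned alongside.
    """
    config.validate()
    rng = _rng(config, seed, 200)
    ann = fixture_annotation_for(config.n_features, config.frac_mito)
    features = ann["feature_id"].to_numpy()
    is_mito = ann["is_mito"].to_numpy(dtype=bool)
    base_log = rng.normal(np.log(1e5), 1.0, size=len(features))
    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    meta = {"degenerate_frac_mito": config.frac_mito in (0.0, 1.0)}
    benchmark = sorted(config.groups)  # alphabetical: benign before tumor
    ref_group = benchmark[0]
    truth_fc = {}
    for gname in benchmark:
        group = config.groups[gname]
        effect = np.zeros(len(features))
        if gname != ref_group:
            effect[is_mito] = np.log(group.content_scale) + group.mito_log2fc * np.log(2.0)
        truth_fc[gname] = effect / np.log(2.0)
        for s in range(group.n_omics_samples):
            noise = (
                rng.normal(0.0, config.abundance_sigma, size=len(features))
                if config.abundance_sigma > 0 else 0.0
            )
            vals = np.exp(base_log + effect + noise)
            rate = group.detection_dropout_rate
            if rate > 0:
                if config.dropout_mode == "uniform":
                    drop = rng.random(len(features)) < rate
                else:  # censor: the lowest `rate` fraction falls below the
                    # per-sample detection limit, so group-level abundance
                    # shifts produce group-exclusive detection sets
                    drop = vals < np.quantile(vals, rate)
                vals = np.where(drop, np.nan, vals)
            sid = f"{gname}_p{s + 1:02d}"
            columns[sid] = vals
            groups[sid] = gname
    values = pd.DataFrame(columns, index=pd.Index(features, name="feature_id"))
    truth = pd.DataFrame(
        {
            "feature_id": features,
            "is_mito": is_mito,
            "true_log2fc": truth_fc[benchmark[-1]],
        }
    )
    return ProteomeSim(
        abundance=AbundanceMatrix(values=values, groups=pd.Series(groups),
                                  layer="protein", meta=meta),
        annotation=ann,
        truth=truth,
    )


def simulate_transcriptome(config: GeneratorConfig, seed: int = 0) -> AbundanceMatrix:
    """Simulate a TPM transcriptome; columns sum to 1e6 exactly.

    OXPHOS subunit blocks follow the per-complex log2 shifts configured for
    each non-reference group (``complex_log2fc``); other genes are
    unshifted.
    """
    config.validate()
    rng = _rng(config, seed, 300)
    ann = fixture_annotation_for(config.n_features, config.frac_mito)
    genes = ann["gene_symbol"].to_numpy()
    cplx = ann["complex"].to_numpy()
    base_log = rng.normal(np.log(50.0), 1.0, size=len(genes))
    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    names = sorted(config.groups)
    ref_group = names[0]
    for gname in names:
        group = config.groups[gname]
        effect = np.zeros(len(genes))
        if gname != ref_group:
            for c, shift in group.complex_log2fc.items():
                if c not in COMPLEX_LABELS:
                    raise ValueError(f"unknown complex '{c}' in complex_log2fc")
                effect[cplx == c] = shift * np.log(2.0)
        for s in range(group.n_omics_samples):
            noise = (
                rng.normal(0.0, config.abundance_sigma, size=len(genes))
                if config.abundance_sigma > 0 else 0.0
            )
            raw = np.exp(base_log + effect + noise)
            sid = f"{gname}_t{s + 1:02d}"
            columns[sid] = raw / raw.sum() * TPM_TOTAL
            groups[sid] = gname
    values = pd.DataFrame(columns, index=pd.Index(genes, name="feature_id"))
    return AbundanceMatrix(values=values, groups=pd.Series(groups), layer="tpm")


def simulate_celltype_tables(
    config: GeneratorConfig, seed: int = 0, cell_types: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the cell-type expression summary and proportion tables.

    Returns ``(expression_summary, proportions)``: per (cell type, OXPHOS
    gene) percent of cells expressing with the reference-atlas cell-type
    proportion (proportions sum to 1), and per (group, cell type) percent
    immunopositive tissue area (per-group sums <= 100, overlap-free
    convention).
    """
    cell_types = cell_types if cell_types is not None else DEFAULT_CELLTYPES
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    rng = _rng(config, seed, 400)
    scref = np.array([v["scref"] for v in cell_types.values()], dtype=float)
    scref = scref / scref.sum()
    genes = [g for genes in OXPHOS_COMPLEX_GENES.values() for g in genes]
    expr_rows = []
    for (ct, spec_), prop in zip(cell_types.items(), scref):
        base = rng.uniform(35.0, 90.0)
        pct = np.clip(base + rng.normal(0.0, 8.0, size=len(genes)), 0.0, 100.0)
        for g, v in zip(genes, pct):
            expr_rows.append(
                {"cell_type": ct, "gene_symbol": g,
                 "pct_expressing": float(v), "scref_proportion": float(prop)}
            )
    prop_rows = []
    for grp, key in (("benign", "benign_pct"), ("tumor", "tumor_pct")):
        vals = np.array([v[key] for v in cell_types.values()], dtype=float)
        vals = vals * rng.lognormal(0.0, 0.05, size=len(vals))
        if vals.sum() > 98.0:  # overlap-free: group areas must sum <= 100
            vals = vals / vals.sum() * 98.0
        for ct, v in zip(cell_types, vals):
            prop_rows.append({"group": grp, "cell_type": ct,
                              "pct_immunopositive": float(v)})
    return pd.DataFrame(expr_rows), pd.DataFrame(prop_rows)


def simulate_bradford(config: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Per-sample Bradford table: (sample_id, group, wet_mg, protein_ug)."""
    config.validate()
    rng = _rng(config, seed, 500)
    rows = []
    for gname in sorted(config.groups):
        group = config.groups[gname]
        for i in range(group.n_omics_samples):
            wet = rng.uniform(8.0, 15.0)
            factor = group.protein_ug_per_mg * (
                rng.lognormal(0.0, np.sqrt(np.log1p(group.protein_cv**2)))
                if group.protein_cv > 0 else 1.0
            )
            rows.append(
                {"sample_id": f"{gname}_b{i + 1:02d}", "group": gname,
                 "wet_mg": float(wet), "protein_ug": float(wet * factor)}
            )
    return pd.DataFrame(rows)


def bradford_from_proteome(
    abundance: AbundanceMatrix, reference_group: str, reference_ug_per_mg: float
) -> dict[str, float]:
    """Per-group protein content tied to the realized proteome.

    Encodes the scenario in which non-mitochondrial protein per mg wet
    weight is identical across groups, so total protein per mg scales with
    the group-mean total abundance of the simulated matrix.  Used by the
    content-contrast scenario to keep the Bradford factor consistent with
    the proteome it accompanies.
    """
    totals = {
        g: float(abundance.values[abundance.sample_ids(g)].fillna(0.0).sum(axis=0).mean())
        for g in abundance.group_names
    }
    ref_total = totals[reference_group]
    return {g: reference_ug_per_mg * tot / ref_total for g, tot in totals.items()}


def central_contrast_config(
    base: GeneratorConfig, content_scale: float = 0.5
) -> GeneratorConfig:
    """Scenario config isolating the normalization algebra.

    The tumor group's mitochondrial protein content is scaled to
    ``content_scale`` of benign while the intrinsic flux per unit
    mitochondrial protein is kept equal, so its whole ground-truth flux
    ladder is the benign ladder times ``content_scale``.  Biological CV is
    reduced and dropout/extra effects are switched off so that the contrast
    reflects normalization arithmetic rather than cohort noise.
    """
    cfg = copy.deepcopy(base)
    benign = cfg.groups["benign"]
    tumor = cfg.groups["tumor"]
    tumor.true_jo2 = {s: v * content_scale for s, v in benign.true_jo2.items()}
    tumor.content_scale = content_scale
    tumor.mito_log2fc = 0.0
    tumor.coupling_fraction = benign.coupling_fraction
    tumor.amount_mg = benign.amount_mg
    for g in (benign, tumor):
        g.biological_cv = 0.10
        g.detection_dropout_rate = 0.0
        g.complex_log2fc = {}
    return cfg.validate()
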