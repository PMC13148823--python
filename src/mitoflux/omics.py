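"""Proteome/transcriptome processing and cross-layer integration.

Covers the descriptive layer of the study: which features are detected in
which group (Venn logic under dropout), a Welch-t + Benjamini–Hochberg
differential-abundance stand-in (externally produced DE tables, e.g. from
DESeq2, are accepted as first-class inputs), mitochondrial filtering and
summed abundances, per-complex OXPHOS summaries, and the integration of
transcript and protein log2 fold changes (matched pairs, Pearson r, joint
significance overlaps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from . import stats as mstats
from .annotation import COMPLEX_LABELS, validate_annotation

__all__ = [
    "AbundanceMatrix",
    "DetectionSets",
    "detect_features",
    "differential_abundance",
    "summed_mito_abundance",
    "complex_summaries",
    "integrate_layers",
]

logger = logging.getLogger(__name__)

TPM_TOTAL = 1_000_000.0
PADJ_THRESHOLD = 0.1  # adjusted-p significance threshold used throughout


@dataclass
class AbundanceMatrix:
    """An omics layer: features x samples values plus sample group labels.

    ``layer`` is ``"protein"`` (label-free intensities; missing values = not
    detected) or ``"tpm"`` (transcripts per million; columns sum to 1e6, no
    missingness).  ``values`` is indexed by feature_id with sample columns;
    ``groups`` maps sample -> group label.
    """

    values: pd.DataFrame
    groups: pd.Series
    layer: str = "protein"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.layer not in ("protein", "tpm"):
            raise ValueError(f"unknown layer '{self.layer}'")
        self.groups = pd.Series(self.groups)
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)[:5]}")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("abundances must be non-negative")
        if self.layer == "tpm":
            if np.isnan(vals).any():
                raise ValueError("tpm layer does not permit missing values")
            sums = self.values.sum(axis=0).to_numpy()
            if not np.allclose(sums, TPM_TOTAL, rtol=1e-6):
                raise ValueError("tpm columns must sum to 1e6")

    @property
    def detection(self) -> pd.DataFrame:
        """Boolean matrix: value observed (not missing)."""
        return self.values.notna()

    def sample_ids(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class DetectionSets:
    """Partition of detected features into shared / group-exclusive sets."""

    shared: frozenset
    group1_only: frozenset
    group2_only: frozenset
    group1: str = "group1"
    group2: str = "group2"

    def __post_init__(self):
        if self.shared & self.group1_only or self.shared & self.group2_only \
                or self.group1_only & self.group2_only:
            raise ValueError("detection sets must be pairwise disjoint")

    @property
    def all_detected(self) -> frozenset:
        return self.shared | self.group1_only | self.group2_only


def detect_features(matrix: AbundanceMatrix, min_samples: int = 3) -> DetectionSets:
    """Partition features by group detection.

    A feature is detected in a group iff it is observed (non-missing) in at
    least ``min_samples`` samples of that group.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    g1, g2 = matrix.group_names[:2]
    det = matrix.detection
    cols1, cols2 = matrix.sample_ids(g1), matrix.sample_ids(g2)
    if min_samples > len(cols1) or min_samples > len(cols2):
        raise ValueError(
            f"min_samples={min_samples} exceeds a group size ({len(cols1)}, {len(cols2)})"
        )
    in1 = det[cols1].sum(axis=1) >= min_samples
    in2 = det[cols2].sum(axis=1) >= min_samples
    idx = matrix.values.index
    return DetectionSets(
        shared=frozenset(idx[in1 & in2]),
        group1_only=frozenset(idx[in1 & ~in2]),
        group2_only=frozenset(idx[~in1 & in2]),
        group1=g1,
        group2=g2,
    )


def differential_abundance(
    matrix: AbundanceMatrix,
    pseudocount: float | None = None,
    group1: str | None = None,
    group2: str | None = None,
    features=None,
) -> pd.DataFrame:
    """Welch-t differential abundance on log2(value + pseudocount).

    log2fc is group2 minus group1 mean log2 abundance (tumor vs benign with
    the default group ordering benign, tumor).  P-values are Welch two-tailed
    and Benjamini–Hochberg adjusted; features are significant at
    padj < 0.1.  Features with zero variance in both groups get p = 1 and
    ``zero_variance=True`` rather than NaN.  By default the test runs on the
    features detected in both groups (shared set, min 2 observed per group).
    """
    if pseudocount is None:
        pseudocount = 0.5 if matrix.layer == "tpm" else 1.0
    names = matrix.group_names
    group1 = group1 or names[0]
    group2 = group2 or names[1]
    cols1, cols2 = matrix.sample_ids(group1), matrix.sample_ids(group2)
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("need >= 2 samples per group")
    vals = matrix.values
    if features is None:
        det = matrix.detection
        keep = (det[cols1].sum(axis=1) >= 2) & (det[cols2].sum(axis=1) >= 2)
        features = vals.index[keep]
    a = np.log2(vals.loc[features, cols1].to_numpy(dtype=float) + pseudocount)
    b = np.log2(vals.loc[features, cols2].to_numpy(dtype=float) + pseudocount)
    log2fc = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.ttest_ind(
            b, a, axis=1, equal_var=False, nan_policy="omit"
        )
    p = np.asarray(res.pvalue, dtype=float)
    var_a = np.nanvar(a, axis=1, ddof=1)
    var_b = np.nanvar(b, axis=1, ddof=1)
    zero_var = (var_a == 0) & (var_b == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    padj = mstats.bh_adjust(p)
    out = pd.DataFrame(
        {
            "feature_id": np.asarray(features),
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "zero_variance": zero_var,
        }
    )
    out["significant"] = out["padj"] < PADJ_THRESHOLD
    out["direction"] = np.where(
        ~out["significant"], "ns", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out


def summed_mito_abundance(
    matrix: AbundanceMatrix, annotation: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Summed abundance of all detected mitochondrial features.

    Returns ``(per_sample, per_group)`` where per_group carries mean and SD
    over the samples of each group.  Missing values count as zero (not
    detected contributes nothing to the sum).
    """
    validate_annotation(annotation)
    mito = annotation.loc[annotation["is_mito"].astype(bool), "feature_id"]
    present = [f for f in mito if f in matrix.values.index]
    per_sample = matrix.values.loc[present].fillna(0.0).sum(axis=0)
    per_sample.name = "summed_mito_abundance"
    rows = []
    for g in matrix.group_names:
        vals = per_sample[matrix.sample_ids(g)]
        rows.append({"group": g, "mean": vals.mean(),
                     "sd": vals.std(ddof=1), "n": len(vals)})
    return per_sample, pd.DataFrame(rows)


def complex_summaries(
    matrix: AbundanceMatrix, annotation: pd.DataFrame, denominator: str = "mito"
) -> pd.DataFrame:
    """Per-complex summed OXPHOS abundance relative to a denominator set.

    For each respiratory complex c: sum of abundances of features assigned
    to c divided by the summed abundance of the denominator set (``mito`` =
    all mitochondrial features, ``total`` = whole matrix).  The two
    denominators differ feature-wise by exactly the per-sample mitochondrial
    enrichment factor.
    """
    if denominator not in ("mito", "total"):
        raise ValueError("denominator must be 'mito' or 'total'")
    validate_annotation(annotation)
    ann = annotation.set_index("feature_id")
    common = matrix.values.index.intersection(ann.index)
    vals = matrix.values.loc[common].fillna(0.0)
    ann = ann.loc[common]
    if denominator == "mito":
        denom = vals.loc[ann["is_mito"].astype(bool)].sum(axis=0)
    else:
        denom = vals.sum(axis=0)
    if (denom <= 0).any():
        bad = list(denom.index[denom <= 0])[:5]
        raise ValueError(f"empty/zero denominator for samples {bad}")
    rows = []
    for cplx in COMPLEX_LABELS:
        feats = ann.index[ann["complex"] == cplx]
        num = vals.loc[feats].sum(axis=0) if len(feats) else pd.Series(0.0, index=vals.columns)
        frac = num / denom
        for sample, v in frac.items():
            rows.append(
                {
                    "complex": cplx,
                    "sample_id": sample,
                    "group": matrix.groups[sample],
                    "relative_abundance": float(v),
                    "denominator": denominator,
                    "n_features": int(len(feats)),
                }
            )
    return pd.DataFrame(rows)


def _collapse_duplicates(de: pd.DataFrame, layer: str) -> pd.DataFrame:
    """Resolve multi-mapped gene symbols: keep the entry with the largest
    mean abundance (``base_mean`` column) when available, else the smallest
    adjusted p; collapses are logged."""
    de = de.copy()
    de["_symbol"] = de["gene_symbol"].str.casefold()
    dup = de["_symbol"].duplicated(keep=False)
    if dup.any():
        logger.info(
            "%s layer: collapsing %d rows with multi-mapped symbols",
            layer, int(dup.sum()),
        )
        key = "base_mean" if "base_mean" in de.columns else None
        if key:
            de = de.sort_values(key, ascending=False)
        else:
            de = de.sort_values("padj", ascending=True)
        de = de.drop_duplicates("_symbol", keep="first")
    return de


@dataclass
class IntegrationResult:
    pairs: pd.DataFrame           # gene, rna_log2fc, protein_log2fc, is_mito, ...
    pearson_r: float
    down_down: frozenset          # jointly significant downregulated genes
    up_up: frozenset


def integrate_layers(
    de_rna: pd.DataFrame, de_protein: pd.DataFrame, annotation: pd.DataFrame
) -> IntegrationResult:
    """Match transcript and protein differential results by gene symbol.

    Matching is case-insensitive; duplicated symbols are collapsed (largest
    mean abundance, else smallest padj).  Returns the matched log2FC pairs
    with mitochondrial flags, their Pearson correlation, and the overlap
    sets of jointly significant down/down and up/up genes (padj < 0.1 in
    both layers).
    """
    for name, de in (("rna", de_rna), ("protein", de_protein)):
        need = {"gene_symbol", "log2fc", "padj"}
        if not need <= set(de.columns):
            raise ValueError(f"{name} DE table missing columns {sorted(need - set(de.columns))}")
    rna = _collapse_duplicates(de_rna, "rna").set_index("_symbol")
    prot = _collapse_duplicates(de_protein, "protein").set_index("_symbol")
    common = rna.index.intersection(prot.index)
    if len(common) == 0:
        raise ValueError("no overlapping gene symbols between layers")
    ann = validate_annotation(annotation).copy()
    ann["_symbol"] = ann["gene_symbol"].str.casefold()
    mito_map = ann.drop_duplicates("_symbol").set_index("_symbol")["is_mito"]
    pairs = pd.DataFrame(
        {
            "gene_symbol": rna.loc[common, "gene_symbol"],
            "rna_log2fc": rna.loc[common, "log2fc"],
            "protein_log2fc": prot.loc[common, "log2fc"],
            "rna_padj": rna.loc[common, "padj"],
            "protein_padj": prot.loc[common, "padj"],
            "is_mito": mito_map.reindex(common).fillna(False).astype(bool),
        }
    ).reset_index(drop=True)
    try:
        r = mstats.pearson(pairs["rna_log2fc"].to_numpy(),
                           pairs["protein_log2fc"].to_numpy())
    except ValueError:  # < 3 pairs or a constant layer
        r = float("nan")
    sig = (pairs["rna_padj"] < PADJ_THRESHOLD) & (pairs["protein_padj"] < PADJ_THRESHOLD)
    down = sig & (pairs["rna_log2fc"] < 0) & (pairs["protein_log2fc"] < 0)
    up = sig & (pairs["rna_log2fc"] > 0) & (pairs["protein_log2fc"] > 0)
    return IntegrationResult(
        pairs=pairs,
        pearson_r=r,
        down_down=frozenset(pairs.loc[down, "gene_symbol"]),
        up_up=frozenset(pairs.loc[up, "gene_symbol"]),
    )
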