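"""Cell-type-weighted OXPHOS mRNA Index and Total OXPHOS mRNA Score.

Combines a single-cell reference atlas summary (percent of cells of each
major type expressing each OXPHOS subunit gene, with the atlas cell-type
proportion) with tissue immunofluorescence cell-type areas:

    %Expression_CT(c, t)  = mean over genes g in complex c of
                            pct_expressing(t, g), times the atlas
                            proportion of cell type t
    Index(group, t, c)    = %Expression_CT(t, c) * %Immunopositive(group, t)
    Total Score(group, t) = sum of Index over Complexes I..V

The index is the literal product of two percent-scale quantities (units
% x %); it is used for ranking cell-type contributions, not as an absolute
rate, so no rescaling is applied.
"""

from __future__ import annotations

import logging
from importlib import resources

import pandas as pd

from .annotation import COMPLEX_LABELS, validate_annotation

__all__ = [
    "weighted_pct_expression",
    "oxphos_index",
    "total_score",
    "default_harmonization",
    "harmonize_cell_types",
]

logger = logging.getLogger(__name__)


def default_harmonization() -> pd.DataFrame:
    """Editable mapping from atlas cell-type names to the IF panel names."""
    text = resources.files("mitoflux.data").joinpath("celltype_harmonization.csv")
    return pd.read_csv(text.open())


def harmonize_cell_types(
    df: pd.DataFrame, mapping: pd.DataFrame | None = None, column: str = "cell_type"
) -> pd.DataFrame:
    """Rename (and drop unmapped) cell types according to a harmonization map.

    ``mapping`` has columns source, target; an empty target drops the type.
    Expression summaries for merged types should afterwards be combined with
    :func:`combine_merged_types`.
    """
    mapping = mapping if mapping is not None else default_harmonization()
    lut = {
        str(s).casefold(): (None if pd.isna(t) or t == "" else t)
        for s, t in zip(mapping["source"], mapping["target"])
    }
    out = df.copy()
    mapped = out[column].str.casefold().map(lambda s: lut.get(s, s))
    dropped = out.loc[mapped.isna(), column].unique()
    if len(dropped):
        logger.info("harmonization dropped cell types: %s", list(dropped))
    out[column] = mapped
    return out.loc[mapped.notna()].reset_index(drop=True)


def combine_merged_types(summary: pd.DataFrame) -> pd.DataFrame:
    """Merge duplicate (cell_type, gene) rows after harmonization.

    pct_expressing is combined as the scref-proportion-weighted mean and the
    proportions are summed, so a merged type behaves like the union of its
    constituents.
    """
    def _agg(df: pd.DataFrame) -> pd.Series:
        w = df["scref_proportion"]
        tot = w.sum()
        pct = (df["pct_expressing"] * w).sum() / tot if tot > 0 else df["pct_expressing"].mean()
        return pd.Series({"pct_expressing": pct, "scref_proportion": tot})

    return (
        summary.groupby(["cell_type", "gene_symbol"], sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )


def _check_summary(summary: pd.DataFrame) -> None:
    need = {"cell_type", "gene_symbol", "pct_expressing", "scref_proportion"}
    if not need <= set(summary.columns):
        raise ValueError(f"expression summary missing columns {sorted(need - set(summary.columns))}")
    if ((summary["pct_expressing"] < 0) | (summary["pct_expressing"] > 100)).any():
        raise ValueError("pct_expressing must lie in [0, 100]")
    if ((summary["scref_proportion"] < 0) | (summary["scref_proportion"] > 1)).any():
        raise ValueError("scref_proportion must lie in [0, 1]")
    if summary.duplicated(["cell_type", "gene_symbol"]).any():
        raise ValueError("one row per (cell_type, gene) required; "
                         "run combine_merged_types after harmonization")


def weighted_pct_expression(
    summary: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Atlas-weighted per-complex percent expression, %Expression_CT.

    Genes are mapped to complexes via the annotation; unmapped genes are
    dropped with a log entry.  For each (cell type, complex): the mean
    pct_expressing over the complex's genes, multiplied by the cell type's
    reference-atlas proportion.
    """
    _check_summary(summary)
    ann = validate_annotation(annotation)
    cmap = (
        ann.loc[ann["complex"] != "none"]
        .assign(_symbol=lambda d: d["gene_symbol"].str.casefold())
        .set_index("_symbol")["complex"]
    )
    s = summary.copy()
    s["complex"] = s["gene_symbol"].str.casefold().map(cmap)
    unmapped = s.loc[s["complex"].isna(), "gene_symbol"].unique()
    if len(unmapped):
        logger.info("dropping %d genes without a complex assignment: %s…",
                    len(unmapped), list(unmapped[:5]))
    s = s.dropna(subset=["complex"])
    counts = s.groupby("complex")["gene_symbol"].nunique()
    empty = [c for c in COMPLEX_LABELS if counts.get(c, 0) == 0]
    if empty:
        raise ValueError(f"no mapped genes for complexes {empty}")
    out = (
        s.groupby(["cell_type", "complex"], sort=False)
        .agg(mean_pct=("pct_expressing", "mean"),
             scref_proportion=("scref_proportion", "first"))
        .reset_index()
    )
    out["pct_expression_ct"] = out["mean_pct"] * out["scref_proportion"]
    return out[["cell_type", "complex", "pct_expression_ct"]]


def oxphos_index(
    expr_ct: pd.DataFrame, proportions: pd.DataFrame
) -> pd.DataFrame:
    """OXPHOS mRNA Index = %Expression_CT x %Immunopositive_CT.

    Cell types are inner-joined between the two tables; types present in
    only one are dropped with a log entry.  Rows: (group, cell_type,
    complex, index).
    """
    need = {"group", "cell_type", "pct_immunopositive"}
    if not need <= set(proportions.columns):
        raise ValueError(f"proportions table missing columns {sorted(need - set(proportions.columns))}")
    if ((proportions["pct_immunopositive"] < 0)
            | (proportions["pct_immunopositive"] > 100)).any():
        raise ValueError("pct_immunopositive must lie in [0, 100]")
    left = set(expr_ct["cell_type"])
    right = set(proportions["cell_type"])
    dropped = left ^ right
    if dropped:
        logger.info("cell types present in only one table, dropped: %s", sorted(dropped))
    merged = expr_ct.merge(proportions, on="cell_type", how="inner")
    if merged.empty:
        raise ValueError("no shared cell types between expression and proportion tables")
    merged["index"] = merged["pct_expression_ct"] * merged["pct_immunopositive"]
    return merged[["group", "cell_type", "complex", "index"]].sort_values(
        ["group", "cell_type", "complex"]
    ).reset_index(drop=True)


def total_score(index_table: pd.DataFrame) -> pd.DataFrame:
    """Total OXPHOS mRNA Score: the index summed over Complexes I-V.

    Every (group, cell_type) must carry all five complexes.
    """
    need = {"group", "cell_type", "complex", "index"}
    if not need <= set(index_table.columns):
        raise ValueError(f"index table missing columns {sorted(need - set(index_table.columns))}")
    out = []
    for (grp, ct), df in index_table.groupby(["group", "cell_type"], sort=False):
        have = set(df["complex"])
        missing = [c for c in COMPLEX_LABELS if c not in have]
        if missing:
            raise ValueError(f"({grp}, {ct}): missing complexes {missing}")
        out.append({"group": grp, "cell_type": ct,
                    "total_score": float(df["index"].sum())})
    return pd.DataFrame(out)
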