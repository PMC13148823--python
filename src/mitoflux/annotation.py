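"""Feature annotation: mitochondrial flags and OXPHOS complex membership.

The built-in fixture annotation carries the mouse OXPHOS subunit inventory
used throughout (electron transport chain Complexes I-IV plus ATP synthase,
Complex V), in MitoCarta-style form: every feature has a gene symbol, a
mitochondrial flag, a complex assignment (``CI``..``CV`` or ``none``) and a
set of free-form pathway tags.  Note that Ndufa4, despite its name, is a
Complex IV subunit and is annotated as such.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "OXPHOS_COMPLEX_GENES",
    "builtin_fixture_annotation",
    "read_annotation",
    "write_annotation",
]

# Mouse OXPHOS subunit gene symbols per respiratory complex.  Ndufa4 sits in
# the CIV list (it is a cytochrome c oxidase subunit, not a CI subunit).
OXPHOS_COMPLEX_GENES: dict[str, tuple[str, ...]] = {
    "CI": (
        "Ndufa1", "Ndufa10", "Ndufa11", "Ndufa12", "Ndufa13", "Ndufa2",
        "Ndufa3", "Ndufa5", "Ndufa6", "Ndufa7", "Ndufa8", "Ndufa9",
        "Ndufab1", "Ndufb10", "Ndufb11", "Ndufb2", "Ndufb3", "Ndufb4",
        "Ndufb5", "Ndufb6", "Ndufb7", "Ndufb8", "Ndufb9", "Ndufc1",
        "Ndufc2", "Ndufs1", "Ndufs2", "Ndufs3", "Ndufs4", "Ndufs5",
        "Ndufs6", "Ndufs7", "Ndufs8", "Ndufv1", "Ndufv2", "Ndufv3",
    ),
    "CII": ("Sdha", "Sdhb", "Sdhc", "Sdhd"),
    "CIII": (
        "Cyc1", "Uqcr10", "Uqcr11", "Uqcrb", "Uqcrc1", "Uqcrc2",
        "Uqcrfs1", "Uqcrh", "Uqcrq",
    ),
    "CIV": (
        "Cox4i1", "Cox4i2", "Cox5a", "Cox5b", "Cox6a1", "Cox6b1",
        "Cox6b2", "Cox6c", "Cox7a1", "Cox7a2", "Cox7a2l", "Cox7b",
        "Cox7c", "Cox8a", "Cox8b", "Ndufa4",
    ),
    "CV": (
        "Atp5a1", "Atp5b", "Atp5c1", "Atp5d", "Atp5e", "Atp5g1",
        "Atp5g2", "Atp5g3", "Atp5h", "Atp5j", "Atp5j2", "Atp5k",
        "Atp5l", "Atp5md", "Atp5mpl", "Atp5o", "Atp5pb", "Atpif1",
        "Dmac2l",
    ),
}

COMPLEX_LABELS = ("CI", "CII", "CIII", "CIV", "CV")

ANNOTATION_COLUMNS = ["feature_id", "gene_symbol", "is_mito", "complex", "pathway_tags"]


def builtin_fixture_annotation(
    n_extra_mito: int = 40, n_background: int = 200
) -> pd.DataFrame:
    """Build the fixture feature annotation.

    The OXPHOS subunit block is fixed (36 CI, 4 CII, 9 CIII, 16 CIV, 19 CV
    genes, all mitochondrial); ``n_extra_mito`` filler mitochondrial features
    (complex ``none``, e.g. matrix enzymes) and ``n_background`` non-
    mitochondrial background features are appended so the matrix resembles a
    whole-tissue proteome rather than an OXPHOS-only panel.

    Returns a DataFrame with columns feature_id, gene_symbol, is_mito,
    complex, pathway_tags (``;``-joined string, possibly empty).
    """
    if n_extra_mito < 0 or n_background < 0:
        raise ValueError("filler feature counts must be non-negative")
    rows: list[dict] = []
    for cplx, genes in OXPHOS_COMPLEX_GENES.items():
        for g in genes:
            rows.append(
                {
                    "feature_id": g,
                    "gene_symbol": g,
                    "is_mito": True,
                    "complex": cplx,
                    "pathway_tags": "oxphos",
                }
            )
    tag_cycle = ("fusion", "fission", "mitophagy", "lipid_metabolism", "tca")
    for i in range(n_extra_mito):
        rows.append(
            {
                "feature_id": f"Mito{i + 1:03d}",
                "gene_symbol": f"Mito{i + 1:03d}",
                "is_mito": True,
                "complex": "none",
                "pathway_tags": tag_cycle[i % len(tag_cycle)],
            }
        )
    for i in range(n_background):
        rows.append(
            {
                "feature_id": f"Bg{i + 1:04d}",
                "gene_symbol": f"Bg{i + 1:04d}",
                "is_mito": False,
                "complex": "none",
                "pathway_tags": "",
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation invariants; returns the (unmodified) frame."""
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if annotation["feature_id"].duplicated().any():
        dup = annotation.loc[annotation["feature_id"].duplicated(), "feature_id"]
        raise ValueError(f"duplicate feature_ids in annotation: {list(dup[:5])}")
    bad = annotation.loc[
        (annotation["complex"] != "none") & (~annotation["is_mito"].astype(bool))
    ]
    if len(bad):
        raise ValueError(
            "features assigned to a respiratory complex must be mitochondrial: "
            f"{list(bad['feature_id'][:5])}"
        )
    valid = set(COMPLEX_LABELS) | {"none"}
    unknown = set(annotation["complex"]) - valid
    if unknown:
        raise ValueError(f"unknown complex labels: {sorted(unknown)}")
    return annotation


def write_annotation(annotation: pd.DataFrame, path) -> None:
    validate_annotation(annotation).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"pathway_tags": str})
    ann["pathway_tags"] = ann["pathway_tags"].fillna("")
    ann["is_mito"] = ann["is_mito"].astype(bool)
    return validate_annotation(ann)


def mito_feature_ids(annotation: pd.DataFrame) -> np.ndarray:
    return annotation.loc[annotation["is_mito"].astype(bool), "feature_id"].to_numpy()
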