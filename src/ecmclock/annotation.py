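"""Matrisome protein annotation tables.

The matrisome — the full complement of extracellular-matrix and
ECM-associated proteins (1027 in human) — is divided into a *core*
matrisome (collagens, ECM glycoproteins, proteoglycans) and a
*matrisome-associated* part (secreted factors, ECM regulators,
ECM-affiliated proteins).  Every enrichment statistic in this package is
computed against an annotation table of this shape, so the table doubles
as the protein universe.

Annotations are plain :class:`pandas.DataFrame` objects indexed by
``protein_id`` with columns ``gene_symbol``, ``division``, ``category``,
``sasp`` and ``druggable``.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

CORE_CATEGORIES: tuple[str, ...] = ("collagens", "ecm_glycoproteins", "proteoglycans")
ASSOCIATED_CATEGORIES: tuple[str, ...] = (
    "secreted_factors",
    "ecm_regulators",
    "ecm_affiliated",
)
MATRISOME_CATEGORIES: tuple[str, ...] = CORE_CATEGORIES + ASSOCIATED_CATEGORIES
DIVISIONS: tuple[str, ...] = ("core", "associated", "non_matrisome")

#: Published category sizes of the human matrisome (1027 proteins total).
HUMAN_MATRISOME_COUNTS: dict[str, int] = {
    "collagens": 44,
    "ecm_glycoproteins": 195,
    "proteoglycans": 35,
    "secreted_factors": 344,
    "ecm_regulators": 238,
    "ecm_affiliated": 171,
}

_CATEGORY_TO_DIVISION = {
    **{c: "core" for c in CORE_CATEGORIES},
    **{c: "associated" for c in ASSOCIATED_CATEGORIES},
    "none": "non_matrisome",
}

ANNOTATION_COLUMNS = ("gene_symbol", "division", "category", "sasp", "druggable")


def make_annotation(
    protein_ids,
    categories,
    gene_symbols=None,
    sasp=None,
    druggable=None,
) -> pd.DataFrame:
    """Assemble a validated annotation table.

    ``division`` is derived from ``category`` so the two can never
    disagree (``category == "none"`` ⇔ ``division == "non_matrisome"``).
    """
    protein_ids = list(protein_ids)
    categories = list(categories)
    if len(categories) != len(protein_ids):
        raise ValueError("categories must align with protein_ids")
    df = pd.DataFrame(
        {
            "gene_symbol": list(gene_symbols) if gene_symbols is not None else protein_ids,
            "division": [_CATEGORY_TO_DIVISION[c] for c in categories],
            "category": categories,
            "sasp": list(sasp) if sasp is not None else False,
            "druggable": list(druggable) if druggable is not None else False,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    validate_annotation(df)
    return df


def validate_annotation(annotation: pd.DataFrame) -> None:
    """Check the structural invariants of an annotation table."""
    if annotation.index.has_duplicates:
        dupes = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein ids in annotation: {dupes[:5]}")
    for col in ANNOTATION_COLUMNS:
        if col not in annotation.columns:
            raise ValueError(f"annotation missing column {col!r}")
    bad_cat = set(annotation["category"]) - set(MATRISOME_CATEGORIES) - {"none"}
    if bad_cat:
        raise ValueError(f"unknown categories: {sorted(bad_cat)}")
    derived = annotation["category"].map(_CATEGORY_TO_DIVISION)
    if not (annotation["division"] == derived).all():
        bad = annotation.index[annotation["division"] != derived].tolist()
        raise ValueError(f"division inconsistent with category for: {bad[:5]}")


def matrisome_ids(annotation: pd.DataFrame) -> pd.Index:
    """Protein ids annotated as matrisome (core or associated)."""
    return annotation.index[annotation["division"] != "non_matrisome"]


def annotation_counts(annotation: pd.DataFrame) -> pd.Series:
    """Per-category protein counts plus core/associated/matrisome totals."""
    counts = {c: int((annotation["category"] == c).sum()) for c in MATRISOME_CATEGORIES}
    counts["non_matrisome"] = int((annotation["category"] == "none").sum())
    counts["core"] = sum(counts[c] for c in CORE_CATEGORIES)
    counts["associated"] = sum(counts[c] for c in ASSOCIATED_CATEGORIES)
    counts["matrisome"] = counts["core"] + counts["associated"]
    return pd.Series(counts, name="n_proteins")


def augment_annotation(annotation: pd.DataFrame, protein_ids) -> pd.DataFrame:
    """Append unknown protein ids as non-matrisome entries (with a warning)."""
    missing = [p for p in protein_ids if p not in annotation.index]
    if not missing:
        return annotation
    logger.warning(
        "%d protein ids absent from annotation; retained as non_matrisome", len(missing)
    )
    extra = make_annotation(missing, ["none"] * len(missing))
    return pd.concat([annotation, extra])


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="protein_id")
    ann["sasp"] = ann["sasp"].astype(bool)
    ann["druggable"] = ann["druggable"].astype(bool)
    validate_annotation(ann)
    return ann


def write_annotation(annotation: pd.DataFrame, path) -> None:
    validate_annotation(annotation)
    annotation.to_csv(path, sep="\t")
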