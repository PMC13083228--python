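"""Protein sets (matreotypes) and protein–phenotype association tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Significance cutoff for a protein–phenotype association (SomaScan-style
#: phenome-wide association tables report p-values at this stringency).
DEFAULT_ASSOCIATION_ALPHA = 1e-5

PROVENANCES = ("aging", "disease", "custom")


@dataclass(frozen=True)
class Matreotype:
    """A named matrisome protein set with derivation provenance.

    A matreotype is a snapshot of ECM composition associated with a
    phenotype — here either the aging signature, the disease signature,
    or a custom set (e.g., stability-selected clock proteins).
    """

    name: str
    proteins: frozenset
    provenance: str = "custom"
    parameters: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        object.__setattr__(self, "proteins", frozenset(self.proteins))

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, protein_id) -> bool:
        return protein_id in self.proteins

    def sorted_proteins(self) -> list:
        return sorted(self.proteins)


def validate_phenotype_associations(
    table: pd.DataFrame, association_alpha: float = DEFAULT_ASSOCIATION_ALPHA
) -> pd.DataFrame:
    """Validate and normalize a protein–phenotype association table.

    Expects columns ``protein_id``, ``phenotype_id``, ``chapter`` (ICD-10
    chapter label) and ``p_value``; adds the derived binary
    ``significant`` indicator (p below ``association_alpha``).
    """
    required = {"protein_id", "phenotype_id", "chapter", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    if table.duplicated(["protein_id", "phenotype_id"]).any():
        raise ValueError("duplicate (protein_id, phenotype_id) rows")
    if table["chapter"].isna().any() or (table["chapter"] == "").any():
        raise ValueError("chapter labels must be non-empty")
    out = table.copy()
    out["significant"] = out["p_value"] < association_alpha
    return out


def read_phenotype_associations(path, association_alpha=DEFAULT_ASSOCIATION_ALPHA) -> pd.DataFrame:
    return validate_phenotype_associations(pd.read_csv(path, sep="\t"), association_alpha)


def write_phenotype_associations(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("protein_id", "phenotype_id", "chapter", "p_value") if c in table]
    table[cols].to_csv(path, sep="\t", index=False)
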