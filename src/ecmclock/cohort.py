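"""Cohorts: abundance matrices plus per-sample metadata.

A :class:`Cohort` couples a strictly positive samples × proteins relative
fluorescence (RFU-style) abundance matrix with per-sample metadata (age,
sex, optional BMI / cohort labels, species, parabiosis group).  Samples
with any missing proteomic value are excluded at load time; downstream
models therefore never see missing abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("F", "M")
SPECIES = ("human", "mouse")
PARABIOSIS_GROUPS = ("YI", "YH", "OI", "OH", "control")

#: 0/1 covariate coding used wherever sex enters a model (F=0, M=1).
SEX_CODES = {"F": 0.0, "M": 1.0}


@dataclass
class Cohort:
    """Validated cohort: positive abundance matrix + aligned metadata.

    Parameters
    ----------
    abundance
        samples × proteins matrix of strictly positive abundances.
    meta
        Per-sample metadata indexed like ``abundance``; must contain
        ``age`` (years for humans, months for mice) and ``sex``.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame
    name: str = field(default="cohort")

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.meta.index):
            raise ValueError("abundance and meta must share the same sample index")
        values = self.abundance.to_numpy()
        if np.isnan(values).any():
            raise ValueError("abundance matrix contains missing values")
        if (values <= 0).any():
            i, j = np.argwhere(values <= 0)[0]
            raise ValueError(
                "non-positive abundance at sample "
                f"{self.abundance.index[i]!r}, protein {self.abundance.columns[j]!r}"
            )
        if "age" not in self.meta or "sex" not in self.meta:
            raise ValueError("meta must contain 'age' and 'sex'")
        if (self.meta["age"] < 0).any():
            raise ValueError("ages must be nonnegative")
        bad_sex = set(self.meta["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.abundance.shape[1]

    @property
    def protein_ids(self) -> pd.Index:
        return self.abundance.columns

    @property
    def ages(self) -> pd.Series:
        return self.meta["age"]

    def sex_indicator(self) -> pd.Series:
        """Sex as the 0/1 covariate coding (F=0, M=1)."""
        return self.meta["sex"].map(SEX_CODES).astype(float)

    def log2_abundance(self) -> pd.DataFrame:
        return np.log2(self.abundance)

    def zscored_abundance(self, drop_constant: bool = False) -> pd.DataFrame:
        """Per-protein z-scores across samples (ddof=0).

        Constant proteins have undefined z-scores; they are dropped when
        ``drop_constant`` is set and raise otherwise.
        """
        sd = self.abundance.std(axis=0, ddof=0)
        constant = sd[sd == 0].index
        if len(constant) and not drop_constant:
            raise ValueError(f"zero-variance proteins: {list(constant[:5])}")
        keep = self.abundance.columns.difference(constant, sort=False)
        x = self.abundance[keep]
        return (x - x.mean(axis=0)) / sd[keep]

    def subset(self, sample_ids=None, protein_ids=None, name: str | None = None) -> "Cohort":
        ab, meta = self.abundance, self.meta
        if sample_ids is not None:
            ab, meta = ab.loc[sample_ids], meta.loc[sample_ids]
        if protein_ids is not None:
            ab = ab[list(protein_ids)]
        return Cohort(ab, meta, name=name or self.name)


def read_cohort(abundance_path, meta_path, annotation: pd.DataFrame | None = None,
                name: str = "cohort") -> Cohort:
    """Read a cohort from TSV files (samples as rows, proteins as columns).

    Samples with any missing abundance are dropped (and counted in the
    log).  Protein ids absent from ``annotation`` trigger a warning; they
    are retained and treated as non-matrisome by downstream stages.
    """
    abundance = pd.read_csv(abundance_path, sep="\t", index_col=0,
                            float_precision="round_trip")
    abundance.index.name = "sample_id"
    meta = pd.read_csv(meta_path, sep="\t", index_col=0,
                       float_precision="round_trip")
    meta.index.name = "sample_id"

    complete = abundance.dropna(axis=0, how="any")
    n_dropped = abundance.shape[0] - complete.shape[0]
    if n_dropped:
        logger.info("dropped %d samples with missing proteomic data", n_dropped)
    shared = complete.index.intersection(meta.index)
    if annotation is not None:
        unknown = complete.columns.difference(annotation.index)
        if len(unknown):
            logger.warning(
                "%d proteins not in annotation (retained as non_matrisome)", len(unknown)
            )
    return Cohort(complete.loc[shared], meta.loc[shared], name=name)


def write_cohort(cohort: Cohort, abundance_path, meta_path) -> None:
    """Write a cohort as TSVs; float text round-trips bit-exactly."""
    cohort.abundance.to_csv(abundance_path, sep="\t")
    cohort.meta.to_csv(meta_path, sep="\t")
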