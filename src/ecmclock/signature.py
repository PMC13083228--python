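"""Per-protein age associations, FDR, replicated aging matreotypes.

Each protein is regressed on age plus cohort-specific covariates
(``Protein ~ Sex [+ BMI + Race/Cohort] + Age``) by ordinary least
squares.  Because every protein shares the same design matrix, the whole
proteome is fitted in one pass of the normal equations; p-values come
from the two-sided t-test on the age coefficient and are BH-adjusted
across all fitted proteins.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, rank_sum_test
from .cohort import Cohort
from .tables import Matreotype

logger = logging.getLogger(__name__)


def _build_design(cohort: Cohort, covariates: Iterable[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, covariates..., age]; age is always last."""
    cols: list[np.ndarray] = [np.ones(cohort.n_samples)]
    names = ["intercept"]
    for cov in covariates:
        if cov == "sex":
            cols.append(cohort.sex_indicator().to_numpy())
            names.append("sex")
            continue
        if cov not in cohort.meta:
            raise ValueError(f"covariate {cov!r} missing from metadata")
        values = cohort.meta[cov]
        if values.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values; refusing to impute")
        if pd.api.types.is_numeric_dtype(values):
            cols.append(values.to_numpy(dtype=float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(values, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
                names.append(c)
    cols.append(cohort.ages.to_numpy(dtype=float))
    names.append("age")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design; collinear covariates among {names}")
    return X, names


def fit_age_associations(
    cohort: Cohort,
    covariates: Iterable[str] = ("sex",),
    standardize: bool = True,
    log2: bool = False,
) -> pd.DataFrame:
    """Covariate-adjusted linear age model per protein.

    Parameters
    ----------
    standardize
        z-score each protein's abundance across samples before fitting
        (the age effect then measures slope per year in SD units); the
        t-statistics and p-values are identical either way.
    log2
        Fit on log2 abundances instead of the values as loaded.

    Returns a per-protein table with ``effect``, ``se``, ``p_value``,
    ``q_value`` and ``direction``.  Zero-variance proteins are flagged
    (``excluded``) and left out of the FDR adjustment.
    """
    covariates = list(covariates)
    X, names = _build_design(cohort, covariates)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples to fit {k} coefficients")

    Y = cohort.log2_abundance() if log2 else cohort.abundance
    sd = Y.std(axis=0, ddof=1)
    excluded = sd[sd == 0].index
    fitted_ids = Y.columns.difference(excluded, sort=False)
    Ym = Y[fitted_ids].to_numpy(dtype=float)
    if standardize:
        Ym = (Ym - Ym.mean(axis=0)) / sd[fitted_ids].to_numpy()

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Ym)
    resid = Ym - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    age_ix = names.index("age")
    effect = beta[age_ix]
    se = np.sqrt(sigma2 * xtx_inv[age_ix, age_ix])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, np.inf * np.sign(effect))
    p = 2.0 * stats.t.sf(np.abs(t), dof)

    table = pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "p_value": np.clip(p, np.nextafter(0, 1), 1.0),
            "q_value": bh_adjust(np.clip(p, 0.0, 1.0)),
            "excluded": False,
        },
        index=fitted_ids.copy(),
    )
    if len(excluded):
        logger.warning("%d zero-variance proteins excluded from age models", len(excluded))
        table = pd.concat(
            [
                table,
                pd.DataFrame(
                    {
                        "effect": np.nan,
                        "se": np.nan,
                        "p_value": np.nan,
                        "q_value": np.nan,
                        "excluded": True,
                    },
                    index=excluded,
                ),
            ]
        )
    table = table.reindex(Y.columns)
    table["direction"] = np.sign(table["effect"])
    table.index.name = "protein_id"
    return table


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (see :func:`ecmclock._stats.bh_adjust`)."""
    return bh_adjust(p_values)


def replicated_aging_matreotype(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    name: str = "aging_matreotype",
) -> Matreotype:
    """Proteins significant (q < alpha) in both cohorts with shared direction."""
    shared = table_a.index.intersection(table_b.index)
    if len(shared) == 0:
        logger.warning("no overlapping proteins between association tables")
        return Matreotype(name, frozenset(), "aging", {"alpha": alpha})
    a, b = table_a.loc[shared], table_b.loc[shared]
    keep = (
        (a["q_value"] < alpha)
        & (b["q_value"] < alpha)
        & (a["direction"] == b["direction"])
        & (a["direction"] != 0)
    )
    return Matreotype(name, frozenset(shared[keep.fillna(False)]), "aging", {"alpha": alpha})


def compare_age_groups(
    cohort: Cohort,
    protein_set,
    bin_edges,
    reference_bin: int | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum of per-sample signature scores per age bin vs a reference.

    The per-sample score is the mean standardized abundance over
    ``protein_set``.  Each bin is compared two-sided against the
    reference bin (default: the oldest); p-values are BH-adjusted over
    the compared bins.
    """
    z = cohort.zscored_abundance(drop_constant=True)
    proteins = [p for p in protein_set if p in z.columns]
    if not proteins:
        raise ValueError("protein_set has no overlap with the cohort")
    scores = z[proteins].mean(axis=1)
    bins = pd.cut(cohort.ages, bins=bin_edges, include_lowest=True)
    categories = list(bins.cat.categories)
    if reference_bin is None:
        reference_bin = len(categories) - 1
    ref_interval = categories[reference_bin]
    ref_scores = scores[bins == ref_interval]
    if len(ref_scores) < 2:
        raise ValueError("reference bin has fewer than 2 samples")

    rows = []
    for i, interval in enumerate(categories):
        group = scores[bins == interval]
        if i == reference_bin:
            rows.append({"bin": str(interval), "n": len(group),
                         "mean_score": float(group.mean()) if len(group) else np.nan,
                         "statistic": np.nan, "p_value": np.nan})
            continue
        if len(group) < 2:
            logger.warning("age bin %s skipped (%d samples)", interval, len(group))
            continue
        stat, p = rank_sum_test(group.to_numpy(), ref_scores.to_numpy())
        rows.append({"bin": str(interval), "n": len(group),
                     "mean_score": float(group.mean()), "statistic": stat, "p_value": p})
    out = pd.DataFrame(rows).set_index("bin")
    tested = out["p_value"].notna()
    out.loc[tested, "q_value"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    return out


def gap_protein_associations(
    cohort: Cohort,
    age_gaps: pd.Series,
    group_covariate: str = "parabiosis_group",
) -> pd.DataFrame:
    """Associate proteins with clock age gaps within an intervention group.

    Fits, per protein, ``gap ~ intervention + standardized protein`` and
    reports the protein coefficient with its (unadjusted) p-value.  A
    constant intervention covariate is dropped with a warning.  The
    Frisch–Waugh projection makes the per-protein fits a single matrix
    pass.
    """
    gaps = age_gaps.loc[cohort.abundance.index].to_numpy(dtype=float)
    cols = [np.ones(cohort.n_samples)]
    if group_covariate is not None and group_covariate in cohort.meta:
        values = cohort.meta[group_covariate]
        if values.nunique() < 2:
            logger.warning("covariate %r constant; dropped", group_covariate)
        else:
            dummies = pd.get_dummies(values, drop_first=True, dtype=float)
            cols.extend(dummies[c].to_numpy() for c in dummies.columns)
    G = np.column_stack(cols)

    Z = cohort.zscored_abundance(drop_constant=True)
    ids = Z.columns
    Zm = Z.to_numpy(dtype=float)
    # Residualize gap and proteins against the intervention design.
    proj = G @ np.linalg.pinv(G)
    ey = gaps - proj @ gaps
    EZ = Zm - proj @ Zm
    szz = (EZ**2).sum(axis=0)
    ok = szz > 0
    beta = np.where(ok, (EZ * ey[:, None]).sum(axis=0) / np.where(ok, szz, 1.0), np.nan)
    dof = cohort.n_samples - G.shape[1] - 1
    ssr = (ey**2).sum() - beta**2 * szz
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(ssr, 0.0) / dof / szz)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame(
        {"effect": beta, "se": se, "p_value": p},
        index=ids.copy(),
    ).rename_axis("protein_id")
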