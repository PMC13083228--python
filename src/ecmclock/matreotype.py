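"""Disease matreotypes, composition tests, and enrichment statistics.

The disease matreotype is the set of matrisome proteins broadly
associated with disease: within each retained ICD-10 chapter, matrisome
proteins are ranked by the number of distinct phenotypes they associate
with; proteins at or above the chapter's 50th-percentile count are kept,
and the final set is the intersection across all retained chapters.
Composition of a signature against the full matrisome is tested by a
chi-squared goodness-of-fit with standardized residuals interpreted as
z-scores, falling back to Monte Carlo when expected counts are small.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import (
    bh_adjust,
    rank_sum_test,
    set_enrichment,
    significance_z_threshold,
)
from .annotation import (
    ASSOCIATED_CATEGORIES,
    CORE_CATEGORIES,
    MATRISOME_CATEGORIES,
    matrisome_ids,
)
from .tables import Matreotype

logger = logging.getLogger(__name__)

DEFAULT_MIN_PHENOTYPES = 10
DEFAULT_PERCENTILE = 0.5


def retained_chapters(assoc: pd.DataFrame, min_phenotypes: int = DEFAULT_MIN_PHENOTYPES):
    """Chapters with at least ``min_phenotypes`` distinct phenotypes."""
    counts = assoc.groupby("chapter")["phenotype_id"].nunique()
    return list(counts.index[counts >= min_phenotypes])


def chapter_association_counts(
    assoc: pd.DataFrame, annotation: pd.DataFrame, chapter: str
) -> pd.Series:
    """Distinct significant phenotype count per matrisome protein in a chapter."""
    ecm = set(matrisome_ids(annotation))
    sig = assoc[(assoc["chapter"] == chapter) & assoc["significant"]]
    sig = sig[sig["protein_id"].isin(ecm)]
    return sig.groupby("protein_id")["phenotype_id"].nunique().sort_values(ascending=False)


def percentile_count_threshold(counts: pd.Series, percentile: float = DEFAULT_PERCENTILE) -> int:
    """Count value at the ceil(n·percentile)-th largest rank.

    Retention uses ``count >= threshold``, so boundary ties can push the
    retained fraction above the nominal percentile.
    """
    if counts.empty:
        raise ValueError("no associated matrisome proteins in chapter")
    ordered = np.sort(counts.to_numpy())[::-1]
    rank = max(1, math.ceil(len(ordered) * percentile))
    return int(ordered[rank - 1])


def derive_disease_matreotype(
    assoc: pd.DataFrame,
    annotation: pd.DataFrame,
    min_phenotypes: int = DEFAULT_MIN_PHENOTYPES,
    percentile: float = DEFAULT_PERCENTILE,
    name: str = "disease_matreotype",
) -> Matreotype:
    """Matrisome proteins in the top association-count half of *every* retained chapter."""
    chapters = retained_chapters(assoc, min_phenotypes)
    if not chapters:
        raise ValueError("no chapters retained; lower min_phenotypes or check input")
    thresholds: dict[str, int] = {}
    per_chapter_sets: list[set] = []
    for chapter in chapters:
        counts = chapter_association_counts(assoc, annotation, chapter)
        if counts.empty:
            logger.warning("chapter %s has no associated matrisome proteins", chapter)
            per_chapter_sets.append(set())
            thresholds[chapter] = 0
            continue
        thr = percentile_count_threshold(counts, percentile)
        thresholds[chapter] = thr
        per_chapter_sets.append(set(counts.index[counts >= thr]))
    final = set.intersection(*per_chapter_sets) if per_chapter_sets else set()
    return Matreotype(
        name,
        frozenset(final),
        "disease",
        {
            "min_phenotypes": min_phenotypes,
            "percentile": percentile,
            "chapters": chapters,
            "thresholds": thresholds,
        },
    )


def chapter_ecm_enrichment(assoc: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """log2 enrichment of chapter association in ECM vs non-ECM proteins.

    Per chapter: the fraction of matrisome proteins significantly
    associated with at least one of its phenotypes over the same
    fraction among non-matrisome proteins, with a two-sided Fisher exact
    test on the 2×2 table and Bonferroni adjustment over chapters.
    """
    ecm = set(matrisome_ids(annotation))
    non_ecm = set(annotation.index) - ecm
    if not ecm or not non_ecm:
        raise ValueError("need both ECM and non-ECM proteins in the annotation")
    sig = assoc[assoc["significant"]]
    chapters = sorted(assoc["chapter"].unique())
    rows = []
    for chapter in chapters:
        assoc_prot = set(sig.loc[sig["chapter"] == chapter, "protein_id"])
        a = len(assoc_prot & ecm)
        c = len(assoc_prot & non_ecm)
        frac_ecm = a / len(ecm)
        frac_non = c / len(non_ecm)
        if frac_non == 0 or frac_ecm == 0:
            enr = math.inf if frac_ecm > 0 else (-math.inf if frac_non > 0 else np.nan)
        else:
            enr = math.log2(frac_ecm / frac_non)
        table = [[a, len(ecm) - a], [c, len(non_ecm) - c]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append(
            {"chapter": chapter, "n_ecm_associated": a, "n_non_ecm_associated": c,
             "log2_enrichment": enr, "p_value": p}
        )
    out = pd.DataFrame(rows).set_index("chapter")
    out["p_bonferroni"] = np.minimum(out["p_value"] * len(out), 1.0)
    return out


@dataclass
class CompositionTestResult:
    """Goodness-of-fit of a signature's category composition vs the matrisome."""

    table: pd.DataFrame  # per group: observed, expected, proportion, std_residual
    statistic: float
    dof: int
    p_value: float
    monte_carlo: bool
    z_threshold: float

    def significant_groups(self) -> list:
        z = self.table["std_residual"].abs()
        return list(self.table.index[z > self.z_threshold])


def composition_test(
    signature: Matreotype,
    annotation: pd.DataFrame,
    grouping: str = "division",
    n_monte_carlo: int = 2000,
    seed: int = 0,
    residual_form: str = "gof",
    alpha: float = 0.05,
) -> CompositionTestResult:
    """Chi-squared goodness-of-fit of signature composition against the matrisome.

    Expected counts come from the proportional category representation
    in the full matrisome of ``annotation``.  Standardized residuals use
    the goodness-of-fit form (O−E)/√(E·(1−p)) so that |z| > 1.96 marks
    over-/under-represented groups at p < 0.05; the plain Pearson form
    (O−E)/√E is available via ``residual_form='pearson'``.  When any
    expected count is below 5 or the signature has fewer than 40
    proteins, the p-value comes from a seeded Monte Carlo multinomial
    simulation (p = (#simulated ≥ observed + 1)/(replicates + 1)).
    """
    if len(signature) == 0:
        raise ValueError("empty signature")
    ecm = annotation.loc[list(matrisome_ids(annotation))]
    outside = set(signature.proteins) - set(ecm.index)
    if outside:
        raise ValueError(f"signature proteins outside matrisome background: {sorted(outside)[:5]}")

    if grouping == "division":
        groups = ["core", "associated"]
        background = ecm["division"]
        observed_labels = ecm.loc[list(signature.proteins), "division"]
    elif grouping == "category":
        groups = list(MATRISOME_CATEGORIES)
        background = ecm["category"]
        observed_labels = ecm.loc[list(signature.proteins), "category"]
    else:
        raise ValueError("grouping must be 'division' or 'category'")

    p_bg = np.array([(background == g).mean() for g in groups])
    observed = np.array([(observed_labels == g).sum() for g in groups], dtype=float)
    n = observed.sum()
    expected = n * p_bg
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    statistic = float(contrib.sum())
    if residual_form == "gof":
        denom = np.sqrt(expected * (1.0 - p_bg))
    elif residual_form == "pearson":
        denom = np.sqrt(expected)
    else:
        raise ValueError("residual_form must be 'gof' or 'pearson'")
    with np.errstate(divide="ignore", invalid="ignore"):
        residuals = np.where(denom > 0, (observed - expected) / denom, 0.0)

    dof = len(groups) - 1
    monte_carlo = bool((expected < 5).any() or n < 40)
    if monte_carlo:
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(int(n), p_bg, size=n_monte_carlo)
        with np.errstate(divide="ignore", invalid="ignore"):
            sim_stats = np.where(
                expected[None, :] > 0,
                (sims - expected[None, :]) ** 2 / expected[None, :],
                0.0,
            ).sum(axis=1)
        p_value = float((np.sum(sim_stats >= statistic - 1e-12) + 1) / (n_monte_carlo + 1))
    else:
        p_value = float(stats.chi2.sf(statistic, dof))

    table = pd.DataFrame(
        {"observed": observed.astype(int), "expected": expected,
         "proportion": p_bg, "std_residual": residuals},
        index=pd.Index(groups, name="group"),
    )
    return CompositionTestResult(
        table=table,
        statistic=statistic,
        dof=dof,
        p_value=p_value,
        monte_carlo=monte_carlo,
        z_threshold=significance_z_threshold(alpha),
    )


def category_enrichment(
    signature: Matreotype, annotation: pd.DataFrame, side: str = "over"
) -> pd.DataFrame:
    """Per-category hypergeometric enrichment with the matrisome as universe."""
    ecm = annotation.loc[list(matrisome_ids(annotation))]
    membership = ecm["category"]
    marked = pd.Series(ecm.index.isin(list(signature.proteins)), index=ecm.index)
    out = set_enrichment(membership, marked, side=side)
    out.index.name = "category"
    return out.rename(columns={"hits": "n_in_signature"})


def disease_burden_comparison(
    assoc: pd.DataFrame, annotation: pd.DataFrame
) -> dict:
    """Distinct-phenotype burden: ECM vs non-ECM, and per category vs non-ECM.

    Returns the overall Wilcoxon comparison and a per-category table
    Bonferroni-corrected over the six category-wise tests.
    """
    counts = (
        assoc[assoc["significant"]]
        .groupby("protein_id")["phenotype_id"]
        .nunique()
        .reindex(annotation.index, fill_value=0)
    )
    is_ecm = annotation["division"] != "non_matrisome"
    ecm_counts = counts[is_ecm]
    non_counts = counts[~is_ecm]
    if ecm_counts.empty or non_counts.empty:
        raise ValueError("need both ECM and non-ECM proteins")
    stat, p = rank_sum_test(ecm_counts.to_numpy(), non_counts.to_numpy())
    overall = {
        "mean_ecm": float(ecm_counts.mean()),
        "mean_non_ecm": float(non_counts.mean()),
        "statistic": stat,
        "p_value": p,
    }
    rows = []
    for cat in MATRISOME_CATEGORIES:
        sub = counts[annotation["category"] == cat]
        if sub.empty:
            continue
        s, pv = rank_sum_test(sub.to_numpy(), non_counts.to_numpy())
        rows.append({"category": cat, "n": len(sub), "mean": float(sub.mean()),
                     "statistic": s, "p_value": pv})
    per_cat = pd.DataFrame(rows).set_index("category")
    per_cat["p_bonferroni"] = np.minimum(per_cat["p_value"] * len(per_cat), 1.0)
    return {"overall": overall, "per_category": per_cat}


def prioritize_targets(
    mr_results: pd.DataFrame,
    min_phenotypes: int = 5,
    min_domains: int = 3,
    alpha: float = 0.05,
    methods: tuple[str, ...] = ("wald_ratio", "ivw"),
) -> pd.DataFrame:
    """Rank causally implicated proteins by breadth of phenotype evidence.

    Keeps rows with an accepted Mendelian-randomization method and
    p < alpha, counts distinct phenotypes and domains per protein, and
    retains proteins implicated in at least ``min_phenotypes`` phenotypes
    across at least ``min_domains`` domains, ranked by
    (n_domains desc, n_phenotypes desc, protein id).
    """
    required = {"protein_id", "phenotype", "domain", "method", "p_value"}
    missing = required - set(mr_results.columns)
    if missing:
        raise ValueError(f"mr_results missing columns: {sorted(missing)}")
    kept = mr_results[
        (mr_results["p_value"] < alpha) & mr_results["method"].isin(methods)
    ]
    grouped = kept.groupby("protein_id").agg(
        n_phenotypes=("phenotype", "nunique"), n_domains=("domain", "nunique")
    )
    grouped = grouped[
        (grouped["n_phenotypes"] >= min_phenotypes) & (grouped["n_domains"] >= min_domains)
    ]
    out = grouped.reset_index().sort_values(
        ["n_domains", "n_phenotypes", "protein_id"], ascending=[False, False, True]
    )
    return out.set_index("protein_id")
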