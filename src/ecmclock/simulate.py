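"""Synthetic cohorts with planted aging structure.

The generator emulates the statistical structure of aptamer-style plasma
proteomics studies of aging: two human cohorts with different age
ranges, a matrisome/non-matrisome protein universe at the published
44:195:35:344:238:171 category proportions, proteins with planted linear
age slopes and U-shaped (quadratic) trajectories on the log2 scale, a
mouse cohort with isochronic/heterochronic parabiosis groups, and a
protein–phenotype association table with tunable ECM enrichment.

All signal and noise is specified on the log2 scale, where the clock
models operate; abundances are exponentiated to strictly positive RFU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import (
    CORE_CATEGORIES,
    HUMAN_MATRISOME_COUNTS,
    MATRISOME_CATEGORIES,
    make_annotation,
    matrisome_ids,
)
from .cohort import Cohort
from .tables import validate_phenotype_associations

_DEFAULT_PROPORTIONS = tuple(
    HUMAN_MATRISOME_COUNTS[c] / sum(HUMAN_MATRISOME_COUNTS.values())
    for c in MATRISOME_CATEGORIES
)

# Child-stream tags so that planted coefficients depend only on the seed
# and annotation, never on how many samples are drawn.
_TRUTH_STREAM = 1
_SAMPLE_STREAM = 2
_ANNOTATION_STREAM = 3
_PHENOTYPE_STREAM = 4


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults emulate an Arthur-style healthy-aging human cohort:
    150 individuals aged 25–80, a measured proteome in which roughly 15%
    of proteins are matrisome members split at the published category
    proportions, ~150 proteins with linear age effects of |slope|
    0.02–0.08 log2-units per year, 50 core-matrisome-weighted U-shaped
    proteins with vertex 45 years, and i.i.d. Gaussian log2 noise with
    SD 0.2.
    """

    seed: int
    n_samples: int = 150
    age_range: tuple[float, float] = (25.0, 80.0)
    n_proteins: int = 2000
    matrisome_fraction: float = 0.15
    category_proportions: tuple[float, ...] = _DEFAULT_PROPORTIONS
    n_linear_aging: int = 150
    beta_range: tuple[float, float] = (0.02, 0.08)
    aging_matrisome_fraction: float = 0.5
    n_ushape: int = 50
    ushape_vertex_age: float = 45.0
    gamma_range: tuple[float, float] = (5e-4, 1.5e-3)
    noise_sd: float = 0.2
    sex_effect_sd: float = 0.1
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    sasp_fraction: float = 0.1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.matrisome_fraction <= 1.0:
            raise ValueError("matrisome_fraction must lie in [0, 1]")
        if self.n_linear_aging < 0 or self.n_linear_aging > self.n_proteins:
            raise ValueError("n_linear_aging must lie in [0, n_proteins]")
        if self.n_ushape < 0 or self.n_ushape > self.n_proteins:
            raise ValueError("n_ushape must lie in [0, n_proteins]")
        total = float(sum(self.category_proportions))
        if len(self.category_proportions) != 6 or total <= 0:
            raise ValueError("category_proportions must be 6 nonnegative weights")
        self.category_proportions = tuple(p / total for p in self.category_proportions)


def scaled_human_config(seed: int, n_samples: int = 150, n_proteins: int = 2000,
                        **overrides) -> SimulationConfig:
    """Human study conditions with planted counts scaled to the proteome size.

    Keeps the default planted fractions (7.5% linear-aging, 2.5%
    U-shaped) when the proteome is scaled down for small runs.
    """
    overrides.setdefault("n_linear_aging", max(5, round(0.075 * n_proteins)))
    overrides.setdefault("n_ushape", round(0.025 * n_proteins))
    return SimulationConfig(seed=seed, n_samples=n_samples, n_proteins=n_proteins,
                            **overrides)


def default_mouse_config(seed: int, **overrides) -> SimulationConfig:
    """Mouse study conditions: ages 1–30 months, 60 non-parabiotic controls.

    Slopes are rescaled from per-year to per-month so planted effects
    span a comparable dynamic range over the murine lifespan.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_samples=60,
        age_range=(1.0, 30.0),
        n_proteins=400,
        matrisome_fraction=0.3,
        n_linear_aging=40,
        beta_range=(0.04, 0.16),
        n_ushape=0,
        ushape_vertex_age=15.0,
        gamma_range=(1e-3, 3e-3),
    )
    return replace(cfg, **overrides) if overrides else cfg


def _largest_remainder(total: int, proportions) -> list[int]:
    quotas = np.asarray(proportions, dtype=float) * total
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for k in order[:remainder]:
        counts[k] += 1
    return counts.tolist()


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministically generate a protein annotation universe."""
    rng = np.random.default_rng([config.seed, _ANNOTATION_STREAM])
    n_matrisome = int(round(config.n_proteins * config.matrisome_fraction))
    per_category = _largest_remainder(n_matrisome, config.category_proportions)
    categories: list[str] = []
    for cat, k in zip(MATRISOME_CATEGORIES, per_category):
        categories.extend([cat] * k)
    categories.extend(["none"] * (config.n_proteins - n_matrisome))
    ids = [f"PROT{i:05d}" for i in range(config.n_proteins)]
    sasp = rng.random(config.n_proteins) < config.sasp_fraction
    druggable = rng.random(config.n_proteins) < 0.3
    return make_annotation(ids, categories, sasp=sasp, druggable=druggable)


def generate_ground_truth(config: SimulationConfig, annotation: pd.DataFrame) -> pd.DataFrame:
    """Plant per-protein coefficients; a function of (seed, annotation) only.

    Linear-aging proteins are drawn with ``aging_matrisome_fraction`` of
    them matrisome members; U-shape proteins are preferentially core
    matrisome.  The two planted sets are disjoint.
    """
    rng = np.random.default_rng([config.seed, _TRUTH_STREAM])
    ids = annotation.index
    matrisome = list(matrisome_ids(annotation))
    non_matrisome = [p for p in ids if p not in set(matrisome)]
    core = list(annotation.index[annotation["division"] == "core"])

    n_ecm = min(int(round(config.n_linear_aging * config.aging_matrisome_fraction)),
                len(matrisome))
    n_non = min(config.n_linear_aging - n_ecm, len(non_matrisome))
    aging = list(rng.choice(matrisome, size=n_ecm, replace=False)) if n_ecm else []
    aging += list(rng.choice(non_matrisome, size=n_non, replace=False)) if n_non else []

    remaining_core = [p for p in core if p not in set(aging)]
    remaining_other = [p for p in ids if p not in set(aging) and p not in set(remaining_core)]
    n_core_u = min(config.n_ushape, len(remaining_core))
    ushape = list(rng.choice(remaining_core, size=n_core_u, replace=False)) if n_core_u else []
    if len(ushape) < config.n_ushape:
        extra = min(config.n_ushape - len(ushape), len(remaining_other))
        if extra:
            ushape += list(rng.choice(remaining_other, size=extra, replace=False))

    truth = pd.DataFrame(
        {
            "slope": 0.0,
            "quad": 0.0,
            "sex_effect": rng.normal(0.0, config.sex_effect_sd, size=len(ids)),
            "baseline": rng.normal(config.baseline_mean, config.baseline_sd, size=len(ids)),
            "is_aging": False,
            "is_ushape": False,
            "sasp": annotation["sasp"].to_numpy(),
        },
        index=ids.copy(),
    )
    lo, hi = config.beta_range
    signs = rng.choice([-1.0, 1.0], size=len(aging))
    truth.loc[aging, "slope"] = signs * rng.uniform(lo, hi, size=len(aging))
    truth.loc[aging, "is_aging"] = True
    glo, ghi = config.gamma_range
    truth.loc[ushape, "quad"] = rng.uniform(glo, ghi, size=len(ushape))
    truth.loc[ushape, "is_ushape"] = True
    return truth


def _log2_levels(config, truth, ages, male, rng, effective_ages=None):
    """log2 abundance = baseline + slope·age + quad·(age−vertex)² + sex + ε."""
    age_lin = ages if effective_ages is None else effective_ages
    base = truth["baseline"].to_numpy()
    slope = truth["slope"].to_numpy()
    quad = truth["quad"].to_numpy()
    sexef = truth["sex_effect"].to_numpy()
    centered = (age_lin[:, None] - config.ushape_vertex_age) ** 2
    log2 = (
        base[None, :]
        + slope[None, :] * age_lin[:, None]
        + quad[None, :] * centered
        + sexef[None, :] * male[:, None]
    )
    if config.noise_sd > 0:
        log2 = log2 + rng.normal(0.0, config.noise_sd, size=log2.shape)
    return log2


def generate_human_cohort(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    name: str = "synthetic_human",
) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a human cohort; returns (cohort, ground truth).

    Passing ``truth`` from a previous call produces a second cohort
    sharing the same planted proteins and coefficients (a replication
    cohort with, e.g., a different age range).
    """
    if truth is None:
        truth = generate_ground_truth(config, annotation)
    rng = np.random.default_rng([config.seed, _SAMPLE_STREAM])
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=config.n_samples)
    sex = rng.choice(["F", "M"], size=config.n_samples)
    male = (sex == "M").astype(float)
    bmi = rng.normal(26.0, 4.0, size=config.n_samples)
    log2 = _log2_levels(config, truth, ages, male, rng)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    abundance = pd.DataFrame(
        np.exp2(log2), index=pd.Index(sample_ids, name="sample_id"),
        columns=annotation.index.copy(),
    )
    meta = pd.DataFrame(
        {"age": ages, "sex": sex, "bmi": bmi, "species": "human"},
        index=abundance.index,
    )
    return Cohort(abundance, meta, name=name), truth


def generate_mouse_parabiosis_cohort(
    config: SimulationConfig,
    shift_young: float = 0.0,
    shift_old: float = 0.0,
    n_per_group: int = 8,
    young_age: float = 3.0,
    old_age: float = 20.0,
    annotation: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
    name: str = "synthetic_mouse",
) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a mouse cohort with isochronic/heterochronic parabionts.

    ``config.n_samples`` non-parabiotic controls span ``age_range``
    (months).  Four parabiosis groups (YI, YH, OI, OH) of ``n_per_group``
    animals sit at ``young_age`` / ``old_age``.  Heterochronic animals
    have their *planted aging proteins* shifted along the aging axis by
    the signed shift (in months): YH by ``shift_young`` (toward the old
    partner) and OH by ``shift_old`` (negative values rejuvenate).
    Controls and isochronic animals are unshifted.
    """
    if annotation is None:
        annotation = generate_annotation(config)
    if truth is None:
        truth = generate_ground_truth(config, annotation)
    rng = np.random.default_rng([config.seed, _SAMPLE_STREAM])
    lo, hi = config.age_range

    groups = (["control"] * config.n_samples
              + ["YI"] * n_per_group + ["YH"] * n_per_group
              + ["OI"] * n_per_group + ["OH"] * n_per_group)
    ages = np.concatenate([
        rng.uniform(lo, hi, size=config.n_samples),
        np.full(n_per_group, young_age), np.full(n_per_group, young_age),
        np.full(n_per_group, old_age), np.full(n_per_group, old_age),
    ])
    shift = np.array(
        [{"YH": shift_young, "OH": shift_old}.get(g, 0.0) for g in groups]
    )
    sex = rng.choice(["F", "M"], size=len(groups))
    male = (sex == "M").astype(float)

    # The shift acts only through planted aging proteins: their
    # age-dependent terms are evaluated at age + shift.
    planted = truth["is_aging"].to_numpy()
    eff = ages[:, None] + shift[:, None] * planted[None, :]
    base = truth["baseline"].to_numpy()
    log2 = (
        base[None, :]
        + truth["slope"].to_numpy()[None, :] * eff
        + truth["quad"].to_numpy()[None, :] * (eff - config.ushape_vertex_age) ** 2
        + truth["sex_effect"].to_numpy()[None, :] * male[:, None]
    )
    if config.noise_sd > 0:
        log2 = log2 + rng.normal(0.0, config.noise_sd, size=log2.shape)

    sample_ids = [f"M{i:04d}" for i in range(len(groups))]
    abundance = pd.DataFrame(
        np.exp2(log2), index=pd.Index(sample_ids, name="sample_id"),
        columns=annotation.index.copy(),
    )
    meta = pd.DataFrame(
        {"age": ages, "sex": sex, "species": "mouse", "parabiosis_group": groups},
        index=abundance.index,
    )
    return Cohort(abundance, meta, name=name), truth


def generate_phenotype_associations(
    annotation: pd.DataFrame,
    n_chapters: int = 8,
    n_phenotypes_per_chapter: int = 20,
    ecm_enrichment: float = 2.0,
    seed: int = 0,
    base_rate: float = 0.15,
    heterogeneity_sd: float = 1.0,
    association_alpha: float = 1e-5,
    planted_proteins=None,
    planted_rate: float = 0.9,
) -> pd.DataFrame:
    """Bernoulli protein–phenotype associations with ECM odds multiplied.

    Each protein carries a lognormal propensity (SD ``heterogeneity_sd``
    on the log-odds scale) shared across chapters — some proteins are
    broadly disease-associated, which is what makes a pan-chapter
    disease matreotype identifiable.  ECM proteins' odds are further
    multiplied by ``ecm_enrichment``.  Every (protein, phenotype) pair
    receives a p-value: associated pairs draw log-uniform below
    ``association_alpha``, the rest above it.  ``planted_proteins``
    (optional) associate at ``planted_rate`` across all chapters,
    planting a deterministic pan-chapter set.
    """
    if n_chapters < 1:
        raise ValueError("n_chapters must be >= 1")
    rng = np.random.default_rng([seed, _PHENOTYPE_STREAM])
    is_ecm = (annotation["division"] != "non_matrisome").to_numpy()
    n_prot = len(annotation)
    base_odds = base_rate / (1.0 - base_rate)
    odds = base_odds * np.where(is_ecm, ecm_enrichment, 1.0)
    if heterogeneity_sd > 0:
        odds = odds * np.exp(rng.normal(0.0, heterogeneity_sd, size=n_prot))
    prob = odds / (1.0 + odds)
    if planted_proteins is not None:
        planted_mask = annotation.index.isin(list(planted_proteins))
        prob = np.where(planted_mask, planted_rate, prob)

    records = []
    log_alpha = np.log10(association_alpha)
    for c in range(n_chapters):
        chapter = f"CH{c + 1:02d}"
        for j in range(n_phenotypes_per_chapter):
            phen = f"{chapter}_PH{j + 1:02d}"
            assoc = rng.random(n_prot) < prob
            logp = np.where(
                assoc,
                rng.uniform(log_alpha - 8.0, log_alpha, size=n_prot),
                rng.uniform(log_alpha, 0.0, size=n_prot),
            )
            records.append(
                pd.DataFrame(
                    {
                        "protein_id": annotation.index,
                        "phenotype_id": phen,
                        "chapter": chapter,
                        "p_value": 10.0 ** logp,
                    }
                )
            )
    table = pd.concat(records, ignore_index=True)
    return validate_phenotype_associations(table, association_alpha)
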