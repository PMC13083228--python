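"""Cross-species concordance and parabiosis rejuvenation analysis.

Human and mouse age associations are compared on the shared protein
universe by signed effects (sign(effect)·−log10 p) and a Pearson
correlation of effect sizes; a protein counts as *shared* when it is
nominally significant (p < 0.05) in both species with the same effect
direction.  In the parabiosis analysis, clocks trained exclusively on
non-parabiotic control animals predict the ages of parabionts; ΔAge =
predicted − chronological per animal (averaged across ensemble models)
is contrasted between heterochronic and isochronic groups by Welch's
t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import welch_t_test
from .clocks import PermutationClockEnsemble, correct_age_gap
from .cohort import Cohort

logger = logging.getLogger(__name__)


def signed_effect(effect, p_value, cap: float = 300.0):
    """sign(effect) · −log10(p); zero effect maps to 0, p=0 capped.

    Works element-wise on arrays.
    """
    effect = np.asarray(effect, dtype=float)
    p = np.asarray(p_value, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        logger.warning("p=0 encountered; signed effect capped at %g", cap)
    with np.errstate(divide="ignore"):
        mag = np.minimum(-np.log10(np.where(p > 0, p, 1.0)), cap)
        mag = np.where(p > 0, mag, cap)
    out = np.sign(effect) * mag
    return out if out.ndim else float(out)


def shared_age_associations(
    human: pd.DataFrame, mouse: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, float, float]:
    """Shared-direction nominal age associations across species.

    Returns (per-protein table, Pearson r of effect sizes over the
    shared universe, correlation p-value).
    """
    shared_ids = human.index.intersection(mouse.index)
    if len(shared_ids) == 0:
        raise ValueError("no shared proteins between the species tables")
    h, m = human.loc[shared_ids], mouse.loc[shared_ids]
    table = pd.DataFrame(
        {
            "human_effect": h["effect"],
            "mouse_effect": m["effect"],
            "human_signed_effect": signed_effect(h["effect"], h["p_value"]),
            "mouse_signed_effect": signed_effect(m["effect"], m["p_value"]),
            "shared": (
                (h["p_value"] < alpha)
                & (m["p_value"] < alpha)
                & (np.sign(h["effect"]) == np.sign(m["effect"]))
                & (h["effect"] != 0)
            ),
        },
        index=shared_ids.copy(),
    )
    ok = h["effect"].notna() & m["effect"].notna()
    if ok.sum() >= 3:
        r, p = stats.pearsonr(h.loc[ok, "effect"], m.loc[ok, "effect"])
    else:
        r, p = float("nan"), float("nan")
    return table, float(r), float(p)


@dataclass
class ParabiosisResult:
    """Per-animal ΔAge and heterochronic-vs-isochronic contrasts."""

    delta_age: pd.Series
    group_means: pd.Series
    contrasts: pd.DataFrame  # index: contrast name, columns: t, df, p_value


def parabiosis_rejuvenation_analysis(
    mouse_cohort: Cohort,
    control_ensemble: PermutationClockEnsemble,
    correct_gaps: bool = False,
) -> ParabiosisResult:
    """ΔAge of parabiotic animals under clocks trained on controls only.

    Each parabiotic animal's age is predicted by every (non-flagged)
    ensemble model using that model's training-set scaling; predictions
    are averaged across models.  ΔAge = predicted − chronological (raw
    by default; ``correct_gaps`` applies the lm-correction fitted on the
    parabiotic predictions).  Contrasts YH–YI and OH–OI use Welch's
    t-test; a missing group skips its contrast with a warning.
    """
    groups = mouse_cohort.meta["parabiosis_group"]
    parabiotic = groups.isin(["YI", "YH", "OI", "OH"])
    para = mouse_cohort.subset(sample_ids=mouse_cohort.meta.index[parabiotic])

    leaked = control_ensemble.train_sample_id_set() & set(para.abundance.index)
    if leaked:
        raise ValueError(
            f"ensemble was trained on parabiotic samples: {sorted(leaked)[:5]}"
        )

    preds = []
    sex = para.sex_indicator()
    for perm in control_ensemble.permutations_:
        if perm.flagged or perm.model is None:
            continue
        preds.append(perm.model.predict(para.abundance, sex=sex, scaling="train"))
    if not preds:
        raise ValueError("ensemble contains no usable models")
    predicted = pd.Series(np.mean(preds, axis=0), index=para.abundance.index)

    if correct_gaps:
        delta = correct_age_gap(predicted, para.ages).unbiased_gap
    else:
        delta = predicted - para.ages
    delta.name = "delta_age"

    para_groups = groups.loc[delta.index]
    group_means = delta.groupby(para_groups).mean()

    rows = {}
    for name, (a, b) in {"YH_vs_YI": ("YH", "YI"), "OH_vs_OI": ("OH", "OI")}.items():
        ga, gb = delta[para_groups == a], delta[para_groups == b]
        if len(ga) < 2 or len(gb) < 2:
            logger.warning("contrast %s skipped (missing group)", name)
            continue
        t, df, p = welch_t_test(ga, gb)
        rows[name] = {"mean_a": float(ga.mean()), "mean_b": float(gb.mean()),
                      "t": t, "df": df, "p_value": p}
    contrasts = pd.DataFrame(rows).T
    return ParabiosisResult(delta_age=delta, group_means=group_means, contrasts=contrasts)
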