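"""Permutation ensembles of penalized-regression aging clocks.

A clock is a penalized linear regression of chronological age on log2,
train-scaled protein abundances (optionally plus a 0/1 sex covariate).
Clocks are built in a permutation fashion: per permutation a random
training subset is drawn, a LASSO (matrisome-restricted "ECM" mode or
all-protein "unsupervised" mode) is fitted with its penalty chosen by
10-fold cross-validation, and held-out predictions are scored by Pearson
correlation.  Matched "random" clocks refit Ridge regressions on
randomly drawn protein sets of the same size per permutation.  Proteins
selected (nonzero LASSO coefficient) in more than half of the
permutations form the stable signature, from which a full-data Ridge
"stable clock" is trained.  Predicted−chronological age gaps are
de-biased by regressing predictions on chronological age
(``lm-correction``): unbiased = (predicted − intercept)/slope.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV, LogisticRegressionCV, RidgeCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from ._stats import pearson_r, rank_sum_test, welch_t_test
from .annotation import matrisome_ids
from .cohort import Cohort
from .tables import Matreotype

logger = logging.getLogger(__name__)

SEX_FEATURE = "__sex__"
DEFAULT_RIDGE_ALPHAS = np.logspace(-3, 3, 21)


@dataclass
class ClockModel:
    """A fitted penalized linear clock with its training-scale statistics."""

    feature_ids: list
    coefficients: np.ndarray
    intercept: float
    train_means: np.ndarray
    train_sds: np.ndarray
    penalty: str  # "L1" | "L2"
    lam: float
    log2_input: bool = True

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.train_means = np.asarray(self.train_means, dtype=float)
        self.train_sds = np.asarray(self.train_sds, dtype=float)
        if not (len(self.feature_ids) == self.coefficients.size
                == self.train_means.size == self.train_sds.size):
            raise ValueError("feature_ids, coefficients and scaling stats must align")
        if (self.train_sds <= 0).any():
            raise ValueError("train_sds must be positive for retained features")

    @property
    def protein_ids(self) -> list:
        return [f for f in self.feature_ids if f != SEX_FEATURE]

    def selected_proteins(self) -> tuple:
        nz = self.coefficients != 0
        return tuple(f for f, keep in zip(self.feature_ids, nz) if keep and f != SEX_FEATURE)

    def _feature_matrix(self, abundance: pd.DataFrame, sex: pd.Series | None) -> np.ndarray:
        missing = [f for f in self.protein_ids if f not in abundance.columns]
        if missing:
            raise ValueError(f"cohort missing clock features: {missing[:10]}")
        cols = []
        for f in self.feature_ids:
            if f == SEX_FEATURE:
                if sex is None:
                    raise ValueError("model uses sex; pass the sex indicator")
                cols.append(sex.to_numpy(dtype=float))
            else:
                v = abundance[f].to_numpy(dtype=float)
                if (v <= 0).any():
                    raise ValueError(f"non-positive abundance for feature {f!r}")
                cols.append(np.log2(v) if self.log2_input else v)
        return np.column_stack(cols)

    def predict(
        self,
        abundance: pd.DataFrame,
        sex: pd.Series | None = None,
        scaling: str = "train",
    ) -> np.ndarray:
        """Predict ages.

        ``scaling='train'`` scales by the stored training statistics
        (leakage-free within-study application); ``scaling='self'`` is
        the off-the-shelf external mode where the target cohort is
        scaled by its own mean/SD.
        """
        X = self._feature_matrix(abundance, sex)
        if scaling == "train":
            mu, sd = self.train_means, self.train_sds
        elif scaling == "self":
            mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            raise ValueError("scaling must be 'train' or 'self'")
        return (X - mu) / sd @ self.coefficients + self.intercept

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "feature_ids": list(self.feature_ids),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "train_means": self.train_means.tolist(),
            "train_sds": self.train_sds.tolist(),
            "penalty": self.penalty,
            "lambda": self.lam,
            "log2_input": self.log2_input,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClockModel":
        return cls(
            feature_ids=list(d["feature_ids"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            train_means=np.asarray(d["train_means"], dtype=float),
            train_sds=np.asarray(d["train_sds"], dtype=float),
            penalty=d["penalty"],
            lam=float(d["lambda"]),
            log2_input=bool(d.get("log2_input", True)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ClockModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ClockPermutation:
    """One permutation: train split, fitted model, held-out performance."""

    train_sample_ids: tuple
    model: ClockModel | None
    selected: tuple
    test_r: float
    flagged: bool = False


def _scale_train(L: np.ndarray, train_idx: np.ndarray):
    mu = L[train_idx].mean(axis=0)
    sd = L[train_idx].std(axis=0, ddof=0)
    return mu, sd


class PermutationClockEnsemble(BaseEstimator):
    """Ensemble of LASSO aging clocks over random train/test permutations.

    Parameters
    ----------
    mode : {'ecm', 'unsupervised', 'random'}
        ECM mode restricts candidate features to matrisome proteins;
        unsupervised mode uses the whole measured proteome.  (Random
        ensembles are produced by :func:`run_random_clocks`.)
    n_permutations : number of independent train/test splits.
    train_size : training samples per permutation; the remainder tests.
    include_sex : offer the 0/1 sex indicator as a (penalizable) feature.
    n_alphas, alpha_min_ratio : LASSO λ path (λ_max down by this factor).
    cv_folds : folds for the per-permutation λ cross-validation.
    random_state : seed for splits, CV folds and everything downstream.

    Fitted attributes: ``permutations_`` (list of
    :class:`ClockPermutation`), ``selection_frequency_`` (per-protein
    fraction of permutations with a nonzero coefficient), ``test_r_``.
    """

    def __init__(
        self,
        mode: str = "ecm",
        n_permutations: int = 10_000,
        train_size: int = 100,
        include_sex: bool = True,
        n_alphas: int = 100,
        alpha_min_ratio: float = 1e-4,
        cv_folds: int = 10,
        max_iter: int = 5000,
        random_state: int | None = None,
    ):
        self.mode = mode
        self.n_permutations = n_permutations
        self.train_size = train_size
        self.include_sex = include_sex
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.cv_folds = cv_folds
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, feature_pool=None, sex: pd.Series | None = None):
        """Fit the ensemble on raw positive abundances ``X`` and ages ``y``."""
        if self.train_size >= X.shape[0]:
            raise ValueError("train_size must be smaller than the number of samples")
        if feature_pool is None:
            feature_pool = list(X.columns)
        feature_pool = [f for f in feature_pool if f in X.columns]
        if not feature_pool:
            raise ValueError("empty feature pool")
        y = np.asarray(y, dtype=float)
        L = np.log2(X[feature_pool].to_numpy(dtype=float))
        sex_vec = None
        if self.include_sex:
            if sex is None:
                raise ValueError("include_sex=True requires the sex indicator")
            sex_vec = sex.loc[X.index].to_numpy(dtype=float)

        root = np.random.default_rng(self.random_state)
        n = X.shape[0]
        permutations: list[ClockPermutation] = []
        counts = np.zeros(len(feature_pool))
        pool_pos = {f: i for i, f in enumerate(feature_pool)}
        for _ in range(self.n_permutations):
            rng = np.random.default_rng(root.integers(0, 2**31 - 1))
            train_idx = rng.choice(n, size=self.train_size, replace=False)
            test_idx = np.setdiff1d(np.arange(n), train_idx)
            perm = self._fit_one(L, y, sex_vec, feature_pool, train_idx, test_idx,
                                 X.index, rng)
            permutations.append(perm)
            for f in perm.selected:
                counts[pool_pos[f]] += 1

        self.feature_pool_ = list(feature_pool)
        self.permutations_ = permutations
        self.selection_frequency_ = pd.Series(
            counts / self.n_permutations, index=pd.Index(feature_pool, name="protein_id"),
            name="selection_frequency",
        )
        self.test_r_ = np.array([p.test_r for p in permutations])
        self.sample_ids_ = list(X.index)
        return self

    def _fit_one(self, L, y, sex_vec, feature_pool, train_idx, test_idx, sample_index, rng):
        mu, sd = _scale_train(L, train_idx)
        keep = sd > 0
        feats = [f for f, k in zip(feature_pool, keep) if k]
        Xtr = (L[np.ix_(train_idx, np.where(keep)[0])] - mu[keep]) / sd[keep]
        feat_ids = list(feats)
        means, sds = list(mu[keep]), list(sd[keep])
        if sex_vec is not None:
            s_mu = sex_vec[train_idx].mean()
            s_sd = sex_vec[train_idx].std(ddof=0)
            if s_sd > 0:
                Xtr = np.column_stack([Xtr, (sex_vec[train_idx] - s_mu) / s_sd])
                feat_ids.append(SEX_FEATURE)
                means.append(s_mu)
                sds.append(s_sd)

        cv = KFold(self.cv_folds, shuffle=True,
                   random_state=int(rng.integers(0, 2**31 - 1)))
        lasso = LassoCV(
            alphas=self.n_alphas, eps=self.alpha_min_ratio, cv=cv,
            max_iter=self.max_iter, tol=1e-4,
        )
        # Features are pre-scaled; LassoCV centers internally.  Loose
        # convergence at near-null permutations is expected and harmless.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            lasso.fit(Xtr, y[train_idx])
        model = ClockModel(
            feature_ids=feat_ids,
            coefficients=lasso.coef_,
            intercept=float(lasso.intercept_),
            train_means=np.array(means),
            train_sds=np.array(sds),
            penalty="L1",
            lam=float(lasso.alpha_),
        )
        selected = model.selected_proteins()
        # Held-out evaluation with train-statistics scaling (no leakage).
        Lte = L[test_idx][:, keep]
        Xte = (Lte - mu[keep]) / sd[keep]
        if SEX_FEATURE in feat_ids:
            Xte = np.column_stack([Xte, (sex_vec[test_idx] - s_mu) / s_sd])
        pred = Xte @ model.coefficients + model.intercept
        flagged = len(selected) == 0 and not np.any(model.coefficients)
        r = pearson_r(pred, y[test_idx]) if not flagged else float("nan")
        return ClockPermutation(
            train_sample_ids=tuple(sample_index[train_idx]),
            model=model,
            selected=selected,
            test_r=r,
            flagged=flagged,
        )

    # -- summaries -----------------------------------------------------
    def mean_test_r(self) -> float:
        r = self.test_r_
        return float(np.nanmean(r)) if np.isfinite(r).any() else float("nan")

    def train_sample_id_set(self) -> set:
        out: set = set()
        for p in self.permutations_:
            out.update(p.train_sample_ids)
        return out


def run_clock_ensemble(
    cohort: Cohort,
    annotation: pd.DataFrame,
    mode: str = "ecm",
    n_permutations: int = 10_000,
    train_size: int = 100,
    include_sex: bool = True,
    seed: int | None = None,
    **kwargs,
) -> PermutationClockEnsemble:
    """Cohort-level wrapper around :class:`PermutationClockEnsemble`."""
    if mode == "ecm":
        pool = [p for p in matrisome_ids(annotation) if p in cohort.protein_ids]
    elif mode == "unsupervised":
        pool = list(cohort.protein_ids)
    else:
        raise ValueError("mode must be 'ecm' or 'unsupervised'")
    est = PermutationClockEnsemble(
        mode=mode, n_permutations=n_permutations, train_size=train_size,
        include_sex=include_sex, random_state=seed, **kwargs,
    )
    sex = cohort.sex_indicator() if include_sex else None
    return est.fit(cohort.abundance, cohort.ages.to_numpy(), feature_pool=pool, sex=sex)


def run_random_clocks(
    cohort: Cohort,
    ensemble: PermutationClockEnsemble,
    seed: int | None = None,
    pool=None,
    ridge_alphas=None,
    cv_folds: int = 10,
) -> PermutationClockEnsemble:
    """Size-matched random Ridge clocks on the same permutations.

    For each permutation of the paired ECM ensemble, draws as many
    proteins (uniformly from the full measured proteome by default) as
    that permutation's LASSO selected, refits a Ridge regression with
    its penalty chosen by 10-fold CV on the identical train split, and
    evaluates on the identical test split.  Permutations where the ECM
    clock selected nothing are skipped and flagged.
    """
    if pool is None:
        pool = list(cohort.protein_ids)
    alphas = DEFAULT_RIDGE_ALPHAS if ridge_alphas is None else ridge_alphas
    y = cohort.ages.to_numpy(dtype=float)
    sample_ids = list(cohort.abundance.index)
    pos = {s: i for i, s in enumerate(sample_ids)}
    L_all = np.log2(cohort.abundance.to_numpy(dtype=float))
    col_pos = {p: j for j, p in enumerate(cohort.protein_ids)}

    root = np.random.default_rng(seed)
    permutations = []
    counts: dict[str, int] = {}
    for perm in ensemble.permutations_:
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        k = len(perm.selected)
        if k == 0:
            permutations.append(ClockPermutation(perm.train_sample_ids, None, (),
                                                 float("nan"), flagged=True))
            continue
        feats = sorted(rng.choice(pool, size=min(k, len(pool)), replace=False).tolist())
        train_idx = np.array([pos[s] for s in perm.train_sample_ids])
        test_idx = np.setdiff1d(np.arange(len(sample_ids)), train_idx)
        cols = np.array([col_pos[f] for f in feats])
        L = L_all[:, cols]
        mu, sd = _scale_train(L, train_idx)
        keep = sd > 0
        feats = [f for f, k_ in zip(feats, keep) if k_]
        Xtr = (L[np.ix_(train_idx, np.where(keep)[0])] - mu[keep]) / sd[keep]
        cv = KFold(cv_folds, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1)))
        ridge = RidgeCV(alphas=alphas, cv=cv)
        ridge.fit(Xtr, y[train_idx])
        model = ClockModel(
            feature_ids=feats, coefficients=ridge.coef_,
            intercept=float(ridge.intercept_),
            train_means=mu[keep], train_sds=sd[keep],
            penalty="L2", lam=float(ridge.alpha_),
        )
        Xte = (L[test_idx][:, keep] - mu[keep]) / sd[keep]
        r = pearson_r(Xte @ model.coefficients + model.intercept, y[test_idx])
        for f in feats:
            counts[f] = counts.get(f, 0) + 1
        permutations.append(ClockPermutation(perm.train_sample_ids, model,
                                             tuple(feats), r))

    out = PermutationClockEnsemble(
        mode="random", n_permutations=ensemble.n_permutations,
        train_size=ensemble.train_size, include_sex=False, random_state=seed,
    )
    out.feature_pool_ = list(pool)
    out.permutations_ = permutations
    out.selection_frequency_ = pd.Series(
        {p: counts.get(p, 0) / ensemble.n_permutations for p in pool},
        name="selection_frequency",
    ).rename_axis("protein_id")
    out.test_r_ = np.array([p.test_r for p in permutations])
    out.sample_ids_ = sample_ids
    return out


def stability_selection(
    ensemble: PermutationClockEnsemble,
    threshold: float = 0.5,
    name: str = "stable_clock_proteins",
) -> Matreotype:
    """Proteins selected in strictly more than ``threshold`` of permutations."""
    freq = ensemble.selection_frequency_
    stable = frozenset(freq.index[freq > threshold])
    return Matreotype(name, stable, "custom",
                      {"threshold": threshold, "mode": ensemble.mode})


class StableClock(BaseEstimator, RegressorMixin):
    """Full-data Ridge clock on a fixed protein signature.

    Trained on the complete cohort (no held-out split) with the Ridge
    penalty chosen by 10-fold CV; sex is excluded by default.  Scaling
    statistics are stored from the full training cohort.
    """

    def __init__(self, proteins=None, include_sex: bool = False,
                 alphas=None, cv_folds: int = 10, random_state: int | None = None):
        self.proteins = proteins
        self.include_sex = include_sex
        self.alphas = alphas
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, sex: pd.Series | None = None):
        feats = list(self.proteins) if self.proteins is not None else list(X.columns)
        missing = [f for f in feats if f not in X.columns]
        if missing:
            raise ValueError(f"proteins not measured: {missing[:10]}")
        y = np.asarray(y, dtype=float)
        L = np.log2(X[feats].to_numpy(dtype=float))
        mu = L.mean(axis=0)
        sd = L.std(axis=0, ddof=0)
        keep = sd > 0
        feats = [f for f, k in zip(feats, keep) if k]
        Xs = (L[:, keep] - mu[keep]) / sd[keep]
        feat_ids, means, sds = list(feats), list(mu[keep]), list(sd[keep])
        if self.include_sex:
            if sex is None:
                raise ValueError("include_sex=True requires the sex indicator")
            s = sex.loc[X.index].to_numpy(dtype=float)
            s_mu, s_sd = s.mean(), s.std(ddof=0)
            if s_sd > 0:
                Xs = np.column_stack([Xs, (s - s_mu) / s_sd])
                feat_ids.append(SEX_FEATURE)
                means.append(s_mu)
                sds.append(s_sd)
        alphas = DEFAULT_RIDGE_ALPHAS if self.alphas is None else self.alphas
        cv = KFold(min(self.cv_folds, len(y)), shuffle=True,
                   random_state=self.random_state)
        ridge = RidgeCV(alphas=alphas, cv=cv)
        ridge.fit(Xs, y)
        self.model_ = ClockModel(
            feature_ids=feat_ids, coefficients=ridge.coef_,
            intercept=float(ridge.intercept_),
            train_means=np.array(means), train_sds=np.array(sds),
            penalty="L2", lam=float(ridge.alpha_),
        )
        self.coef_ = ridge.coef_
        self.intercept_ = float(ridge.intercept_)
        self.alpha_ = float(ridge.alpha_)
        self.in_sample_r_ = pearson_r(self.model_.predict(X, sex=sex), y)
        return self

    def predict(self, X: pd.DataFrame, sex: pd.Series | None = None,
                scaling: str = "train") -> np.ndarray:
        return self.model_.predict(X, sex=sex, scaling=scaling)


def fit_stable_clock(
    cohort: Cohort, protein_set, include_sex: bool = False,
    seed: int | None = None, **kwargs,
) -> ClockModel:
    """Fit a full-data Ridge clock on ``protein_set``; returns the model."""
    est = StableClock(proteins=sorted(protein_set), include_sex=include_sex,
                      random_state=seed, **kwargs)
    sex = cohort.sex_indicator() if include_sex else None
    est.fit(cohort.abundance, cohort.ages.to_numpy(), sex=sex)
    return est.model_


def predict_age(model: ClockModel, cohort: Cohort, scaling: str = "train") -> pd.Series:
    """Apply a clock to a cohort; see :meth:`ClockModel.predict`."""
    sex = cohort.sex_indicator() if SEX_FEATURE in model.feature_ids else None
    pred = model.predict(cohort.abundance, sex=sex, scaling=scaling)
    return pd.Series(pred, index=cohort.abundance.index, name="predicted_age")


@dataclass
class AgeGapResult:
    """Bias-corrected clock age gaps.

    ``unbiased = (predicted − intercept) / slope`` where intercept and
    slope come from the lm-correction regression of predicted on
    chronological age; gaps are unbiased − chronological.
    """

    samples: pd.DataFrame = field(repr=False)
    correction_intercept: float = 0.0
    correction_slope: float = 1.0

    @property
    def unbiased_gap(self) -> pd.Series:
        return self.samples["unbiased_gap"]


def correct_age_gap(predicted, chronological) -> AgeGapResult:
    """De-bias age predictions by the lm-correction regression."""
    pred = pd.Series(predicted).astype(float)
    chron = pd.Series(np.asarray(chronological, dtype=float), index=pred.index)
    if len(pred) < 3:
        raise ValueError("need at least 3 samples for lm-correction")
    if chron.var(ddof=0) == 0:
        raise ValueError("chronological age has zero variance")
    slope, intercept = np.polyfit(chron.to_numpy(), pred.to_numpy(), 1)
    if abs(slope) < 1e-8:
        raise ValueError("uninformative clock: lm-correction slope ~ 0")
    unbiased = (pred - intercept) / slope
    samples = pd.DataFrame(
        {
            "predicted_age": pred,
            "chronological_age": chron,
            "raw_gap": pred - chron,
            "unbiased_prediction": unbiased,
            "unbiased_gap": unbiased - chron,
        }
    )
    return AgeGapResult(samples, float(intercept), float(slope))


def loocv_auc(
    features: pd.DataFrame,
    labels,
    Cs: int = 5,
    cv_folds: int = 3,
    random_state: int | None = None,
) -> tuple[float, pd.Series]:
    """Aggregated leave-one-out AUC of an L1 logistic case/control classifier.

    For each sample an L1-regularized logistic model (penalty chosen by
    internal CV) is fitted on the remaining samples with train-scaled
    features; the held-out predicted probabilities are pooled into a
    single ROC/AUC.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mu = X[mask].mean(axis=0)
        sd = X[mask].std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (X[mask] - mu) / sd
        cv = min(cv_folds, int(np.min(np.bincount(y[mask]))))
        clf = LogisticRegressionCV(
            Cs=Cs, cv=cv, penalty="l1", solver="liblinear",
            scoring="neg_log_loss", random_state=random_state, max_iter=200,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(Xtr, y[mask])
        probs[i] = clf.predict_proba(((X[i] - mu) / sd).reshape(1, -1))[0, 1]
    auc = float(roc_auc_score(y, probs))
    return auc, pd.Series(probs, index=features.index, name="loocv_probability")


def compare_age_gaps(
    gaps: pd.Series,
    grouping: pd.Series,
    reference,
    test: str = "welch",
) -> pd.DataFrame:
    """Pairwise group-vs-reference tests on clock age gaps.

    ``test='welch'`` (within-study contrasts) or ``'wilcoxon'``
    (external-validation mode).
    """
    grouping = grouping.loc[gaps.index]
    ref = gaps[grouping == reference]
    if len(ref) < 2:
        raise ValueError(f"reference group {reference!r} has fewer than 2 samples")
    rows = []
    for group in [g for g in pd.unique(grouping) if g != reference]:
        vals = gaps[grouping == group]
        if len(vals) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        if test == "welch":
            t, df, p = welch_t_test(vals, ref)
            rows.append({"group": group, "n": len(vals), "mean_gap": float(vals.mean()),
                         "statistic": t, "df": df, "p_value": p})
        elif test == "wilcoxon":
            s, p = rank_sum_test(vals.to_numpy(), ref.to_numpy())
            rows.append({"group": group, "n": len(vals), "mean_gap": float(vals.mean()),
                         "statistic": s, "df": np.nan, "p_value": p})
        else:
            raise ValueError("test must be 'welch' or 'wilcoxon'")
    out = pd.DataFrame(rows).set_index("group")
    out.attrs["reference"] = reference
    out.attrs["reference_mean_gap"] = float(ref.mean())
    return out
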