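"""Respondent-level risk model: L1-penalized logistic regression of
non-completion on sociodemographic and military covariates.

Categorical covariates are dummy coded against explicit reference levels and
continuous covariates min-max normalized (optionally only centered at the
minimum).  The cohort is split 75/25 into train/test; the model minimizes
the summed negative log-likelihood plus alpha * sum(|beta|) with the
intercept unpenalized, and is scored by balanced accuracy (mean of
sensitivity and specificity at the 0.5 probability threshold) on both
splits.  Confidence intervals are not well defined under L1, so Wald CIs
come from an unpenalized refit restricted to the L1-selected support;
L1-zeroed terms are reported as OR 1.00 with p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split

__all__ = [
    "CovariateEncoder",
    "RespondentModelFit",
    "L1LogisticRiskModel",
    "prepare_features",
    "fit_l1_logistic",
]


class CovariateEncoder(BaseEstimator, TransformerMixin):
    """Dummy coding + min-max normalization of a covariates table.

    Parameters
    ----------
    continuous : sequence of column names mapped x -> (x - min)/(max - min)
        (or x -> x - min when ``min_center_only``).
    categorical : sequence of column names expanded into one dummy column per
        non-reference level.
    reference_levels : mapping column -> reference level (required for every
        categorical column).
    add_intercept : bool, default True — prepend a constant column.

    ``transform`` raises on categories unseen at fit time and on continuous
    columns that were constant at fit time (zero range).
    """

    def __init__(
        self,
        continuous: Sequence[str] = (),
        categorical: Sequence[str] = (),
        reference_levels: Mapping[str, str] | None = None,
        min_center_only: bool = False,
        add_intercept: bool = True,
    ):
        self.continuous = continuous
        self.categorical = categorical
        self.reference_levels = reference_levels
        self.min_center_only = min_center_only
        self.add_intercept = add_intercept

    def fit(self, X: pd.DataFrame, y=None) -> "CovariateEncoder":
        refs = dict(self.reference_levels or {})
        for col in self.categorical:
            if col not in refs:
                raise ValueError(f"no reference level given for categorical column {col!r}")
            levels = sorted(map(str, X[col].unique()))
            if refs[col] not in levels:
                raise ValueError(
                    f"reference level {refs[col]!r} not present in column {col!r}"
                )
        self.levels_ = {
            col: [l for l in sorted(map(str, X[col].unique())) if l != refs[col]]
            for col in self.categorical
        }
        self.mins_ = {c: float(X[c].min()) for c in self.continuous}
        self.maxs_ = {c: float(X[c].max()) for c in self.continuous}
        for c in self.continuous:
            if not self.min_center_only and self.maxs_[c] == self.mins_[c]:
                raise ValueError(f"continuous column {c!r} is constant (zero range)")
        self.feature_names_ = (
            (["intercept"] if self.add_intercept else [])
            + list(self.continuous)
            + [f"{col}[{lvl}]" for col in self.categorical for lvl in self.levels_[col]]
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=X.index)
        if self.add_intercept:
            out["intercept"] = 1.0
        for c in self.continuous:
            v = X[c].to_numpy(dtype=float) - self.mins_[c]
            if not self.min_center_only:
                v = v / (self.maxs_[c] - self.mins_[c])
            out[c] = v
        refs = dict(self.reference_levels or {})
        for col in self.categorical:
            vals = X[col].astype(str)
            known = set(self.levels_[col]) | {refs[col]}
            unseen = sorted(set(vals.unique()) - known)
            if unseen:
                raise ValueError(f"unseen categories in column {col!r}: {unseen}")
            for lvl in self.levels_[col]:
                out[f"{col}[{lvl}]"] = (vals == lvl).astype(float)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array(self.feature_names_)


def prepare_features(
    covariates: pd.DataFrame,
    continuous_fields: Sequence[str],
    categorical_fields: Sequence[str],
    reference_levels: Mapping[str, str],
    min_center_only: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix (with intercept column) and term names for the risk model."""
    enc = CovariateEncoder(
        continuous=continuous_fields,
        categorical=categorical_fields,
        reference_levels=reference_levels,
        min_center_only=min_center_only,
    ).fit(covariates)
    X = enc.transform(covariates)
    return X, list(enc.feature_names_)


@dataclass(frozen=True)
class RespondentModelFit:
    """L1 logistic fit: odds-ratio table, penalty metadata, and accuracy.

    ``params`` has one row per term with columns coef, or, ci_low, ci_high,
    p, selected.  Odds ratios and Wald CIs for selected terms come from the
    unpenalized post-selection refit; unselected terms carry OR 1, p 1, and
    NaN CIs.  ``penalty_convention`` records the objective normalization.
    """

    params: pd.DataFrame
    alpha: float
    split_fraction: float
    seed: int
    balanced_accuracy_train: float
    balanced_accuracy_test: float
    pseudo_r2: float
    converged: bool
    penalty_convention: str = "alpha * sum|beta| added to the summed negative log-likelihood; intercept unpenalized"


class L1LogisticRiskModel(BaseEstimator):
    """L1-penalized logistic regression with an internal train/test split.

    Parameters
    ----------
    alpha : float, default 10 — L1 penalty strength on the summed-NLL scale
        (sklearn C = 1/alpha).
    split_fraction : float, default 0.75 — training share of the split.
    seed : int — controls the split and the saga solver; same seed, same fit.
    max_iter, tol : solver controls.

    After ``fit(X, y)``: ``fit_`` (:class:`RespondentModelFit`), ``coef_``,
    ``intercept_``, ``train_index_``, ``test_index_``.
    """

    def __init__(
        self,
        alpha: float = 10.0,
        split_fraction: float = 0.75,
        seed: int = 0,
        max_iter: int = 5000,
        tol: float = 1e-6,
    ):
        self.alpha = alpha
        self.split_fraction = split_fraction
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: pd.DataFrame | np.ndarray, y) -> "L1LogisticRiskModel":
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        Xdf = pd.DataFrame(X).copy()
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary 0/1")
        # the encoder's intercept column is redundant here: the solver fits
        # its own (unpenalized) intercept
        const_cols = [c for c in Xdf.columns if Xdf[c].nunique() == 1]
        terms = [c for c in Xdf.columns if c not in const_cols]
        Xmat = Xdf[terms].to_numpy(dtype=float)

        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx, train_size=self.split_fraction, random_state=self.seed
        )
        ytr, yte = y[train_idx], y[test_idx]
        if len(np.unique(ytr)) < 2:
            raise ValueError("training split contains a single outcome class")
        Xtr, Xte = Xmat[train_idx], Xmat[test_idx]

        clf = LogisticRegression(
            l1_ratio=1.0,  # pure L1 penalty
            C=1.0 / self.alpha,
            solver="saga",
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.seed,
        ).fit(Xtr, ytr)
        coef = clf.coef_[0]
        selected = np.abs(coef) > 1e-8

        # post-selection unpenalized refit for Wald inference
        converged = True
        or_ = np.ones(len(terms))
        ci_low = np.full(len(terms), np.nan)
        ci_high = np.full(len(terms), np.nan)
        pvals = np.ones(len(terms))
        coefs_out = np.zeros(len(terms))
        intercept_out = float(clf.intercept_[0])
        if selected.any():
            Xsel = sm.add_constant(Xtr[:, selected], has_constant="add")
            try:
                refit = sm.Logit(ytr, Xsel).fit(disp=0, maxiter=200)
                converged = bool(refit.mle_retvals.get("converged", True))
                ci = refit.conf_int()
                sel_idx = np.flatnonzero(selected)
                coefs_out[sel_idx] = refit.params[1:]
                or_[sel_idx] = np.exp(refit.params[1:])
                ci_low[sel_idx] = np.exp(ci[1:, 0])
                ci_high[sel_idx] = np.exp(ci[1:, 1])
                pvals[sel_idx] = refit.pvalues[1:]
                intercept_out = float(refit.params[0])
            except Exception:
                converged = False
                sel_idx = np.flatnonzero(selected)
                coefs_out[sel_idx] = coef[selected]
                or_[sel_idx] = np.exp(coef[selected])

        # McFadden pseudo-R^2 of the penalized model on the training split
        p_tr = clf.predict_proba(Xtr)[:, 1]
        eps = 1e-12
        ll = float(np.sum(ytr * np.log(p_tr + eps) + (1 - ytr) * np.log(1 - p_tr + eps)))
        base = ytr.mean()
        ll0 = float(
            len(ytr) * (base * np.log(base + eps) + (1 - base) * np.log(1 - base + eps))
        )
        pseudo_r2 = 1.0 - ll / ll0 if ll0 != 0 else float("nan")

        ba_train = balanced_accuracy_score(ytr, p_tr >= 0.5)
        ba_test = balanced_accuracy_score(yte, clf.predict_proba(Xte)[:, 1] >= 0.5)

        params = pd.DataFrame(
            {
                "coef": coefs_out,
                "or": or_,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "p": pvals,
                "selected": selected,
            },
            index=terms,
        )
        params.loc["intercept"] = [
            intercept_out, np.exp(intercept_out), np.nan, np.nan, np.nan, True,
        ]
        self.terms_ = terms
        self.coef_ = coef
        self.intercept_ = float(clf.intercept_[0])
        self.train_index_ = train_idx
        self.test_index_ = test_idx
        self._clf = clf
        self._const_cols = const_cols
        self.fit_ = RespondentModelFit(
            params=params,
            alpha=self.alpha,
            split_fraction=self.split_fraction,
            seed=self.seed,
            balanced_accuracy_train=float(ba_train),
            balanced_accuracy_test=float(ba_test),
            pseudo_r2=float(pseudo_r2),
            converged=converged,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        Xdf = pd.DataFrame(X)
        return self._clf.predict_proba(Xdf[self.terms_].to_numpy(dtype=float))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_l1_logistic(
    X: pd.DataFrame | np.ndarray,
    y,
    alpha: float = 10.0,
    split_fraction: float = 0.75,
    seed: int = 0,
) -> RespondentModelFit:
    """Fit the L1 respondent risk model; see :class:`L1LogisticRiskModel`."""
    return L1LogisticRiskModel(
        alpha=alpha, split_fraction=split_fraction, seed=seed
    ).fit(X, y).fit_
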