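"""Section-level Poisson model of quit counts on survey attributes.

The observations are survey sections; the outcome is how many respondents
quit within each section.  Because a section with more questions offers more
opportunities to quit, the question count enters as an exposure (log offset)
— and, separately, as a standardized predictor, so the model can still speak
to whether short or long sections are risky per question asked.  Predictors
are z-scored by default so coefficient magnitudes are comparable across
attributes; exponentiated coefficients are reported as relative risks (RR).
Goodness of fit is McFadden's pseudo-R^2 = 1 - ll_model / ll_null with the
null model retaining the offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .missingness import DegenerateDataError

__all__ = [
    "AttributeModelFit",
    "SectionPoissonModel",
    "fit_section_poisson",
    "rr_from_coefficient",
]

_PREDICTORS = ["mean_location", "mean_sensitivity", "question_count"]


@dataclass(frozen=True)
class AttributeModelFit:
    """Coefficient table and fit statistics of the section Poisson model.

    ``params`` has one row per term (const + predictors) with columns
    b, se, z, p, ci_low, ci_high, rr (rr = exp(b)).
    """

    params: pd.DataFrame
    pseudo_r2: float
    converged: bool
    standardized: bool
    n_sections: int
    llf: float
    llnull: float

    def rr(self, term: str) -> float:
        return float(self.params.loc[term, "rr"])


class SectionPoissonModel(BaseEstimator):
    """Poisson GLM of section quit counts with question-count exposure.

    Parameters
    ----------
    standardize : bool, default True
        z-score the three predictors before fitting.  The raw-scale fit is
        available with ``standardize=False``.

    After ``fit``: ``result_`` (statsmodels GLMResults), ``fit_``
    (:class:`AttributeModelFit`).
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, sections: pd.DataFrame, y=None) -> "SectionPoissonModel":
        required = set(_PREDICTORS) | {"quit_count"}
        missing = required - set(sections.columns)
        if missing:
            raise ValueError(f"sections table is missing columns: {sorted(missing)}")
        if len(sections) < 5:
            raise ValueError("need at least 5 sections to fit the attribute model")
        counts = sections["quit_count"].to_numpy(dtype=float)
        if (counts == 0).all():
            raise DegenerateDataError("all section quit counts are zero")
        Z = sections[_PREDICTORS].to_numpy(dtype=float)
        if self.standardize:
            sd = Z.std(axis=0, ddof=0)
            if (sd == 0).any():
                zero = [p for p, s in zip(_PREDICTORS, sd) if s == 0]
                raise ValueError(f"constant predictor(s) cannot be standardized: {zero}")
            Z = (Z - Z.mean(axis=0)) / sd
        X = sm.add_constant(pd.DataFrame(Z, columns=_PREDICTORS), has_constant="add")
        offset = np.log(sections["question_count"].to_numpy(dtype=float))
        model = sm.GLM(counts, X, family=sm.families.Poisson(), offset=offset)
        res = model.fit()
        null = sm.GLM(
            counts, np.ones((len(counts), 1)), family=sm.families.Poisson(), offset=offset
        ).fit()
        ci = res.conf_int()
        params = pd.DataFrame(
            {
                "b": res.params,
                "se": res.bse,
                "z": res.tvalues,
                "p": res.pvalues,
                "ci_low": ci.iloc[:, 0],
                "ci_high": ci.iloc[:, 1],
                "rr": np.exp(res.params),
            }
        )
        self.result_ = res
        self.fit_ = AttributeModelFit(
            params=params,
            pseudo_r2=float(1.0 - res.llf / null.llf),
            converged=bool(res.converged),
            standardized=self.standardize,
            n_sections=len(sections),
            llf=float(res.llf),
            llnull=float(null.llf),
        )
        return self

    def predict(self, sections: pd.DataFrame) -> np.ndarray:
        """Expected quit counts for new sections (on the fitted scale)."""
        Z = sections[_PREDICTORS].to_numpy(dtype=float)
        if self.standardize:
            raise NotImplementedError(
                "prediction on new sections is only supported with standardize=False"
            )
        X = sm.add_constant(pd.DataFrame(Z, columns=_PREDICTORS), has_constant="add")
        offset = np.log(sections["question_count"].to_numpy(dtype=float))
        return np.asarray(self.result_.predict(X, offset=offset))


def fit_section_poisson(sections: pd.DataFrame, standardize: bool = True) -> AttributeModelFit:
    """Fit the section-level Poisson model; see :class:`SectionPoissonModel`."""
    return SectionPoissonModel(standardize=standardize).fit(sections).fit_


def rr_from_coefficient(b: float) -> float:
    """Relative risk implied by a Poisson log-link coefficient: exp(b)."""
    if not np.isfinite(b):
        raise ValueError("coefficient must be finite")
    return float(np.exp(b))
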