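"""Per-respondent breakoff detection from missing-value flags.

The detector treats each respondent's row of missingness flags as a binary
sequence over item location and asks where (if anywhere) the sequence turns
into a terminal run of 1s.  For each respondent it fits a ridge-stabilized
univariate logistic regression of the flags on item index (the data are
usually perfectly separated, so a small ridge keeps the fit finite) and then
selects the quit index as the accuracy-maximizing step threshold, with ties
broken toward the completer call (largest threshold).  The real-valued
logistic decision boundary is recorded alongside the integer quit index.

A respondent is a non-completer exactly when the selected threshold lies
before the end of the survey; their quit index is the location of the first
item of the terminal missing run.  Scattered (MAR) item skips before the
quit point lower the per-respondent accuracy, which is reported per person
and averaged over the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .survey import MissingFlagMatrix

__all__ = [
    "RespondentClassification",
    "CohortDetectionSummary",
    "BreakoffClassifier",
    "NaiveCutoffClassifier",
    "fit_respondent_classifier",
    "brute_force_threshold",
    "classify_cohort",
    "naive_cutoff_classifier",
]

CLASSIFICATION_COLUMNS = [
    "respondent_id",
    "intercept",
    "slope",
    "boundary",
    "quit_index",
    "is_noncompleter",
    "accuracy",
]


@dataclass(frozen=True)
class RespondentClassification:
    """Fitted threshold classification for one respondent."""

    respondent_id: str
    intercept: float
    slope: float
    boundary: float  # real-valued index where fitted probability crosses 1/2 (NaN if none)
    quit_index: int  # first item of the terminal missing run; n_items for completers
    is_noncompleter: bool
    accuracy: float  # step-function prediction accuracy over all items


@dataclass(frozen=True)
class CohortDetectionSummary:
    """Cohort-level moments of the per-respondent classifications."""

    n_respondents: int
    n_noncompleters: int
    noncompletion_rate: float  # percent
    accuracy_mean: float
    accuracy_sd: float
    quit_location_mean: float  # non-completers only; NaN if none
    quit_location_sd: float


def _as_flag_array(X) -> np.ndarray:
    if isinstance(X, MissingFlagMatrix):
        return X.flags
    arr = np.asarray(X)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D flag array, got shape {arr.shape}")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("flags must contain only 0 and 1")
    return arr.astype(np.int8, copy=False)


def _step_accuracy(flags: np.ndarray) -> np.ndarray:
    """Accuracy of every step threshold, vectorized over rows.

    For threshold t the predictor is 0 at indices < t and 1 at indices >= t.
    correct(t) = (#zeros before t) + (#ones at or after t)
               = (t - ones_before_t) + (total_ones - ones_before_t).
    Returns an array of shape (n_rows, n + 1).
    """
    R, n = flags.shape
    ones_before = np.concatenate(
        [np.zeros((R, 1), dtype=np.int64), np.cumsum(flags, axis=1, dtype=np.int64)],
        axis=1,
    )
    total = ones_before[:, -1:]
    t = np.arange(n + 1, dtype=np.int64)
    return ((t - ones_before) + (total - ones_before)) / n


def _best_thresholds(flags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Accuracy-maximizing threshold per row, ties broken to the largest t."""
    acc = _step_accuracy(flags)
    n = flags.shape[1]
    # argmax on the reversed axis finds the *last* maximizer
    t_star = n - np.argmax(acc[:, ::-1], axis=1)
    return t_star, acc[np.arange(flags.shape[0]), t_star]


def _ridge_logistic_rows(
    flags: np.ndarray, ridge: float, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Batched damped-Newton ridge logistic fit of each row on item index.

    The index is affinely rescaled to [-1, 1] for conditioning; returned
    intercept/slope are on the raw 0-based index scale.  The ridge penalty
    (applied on the rescaled coefficients) keeps perfectly separated rows —
    the typical case — at a finite optimum.
    """
    R, n = flags.shape
    m = (n - 1) / 2.0
    s = max(m, 1.0)
    x = (np.arange(n) - m) / s
    y = flags.astype(np.float64)
    b0 = np.zeros(R)
    b1 = np.zeros(R)

    def loss(b0, b1, ysub):
        eta = b0[:, None] + b1[:, None] * x
        return (
            np.logaddexp(0.0, eta).sum(axis=1)
            - (ysub * eta).sum(axis=1)
            + 0.5 * ridge * (b0**2 + b1**2)
        )

    cur = loss(b0, b1, y)
    active = np.ones(R, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = b0[active, None] + b1[active, None] * x
        p = 1.0 / (1.0 + np.exp(-eta))
        r = p - y[active]
        g0 = r.sum(axis=1) + ridge * b0[active]
        g1 = r @ x + ridge * b1[active]
        w = p * (1.0 - p)
        h00 = w.sum(axis=1) + ridge
        h01 = w @ x
        h11 = w @ (x * x) + ridge
        det = h00 * h11 - h01 * h01
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        # backtracking line search, vectorized over rows
        step = np.ones(d0.shape)
        y_act = y[active]
        nb0, nb1 = b0[active] - d0, b1[active] - d1
        new = loss(nb0, nb1, y_act)
        for _half in range(30):
            worse = new > cur[active] + 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
            nb0 = np.where(worse, b0[active] - step * d0, nb0)
            nb1 = np.where(worse, b1[active] - step * d1, nb1)
            new = new.copy()
            new[worse] = loss(nb0[worse], nb1[worse], y_act[worse])
        moved = np.maximum(np.abs(nb0 - b0[active]), np.abs(nb1 - b1[active]))
        b0[active], b1[active] = nb0, nb1
        cur[active] = new
        still = moved > tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    # map back to raw index scale: eta = b0 + b1 * (j - m)/s
    slope = b1 / s
    intercept = b0 - b1 * m / s
    return intercept, slope


class BreakoffClassifier(BaseEstimator):
    """Per-respondent threshold classifier for survey breakoff.

    Parameters
    ----------
    ridge : float, default 1e-3
        L2 stabilizer on the per-respondent logistic coefficients (rescaled
        index space).  Only the decision boundary, not the coefficients, is
        the quantity of record, so the exact value is uncritical.
    max_iter, tol : Newton iteration controls for the logistic fits.
    chunk_size : int, default 4096
        Rows per batch in the vectorized fit (bounds peak memory).

    Attributes (after :meth:`fit`)
    ------------------------------
    quit_index_, is_noncompleter_, accuracy_, boundary_, intercept_, slope_ :
        per-respondent arrays;
    classifications_ : tidy DataFrame of the same;
    summary_ : :class:`CohortDetectionSummary`.

    The procedure is deterministic: ``fit`` is a pure function of the flag
    matrix.
    """

    def __init__(self, ridge: float = 1e-3, max_iter: int = 100, tol: float = 1e-8,
                 chunk_size: int = 4096):
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol
        self.chunk_size = chunk_size

    def _classify(self, flags: np.ndarray) -> pd.DataFrame:
        R, n = flags.shape
        if n < 1:
            raise ValueError("rows must contain at least one item")
        quit_index = np.empty(R, dtype=np.int64)
        accuracy = np.empty(R)
        intercept = np.empty(R)
        slope = np.empty(R)
        for lo in range(0, R, self.chunk_size):
            sl = slice(lo, min(lo + self.chunk_size, R))
            chunk = flags[sl]
            t, a = _best_thresholds(chunk)
            quit_index[sl], accuracy[sl] = t, a
            b0, b1 = _ridge_logistic_rows(chunk, self.ridge, self.max_iter, self.tol)
            intercept[sl], slope[sl] = b0, b1
        # slopes below float-noise level mean the fitted probability never
        # crosses 1/2 upward; report no boundary rather than a huge ratio
        eff = np.where(np.abs(slope) < 1e-9, 0.0, slope)
        boundary = np.where(eff > 0, -intercept / np.where(eff == 0, np.nan, eff), np.nan)
        return pd.DataFrame(
            {
                "intercept": intercept,
                "slope": slope,
                "boundary": boundary,
                "quit_index": quit_index,
                "is_noncompleter": quit_index < n,
                "accuracy": accuracy,
            }
        )

    def fit(self, X, y=None) -> "BreakoffClassifier":
        """Classify every row of the flag matrix ``X``."""
        flags = _as_flag_array(X)
        if flags.shape[0] == 0:
            raise ValueError("cannot fit on an empty matrix")
        df = self._classify(flags)
        if isinstance(X, MissingFlagMatrix):
            ids = list(X.respondent_ids)
        else:
            ids = [str(i) for i in range(flags.shape[0])]
        df.insert(0, "respondent_id", ids)
        self.n_items_ = flags.shape[1]
        self.classifications_ = df[CLASSIFICATION_COLUMNS]
        self.quit_index_ = df["quit_index"].to_numpy()
        self.is_noncompleter_ = df["is_noncompleter"].to_numpy()
        self.accuracy_ = df["accuracy"].to_numpy()
        self.boundary_ = df["boundary"].to_numpy()
        self.intercept_ = df["intercept"].to_numpy()
        self.slope_ = df["slope"].to_numpy()
        self.summary_ = self._summarize(df)
        return self

    @staticmethod
    def _summarize(df: pd.DataFrame) -> CohortDetectionSummary:
        R = len(df)
        nc = df["is_noncompleter"].to_numpy()
        quits = df.loc[nc, "quit_index"].to_numpy(dtype=float)
        return CohortDetectionSummary(
            n_respondents=R,
            n_noncompleters=int(nc.sum()),
            noncompletion_rate=float(100.0 * nc.sum() / R),
            accuracy_mean=float(df["accuracy"].mean()),
            accuracy_sd=float(df["accuracy"].std(ddof=1)) if R > 1 else 0.0,
            quit_location_mean=float(quits.mean()) if quits.size else float("nan"),
            quit_location_sd=float(quits.std(ddof=1)) if quits.size > 1 else float("nan"),
        )

    def predict(self, X) -> np.ndarray:
        """Non-completer flags for rows of ``X`` (each row fit independently)."""
        flags = _as_flag_array(X)
        return self._classify(flags)["is_noncompleter"].to_numpy()

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).is_noncompleter_


class NaiveCutoffClassifier(BaseEstimator):
    """Percent-missing comparator: non-completer iff missing fraction >= cutoff.

    This is the conventional ad-hoc rule the threshold classifier improves on;
    it cannot distinguish a terminal missing run from scattered skips and
    under-calls respondents who quit near the end of the survey.
    """

    def __init__(self, max_missing_frac: float = 0.15):
        self.max_missing_frac = max_missing_frac

    def fit(self, X, y=None) -> "NaiveCutoffClassifier":
        if not 0 < self.max_missing_frac < 1:
            raise ValueError("max_missing_frac must be in (0, 1)")
        self.is_noncompleter_ = self.predict(X)
        return self

    def predict(self, X) -> np.ndarray:
        if not 0 < self.max_missing_frac < 1:
            raise ValueError("max_missing_frac must be in (0, 1)")
        flags = _as_flag_array(X)
        frac = flags.mean(axis=1)
        return frac >= self.max_missing_frac


# ---------------------------------------------------------------------------
# functional interface


def fit_respondent_classifier(
    flags_row: Sequence[int] | np.ndarray,
    respondent_id: str = "0",
    ridge: float = 1e-3,
) -> RespondentClassification:
    """Classify a single respondent's flag row.

    Returns the fitted logistic intercept/slope, the real-valued decision
    boundary (NaN when the fitted probability never crosses 1/2 upward), the
    integer quit index, the non-completer call, and the step-prediction
    accuracy over all items.
    """
    row = np.asarray(flags_row)
    if row.ndim != 1 or row.size == 0:
        raise ValueError("flags_row must be a non-empty 1-D sequence")
    clf = BreakoffClassifier(ridge=ridge).fit(row[None, :])
    rec = clf.classifications_.iloc[0]
    return RespondentClassification(
        respondent_id=respondent_id,
        intercept=float(rec["intercept"]),
        slope=float(rec["slope"]),
        boundary=float(rec["boundary"]),
        quit_index=int(rec["quit_index"]),
        is_noncompleter=bool(rec["is_noncompleter"]),
        accuracy=float(rec["accuracy"]),
    )


def brute_force_threshold(flags_row: Sequence[int] | np.ndarray) -> tuple[int, float]:
    """Independent oracle: exhaustively score every step threshold.

    Enumerates t in {0..n}; the predictor is 0 below t and 1 at/above t.
    Returns the accuracy-maximizing t, ties broken to the LARGEST t (prefer
    the completer call), and its accuracy.  Deliberately naive O(n^2).
    """
    y = np.asarray(flags_row)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("flags_row must be a non-empty 1-D sequence")
    n = y.size
    best_t, best_acc = 0, -1.0
    for t in range(n + 1):
        pred = (np.arange(n) >= t).astype(int)
        acc = float((pred == y).mean())
        if acc >= best_acc:  # >= so later (larger) t wins ties
            best_t, best_acc = t, acc
    return best_t, best_acc


def classify_cohort(
    matrix: MissingFlagMatrix | np.ndarray, **params
) -> tuple[pd.DataFrame, CohortDetectionSummary]:
    """Classify every respondent and summarize the cohort.

    Returns the per-respondent classification table and a
    :class:`CohortDetectionSummary`.  Deterministic given the matrix.
    """
    clf = BreakoffClassifier(**params).fit(matrix)
    return clf.classifications_, clf.summary_


def naive_cutoff_classifier(
    matrix: MissingFlagMatrix | np.ndarray, max_missing_frac: float = 0.15
) -> np.ndarray:
    """Non-completer flags under the naive percent-missing rule."""
    return NaiveCutoffClassifier(max_missing_frac).predict(matrix)
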