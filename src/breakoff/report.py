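"""Figures and human-readable run reports.

Figures are written straight to files (Agg backend, no display) so reports
can be produced in batch pipelines.  The rendered report is deterministic:
regenerating it from the same bundle yields an identical file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .attributes import AttributeModelFit
from .detect import CohortDetectionSummary
from .missingness import StationarityResult, summed_missingness_series
from .respondent import RespondentModelFit
from .survey import MissingFlagMatrix

__all__ = [
    "ReportBundle",
    "plot_quit_histogram",
    "plot_decomposition",
    "render_report",
]


@dataclass
class ReportBundle:
    """Everything a rendered report can draw on; unset parts render 'not run'."""

    detection: CohortDetectionSummary | None = None
    stationarity: StationarityResult | None = None
    attribute_fit: AttributeModelFit | None = None
    respondent_fit: RespondentModelFit | None = None
    figures: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def plot_quit_histogram(
    classifications: pd.DataFrame,
    n_items: int,
    path: str | Path,
    bin_width: int = 5,
) -> Path | None:
    """Histogram of quit locations among non-completers.

    Returns None (with a warning) when the cohort has no non-completers.
    """
    quits = classifications.loc[
        classifications["is_noncompleter"].astype(bool), "quit_index"
    ].to_numpy()
    if quits.size == 0:
        warnings.warn("no non-completers: quit-location histogram skipped")
        return None
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4))
    bins = np.arange(0, n_items + bin_width, bin_width)
    ax.hist(quits, bins=bins, color="#32617f", edgecolor="white", linewidth=0.3)
    ax.set_xlabel("Item location (first item = 0)")
    ax.set_ylabel("Non-completers")
    ax.set_title("Quit locations")
    ax.set_xlim(0, n_items)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_decomposition(
    matrix: MissingFlagMatrix,
    classifications: pd.DataFrame,
    path: str | Path,
) -> Path:
    """Per-item missingness split into completer vs non-completer series.

    The non-completer series aggregates everyone who has already quit, so on
    pure-breakoff data it is non-decreasing over item location; the completer
    series shows only scattered skip spikes.
    """
    if matrix.n_respondents == 0:
        raise ValueError("cannot decompose an empty matrix")
    nc = classifications["is_noncompleter"].to_numpy(dtype=bool)
    series_nc = summed_missingness_series(matrix.flags[nc])
    series_c = summed_missingness_series(matrix.flags[~nc])
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(matrix.n_items)
    ax.plot(x, series_nc, label="Non-completers (MNAR)", color="#b3403a", lw=1.2)
    ax.plot(x, series_c, label="Completers (MAR)", color="#32617f", lw=1.2)
    ax.set_xlabel("Item location (first item = 0)")
    ax.set_ylabel("Missing responses")
    ax.set_title("Missingness decomposition")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _fmt(x: float, nd: int = 2) -> str:
    return "nan" if x != x else f"{x:.{nd}f}"


def render_report(bundle: ReportBundle, path: str | Path) -> Path:
    """Render the bundle as a markdown report mirroring the analysis flow."""
    lines: list[str] = ["# Survey breakoff report", ""]
    if bundle.metadata:
        lines.append("## Run metadata")
        for k in sorted(bundle.metadata):
            lines.append(f"- {k}: {bundle.metadata[k]}")
        lines.append("")

    lines.append("## Breakoff detection")
    d = bundle.detection
    if d is None:
        lines.append("_not run_")
    else:
        lines += [
            f"- respondents: {d.n_respondents}",
            f"- non-completers: {d.n_noncompleters} ({_fmt(d.noncompletion_rate)}%)",
            f"- classifier accuracy: M = {_fmt(d.accuracy_mean, 3)}, SD = {_fmt(d.accuracy_sd, 3)}",
            f"- quit location: M = {_fmt(d.quit_location_mean)}, SD = {_fmt(d.quit_location_sd)}",
        ]
    lines.append("")

    lines.append("## Tests of missingness")
    s = bundle.stationarity
    if s is None:
        lines.append("_not run_")
    else:
        lines += [
            f"- ADF = {_fmt(s.adf_statistic)}, p = {_fmt(s.p_value, 3)} "
            f"(lags = {s.n_lags_used}, terms = '{s.regression_terms}', alpha = {s.alpha})",
            f"- verdict: **{s.verdict}**",
        ]
    lines.append("")

    lines.append("## Survey attribute model (section Poisson)")
    a = bundle.attribute_fit
    if a is None:
        lines.append("_not run_")
    else:
        lines.append(
            f"- {a.n_sections} sections, pseudo-R2 = {_fmt(a.pseudo_r2, 3)}, "
            f"converged = {a.converged}, standardized = {a.standardized}"
        )
        lines.append("")
        lines.append("| term | b | RR | 95% CI | z | p |")
        lines.append("|---|---|---|---|---|---|")
        for term, row in a.params.iterrows():
            lines.append(
                f"| {term} | {_fmt(row['b'])} | {_fmt(row['rr'])} | "
                f"[{_fmt(row['ci_low'])}, {_fmt(row['ci_high'])}] | "
                f"{_fmt(row['z'])} | {_fmt(row['p'], 3)} |"
            )
    lines.append("")

    lines.append("## Respondent risk model (L1 logistic)")
    r = bundle.respondent_fit
    if r is None:
        lines.append("_not run_")
    else:
        lines += [
            f"- alpha = {r.alpha}, split = {r.split_fraction}, seed = {r.seed}",
            f"- balanced accuracy: train = {_fmt(r.balanced_accuracy_train)}, "
            f"test = {_fmt(r.balanced_accuracy_test)}",
            f"- pseudo-R2 = {_fmt(r.pseudo_r2, 3)}, converged = {r.converged}",
            "",
            "| term | OR | 95% CI | p |",
            "|---|---|---|---|",
        ]
        for term, row in r.params.iterrows():
            lines.append(
                f"| {term} | {_fmt(row['or'])} | "
                f"[{_fmt(row['ci_low'])}, {_fmt(row['ci_high'])}] | {_fmt(row['p'], 3)} |"
            )
    lines.append("")

    if bundle.figures:
        lines.append("## Figures")
        for name in sorted(bundle.figures):
            lines.append(f"- {name}: {bundle.figures[name]}")
        lines.append("")

    path = Path(path)
    path.write_text("\n".join(lines))
    return path
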