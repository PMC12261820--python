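"""Survey templates, response tables, and missing-value flag matrices.

A survey template is an ordered list of items, each belonging to exactly one
contiguous section and carrying a 0-2 sensitivity code (0 = low, 2 = high).
Items are indexed by presentation order, 0-based, so a 250-item instrument
spans locations 0..249.  Responses are held only as binary missingness flags
(1 = missing, 0 = answered): the analyses in this package never look at
answer content, only at which cells are blank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "TemplateValidationError",
    "Item",
    "SurveyTemplate",
    "MissingFlagMatrix",
    "SectionSummary",
    "DEFAULT_SENTINELS",
    "load_template",
    "load_responses",
    "write_responses",
    "summarize_sections",
]


class FormatError(ValueError):
    """An input file does not have the expected columns/shape."""


class TemplateValidationError(ValueError):
    """A template violates a structural invariant (ordering, contiguity, codes)."""


#: Cell values (case-insensitive, after stripping) treated as missing.
DEFAULT_SENTINELS = ("", "na", "nan")


@dataclass(frozen=True)
class Item:
    """A single survey question: its 0-based location, section, and sensitivity."""

    index: int
    item_id: str
    section_id: str
    sensitivity: int


@dataclass(frozen=True)
class SurveyTemplate:
    """An ordered survey instrument partitioned into contiguous sections."""

    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        n = len(self.items)
        if n == 0:
            raise TemplateValidationError("template has no items")
        indices = [it.index for it in self.items]
        if indices != list(range(n)):
            missing = sorted(set(range(n)) - set(indices))
            raise TemplateValidationError(
                f"item indices must be exactly 0..{n - 1} in ascending order; "
                f"got {indices[:10]}{'...' if n > 10 else ''}"
                + (f" (gap at {missing[:5]})" if missing else "")
            )
        for it in self.items:
            if it.sensitivity not in (0, 1, 2):
                raise TemplateValidationError(
                    f"item {it.item_id!r} has sensitivity {it.sensitivity}; must be 0, 1, or 2"
                )
        # sections must be contiguous blocks of the index axis
        seen: dict[str, int] = {}
        prev = None
        for it in self.items:
            if it.section_id in seen and it.section_id != prev:
                raise TemplateValidationError(
                    f"section {it.section_id!r} is not contiguous "
                    f"(reappears at index {it.index})"
                )
            seen.setdefault(it.section_id, it.index)
            prev = it.section_id

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def sections(self) -> tuple[str, ...]:
        """Section identifiers in survey order."""
        out: list[str] = []
        for it in self.items:
            if not out or out[-1] != it.section_id:
                out.append(it.section_id)
        return tuple(out)

    @property
    def section_slices(self) -> dict[str, slice]:
        """Half-open index range [start, end) of each section."""
        slices: dict[str, slice] = {}
        start = 0
        for i, it in enumerate(self.items):
            if it.section_id != self.items[start].section_id:
                slices[self.items[start].section_id] = slice(start, i)
                start = i
        slices[self.items[start].section_id] = slice(start, self.n_items)
        return slices

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def sensitivities(self) -> np.ndarray:
        return np.array([it.sensitivity for it in self.items], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": [it.item_id for it in self.items],
                "index": [it.index for it in self.items],
                "section": [it.section_id for it in self.items],
                "sensitivity": [it.sensitivity for it in self.items],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyTemplate":
        required = {"item_id", "index", "section", "sensitivity"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"template is missing columns: {sorted(missing)}")
        df = df.sort_values("index", kind="stable")
        try:
            idx = df["index"].astype(int)
            sens = df["sensitivity"].astype(int)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-integer index/sensitivity column: {exc}") from None
        items = tuple(
            Item(index=int(i), item_id=str(iid), section_id=str(sec), sensitivity=int(s))
            for i, iid, sec, s in zip(idx, df["item_id"], df["section"], sens)
        )
        return cls(items)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


@dataclass(frozen=True)
class MissingFlagMatrix:
    """Respondent x item binary missingness flags (1 = missing, 0 = answered)."""

    respondent_ids: tuple[str, ...]
    flags: np.ndarray  # shape (n_respondents, n_items), int8 in {0, 1}

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags)
        if flags.ndim != 2:
            raise ValueError(f"flags must be 2-D, got shape {flags.shape}")
        if flags.shape[0] != len(self.respondent_ids):
            raise ValueError(
                f"{len(self.respondent_ids)} respondent ids but {flags.shape[0]} flag rows"
            )
        if flags.size and not np.isin(flags, (0, 1)).all():
            raise ValueError("flags must contain only 0 and 1")
        object.__setattr__(self, "flags", flags.astype(np.int8, copy=False))

    @property
    def n_respondents(self) -> int:
        return self.flags.shape[0]

    @property
    def n_items(self) -> int:
        return self.flags.shape[1]

    @property
    def row_missing_counts(self) -> np.ndarray:
        """Per-respondent number of missing items."""
        return self.flags.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.flags.sum())

    def to_frame(self, template: SurveyTemplate | None = None) -> pd.DataFrame:
        cols = template.item_ids if template is not None else [
            f"item_{j}" for j in range(self.n_items)
        ]
        df = pd.DataFrame(self.flags, columns=list(cols))
        df.insert(0, "respondent_id", list(self.respondent_ids))
        return df


def load_template(path: str | Path) -> SurveyTemplate:
    """Read and validate a survey template CSV.

    Expects columns ``item_id,index,section,sensitivity``.  Raises
    :class:`FormatError` on missing columns and
    :class:`TemplateValidationError` on index gaps/duplicates, non-contiguous
    sections, or sensitivity codes outside {0, 1, 2}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return SurveyTemplate.from_frame(pd.read_csv(path))


def load_responses(
    path: str | Path,
    template: SurveyTemplate,
    sentinels: Iterable[str] = DEFAULT_SENTINELS,
) -> MissingFlagMatrix:
    """Convert a wide respondent x item response CSV into missingness flags.

    The file must have a ``respondent_id`` column plus one column per item of
    the template, named by ``item_id``.  Blank cells and any value in
    ``sentinels`` (case-insensitive) become flag 1; everything else flag 0.
    Columns are re-ordered to template index order if necessary.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "respondent_id" not in df.columns:
        raise FormatError("response table is missing the respondent_id column")
    expected = list(template.item_ids)
    got = [c for c in df.columns if c != "respondent_id"]
    if set(got) != set(expected):
        extra = sorted(set(got) - set(expected))[:5]
        miss = sorted(set(expected) - set(got))[:5]
        raise FormatError(
            f"response columns do not match template items "
            f"(missing {miss}, unexpected {extra})"
        )
    sentinel_set = {s.strip().lower() for s in sentinels} | {""}
    values = df[expected].to_numpy(dtype=object)
    stripped = np.char.strip(values.astype(str))
    flags = np.isin(np.char.lower(stripped), sorted(sentinel_set)).astype(np.int8)
    return MissingFlagMatrix(tuple(df["respondent_id"].astype(str)), flags)


def write_responses(
    matrix: MissingFlagMatrix, template: SurveyTemplate, path: str | Path
) -> Path:
    """Write a response CSV (answered cells ``1``, missing cells blank).

    ``load_responses`` on the written file reproduces the flag matrix exactly.
    """
    path = Path(path)
    df = matrix.to_frame(template)
    items = list(template.item_ids)
    # answered -> "1", missing -> "" (blank cell)
    df[items] = np.where(matrix.flags == 1, "", "1")
    df.to_csv(path, index=False)
    return path


def write_flags(matrix: MissingFlagMatrix, template: SurveyTemplate, path: str | Path) -> Path:
    """Write the raw 0/1 flag matrix as CSV for pipeline handoff."""
    path = Path(path)
    matrix.to_frame(template).to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class SectionSummary:
    """Per-section aggregates used by the attribute (Poisson) model."""

    section_id: str
    mean_location: float
    mean_sensitivity: float
    question_count: int
    quit_count: int
    missing_count: int


SECTION_COLUMNS = [
    "section_id",
    "mean_location",
    "mean_sensitivity",
    "question_count",
    "quit_count",
    "missing_count",
]


def summarize_sections(
    template: SurveyTemplate,
    matrix: MissingFlagMatrix,
    classifications: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate missingness and quit locations into section-level rows.

    ``classifications`` is the per-respondent table produced by
    :func:`breakoff.detect.classify_cohort` (needs ``quit_index`` and
    ``is_noncompleter`` columns computed on the same matrix).  Returns one row
    per section with mean item location, mean sensitivity, question count,
    quit count (non-completers whose quit index falls in the section), and
    missing count (total flags over the section's columns).
    """
    if matrix.n_items != template.n_items:
        raise ValueError(
            f"matrix has {matrix.n_items} items but template has {template.n_items}"
        )
    quit_idx = classifications.loc[
        classifications["is_noncompleter"].astype(bool), "quit_index"
    ].to_numpy()
    sens = template.sensitivities
    rows = []
    for sec, sl in template.section_slices.items():
        idx = np.arange(sl.start, sl.stop)
        rows.append(
            {
                "section_id": sec,
                "mean_location": float(idx.mean()),
                "mean_sensitivity": float(sens[sl].mean()),
                "question_count": int(sl.stop - sl.start),
                "quit_count": int(((quit_idx >= sl.start) & (quit_idx < sl.stop)).sum()),
                "missing_count": int(matrix.flags[:, sl].sum()),
            }
        )
    return pd.DataFrame(rows, columns=SECTION_COLUMNS)
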