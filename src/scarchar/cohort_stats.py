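"""Group-comparison statistics for the primary- vs secondary-prevention cohort.

Continuous metrics are compared by Student's t test (classical equal-variance
form; Welch behind a flag) or the Mann-Whitney U test; categorical 2x2 tables
by chi-square (no Yates correction by default) or the Fisher exact test.  All
p-values are two-sided.  ``method='auto'`` encodes a documented selection
rule, since published clinical tables rarely state one:

* continuous — Shapiro-Wilk on both groups at alpha 0.05 (needs n >= 3);
  both normal -> t test, otherwise Mann-Whitney;
* categorical — Fisher exact whenever any expected cell count is < 5,
  chi-square otherwise.

The two-sided Fisher p is the sum of probabilities of all tables (fixed
margins) no more probable than the observed one — the convention scipy
implements; stated here because two-sided Fisher definitions differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, DomainError
from .io_formats import PatientRecord, cohort_frame

__all__ = [
    "GroupComparison",
    "EventTable2x2",
    "compare_continuous",
    "compare_categorical",
    "summarize_cohort",
    "STRATIFIERS",
]


@dataclass
class GroupComparison:
    """One table row: a variable, its per-group summaries, and the test."""

    variable: str
    n_a: int
    n_b: int
    summary_a: str
    summary_b: str
    test: str                 # t | welch_t | mann_whitney | chi_square | fisher
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise DomainError("p-value outside [0, 1]")


@dataclass(frozen=True)
class EventTable2x2:
    """Event/no-event by group: rows = groups, columns = (event, no event).

    For the study's follow-up comparison: 3 of 66 primary-prevention
    patients vs 9 of 29 secondary-prevention patients with appropriate ICD
    therapy gives ``EventTable2x2(3, 63, 9, 20)``.
    """

    a: int  # group A, event
    b: int  # group A, no event
    c: int  # group B, event
    d: int  # group B, no event

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(v < 0 or v != int(v) for v in cells):
            raise DomainError("2x2 cells must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def check_margins(self) -> None:
        t = self.as_array()
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            raise DomainError("2x2 table has a zero margin; test undefined")


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
    return f"{np.median(x):.2f} ({x.min():.2f}–{x.max():.2f})"


def compare_continuous(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "auto",
    variable: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Two-sample comparison of a continuous metric; two-sided p.

    ``method``: ``'t'``, ``'mann_whitney'``, or ``'auto'`` (Shapiro-based
    rule above).  The t test uses the classical equal-variance form unless
    ``welch=True``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if method not in ("auto", "t", "mann_whitney"):
        raise DomainError(f"unknown method {method!r}")
    normal = _is_normal(a) and _is_normal(b)
    if method == "auto":
        method = "t" if normal else "mann_whitney"
    if method == "t":
        if a.size < 2 or b.size < 2:
            raise DomainError("t test needs >= 2 observations per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            raise DegenerateVarianceError(
                "both samples constant and identical; t statistic undefined"
            )
        res = stats.ttest_ind(a, b, equal_var=not welch)
        test = "welch_t" if welch else "t"
    else:
        if a.size < 1 or b.size < 1:
            raise DomainError("Mann-Whitney needs >= 1 observation per group")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        test = "mann_whitney"
    return GroupComparison(
        variable=variable,
        n_a=a.size,
        n_b=b.size,
        summary_a=_summary(a, normal),
        summary_b=_summary(b, normal),
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def compare_categorical(
    table: EventTable2x2,
    method: str = "auto",
    variable: str = "",
    yates: bool = False,
) -> GroupComparison:
    """2x2 comparison by chi-square or Fisher exact; two-sided p.

    ``method='auto'`` picks Fisher whenever any expected cell count is < 5.
    """
    table.check_margins()
    arr = table.as_array()
    if method not in ("auto", "chi_square", "fisher"):
        raise DomainError(f"unknown method {method!r}")
    if method == "auto":
        n = arr.sum()
        expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
        method = "fisher" if (expected < 5).any() else "chi_square"
    if method == "fisher":
        res = stats.fisher_exact(arr, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        chi2 = stats.chi2_contingency(arr, correction=yates)
        statistic, p = float(chi2.statistic), float(chi2.pvalue)
    na, nb = int(arr[0].sum()), int(arr[1].sum())
    return GroupComparison(
        variable=variable,
        n_a=na,
        n_b=nb,
        summary_a=f"{table.a}/{na} ({100.0 * table.a / na:.0f}%)",
        summary_b=f"{table.c}/{nb} ({100.0 * table.c / nb:.0f}%)",
        test=method,
        statistic=statistic,
        p_value=p,
    )


# named subgroup filters used in the study's sub-analyses
STRATIFIERS: dict[str, Callable[[pd.DataFrame], pd.DataFrame]] = {
    "lvef_le_35": lambda df: df[df["lvef_pct"] <= 35.0],
    "anterior": lambda df: df[df["localization"] == "anterior"],
    "nonanterior": lambda df: df[df["localization"] == "nonanterior"],
}


def summarize_cohort(
    records: Iterable[PatientRecord] | pd.DataFrame,
    variables: Sequence[str] | None = None,
    categorical: Sequence[str] = ("appropriate_therapy", "death", "mace"),
    stratifier: str | Callable[[pd.DataFrame], pd.DataFrame] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-metric group comparisons in the style of a clinical baseline table.

    One row per variable with group summaries (mean ± SD when both groups
    pass normality, otherwise median and range), the auto-selected test, and
    its two-sided p.  ``stratifier`` restricts to a named subgroup
    (``'lvef_le_35'``, ``'anterior'``, ``'nonanterior'``) or any callable on
    the flattened DataFrame.  An empty stratum yields a flagged row with no
    test (NaN p) rather than an exception.
    """
    df = records if isinstance(records, pd.DataFrame) else cohort_frame(records)
    if stratifier is not None:
        fn = STRATIFIERS[stratifier] if isinstance(stratifier, str) else stratifier
        df = fn(df)
    groups = sorted(df[group_col].unique()) if len(df) else []
    rows: list[dict] = []
    if len(groups) != 2:
        return pd.DataFrame(
            [{"variable": "(stratum)", "note": "needs exactly two groups; stratum empty or one-sided"}]
        )
    ga = df[df[group_col] == groups[0]]
    gb = df[df[group_col] == groups[1]]
    if variables is None:
        skip = {group_col, "id", "localization", *categorical}
        variables = [
            c for c in df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(df[c])
        ]
    for var in variables:
        a = ga[var].dropna().to_numpy(dtype=float)
        b = gb[var].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            rows.append({"variable": var, "note": "insufficient observations",
                         "p_value": np.nan})
            continue
        cmp = compare_continuous(a, b, method="auto", variable=var)
        rows.append(_row(cmp, groups))
    for var in categorical:
        if var not in df.columns:
            continue
        tbl = EventTable2x2(
            int(ga[var].sum()), int((~ga[var].astype(bool)).sum()),
            int(gb[var].sum()), int((~gb[var].astype(bool)).sum()),
        )
        try:
            cmp = compare_categorical(tbl, method="auto", variable=var)
        except DomainError:
            rows.append({"variable": var, "note": "zero margin", "p_value": np.nan})
            continue
        rows.append(_row(cmp, groups))
    return pd.DataFrame(rows)


def _row(cmp: GroupComparison, groups: Sequence[str]) -> dict:
    return {
        "variable": cmp.variable,
        f"{groups[0]} (n={cmp.n_a})": cmp.summary_a,
        f"{groups[1]} (n={cmp.n_b})": cmp.summary_b,
        "test": cmp.test,
        "statistic": cmp.statistic,
        "p_value": cmp.p_value,
    }
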