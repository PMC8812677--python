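"""Inferential contrasts: pandemic vs pre-pandemic follow-up behaviour.

Two families of tests, both at the index-visit level:

* **Regression-based unpaired t-tests with robust standard errors.**  The
  number of follow-up contacts per index visit (total or of one modality)
  is regressed on a pandemic-period indicator; the coefficient is
  numerically the difference in group means, and its standard error is
  heteroskedasticity-consistent (HC1 by default — count outcomes are
  nothing like homoskedastic).
* **Pearson χ² tests of follow-up composition.**  The 2 × 3 contingency
  table of follow-up *contacts* (period group × follow-up modality) tests
  whether the modality mix of follow-ups changed; df = (2−1)(3−1) = 2.

The pandemic group is episodes indexed March–June 2020; the comparison
group pools March–June of 2018 and 2019.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .episodes import TYPOLOGIES

__all__ = [
    "PANDEMIC_WINDOW",
    "COMPARISON_WINDOWS",
    "OUTCOME_COLUMNS",
    "DiffTestResult",
    "ChiSquareResult",
    "DegenerateMarginError",
    "index_level_records",
    "robust_diff_test",
    "composition_chisq",
    "table5_contrasts",
]

PANDEMIC_WINDOW = (dt.date(2020, 3, 1), dt.date(2020, 6, 30))
COMPARISON_WINDOWS = (
    (dt.date(2018, 3, 1), dt.date(2018, 6, 30)),
    (dt.date(2019, 3, 1), dt.date(2019, 6, 30)),
)

#: Outcomes testable per index visit: total follow-ups and one column per
#: follow-up modality.
OUTCOME_COLUMNS = ("fu_total", *[f"fu_{t}" for t in TYPOLOGIES])


class DegenerateMarginError(ValueError):
    """A contingency-table margin is zero; the χ² test is undefined."""


@dataclass(frozen=True)
class DiffTestResult:
    """Difference in mean follow-ups per index (pandemic − comparison)."""

    outcome: str
    estimate: float
    se: float
    p_value: float
    n_pandemic: int
    n_comparison: int
    cov_type: str = "HC1"
    degenerate: bool = False


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame


def index_level_records(
    episodes: pd.DataFrame,
    pandemic_window: tuple[dt.date, dt.date] = PANDEMIC_WINDOW,
    comparison_windows: Sequence[tuple[dt.date, dt.date]] = COMPARISON_WINDOWS,
) -> pd.DataFrame:
    """Episodes restricted to the contrast windows, with a group indicator.

    Returns one row per index visit with ``group`` = 1 (pandemic window) or
    0 (pooled comparison windows); episodes outside every window are
    dropped.
    """
    dates = pd.to_datetime(episodes["index_date"]).dt.date
    group = np.full(len(episodes), -1)
    lo, hi = pandemic_window
    group[(dates >= lo) & (dates <= hi)] = 1
    for lo, hi in comparison_windows:
        group[(dates >= lo) & (dates <= hi)] = 0
    out = episodes.loc[group >= 0, ["episode_id", "index_type", *OUTCOME_COLUMNS]].copy()
    out["group"] = group[group >= 0]
    return out


def robust_diff_test(
    records: pd.DataFrame,
    outcome: str = "fu_total",
    cov_type: str = "HC1",
) -> DiffTestResult:
    """OLS of the count on the group indicator with sandwich (HC) errors.

    The coefficient equals the raw difference in group means; the p-value
    is two-sided from the t reference with n − 2 residual df.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome {outcome!r}")
    groups = records["group"].unique()
    if len(groups) < 2:
        raise ValueError("both period groups are required for a contrast")
    y = records[outcome].to_numpy(dtype=float)
    g = records["group"].to_numpy(dtype=float)
    n1 = int((g == 1).sum())
    n0 = int((g == 0).sum())
    if np.ptp(y) == 0:
        # zero-variance outcome: the difference is exactly 0 (or the group
        # means are equal constants); no sampling distribution to speak of
        est = float(y[g == 1].mean() - y[g == 0].mean())
        return DiffTestResult(outcome, est, 0.0, float("nan"), n1, n0,
                              cov_type, degenerate=True)
    model = sm.OLS(y, sm.add_constant(g))
    fit = model.fit(cov_type=cov_type, use_t=True)
    return DiffTestResult(
        outcome=outcome,
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n_pandemic=n1,
        n_comparison=n0,
        cov_type=cov_type,
    )


def composition_chisq(records: pd.DataFrame) -> ChiSquareResult:
    """Pearson χ² on the 2 × 3 table of follow-up contacts by modality.

    Units are follow-up *contacts* (each index visit contributes its
    counts), matching the contact-level framing of the composition
    question.  Raises :class:`DegenerateMarginError` if any row or column
    margin is zero.
    """
    table = pd.DataFrame(
        {
            t: [
                int(records.loc[records["group"] == 0, f"fu_{t}"].sum()),
                int(records.loc[records["group"] == 1, f"fu_{t}"].sum()),
            ]
            for t in TYPOLOGIES
        },
        index=pd.Index([0, 1], name="group"),
    )
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    for label, margin in (("row", row_sums), ("column", col_sums)):
        zero = margin[margin == 0]
        if len(zero):
            raise DegenerateMarginError(
                f"zero {label} margin for {list(zero.index)}: χ² undefined"
            )
    stat, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return ChiSquareResult(float(stat), int(df), float(p), table)


def table5_contrasts(
    records: pd.DataFrame, cov_type: str = "HC1"
) -> pd.DataFrame:
    """Full contrast table: one row per index-typology stratum plus 'all'.

    Each row carries the robust difference test for all four follow-up
    outcomes and the composition χ².  Strata that cannot be tested (empty,
    single-group, or degenerate margins) are emitted flagged rather than
    dropped.
    """
    rows = []
    strata = {"all": records}
    for typ in TYPOLOGIES:
        strata[typ] = records[records["index_type"] == typ]
    for name, sub in strata.items():
        row: dict = {"index_type": name}
        flags: list[str] = []
        n1 = int((sub["group"] == 1).sum()) if len(sub) else 0
        n0 = int((sub["group"] == 0).sum()) if len(sub) else 0
        row["n_pandemic"], row["n_comparison"] = n1, n0
        for outcome in OUTCOME_COLUMNS:
            key = outcome.removeprefix("fu_")
            if n1 == 0 or n0 == 0:
                row[f"diff_{key}"] = np.nan
                row[f"se_{key}"] = np.nan
                row[f"p_{key}"] = np.nan
                continue
            res = robust_diff_test(sub, outcome, cov_type=cov_type)
            row[f"diff_{key}"] = res.estimate
            row[f"se_{key}"] = res.se
            row[f"p_{key}"] = res.p_value
            if res.degenerate:
                flags.append(f"degenerate:{outcome}")
        if n1 == 0 or n0 == 0:
            flags.append("empty_group")
            row["chi2"] = np.nan
            row["chi2_df"] = np.nan
            row["chi2_p"] = np.nan
        else:
            try:
                chi = composition_chisq(sub)
                row["chi2"] = chi.statistic
                row["chi2_df"] = chi.df
                row["chi2_p"] = chi.p_value
            except DegenerateMarginError as exc:
                flags.append(str(exc))
                row["chi2"] = np.nan
                row["chi2_df"] = np.nan
                row["chi2_p"] = np.nan
        row["flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)
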