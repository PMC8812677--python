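"""Aggregation of episodes into period summaries, follow-up matrices and
monthly trend series.

All published-style numbers are per-1000-inhabitant rates (denominator: the
registered population on December 31 of the preceding year) or per-index
ratios, displayed with half-up rounding to two decimals.  Every function can
also return unrounded values (``ndigits=None``) so tests can separate
arithmetic from display precision.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal, localcontext
from typing import Mapping

import numpy as np
import pandas as pd

from .episodes import TYPOLOGIES, StudyConfig, count_hospitalized_patients

__all__ = [
    "round_half_up",
    "per_1000",
    "followups_per_index",
    "PeriodSummary",
    "summarize_period",
    "period_summary_table",
    "followup_matrix",
    "monthly_series",
    "UndefinedRateError",
]


class UndefinedRateError(ZeroDivisionError):
    """A ratio was requested with a zero denominator."""


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _dec(x) -> Decimal:
    if isinstance(x, (int, np.integer)):
        return Decimal(int(x))
    return Decimal(repr(float(x)))


def _ratio(numer: int | float, denom: int | float, scale: int, ndigits: int | None):
    with localcontext() as ctx:
        ctx.prec = 40
        exact = _dec(numer) * scale / _dec(denom)
    if ndigits is None:
        return float(exact)
    q = Decimal(1).scaleb(-ndigits)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP))


def per_1000(count: int, population: int, ndigits: int | None = 2) -> float:
    """Events per 1000 inhabitants: ``1000 * count / population``.

    Exact decimal arithmetic with half-up rounding, so printed-precision
    reproduction does not depend on binary float artefacts.
    """
    if population <= 0:
        raise UndefinedRateError("population must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return _ratio(count, population, 1000, ndigits)


def followups_per_index(
    followup_total: int, index_total: int, ndigits: int | None = 2
) -> float:
    """Follow-up contacts per index contact.

    Raises :class:`UndefinedRateError` for zero indexes rather than
    returning a silent 0.
    """
    if index_total <= 0:
        raise UndefinedRateError("follow-ups per index undefined with zero indexes")
    if followup_total < 0:
        raise ValueError("followup_total must be non-negative")
    return _ratio(followup_total, index_total, 1, ndigits)


@dataclass(frozen=True)
class PeriodSummary:
    """One study period's aggregate: the published yearly-comparison shape."""

    period: str
    population: int
    index_total: int
    index_per_1000: float
    index_shares: dict[str, float | None]
    followup_total: int
    followup_per_1000: float
    followup_shares: dict[str, float | None]
    followups_per_index: float | None
    hospitalized_patients: int
    hospitalized_per_1000: float
    degenerate: bool = False  # zero episodes: shares/ratios undefined

    def to_row(self) -> dict:
        row: dict = {
            "period": self.period,
            "population": self.population,
            "index_total": self.index_total,
            "index_per_1000": self.index_per_1000,
        }
        for typ in TYPOLOGIES:
            row[f"index_share_{typ}"] = self.index_shares[typ]
        row["followup_total"] = self.followup_total
        row["followup_per_1000"] = self.followup_per_1000
        for typ in TYPOLOGIES:
            row[f"followup_share_{typ}"] = self.followup_shares[typ]
        row["followups_per_index"] = self.followups_per_index
        row["hospitalized_patients"] = self.hospitalized_patients
        row["hospitalized_per_1000"] = self.hospitalized_per_1000
        row["degenerate"] = self.degenerate
        return row


def _shares(counts: Mapping[str, int], total: int, ndigits: int | None):
    if total <= 0:
        return {t: None for t in TYPOLOGIES}
    return {t: _ratio(counts.get(t, 0), total, 1, ndigits) for t in TYPOLOGIES}


def summarize_period(
    episodes: pd.DataFrame,
    hospitalized_patients: int,
    population: int,
    period: str | None = None,
    ndigits: int | None = 2,
) -> PeriodSummary:
    """Reduce one period's episodes to totals, per-1000 rates and shares.

    ``episodes`` must all belong to one period (the builder's ``period``
    column is checked when present).  An empty episode set yields a zero
    summary flagged ``degenerate`` with undefined shares.
    """
    if "period" in episodes.columns and len(episodes):
        labels = episodes["period"].unique()
        if len(labels) > 1:
            raise ValueError(f"episodes span several periods: {sorted(labels)}")
        period = period or labels[0]

    index_total = int(len(episodes))
    idx_counts = (
        episodes["index_type"].value_counts().to_dict() if index_total else {}
    )
    followup_total = int(episodes["fu_total"].sum()) if index_total else 0
    fu_counts = {
        t: int(episodes[f"fu_{t}"].sum()) if index_total else 0 for t in TYPOLOGIES
    }
    return PeriodSummary(
        period=period or "",
        population=population,
        index_total=index_total,
        index_per_1000=per_1000(index_total, population, ndigits),
        index_shares=_shares(idx_counts, index_total, ndigits),
        followup_total=followup_total,
        followup_per_1000=per_1000(followup_total, population, ndigits),
        followup_shares=_shares(fu_counts, followup_total, ndigits),
        followups_per_index=(
            followups_per_index(followup_total, index_total, ndigits)
            if index_total
            else None
        ),
        hospitalized_patients=hospitalized_patients,
        hospitalized_per_1000=per_1000(hospitalized_patients, population, ndigits),
        degenerate=index_total == 0,
    )


def period_summary_table(
    episodes: pd.DataFrame,
    contacts: pd.DataFrame,
    populations: Mapping[int, int] | pd.DataFrame,
    config: StudyConfig | None = None,
    ndigits: int | None = 2,
) -> pd.DataFrame:
    """One summary row per configured study period (Table-3 shape)."""
    if config is None:
        config = StudyConfig()
    pops = _population_map(populations)
    codeset = config.compiled_code_set()
    rows = []
    for start, end in config.index_periods:
        label = config.period_label(start)
        sub = episodes[episodes["period"] == label] if len(episodes) else episodes
        hosp = count_hospitalized_patients(contacts, codeset, (start, end))
        rows.append(
            summarize_period(sub, hosp, pops[start.year], label, ndigits).to_row()
        )
    return pd.DataFrame(rows)


def followup_matrix(
    episodes: pd.DataFrame, ndigits: int | None = 2
) -> pd.DataFrame:
    """Follow-ups per index by index type × follow-up type (Table-4 shape).

    Rows: each index typology plus a pooled ``all`` row; columns: each
    follow-up typology plus their ``all`` sum.  Cell (i, j) is the number of
    type-j follow-up contacts attached to type-i indexes divided by the
    number of type-i indexes; a typology with zero indexes yields NaN cells.
    """
    rows = {}
    groups = {"all": episodes}
    for typ in TYPOLOGIES:
        groups[typ] = episodes[episodes["index_type"] == typ] if len(episodes) else episodes
    for name, sub in groups.items():
        n = len(sub)
        if n == 0:
            rows[name] = {"all": np.nan, **{t: np.nan for t in TYPOLOGIES}}
            continue
        cells = {
            t: followups_per_index(int(sub[f"fu_{t}"].sum()), n, ndigits)
            for t in TYPOLOGIES
        }
        cells["all"] = followups_per_index(int(sub["fu_total"].sum()), n, ndigits)
        rows[name] = cells
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "index_type"
    return out[["all", *TYPOLOGIES]].loc[["all", *TYPOLOGIES]]


def _population_map(populations) -> dict[int, int]:
    if isinstance(populations, pd.DataFrame):
        return dict(
            zip(populations["year"].astype(int), populations["population"].astype(int))
        )
    return {int(k): int(v) for k, v in populations.items()}


def monthly_series(
    episodes: pd.DataFrame,
    populations: Mapping[int, int] | pd.DataFrame,
    ndigits: int | None = None,
) -> pd.DataFrame:
    """Per-(year, month) trend series behind the monthly figures.

    Follow-up contacts are attributed to their index's month, which keeps
    the per-index ratio coherent within each month.  Only months containing
    episodes appear (with the default periods: January–June).
    """
    pops = _population_map(populations)
    if not len(episodes):
        return pd.DataFrame(
            columns=[
                "year", "month", "index_total", "index_per_1000",
                "share_remote",
                *[f"index_per_1000_{t}" for t in TYPOLOGIES],
                "followup_total", "followup_per_1000", "followups_per_index",
                *[f"followup_share_{t}" for t in TYPOLOGIES],
            ]
        )
    ep = episodes.copy()
    dates = pd.to_datetime(ep["index_date"])
    ep["year"] = dates.dt.year
    ep["month"] = dates.dt.month
    rows = []
    for (year, month), sub in ep.groupby(["year", "month"], sort=True):
        pop = pops[int(year)]
        n = len(sub)
        type_counts = sub["index_type"].value_counts().to_dict()
        fu_total = int(sub["fu_total"].sum())
        remote = type_counts.get("remote_traditional", 0) + type_counts.get(
            "telemedicine", 0
        )
        row = {
            "year": int(year),
            "month": int(month),
            "index_total": n,
            "index_per_1000": per_1000(n, pop, ndigits),
            "share_remote": _ratio(remote, n, 1, ndigits),
        }
        for typ in TYPOLOGIES:
            row[f"index_per_1000_{typ}"] = per_1000(
                type_counts.get(typ, 0), pop, ndigits
            )
        row["followup_total"] = fu_total
        row["followup_per_1000"] = per_1000(fu_total, pop, ndigits)
        row["followups_per_index"] = followups_per_index(fu_total, n, ndigits)
        for typ in TYPOLOGIES:
            row[f"followup_share_{typ}"] = (
                _ratio(int(sub[f"fu_{typ}"].sum()), fu_total, 1, ndigits)
                if fu_total
                else None
            )
        rows.append(row)
    return pd.DataFrame(rows)
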