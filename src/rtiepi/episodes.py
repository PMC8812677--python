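"""Index / follow-up / limbo classification and episode assembly.

A person's physician contacts are scanned chronologically and every contact
receives exactly one label:

``index``
    An outpatient (primary-care or emergency-room, including telemedicine
    providers) physician contact carrying an RTI-relevant diagnosis, with no
    RTI-relevant physician contact of the same person in the preceding 181
    days (the washout, or "clean", period).
``follow_up``
    Any outpatient physician contact — regardless of diagnosis — dated 1–30
    days after an index contact of the same person.
``limbo``
    An RTI-relevant outpatient physician contact that is neither: it falls
    31–181 days after the person's most recent RTI-relevant contact.  Limbo
    contacts appear in no tally but still reset the washout clock.
``other``
    Everything else: non-physician contacts, inpatient stays, and outpatient
    physician contacts with no qualifying diagnosis outside any follow-up
    window.

Every RTI-relevant physician contact (index, follow-up, limbo, or an
inpatient stay) resets the washout clock, so a fresh index requires 181
diagnosis-free days counted from the person's last RTI-relevant contact, not
from the last index.  Two same-day RTI contacts cannot both be indexes: the
one sorting earlier blocks the later one (the washout gap of zero days is
not "more than 181").

Episodes are then assembled from indexes falling inside the configured
half-year study periods, each carrying its attributed follow-up contacts by
modality type.  Follow-ups occurring after a period's end are retained: the
attribution window belongs to the index date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .icd import DEFAULT_RTI_CODES, CompiledCodeSet, compile_code_set

__all__ = [
    "INDEX",
    "FOLLOW_UP",
    "LIMBO",
    "OTHER",
    "TYPOLOGIES",
    "OUTPATIENT_SETTINGS",
    "StudyConfig",
    "contact_typology",
    "rti_flags",
    "classify_contacts",
    "label_contacts",
    "build_episodes",
    "count_hospitalized_patients",
]

INDEX = "index"
FOLLOW_UP = "follow_up"
LIMBO = "limbo"
OTHER = "other"

#: Contact modality typology used throughout the analysis: in-person visits,
#: remote contacts with a traditional provider (primary-care centre or
#: emergency room, typically phone/chat), and contacts with on-demand
#: telemedicine providers (remote by definition).
TYPOLOGIES = ("in_person", "remote_traditional", "telemedicine")

OUTPATIENT_SETTINGS = frozenset({"primary_care", "emergency_room"})

DIAG_COLUMNS = tuple(f"diag{i}" for i in range(1, 9))


class ContractViolation(ValueError):
    """Input violated a documented precondition (e.g. unsorted contacts)."""


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class StudyConfig:
    """Windows, study periods and code set defining the episode rules.

    Parameters
    ----------
    washout_days:
        Length of the diagnosis-free lookback required for index status.
        A prior RTI contact exactly ``washout_days`` days earlier still
        blocks index status (the window is ``[date-181, date-1]``).
    followup_days:
        Attribution window after an index; contacts on days 1..30 count.
    index_periods:
        Inclusive (start, end) date intervals; one episode stream per
        period.  Defaults to January–June of 2018, 2019 and 2020.
    code_set:
        Code-or-range strings defining RTI relevance.
    """

    washout_days: int = 181
    followup_days: int = 30
    index_periods: tuple[tuple[dt.date, dt.date], ...] = (
        (dt.date(2018, 1, 1), dt.date(2018, 6, 30)),
        (dt.date(2019, 1, 1), dt.date(2019, 6, 30)),
        (dt.date(2020, 1, 1), dt.date(2020, 6, 30)),
    )
    code_set: tuple[str, ...] = DEFAULT_RTI_CODES

    def __post_init__(self) -> None:
        if self.washout_days <= self.followup_days:
            raise ValueError("washout_days must exceed followup_days")
        periods = tuple(
            (_parse_date(a), _parse_date(b)) for a, b in self.index_periods
        )
        for start, end in periods:
            if start > end:
                raise ValueError(f"period {start}..{end} has start > end")
        for (a0, a1), (b0, b1) in zip(periods, periods[1:]):
            if b0 <= a1:
                raise ValueError("index periods must be sorted and non-overlapping")
        object.__setattr__(self, "index_periods", periods)

    def compiled_code_set(self) -> CompiledCodeSet:
        return compile_code_set(self.code_set)

    def period_label(self, day: dt.date) -> str | None:
        """Name of the study period containing ``day``, or None."""
        for start, end in self.index_periods:
            if start <= day <= end:
                if (start.month, start.day, end.month, end.day) == (1, 1, 6, 30):
                    return f"{start.year}H1"
                return f"{start.isoformat()}..{end.isoformat()}"
        return None


def contact_typology(mode: pd.Series, provider_class: pd.Series) -> pd.Series:
    """Modality typology of each contact (see :data:`TYPOLOGIES`)."""
    out = np.where(
        provider_class.to_numpy() == "telemedicine",
        "telemedicine",
        np.where(mode.to_numpy() == "remote", "remote_traditional", "in_person"),
    )
    return pd.Series(out, index=mode.index)


def rti_flags(contacts: pd.DataFrame, codeset: CompiledCodeSet) -> pd.Series:
    """Boolean per row: does any registered diagnosis match the code set?

    Vectorised over the up-to-eight diagnosis columns by memoising the
    verdict per distinct code string.
    """
    flags = np.zeros(len(contacts), dtype=bool)
    cache: dict[str, bool] = {"": False}
    for col in DIAG_COLUMNS:
        if col not in contacts.columns:
            continue
        codes = contacts[col].fillna("").astype(str)
        for code in codes.unique():
            if code not in cache:
                cache[code] = codeset.matches(code)
        flags |= codes.map(cache).to_numpy(dtype=bool)
    return pd.Series(flags, index=contacts.index)


def _scan_person(
    days: Sequence[int],
    ids: Sequence,
    physician: Sequence[bool],
    outpatient: Sequence[bool],
    rti: Sequence[bool],
    washout_days: int,
    followup_days: int,
) -> tuple[list[str], list]:
    """Single chronological pass over one person's contacts."""
    labels: list[str] = []
    parents: list = []
    last_rti = None
    active_day = None
    active_id = None
    for day, cid, phys, outp, is_rti in zip(days, ids, physician, outpatient, rti):
        label = OTHER
        parent = None
        if phys:
            in_window = (
                active_day is not None and 1 <= day - active_day <= followup_days
            )
            if outp and in_window:
                label = FOLLOW_UP
                parent = active_id
            elif outp and is_rti:
                if last_rti is None or day - last_rti > washout_days:
                    label = INDEX
                    active_day, active_id = day, cid
                else:
                    label = LIMBO
            if is_rti:
                last_rti = day
        labels.append(label)
        parents.append(parent)
    return labels, parents


def classify_contacts(
    contacts: pd.DataFrame,
    config: StudyConfig,
    codeset: CompiledCodeSet | None = None,
) -> pd.DataFrame:
    """Label one person's date-sorted contacts (single-pass scan).

    Input must contain one person's contacts sorted ascending by date
    (ties already broken); raises :class:`ContractViolation` otherwise.
    Returns the input with ``label``, ``parent_index_id``, ``typology`` and
    ``rti`` columns appended.
    """
    if contacts["person_id"].nunique() > 1:
        raise ContractViolation("classify_contacts expects a single person")
    dates = pd.to_datetime(contacts["date"])
    if not dates.is_monotonic_increasing:
        raise ContractViolation("contacts must be sorted ascending by date")
    if codeset is None:
        codeset = config.compiled_code_set()
    return _label_sorted(contacts, dates, config, codeset)


def _label_sorted(
    contacts: pd.DataFrame,
    dates: pd.Series,
    config: StudyConfig,
    codeset: CompiledCodeSet,
) -> pd.DataFrame:
    days = (dates.to_numpy().astype("datetime64[D]")).astype(np.int64)
    physician = (contacts["profession"].to_numpy() == "physician")
    outpatient = np.isin(contacts["setting"].to_numpy(), list(OUTPATIENT_SETTINGS))
    rti = rti_flags(contacts, codeset).to_numpy()
    ids = contacts["contact_id"].to_numpy()
    persons = contacts["person_id"].to_numpy()

    labels = np.empty(len(contacts), dtype=object)
    parents = np.empty(len(contacts), dtype=object)
    # person boundaries in the (person-sorted) table
    if len(contacts):
        boundaries = np.flatnonzero(np.r_[True, persons[1:] != persons[:-1]])
        boundaries = np.r_[boundaries, len(persons)]
        for lo, hi in zip(boundaries[:-1], boundaries[1:]):
            lab, par = _scan_person(
                days[lo:hi],
                ids[lo:hi],
                physician[lo:hi],
                outpatient[lo:hi],
                rti[lo:hi],
                config.washout_days,
                config.followup_days,
            )
            labels[lo:hi] = lab
            parents[lo:hi] = par

    out = contacts.copy()
    out["date"] = dates
    out["label"] = labels
    out["parent_index_id"] = parents
    out["typology"] = contact_typology(out["mode"], out["provider_class"])
    out["rti"] = rti
    return out


def label_contacts(
    contacts: pd.DataFrame,
    config: StudyConfig | None = None,
    codeset: CompiledCodeSet | None = None,
) -> pd.DataFrame:
    """Label a full multi-person contact table.

    Rows are sorted by person and date with same-day ties broken
    deterministically by (setting, provider_class, source, input order); the
    returned frame is in that scan order.
    """
    if config is None:
        config = StudyConfig()
    if codeset is None:
        codeset = config.compiled_code_set()
    work = contacts.copy()
    work["date"] = pd.to_datetime(work["date"])
    work = work.sort_values(
        ["person_id", "date", "setting", "provider_class", "source"],
        kind="stable",
    )
    return _label_sorted(work, work["date"], config, codeset)


def build_episodes(labeled: pd.DataFrame, config: StudyConfig | None = None) -> pd.DataFrame:
    """Assemble episodes: one row per index contact inside a study period.

    Returns columns: ``episode_id`` (the index contact id), ``person_id``,
    ``index_date``, ``index_type``, ``period``, per-typology follow-up
    counts ``fu_in_person`` / ``fu_remote_traditional`` / ``fu_telemedicine``
    and ``fu_total``.  Indexes outside every period produce no episode (they
    still shaped the washout during labelling); follow-ups dated after the
    period end remain attached to their index.
    """
    if config is None:
        config = StudyConfig()
    idx = labeled[labeled["label"] == INDEX]
    periods = idx["date"].map(lambda d: config.period_label(d.date()))
    idx = idx.assign(period=periods).dropna(subset=["period"])

    episodes = pd.DataFrame(
        {
            "episode_id": idx["contact_id"].to_numpy(),
            "person_id": idx["person_id"].to_numpy(),
            "index_date": idx["date"].to_numpy(),
            "index_type": idx["typology"].to_numpy(),
            "period": idx["period"].to_numpy(),
        }
    )
    for typ in TYPOLOGIES:
        episodes[f"fu_{typ}"] = 0

    fus = labeled[labeled["label"] == FOLLOW_UP]
    if len(fus):
        counts = (
            fus.groupby(["parent_index_id", "typology"], sort=False)
            .size()
            .unstack(fill_value=0)
        )
        aligned = counts.reindex(episodes["episode_id"]).fillna(0)
        for typ in TYPOLOGIES:
            if typ in aligned.columns:
                episodes[f"fu_{typ}"] = aligned[typ].to_numpy(dtype=np.int64)
    episodes["fu_total"] = sum(episodes[f"fu_{t}"] for t in TYPOLOGIES)
    return episodes


def count_hospitalized_patients(
    contacts: pd.DataFrame,
    codeset: CompiledCodeSet,
    period: tuple[dt.date, dt.date],
) -> int:
    """Unique patients with ≥1 RTI-coded inpatient stay dated in ``period``.

    Each patient counts once per period however many stays they have.
    """
    start, end = (_parse_date(period[0]), _parse_date(period[1]))
    dates = pd.to_datetime(contacts["date"]).dt.date
    inpatient = contacts[
        (contacts["setting"] == "inpatient")
        & (dates >= start)
        & (dates <= end)
    ]
    if inpatient.empty:
        return 0
    relevant = rti_flags(inpatient, codeset)
    return int(inpatient.loc[relevant.to_numpy(), "person_id"].nunique())
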