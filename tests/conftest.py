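"""Shared fixtures and independent reference implementations.

The brute-force classifier here is deliberately declarative and O(n²):
every label is derived by scanning a person's whole history, with no
single-pass state.  It serves as the oracle the production classifier is
checked against.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from rtiepi.icd import DEFAULT_RTI_CODES, compile_code_set
from rtiepi.simulate import BACKGROUND_CODES, RTI_SAMPLE_CODES

OUTPATIENT = {"primary_care", "emergency_room"}


@pytest.fixture(scope="session")
def codeset():
    return compile_code_set(DEFAULT_RTI_CODES)


def make_contacts(rows, base_date: dt.date = dt.date(2019, 1, 1)) -> pd.DataFrame:
    """Build a schema-complete contact frame from terse row dicts.

    A ``day`` key is an integer offset from ``base_date``; unspecified
    fields default to an in-person primary-care physician visit.
    """
    defaults = {
        "person_id": "P1",
        "setting": "primary_care",
        "mode": "in_person",
        "provider_class": "traditional",
        "profession": "physician",
        "source": "regional",
    }
    recs = []
    for i, row in enumerate(rows):
        rec = {**defaults, **row}
        if "day" in rec:
            rec["date"] = base_date + dt.timedelta(days=int(rec.pop("day")))
        rec.setdefault("contact_id", f"C{i:08d}")
        for j in range(1, 9):
            rec.setdefault(f"diag{j}", "")
        recs.append(rec)
    df = pd.DataFrame(recs)
    df["date"] = pd.to_datetime(df["date"])
    return df


def random_registry(rng: np.random.Generator, n_persons: int = 6,
                    max_contacts: int = 50) -> pd.DataFrame:
    """Adversarial random registry: dense dates, junk codes, mixed settings."""
    pool = (
        list(RTI_SAMPLE_CODES)
        + list(BACKGROUND_CODES)
        + ["", "", "", "x!", "j06.9"]
    )
    rows = []
    for p in range(n_persons):
        for _ in range(int(rng.integers(1, max_contacts + 1))):
            provider = "telemedicine" if rng.random() < 0.2 else "traditional"
            remote = provider == "telemedicine" or rng.random() < 0.2
            setting = (
                "primary_care"
                if provider == "telemedicine"
                else str(rng.choice(["primary_care", "emergency_room", "inpatient"]))
            )
            rows.append(
                {
                    "person_id": f"P{p}",
                    "day": int(rng.integers(0, 500)),
                    "setting": setting,
                    "mode": "remote" if remote else "in_person",
                    "provider_class": provider,
                    "profession": "physician" if rng.random() < 0.85 else "other",
                    "diag1": str(rng.choice(pool)),
                    "diag2": str(rng.choice(pool)) if rng.random() < 0.3 else "",
                    "source": str(
                        rng.choice(["regional", "extra_regional", "telemedicine_register"])
                    ),
                }
            )
    return make_contacts(rows, base_date=dt.date(2018, 1, 1))


def reference_labels(sorted_contacts: pd.DataFrame, washout: int = 181,
                     followup: int = 30, codeset=None):
    """O(n²) declarative classifier over an already scan-ordered frame.

    A contact is an index iff it is an RTI-relevant outpatient physician
    contact with no RTI-relevant physician contact of the same person
    1..washout days earlier (or earlier in scan order on the same day); a
    follow-up iff it is an outpatient physician contact 1..followup days
    after an index; a limbo iff RTI-relevant outpatient physician and
    neither; other otherwise.
    """
    if codeset is None:
        codeset = compile_code_set(DEFAULT_RTI_CODES)
    df = sorted_contacts
    days = pd.to_datetime(df["date"]).map(lambda d: d.toordinal()).to_numpy()
    person = df["person_id"].to_numpy()
    phys = (df["profession"] == "physician").to_numpy()
    outp = df["setting"].isin(OUTPATIENT).to_numpy()
    diag_cols = [c for c in df.columns if c.startswith("diag")]
    diags = df[diag_cols].fillna("").astype(str).to_numpy()
    rti = np.array([any(v and codeset.matches(v) for v in row) for row in diags])
    ids = df["contact_id"].to_numpy()
    n = len(df)

    is_index = np.zeros(n, bool)
    for i in range(n):
        if not (phys[i] and outp[i] and rti[i]):
            continue
        blocked = False
        for j in range(n):
            if j == i or person[j] != person[i] or not (phys[j] and rti[j]):
                continue
            d = days[i] - days[j]
            if 1 <= d <= washout or (d == 0 and j < i):
                blocked = True
                break
        is_index[i] = not blocked

    labels, parents = [], []
    for i in range(n):
        lab, par = "other", None
        if phys[i] and outp[i]:
            if is_index[i]:
                lab = "index"
            else:
                for j in range(n):
                    if (
                        person[j] == person[i]
                        and is_index[j]
                        and 1 <= days[i] - days[j] <= followup
                    ):
                        lab, par = "follow_up", ids[j]
                        break
                if lab == "other" and rti[i]:
                    lab = "limbo"
        labels.append(lab)
        parents.append(par)
    return labels, parents
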