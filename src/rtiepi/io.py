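"""File formats, schema validation, configuration and the pipeline driver.

The contact table is a UTF-8, comma-delimited CSV with an exact header::

    person_id,date,setting,mode,provider_class,profession,
    diag1,...,diag8,source

Dates are ISO-8601 days; enumerations are validated and rows violating the
schema (bad enum, unparseable date, a telemedicine provider recorded as
in-person) are rejected individually with their row numbers, not silently
dropped.  ``run_pipeline`` wires the stages together: (optional) simulation,
labelling, episode assembly, aggregation and the contrast tests, writing one
tidy CSV per product plus the resolved configuration and a stage log.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aggregate, episodes as ep, inference, simulate
from .icd import DEFAULT_RTI_CODES

__all__ = [
    "CONTACT_COLUMNS",
    "SchemaError",
    "read_contacts",
    "write_contacts",
    "read_population",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("rtiepi")

DIAG_COLUMNS = [f"diag{i}" for i in range(1, 9)]
CONTACT_COLUMNS = [
    "person_id",
    "date",
    "setting",
    "mode",
    "provider_class",
    "profession",
    *DIAG_COLUMNS,
    "source",
]

_ENUMS = {
    "setting": {"primary_care", "emergency_room", "inpatient"},
    "mode": {"in_person", "remote"},
    "provider_class": {"traditional", "telemedicine"},
    "profession": {"physician", "other"},
    "source": {"regional", "extra_regional", "telemedicine_register"},
}


class SchemaError(ValueError):
    """The file cannot be read under the documented schema."""


def read_contacts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a contact CSV.

    Returns ``(contacts, rejected)``: typed accepted rows (with a
    ``contact_id`` assigned from file order) and a rejection report with
    1-based data row numbers and reasons.  Missing or misnamed columns
    raise :class:`SchemaError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != CONTACT_COLUMNS:
        raise SchemaError(
            f"{path}: header mismatch; expected {CONTACT_COLUMNS}, "
            f"got {list(raw.columns)}"
        )
    reasons = pd.Series("", index=raw.index, dtype=object)

    dates = pd.to_datetime(raw["date"], format="%Y-%m-%d", errors="coerce")
    reasons[dates.isna()] += "unparseable date;"
    for col, allowed in _ENUMS.items():
        bad = ~raw[col].isin(allowed)
        reasons[bad] += f"invalid {col};"
    tele_in_person = (raw["provider_class"] == "telemedicine") & (
        raw["mode"] != "remote"
    )
    reasons[tele_in_person] += "telemedicine provider must be remote;"

    bad_mask = reasons != ""
    rejected = pd.DataFrame(
        {"row": raw.index[bad_mask] + 1, "reason": reasons[bad_mask]}
    ).reset_index(drop=True)
    contacts = raw[~bad_mask].copy()
    contacts.insert(
        0,
        "contact_id",
        [f"C{i:08d}" for i in contacts.index],
    )
    contacts["date"] = dates[~bad_mask]
    contacts = contacts.reset_index(drop=True)
    if len(rejected):
        logger.warning("%s: rejected %d malformed rows", path, len(rejected))
    return contacts, rejected


def write_contacts(contacts: pd.DataFrame, path: str | Path) -> None:
    out = contacts[CONTACT_COLUMNS].copy()
    out["date"] = pd.to_datetime(contacts["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_population(path: str | Path) -> pd.DataFrame:
    pop = pd.read_csv(path)
    if not {"year", "population"}.issubset(pop.columns):
        raise SchemaError(f"{path}: expected columns year, population")
    pop = pop[["year", "population"]].astype(int)
    if (pop["population"] <= 0).any():
        raise SchemaError(f"{path}: population must be positive")
    return pop


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run (YAML-serialisable)."""

    washout_days: int = 181
    followup_days: int = 30
    index_periods: list[list[str]] = field(
        default_factory=lambda: [
            ["2018-01-01", "2018-06-30"],
            ["2019-01-01", "2019-06-30"],
            ["2020-01-01", "2020-06-30"],
        ]
    )
    code_set: list[str] = field(default_factory=lambda: list(DEFAULT_RTI_CODES))
    cov_type: str = "HC1"
    # simulation inputs (used when no contact file is given)
    scenario: str | None = None
    population_size: int = 50_000
    seed: int = 0
    # file inputs (used when scenario is None)
    contacts_path: str | None = None
    population_path: str | None = None

    def study_config(self) -> ep.StudyConfig:
        return ep.StudyConfig(
            washout_days=self.washout_days,
            followup_days=self.followup_days,
            index_periods=tuple(
                (dt.date.fromisoformat(a), dt.date.fromisoformat(b))
                for a, b in self.index_periods
            ),
            code_set=tuple(self.code_set),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path
) -> dict[str, pd.DataFrame]:
    """Execute simulate? → label → episodes → summaries → contrasts.

    Writes ``labeled_contacts.csv``, ``episodes.csv``,
    ``period_summary.csv``, ``followup_matrix.csv``, ``monthly_series.csv``,
    ``contrasts.csv`` (plus ``contacts.csv``/``population.csv``/
    ``ground_truth.csv`` when simulating), the resolved config, and a run
    log with per-stage record counts.  Returns the in-memory frames.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = config.study_config()
    log_lines: list[str] = []

    def stage(name: str):
        logger.info("stage: %s", name)
        log_lines.append(f"stage {name}")

    try:
        if config.scenario is not None:
            stage("simulate")
            params = simulate.paper_like_params(
                config.scenario, config.population_size, config.seed
            )
            contacts, population, truth = simulate.simulate_registry(params)
            write_contacts(contacts, outdir / "contacts.csv")
            population.to_csv(outdir / "population.csv", index=False)
            truth.to_csv(outdir / "ground_truth.csv", index=False)
            rejected = pd.DataFrame(columns=["row", "reason"])
        else:
            stage("read")
            if not config.contacts_path or not config.population_path:
                raise SchemaError(
                    "either a scenario or contacts_path+population_path is required"
                )
            contacts, rejected = read_contacts(config.contacts_path)
            population = read_population(config.population_path)
        log_lines.append(
            f"contacts in={len(contacts) + len(rejected)} "
            f"accepted={len(contacts)} rejected={len(rejected)}"
        )

        stage("label")
        codeset = study.compiled_code_set()
        labeled = ep.label_contacts(contacts, study, codeset)
        for label in (ep.INDEX, ep.FOLLOW_UP, ep.LIMBO, ep.OTHER):
            log_lines.append(f"label {label}={int((labeled['label'] == label).sum())}")

        stage("episodes")
        eps = ep.build_episodes(labeled, study)
        log_lines.append(f"episodes={len(eps)}")

        stage("summarize")
        summary = aggregate.period_summary_table(eps, contacts, population, study)
        matrix = aggregate.followup_matrix(eps)
        monthly = aggregate.monthly_series(eps, population, ndigits=2)

        stage("compare")
        records = inference.index_level_records(eps)
        if len(records) and records["group"].nunique() == 2:
            contrasts = inference.table5_contrasts(records, cov_type=config.cov_type)
        else:
            log_lines.append("contrasts skipped: need both period groups")
            contrasts = pd.DataFrame(
                columns=["index_type", "n_pandemic", "n_comparison", "flags"]
            )

        stage("write")
        labeled_out = labeled[
            ["contact_id", "person_id", "date", "label", "parent_index_id", "typology"]
        ].copy()
        labeled_out["date"] = labeled_out["date"].dt.strftime("%Y-%m-%d")
        labeled_out.to_csv(outdir / "labeled_contacts.csv", index=False)
        eps_out = eps.copy()
        if len(eps_out):
            eps_out["index_date"] = pd.to_datetime(eps_out["index_date"]).dt.strftime(
                "%Y-%m-%d"
            )
        eps_out.to_csv(outdir / "episodes.csv", index=False)
        summary.to_csv(outdir / "period_summary.csv", index=False)
        matrix.to_csv(outdir / "followup_matrix.csv")
        monthly.to_csv(outdir / "monthly_series.csv", index=False)
        contrasts.to_csv(outdir / "contrasts.csv", index=False)
        if len(rejected):
            rejected.to_csv(outdir / "rejected_rows.csv", index=False)
        config.to_yaml(outdir / "resolved_config.yaml")
    except Exception as exc:
        log_lines.append(f"FAILED: {type(exc).__name__}: {exc}")
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "contacts": contacts,
        "labeled": labeled,
        "episodes": eps,
        "period_summary": summary,
        "followup_matrix": matrix,
        "monthly_series": monthly,
        "contrasts": contrasts,
        "population": population,
        "rejected": rejected,
    }
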