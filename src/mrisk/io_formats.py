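"""Readers, writers and domain records for the recurrence-risk pipeline.

External representations handled here:

* case listings — one row per registered woman (CSV/TSV with header),
* population rate tables — annual death probabilities by age, sex and
  calendar year, used as the expected-mortality input,
* run configurations (YAML),
* output tables (life tables, fit summaries, risk tables) as CSV.

Dates are held at month resolution throughout: registries supply follow-up
at month precision and survival is measured in completed months, which is
what makes the "zero months of survival" exclusion well defined.  A calendar
month is stored as the pair (year, month 1..12) and manipulated internally
as the month index ``12*year + (month-1)``.

All probabilities are fractions internally; percentages appear only at the
reporting boundary.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mrisk")

STAGES = ("I", "II", "III", "IV", "missing")
PROFILES = ("HR+/HER2-", "HER2+", "TN", "unknown")
VITAL_STATUSES = ("alive", "dead")
BASES = ("clinical/path", "DCO", "autopsy")

CASE_COLUMNS = (
    "id", "sex", "age_dx", "year_dx", "month_dx", "stage", "profile",
    "vital_status", "year_end", "month_end", "basis",
)


def month_index(year: int, month: int) -> int:
    """Serial month number; January of year y is ``12*y``."""
    return 12 * int(year) + int(month) - 1


# ---------------------------------------------------------------------------
# Case records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseRecord:
    """One woman's registration at month resolution.

    ``date_end`` is the month of death (vital_status == "dead") or of the
    last follow-up (alive).  Survival time is completed months between
    diagnosis and end of follow-up.
    """

    id: str
    sex: str
    age_dx: int
    year_dx: int
    month_dx: int
    stage: str
    profile: str
    vital_status: str
    year_end: int
    month_end: int
    basis: str

    @property
    def month_index_dx(self) -> int:
        return month_index(self.year_dx, self.month_dx)

    @property
    def month_index_end(self) -> int:
        return month_index(self.year_end, self.month_end)

    @property
    def survival_months(self) -> int:
        return self.month_index_end - self.month_index_dx

    @property
    def died(self) -> bool:
        return self.vital_status == "dead"

    def validate(self) -> None:
        if self.sex != "female":
            raise ValueError(f"unsupported sex {self.sex!r}")
        if self.age_dx < 0:
            raise ValueError("age_dx must be non-negative")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.vital_status not in VITAL_STATUSES:
            raise ValueError(f"unknown vital_status {self.vital_status!r}")
        if self.basis not in BASES:
            raise ValueError(f"unknown basis {self.basis!r}")
        if not 1 <= self.month_dx <= 12 or not 1 <= self.month_end <= 12:
            raise ValueError("calendar months must be in 1..12")
        if self.survival_months < 0:
            raise ValueError("date_end precedes date_dx")


@dataclass
class ParseResult:
    """Outcome of reading a case listing: parsed records plus row errors."""

    records: list[CaseRecord]
    errors: list[tuple[int, str]]  # (1-based data row number, message)


def read_case_listing(path: str | Path, dialect: str | None = None) -> ParseResult:
    """Read a delimited case listing.

    A missing required column is fatal; a malformed row is collected as a
    row-level error (with its 1-based data row number) and the record is
    excluded.  ``dialect`` may be "csv" or "tsv"; by default it is inferred
    from the file suffix (``.tsv`` → tab, anything else → comma).
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    sep = "\t" if dialect == "tsv" else ","

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"case listing {path} lacks required column(s): "
                         + ", ".join(missing))

    records: list[CaseRecord] = []
    errors: list[tuple[int, str]] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            rec = CaseRecord(
                id=row_d["id"],
                sex=row_d["sex"],
                age_dx=int(row_d["age_dx"]),
                year_dx=int(row_d["year_dx"]),
                month_dx=int(row_d["month_dx"]),
                stage=row_d["stage"],
                profile=row_d["profile"],
                vital_status=row_d["vital_status"],
                year_end=int(row_d["year_end"]),
                month_end=int(row_d["month_end"]),
                basis=row_d["basis"],
            )
            rec.validate()
        except (ValueError, KeyError) as exc:
            errors.append((row_no, str(exc)))
            continue
        records.append(rec)
    if errors:
        logger.warning("case listing %s: %d malformed row(s) excluded", path,
                       len(errors))
    return ParseResult(records=records, errors=errors)


def write_case_listing(records: Iterable[CaseRecord], path: str | Path,
                       dialect: str = "csv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(CASE_COLUMNS)
        for r in records:
            writer.writerow([r.id, r.sex, r.age_dx, r.year_dx, r.month_dx,
                             r.stage, r.profile, r.vital_status, r.year_end,
                             r.month_end, r.basis])


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

EXCLUSION_REASONS = (
    "age above bound",
    "missing stage",
    "DCO or autopsy",
    "zero-month survival",
)


@dataclass
class ExclusionTally:
    """Counts of excluded records by reason, in the fixed application order."""

    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS})
    n_input: int = 0
    n_eligible: int = 0

    @property
    def total_excluded(self) -> int:
        return sum(self.counts.values())


def apply_eligibility(records: Sequence[CaseRecord],
                      max_age_dx: int = 74,
                      allow_empty: bool = False,
                      ) -> tuple[list[CaseRecord], ExclusionTally]:
    """Apply the cohort eligibility filters in a fixed, reproducible order.

    Order: age bound → missing stage → DCO/autopsy registration → zero
    completed months of survival.  Each record is tallied under the first
    rule it violates, so the tallies sum with the eligible count to the
    input size and the operation is idempotent.
    """
    tally = ExclusionTally(n_input=len(records))
    eligible: list[CaseRecord] = []
    for rec in records:
        if rec.age_dx > max_age_dx:
            tally.counts["age above bound"] += 1
        elif rec.stage == "missing":
            tally.counts["missing stage"] += 1
        elif rec.basis in ("DCO", "autopsy"):
            tally.counts["DCO or autopsy"] += 1
        elif rec.survival_months == 0:
            tally.counts["zero-month survival"] += 1
        else:
            eligible.append(rec)
    tally.n_eligible = len(eligible)
    if not eligible and not allow_empty:
        raise ValueError("no eligible records remain after exclusions")
    return eligible, tally


# ---------------------------------------------------------------------------
# Population rate tables
# ---------------------------------------------------------------------------

class PopulationRateTable:
    """Annual probabilities of death q(age, sex, year) for the population.

    Internally one dense (age × year) grid per sex.  Missing calendar years
    are filled by carrying the nearest earlier year forward (years before
    the first available are filled backward from it); ages beyond the table
    use the terminal age row.  Lookups warn once per run on clamping.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"age", "sex", "year", "qpop"}
        if not required.issubset(frame.columns):
            raise ValueError(f"rate table needs columns {sorted(required)}")
        q = frame["qpop"].astype(float)
        if (q < 0).any() or (q > 1).any():
            raise ValueError("rate table has q outside [0, 1]")
        self._grids: dict[str, np.ndarray] = {}
        self._age0: dict[str, int] = {}
        self._year0: dict[str, int] = {}
        self._warned_clamp = False
        for sex, sub in frame.groupby("sex"):
            pivot = sub.pivot_table(index="age", columns="year", values="qpop")
            full_years = range(int(pivot.columns.min()), int(pivot.columns.max()) + 1)
            pivot = pivot.reindex(columns=list(full_years))
            if pivot.isna().any().any():
                logger.warning(
                    "rate table (%s): missing cells filled by nearest-year "
                    "carry-forward", sex)
                pivot = pivot.ffill(axis=1).bfill(axis=1)
            full_ages = range(int(pivot.index.min()), int(pivot.index.max()) + 1)
            pivot = pivot.reindex(index=list(full_ages))
            if pivot.isna().any().any():
                raise ValueError(f"rate table ({sex}): ages not contiguous")
            self._grids[str(sex)] = pivot.to_numpy(dtype=float)
            self._age0[str(sex)] = int(pivot.index.min())
            self._year0[str(sex)] = int(pivot.columns.min())
        self.frame = frame.reset_index(drop=True)

    def annual_q(self, age, year, sex: str = "female") -> np.ndarray:
        """Annual death probability, vectorised over age/year arrays."""
        grid = self._grids[sex]
        a = np.asarray(age, dtype=int) - self._age0[sex]
        y = np.asarray(year, dtype=int) - self._year0[sex]
        clamped = (a < 0) | (a >= grid.shape[0]) | (y < 0) | (y >= grid.shape[1])
        if clamped.any() and not self._warned_clamp:
            logger.warning("rate table lookup beyond coverage: using nearest "
                           "age/year row")
            self._warned_clamp = True
        a = np.clip(a, 0, grid.shape[0] - 1)
        y = np.clip(y, 0, grid.shape[1] - 1)
        return grid[a, y]

    def monthly_q(self, age, year, sex: str = "female") -> np.ndarray:
        """Monthly death probability 1 − (1 − q_annual)^(1/12)."""
        return 1.0 - (1.0 - self.annual_q(age, year, sex)) ** (1.0 / 12.0)

    @classmethod
    def constant(cls, q: float, ages=range(0, 100),
                 years=range(1990, 2031), sex: str = "female"
                 ) -> "PopulationRateTable":
        rows = [(a, sex, y, q) for a in ages for y in years]
        return cls(pd.DataFrame(rows, columns=["age", "sex", "year", "qpop"]))


def read_rate_table(path: str | Path) -> PopulationRateTable:
    """Read a long-format rate table (age, sex, year, qpop)."""
    df = pd.read_csv(path)
    return PopulationRateTable(df)


def write_rate_table(table: PopulationRateTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Estimation-run settings mirrored by the YAML config file."""

    interval_width: int = 12          # months per life-table interval
    max_horizon: int = 180            # months; 15 years
    max_age_dx: int = 74
    cure_family: str = "auto"         # auto | weibull | loglogistic
    r_default: float = 1.33
    r_grid: tuple[float, ...] = (1.00, 1.33, 1.50, 1.70)
    deconv_step: int = 1              # months
    seed: int = 0
    age_bands: tuple[tuple[int, int], ...] = (
        (15, 44), (45, 54), (55, 64), (65, 74))
    periods: tuple[tuple[int, int], ...] = ((1997, 2006), (2007, 2017))
    covariates: tuple[str, ...] = ()  # subset of {"age_group", "period"}
    stages: tuple[str, ...] = ("I", "II", "III")
    profiles: tuple[str, ...] = ()    # stage × profile strata when non-empty
    birthday_offset: int = 6          # months from diagnosis to next birthday

    def __post_init__(self) -> None:
        if self.r_default <= 0 or any(r <= 0 for r in self.r_grid):
            raise ValueError("r values must be positive")
        if self.interval_width % self.deconv_step != 0:
            raise ValueError("deconvolution grid step must divide the "
                             "interval width")
        if self.cure_family not in ("auto", "weibull", "loglogistic"):
            raise ValueError(f"unknown cure family {self.cure_family!r}")

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def run_config_from_dict(raw: dict) -> RunConfig:
    kw = {}
    for fld in ("interval_width", "max_horizon", "max_age_dx", "cure_family",
                "r_default", "deconv_step", "seed", "birthday_offset"):
        if fld in raw:
            kw[fld] = raw[fld]
    if "r_grid" in raw:
        kw["r_grid"] = tuple(float(r) for r in raw["r_grid"])
    if "age_bands" in raw:
        kw["age_bands"] = tuple((int(a), int(b)) for a, b in raw["age_bands"])
    if "periods" in raw:
        kw["periods"] = tuple((int(a), int(b)) for a, b in raw["periods"])
    if "covariates" in raw:
        kw["covariates"] = tuple(raw["covariates"])
    if "stages" in raw:
        kw["stages"] = tuple(raw["stages"])
    if "profiles" in raw:
        kw["profiles"] = tuple(raw["profiles"])
    return RunConfig(**kw)


def load_run_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    return run_config_from_dict(raw)


def age_band_label(age: int, bands: Sequence[tuple[int, int]]) -> str | None:
    for lo, hi in bands:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return None


def period_label(year: int, periods: Sequence[tuple[int, int]]) -> str | None:
    for lo, hi in periods:
        if lo <= year <= hi:
            return f"{lo}-{hi}"
    return None
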