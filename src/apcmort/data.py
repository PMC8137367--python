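"""Lexis-gridded perinatal count data: types, validation, cohort indexing, CSV IO.

The study data are aggregated vital-statistics counts of perinatal deaths and
births on a 2 (worker type) x 7 (5-year maternal age group) x 5 (quinquennial
period 1995-2015) grid.  Birth cohorts run along the grid diagonals: the oldest
cohort was aged 45-49 in 1995 (born 1946-1950), the youngest aged 15-19 in 2015
(born 1996-2000), giving 11 cohorts.

The rate denominator throughout is *exposure* = births + perinatal deaths,
matching the vital-statistics definition of the perinatal mortality rate
(deaths per 1,000 of births + perinatal deaths).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AGE_LABELS",
    "PERIOD_YEARS",
    "WORKER_TYPES",
    "AgeGroup",
    "Period",
    "Cohort",
    "CountsTable",
    "cohort_index",
    "cohort_label",
    "load_counts",
    "write_counts",
    "load_bundled",
    "validate",
]

AGE_LABELS: tuple[str, ...] = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
)
PERIOD_YEARS: tuple[int, ...] = (1995, 2000, 2005, 2010, 2015)
WORKER_TYPES: tuple[str, ...] = ("white_collar", "blue_collar")

_FIXTURE_NAME = "perinatal_counts_japan_1995_2015.csv"
_CSV_COLUMNS = ["worker_type", "age_group", "year", "births", "deaths"]


@dataclass(frozen=True)
class AgeGroup:
    """A 5-year maternal age band, e.g. index 0 <-> '15-19'."""

    index: int
    label: str

    @property
    def lower(self) -> int:
        return int(self.label.split("-")[0])

    @property
    def upper(self) -> int:
        return int(self.label.split("-")[1])


@dataclass(frozen=True)
class Period:
    """A quinquennial reporting year."""

    index: int
    year: int


@dataclass(frozen=True)
class Cohort:
    """A 5-year birth cohort, labelled by its birth-year range."""

    index: int
    label: str


def cohort_index(a: int, p: int, n_ages: int = 7, n_periods: int = 5) -> int:
    """Map (age index, period index) to the cohort diagonal index.

    Cohorts are numbered from oldest (k=0: highest age at the first period)
    to youngest (k = A+P-2).  k = p - a + (A - 1).
    """
    if not (0 <= a < n_ages):
        raise IndexError(f"age index {a} out of range 0..{n_ages - 1}")
    if not (0 <= p < n_periods):
        raise IndexError(f"period index {p} out of range 0..{n_periods - 1}")
    return p - a + (n_ages - 1)


def cohort_label(k: int, age_labels=AGE_LABELS, years=PERIOD_YEARS) -> str:
    """Birth-year range of cohort k, derived from the grid geometry.

    Cohort k was aged `age_labels[A-1-k']`... concretely: members of cohort k
    observed in cell (a, p) with p - a + A - 1 = k were born between
    years[p] - upper(a) and years[p] - lower(a).  For 5-year bands on a
    quinquennial grid this range is the same for every cell on the diagonal.
    """
    n_ages = len(age_labels)
    n_cohorts = n_ages + len(years) - 1
    if not (0 <= k < n_cohorts):
        raise IndexError(f"cohort index {k} out of range 0..{n_cohorts - 1}")
    # any cell on the diagonal gives the same birth-year range; use the first
    p = max(0, k - (n_ages - 1))
    a = p - k + (n_ages - 1)
    lo, hi = (int(x) for x in age_labels[a].split("-"))
    return f"{years[p] - hi}-{years[p] - lo}"


@dataclass(frozen=True)
class CountsTable:
    """Complete Lexis grid of deaths and births for both worker types.

    Arrays are indexed ``[worker, age, period]`` with workers in the order
    ``(white_collar, blue_collar)``.  Exposure is births + deaths.
    """

    deaths: np.ndarray
    births: np.ndarray
    age_labels: tuple[str, ...] = AGE_LABELS
    years: tuple[int, ...] = PERIOD_YEARS
    worker_types: tuple[str, ...] = WORKER_TYPES

    def __post_init__(self):
        d = np.asarray(self.deaths)
        b = np.asarray(self.births)
        expect = (len(self.worker_types), len(self.age_labels), len(self.years))
        if d.shape != expect or b.shape != expect:
            raise ValueError(
                f"deaths/births must have shape {expect}, got {d.shape}/{b.shape}"
            )
        object.__setattr__(self, "deaths", d)
        object.__setattr__(self, "births", b)

    @property
    def exposure(self) -> np.ndarray:
        """Rate denominator n = births + deaths, per cell."""
        return self.births + self.deaths

    @property
    def n_ages(self) -> int:
        return len(self.age_labels)

    @property
    def n_periods(self) -> int:
        return len(self.years)

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1

    @property
    def cohort_labels(self) -> tuple[str, ...]:
        return tuple(
            cohort_label(k, self.age_labels, self.years)
            for k in range(self.n_cohorts)
        )

    @property
    def cohort_of_cell(self) -> np.ndarray:
        """(A, P) integer array of cohort indices."""
        a = np.arange(self.n_ages)[:, None]
        p = np.arange(self.n_periods)[None, :]
        return p - a + (self.n_ages - 1)

    def is_canonical(self) -> bool:
        """True for the study's 2x7x5 grid with the standard labels."""
        return (
            self.age_labels == AGE_LABELS
            and self.years == PERIOD_YEARS
            and self.worker_types == WORKER_TYPES
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iw, w in enumerate(self.worker_types):
            for ia, a in enumerate(self.age_labels):
                for ip, y in enumerate(self.years):
                    rows.append(
                        (w, a, y, int(self.births[iw, ia, ip]),
                         int(self.deaths[iw, ia, ip]))
                    )
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def validate(t: CountsTable) -> list[str]:
    """Check table invariants; returns a list of violations (empty = valid)."""
    problems: list[str] = []
    for name, arr in (("deaths", t.deaths), ("births", t.births)):
        if not np.issubdtype(np.asarray(arr).dtype, np.integer):
            if not np.all(np.asarray(arr) == np.round(arr)):
                problems.append(f"{name} contains non-integer values")
            else:
                problems.append(f"{name} stored as non-integer dtype")
        if np.any(np.asarray(arr) < 0):
            idx = tuple(int(i[0]) for i in np.where(np.asarray(arr) < 0))
            problems.append(f"negative {name} at (worker,age,period)={idx}")
    # deaths must not exceed exposure; with exposure = B + D this is
    # equivalent to births >= 0, but check the stated form explicitly
    if np.any(t.deaths > t.births + t.deaths):
        problems.append("deaths exceed exposure (births + deaths) in a cell")
    return problems


def _reject(path, msg: str):
    raise ValueError(f"{path}: {msg}")


def load_counts(path) -> CountsTable:
    """Read a counts CSV (``worker_type,age_group,year,births,deaths``).

    Every (worker, age, year) cell of the grid implied by the file's labels
    must be present exactly once; counts must be non-negative integers;
    labels must come from the study vocabulary.
    """
    df = pd.read_csv(path)
    if list(df.columns) != _CSV_COLUMNS:
        _reject(path, f"expected header {','.join(_CSV_COLUMNS)}, "
                      f"got {','.join(map(str, df.columns))}")
    bad_w = set(df["worker_type"]) - set(WORKER_TYPES)
    if bad_w:
        _reject(path, f"unknown worker_type label(s) {sorted(bad_w)}")
    bad_a = set(df["age_group"]) - set(AGE_LABELS)
    if bad_a:
        _reject(path, f"unknown age_group label(s) {sorted(bad_a)}")
    for col in ("births", "deaths"):
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df.loc[df[col] != np.floor(df[col])]
            if len(bad) or df[col].isna().any():
                row = bad.iloc[0] if len(bad) else df[df[col].isna()].iloc[0]
                _reject(path, f"non-integer {col} in row "
                              f"({row['worker_type']},{row['age_group']},{row['year']})")
            df[col] = df[col].astype(int)
        neg = df.loc[df[col] < 0]
        if len(neg):
            row = neg.iloc[0]
            _reject(path, f"negative {col} in row "
                          f"({row['worker_type']},{row['age_group']},{row['year']})")

    ages = tuple(a for a in AGE_LABELS if a in set(df["age_group"]))
    years = tuple(sorted(int(y) for y in df["year"].unique()))
    workers = WORKER_TYPES
    if len(years) > 1:
        gaps = np.diff(years)
        if not np.all(gaps == gaps[0]):
            _reject(path, f"years {years} are not evenly spaced")

    dup = df.duplicated(subset=["worker_type", "age_group", "year"])
    if dup.any():
        row = df[dup].iloc[0]
        _reject(path, f"duplicate cell "
                      f"({row['worker_type']},{row['age_group']},{row['year']})")

    deaths = np.zeros((len(workers), len(ages), len(years)), dtype=np.int64)
    births = np.zeros_like(deaths)
    seen = np.zeros(deaths.shape, dtype=bool)
    a_idx = {a: i for i, a in enumerate(ages)}
    y_idx = {y: i for i, y in enumerate(years)}
    w_idx = {w: i for i, w in enumerate(workers)}
    for row in df.itertuples(index=False):
        iw, ia, ip = w_idx[row.worker_type], a_idx[row.age_group], y_idx[int(row.year)]
        deaths[iw, ia, ip] = row.deaths
        births[iw, ia, ip] = row.births
        seen[iw, ia, ip] = True
    if not seen.all():
        iw, ia, ip = (int(i[0]) for i in np.where(~seen))
        _reject(path, f"missing cell ({workers[iw]},{ages[ia]},{years[ip]})")

    return CountsTable(deaths=deaths, births=births,
                       age_labels=ages, years=years, worker_types=workers)


def write_counts(t: CountsTable, path) -> None:
    t.to_frame().to_csv(path, index=False)


def load_bundled() -> CountsTable:
    """The published 1995-2015 Japanese perinatal counts by worker type."""
    with resources.as_file(
        resources.files("apcmort").joinpath("fixtures", _FIXTURE_NAME)
    ) as p:
        return load_counts(p)
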