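"""National incidence data, population trajectories and fitting scenarios.

The package ships the annual INEGI/SIESVIM counts of people treated in
Mexican medical units by injury intentionality (family, non-family and
self-inflicted violence), segregated by sex, 2010-2023.  Counts are
individuals; the models work in millions, so scenario construction
divides by 1e6.

Aggressor and susceptible compartments are not observed directly.
Fitting targets for them are built as fixed percentages of the total
national population (a *scenario*, e.g. 20% aggressors / 40%
susceptibles), interpolated linearly between census anchor years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .model import ModelParams

__all__ = [
    "IncidenceTable",
    "PopulationTrajectory",
    "ScenarioConfig",
    "ScenarioSeries",
    "load_incidence",
    "validate_incidence",
    "population_at",
    "build_scenario",
    "VIOLENCE_TYPES",
    "SEXES",
    "FAMILY_VIOLENCE_PARAMS",
    "NON_FAMILY_VIOLENCE_PARAMS",
]

VIOLENCE_TYPES = ("family", "non_family", "self_inflicted")
SEXES = ("F", "M")

#: An incidence table is a tidy DataFrame with columns
#: ``year, violence_type, sex, count`` (one row per combination).
IncidenceTable = pd.DataFrame

# Annual counts of individuals treated in medical units, by injury
# intentionality and sex, Mexico 2010-2023 (INEGI/SIESVIM, "People
# Treated in Medical Units, According to the Intentionality of the
# Injury").  Column order: family F/M, non-family F/M, self-inflicted F/M.
_INCIDENCE_ROWS: tuple[tuple[int, int, int, int, int, int, int], ...] = (
    (2010, 16240, 2395, 3703, 17850, 1395, 1449),
    (2011, 22765, 2983, 4790, 21775, 1582, 1410),
    (2012, 33177, 3491, 5428, 22299, 1505, 1501),
    (2013, 44683, 4686, 7763, 28114, 1837, 2134),
    (2014, 62434, 5902, 9302, 30034, 2158, 1930),
    (2015, 76934, 7139, 9976, 29963, 2224, 2271),
    (2016, 101178, 8458, 11453, 32612, 2886, 2721),
    (2017, 96651, 6695, 10818, 28654, 2497, 2210),
    (2018, 96700, 6018, 12038, 27731, 2635, 2440),
    (2019, 110210, 6538, 13541, 28410, 2974, 2642),
    (2020, 65242, 4702, 10432, 23403, 2271, 2191),
    (2021, 86284, 6040, 15286, 33190, 4264, 3487),
    (2022, 87591, 6782, 17275, 34268, 5879, 4113),
    (2023, 79295, 7485, 18354, 39497, 7132, 5305),
)

# Published point estimates for the base model under the 20%/40%
# scenario, one set per violence category that the model describes.
# These serve as reference inputs for projections and equilibrium
# analysis; refitting from the incidence table will not reproduce these
# digits exactly (optimizer and weighting choices differ) but lands in
# the same regime.
FAMILY_VIOLENCE_PARAMS = ModelParams(
    r_A=0.054631, k_A=30.325876, r_S=0.054604, k_S=61.712497,
    beta_F=0.000028, beta_M=0.000003, alpha_F=0.350354, alpha_M=0.561616,
)
NON_FAMILY_VIOLENCE_PARAMS = ModelParams(
    r_A=0.054622, k_A=30.327267, r_S=0.054602, k_S=61.510064,
    beta_F=0.000002, beta_M=0.000023, alpha_F=0.111478, alpha_M=0.927221,
)


def _fixture_frame() -> pd.DataFrame:
    records = []
    for year, fam_f, fam_m, non_f, non_m, self_f, self_m in _INCIDENCE_ROWS:
        by_type = {"family": (fam_f, fam_m), "non_family": (non_f, non_m),
                   "self_inflicted": (self_f, self_m)}
        for vtype, (f, m) in by_type.items():
            records.append((year, vtype, "F", f))
            records.append((year, vtype, "M", m))
    return pd.DataFrame(records, columns=["year", "violence_type", "sex", "count"])


def validate_incidence(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy incidence table; returns it with canonical dtypes.

    Requires the four canonical columns, known type/sex labels,
    nonnegative integer counts, and a complete year x type x sex grid
    over the combinations present (no missing cells).
    """
    required = ["year", "violence_type", "sex", "count"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"incidence table missing columns: {missing}")
    table = table[required].copy()
    bad_types = set(table["violence_type"]) - set(VIOLENCE_TYPES)
    if bad_types:
        raise ValueError(f"unknown violence_type labels: {sorted(bad_types)}")
    bad_sex = set(table["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    counts = pd.to_numeric(table["count"], errors="raise")
    if (counts < 0).any():
        raise ValueError("negative counts in incidence table")
    if not np.allclose(counts, counts.round()):
        raise ValueError("counts must be integers (persons)")
    table["count"] = counts.round().astype(np.int64)
    table["year"] = table["year"].astype(int)

    years = sorted(table["year"].unique())
    types = sorted(table["violence_type"].unique())
    grid = len(years) * len(types) * len(SEXES)
    dedup = table.drop_duplicates(["year", "violence_type", "sex"])
    if len(dedup) != len(table):
        raise ValueError("duplicate year/violence_type/sex rows")
    if len(table) != grid:
        raise ValueError(
            f"incomplete incidence table: {len(table)} rows, expected "
            f"{grid} for {len(years)} years x {len(types)} types x 2 sexes"
        )
    return table.sort_values(["year", "violence_type", "sex"]).reset_index(drop=True)


def load_incidence(source: Union[str, Path] = "fixture") -> IncidenceTable:
    """Load the bundled national dataset or a CSV in the same layout.

    ``source="fixture"`` returns the 84-row 2010-2023 table shipped with
    the package; otherwise ``source`` is a path to a CSV with header
    ``year,violence_type,sex,count`` (UTF-8, no thousands separators).
    """
    if isinstance(source, str) and source == "fixture":
        return validate_incidence(_fixture_frame())
    return validate_incidence(pd.read_csv(source))


@dataclass(frozen=True)
class PopulationTrajectory:
    """Piecewise-linear total-population curve through census anchors.

    ``anchors`` are ``(year, millions)`` pairs, strictly increasing in
    year.  Linear extrapolation is allowed up to 5 years before the
    first anchor and 15 years past the last (the projection horizon
    needs 2021-2034 from 2010/2015/2020 anchors).
    """

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        anchors = tuple((float(y), float(p)) for y, p in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        if not anchors:
            raise ValueError("PopulationTrajectory requires at least one anchor")
        years = [y for y, _ in anchors]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("anchor years must be strictly increasing")
        if any(p <= 0 for _, p in anchors):
            raise ValueError("anchor populations must be > 0")

    def __call__(self, year) -> np.ndarray | float:
        return population_at(self, year)


def population_at(traj: PopulationTrajectory, year) -> np.ndarray | float:
    """Total population (millions) at ``year`` by linear inter/extrapolation."""
    years = np.array([y for y, _ in traj.anchors])
    pops = np.array([p for _, p in traj.anchors])
    year_arr = np.asarray(year, dtype=float)
    lo, hi = years[0] - 5.0, years[-1] + 15.0
    if np.any(year_arr < lo) or np.any(year_arr > hi):
        raise ValueError(
            f"year {year} outside the supported range [{lo}, {hi}] "
            "(extrapolation limited to -5/+15 years around the anchors)"
        )
    if len(years) == 1:
        out = np.full_like(year_arr, pops[0])
        return out if year_arr.ndim else float(pops[0])
    out = np.interp(year_arr, years, pops)
    # np.interp clamps; replace the ends with linear extrapolation
    slope_lo = (pops[1] - pops[0]) / (years[1] - years[0])
    slope_hi = (pops[-1] - pops[-2]) / (years[-1] - years[-2])
    out = np.where(year_arr < years[0], pops[0] + slope_lo * (year_arr - years[0]), out)
    out = np.where(year_arr > years[-1], pops[-1] + slope_hi * (year_arr - years[-1]), out)
    return out if year_arr.ndim else float(out)


@dataclass(frozen=True)
class ScenarioConfig:
    """A population-percentage scenario for unobserved compartments.

    ``pct_aggressor`` / ``pct_susceptible`` are fractions of the total
    population (the published scenarios are 0.20/0.40, 0.40/0.20 and
    0.05/0.30).  Fit years default to 2010-2022 with 2023 held out for
    validation.
    """

    pct_aggressor: float = 0.20
    pct_susceptible: float = 0.40
    violence_type: str = "family"
    fit_years: tuple[int, ...] = tuple(range(2010, 2023))
    holdout_years: tuple[int, ...] = (2023,)

    def __post_init__(self) -> None:
        for name in ("pct_aggressor", "pct_susceptible"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.violence_type not in VIOLENCE_TYPES:
            raise ValueError(f"unknown violence_type {self.violence_type!r}")
        object.__setattr__(self, "fit_years", tuple(int(y) for y in self.fit_years))
        object.__setattr__(self, "holdout_years",
                           tuple(int(y) for y in self.holdout_years))
        if set(self.fit_years) & set(self.holdout_years):
            raise ValueError("fit and holdout years overlap")


@dataclass(frozen=True)
class ScenarioSeries:
    """Annual fitting targets in millions for one scenario.

    ``data`` has one row per year with columns ``A_obs, S_obs, V_M_obs,
    V_F_obs``; ``fit_years``/``holdout_years`` partition the index.
    """

    data: pd.DataFrame
    fit_years: tuple[int, ...]
    holdout_years: tuple[int, ...]
    config: ScenarioConfig = field(compare=False, default=None)

    @property
    def fit_frame(self) -> pd.DataFrame:
        return self.data.loc[list(self.fit_years)]

    @property
    def holdout_frame(self) -> pd.DataFrame:
        return self.data.loc[list(self.holdout_years)]


def build_scenario(
    table: IncidenceTable,
    traj: PopulationTrajectory,
    cfg: ScenarioConfig,
) -> ScenarioSeries:
    """Assemble per-year targets (millions) for one violence type.

    Aggressor/susceptible targets are the scenario percentages of the
    interpolated population of each observation year; victim targets are
    the incidence counts divided by 1e6.
    """
    sub = table[table["violence_type"] == cfg.violence_type]
    if sub.empty:
        raise ValueError(f"no rows for violence_type {cfg.violence_type!r}")
    years = sorted(set(cfg.fit_years) | set(cfg.holdout_years))
    missing = set(years) - set(sub["year"])
    if missing:
        raise ValueError(f"incidence table missing years {sorted(missing)}")
    wide = sub.pivot(index="year", columns="sex", values="count").loc[years]
    pop = population_at(traj, np.array(years, dtype=float))
    data = pd.DataFrame(
        {
            "A_obs": cfg.pct_aggressor * pop,
            "S_obs": cfg.pct_susceptible * pop,
            "V_M_obs": wide["M"].to_numpy() / 1e6,
            "V_F_obs": wide["F"].to_numpy() / 1e6,
        },
        index=pd.Index(years, name="year"),
    )
    return ScenarioSeries(data=data, fit_years=cfg.fit_years,
                          holdout_years=cfg.holdout_years, config=cfg)
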