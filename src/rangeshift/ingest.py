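"""Survey-table ingest: schema validation, substrate join, inclusion filters.

The filters mirror standard trawl-survey cleaning practice: restrict to
strata sampled in every year of the study window in every season, then
keep only species that occur regularly (present in at least a fraction
of years in each season) and that were caught in non-trivial amounts in
both the first and the last few years of the window (so that two-period
range comparisons are defined at both ends).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd

from ._geo import haversine_km
from .simulate import SURVEY_COLUMNS

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = SURVEY_COLUMNS  # haul_id .. species, cpue


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class EmptyResultError(ValueError):
    """A filter removed every remaining record."""


@dataclass(frozen=True)
class FilterRules:
    """Thresholds for the strata / species inclusion filters.

    Defaults encode a 33-year window (1986-2018): presence in at least
    half of the years per season, and summed CPUE strictly greater than
    ``edge_cpue_min`` within the first and last ``edge_period_years``
    of the window, again per season.
    """
    year_min: int = 1986
    year_max: int = 2018
    min_presence_fraction: float = 0.5
    edge_period_years: int = 5
    edge_cpue_min: float = 20.0

    def __post_init__(self):
        if not (0 < self.min_presence_fraction <= 1):
            raise ValueError("min_presence_fraction must be in (0, 1]")
        if self.edge_period_years < 1:
            raise ValueError("edge_period_years must be >= 1")
        if not self.year_min < self.year_max:
            raise ValueError("year_min must be < year_max")

    @property
    def n_years(self) -> int:
        return self.year_max - self.year_min + 1

    @property
    def min_presence_years(self) -> int:
        # "at least half of 33 years" is read as 16, so the fraction is
        # floored (never below 1 year)
        return max(1, int(self.min_presence_fraction * self.n_years))


def read_survey(path) -> pd.DataFrame:
    """Read a long-format survey CSV into a typed haul-by-species table.

    Rows with unparseable coordinates, coordinates out of range, or
    negative CPUE are dropped with a logged count. Missing grain size is
    allowed (it may be joined later from a substrate layer).
    """
    df = pd.read_csv(path, dtype={"haul_id": str, "season": str,
                                  "stratum": str, "species": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey table is missing required column(s): {missing}")
    if df.empty:
        logger.warning("survey file %s contains a header but no rows", path)
        return df[REQUIRED_COLUMNS]
    n0 = len(df)
    for col in ("year", "lat", "lon", "depth", "btemp", "bsalin", "grainsize", "cpue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (df["lat"].between(-90, 90) & df["lon"].between(-180, 180)
          & df["year"].notna() & (df["cpue"] >= 0))
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.info("read_survey: rejected %d of %d rows (bad coordinates, "
                    "missing year, or negative CPUE)", dropped, n0)
    df = df.loc[ok].reset_index(drop=True)
    df["year"] = df["year"].astype(int)
    return df[REQUIRED_COLUMNS]


def write_survey(df: pd.DataFrame, path) -> None:
    df[REQUIRED_COLUMNS].to_csv(path, index=False)


def join_substrate(records: pd.DataFrame, substrate: pd.DataFrame,
                   max_distance_km: float = 50.0) -> pd.DataFrame:
    """Fill ``grainsize`` from the nearest substrate point (great circle).

    Each haul location is matched to its great-circle nearest neighbour
    in the substrate table; exact distance ties go to the lower-index
    donor point. Hauls farther than ``max_distance_km`` from every donor
    keep a missing grain size. A ``substrate_distance_km`` column records
    the donor distance.
    """
    for col in ("lon", "lat"):
        if col not in substrate.columns:
            raise SchemaError(f"substrate table is missing column {col!r}")
    grain_col = "grainsize_mm" if "grainsize_mm" in substrate.columns else "grainsize"
    if grain_col not in substrate.columns:
        raise SchemaError("substrate table is missing a grainsize column")
    if substrate.empty:
        raise ValueError("substrate table is empty")

    sub = substrate.reset_index(drop=True)
    # unique haul locations, matched on the unit sphere via a 3-D KD-tree
    from scipy.spatial import cKDTree

    def to_xyz(lat, lon):
        la, lo = np.radians(lat), np.radians(lon)
        return np.column_stack([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo),
                                np.sin(la)])

    hauls = records[["haul_id", "lat", "lon"]].drop_duplicates("haul_id")
    tree = cKDTree(to_xyz(sub["lat"].to_numpy(), sub["lon"].to_numpy()))
    k = min(4, len(sub))
    dist, idx = tree.query(to_xyz(hauls["lat"].to_numpy(), hauls["lon"].to_numpy()), k=k)
    dist, idx = np.atleast_2d(dist.T).T, np.atleast_2d(idx.T).T
    # lowest donor index among neighbours tied for the minimum chord distance
    tie = dist <= dist[:, [0]] * (1 + 1e-12) + 1e-12
    masked = np.where(tie, idx, len(sub) + 1)
    donor = masked.min(axis=1)
    arc_km = haversine_km(hauls["lat"].to_numpy(), hauls["lon"].to_numpy(),
                          sub["lat"].to_numpy()[donor], sub["lon"].to_numpy()[donor])
    arc_km = np.atleast_1d(arc_km)
    grain = np.where(arc_km <= max_distance_km,
                     sub[grain_col].to_numpy()[donor], np.nan)
    lut = pd.DataFrame({"haul_id": hauls["haul_id"].to_numpy(),
                        "grainsize": grain, "substrate_distance_km": arc_km})
    out = records.drop(columns=["grainsize"], errors="ignore").merge(lut, on="haul_id")
    n_missing = int(out["grainsize"].isna().groupby(out["haul_id"]).first().sum())
    if n_missing:
        logger.info("join_substrate: %d haul(s) beyond %.0f km of any substrate "
                    "point; grainsize left missing", n_missing, max_distance_km)
    return out[REQUIRED_COLUMNS + ["substrate_distance_km"]]


def filter_strata(records: pd.DataFrame, rules: FilterRules) -> pd.DataFrame:
    """Keep only strata with at least one haul in every (year, season) cell.

    The coverage requirement spans every year in [year_min, year_max] and
    every season present in the data; records outside the year window are
    dropped first.
    """
    if records.empty:
        raise EmptyResultError("no records to filter")
    df = records[records["year"].between(rules.year_min, rules.year_max)]
    if df.empty:
        raise EmptyResultError(
            f"no records within [{rules.year_min}, {rules.year_max}]")
    seasons = df["season"].unique()
    required = rules.n_years * len(seasons)
    cells = (df.drop_duplicates(["stratum", "year", "season"])
               .groupby("stratum").size())
    keep = cells.index[cells == required]
    dropped = sorted(set(df["stratum"]) - set(keep))
    if dropped:
        logger.info("filter_strata: dropped %d stratum(a) with incomplete "
                    "year x season coverage: %s", len(dropped), dropped)
    if len(keep) == 0:
        raise EmptyResultError("no stratum is sampled in every year and season")
    return df[df["stratum"].isin(keep)].reset_index(drop=True)


def filter_species(records: pd.DataFrame,
                   rules: FilterRules) -> tuple[list[str], pd.DataFrame]:
    """Apply the species inclusion rules; returns (retained, decision_log).

    A species is retained iff, in EVERY season present in the data:

    * it is present (CPUE > 0 in at least one haul) in at least
      ``floor(min_presence_fraction * n_years)`` distinct years (16 of
      33 under the defaults), and
    * its summed CPUE is strictly greater than ``edge_cpue_min`` within
      the first ``edge_period_years`` of the window and, separately,
      within the last ``edge_period_years``.

    The decision log has one row per (species, season) with the counts
    behind the decision and the reason for any drop.
    """
    df = records[records["year"].between(rules.year_min, rules.year_max)]
    seasons = sorted(df["season"].unique())
    first_years = range(rules.year_min, rules.year_min + rules.edge_period_years)
    last_years = range(rules.year_max - rules.edge_period_years + 1, rules.year_max + 1)
    need_years = rules.min_presence_years

    rows = []
    for (species, season), g in df.groupby(["species", "season"]):
        pos = g[g["cpue"] > 0]
        n_pres = pos["year"].nunique()
        first_sum = g.loc[g["year"].isin(first_years), "cpue"].sum()
        last_sum = g.loc[g["year"].isin(last_years), "cpue"].sum()
        reasons = []
        if n_pres < need_years:
            reasons.append("presence")
        if not (first_sum > rules.edge_cpue_min and last_sum > rules.edge_cpue_min):
            reasons.append("edge_cpue")
        rows.append({"species": species, "season": season,
                     "years_present": n_pres, "years_required": need_years,
                     "first_period_cpue": first_sum, "last_period_cpue": last_sum,
                     "pass": not reasons, "reason": ";".join(reasons) or ""})
    log = pd.DataFrame(rows)
    if log.empty:
        return [], log
    by_species = log.groupby("species")["pass"].agg(
        lambda s: s.all() and s.size == len(seasons))
    retained = sorted(by_species.index[by_species])
    for sp in by_species.index[~by_species]:
        why = log.loc[(log.species == sp) & ~log["pass"], "reason"].unique()
        logger.info("filter_species: dropped %s (%s)", sp, ",".join(why))
    return retained, log


def apply_filters(records: pd.DataFrame,
                  rules: FilterRules) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Strata filter, then species filter; returns (records, species, log)."""
    kept = filter_strata(records, rules)
    retained, log = filter_species(kept, rules)
    return kept[kept["species"].isin(retained)].reset_index(drop=True), retained, log
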