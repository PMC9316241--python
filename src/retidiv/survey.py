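"""Survey dataset container and stratified tabulation.

A survey is a set of GPS-recorded sites, each belonging to a county and to one
of two strata (north/south of a dividing "fall line"), plus the samples
collected at those sites with a species per sample. Tabulation reduces it to
the classic survey table: per-species counts and percentages of counties,
sites and samples, statewide and per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional

import pandas as pd

STRATA = ("north", "south")
BLOCKS = ("counties", "sites", "samples")


def assign_stratum(site: tuple[float, float], fall_line_y: float) -> str:
    """North iff y >= fall line; points exactly on the line count as north."""
    _, y = site
    return "north" if y >= fall_line_y else "south"


def percent(count: float, total: float, decimals: int = 1) -> float:
    """100*count/total rounded half-up, the convention of printed tables."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) / Decimal(total) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


def mean_area_per_site(area_km2: float, n_sites: int) -> float:
    """Average surveyed area per site, km² — the survey's sampling density."""
    if n_sites < 1:
        raise ValueError("need at least one site")
    return area_km2 / n_sites


@dataclass
class SurveyDataset:
    """Sites (site_id, x, y, county_id, stratum) + samples (sample_id, site_id, species)."""

    sites: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        need_sites = {"site_id", "x", "y", "county_id", "stratum"}
        need_samples = {"sample_id", "site_id", "species"}
        if not need_sites <= set(self.sites.columns):
            raise ValueError(f"sites table needs columns {sorted(need_sites)}")
        if not need_samples <= set(self.samples.columns):
            raise ValueError(f"samples table needs columns {sorted(need_samples)}")
        if self.sites.site_id.duplicated().any():
            raise ValueError("duplicate site ids")
        bad = set(self.samples.site_id) - set(self.sites.site_id)
        if bad:
            raise ValueError(f"samples reference unknown sites: {sorted(bad)[:5]}")
        unknown_strata = set(self.sites.stratum) - set(STRATA)
        if unknown_strata:
            raise ValueError(f"unknown strata: {sorted(unknown_strata)}")
        empty = set(self.sites.site_id) - set(self.samples.site_id)
        if empty:
            raise ValueError(
                f"{len(empty)} sites have no samples, e.g. {sorted(empty)[:3]}"
            )

    @property
    def species(self) -> list[str]:
        return sorted(self.samples.species.unique())

    @classmethod
    def from_coordinates(
        cls, sites: pd.DataFrame, samples: pd.DataFrame, fall_line_y: float
    ) -> "SurveyDataset":
        """Build a dataset, deriving each site's stratum from the fall line."""
        sites = sites.copy()
        sites["stratum"] = [
            assign_stratum((x, y), fall_line_y) for x, y in zip(sites.x, sites.y)
        ]
        return cls(sites, samples)

    @classmethod
    def from_csv(cls, sites_path: str | Path, samples_path: str | Path) -> "SurveyDataset":
        return cls(pd.read_csv(sites_path), pd.read_csv(samples_path))

    def to_csv(self, sites_path: str | Path, samples_path: str | Path) -> None:
        self.sites.to_csv(sites_path, index=False)
        self.samples.to_csv(samples_path, index=False)

    def county_strata(self) -> pd.Series:
        """Stratum per county: the majority stratum of its sites (ties north)."""
        def majority(s: pd.Series) -> str:
            n_north = (s == "north").sum()
            return "north" if n_north >= len(s) - n_north else "south"

        return self.sites.groupby("county_id")["stratum"].agg(majority)


@dataclass
class SurveyTable:
    """Long-form survey table: block x stratum x species counts and percentages."""

    data: pd.DataFrame  # columns: block, stratum, species, count, total, percent

    def lookup(self, block: str, stratum: str, species: str) -> tuple[int, float]:
        row = self.data.query(
            "block == @block and stratum == @stratum and species == @species"
        )
        if row.empty:
            return 0, 0.0
        return int(row["count"].iloc[0]), float(row["percent"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurveyTable":
        return cls(pd.read_csv(path))


def tabulate_survey(ds: SurveyDataset, species: Optional[list[str]] = None) -> SurveyTable:
    """Per-species counts/percentages of counties, sites and samples by stratum.

    A species counts once per site (presence), once per county (>=1 sample at
    >=1 site of the county), once per sample. Denominators are the stratum's
    totals of counties, sites and samples.
    """
    species = species if species is not None else ds.species
    unknown = set(ds.samples.species) - set(species)
    if unknown:
        raise ValueError(f"unknown species tokens: {sorted(unknown)}")

    merged = ds.samples.merge(
        ds.sites[["site_id", "county_id", "stratum"]], on="site_id"
    )
    county_stratum = ds.county_strata()

    rows = []
    strata = ("statewide",) + STRATA
    for stratum in strata:
        if stratum == "statewide":
            sub = merged
            n_counties = ds.sites.county_id.nunique()
            n_sites = len(ds.sites)
        else:
            sub = merged[merged.stratum == stratum]
            n_counties = int((county_stratum == stratum).sum())
            n_sites = int((ds.sites.stratum == stratum).sum())
        n_samples = len(sub)
        for sp in species:
            sp_rows = sub[sub.species == sp]
            # county presence is judged against the county's own stratum
            if stratum == "statewide":
                c = sp_rows.county_id.nunique()
            else:
                in_stratum = county_stratum[county_stratum == stratum].index
                c = sp_rows[sp_rows.county_id.isin(in_stratum)].county_id.nunique()
            for block, count, total in (
                ("counties", c, n_counties),
                ("sites", sp_rows.site_id.nunique(), n_sites),
                ("samples", len(sp_rows), n_samples),
            ):
                rows.append(
                    {
                        "block": block,
                        "stratum": stratum,
                        "species": sp,
                        "count": int(count),
                        "total": int(total),
                        "percent": percent(count, total),
                    }
                )
    return SurveyTable(pd.DataFrame(rows))


def site_cooccurrence_summary(ds: SurveyDataset) -> pd.DataFrame:
    """Histogram of per-site species richness with percentages of all sites."""
    richness = (
        ds.samples.merge(ds.sites[["site_id"]], on="site_id")
        .groupby("site_id")["species"]
        .nunique()
    )
    n_sites = len(ds.sites)
    counts = richness.value_counts().sort_index()
    return pd.DataFrame(
        {
            "richness": counts.index.astype(int),
            "n_sites": counts.values,
            "percent_of_sites": [100 * c / n_sites for c in counts.values],
        }
    )
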