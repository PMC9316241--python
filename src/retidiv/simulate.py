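"""Synthetic sequence panels and spatial survey datasets.

The generators mirror the statistical structure of a statewide barcode survey:

* a reference panel with a clear barcode gap — species ancestors diverge from
  a common root, haplotypes fan out star-like around each ancestor under
  Jukes-Cantor-style substitution (equal-rate, closed-form pairwise
  expectations, which is what makes oracle tests possible);
* a survey of sites scattered over a rectangular window split by a horizontal
  "fall line" into a north and a south stratum, counties as grid cells, some
  species present statewide and some confined to one stratum, some spatially
  clustered (Thomas parent/offspring process) and some near-CSR.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sequences import BASES, ReferencePanel, SequenceRecord, write_fasta
from .survey import SurveyDataset, assign_stratum
from . import geo

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# sequences


@dataclass(frozen=True)
class SimSeqConfig:
    """Parameters of the synthetic reference panel + query set.

    Divergences are expected substitutions per site; the barcode gap is
    enforced by requiring between-species divergence to exceed twice the
    within-species divergence.
    """

    n_species: int = 5
    refs_per_species: int = 11
    queries_per_species: int = 20
    seq_length: int = 685
    between_divergence: float = 0.05
    within_divergence: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.refs_per_species, self.queries_per_species) < 1:
            raise ValueError("all counts must be >= 1")
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")
        if not self.between_divergence > 2 * self.within_divergence:
            raise ValueError(
                "barcode-gap invariant violated: need between_divergence > "
                f"2 * within_divergence ({self.between_divergence} <= "
                f"{2 * self.within_divergence})"
            )


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(length: int, rng: Union[int, np.random.Generator]) -> str:
    rng = _as_rng(rng)
    return "".join(rng.choice(BASES, size=length))


def mutate_sequence(
    base: str, expected_subs_per_site: float, seed: Union[int, np.random.Generator]
) -> str:
    """Apply site-independent substitutions at a given expected rate.

    Each site changes with probability (3/4)(1 - e^(-4d/3)) — the
    Jukes-Cantor probability of observing a difference after d expected
    substitutions per site — to one of the three other bases uniformly.
    """
    if expected_subs_per_site < 0:
        raise ValueError("substitution rate must be nonnegative")
    for i, b in enumerate(base):
        if b not in _BASE_INDEX:
            raise ValueError(f"non-ACGT base {b!r} at position {i}")
    rng = _as_rng(seed)
    p = 0.75 * (1.0 - math.exp(-4.0 * expected_subs_per_site / 3.0))
    arr = np.frombuffer(base.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < p)
    if hit.size:
        # shift by 1..3 in base index: uniform over the other three bases
        idx = np.array([_BASE_INDEX[base[i]] for i in hit])
        new = (idx + rng.integers(1, 4, size=hit.size)) % 4
        for k, i in enumerate(hit):
            arr[i] = BASES[new[k]].encode()
    return arr.tobytes().decode()


def simulate_reference_panel(
    cfg: SimSeqConfig,
) -> tuple[ReferencePanel, list[SequenceRecord]]:
    """Star phylogeny per species: root -> ancestors -> haplotypes.

    Returns the labeled reference panel and a query set whose records carry
    their ground-truth species in ``label`` (for recovery tests; serialized
    queries keep truth in a sidecar, not the FASTA header).
    """
    rng = np.random.default_rng(cfg.seed)
    root = random_sequence(cfg.seq_length, rng)
    refs: dict[str, list[SequenceRecord]] = {}
    queries: list[SequenceRecord] = []
    for s in range(cfg.n_species):
        species = f"sp{s + 1}"
        ancestor = mutate_sequence(root, cfg.between_divergence, rng)
        refs[species] = [
            SequenceRecord(
                f"{species}|ref{i + 1}",
                mutate_sequence(ancestor, cfg.within_divergence, rng),
                label=species,
            )
            for i in range(cfg.refs_per_species)
        ]
        for i in range(cfg.queries_per_species):
            queries.append(
                SequenceRecord(
                    f"q{s * cfg.queries_per_species + i + 1}",
                    mutate_sequence(ancestor, cfg.within_divergence, rng),
                    label=species,
                )
            )
    return ReferencePanel(refs), queries


def write_panel_files(
    panel: ReferencePanel,
    queries: list[SequenceRecord],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write refs.fasta, queries.fasta and the query-truth sidecar CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": outdir / "refs.fasta",
        "queries": outdir / "queries.fasta",
        "query_truth": outdir / "query_truth.csv",
    }
    panel.to_fasta(paths["panel"])
    write_fasta(
        [SequenceRecord(q.id, q.bases) for q in queries], paths["queries"]
    )
    pd.DataFrame(
        {"query_id": [q.id for q in queries], "species": [q.label for q in queries]}
    ).to_csv(paths["query_truth"], index=False)
    return paths


# ---------------------------------------------------------------------------
# point patterns


def simulate_csr(
    n: int, window: tuple[float, float, float, float],
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """n points uniform (binomial CSR) in a rectangular window."""
    rng = _as_rng(seed)
    xmin, ymin, xmax, ymax = window
    pts = rng.random((n, 2))
    pts[:, 0] = xmin + pts[:, 0] * (xmax - xmin)
    pts[:, 1] = ymin + pts[:, 1] * (ymax - ymin)
    return pts


def simulate_thomas(
    window: tuple[float, float, float, float],
    parent_intensity: float,
    mean_offspring: float,
    cluster_sd: float,
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """Thomas cluster process: Poisson parents, Gaussian-scattered offspring.

    Offspring falling outside the window are discarded (border thinning).
    """
    rng = _as_rng(seed)
    xmin, ymin, xmax, ymax = window
    area = (xmax - xmin) * (ymax - ymin)
    n_parents = rng.poisson(parent_intensity * area)
    pts = []
    for _ in range(n_parents):
        parent = np.array(
            [xmin + rng.random() * (xmax - xmin), ymin + rng.random() * (ymax - ymin)]
        )
        k = rng.poisson(mean_offspring)
        if k:
            pts.append(parent + rng.normal(0.0, cluster_sd, size=(k, 2)))
    if not pts:
        return np.empty((0, 2))
    pts = np.vstack(pts)
    inside = (
        (pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
        & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax)
    )
    return pts[inside]


# ---------------------------------------------------------------------------
# survey


@dataclass(frozen=True)
class ThomasPattern:
    """Clustered spatial pattern parameters (parents per km², offspring per
    parent, Gaussian offspring spread in km)."""

    parent_intensity: float
    mean_offspring: float
    cluster_sd: float


Pattern = Union[str, ThomasPattern]  # "csr" or a ThomasPattern


@dataclass(frozen=True)
class SimSurveyConfig:
    """Study-structure parameters for the synthetic statewide survey.

    ``occupancy[species][stratum]`` is the probability a site in that stratum
    yields the species; a stratum-restricted species simply has occupancy 0 in
    the excluded stratum. ``patterns`` optionally replaces a species' CSR
    presence draw with a Thomas cluster realization thinned to sites.
    """

    # 450 x 342 km = 153 900 km², the surveyed land area; the fall line at
    # y = 192 gives the survey's north/south site split under uniform placement
    window: tuple[float, float, float, float] = (0.0, 0.0, 450.0, 342.0)
    fall_line_y: float = 192.0
    county_grid: tuple[int, int] = (12, 13)
    n_sites: int = 1570
    occupancy: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # three statewide species, two confined to the north stratum;
            # rates follow the surveyed per-stratum site proportions
            "sp1": {"north": 0.733, "south": 0.711},
            "sp2": {"north": 0.189, "south": 0.486},
            "sp3": {"north": 0.455, "south": 0.0},
            "sp4": {"north": 0.141, "south": 0.251},
            "sp5": {"north": 0.031, "south": 0.0},
        }
    )
    patterns: dict[str, Pattern] = field(
        default_factory=lambda: {
            "sp3": ThomasPattern(4e-4, 25.0, 12.0),
            "sp5": ThomasPattern(6e-5, 30.0, 8.0),
        }
    )
    samples_per_site_range: tuple[int, int] = (1, 7)
    placement: str = "csr"  # or "stratified_by_county"
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.window
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("window must have positive extent")
        if not (ymin < self.fall_line_y < ymax):
            raise ValueError("fall_line_y must lie strictly inside the window")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        total = 0.0
        for sp, occ in self.occupancy.items():
            for stratum, p in occ.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"occupancy[{sp}][{stratum}]={p} not in [0,1]")
                total += p
        if total == 0:
            raise ValueError(
                "every species has zero occupancy everywhere; no site could "
                "yield a sample"
            )
        lo, hi = self.samples_per_site_range
        if not (1 <= lo <= hi):
            raise ValueError("samples_per_site_range must satisfy 1 <= min <= max")
        if self.placement not in ("csr", "stratified_by_county"):
            raise ValueError(f"unknown placement {self.placement!r}")

    @property
    def species(self) -> list[str]:
        return list(self.occupancy)

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)


def _place_sites(cfg: SimSurveyConfig, rng: np.random.Generator) -> pd.DataFrame:
    xmin, ymin, xmax, ymax = cfg.window
    rows, cols = cfg.county_grid
    if cfg.placement == "csr":
        pts = simulate_csr(cfg.n_sites, cfg.window, rng)
    else:
        # round-robin over county cells, uniform within each cell: guarantees
        # every county holds a site once n_sites >= rows*cols
        cells = [(r, c) for r in range(rows) for c in range(cols)]
        w, h = (xmax - xmin) / cols, (ymax - ymin) / rows
        pts = np.empty((cfg.n_sites, 2))
        for i in range(cfg.n_sites):
            r, c = cells[i % len(cells)]
            pts[i] = (
                xmin + (c + rng.random()) * w,
                ymin + (r + rng.random()) * h,
            )
    col = np.clip(((pts[:, 0] - xmin) / (xmax - xmin) * cols).astype(int), 0, cols - 1)
    row = np.clip(((pts[:, 1] - ymin) / (ymax - ymin) * rows).astype(int), 0, rows - 1)
    return pd.DataFrame(
        {
            "site_id": [f"site{i + 1}" for i in range(cfg.n_sites)],
            "x": pts[:, 0],
            "y": pts[:, 1],
            "county_id": [f"c{r}_{c}" for r, c in zip(row, col)],
            "stratum": [
                assign_stratum((x, y), cfg.fall_line_y) for x, y in pts
            ],
        }
    )


def simulate_survey(cfg: SimSurveyConfig) -> SurveyDataset:
    """Realize sites, per-site species presence, and per-sample species."""
    rng = np.random.default_rng(cfg.seed)
    sites = _place_sites(cfg, rng)
    n = len(sites)
    strata = sites.stratum.to_numpy()
    presence: dict[str, np.ndarray] = {}
    tree = cKDTree(sites[["x", "y"]].to_numpy())

    for sp in cfg.species:
        occ = cfg.occupancy[sp]
        pattern = cfg.patterns.get(sp, "csr")
        if pattern == "csr":
            p = np.array([occ[s] for s in strata])
            present = rng.random(n) < p
        else:
            offspring = simulate_thomas(
                cfg.window, pattern.parent_intensity, pattern.mean_offspring,
                pattern.cluster_sd, rng,
            )
            present = np.zeros(n, dtype=bool)
            if len(offspring):
                _, idx = tree.query(offspring)
                present[np.unique(idx)] = True
            # stratum restriction still binds for clustered species
            zero = np.array([occ.get(s, 0.0) == 0.0 for s in strata])
            present &= ~zero
        presence[sp] = present

    # every site must be able to yield a sample: backfill empty sites with one
    # species drawn with probability proportional to its stratum occupancy
    matrix = np.column_stack([presence[sp] for sp in cfg.species])
    for i in np.flatnonzero(~matrix.any(axis=1)):
        weights = np.array([cfg.occupancy[sp][strata[i]] for sp in cfg.species])
        if weights.sum() == 0:
            raise ValueError(
                f"site {sites.site_id.iloc[i]} lies in stratum {strata[i]!r} "
                "where every species has zero occupancy"
            )
        pick = rng.choice(len(cfg.species), p=weights / weights.sum())
        matrix[i, pick] = True

    lo, hi = cfg.samples_per_site_range
    sample_rows = []
    k_per_site = rng.integers(lo, hi + 1, size=n)
    sp_names = np.array(cfg.species)
    for i in range(n):
        pool = sp_names[matrix[i]]
        for j in range(k_per_site[i]):
            sample_rows.append(
                {
                    "sample_id": f"s{len(sample_rows) + 1}",
                    "site_id": sites.site_id.iloc[i],
                    "species": rng.choice(pool),
                }
            )
    return SurveyDataset(sites, pd.DataFrame(sample_rows))


def write_survey_files(
    ds: SurveyDataset, cfg: SimSurveyConfig, outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": outdir / "sites.csv",
        "samples": outdir / "samples.csv",
        "window": outdir / "window.geojson",
    }
    ds.to_csv(paths["sites"], paths["samples"])
    geo.write_window_geojson(
        geo.window_box(*cfg.window), cfg.fall_line_y, paths["window"]
    )
    return paths


def write_manifest(
    paths: dict[str, Path], seed: int, outdir: str | Path
) -> Path:
    """Echo emitted paths and the seed so a run is self-describing."""
    manifest = Path(outdir) / "sim_manifest.json"
    manifest.write_text(
        json.dumps(
            {"seed": seed, "outputs": {k: str(v) for k, v in paths.items()}},
            indent=1,
        )
    )
    return manifest
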