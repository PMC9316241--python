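"""Hill-number diversity profiles from species detection counts.

Hill numbers express diversity in "effective species" at increasing order r:

* N0 — richness, the number of species detected;
* N1 — exponential Shannon entropy, exp(-Σ p_i ln p_i);
* N2 — inverse Simpson concentration, here in its finite-sample form
  1 / (Σ n_i(n_i - 1) / (N(N - 1))) with N the total number of detections;
* N∞ — inverse Berger-Parker dominance, 1 / max p_i.

Counts are site-level detections (number of sites where a species was found)
within a stratum; p_i is a species' share of the stratum's total detections.
The finite-sample N2 needs integer counts and N >= 2; when every species is a
singleton the unbiased Simpson sum is zero and N2 is reported as ``inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .survey import SurveyDataset

CountsLike = Union["DetectionCounts", Sequence[int], Mapping[str, int]]


@dataclass(frozen=True)
class DetectionCounts:
    """Per-species detection counts within one stratum."""

    counts: tuple[int, ...]
    stratum: str = "statewide"
    species: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")
        if any(int(c) != c for c in self.counts):
            raise ValueError("counts must be integers")
        if not any(c > 0 for c in self.counts):
            raise ValueError("need at least one species with a positive count")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))


def _as_counts(counts: CountsLike) -> np.ndarray:
    if isinstance(counts, DetectionCounts):
        arr = np.array(counts.counts, dtype=float)
    elif isinstance(counts, Mapping):
        arr = np.array(list(counts.values()), dtype=float)
    else:
        arr = np.array(list(counts), dtype=float)
    if arr.size == 0 or not np.any(arr > 0):
        raise ValueError("need at least one species with a positive count")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    return arr[arr > 0]


def hill_n0(counts: CountsLike) -> int:
    """Richness: the number of species with at least one detection."""
    return int(_as_counts(counts).size)


def hill_n1(counts: CountsLike) -> float:
    """Exponential Shannon entropy; zero-count species contribute nothing."""
    c = _as_counts(counts)
    p = c / c.sum()
    return float(np.exp(-np.sum(p * np.log(p))))


def hill_n2(counts: CountsLike) -> float:
    """Finite-sample inverse Simpson, 1 / (Σ n(n-1) / (N(N-1)))."""
    c = _as_counts(counts)
    if np.any(c != np.round(c)):
        raise ValueError("finite-sample inverse Simpson requires integer counts")
    N = c.sum()
    if N < 2:
        raise ValueError("inverse Simpson needs at least 2 detections")
    s = np.sum(c * (c - 1.0))
    if s == 0:
        return math.inf  # all singletons: unbiased Simpson concentration is 0
    return float(N * (N - 1.0) / s)


def hill_ninf(counts: CountsLike) -> float:
    """Inverse Berger-Parker dominance, 1 / max p_i."""
    c = _as_counts(counts)
    return float(c.sum() / c.max())


@dataclass(frozen=True)
class HillProfile:
    """Diversity profile of one stratum, in effective species."""

    stratum: str
    n0: int
    n1: float
    n2: float
    n_inf: float

    @classmethod
    def from_counts(cls, counts: CountsLike, stratum: str = "statewide") -> "HillProfile":
        return cls(
            stratum=stratum,
            n0=hill_n0(counts),
            n1=hill_n1(counts),
            n2=hill_n2(counts),
            n_inf=hill_ninf(counts),
        )

    def rounded(self, decimals: int = 2) -> tuple[int, float, float, float]:
        # half-up, the convention of printed diversity tables
        def r(x: float) -> float:
            return math.floor(x * 10**decimals + 0.5) / 10**decimals
        return self.n0, r(self.n1), r(self.n2), r(self.n_inf)


def detection_counts_by_stratum(ds: SurveyDataset) -> dict[str, DetectionCounts]:
    """Per-stratum site-detection counts (sites where each species occurs)."""
    merged = ds.samples.merge(ds.sites[["site_id", "stratum"]], on="site_id")
    out: dict[str, DetectionCounts] = {}
    for stratum in ("statewide", "north", "south"):
        sub = merged if stratum == "statewide" else merged[merged.stratum == stratum]
        if sub.empty:
            continue
        counts = sub.groupby("species")["site_id"].nunique().sort_index()
        out[stratum] = DetectionCounts(
            tuple(int(v) for v in counts.values),
            stratum=stratum,
            species=tuple(counts.index),
        )
    return out


def hill_profile(ds: SurveyDataset) -> dict[str, HillProfile]:
    """Hill profiles statewide and per stratum; empty strata are omitted."""
    import warnings

    profiles = {}
    by_stratum = detection_counts_by_stratum(ds)
    for stratum in ("statewide", "north", "south"):
        if stratum not in by_stratum:
            warnings.warn(f"stratum {stratum!r} has no detections; omitted")
            continue
        profiles[stratum] = HillProfile.from_counts(by_stratum[stratum], stratum)
    return profiles


def profiles_to_csv(profiles: Iterable[HillProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        n0, n1, n2, ninf = p.rounded()
        rows.append({"stratum": p.stratum, "N0": n0, "N1": n1, "N2": n2, "Ninf": ninf})
    pd.DataFrame(rows).to_csv(path, index=False)
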