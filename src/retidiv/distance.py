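"""Pairwise nucleotide distances (p, Jukes-Cantor, Kimura 2-parameter).

All distances are in expected substitutions per site and are computed with
pairwise deletion: a column is compared only when both sequences carry an
unambiguous base (A, C, G or T) there. A saturated pair — one whose observed
divergence pushes a correction's log argument to or below zero — is reported
as ``math.inf``; downstream consumers treat non-finite entries as the
saturated flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequences import SequenceRecord

MODELS = ("p", "jc", "k2p")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _site_counts(a: str, b: str) -> tuple[int, int, int]:
    """Comparable sites, transitions, transversions under pairwise deletion."""
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x in "N-" or y in "N-":
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def distance_from_counts(
    n_sites: int, transitions: int, transversions: int, model: str = "k2p"
) -> float:
    """Distance from per-pair substitution counts.

    Exposed separately so closed-form checks can hit the arithmetic directly.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if n_sites < 1:
        raise ValueError("need at least one comparable site")
    p = (transitions + transversions) / n_sites
    if model == "p":
        return p
    if model == "jc":
        arg = 1.0 - 4.0 * p / 3.0
        return math.inf if arg <= 0 else -0.75 * math.log(arg)
    P = transitions / n_sites
    Q = transversions / n_sites
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        return math.inf
    return 0.5 * math.log(1.0 / a1) + 0.25 * math.log(1.0 / a2)


def pairwise_distance(
    a: SequenceRecord, b: SequenceRecord, model: str = "k2p"
) -> float:
    """Distance between two aligned records; ``inf`` flags saturation."""
    if len(a) != len(b):
        raise ValueError(
            f"unequal aligned lengths: {a.id!r} has {len(a)}, {b.id!r} has {len(b)}"
        )
    n, ts, tv = _site_counts(a.bases, b.bases)
    if n == 0:
        raise ValueError(
            f"no comparable columns between {a.id!r} and {b.id!r} "
            "after pairwise deletion"
        )
    return distance_from_counts(n, ts, tv, model)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distance matrix keyed by taxon id.

    ``inf`` entries mark saturated pairs; the diagonal is zero.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite]):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v[finite] < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, taxon: str) -> int:
        return self.ids.index(taxon)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.index(pair[0]), self.index(pair[1]))
        return float(self.values[i, j])

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if not math.isfinite(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


def distance_matrix(
    records: Sequence[SequenceRecord], model: str = "k2p"
) -> DistanceMatrix:
    """All-pairs distances over aligned records, pairwise deletion per pair."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")
    n = len(records)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(records[i], records[j], model)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(tuple(ids), m)
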