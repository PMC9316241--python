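"""Distance-based species assignment against a labeled reference panel.

A query is assigned the species of its nearest reference (species distance =
minimum over that species' references). The approach is reliable exactly when
the panel shows a barcode gap — maximum within-species distance strictly below
minimum between-species distance — which :func:`panel_separability` checks and
reports before anyone trusts an assignment. Support comes from a
column-resampling bootstrap, and :func:`audit_labels` screens labeled
collections (e.g. public-database accessions) for records whose assignment
contradicts their claimed species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distance import distance_from_counts, pairwise_distance, _site_counts
from .sequences import ReferencePanel, SequenceRecord

#: Two species distances closer than this are an assignment tie.
TIE_TOLERANCE = 1e-12
DEFAULT_BOOTSTRAP = 1000


@dataclass(frozen=True)
class AssignmentResult:
    query_id: str
    assigned_species: Optional[str]
    nearest_distance: float
    margin: float
    bootstrap_support: Optional[float]
    flags: frozenset[str] = frozenset({"ok"})

    @property
    def ok(self) -> bool:
        return "ok" in self.flags


@dataclass(frozen=True)
class SeparabilityReport:
    max_within: float
    min_between: float
    gap: float
    passed: bool
    worst_pair: Optional[tuple[str, str]] = None


@dataclass(frozen=True)
class MismatchReport:
    record_id: str
    claimed_label: str
    assigned_species: Optional[str]
    distance: float
    margin: float


def _species_distances(
    query: SequenceRecord, panel: ReferencePanel, model: str
) -> dict[str, float]:
    return {
        sp: min(pairwise_distance(query, ref, model) for ref in refs)
        for sp, refs in panel
    }


def assign_species(
    query: SequenceRecord,
    panel: ReferencePanel,
    model: str = "k2p",
    n_bootstrap: int = 0,
    seed: Optional[int] = None,
) -> AssignmentResult:
    """Assign a query to its nearest-reference species.

    Bootstrap support resamples aligned columns with replacement and reports
    the fraction of replicates whose nearest species agrees with the point
    assignment. ``flags`` is one of {ok, ambiguous, saturated}.
    """
    if len(query) != panel.alignment_length:
        raise ValueError(
            f"query {query.id!r} length {len(query)} != panel alignment "
            f"length {panel.alignment_length}"
        )
    dists = _species_distances(query, panel, model)
    ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
    best_species, best_d = ranked[0]

    if not math.isfinite(best_d):
        return AssignmentResult(
            query.id, None, math.inf, 0.0, None, frozenset({"saturated"})
        )

    margin = (ranked[1][1] - best_d) if len(ranked) > 1 else math.inf
    if margin < TIE_TOLERANCE:
        return AssignmentResult(
            query.id, None, best_d, 0.0, None, frozenset({"ambiguous"})
        )

    support = None
    if n_bootstrap > 0:
        if seed is None:
            raise ValueError("bootstrap requires a seed")
        support = _bootstrap_support(
            query, panel, model, best_species, n_bootstrap, seed
        )

    return AssignmentResult(query.id, best_species, best_d, margin, support)


def _bootstrap_support(
    query: SequenceRecord,
    panel: ReferencePanel,
    model: str,
    point_species: str,
    n_bootstrap: int,
    seed: int,
) -> float:
    """Fraction of column-resampled replicates agreeing with the assignment."""
    rng = np.random.default_rng(seed)
    L = panel.alignment_length
    q = np.frombuffer(query.bases.encode(), dtype="S1")
    refs = [
        (sp, np.frombuffer(r.bases.encode(), dtype="S1"))
        for sp, recs in panel
        for r in recs
    ]
    agree = 0
    for _ in range(n_bootstrap):
        cols = rng.integers(0, L, size=L)
        qb = q[cols].tobytes().decode()
        best_sp, best_d = None, math.inf
        for sp, arr in refs:
            rb = arr[cols].tobytes().decode()
            n, ts, tv = _site_counts(qb, rb)
            if n == 0:
                continue
            d = distance_from_counts(n, ts, tv, model)
            if d < best_d:
                best_sp, best_d = sp, d
        if best_sp == point_species:
            agree += 1
    return agree / n_bootstrap


def assign_all(
    queries: Sequence[SequenceRecord],
    panel: ReferencePanel,
    model: str = "k2p",
    n_bootstrap: int = 0,
    seed: Optional[int] = None,
) -> list[AssignmentResult]:
    """Assign every query; per-query bootstrap seeds split from ``seed``."""
    results = []
    for k, q in enumerate(queries):
        sub = None if seed is None else (seed + k) % (2**31)
        results.append(assign_species(q, panel, model, n_bootstrap, sub))
    return results


def panel_separability(
    panel: ReferencePanel, model: str = "k2p"
) -> SeparabilityReport:
    """Barcode-gap check: max within-species vs min between-species distance."""
    if len(panel.species) < 2:
        raise ValueError("separability needs >= 2 species in the panel")
    max_within = 0.0
    min_between = math.inf
    worst: Optional[tuple[str, str]] = None
    records = [(sp, r) for sp, recs in panel for r in recs]
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            (sp_a, a), (sp_b, b) = records[i], records[j]
            d = pairwise_distance(a, b, model)
            if sp_a == sp_b:
                max_within = max(max_within, d)
            elif d < min_between:
                min_between = d
                worst = (a.id, b.id)
    gap = min_between - max_within
    return SeparabilityReport(
        max_within=max_within,
        min_between=min_between,
        gap=gap,
        passed=gap > 0,
        worst_pair=None if gap > 0 else worst,
    )


def audit_labels(
    records: Sequence[SequenceRecord],
    panel: ReferencePanel,
    model: str = "k2p",
) -> list[MismatchReport]:
    """Report every labeled record whose assignment contradicts its label."""
    mismatches = []
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} carries no label to audit")
        if rec.label not in panel:
            raise ValueError(
                f"label {rec.label!r} of record {rec.id!r} is not in the panel"
            )
        res = assign_species(rec, panel, model)
        if res.assigned_species != rec.label:
            mismatches.append(
                MismatchReport(
                    rec.id, rec.label, res.assigned_species,
                    res.nearest_distance, res.margin,
                )
            )
    return mismatches
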