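"""Multi-dataset overlap percentages and Phantom-Peak classification.

Overlap counting is record-based on the query side: a query region
overlapping three target regions counts once. Multi-experiment factor
tracks are expected to be concatenated and merged upstream
(:func:`bmpchip.peaks.merge_factor_datasets`) so the target side cannot
double-count either.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import pandas as pd

from .core import IntervalCollection, intersect_u, subtract_u
from .peaks import merge_factor_datasets

__all__ = [
    "OverlapMatrix",
    "PhantomClassification",
    "percentage_overlap",
    "exclusive_prep",
    "at_least_one",
    "overlap_matrix",
    "phantom_classify",
]


@dataclasses.dataclass
class OverlapMatrix:
    """Query-set x target-factor percentage overlaps (0-100)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.table.to_numpy()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError("overlap percentages must lie in [0, 100]")


@dataclasses.dataclass
class PhantomClassification:
    """Partition of candidate Phantom Peaks into real vs phantom.

    Candidates are the dual-bound regions intersecting a published
    Phantom-Peak list; those present in the antibody-free DamID track
    are reassigned as real, the remainder stay potential phantoms.
    ``pct_phantom`` is relative to the dual-bound set.
    """

    candidates: IntervalCollection
    real: IntervalCollection
    phantom: IntervalCollection
    pct_phantom: float


def percentage_overlap(
    query: IntervalCollection, target: IntervalCollection
) -> float:
    """100 x (query records sharing >=1 bp with target) / |query|."""
    if len(query) == 0:
        raise ValueError("query collection is empty")
    return 100.0 * len(intersect_u(query, target)) / len(query)


def exclusive_prep(
    other: IntervalCollection, bmp: IntervalCollection
) -> IntervalCollection:
    """Remove from an external enhancer set the regions overlapping the
    BMP peaks, so its overlap statistics describe non-BMP regions only."""
    return subtract_u(other, bmp)


def at_least_one(
    query: IntervalCollection, targets: Sequence[IntervalCollection]
) -> float:
    """% of query records overlapping the union of the target tracks."""
    if not targets:
        raise ValueError("need at least one target collection")
    return percentage_overlap(query, merge_factor_datasets(list(targets)))


def overlap_matrix(
    queries: dict[str, IntervalCollection],
    targets: dict[str, IntervalCollection],
) -> OverlapMatrix:
    """Pairwise percentage-overlap table over named query/target sets."""
    data = {
        tname: [percentage_overlap(q, t) for q in queries.values()]
        for tname, t in targets.items()
    }
    return OverlapMatrix(pd.DataFrame(data, index=list(queries)))


def phantom_classify(
    dual_bound: IntervalCollection,
    phantom_list: IntervalCollection,
    damid: IntervalCollection,
) -> PhantomClassification:
    """Classify dual-bound regions against the Phantom-Peak catalogue.

    candidates = dual_bound regions intersecting the phantom list;
    real = candidates present in DamID; phantom = the rest.
    """
    if len(dual_bound) == 0:
        raise ValueError("dual_bound collection is empty")
    candidates = intersect_u(dual_bound, phantom_list)
    real = intersect_u(candidates, damid)
    phantom = subtract_u(candidates, damid)
    return PhantomClassification(
        candidates=candidates,
        real=real,
        phantom=phantom,
        pct_phantom=100.0 * len(phantom) / len(dual_bound),
    )
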