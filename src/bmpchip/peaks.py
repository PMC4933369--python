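"""Final peak-set construction.

Builds the analysis-ready binding-region lists from raw called peaks:
replicate reproducibility filtering, coordinate refinement using the
higher-stringency call set, combination of time points and factors under
explicit coordinate-precedence rules, and the read-track normalization
factors used for browser display.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np

from .core import (
    GenomicInterval,
    IntervalCollection,
    Peak,
    _rec_interval,
    intersect_u,
    merge,
)

__all__ = [
    "StringencyPair",
    "NormalizationFactors",
    "reproducible_peaks",
    "stringency_refine",
    "combine_timepoints",
    "combine_bmp",
    "merge_factor_datasets",
    "normalization_factors",
]


@dataclasses.dataclass
class StringencyPair:
    """Peak calls for one factor/time point at two p-value cutoffs.

    ``loose`` holds the p < 1e-4 calls, ``strict`` the p < 1e-5 calls
    whose narrower coordinates refine the loose regions.
    """

    loose: IntervalCollection
    strict: IntervalCollection


@dataclasses.dataclass
class NormalizationFactors:
    """Per-sample scaling factors that equalize read-track medians.

    factor[i] = mean(all sample medians) / median[i]; multiplying each
    sample by its factor brings every median to the grand mean.
    """

    sample_medians: list[float]
    factors: list[float]


def reproducible_peaks(
    rep1: IntervalCollection, rep2: IntervalCollection, span: str = "rep1"
) -> IntervalCollection:
    """Peaks present in both replicates (>=1 bp overlap).

    ``span="rep1"`` keeps replicate-1 coordinates (default);
    ``span="intersection"`` emits the shared span of each overlapping
    rep1/rep2 pair instead.
    """
    if span == "rep1":
        return intersect_u(rep1, rep2)
    if span != "intersection":
        raise ValueError(f"unknown span mode {span!r}")
    out = []
    for rec in rep1.records:
        iv = _rec_interval(rec)
        for other in rep2.overlapping(iv):
            oiv = _rec_interval(other)
            out.append(
                GenomicInterval(iv.chrom, max(iv.start, oiv.start),
                                min(iv.end, oiv.end), name=iv.name)
            )
    return merge(IntervalCollection(out, name=rep1.name))


def stringency_refine(pair: StringencyPair) -> IntervalCollection:
    """Replace loose-call coordinates with overlapping strict-call ones.

    Every loose peak overlapped by >=1 strict peak is dropped in favor of
    the overlapping strict coordinates (all of them, if several strict
    peaks fall inside one loose region); loose peaks with no strict
    overlap are retained unchanged. Strict peaks overlapping no loose
    peak trigger a warning (they indicate inconsistent call sets) and
    are ignored.
    """
    orphan = [
        s for s in pair.strict.records
        if not pair.loose.overlaps_any(_rec_interval(s))
    ]
    if orphan:
        warnings.warn(
            f"{len(orphan)} strict peak(s) overlap no loose peak; ignored",
            stacklevel=2,
        )
    out = []
    emitted = set()
    for rec in pair.loose.records:
        iv = _rec_interval(rec)
        strict_hits = pair.strict.overlapping(iv)
        if not strict_hits:
            out.append(rec)
        else:
            for s in strict_hits:
                key = id(s)
                if key not in emitted:
                    emitted.add(key)
                    out.append(s)
    return IntervalCollection(out, name=pair.loose.name)


def _as_peak(rec, source: str, extra_sources: Sequence[str] = ()) -> Peak:
    iv = _rec_interval(rec)
    summit = rec.summit if isinstance(rec, Peak) else None
    attrs = tuple(("source:" + s, True) for s in [source, *extra_sources])
    return Peak.from_interval(iv, summit=summit, source=source, attrs=attrs)


def _sources_of(p: Peak) -> set[str]:
    return {k.split(":", 1)[1] for k, v in p.attrs if k.startswith("source:") and v}


def combine_timepoints(
    early: IntervalCollection,
    late: IntervalCollection,
    early_label: str = "early",
    late_label: str = "late",
) -> IntervalCollection:
    """Combine two time points for one factor; late coordinates win.

    Output = every late record (labeled with both time points if some
    early record overlaps it) plus the early records with no late
    overlap. Early records overlapping a late record contribute only
    their label, never their coordinates.
    """
    out = []
    for rec in late.records:
        iv = _rec_interval(rec)
        extra = [early_label] if early.overlaps_any(iv) else []
        out.append(_as_peak(rec, late_label, extra))
    for rec in early.records:
        if not late.overlaps_any(_rec_interval(rec)):
            out.append(_as_peak(rec, early_label))
    return IntervalCollection(out, name=f"{late.name}+{early.name}")


def combine_bmp(
    pmad_early: IntervalCollection,
    pmad_late: IntervalCollection,
    brk_early: IntervalCollection,
    brk_late: IntervalCollection,
) -> IntervalCollection:
    """Build the combined BMP (pMad + Brk, both time points) peak list.

    Coordinate precedence: pMad 3-3.5 h > Brk 3-3.5 h > pMad 2-2.5 h >
    Brk 2-2.5 h. A lower-precedence record overlapping an already
    accepted record contributes only its factor/time-point flag; chains
    of overlaps collapse onto the highest-precedence coordinates. Each
    output record carries ``source:<label>`` attrs for every
    contributing set.
    """
    ordered = [
        ("pMad3", pmad_late),
        ("Brk3", brk_late),
        ("pMad2", pmad_early),
        ("Brk2", brk_early),
    ]
    accepted: list[tuple[Peak, set[str]]] = []
    acc_coll = IntervalCollection(name="bmp")  # rebuilt as we add
    for label, coll in ordered:
        for rec in coll.records:
            iv = _rec_interval(rec)
            hits = acc_coll.overlapping(iv)
            if hits:
                hit_ids = {id(h) for h in hits}
                for peak, flags in accepted:
                    if id(peak) in hit_ids:
                        flags.add(label)
            else:
                peak = _as_peak(rec, label)
                accepted.append((peak, {label}))
                acc_coll = IntervalCollection(
                    [p for p, _ in accepted], name="bmp"
                )
    final = [
        Peak.from_interval(
            p.interval,
            summit=p.summit,
            source=p.source,
            attrs=tuple(("source:" + s, True) for s in sorted(flags)),
        )
        for p, flags in accepted
    ]
    return IntervalCollection(final, name="BMP")


def merge_factor_datasets(
    collections: Sequence[IntervalCollection], name: str = ""
) -> IntervalCollection:
    """Concatenate several source experiments for one factor and merge.

    Used to build a single disjoint interval track per external factor
    so overlap percentages cannot double-count across experiments.
    """
    if not collections:
        raise ValueError("need at least one collection")
    pooled = [rec for coll in collections for rec in coll.records]
    return merge(IntervalCollection(pooled, name=name or collections[0].name))


def normalization_factors(sample_medians: Sequence[float]) -> NormalizationFactors:
    """Correction factors: mean of all medians divided by each sample median."""
    med = np.asarray(sample_medians, dtype=float)
    if med.size == 0:
        raise ValueError("need at least one sample median")
    if np.any(med <= 0):
        raise ValueError("sample medians must be positive")
    factors = med.mean() / med
    return NormalizationFactors(
        sample_medians=list(map(float, med)), factors=list(map(float, factors))
    )
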