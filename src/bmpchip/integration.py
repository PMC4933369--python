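"""Gene <-> peak association and its significance tests.

Distances are measured between a peak's summit and a gene's
transcription start site (TSS), on the same chromosome, with an
inclusive window boundary (|TSS - summit| <= d). Association strength
is assessed on the 2x2 table {DE, non-DE} x {near, not near} with
Pearson's chi-square (no continuity correction) and a one-sided
binomial test of whether DE genes are more often near a summit than the
non-DE rate predicts.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneRecord, IntervalCollection, Peak, _rec_interval

__all__ = [
    "AssociationConfig",
    "AssociationResult",
    "gene_to_peak",
    "peak_to_gene",
    "association_test",
    "proximity_fractions",
]

DEFAULT_DISTANCES = (5_000, 10_000, 20_000, 40_000)


@dataclasses.dataclass(frozen=True)
class AssociationConfig:
    """Window half-widths (bp) and the anchors used on each side."""

    distances: tuple[int, ...] = DEFAULT_DISTANCES
    peak_anchor: str = "summit"
    gene_anchor: str = "tss"

    def __post_init__(self) -> None:
        d = self.distances
        if not d or any(x <= 0 for x in d) or list(d) != sorted(d):
            raise ValueError("distances must be positive and ascending")


@dataclasses.dataclass
class AssociationResult:
    """2x2 near/DE counts at one distance, with test p-values."""

    distance: int
    near_de: int
    near_nonde: int
    tot_de: int
    tot_nonde: int
    chi2_stat: float
    chi2_p: float
    binom_p: float
    frac_peaks_with_de: float
    degenerate_null: bool = False

    def table(self) -> np.ndarray:
        """The 2x2 contingency table [[near, far] x [DE, non-DE]]."""
        return np.array(
            [
                [self.near_de, self.tot_de - self.near_de],
                [self.near_nonde, self.tot_nonde - self.near_nonde],
            ]
        )


def _summit(rec) -> int:
    if isinstance(rec, Peak):
        return rec.summit
    iv = _rec_interval(rec)
    return (iv.start + iv.end) // 2


def _peak_id(rec, idx: int) -> str:
    iv = _rec_interval(rec)
    return iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"


def _summits_by_chrom(peaks: IntervalCollection):
    """Sorted summit arrays and peak ids, keyed by chromosome."""
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for i, rec in enumerate(peaks.records):
        iv = _rec_interval(rec)
        by_chrom.setdefault(iv.chrom, []).append((_summit(rec), _peak_id(rec, i)))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out[chrom] = (
            np.array([s for s, _ in pairs]),
            [pid for _, pid in pairs],
        )
    return out


def gene_to_peak(
    peaks: IntervalCollection, genes: Sequence[GeneRecord], d: int
) -> pd.DataFrame:
    """All (peak, gene) pairs with |TSS - summit| <= d on one chromosome.

    Returns a pairing table with columns ``peak_id``, ``gene_id`` and
    ``distance`` (signed, TSS minus summit).
    """
    summits = _summits_by_chrom(peaks)
    rows = []
    for g in genes:
        if g.chrom not in summits:
            continue
        pos, ids = summits[g.chrom]
        lo = int(np.searchsorted(pos, g.tss - d, side="left"))
        hi = int(np.searchsorted(pos, g.tss + d, side="right"))
        for k in range(lo, hi):
            rows.append((ids[k], g.gene_id, int(g.tss - pos[k])))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])


def peak_to_gene(
    peaks: IntervalCollection,
    genes: Sequence[GeneRecord],
    d: int,
    gene_subset: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Summit-TSS pairs restricted to DE genes (or an explicit subset)."""
    if gene_subset is not None:
        keep = set(gene_subset)
        sub = [g for g in genes if g.gene_id in keep]
    else:
        sub = [g for g in genes if g.is_de]
    return gene_to_peak(peaks, sub, d)


def _near_flags(
    peaks: IntervalCollection, genes: Sequence[GeneRecord], d: int
) -> np.ndarray:
    """Boolean per gene: >=1 summit within d of its TSS. Genes on
    chromosomes carrying no peak count as not near (never dropped)."""
    summits = {c: v[0] for c, v in _summits_by_chrom(peaks).items()}
    flags = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        pos = summits.get(g.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, g.tss - d, side="left")
        hi = np.searchsorted(pos, g.tss + d, side="right")
        flags[i] = hi > lo
    return flags


def _peaks_with_de_fraction(
    peaks: IntervalCollection, genes: Sequence[GeneRecord], d: int
) -> float:
    if len(peaks) == 0:
        return 0.0
    de_tss: dict[str, np.ndarray] = {}
    for g in genes:
        if g.is_de:
            de_tss.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    de_tss = {c: np.sort(np.array(v)) for c, v in de_tss.items()}
    n_hit = 0
    for rec in peaks.records:
        iv = _rec_interval(rec)
        tss = de_tss.get(iv.chrom)
        if tss is None:
            continue
        s = _summit(rec)
        if np.searchsorted(tss, s + d, side="right") > np.searchsorted(
            tss, s - d, side="left"
        ):
            n_hit += 1
    return n_hit / len(peaks)


def association_test(
    peaks: IntervalCollection, genes: Sequence[GeneRecord], d: int
) -> AssociationResult:
    """Test whether DE genes lie nearer to peak summits than non-DE genes.

    Builds the 2x2 table of {DE, non-DE} x {>=1 summit within d of TSS,
    none}; reports Pearson's chi-square (df=1, two-sided, no continuity
    correction) and a one-sided upper-tail binomial test of >= near_de
    successes in tot_de trials at success probability
    near_nonde / tot_nonde.
    """
    is_de = np.array([g.is_de for g in genes])
    tot_de, tot_nonde = int(is_de.sum()), int((~is_de).sum())
    if tot_de < 1 or tot_nonde < 1:
        raise ValueError("need at least one DE and one non-DE gene")
    near = _near_flags(peaks, genes, d)
    near_de = int((near & is_de).sum())
    near_nonde = int((near & ~is_de).sum())

    table = np.array(
        [[near_de, tot_de - near_de], [near_nonde, tot_nonde - near_nonde]]
    )
    if table.sum(axis=0).min() == 0:
        # a zero column (all near or none near): no association detectable
        chi2_stat, chi2_p = 0.0, 1.0
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)

    degenerate = near_nonde == 0 and near_de > 0
    if degenerate:
        binom_p = 0.0
    else:
        p0 = near_nonde / tot_nonde
        binom_p = float(
            stats.binomtest(near_de, tot_de, p0, alternative="greater").pvalue
        )

    return AssociationResult(
        distance=d,
        near_de=near_de,
        near_nonde=near_nonde,
        tot_de=tot_de,
        tot_nonde=tot_nonde,
        chi2_stat=float(chi2_stat),
        chi2_p=float(chi2_p),
        binom_p=binom_p,
        frac_peaks_with_de=_peaks_with_de_fraction(peaks, genes, d),
        degenerate_null=degenerate,
    )


def proximity_fractions(
    peaks: IntervalCollection,
    genes: Sequence[GeneRecord],
    config: AssociationConfig = AssociationConfig(),
) -> pd.DataFrame:
    """Per distance: % peaks with a DE gene in the window and % DE genes
    with a summit in the window. Both are non-decreasing in distance."""
    de_genes = [g for g in genes if g.is_de]
    rows = []
    for d in config.distances:
        pct_peaks = 100.0 * _peaks_with_de_fraction(peaks, genes, d)
        if de_genes:
            pct_genes = 100.0 * float(_near_flags(peaks, de_genes, d).mean())
        else:
            pct_genes = 0.0
        rows.append((d, pct_peaks, pct_genes))
    return pd.DataFrame(
        rows, columns=["distance", "pct_peaks_with_de_gene", "pct_de_genes_with_peak"]
    )
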