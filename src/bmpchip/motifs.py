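"""Summit-centered motif occurrence and enrichment vs control enhancers.

A motif is an IUPAC consensus (e.g. the Zld sites CAGGTAG / CAGGTAA, or
Mad/Med/Brk consensus strings supplied by configuration). Occurrence is
binary per window: a 250 bp summit-centered window "contains" the motif
if the consensus matches at any offset on either strand. Enrichment is
the ratio of containment percentages in test windows vs a control set
(housekeeping enhancers), with a two-tailed Fisher's exact p-value.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from collections.abc import Mapping, Sequence
from pathlib import Path
from typing import Optional, Union

from scipy import stats

from .core import IntervalCollection, Peak, _rec_interval

__all__ = [
    "MotifConsensus",
    "EnrichmentResult",
    "IUPAC",
    "reverse_complement",
    "extract_summit_windows",
    "scan_motif",
    "fisher_two_tailed",
    "enrichment",
]

logger = logging.getLogger(__name__)

WINDOW_FLANK = 125  # bp either side of the summit

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class MotifConsensus:
    """A named IUPAC consensus string."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC symbols in consensus: {sorted(bad)}")

    def _pattern(self, consensus: str) -> re.Pattern:
        # character classes over ACGT only, so N in the *sequence*
        # matches nothing
        return re.compile(
            "".join(f"[{IUPAC[c]}]" for c in consensus.upper())
        )

    @property
    def forward(self) -> re.Pattern:
        return self._pattern(self.consensus)

    @property
    def reverse(self) -> re.Pattern:
        return self._pattern(reverse_complement(self.consensus))


@dataclasses.dataclass
class EnrichmentResult:
    """Motif containment percentages, their ratio and Fisher's exact p.

    ``ratio`` is pct_test / pct_control; ``inf`` (flagged by
    ``control_empty``) when no control window contains the motif.
    """

    motif: str
    pct_test: float
    pct_control: float
    ratio: float
    fisher_p: float
    n_test: int
    n_control: int
    control_empty: bool = False


def extract_summit_windows(
    peaks: IntervalCollection,
    genome: Union[Mapping[str, str], str, Path],
    flank: int = WINDOW_FLANK,
) -> list[str]:
    """One uppercase (2*flank) bp sequence per peak, centered on its summit.

    ``genome`` is a chrom -> sequence mapping or a FASTA path (indexed
    with pyfaidx). Peaks whose window would run off a chromosome end are
    skipped with a logged warning.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome))
        lengths = {name: len(fa[name]) for name in fa.keys()}

        def fetch(chrom: str, start: int, end: int) -> str:
            return str(fa[chrom][start:end])
    else:
        lengths = {c: len(s) for c, s in genome.items()}

        def fetch(chrom: str, start: int, end: int) -> str:
            return genome[chrom][start:end]

    windows = []
    for rec in peaks.records:
        iv = _rec_interval(rec)
        summit = rec.summit if isinstance(rec, Peak) else (iv.start + iv.end) // 2
        start, end = summit - flank, summit + flank
        if iv.chrom not in lengths:
            logger.warning("chromosome %s absent from genome; peak skipped", iv.chrom)
            continue
        if start < 0 or end > lengths[iv.chrom]:
            logger.warning(
                "summit window [%d, %d) off end of %s (length %d); peak skipped",
                start, end, iv.chrom, lengths[iv.chrom],
            )
            continue
        windows.append(fetch(iv.chrom, start, end).upper())
    return windows


def scan_motif(seq: str, motif: MotifConsensus) -> bool:
    """True iff the consensus matches anywhere on either strand of seq."""
    seq = seq.upper()
    return bool(motif.forward.search(seq) or motif.reverse.search(seq))


def fisher_two_tailed(table) -> float:
    """Two-tailed Fisher's exact p on a 2x2 table (the route used by
    :func:`enrichment`): sum of all hypergeometric tables with the same
    margins whose probability does not exceed the observed one."""
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def enrichment(
    test_windows: Sequence[str],
    control_windows: Sequence[str],
    motif: MotifConsensus,
) -> EnrichmentResult:
    """Motif enrichment of test windows over the control set.

    Fisher's exact test is two-tailed on the 2x2 table
    (with/without motif) x (test/control).
    """
    if not test_windows or not control_windows:
        raise ValueError("test and control window lists must be non-empty")
    k_test = sum(scan_motif(s, motif) for s in test_windows)
    k_ctrl = sum(scan_motif(s, motif) for s in control_windows)
    n_test, n_ctrl = len(test_windows), len(control_windows)
    pct_test = 100.0 * k_test / n_test
    pct_ctrl = 100.0 * k_ctrl / n_ctrl
    control_empty = k_ctrl == 0
    ratio = float("inf") if control_empty else pct_test / pct_ctrl
    if control_empty and k_test == 0:
        ratio = 1.0  # neither set contains it: no enrichment either way
        control_empty = False
    table = [[k_test, n_test - k_test], [k_ctrl, n_ctrl - k_ctrl]]
    fisher_p = fisher_two_tailed(table)
    return EnrichmentResult(
        motif=motif.name,
        pct_test=pct_test,
        pct_control=pct_ctrl,
        ratio=ratio,
        fisher_p=float(fisher_p),
        n_test=n_test,
        n_control=n_ctrl,
        control_empty=control_empty,
    )
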