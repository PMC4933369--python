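"""Genomic coordinate model, interval algebra and file readers/writers.

All internal coordinates are 0-based, half-open (BED convention). Tabular
coordinates coming from browser-style spreadsheets are treated as 1-based,
fully-closed and converted on read (configurable).

The interval algebra mirrors the BEDTools operations the downstream
analyses are built on: ``intersect -u`` style membership queries and
book-ended ``merge``.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Sequence
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneRecord",
    "IntervalCollection",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_supplementary_xlsx",
    "intersect_u",
    "subtract_u",
    "merge",
    "normalize_chrom",
]

DE_STATUSES = ("up", "down", "not_de")


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A half-open span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclasses.dataclass(frozen=True)
class Peak:
    """A ChIP binding region with its summit (base of maximal signal).

    ``source`` labels the factor and time point (e.g. ``pMad/2-2.5h``);
    ``stringency`` records the peak-calling p-value cutoff tier
    (``p4`` = 1e-4, ``p5`` = 1e-5). ``attrs`` carries annotation flags
    (e.g. overlap columns from a supplementary workbook).
    """

    interval: GenomicInterval
    summit: int
    source: str = ""
    stringency: str = "p4"
    attrs: tuple = ()

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, "
                f"{self.interval.end}) on {self.interval.chrom}"
            )
        if self.stringency not in ("p4", "p5"):
            raise ValueError(f"unknown stringency {self.stringency!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @classmethod
    def from_interval(
        cls,
        iv: GenomicInterval,
        summit: Optional[int] = None,
        source: str = "",
        stringency: str = "p4",
        attrs: tuple = (),
    ) -> "Peak":
        # midpoint fallback when no summit is recorded
        if summit is None:
            summit = (iv.start + iv.end) // 2
        return cls(iv, summit, source, stringency, attrs)


Record = Union[GenomicInterval, Peak]


def _rec_interval(rec: Record) -> GenomicInterval:
    return rec.interval if isinstance(rec, Peak) else rec


def _rec_key(rec: Record) -> tuple:
    iv = _rec_interval(rec)
    return (iv.chrom, iv.start, iv.end)


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """A TSS-anchored gene with its differential-expression call.

    ``de_status`` is ``up``/``down`` for genes passing the expression
    screen (adjusted p < 0.03) or ``not_de`` otherwise.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    de_status: str = "not_de"
    adj_p: Optional[float] = None

    DE_P_CUTOFF = 0.03

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.de_status not in DE_STATUSES:
            raise ValueError(
                f"unknown de_status {self.de_status!r} for {self.gene_id}"
            )
        if (
            self.de_status in ("up", "down")
            and self.adj_p is not None
            and self.adj_p >= self.DE_P_CUTOFF
        ):
            raise ValueError(
                f"{self.gene_id}: de_status={self.de_status} requires "
                f"adj_p < {self.DE_P_CUTOFF}, got {self.adj_p}"
            )

    @property
    def is_de(self) -> bool:
        return self.de_status in ("up", "down")


class IntervalCollection:
    """A named, per-chromosome position-sorted set of interval records.

    Records may be plain :class:`GenomicInterval` or :class:`Peak`
    objects; they are kept sorted by (chrom, start, end).
    """

    def __init__(self, records: Iterable[Record] = (), name: str = ""):
        self.name = name
        self.records: list[Record] = sorted(records, key=_rec_key)
        self._trees: Optional[dict[str, IntervalTree]] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalCollection):
            return NotImplemented
        return [_rec_key(r) for r in self.records] == [
            _rec_key(r) for r in other.records
        ]

    def __repr__(self) -> str:
        return f"IntervalCollection({self.name!r}, n={len(self)})"

    def intervals(self) -> list[GenomicInterval]:
        return [_rec_interval(r) for r in self.records]

    def chroms(self) -> list[str]:
        return sorted({_rec_interval(r).chrom for r in self.records})

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries (cached)."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for rec in self.records:
                iv = _rec_interval(rec)
                trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, rec
                )
            self._trees = trees
        return self._trees

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        tree = self.trees().get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    def overlapping(self, iv: GenomicInterval) -> list[Record]:
        tree = self.trees().get(iv.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        return sorted(hits, key=_rec_key)


def normalize_chrom(name: str, style: Optional[str] = None) -> str:
    """Normalize a chromosome name to ``"chr"``-prefixed or bare style.

    ``style`` is ``"chr"``, ``"plain"`` or None (leave unchanged).
    Mismatched naming between tracks is the most common silent failure
    in interval overlap work, so every reader accepts this flag.
    """
    if style is None:
        return name
    bare = name[3:] if name.lower().startswith("chr") else name
    if style == "chr":
        return "chr" + bare
    if style == "plain":
        return bare
    raise ValueError(f"unknown chromosome style {style!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bed(
    path: Union[str, Path],
    name: str = "",
    chrom_style: Optional[str] = None,
    summit_col: Optional[int] = None,
) -> IntervalCollection:
    """Read a BED (3+ column) file into an IntervalCollection.

    BED is 0-based half-open and is preserved verbatim. An optional 4th
    column becomes the record name. ``summit_col`` (0-based column
    index) names a column holding the summit *offset from start*; when
    given, records become :class:`Peak` objects.
    """
    path = Path(path)
    records: list[Record] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = normalize_chrom(fields[0], chrom_style)
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            rec_name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            iv = GenomicInterval(chrom, start, end, name=rec_name)
            if summit_col is not None:
                if summit_col >= len(fields):
                    raise ValueError(
                        f"{path}:{lineno}: summit column {summit_col} missing"
                    )
                records.append(
                    Peak.from_interval(iv, summit=start + int(fields[summit_col]))
                )
            else:
                records.append(iv)
    return IntervalCollection(records, name=name or path.stem)


def write_bed(collection: IntervalCollection, path: Union[str, Path]) -> None:
    """Write records as BED; Peaks gain name and summit-offset columns."""
    with open(path, "w") as fh:
        for rec in collection.records:
            iv = _rec_interval(rec)
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if isinstance(rec, Peak):
                fields.append(iv.name or ".")
                fields.append(str(rec.summit - iv.start))
            elif iv.name is not None:
                fields.append(iv.name)
            fh.write("\t".join(fields) + "\n")


_GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "de_status", "adj_p"]


def read_gene_table(
    path: Union[str, Path], chrom_style: Optional[str] = None
) -> list[GeneRecord]:
    """Read a TSV gene table (gene_id, chrom, tss, strand, de_status, adj_p)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        adj_p = getattr(row, "adj_p", None)
        if adj_p is not None and pd.isna(adj_p):
            adj_p = None
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                chrom=normalize_chrom(str(row.chrom), chrom_style),
                tss=int(row.tss),
                strand=str(row.strand),
                de_status=str(row.de_status),
                adj_p=None if adj_p is None else float(adj_p),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.tss, g.strand, g.de_status, g.adj_p)
            for g in genes
        ],
        columns=_GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def _find_column(df: pd.DataFrame, candidates: Sequence[str]) -> Optional[str]:
    lowered = {str(c).strip().lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def read_supplementary_xlsx(
    path: Union[str, Path],
    sheet: str,
    schema: str,
    exclude: Iterable[str] = (),
    one_based: bool = True,
    chrom_style: Optional[str] = None,
    source: str = "",
):
    """Read a supplementary workbook sheet of peaks or genes.

    ``schema`` is ``"peaks"`` (chromosome/start/end plus optional summit
    and annotation columns, retained as boolean attrs) or ``"genes"``
    (gene id, chromosome, TSS, strand, DE direction, adjusted p).
    Spreadsheet coordinates are treated as 1-based inclusive and
    converted to 0-based half-open unless ``one_based=False``.
    ``exclude`` drops rows whose gene id / name matches (e.g. transgene
    artifacts).
    """
    xls = pd.ExcelFile(path, engine="openpyxl")
    if sheet not in xls.sheet_names:
        raise ValueError(
            f"unknown sheet {sheet!r}; available: {', '.join(xls.sheet_names)}"
        )
    df = xls.parse(sheet)
    exclude = {str(e).lower() for e in exclude}
    offset = 1 if one_based else 0

    if schema == "peaks":
        chrom_c = _find_column(df, ["chrom", "chromosome", "chr"])
        start_c = _find_column(df, ["start", "peak start", "region start"])
        end_c = _find_column(df, ["end", "peak end", "region end"])
        if not (chrom_c and start_c and end_c):
            raise ValueError(
                f"sheet {sheet!r}: peak schema needs chromosome/start/end columns"
            )
        summit_c = _find_column(df, ["summit"])
        name_c = _find_column(df, ["name", "peak id", "region"])
        meta = {chrom_c, start_c, end_c, summit_c, name_c} - {None}
        attr_cols = [c for c in df.columns if c not in meta]
        peaks = []
        for _, row in df.iterrows():
            nm = str(row[name_c]) if name_c else None
            if nm is not None and nm.lower() in exclude:
                continue
            iv = GenomicInterval(
                normalize_chrom(str(row[chrom_c]), chrom_style),
                int(row[start_c]) - offset,
                int(row[end_c]),
                name=nm,
            )
            summit = None
            if summit_c is not None and not pd.isna(row[summit_c]):
                summit = int(row[summit_c]) - offset
            attrs = tuple(
                (str(c), bool(row[c])) for c in attr_cols if not pd.isna(row[c])
            )
            peaks.append(
                Peak.from_interval(iv, summit=summit, source=source or sheet,
                                   attrs=attrs)
            )
        return IntervalCollection(peaks, name=source or sheet)

    if schema == "genes":
        gene_c = _find_column(df, ["gene_id", "gene id", "gene", "symbol"])
        chrom_c = _find_column(df, ["chrom", "chromosome", "chr"])
        tss_c = _find_column(df, ["tss", "transcription start site", "start"])
        strand_c = _find_column(df, ["strand"])
        de_c = _find_column(df, ["de_status", "direction", "regulation"])
        p_c = _find_column(df, ["adj_p", "adjusted p", "padj", "adjusted p-value"])
        if not (gene_c and chrom_c and tss_c):
            raise ValueError(
                f"sheet {sheet!r}: gene schema needs gene id/chromosome/tss columns"
            )
        genes = []
        for _, row in df.iterrows():
            gid = str(row[gene_c])
            if gid.lower() in exclude:
                continue
            de = str(row[de_c]).lower() if de_c else "not_de"
            de = {"upregulated": "up", "downregulated": "down"}.get(de, de)
            adj_p = None
            if p_c is not None and not pd.isna(row[p_c]):
                adj_p = float(row[p_c])
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    chrom=normalize_chrom(str(row[chrom_c]), chrom_style),
                    tss=int(row[tss_c]) - offset,
                    strand=str(row[strand_c]) if strand_c else "+",
                    de_status=de,
                    adj_p=adj_p,
                )
            )
        return genes

    raise ValueError(f"unknown schema {schema!r}; expected 'peaks' or 'genes'")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def intersect_u(a: IntervalCollection, b: IntervalCollection) -> IntervalCollection:
    """Records of ``a`` sharing >=1 base with any record of ``b``.

    Equivalent to ``bedtools intersect -u``: each qualifying record of
    ``a`` is reported once, with its original coordinates, in order.
    """
    hits = [rec for rec in a.records if b.overlaps_any(_rec_interval(rec))]
    return IntervalCollection(hits, name=a.name)


def subtract_u(a: IntervalCollection, b: IntervalCollection) -> IntervalCollection:
    """Records of ``a`` sharing no base with any record of ``b`` (complement
    of :func:`intersect_u`; whole records are kept or dropped, never clipped)."""
    miss = [rec for rec in a.records if not b.overlaps_any(_rec_interval(rec))]
    return IntervalCollection(miss, name=a.name)


def merge(a: IntervalCollection) -> IntervalCollection:
    """Union overlapping or book-ended records per chromosome.

    Matches ``bedtools merge`` defaults (join at distance 0). Output is
    disjoint, sorted plain intervals; idempotent.
    """
    merged: list[GenomicInterval] = []
    cur: Optional[list] = None  # [chrom, start, end]
    for rec in a.records:
        iv = _rec_interval(rec)
        if cur is not None and iv.chrom == cur[0] and iv.start <= cur[2]:
            cur[2] = max(cur[2], iv.end)
        else:
            if cur is not None:
                merged.append(GenomicInterval(*cur))
            cur = [iv.chrom, iv.start, iv.end]
    if cur is not None:
        merged.append(GenomicInterval(*cur))
    return IntervalCollection(merged, name=a.name)
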