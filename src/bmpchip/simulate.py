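"""Seeded synthetic regulatory-genomics data with planted structure.

The generator emulates the statistical shape of an embryo ChIP-seq /
RNA-seq study: a small multi-chromosome genome, a gene set with a
differentially-expressed (DE) subset, peak sets whose summits are
enriched near DE-gene TSSs with a configurable effect size, a noisy
second replicate, sequences with a motif planted at different rates in
test vs control windows, and interval tracks with a configurable
overlap fraction. Everything is deterministic under the seed.

The DE placement rule is exact by construction: a DE gene falls inside
the union of +/- d0 summit windows with probability
p_near + (1 - p_near) * b where b is the genomic fraction covered by
those windows and p_near = (effect - 1) * b / (1 - b), which makes the
DE near-rate equal effect * b and hence the DE/non-DE near-rate ratio
equal the configured proximity_effect.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import GeneRecord, GenomicInterval, IntervalCollection, Peak, merge

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_genes_and_peaks",
    "simulate_tracks",
    "simulate_motif_windows",
    "write_fasta",
    "write_workbook",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the default scale chosen
    so a full generate-analyze round trip runs in seconds.

    proximity_effect is the planted DE/non-DE near-rate ratio within
    ``d0`` bp of a peak summit; replicate 2 is replicate 1 with
    Gaussian summit jitter (sd ``replicate_jitter_sd`` bp) and Bernoulli
    peak dropout.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    n_genes: int = 2000
    de_fraction: float = 0.15
    n_peaks: int = 300
    proximity_effect: float = 3.0
    d0: int = 5_000
    peak_width: tuple[int, int] = (200, 600)
    replicate_jitter_sd: float = 20.0
    replicate_dropout: float = 0.1
    motif_rate_test: float = 0.4
    motif_rate_control: float = 0.1
    track_overlap_fraction: float = 0.6
    gc_content: float = 0.42

    def __post_init__(self) -> None:
        for prop in (
            self.de_fraction,
            self.replicate_dropout,
            self.motif_rate_test,
            self.motif_rate_control,
            self.track_overlap_fraction,
            self.gc_content,
        ):
            if not 0.0 <= prop <= 1.0:
                raise ValueError(f"proportion {prop} outside [0, 1]")
        if any(ln <= 0 for ln in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.proximity_effect < 1.0:
            raise ValueError("proximity_effect must be >= 1")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths)


def simulate_genome(cfg: SimulationConfig) -> dict[str, str]:
    """I.i.d. bases at the configured GC content, one string per chromosome."""
    rng = np.random.default_rng(cfg.seed)
    at, gc = (1.0 - cfg.gc_content) / 2.0, cfg.gc_content / 2.0
    genome = {}
    for name, length in zip(cfg.chrom_names, cfg.chrom_lengths):
        arr = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
        genome[name] = arr.tobytes().decode("ascii")
    return genome


def _weighted_chrom(rng: np.random.Generator, cfg: SimulationConfig, n: int):
    probs = np.array(cfg.chrom_lengths, dtype=float)
    probs /= probs.sum()
    return rng.choice(len(cfg.chrom_lengths), size=n, p=probs)


def _near_region(
    summits: list[tuple[str, int]], cfg: SimulationConfig
) -> IntervalCollection:
    lengths = dict(zip(cfg.chrom_names, cfg.chrom_lengths))
    ivs = [
        GenomicInterval(c, max(0, s - cfg.d0), min(lengths[c], s + cfg.d0 + 1))
        for c, s in summits
    ]
    return merge(IntervalCollection(ivs, name="near"))


def _sample_in_region(
    rng: np.random.Generator, region: IntervalCollection
) -> tuple[str, int]:
    lens = np.array([iv.end - iv.start for iv in region.intervals()])
    cum = np.cumsum(lens)
    offset = int(rng.integers(0, cum[-1]))
    idx = int(np.searchsorted(cum, offset, side="right"))
    iv = region.intervals()[idx]
    inner = offset - (cum[idx] - lens[idx])
    return iv.chrom, iv.start + inner


def simulate_genes_and_peaks(
    cfg: SimulationConfig,
) -> tuple[list[GeneRecord], IntervalCollection, IntervalCollection]:
    """Genes with a DE subset planted near peak summits, plus 2 replicates.

    Returns ``(genes, rep1, rep2)``. Peak summits are uniform over the
    genome (1 kb margins keep summit windows on-chromosome); DE TSSs are
    placed in the union of +/- d0 summit windows with the probability
    that makes the DE/non-DE near-rate ratio equal proximity_effect.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = dict(zip(cfg.chrom_names, cfg.chrom_lengths))
    margin = 1000

    # replicate-1 peaks
    chrom_idx = _weighted_chrom(rng, cfg, cfg.n_peaks)
    peaks1 = []
    summits: list[tuple[str, int]] = []
    for i in range(cfg.n_peaks):
        chrom = cfg.chrom_names[chrom_idx[i]]
        summit = int(rng.integers(margin, lengths[chrom] - margin))
        width = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
        start = max(0, summit - width // 2)
        end = min(lengths[chrom], start + width)
        iv = GenomicInterval(chrom, start, end, name=f"peak{i:04d}")
        peaks1.append(Peak.from_interval(iv, summit=summit, source="rep1"))
        summits.append((chrom, summit))
    rep1 = IntervalCollection(peaks1, name="rep1")

    near = _near_region(summits, cfg)
    covered = sum(len(iv) for iv in near.intervals())
    b = covered / cfg.genome_length
    if b >= 1.0:
        raise ValueError("d0 windows cover the whole genome; placement infeasible")
    p_near = min(1.0, (cfg.proximity_effect - 1.0) * b / (1.0 - b))

    n_de = int(round(cfg.n_genes * cfg.de_fraction))
    genes = []
    for i in range(cfg.n_genes):
        is_de = i < n_de
        if is_de and rng.random() < p_near:
            chrom, tss = _sample_in_region(rng, near)
        else:
            ci = int(_weighted_chrom(rng, cfg, 1)[0])
            chrom = cfg.chrom_names[ci]
            tss = int(rng.integers(0, lengths[chrom]))
        if is_de:
            status = "up" if rng.random() < 0.5 else "down"
            adj_p = float(rng.uniform(0.0, GeneRecord.DE_P_CUTOFF))
        else:
            status, adj_p = "not_de", float(rng.uniform(0.03, 1.0))
        genes.append(
            GeneRecord(
                gene_id=f"g{i:05d}",
                chrom=chrom,
                tss=tss,
                strand="+" if rng.random() < 0.5 else "-",
                de_status=status,
                adj_p=adj_p,
            )
        )

    # replicate 2: jitter + dropout
    peaks2 = []
    for p in peaks1:
        if rng.random() < cfg.replicate_dropout:
            continue
        delta = int(round(rng.normal(0.0, cfg.replicate_jitter_sd)))
        lo, hi = 0, lengths[p.chrom]
        start = max(lo, p.start + delta)
        end = min(hi, p.end + delta)
        summit = min(max(p.summit + delta, start), end - 1)
        iv = GenomicInterval(p.chrom, start, end, name=p.interval.name)
        peaks2.append(Peak.from_interval(iv, summit=summit, source="rep2"))
    rep2 = IntervalCollection(peaks2, name="rep2")
    return genes, rep1, rep2


def simulate_tracks(
    cfg: SimulationConfig,
    reference: IntervalCollection,
    seed_offset: int = 1,
) -> IntervalCollection:
    """An interval track overlapping a Bernoulli fraction of reference records.

    Each reference record is overlapped independently with probability
    ``track_overlap_fraction``; an equal-sized complement of decoy
    intervals is placed away from every reference record.
    """
    rng = np.random.default_rng(cfg.seed + seed_offset)
    lengths = dict(zip(cfg.chrom_names, cfg.chrom_lengths))
    width = 400
    track = []
    n_decoy = 0
    for rec in reference.records:
        iv = rec.interval if isinstance(rec, Peak) else rec
        if rng.random() < cfg.track_overlap_fraction:
            anchor = int(rng.integers(iv.start, iv.end))
            start = max(0, anchor - width // 2)
            end = min(lengths[iv.chrom], start + width)
            track.append(GenomicInterval(iv.chrom, start, end))
        else:
            n_decoy += 1
    for _ in range(n_decoy):
        for _attempt in range(1000):
            ci = int(_weighted_chrom(rng, cfg, 1)[0])
            chrom = cfg.chrom_names[ci]
            start = int(rng.integers(0, lengths[chrom] - width))
            cand = GenomicInterval(chrom, start, start + width)
            if not reference.overlaps_any(cand):
                track.append(cand)
                break
        else:  # pragma: no cover - genome saturated with reference records
            raise RuntimeError("could not place decoy interval off-reference")
    return IntervalCollection(track, name="track")


def simulate_motif_windows(
    cfg: SimulationConfig,
    motif: str,
    n_test: int = 200,
    n_control: int = 200,
    window: int = 250,
    seed_offset: int = 2,
) -> tuple[list[str], list[str]]:
    """Random windows with the motif planted at the test/control rates.

    The motif (a literal ACGT string here) is inserted at a random
    offset in a Bernoulli-selected subset of each window list.
    """
    rng = np.random.default_rng(cfg.seed + seed_offset)
    at, gc = (1.0 - cfg.gc_content) / 2.0, cfg.gc_content / 2.0

    def make(n: int, rate: float) -> list[str]:
        out = []
        for _ in range(n):
            arr = rng.choice(_BASES, size=window, p=[at, gc, gc, at])
            seq = arr.tobytes().decode("ascii")
            if rng.random() < rate:
                pos = int(rng.integers(0, window - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
            out.append(seq)
        return out

    return make(n_test, cfg.motif_rate_test), make(n_control, cfg.motif_rate_control)


def write_fasta(
    genome: dict[str, str], path: Union[str, Path], width: int = 80
) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_workbook(
    sheets: dict[str, Union[IntervalCollection, list]],
    path: Union[str, Path],
    one_based: bool = True,
) -> None:
    """Write peak collections / gene lists as a supplementary-style XLSX
    workbook (1-based inclusive coordinates by default), one sheet each."""
    offset = 1 if one_based else 0
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, data in sheets.items():
            if isinstance(data, IntervalCollection):
                rows = []
                for rec in data.records:
                    iv = rec.interval if isinstance(rec, Peak) else rec
                    summit = rec.summit + offset if isinstance(rec, Peak) else None
                    rows.append(
                        (iv.chrom, iv.start + offset, iv.end, iv.name, summit)
                    )
                df = pd.DataFrame(
                    rows, columns=["chromosome", "start", "end", "name", "summit"]
                )
            else:  # gene records
                df = pd.DataFrame(
                    [
                        (
                            g.gene_id,
                            g.chrom,
                            g.tss + offset,
                            g.strand,
                            g.de_status,
                            g.adj_p,
                        )
                        for g in data
                    ],
                    columns=["gene_id", "chromosome", "tss", "strand",
                             "de_status", "adj_p"],
                )
            df.to_excel(writer, sheet_name=name, index=False)
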