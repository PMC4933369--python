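"""End-to-end orchestration: simulate -> peaks -> integrate -> overlap ->
motifs -> report, plus a supplementary-workbook reproduction mode.

Every stage logs its record counts at INFO so any discrepancy against an
expected table can be localized to the stage that introduced it. Reports
are plain JSON with sorted keys, so a fixed seed reproduces them
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .core import (
    IntervalCollection,
    intersect_u,
    read_supplementary_xlsx,
    write_bed,
    write_gene_table,
)
from .integration import (
    AssociationConfig,
    association_test,
    proximity_fractions,
)
from .motifs import MotifConsensus, enrichment
from .overlap import at_least_one, percentage_overlap, phantom_classify
from .peaks import reproducible_peaks
from .simulate import (
    SimulationConfig,
    simulate_genes_and_peaks,
    simulate_motif_windows,
    simulate_tracks,
)

__all__ = ["RunManifest", "run_pipeline", "reproduce_supplementary"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunManifest:
    """What a pipeline run needs: config, registered inputs, output dir.

    ``inputs`` maps logical names to paths of user-supplied files
    (external tracks, workbooks); every registered input must exist
    before any stage runs.
    """

    config: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    distances: tuple[int, ...] = AssociationConfig().distances
    motif: str = "CAGGTAG"
    outdir: Optional[Path] = None
    inputs: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        missing = [
            f"{name} -> {path}"
            for name, path in self.inputs.items()
            if not Path(path).exists()
        ]
        if missing:
            raise FileNotFoundError(
                "missing registered input(s): " + "; ".join(missing)
            )


def run_pipeline(manifest: RunManifest) -> dict:
    """Execute the synthetic end-to-end analysis and return the report.

    Stages: generate genes + replicate peak sets; filter to reproducible
    peaks; test peak-gene association at every configured distance;
    overlap the peaks with simulated external tracks and classify
    phantom candidates; score motif enrichment on planted windows.
    When ``manifest.outdir`` is set, BED/TSV/JSON artifacts are written
    there along with the report.
    """
    manifest.validate()
    cfg = manifest.config
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
    }

    genes, rep1, rep2 = simulate_genes_and_peaks(cfg)
    logger.info("simulate: %d genes, %d/%d replicate peaks",
                len(genes), len(rep1), len(rep2))
    report["stages"]["simulate"] = {
        "n_genes": len(genes),
        "n_de": sum(g.is_de for g in genes),
        "n_rep1": len(rep1),
        "n_rep2": len(rep2),
    }

    final = reproducible_peaks(rep1, rep2)
    logger.info("peaks: %d reproducible of %d", len(final), len(rep1))
    report["stages"]["peaks"] = {"n_reproducible": len(final)}

    assoc = {}
    for res in (association_test(final, genes, d) for d in manifest.distances):
        assoc[str(res.distance)] = {
            "near_de": res.near_de,
            "near_nonde": res.near_nonde,
            "tot_de": res.tot_de,
            "tot_nonde": res.tot_nonde,
            "chi2_p": res.chi2_p,
            "binom_p": res.binom_p,
            "pct_peaks_with_de": 100.0 * res.frac_peaks_with_de,
        }
    fractions = proximity_fractions(
        final, genes, AssociationConfig(distances=tuple(manifest.distances))
    )
    report["stages"]["integrate"] = {
        "association": assoc,
        "proximity": fractions.to_dict(orient="records"),
    }
    logger.info("integrate: association tested at %s", list(manifest.distances))

    track = simulate_tracks(cfg, final, seed_offset=1)
    phantom_list = simulate_tracks(cfg, final, seed_offset=2)
    damid = simulate_tracks(cfg, final, seed_offset=3)
    pct = percentage_overlap(final, track)
    pct_any = at_least_one(final, [track, phantom_list])
    dual = intersect_u(final, track)
    overlap_stage: dict = {
        "pct_overlap_track": pct,
        "pct_at_least_one": pct_any,
        "n_dual_bound": len(dual),
    }
    if len(dual) > 0:
        cls = phantom_classify(dual, phantom_list, damid)
        overlap_stage["phantom"] = {
            "n_candidates": len(cls.candidates),
            "n_real": len(cls.real),
            "n_phantom": len(cls.phantom),
            "pct_phantom": cls.pct_phantom,
        }
    report["stages"]["overlap"] = overlap_stage
    logger.info("overlap: %.1f%% of %d peaks on track", pct, len(final))

    test_w, ctrl_w = simulate_motif_windows(cfg, manifest.motif)
    enr = enrichment(test_w, ctrl_w, MotifConsensus("planted", manifest.motif))
    report["stages"]["motifs"] = {
        "motif": manifest.motif,
        "pct_test": enr.pct_test,
        "pct_control": enr.pct_control,
        "ratio": enr.ratio,
        "fisher_p": enr.fisher_p,
    }
    logger.info("motifs: ratio %.2f (p=%.2g)", enr.ratio, enr.fisher_p)

    if manifest.outdir is not None:
        outdir = Path(manifest.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed(final, outdir / "peaks.bed")
        write_gene_table(genes, outdir / "genes.tsv")
        fractions.to_csv(outdir / "proximity.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def reproduce_supplementary(
    s1: Union[str, Path],
    s2: Union[str, Path],
    gene_sheet: str,
    peak_sheets: list[str],
    timepoint_pairs: tuple = (),
    distances: tuple[int, ...] = AssociationConfig().distances,
    exclude: tuple[str, ...] = (),
    expected: Optional[dict] = None,
) -> dict:
    """Recompute counts and overlaps from supplementary-style workbooks.

    ``s1`` holds the gene list (one sheet), ``s2`` the peak sheets.
    Recomputes, from the coordinates alone: per-sheet peak counts, DE
    gene counts by direction, all ordered pairwise peak-sheet overlap
    counts, early-to-late retention fractions for the given
    ``timepoint_pairs`` (early sheet, late sheet), and the fraction of
    peaks (pooled over sheets) with a DE gene within each distance.
    When ``expected`` supplies reference numbers (same key layout),
    they are reported side by side with the computed values.
    """
    genes = read_supplementary_xlsx(s1, gene_sheet, "genes", exclude=exclude)
    peak_sets: dict[str, IntervalCollection] = {
        name: read_supplementary_xlsx(s2, name, "peaks", exclude=exclude)
        for name in peak_sheets
    }

    computed: dict = {
        "gene_counts": {
            "total_de": sum(g.is_de for g in genes),
            "up": sum(g.de_status == "up" for g in genes),
            "down": sum(g.de_status == "down" for g in genes),
        },
        "peak_counts": {name: len(c) for name, c in peak_sets.items()},
        "pairwise_overlap": {
            f"{a}&{b}": len(intersect_u(peak_sets[a], peak_sets[b]))
            for a in peak_sheets
            for b in peak_sheets
            if a != b
        },
    }
    retention = {}
    for early, late in timepoint_pairs:
        n_early = len(peak_sets[early])
        kept = len(intersect_u(peak_sets[early], peak_sets[late]))
        retention[f"{early}->{late}"] = kept / n_early if n_early else 0.0
    if retention:
        computed["retention"] = retention

    pooled = IntervalCollection(
        [rec for c in peak_sets.values() for rec in c.records], name="pooled"
    )
    fractions = proximity_fractions(
        pooled, genes, AssociationConfig(distances=tuple(distances))
    )
    computed["proximity"] = {
        str(int(row.distance)): row.pct_peaks_with_de_gene
        for row in fractions.itertuples(index=False)
    }

    report = {"computed": computed}
    if expected is not None:
        report["expected"] = expected
        report["comparison"] = _compare(computed, expected)
    return report


def _compare(computed: dict, expected: dict, prefix: str = "") -> list[dict]:
    rows = []
    for key, exp in expected.items():
        comp = computed.get(key)
        if isinstance(exp, dict) and isinstance(comp, dict):
            rows.extend(_compare(comp, exp, prefix=f"{prefix}{key}."))
        else:
            rows.append(
                {
                    "quantity": f"{prefix}{key}",
                    "computed": comp,
                    "expected": exp,
                    "match": comp == exp,
                }
            )
    return rows
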