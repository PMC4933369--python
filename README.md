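# bmpchip

Peak-gene integration, interval overlap and motif-enrichment analysis for
BMP-responsive transcriptional networks.

## The problem

In the early *Drosophila* embryo, the BMP ligand Dpp patterns the dorsal
ectoderm through the signal-activated Smad transcription factor pMad and the
competing repressor Brinker (Brk). Deciphering this network computationally
means answering four linked questions from ChIP-seq peak sets and an RNA-seq
differential-expression (DE) gene list:

1. **Which binding regions are real?** Peaks must be present in both ChIP
   replicates, take their coordinates from the higher-stringency call set
   where available, and be combined across time points and factors under
   explicit coordinate-precedence rules (late pMad coordinates win).
2. **Are DE genes near the peaks?** For window half-widths *d* ∈
   {5, 10, 20, 40} kb, count genes with ≥ 1 peak summit within *d* of their
   TSS and test the 2×2 table {DE, non-DE} × {near, not near} with Pearson's
   χ² (df = 1, no continuity correction) and a one-sided binomial test of
   near<sub>DE</sub> successes in tot<sub>DE</sub> trials at rate
   near<sub>non-DE</sub>/tot<sub>non-DE</sub>.
3. **Who co-binds?** Percentage overlap (≥ 1 bp, query-record based) with
   insulator proteins, pioneer-factor and enhancer tracks, with BMP-bound
   regions removed from external sets before comparison, and candidate
   "Phantom Peaks" reassigned as real when present in antibody-free DamID
   data.
4. **Which motifs are enriched?** IUPAC consensus occurrence in 250 bp
   summit-centered windows versus housekeeping-enhancer controls, scored as
   a containment-percentage ratio with a two-tailed Fisher's exact test.

Because the raw sequencing data are not desk-scale inputs, the package ships
a fully seeded synthetic-data generator that plants every effect the
analysis is meant to detect (proximity enrichment of DE genes near summits,
replicate noise, motif plant rates, track overlap fractions), so the whole
pipeline is testable end to end without downloads. Supplementary-style XLSX
peak/gene workbooks can also be read and their counts recomputed from
coordinates alone.

## Worked example

```python
from bmpchip import SimulationConfig, association_test, reproducible_peaks
from bmpchip.simulate import simulate_genes_and_peaks

cfg = SimulationConfig(seed=1)              # 2 x 5 Mb, 2000 genes, 300 peaks
genes, rep1, rep2 = simulate_genes_and_peaks(cfg)
peaks = reproducible_peaks(rep1, rep2)      # present in both replicates
res = association_test(peaks, genes, d=cfg.d0)
print(f"{res.near_de}/{res.tot_de} DE vs {res.near_nonde}/{res.tot_nonde} "
      f"non-DE genes near a summit (chi2 p = {res.chi2_p:.3g}, "
      f"binomial p = {res.binom_p:.3g})")
```

prints

```
217/300 DE vs 389/1700 non-DE genes near a summit (chi2 p = 3.54e-66, binomial p = 1.78e-73)
```

The generator planted a 3× proximity effect within 5 kb of a summit:
217/300 = 72% of DE genes sit near a summit versus 389/1700 = 23% of non-DE
genes (a 3.16× ratio), and both tests reject decisively.

A command-line interface exposes the same stages (`bmpchip simulate`,
`bmpchip peaks combine`, `bmpchip integrate`, `bmpchip overlap`,
`bmpchip motifs`, `bmpchip phantom`, `bmpchip run`, `bmpchip reproduce`);
`bmpchip run --seed 5 --outdir out/` executes the full synthetic pipeline
and writes a JSON report that is byte-identical across reruns of the same
seed.

## Layout

- `src/bmpchip/core.py` — coordinate model (0-based half-open), BED/TSV/XLSX
  readers and writers, `intersect -u`-style and `merge` interval algebra
- `src/bmpchip/peaks.py` — replicate reproducibility, stringency refinement,
  time-point/factor combination, read-track normalization factors
- `src/bmpchip/integration.py` — gene↔peak pairing tables, association tests,
  proximity fractions
- `src/bmpchip/overlap.py` — overlap percentages, remove-before-compare,
  at-least-one aggregation, Phantom-Peak classification
- `src/bmpchip/motifs.py` — summit windows, IUPAC scanning on both strands,
  Fisher-based enrichment
- `src/bmpchip/simulate.py` — seeded generators for genome, genes/peaks,
  tracks and motif windows
- `src/bmpchip/pipeline.py`, `src/bmpchip/cli.py` — orchestration and CLI

See `docs/methods.md` for the modeling choices and their rationale.
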