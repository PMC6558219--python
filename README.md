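# cobindsi

Signal-integration and STAT1/p65 co-binding analysis for IFN+LPS
transcriptional responses, with a fully seeded multi-omic simulator.

## The problem

Interferon "priming" followed by TLR4 stimulation (LPS) can drive
pro-inflammatory genes far harder than either stimulus alone. Mechanistically
this *signal integration* (SI) involves STAT1-containing complexes — GAF
(STAT1 homodimers) binding GAS elements, ISGF3 (STAT1–STAT2–IRF9) binding
ISRE elements — co-operating with NFκB (p65–p50) at closely spaced composite
sites. Characterizing it from data takes an integrative RNA-seq + ChIP-seq
analysis: which genes respond super-additively to IFNα+LPS or IFNγ+LPS
across cell types (vascular smooth muscle cells, macrophages, dendritic
cells), which GAS/ISRE/NFκB motifs are actually occupied by STAT1 or p65
peaks near those genes, and in which combinations ("binding modes").

`cobindsi` implements that analysis end to end for computational biologists
who want the statistics reproducible and testable:

* **Expression** — median-of-ratios normalization, an expressed-signal
  filter (normalized mean > 8), fold changes vs control, up-regulated lists
  (FC ≥ 2), three-way cross-cell-type Venn commonality, and the SI statistic

  `SI  ⇔  FC(IFN+LPS) > FC(IFN) + FC(LPS)`  (strict),

  plus hypergeometric gene-set enrichment over user-supplied GMT collections.
* **Motif scanning** — two PWM dialects: genome-wide natural-log log-odds
  with per-class score thresholds (GAS 6, ISRE 6, NFκB 7) and a promoter
  (−950/+50 bp) matrix-similarity scan with min–max normalized scores
  (thresholds 0.85 / 0.90).
* **ChIP integration** — bedtools-style interval algebra, motif-in-peak
  occupancy (full containment, factor-matched), nearest-TSS annotation with
  a ±100 kb filter, seven-category genomic classification, per-gene binding
  modes (GAS / ISRE / NFκB / GAS-ISRE / GAS-NFκB / ISRE-NFκB /
  GAS-ISRE-NFκB), mode-overlap tables, STAT1↔p65 summit-distance histograms
  (±1 kb, 25-bp bins), and RPKM occupancy matrices clustered by k-means.
* **Simulator** — a seeded generator that plants genes, motifs (composite
  sites spaced 38–264 bp), negative-binomial counts with super-additive
  synergy, and condition-dependent STAT1/p65 peaks with tag coverage; the
  planted truth is the recovery oracle for the whole pipeline.

## Worked example

```bash
cobindsi run --seed 3 --outdir out/
cobindsi report --summary out/summary.json
```

runs the default simulated study (160 genes, 3 cell types × 6 conditions ×
3 replicates, 2 factors × 6 ChIP samples) and prints, among other tables:

```
Published top-30 table SI regression:
  table1a: 25/30 SI-flagged (matches published marks)
  table1b: 26/30 SI-flagged (matches published marks)

Recovery vs planted truth:
  mode_accuracy_pct: 100.0
  si_sensitivity_pct: 100.0
  si_specificity_pct: 99.75
  composite_distance_in_band_pct: 100.0
  archetype_ari: 1.0
```

The first block applies the SI statistic to the two packaged published
top-30 fold-change tables: of 30 genes each, exactly 25 (IFNα+LPS) and 26
(IFNγ+LPS) satisfy the strict super-additivity inequality, matching the
published synergy marks row for row. The recovery block scores the analysis
against the planted truth: every motif-bearing gene's binding mode was
classified correctly, SI flagging achieved 100% sensitivity / 99.75%
specificity over gene × cell type × condition combinations, all planted
composite STAT1–p65 summit distances fell inside the configured 38–264 bp
spacing band, and k-means separated the STAT1-only from the co-bound
occupancy archetypes perfectly (adjusted Rand index 1.0).

The output directory also holds every intermediate table (up-regulated
lists, Venn counts, SI records, promoter site profiles, the motif-hit BED
catalog, per-condition mode tables, summit histograms, RPKM occupancy with
cluster assignments) as TSV/BED/JSON.

As a library:

```python
from cobindsi import SimConfig, simulate_genome, simulate_expression
from cobindsi import expression as xp
```

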