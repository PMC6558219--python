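"""Configuration-driven end-to-end runs: simulate -> analyze -> report.

``run_pipeline`` executes, in order: expression records, up-regulated lists,
cross-cell-type Venn counts, SI records, promoter site profiles, the
genome-wide motif hit catalog, occupied sites and binding modes per combined
condition, mode-overlap tables, summit-distance histograms, RPKM occupancy
clustering, and a machine-readable JSON summary. On simulated input it also
scores recovery against the planted truth (mode accuracy, SI sensitivity/
specificity, composite summit-distance band coverage, two-archetype
clustering agreement). Runs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import expression as xp
from .core import (
    COMBO_CONDITIONS,
    COMBO_PARTS,
    CONDITIONS,
    CountMatrix,
    GenomeModel,
    MOTIF_CLASSES,
    parse_counts_table,
    parse_fasta,
    parse_gene_models,
    parse_gmt,
    parse_jaspar_pfm,
    parse_narrowpeak,
    parse_sample_sheet,
    write_bedgraph,
    write_counts_table,
    write_fasta,
    write_gene_models,
    write_narrowpeak,
)
from .fixtures import default_motifs, load_table1
from .integration import (
    IntegrationParams,
    classify_binding_modes,
    interval_ops,
    mode_overlap_table,
    occupied_sites,
    rpkm_and_cluster,
    summit_distance_histogram,
)
from .motifs import PromoterScanParams, ScanParams, log_odds_scan, promoter_site_profile
from .simulate import (
    SimConfig,
    SyntheticTruth,
    mode_classes,
    simulate_chip,
    simulate_expression,
    simulate_genome,
)

log = logging.getLogger("cobindsi")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """Inputs (paths or a simulation block) plus all analysis thresholds."""

    outdir: str = "cobindsi_out"
    simulate: SimConfig | None = None
    genome_fasta: str | None = None
    genes_bed: str | None = None
    counts_tsv: str | None = None
    samples_tsv: str | None = None
    peaks: dict | None = None  # factor -> condition -> path
    motif_files: dict | None = None  # class -> PFM path
    gene_sets_gmt: str | None = None
    fc_cutoff: float = 2.0
    strict_fc_boundary: bool = False
    expression_cutoff: float = 8.0
    fc_pseudocount: float = 0.5
    scan: ScanParams = field(default_factory=ScanParams)
    promoter_scan: PromoterScanParams = field(default_factory=PromoterScanParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    write_coverage: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None:
            required = {
                "genome_fasta": self.genome_fasta,
                "genes_bed": self.genes_bed,
                "counts_tsv": self.counts_tsv,
                "samples_tsv": self.samples_tsv,
                "peaks": self.peaks,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise PipelineError(
                    f"config validation: no simulate block and missing inputs {missing}"
                )
            for key in ("genome_fasta", "genes_bed", "counts_tsv", "samples_tsv"):
                path = getattr(self, key)
                if not Path(path).exists():
                    raise PipelineError(f"config validation: {key} path {path!r} not found")
        if self.fc_cutoff <= 0 or self.expression_cutoff < 0:
            raise PipelineError("config validation: thresholds out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            sim = kwargs["simulate"]
            kwargs["simulate"] = sim if isinstance(sim, SimConfig) else SimConfig(**sim)
        for key, klass in (
            ("scan", ScanParams),
            ("promoter_scan", PromoterScanParams),
            ("integration", IntegrationParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"config validation: unknown keys {sorted(unknown)}")
        return cls(**kwargs)


def _stage(name: str):
    log.info("stage: %s", name)


def _round_floats(obj, ndigits: int = 4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # ---------------- inputs ----------------
    truth: SyntheticTruth | None = None
    if config.simulate is not None:
        _stage("simulate")
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        genome, genes, truth = simulate_genome(sim)
        counts = simulate_expression(truth, sim)
        peaks_by, coverage_by = simulate_chip(truth, sim)
        write_fasta(genome, outdir / "genome.fa")
        write_gene_models(genes, outdir / "genes.bed12")
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        write_counts_table(counts, outdir / "counts.tsv", outdir / "samples.tsv")
        peak_dir = outdir / "peaks"
        peak_dir.mkdir(exist_ok=True)
        for (factor, cond), plist in peaks_by.items():
            write_narrowpeak(plist, peak_dir / f"{factor}_{cond}.narrowPeak")
        if config.write_coverage:
            cov_dir = outdir / "coverage"
            cov_dir.mkdir(exist_ok=True)
            for (factor, cond), cov in coverage_by.items():
                write_bedgraph(
                    cov.to_bedgraph_records(), cov_dir / f"{factor}_{cond}.bedGraph"
                )
        pwms = default_motifs()
    else:
        _stage("load inputs")
        genome = parse_fasta(config.genome_fasta)
        genes = parse_gene_models(config.genes_bed)
        samples = parse_sample_sheet(config.samples_tsv)
        counts = parse_counts_table(config.counts_tsv, samples)
        peaks_by = {}
        for factor, by_cond in (config.peaks or {}).items():
            for cond, path in by_cond.items():
                peaks_by[(factor, cond)] = parse_narrowpeak(path, factor, cond)
        coverage_by = {}
        if config.motif_files:
            pwms = {
                cls: parse_jaspar_pfm(path, cls) for cls, path in config.motif_files.items()
            }
        else:
            pwms = default_motifs()

    # ---------------- expression ----------------
    _stage("expression")
    try:
        factors = xp.size_factors(counts)
        normalized, expressed = xp.normalize_and_filter(
            counts, factors, config.expression_cutoff
        )
        records = xp.fold_changes(
            counts, normalized, expressed,
            pseudocount=config.fc_pseudocount,
            fc_cutoff=config.fc_cutoff,
            strict_boundary=config.strict_fc_boundary,
        )
    except ValueError as exc:
        raise PipelineError(f"stage expression failed on counts input: {exc}") from exc
    up_lists = xp.up_regulated_lists(records)
    pd.DataFrame(
        [
            {"cell_type": ct, "condition": cond, "rank": i + 1, "gene_id": g}
            for (ct, cond), glist in sorted(up_lists.items())
            for i, g in enumerate(glist)
        ]
    ).to_csv(outdir / "up_lists.tsv", sep="\t", index=False)
    log.info("up lists: %s", {k: len(v) for k, v in sorted(up_lists.items())})

    cell_types = counts.cell_types
    common_by_combo: dict[str, set] = {}
    venn_rows = []
    for combo in COMBO_CONDITIONS:
        lists = [up_lists.get((ct, combo), []) for ct in cell_types]
        common, venn = xp.common_genes(lists)
        common_by_combo[combo] = common
        summary.setdefault("common_up", {})[combo] = len(common)
        summary.setdefault("venn", {})[combo] = venn
        venn_rows.extend(
            {"condition": combo, "region": k, "count": v} for k, v in sorted(venn.items())
        )
    pd.DataFrame(venn_rows).to_csv(outdir / "venn.tsv", sep="\t", index=False)
    summary["common_overlap_jaccard_pct"] = round(
        xp.pairwise_overlap(
            common_by_combo["IFNa_LPS"], common_by_combo["IFNg_LPS"], "jaccard"
        ),
        2,
    )

    si_records = xp.si_flags(records)
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id, "cell_type": r.cell_type, "combo": r.combo,
                "fc_combo": round(r.fc_combo, 4), "fc_ifn": round(r.fc_ifn, 4),
                "fc_lps": round(r.fc_lps, 4), "si_flag": int(r.si_flag),
            }
            for r in si_records
        ]
    ).to_csv(outdir / "si_records.tsv", sep="\t", index=False)
    summary["si_flagged"] = {
        combo: sum(
            1 for r in si_records if r.combo == combo and r.si_flag
        )
        for combo in COMBO_CONDITIONS
    }

    if config.gene_sets_gmt:
        _stage("gene-set enrichment")
        gene_sets = parse_gmt(config.gene_sets_gmt)
        enrich_rows = []
        for combo in COMBO_CONDITIONS:
            universe = set.union(*(expressed[ct] for ct in cell_types))
            table = xp.enrich_gene_sets(
                common_by_combo[combo] & universe, universe, gene_sets
            )
            table.insert(0, "condition", combo)
            enrich_rows.append(table)
        pd.concat(enrich_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # Standing regression fixture: published top-30 FC tables.
    table_check = {}
    for which in ("a", "b"):
        table = load_table1(which)
        flags = xp.si_flags_from_fc(table)
        table_check[f"table1{which}"] = {
            "flagged": int(flags.sum()),
            "total": int(len(table)),
            "matches_published_marks": bool(
                (flags.astype(int) == table["si_marked"]).all()
            ),
        }
    summary["published_table_si_check"] = table_check

    # ---------------- promoter profiles ----------------
    _stage("promoter scan")
    presence, promoter_venn = promoter_site_profile(
        genes, genome, pwms, config.promoter_scan
    )
    pd.DataFrame(
        [
            {"gene_id": g, "classes": "-".join(c for c in MOTIF_CLASSES if c in cls)}
            for g, cls in sorted(presence.items())
        ]
    ).to_csv(outdir / "promoter_profile.tsv", sep="\t", index=False)
    summary["promoter_venn"] = promoter_venn

    # ---------------- genome-wide motif catalog ----------------
    _stage("motif scan")
    all_hits = []
    for cls, pwm in pwms.items():
        for chrom in genome.chroms:
            all_hits.extend(
                log_odds_scan(genome.sequence(chrom), pwm, config.scan, chrom=chrom)
            )
    with open(outdir / "motif_hits.bed", "w") as fh:
        for h in sorted(all_hits, key=lambda h: (h.chrom, h.start)):
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.pwm_id}\t{h.log_odds:.3f}\t"
                f"{h.strand}\t{h.pwm_id}\t{h.motif_class}\n"
            )
    summary["motif_hits"] = {
        cls: sum(1 for h in all_hits if h.motif_class == cls) for cls in pwms
    }
    log.info("motif hits: %s", summary["motif_hits"])

    # ---------------- binding modes per combined condition ----------------
    _stage("integration")
    modes_by_combo = {}
    occupied_counts = {}
    for combo in COMBO_CONDITIONS:
        peaks_combo = [
            p for (factor, cond), plist in peaks_by.items() if cond == combo
            for p in plist
        ]
        occupied = occupied_sites(all_hits, peaks_combo, combo)
        occupied_counts[combo] = len(occupied)
        modes = classify_binding_modes(occupied, genes, combo, config.integration)
        modes_by_combo[combo] = modes
        pd.DataFrame(
            [
                {
                    "gene_id": rec.gene_id,
                    "condition_pair": rec.condition_pair,
                    "mode": rec.mode,
                    "n_sites": len(rec.sites),
                    "min_site_spacing": rec.min_site_spacing() or "",
                    "categories": ",".join(sorted({s[3] for s in rec.sites})),
                }
                for rec in sorted(modes.values(), key=lambda r: r.gene_id)
            ]
        ).to_csv(outdir / f"mode_table_{combo}.tsv", sep="\t", index=False)
        mode_counts: dict[str, int] = {}
        for rec in modes.values():
            mode_counts[rec.mode] = mode_counts.get(rec.mode, 0) + 1
        summary.setdefault("mode_counts", {})[combo] = dict(sorted(mode_counts.items()))
    summary["occupied_sites"] = occupied_counts

    overlap = mode_overlap_table(
        modes_by_combo["IFNa_LPS"], modes_by_combo["IFNg_LPS"]
    )
    overlap.to_csv(outdir / "mode_overlap.tsv", sep="\t", index=False)
    summary["mode_overlap_pct_sum"] = {
        row["mode"]: row["pct_sum"] for _, row in overlap.iterrows()
    }

    # ---------------- summit geometry ----------------
    hist_stats = {}
    for combo in COMBO_CONDITIONS:
        stat1 = peaks_by.get(("STAT1", combo), [])
        p65 = peaks_by.get(("p65", combo), [])
        if not stat1 or not p65:
            continue
        distances, hist = summit_distance_histogram(stat1, p65, config.integration)
        hist.to_csv(outdir / f"summit_hist_{combo}.tsv", sep="\t", index=False)
        hist_stats[combo] = {
            "n_distances": len(distances),
            "median_abs": float(np.median(np.abs(distances))) if distances else None,
        }
    summary["summit_distances"] = hist_stats

    # ---------------- occupancy clustering ----------------
    if coverage_by:
        _stage("occupancy clustering")
        all_peak_intervals = [
            (p.chrom, p.start, p.end) for plist in peaks_by.values() for p in plist
        ]
        merged = interval_ops(all_peak_intervals, [], "merge")
        cov = {f"{factor}_{cond}": c for (factor, cond), c in coverage_by.items()}
        k = min(config.integration.kmeans_k, len(merged))
        occ = rpkm_and_cluster(merged, cov, config.integration, k=k)
        out = occ.rpkm.round(4).copy()
        out["cluster"] = occ.clusters
        out.to_csv(outdir / "occupancy.tsv", sep="\t", index_label="region")
        occ.rd.round(4).to_csv(outdir / "rd_matrix.tsv", sep="\t", index_label="region")
        sizes = {}
        for c in occ.clusters:
            sizes[int(c)] = sizes.get(int(c), 0) + 1
        summary["occupancy_clusters"] = dict(sorted(sizes.items()))

    # ---------------- recovery vs planted truth ----------------
    if truth is not None:
        _stage("recovery")
        summary["recovery"] = recovery_metrics(
            truth, modes_by_combo, si_records, peaks_by, coverage_by, config.integration
        )

    summary_json = json.dumps(_round_floats(summary), sort_keys=True, indent=2)
    (outdir / "summary.json").write_text(summary_json + "\n")
    (outdir / "report.txt").write_text(write_report(summary))
    return outdir


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def recovery_metrics(
    truth: SyntheticTruth,
    modes_by_combo: dict,
    si_records,
    peaks_by,
    coverage_by,
    params: IntegrationParams,
) -> dict:
    """Score the analysis against the planted truth."""
    out: dict = {}

    # mode accuracy over motif-bearing genes, per combined condition
    bearing = [g for g in truth.mode if truth.mode[g] != "none"]
    correct = total = 0
    for combo, modes in modes_by_combo.items():
        for gid in bearing:
            total += 1
            rec = modes.get(gid)
            if rec is not None and rec.mode == truth.mode[gid]:
                correct += 1
    out["mode_accuracy_pct"] = 100.0 * correct / total if total else None
    out["n_motif_bearing_genes"] = len(bearing)

    # SI sensitivity/specificity over gene x cell type x combo
    tp = fp = tn = fn = 0
    for r in si_records:
        actual = truth.is_si(r.gene_id, r.cell_type, r.combo)
        if actual and r.si_flag:
            tp += 1
        elif actual:
            fn += 1
        elif r.si_flag:
            fp += 1
        else:
            tn += 1
    out["si_sensitivity_pct"] = 100.0 * tp / (tp + fn) if (tp + fn) else None
    out["si_specificity_pct"] = 100.0 * tn / (tn + fp) if (tn + fp) else None

    # composite-site summit distances inside the configured spacing band
    smin, smax = truth.config.composite_spacing
    in_band = total_d = 0
    composite = {
        g for g, m in truth.mode.items()
        if "NFKB" in mode_classes(m) and set(mode_classes(m)) & {"GAS", "ISRE"}
    }
    for combo in COMBO_CONDITIONS:
        stat1 = [
            p for p in peaks_by.get(("STAT1", combo), [])
            if p.name.split(":")[0] in composite
        ]
        p65 = peaks_by.get(("p65", combo), [])
        distances, _ = summit_distance_histogram(stat1, p65, params)
        for d in distances:
            total_d += 1
            if smin <= abs(d) <= smax:
                in_band += 1
    out["composite_distance_in_band_pct"] = (
        100.0 * in_band / total_d if total_d else None
    )

    # two-archetype occupancy clustering agreement
    out["archetype_ari"] = archetype_clustering_ari(
        truth, peaks_by, coverage_by, params
    )
    return out


def archetype_clustering_ari(
    truth: SyntheticTruth, peaks_by, coverage_by, params: IntegrationParams
) -> float | None:
    """Adjusted Rand index of k=2 clustering vs STAT1-only / co-bound truth.

    One region per STAT1-binding gene, spanning that gene's full planted
    site block (all motif midpoints ± half a peak width), labelled by
    whether the gene also carries an NFκB motif (co-bound archetype);
    k-means with k=2 on log RPKM across the 12 samples is compared to
    those labels.
    """
    if not coverage_by:
        return None
    regions, labels = [], []
    w = truth.config.peak_width // 2
    for gid, motifs in truth.motifs.items():
        classes = set(motifs)
        if not classes & {"GAS", "ISRE"}:
            continue
        mids = [(s + e) // 2 for _, s, e in motifs.values()]
        chrom = next(iter(motifs.values()))[0]
        regions.append((chrom, min(mids) - w, max(mids) + w))
        labels.append(int("NFKB" in classes))
    if len(set(labels)) < 2:
        return None
    cov = {f"{factor}_{cond}": c for (factor, cond), c in coverage_by.items()}
    occ = rpkm_and_cluster(regions, cov, params, k=2)
    return float(adjusted_rand_score(labels, occ.clusters))


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def write_report(summary: dict) -> str:
    """Human-readable tabulation of a pipeline summary."""
    lines = ["cobindsi pipeline report", "=" * 40, ""]
    if "common_up" in summary:
        lines.append("Commonly up-regulated genes per combined condition:")
        for combo, n in summary["common_up"].items():
            lines.append(f"  {combo}: {n}")
        if "common_overlap_jaccard_pct" in summary:
            lines.append(
                f"  overlap between combined conditions: "
                f"{summary['common_overlap_jaccard_pct']:.2f}% (jaccard)"
            )
        lines.append("")
    if "si_flagged" in summary:
        lines.append("SI-flagged gene records per combined condition:")
        for combo, n in summary["si_flagged"].items():
            lines.append(f"  {combo}: {n}")
        lines.append("")
    if "published_table_si_check" in summary:
        lines.append("Published top-30 table SI regression:")
        for name, res in summary["published_table_si_check"].items():
            ok = "matches" if res["matches_published_marks"] else "MISMATCH with"
            lines.append(
                f"  {name}: {res['flagged']}/{res['total']} SI-flagged ({ok} published marks)"
            )
        lines.append("")
    if "mode_counts" in summary:
        lines.append("Binding-mode counts per combined condition:")
        for combo, counts in summary["mode_counts"].items():
            lines.append(f"  {combo}:")
            for mode, n in counts.items():
                lines.append(f"    {mode}: {n}")
        lines.append("")
    if "mode_overlap_pct_sum" in summary:
        lines.append("Mode overlap between combined conditions (sum method, %):")
        for mode, pct in summary["mode_overlap_pct_sum"].items():
            lines.append(f"  {mode}: {pct:.2f}%")
        lines.append("")
    if "recovery" in summary:
        rec = summary["recovery"]
        lines.append("Recovery vs planted truth:")
        for key in (
            "mode_accuracy_pct", "si_sensitivity_pct", "si_specificity_pct",
            "composite_distance_in_band_pct", "archetype_ari",
        ):
            val = rec.get(key)
            lines.append(f"  {key}: {val if val is None else round(val, 2)}")
        lines.append("")
    return "\n".join(lines) + "\n"
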