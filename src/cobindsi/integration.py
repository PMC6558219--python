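"""ChIP-seq integration: interval algebra, motif occupancy, gene annotation,
binding-mode classification, summit-distance geometry and occupancy clustering.

A gene's *binding mode* is the subset of {GAS, ISRE, NFκB} motif classes
with at least one occupied site — a motif hit fully contained in a peak of
the matching factor (STAT1 for GAS/ISRE, p65 for NFκB) — within ±100 kb of
the gene's TSS. "Single" modes involve one factor only; "co-binding" modes
pair a STAT1 class with NFκB.

Interval semantics are 0-based half-open throughout; ``merge`` coalesces
touching intervals, matching bedtools behaviour.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import CLASS_FACTOR, Coverage, GeneModel, MOTIF_CLASSES, MotifHit, Peak
from .simulate import classes_to_mode

GENOMIC_CATEGORIES = (
    "promoter/TSS", "TTS", "5'UTR", "3'UTR", "exon", "intron", "intergenic",
)

Interval = tuple[str, int, int]


@dataclass
class IntegrationParams:
    tss_window: int = 100_000
    promoter_tss: tuple[int, int] = (-1_000, 100)
    tts_window: int = 100
    hist_half_window: int = 1_000
    hist_bin: int = 25
    kmeans_k: int = 10
    kmeans_seed: int = 0

    def validate(self) -> None:
        if self.tss_window <= 0 or self.hist_half_window <= 0 or self.hist_bin <= 0:
            raise ValueError("window and bin parameters must be positive")
        if (2 * self.hist_half_window) % self.hist_bin != 0:
            raise ValueError("hist_bin must divide 2 * hist_half_window")


@dataclass
class BindingModeRecord:
    gene_id: str
    condition_pair: str
    occupied_classes: frozenset
    mode: str
    sites: list  # (MotifHit, Peak, signed TSS distance, genomic category)

    @property
    def is_cobinding(self) -> bool:
        return "NFKB" in self.occupied_classes and bool(
            self.occupied_classes & {"GAS", "ISRE"}
        )

    def min_site_spacing(self) -> int | None:
        """Smallest midpoint distance between sites of different classes."""
        mids = [(hit.motif_class, hit.midpoint) for hit, *_ in self.sites]
        best = None
        for i, (ci, mi) in enumerate(mids):
            for cj, mj in mids[i + 1 :]:
                if ci != cj:
                    d = abs(mi - mj)
                    best = d if best is None else min(best, d)
        return best


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def _by_chrom(intervals) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if start >= end:
            raise ValueError(f"malformed interval [{start}, {end}) on {chrom}")
        out.setdefault(chrom, []).append((start, end))
    for ivs in out.values():
        ivs.sort()
    return out


def _merge_sorted(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:  # touching intervals coalesce
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_ops(set_a, set_b, op: str) -> list[Interval]:
    """bedtools-style ``intersect``, ``subtract`` or ``merge`` on half-open intervals.

    ``merge`` coalesces the union of both inputs (pass an empty second set to
    merge one list); chromosomes are handled independently.
    """
    a, b = _by_chrom(set_a), _by_chrom(set_b)
    out: list[Interval] = []
    if op == "merge":
        for chrom in sorted(set(a) | set(b)):
            ivs = sorted(a.get(chrom, []) + b.get(chrom, []))
            out.extend((chrom, s, e) for s, e in _merge_sorted(ivs))
    elif op == "intersect":
        for chrom in sorted(set(a) & set(b)):
            merged_b = _merge_sorted(b[chrom])
            for s, e in a[chrom]:
                for bs, be in merged_b:
                    lo, hi = max(s, bs), min(e, be)
                    if lo < hi:
                        out.append((chrom, lo, hi))
    elif op == "subtract":
        for chrom in sorted(a):
            merged_b = _merge_sorted(b.get(chrom, []))
            for s, e in a[chrom]:
                cursor = s
                for bs, be in merged_b:
                    if be <= cursor or bs >= e:
                        continue
                    if bs > cursor:
                        out.append((chrom, cursor, bs))
                    cursor = max(cursor, be)
                    if cursor >= e:
                        break
                if cursor < e:
                    out.append((chrom, cursor, e))
    else:
        raise ValueError(f"unknown interval op {op!r}")
    return out


# ---------------------------------------------------------------------------
# Occupancy and annotation
# ---------------------------------------------------------------------------

def occupied_sites(
    hits: list[MotifHit], peaks: list[Peak], condition: str
) -> list[tuple[MotifHit, Peak]]:
    """Hits fully contained in a same-condition peak of the matching factor.

    GAS/ISRE hits can only be occupied by STAT1 peaks, NFκB hits only by p65
    peaks; partial overlap (a hit straddling a peak edge) does not count.
    """
    index: dict[tuple[str, str], tuple[list[int], list[Peak]]] = {}
    for factor in ("STAT1", "p65"):
        for chrom in {p.chrom for p in peaks}:
            group = sorted(
                (p for p in peaks
                 if p.factor == factor and p.chrom == chrom and p.condition == condition),
                key=lambda p: p.start,
            )
            if group:
                index[(factor, chrom)] = ([p.start for p in group], group)
    out: list[tuple[MotifHit, Peak]] = []
    for hit in hits:
        key = (CLASS_FACTOR[hit.motif_class], hit.chrom)
        if key not in index:
            continue
        starts, group = index[key]
        hi = bisect_left(starts, hit.start + 1)
        best = None
        for p in group[:hi]:
            if p.end >= hit.end and (best is None or p.score > best.score):
                best = p
        if best is not None:
            out.append((hit, best))
    return out


def annotate_nearest_tss(
    site_midpoint: int, chrom: str, genes: list[GeneModel],
    params: IntegrationParams | None = None,
) -> tuple[str, int] | None:
    """Nearest gene by absolute TSS distance within the ±100 kb window.

    The distance is signed gene-relative: positive downstream of the TSS in
    the gene's orientation. Ties break lexicographically on gene id.
    """
    params = params or IntegrationParams()
    best: tuple[int, str, int] | None = None  # (|d|, gene_id, signed d)
    for gene in genes:
        if gene.chrom != chrom:
            continue
        d = site_midpoint - gene.tss
        if gene.strand == "-":
            d = -d
        key = (abs(d), gene.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(d), gene.gene_id, d)
    if best is None or best[0] > params.tss_window:
        return None
    return best[1], best[2]


def genomic_category(
    site_midpoint: int, gene: GeneModel | None, params: IntegrationParams | None = None
) -> str:
    """One of 7 genomic categories for a site, with fixed precedence.

    Precedence: promoter/TSS (−1 kb..+100 bp of the TSS, strand-aware) >
    TTS (±100 bp) > 5'UTR > 3'UTR > exon > intron > intergenic.
    """
    params = params or IntegrationParams()
    if gene is None:
        return "intergenic"
    mid = site_midpoint
    rel_tss = mid - gene.tss if gene.strand == "+" else gene.tss - mid
    lo, hi = params.promoter_tss
    if lo <= rel_tss < hi:
        return "promoter/TSS"
    if abs(mid - gene.tts) <= params.tts_window:
        return "TTS"
    if gene.start <= mid < gene.end:
        in_exon = any(s <= mid < e for s, e in gene.exons)
        cds_s, cds_e = gene.cds_start, gene.cds_end
        has_cds = cds_s is not None and cds_e is not None and cds_s < cds_e
        if in_exon and has_cds:
            if mid < cds_s:
                return "5'UTR" if gene.strand == "+" else "3'UTR"
            if mid >= cds_e:
                return "3'UTR" if gene.strand == "+" else "5'UTR"
        return "exon" if in_exon else "intron"
    return "intergenic"


def classify_binding_modes(
    occupied: list[tuple[MotifHit, Peak]],
    genes: list[GeneModel],
    condition_pair: str,
    params: IntegrationParams | None = None,
) -> dict[str, BindingModeRecord]:
    """Assign each gene the mode of its occupied classes within ±100 kb.

    Sites are annotated to their nearest TSS; genes with no occupied site in
    range receive no record. A gene with several co-binding regions
    contributes the union of its sites to a single gene-level mode.
    """
    params = params or IntegrationParams()
    params.validate()
    gene_by_id = {g.gene_id: g for g in genes}
    per_gene: dict[str, list] = {}
    for hit, peak in occupied:
        annot = annotate_nearest_tss(hit.midpoint, hit.chrom, genes, params)
        if annot is None:
            continue
        gene_id, distance = annot
        category = genomic_category(hit.midpoint, gene_by_id[gene_id], params)
        per_gene.setdefault(gene_id, []).append((hit, peak, distance, category))
    records: dict[str, BindingModeRecord] = {}
    for gene_id, sites in per_gene.items():
        classes = frozenset(hit.motif_class for hit, *_ in sites)
        records[gene_id] = BindingModeRecord(
            gene_id, condition_pair, classes, classes_to_mode(classes), sites
        )
    return records


def mode_overlap_table(
    modes_a: dict[str, BindingModeRecord] | dict[str, str],
    modes_b: dict[str, BindingModeRecord] | dict[str, str],
) -> pd.DataFrame:
    """Per-mode gene-list comparison between two condition pairs.

    Reports list sizes, the intersection and both percentage conventions;
    the sum-method percentage (100·|A∩B|/(|A|+|B|)) is the headline column.
    """
    def as_modes(d):
        return {
            g: (r.mode if isinstance(r, BindingModeRecord) else r) for g, r in d.items()
        }

    a, b = as_modes(modes_a), as_modes(modes_b)
    all_modes = [m for m in _MODE_ORDER if m in set(a.values()) | set(b.values())]
    rows = []
    for mode in all_modes:
        ga = {g for g, m in a.items() if m == mode}
        gb = {g for g, m in b.items() if m == mode}
        inter = len(ga & gb)
        union = len(ga | gb)
        rows.append(
            {
                "mode": mode,
                "n_a": len(ga),
                "n_b": len(gb),
                "n_common": inter,
                "pct_sum": round(100.0 * inter / (len(ga) + len(gb)), 2)
                if ga or gb else 0.0,
                "pct_jaccard": round(100.0 * inter / union, 2) if union else 0.0,
            }
        )
    return pd.DataFrame(rows)


_MODE_ORDER = (
    "GAS", "ISRE", "NFKB", "GAS-ISRE", "GAS-NFKB", "ISRE-NFKB", "GAS-ISRE-NFKB",
)


# ---------------------------------------------------------------------------
# Summit geometry
# ---------------------------------------------------------------------------

def summit_distance_histogram(
    stat1_peaks: list[Peak], p65_peaks: list[Peak],
    params: IntegrationParams | None = None,
) -> tuple[list[int], pd.DataFrame]:
    """Signed distance from each STAT1 summit to the closest p65 summit.

    Distance is p65 minus STAT1 in genome orientation. The histogram covers
    [−half_window, +half_window) in ``hist_bin`` steps; out-of-range
    distances stay in the returned distance list but not in the histogram.
    """
    params = params or IntegrationParams()
    params.validate()
    p65_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in p65_peaks}:
        p65_by_chrom[chrom] = np.array(
            sorted(p.summit for p in p65_peaks if p.chrom == chrom)
        )
    distances: list[int] = []
    for peak in stat1_peaks:
        summits = p65_by_chrom.get(peak.chrom)
        if summits is None or len(summits) == 0:
            continue
        i = int(np.searchsorted(summits, peak.summit))
        candidates = summits[max(0, i - 1) : i + 1]
        nearest = int(candidates[np.argmin(np.abs(candidates - peak.summit))])
        distances.append(nearest - peak.summit)
    half, width = params.hist_half_window, params.hist_bin
    edges = np.arange(-half, half + width, width)
    counts, _ = np.histogram(
        [d for d in distances if -half <= d < half], bins=edges
    )
    hist = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts})
    return distances, hist


# ---------------------------------------------------------------------------
# Occupancy matrix / RD clustering
# ---------------------------------------------------------------------------

@dataclass
class OccupancyMatrix:
    regions: list[Interval]
    sample_labels: list[str]
    rpkm: pd.DataFrame  # regions x samples
    clusters: np.ndarray  # 1..k per region
    rd: pd.DataFrame  # regions x (samples x bins), depth-normalized


def rpkm_values(
    regions: list[Interval], coverage: dict[str, Coverage]
) -> pd.DataFrame:
    """RPKM per merged region per sample.

    ``RPKM = reads_in_region / ((length/1000) * (total_reads/1e6))``; a
    sample with zero total tags yields zeros.
    """
    labels = [f"{chrom}:{start}-{end}" for chrom, start, end in regions]
    data = {}
    for name, cov in coverage.items():
        total = cov.total()
        col = np.zeros(len(regions))
        if total > 0:
            for i, (chrom, start, end) in enumerate(regions):
                reads = cov.region_sum(chrom, start, end)
                col[i] = reads / ((end - start) / 1_000.0) / (total / 1e6)
        data[name] = col
    return pd.DataFrame(data, index=labels)


def rpkm_and_cluster(
    regions: list[Interval],
    coverage: dict[str, Coverage],
    params: IntegrationParams | None = None,
    k: int | None = None,
) -> OccupancyMatrix:
    """RPKM occupancy matrix, k-means row clusters and the RD bin matrix.

    Clustering runs on log2(RPKM + 1) rows with a fixed seed. The RD (read
    density) matrix holds depth-normalized tag counts in ``hist_bin`` bins
    across ±``hist_half_window`` around each region center.
    """
    params = params or IntegrationParams()
    params.validate()
    k = k if k is not None else params.kmeans_k
    if k > len(regions):
        raise ValueError(f"k={k} exceeds the number of regions ({len(regions)})")
    rpkm = rpkm_values(regions, coverage)
    log_rpkm = np.log2(rpkm.to_numpy() + 1.0)
    km = KMeans(n_clusters=k, random_state=params.kmeans_seed, n_init=10)
    clusters = km.fit_predict(log_rpkm) + 1

    n_bins = 2 * params.hist_half_window // params.hist_bin
    rd_cols = {}
    for name, cov in coverage.items():
        total = cov.total()
        scale = 1e6 / total if total > 0 else 0.0
        block = np.zeros((len(regions), n_bins))
        for i, (chrom, start, end) in enumerate(regions):
            center = (start + end) // 2
            left = center - params.hist_half_window
            for b in range(n_bins):
                s = left + b * params.hist_bin
                block[i, b] = cov.region_sum(chrom, s, s + params.hist_bin) * scale
        for b in range(n_bins):
            rd_cols[f"{name}:bin{b:02d}"] = block[:, b]
    rd = pd.DataFrame(rd_cols, index=rpkm.index)
    return OccupancyMatrix(regions, list(rpkm.columns), rpkm, clusters, rd)
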