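"""Seeded generator of a toy genome, expression counts and ChIP peaks/coverage.

The generator plants a known truth — per-gene motif composition ("mode"),
expression effects with optional super-additive synergy, and a factor- and
condition-dependent peak schedule — and the analysis modules are scored
against that truth. Everything is a deterministic function of
``SimConfig.seed``: the same seed yields byte-identical FASTA, count tables
and peak files.

Model in brief
--------------
* Background sequence is i.i.d. uniform over ``{A, C, G, T}`` (order-0),
  which makes motif-scanner false-positive rates analytically predictable.
* Each gene is assigned one of 8 modes (``none`` plus the 7 non-empty
  subsets of {GAS, ISRE, NFκB}); the consensus string of each planted class
  is written into the promoter (−950/+50 around the TSS) or a distal
  position, with composite motifs spaced so that every pairwise midpoint
  distance stays inside ``composite_spacing`` (default 38–264 bp).
* Counts are negative binomial with mean ``base_mean · FC`` per condition.
  Genes with a STAT1 class (GAS/ISRE) respond to IFNα and IFNγ; NFκB genes
  respond to LPS. For synergy (SI) genes the combined-treatment mean is
  ``(FC_IFN + FC_LPS) · 2^synergy_log2_bonus`` — strictly super-additive —
  while non-SI genes saturate at ``max(FC_IFN, FC_LPS)``.
* STAT1 peaks cover planted GAS/ISRE motifs under IFN and IFN+LPS
  conditions; p65 peaks cover NFκB motifs under LPS and IFN+LPS, and — if
  ``sequential_recruitment`` is on — under IFN alone at composite sites
  only. Tag coverage is Poisson background with enriched bins under peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CELL_TYPES,
    CLASS_FACTOR,
    COMBO_PARTS,
    CONDITIONS,
    Coverage,
    CountMatrix,
    GeneModel,
    GenomeModel,
    MOTIF_CLASSES,
    Peak,
)
from .fixtures import default_motifs

MODES = (
    "none",
    "GAS",
    "ISRE",
    "NFKB",
    "GAS-ISRE",
    "GAS-NFKB",
    "ISRE-NFKB",
    "GAS-ISRE-NFKB",
)


def mode_classes(mode: str) -> tuple[str, ...]:
    """Motif classes planted for a mode, in canonical GAS < ISRE < NFKB order."""
    return () if mode == "none" else tuple(mode.split("-"))


def classes_to_mode(classes) -> str:
    ordered = [c for c in MOTIF_CLASSES if c in set(classes)]
    return "-".join(ordered) if ordered else "none"


@dataclass
class SimConfig:
    """Parameters of the simulated study (3 cell types x 6 conditions)."""

    n_chroms: int = 4
    chrom_length: int = 600_000
    n_genes: int = 160
    gene_length: int = 2_000
    # majority-null transcriptome: median-of-ratios normalization assumes
    # most genes are unchanged, as in real RNA-seq
    mode_fractions: dict[str, float] = field(
        default_factory=lambda: {
            m: (0.65 if m == "none" else 0.05) for m in MODES
        }
    )
    promoter_fraction: float = 0.5
    distal_range: tuple[int, int] = (1_500, 5_000)
    composite_spacing: tuple[int, int] = (38, 264)
    base_mean: float = 60.0
    dispersion: float = 0.05
    log2fc_ifn: float = 3.0
    log2fc_lps: float = 3.0
    synergy_log2_bonus: float = 2.0
    fraction_si: float = 0.5
    shared_fraction: float = 0.8
    n_replicates: int = 3
    peak_width: int = 200
    summit_jitter: int = 0
    tag_depth: int = 200_000
    coverage_bin: int = 25
    peak_enrichment: float = 20.0
    sequential_recruitment: bool = True
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.mode_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("mode fractions must sum to 1")
        if set(self.mode_fractions) - set(MODES):
            raise ValueError(f"unknown modes: {set(self.mode_fractions) - set(MODES)}")
        if self.composite_spacing[0] <= 0 or self.composite_spacing[0] > self.composite_spacing[1]:
            raise ValueError("composite spacing range must be positive and ordered")
        if self.base_mean <= 0:
            raise ValueError("base mean must be positive")
        if self.distal_range[1] > 100_000:
            raise ValueError("distal motifs must stay within 100 kb of the TSS")

    def rng(self, stream: int) -> np.random.Generator:
        # independent named substreams so each generator stage is reproducible
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SyntheticTruth:
    """Planted ground truth used as the recovery oracle."""

    config: SimConfig
    genes: list[GeneModel]
    mode: dict[str, str]
    motifs: dict[str, dict[str, tuple[str, int, int]]]
    affected_cell_types: dict[str, tuple[str, ...]]
    si_flag: dict[str, bool]

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def expected_fc(self, gene_id: str, cell_type: str, condition: str) -> float:
        """Planted linear fold change vs control for one gene/sample group."""
        if condition == "control":
            return 1.0
        cfg = self.config
        classes = set(mode_classes(self.mode[gene_id]))
        affected = cell_type in self.affected_cell_types[gene_id]
        fc_ifn = 2.0 ** cfg.log2fc_ifn if affected and classes & {"GAS", "ISRE"} else 1.0
        fc_lps = 2.0 ** cfg.log2fc_lps if affected and "NFKB" in classes else 1.0
        if condition in ("IFNa", "IFNg"):
            return fc_ifn
        if condition == "LPS":
            return fc_lps
        if condition in COMBO_PARTS:
            if affected and self.si_flag[gene_id]:
                return (fc_ifn + fc_lps) * 2.0 ** cfg.synergy_log2_bonus
            return max(fc_ifn, fc_lps)
        raise ValueError(f"unknown condition {condition!r}")

    def is_si(self, gene_id: str, cell_type: str, combo: str) -> bool:
        """Truth of the SI statistic: FC(combo) strictly exceeds the FC sum."""
        ifn, lps = COMBO_PARTS[combo]
        return self.expected_fc(gene_id, cell_type, combo) > (
            self.expected_fc(gene_id, cell_type, ifn)
            + self.expected_fc(gene_id, cell_type, lps)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            motifs = self.motifs[g.gene_id]
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "mode": self.mode[g.gene_id],
                    "si_flag": int(self.si_flag[g.gene_id]),
                    "affected_cell_types": ",".join(self.affected_cell_types[g.gene_id]),
                    "motif_coords": ";".join(
                        f"{c}:{chrom}:{s}-{e}" for c, (chrom, s, e) in motifs.items()
                    ),
                }
            )
        return pd.DataFrame(rows)


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    codes = rng.integers(0, 4, size=length)
    return bytearray(np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes())


def simulate_genome(config: SimConfig) -> tuple[GenomeModel, list[GeneModel], SyntheticTruth]:
    """Generate the toy genome with planted motifs and the truth record."""
    config.validate()
    rng = config.rng(1)
    pwms = default_motifs()
    consensus = {c: pwms[c].consensus for c in MOTIF_CLASSES}
    motif_len = {c: len(s) for c, s in consensus.items()}

    per_chrom = -(-config.n_genes // config.n_chroms)
    slot = config.chrom_length // per_chrom
    margin = config.distal_range[1] + config.composite_spacing[1] + 1_000
    if slot < config.gene_length + 2 * margin:
        raise ValueError(
            "genes do not fit on the genome; increase chrom_length "
            f"(need >= {per_chrom * (config.gene_length + 2 * margin)} bp per chromosome)"
        )

    seqs = {
        f"chr{i + 1}": _random_sequence(rng, config.chrom_length)
        for i in range(config.n_chroms)
    }

    # per-gene planted attributes
    modes = list(config.mode_fractions)
    probs = np.array([config.mode_fractions[m] for m in modes])
    gene_modes = rng.choice(modes, size=config.n_genes, p=probs)

    genes: list[GeneModel] = []
    mode_of: dict[str, str] = {}
    motif_of: dict[str, dict[str, tuple[str, int, int]]] = {}
    affected: dict[str, tuple[str, ...]] = {}
    si: dict[str, bool] = {}

    for idx in range(config.n_genes):
        gene_id = f"gene{idx + 1:04d}"
        chrom = f"chr{idx % config.n_chroms + 1}"
        slot_idx = idx // config.n_chroms
        start = slot_idx * slot + margin
        end = start + config.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        exon1 = (start, start + min(400, config.gene_length // 4))
        exon2 = (end - min(1_200, config.gene_length // 2), end)
        gene = GeneModel(
            gene_id,
            chrom,
            strand,
            start,
            end,
            (exon1, exon2),
            cds_start=start + min(300, config.gene_length // 6),
            cds_end=end - min(300, config.gene_length // 6),
        )
        genes.append(gene)
        mode = str(gene_modes[idx])
        mode_of[gene_id] = mode
        classes = mode_classes(mode)

        coords: dict[str, tuple[str, int, int]] = {}
        if classes:
            # total block width from per-adjacent midpoint spacings
            k = len(classes)
            smin, smax = config.composite_spacing
            hi = max(smin, smax // max(1, k - 1))
            spacings = [int(rng.integers(smin, hi + 1)) for _ in range(k - 1)]
            width = motif_len[classes[-1]] + sum(spacings)
            in_promoter = rng.random() < config.promoter_fraction
            if in_promoter:
                # strand-aware promoter window (-950/+50), forward coordinates
                if strand == "+":
                    win_lo, win_hi = gene.tss - 950, gene.tss + 50
                else:
                    win_lo, win_hi = gene.tss - 49, gene.tss + 951
                block_start = int(rng.integers(win_lo, win_hi - width))
            else:
                offset = int(rng.integers(config.distal_range[0], config.distal_range[1] + 1))
                sign = 1 if rng.random() < 0.5 else -1
                anchor = gene.tss + sign * offset
                block_start = anchor - width // 2
            pos = block_start
            for j, cls in enumerate(classes):
                s, e = pos, pos + motif_len[cls]
                seqs[chrom][s:e] = consensus[cls].encode()
                coords[cls] = (chrom, s, e)
                if j < k - 1:
                    pos += spacings[j]
        motif_of[gene_id] = coords

        if rng.random() < config.shared_fraction:
            affected[gene_id] = CELL_TYPES
        else:
            affected[gene_id] = (str(rng.choice(CELL_TYPES)),)
        si[gene_id] = bool(classes) and rng.random() < config.fraction_si

    genome = GenomeModel(
        {c: len(s) for c, s in seqs.items()},
        {c: s.decode() for c, s in seqs.items()},
    )
    truth = SyntheticTruth(config, genes, mode_of, motif_of, affected, si)
    return genome, genes, truth


def simulate_expression(truth: SyntheticTruth, config: SimConfig | None = None) -> CountMatrix:
    """Draw negative-binomial counts for 3 cell types x 6 conditions x replicates."""
    config = config or truth.config
    if config.base_mean <= 0:
        raise ValueError("base mean must be positive")
    rng = config.rng(2)
    sample_rows = []
    for ct in CELL_TYPES:
        for cond in CONDITIONS:
            for rep in range(1, config.n_replicates + 1):
                sample_rows.append(
                    {"sample": f"{ct}_{cond}_r{rep}", "cell_type": ct,
                     "condition": cond, "replicate": rep}
                )
    samples = pd.DataFrame(sample_rows)

    gene_ids = [g.gene_id for g in truth.genes]
    mu = np.empty((len(gene_ids), len(samples)))
    for i, gid in enumerate(gene_ids):
        for j, row in samples.iterrows():
            mu[i, j] = config.base_mean * truth.expected_fc(
                gid, row["cell_type"], row["condition"]
            )
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)
    table = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                         columns=list(samples["sample"]))
    return CountMatrix(table, samples)


def peak_conditions(motif_class: str, gene_mode: str, config: SimConfig) -> tuple[str, ...]:
    """Conditions under which a planted motif instance carries a peak."""
    classes = set(mode_classes(gene_mode))
    if motif_class in ("GAS", "ISRE"):
        return ("IFNa", "IFNg", "IFNa_LPS", "IFNg_LPS")
    conds = ["LPS", "IFNa_LPS", "IFNg_LPS"]
    composite = bool(classes & {"GAS", "ISRE"})
    if config.sequential_recruitment and composite:
        conds = ["IFNa", "IFNg"] + conds
    return tuple(conds)


def simulate_chip(
    truth: SyntheticTruth, config: SimConfig | None = None
) -> tuple[dict[tuple[str, str], list[Peak]], dict[tuple[str, str], Coverage]]:
    """Generate peak sets and binned tag coverage for 2 factors x 6 conditions."""
    config = config or truth.config
    rng = config.rng(3)
    lengths = {g.chrom: config.chrom_length for g in truth.genes}
    for i in range(config.n_chroms):
        lengths[f"chr{i + 1}"] = config.chrom_length

    peaks: dict[tuple[str, str], list[Peak]] = {
        (f, c): [] for f in ("STAT1", "p65") for c in CONDITIONS
    }
    for gene in truth.genes:
        gid = gene.gene_id
        for cls, (chrom, m_start, m_end) in truth.motifs[gid].items():
            factor = CLASS_FACTOR[cls]
            mid = (m_start + m_end) // 2
            start = max(0, mid - config.peak_width // 2)
            end = min(lengths[chrom], start + config.peak_width)
            base_summit = mid - start
            for cond in peak_conditions(cls, truth.mode[gid], config):
                jitter = (
                    int(rng.integers(-config.summit_jitter, config.summit_jitter + 1))
                    if config.summit_jitter > 0
                    else 0
                )
                summit = min(max(base_summit + jitter, 0), end - start - 1)
                peaks[(factor, cond)].append(
                    Peak(chrom, start, end, summit, factor, cond,
                         score=config.peak_enrichment, name=f"{gid}:{cls}")
                )
    for key in peaks:
        peaks[key].sort(key=lambda p: (p.chrom, p.start, p.end))

    n_bins = {c: -(-l // config.coverage_bin) for c, l in lengths.items()}
    total_bins = sum(n_bins.values())
    bg_rate = config.tag_depth / total_bins
    coverage: dict[tuple[str, str], Coverage] = {}
    for factor in ("STAT1", "p65"):
        for cond in CONDITIONS:
            lam = {c: np.full(n, bg_rate) for c, n in n_bins.items()}
            for p in peaks[(factor, cond)]:
                lo = p.start // config.coverage_bin
                hi = -(-p.end // config.coverage_bin)
                lam[p.chrom][lo:hi] *= config.peak_enrichment
            values = {c: rng.poisson(a).astype(float) for c, a in lam.items()}
            coverage[(factor, cond)] = Coverage(config.coverage_bin, values)
    return peaks, coverage
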