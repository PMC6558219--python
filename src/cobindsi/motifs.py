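"""Two PWM-scanning dialects and per-gene promoter site profiles.

``log_odds_scan`` is the genome-wide dialect: natural-log likelihood ratio of
the PWM against a background base distribution, thresholded per motif class
by a Motif Score Threshold (MST; defaults GAS 6, ISRE 6, NFκB 7).

``matrix_similarity_scan`` is the promoter dialect: the per-window sum of
matched-base probabilities, min-max normalized to [0, 1] using the
per-column maximum and minimum probabilities, so the consensus scores 1
for any non-degenerate matrix. The exact normalization is this package's
documented dialect; thresholds default to 0.85 (GAS/ISRE) and 0.90 (NFκB).

Both dialects scan both strands by default, report reverse-strand hits in
forward coordinates, and score ``N`` as background (zero log-odds
contribution; background probability under the similarity dialect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GeneModel, GenomeModel, MotifHit, PWM

_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
_COMP_ROW = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N fixed


@dataclass
class ScanParams:
    """Genome-wide log-odds scan parameters."""

    mst: dict[str, float] = field(
        default_factory=lambda: {"GAS": 6.0, "ISRE": 6.0, "NFKB": 7.0}
    )
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    both_strands: bool = True
    pseudocount: float = 1e-3
    log_base: float | None = None  # None = natural log

    def validate(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if min(self.background) <= 0 and self.pseudocount <= 0:
            raise ValueError(
                "zero background frequency cannot be scored without a pseudocount"
            )


@dataclass
class PromoterScanParams:
    """Promoter-window matrix-similarity scan parameters."""

    window: tuple[int, int] = (-950, 50)  # relative to TSS, half-open
    thresholds: dict[str, float] = field(
        default_factory=lambda: {"GAS": 0.85, "ISRE": 0.85, "NFKB": 0.90}
    )
    both_strands: bool = True

    def validate(self) -> None:
        lo, hi = self.window
        if hi - lo <= 0:
            raise ValueError("promoter window must have positive length")
        for cls, t in self.thresholds.items():
            if not 0.0 < t <= 1.0:
                raise ValueError(f"{cls}: similarity threshold must be in (0, 1]")


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Sum ``matrix[code[i+j], j]`` over j for every window start i.

    ``matrix`` is 5 x L (rows A, C, G, T, N). Accumulates column by column to
    avoid materializing the full windows-by-L intermediate.
    """
    length = matrix.shape[1]
    n_windows = len(codes) - length + 1
    if n_windows <= 0:
        return np.empty(0)
    scores = np.zeros(n_windows)
    for j in range(length):
        scores += matrix[codes[j : j + n_windows], j]
    return scores


def _log_odds_matrix(pwm: PWM, params: ScanParams) -> np.ndarray:
    eps = params.pseudocount
    probs = (pwm.probs + eps) / (1.0 + 4.0 * eps)
    q = np.asarray(params.background)[:, None]
    with np.errstate(divide="ignore"):
        m = np.log(probs / q)
    if params.log_base is not None:
        m /= np.log(params.log_base)
    full = np.vstack([m, np.zeros(pwm.length)])  # N row scores as background
    return full


def _revcomp_matrix(matrix: np.ndarray) -> np.ndarray:
    return matrix[_COMP_ROW][:, ::-1]


def log_odds_scan(
    sequence: str, pwm: PWM, params: ScanParams | None = None, chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """All windows scoring at least the class MST on either strand.

    Reverse-strand hits are reported in forward coordinates. ``offset`` is
    added to hit coordinates (for scanning sub-sequences in place).
    """
    params = params or ScanParams()
    params.validate()
    codes = _encode(sequence)
    matrix = _log_odds_matrix(pwm, params)
    threshold = params.mst[pwm.motif_class]
    hits: list[MotifHit] = []
    strands = [("+", matrix)]
    if params.both_strands:
        strands.append(("-", _revcomp_matrix(matrix)))
    for strand, m in strands:
        scores = _window_scores(codes, m)
        for i in np.nonzero(scores >= threshold)[0]:
            hits.append(
                MotifHit(pwm.pwm_id, pwm.motif_class, chrom,
                         offset + int(i), offset + int(i) + pwm.length,
                         strand, float(scores[i]))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def matrix_similarity_scan(
    sequence: str, pwm: PWM, threshold: float, both_strands: bool = True,
    chrom: str = "seq", offset: int = 0,
) -> list[MotifHit]:
    """Windows whose min-max normalized probability sum reaches ``threshold``.

    ``similarity = (raw - raw_min) / (raw_max - raw_min)`` where raw is the
    per-window sum of matched-base probabilities and raw_max/raw_min use the
    per-column maximum/minimum. Invariant to affine rescaling of raw scores.
    """
    raw_max = float(pwm.probs.max(axis=0).sum())
    raw_min = float(pwm.probs.min(axis=0).sum())
    if raw_max <= raw_min:
        raise ValueError(f"{pwm.pwm_id}: degenerate PWM (raw_max == raw_min)")
    codes = _encode(sequence)
    base_matrix = np.vstack([pwm.probs, np.full(pwm.length, 0.25)])
    hits: list[MotifHit] = []
    strands = [("+", base_matrix)]
    if both_strands:
        strands.append(("-", _revcomp_matrix(base_matrix)))
    for strand, m in strands:
        raw = _window_scores(codes, m)
        sim = (raw - raw_min) / (raw_max - raw_min)
        for i in np.nonzero(sim >= threshold)[0]:
            hits.append(
                MotifHit(pwm.pwm_id, pwm.motif_class, chrom,
                         offset + int(i), offset + int(i) + pwm.length, strand,
                         log_odds=float(raw[i]),
                         similarity=float(min(sim[i], 1.0)))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def promoter_window(gene: GeneModel, params: PromoterScanParams) -> tuple[int, int]:
    """Strand-aware promoter interval in forward genome coordinates.

    On the plus strand the relative window [lo, hi) maps directly; on the
    minus strand it is mirrored around the TSS, so the default −950/+50
    window becomes ``[tss - hi + 1, tss - lo + 1)``.
    """
    lo, hi = params.window
    if gene.strand == "+":
        return gene.tss + lo, gene.tss + hi
    return gene.tss - hi + 1, gene.tss - lo + 1


def promoter_site_profile(
    genes: list[GeneModel],
    genome: GenomeModel,
    pwms: dict[str, PWM | list[PWM]],
    params: PromoterScanParams | None = None,
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Per-gene promoter presence sets and their 7-region Venn counts.

    A motif class is present for a gene iff at least one matrix-similarity
    hit of any PWM of that class falls inside the strand-aware promoter
    window (clipped to the chromosome). The Venn partition covers the genes
    with at least one class present.
    """
    params = params or PromoterScanParams()
    params.validate()
    presence: dict[str, set[str]] = {}
    for gene in genes:
        length = genome.lengths[gene.chrom]
        if not 0 <= gene.tss < length:
            raise ValueError(f"{gene.gene_id}: TSS outside chromosome {gene.chrom}")
        lo, hi = promoter_window(gene, params)
        lo, hi = max(0, lo), min(length, hi)
        window_seq = genome.sequence(gene.chrom)[lo:hi]
        found: set[str] = set()
        for cls, pwm_or_list in pwms.items():
            candidates = pwm_or_list if isinstance(pwm_or_list, list) else [pwm_or_list]
            threshold = params.thresholds[cls]
            for pwm in candidates:
                if matrix_similarity_scan(
                    window_seq, pwm, threshold, params.both_strands, gene.chrom, lo
                ):
                    found.add(cls)
                    break
        presence[gene.gene_id] = found

    from .expression import common_genes  # local import to avoid cycles

    class_lists = [
        [g for g, classes in presence.items() if cls in classes]
        for cls in ("GAS", "ISRE", "NFKB")
    ]
    _, venn = common_genes(class_lists)
    return presence, venn
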