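"""Domain types and readers/writers for the standard formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) throughout the
package; any 1-based coordinate only ever appears in formatted output. The TSS
of a minus-strand gene is the last base of its span (``end - 1``), a point
coordinate, matching the nearest-TSS semantics of standard peak annotators.

Sequences are stored upper-case over the alphabet ``{A, C, G, T, N}``; ``N``
bases score as background under every scanning dialect rather than failing.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CELL_TYPES = ("VSMC", "MP", "DC")
CONDITIONS = ("control", "IFNa", "IFNg", "LPS", "IFNa_LPS", "IFNg_LPS")
COMBO_CONDITIONS = ("IFNa_LPS", "IFNg_LPS")
#: single-treatment components of each combined condition
COMBO_PARTS = {"IFNa_LPS": ("IFNa", "LPS"), "IFNg_LPS": ("IFNg", "LPS")}
FACTORS = ("STAT1", "p65")
MOTIF_CLASSES = ("GAS", "ISRE", "NFKB")
#: which ChIP factor can occupy each motif class
CLASS_FACTOR = {"GAS": "STAT1", "ISRE": "STAT1", "NFKB": "p65"}

DNA_ALPHABET = set("ACGTN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """A set of named chromosome sequences (or bare lengths)."""

    lengths: dict[str, int]
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
            seq = self.sequences.get(chrom)
            if seq is not None and len(seq) != length:
                raise ValueError(
                    f"chromosome {chrom!r}: sequence length {len(seq)} != declared {length}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def sequence(self, chrom: str) -> str:
        return self.sequences[chrom]


@dataclass(frozen=True)
class GeneModel:
    """A gene as a stranded span with exon blocks (BED12 semantics).

    ``cds_start``/``cds_end`` mirror BED12 thickStart/thickEnd and delimit the
    coding span; equal values mean a non-coding transcript (no UTRs).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: invalid span [{self.start}, {self.end})")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValueError(f"{self.gene_id}: exon [{s}, {e}) violates span/order")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site (point coordinate)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site (point coordinate)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Peak:
    """A factor- and condition-labelled ChIP interval with a summit."""

    chrom: str
    start: int
    end: int
    summit_offset: int
    factor: str
    condition: str
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid peak interval [{self.start}, {self.end})")
        if not 0 <= self.summit_offset < self.end - self.start:
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length {self.end - self.start}"
            )

    @property
    def summit(self) -> int:
        return self.start + self.summit_offset


@dataclass
class PWM:
    """Position weight matrix: base probabilities per column.

    ``probs`` is a 4 x L array in A, C, G, T row order. Probabilities are
    regularized as ``(count + pseudocount) / (total + 4 * pseudocount)``.
    """

    pwm_id: str
    motif_class: str
    probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError(f"{self.pwm_id}: PWM must be 4 x L with L >= 4")
        col_sums = self.probs.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-6):
            raise ValueError(f"{self.pwm_id}: column probabilities do not sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))

    @classmethod
    def from_counts(
        cls, pwm_id: str, motif_class: str, counts: np.ndarray, pseudocount: float = 0.0
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"{pwm_id}: counts must be a 4 x L table")
        if (counts < 0).any():
            raise ValueError(f"{pwm_id}: negative counts")
        totals = counts.sum(axis=0) + 4 * pseudocount
        if (totals == 0).any():
            raise ValueError(f"{pwm_id}: all-zero column with zero pseudocount")
        probs = (counts + pseudocount) / totals
        return cls(pwm_id, motif_class, probs, pseudocount)


@dataclass(frozen=True)
class MotifHit:
    """A located, scored PWM occurrence in forward-strand coordinates."""

    pwm_id: str
    motif_class: str
    chrom: str
    start: int
    end: int
    strand: str
    log_odds: float
    similarity: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_odds):
            raise ValueError("log-odds score must be finite")
        if self.similarity is not None and not 0.0 <= self.similarity <= 1.0 + 1e-9:
            raise ValueError(f"similarity {self.similarity} outside [0, 1]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class CountMatrix:
    """Replicate-level gene counts with sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Genes x samples table of non-negative integers; index is gene ids.
    samples : pandas.DataFrame
        One row per count column with columns ``sample``, ``cell_type``,
        ``condition``, ``replicate``; order matches the count columns.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame) -> None:
        samples = samples.reset_index(drop=True)
        required = {"sample", "cell_type", "condition", "replicate"}
        missing = required - set(samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if samples["sample"].duplicated().any():
            dups = samples.loc[samples["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample labels: {dups}")
        if list(counts.columns) != list(samples["sample"]):
            raise ValueError("count columns do not match sample sheet order")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        for cell_type, group in samples.groupby("cell_type"):
            if not (group["condition"] == "control").any():
                raise ValueError(f"cell type {cell_type!r} has no control sample")
        self.counts = counts
        self.samples = samples

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.samples["cell_type"]))

    def columns_for(self, cell_type: str, condition: str | None = None) -> list[str]:
        mask = self.samples["cell_type"] == cell_type
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.loc[mask, "sample"])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path) -> GenomeModel:
    """Read a FASTA file into a :class:`GenomeModel`, case-folded to upper.

    Raises on duplicate headers and on characters outside ``{A,C,G,T,N}``.
    """
    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise FormatError(f"duplicate FASTA header: {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(f"non-DNA characters {sorted(bad)} in {name!r}")
        sequences[name] = seq
        lengths[name] = len(seq)
    if not lengths:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeModel(lengths, sequences)


def write_fasta(genome: GenomeModel, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[c]), id=c, description="") for c in genome.chroms
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# narrowPeak / BED6 peaks
# ---------------------------------------------------------------------------

def parse_narrowpeak(path, factor: str, condition: str) -> list[Peak]:
    """Read a 6- or 10-column BED peak file into sorted :class:`Peak` objects.

    Ten-column (narrowPeak) input carries the summit offset in column 10; for
    6-column input the summit defaults to the interval midpoint.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) not in (6, 10):
                raise FormatError(
                    f"{path}:{lineno}: expected 6 or 10 columns, got {len(fields)}"
                )
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: empty interval [{start}, {end})")
            name = fields[3] if len(fields) >= 4 else "."
            try:
                score = float(fields[4]) if fields[4] != "." else 0.0
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad score {fields[4]!r}") from None
            if len(fields) == 10:
                summit = int(fields[9])
                if not 0 <= summit < end - start:
                    raise FormatError(
                        f"{path}:{lineno}: summit offset {summit} outside interval"
                    )
            else:
                summit = (end - start) // 2
            peaks.append(Peak(chrom, start, end, summit, factor, condition, score, name))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_narrowpeak(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\t"
                f"0\t-1\t-1\t{p.summit_offset}\n"
            )


# ---------------------------------------------------------------------------
# BED12 gene models
# ---------------------------------------------------------------------------

def parse_gene_models(path) -> list[GeneModel]:
    """Read BED12 gene models, reconstructing exons from the block columns."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            cds_start, cds_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            for s, e in exons:
                if e > end or s < start:
                    raise FormatError(f"{path}:{lineno}: block [{s}, {e}) exceeds span")
            try:
                genes.append(
                    GeneModel(name, chrom, strand, start, end, exons, cds_start, cds_end)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_models(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, e in g.exons)
            cds_s = g.cds_start if g.cds_start is not None else g.start
            cds_e = g.cds_end if g.cds_end is not None else g.start
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{cds_s}\t{cds_e}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

def parse_jaspar_pfm(path, motif_class: str, pseudocount: float = 0.0) -> PWM:
    """Read a JASPAR-style PFM (4 rows of counts, A/C/G/T) into a :class:`PWM`.

    Accepts both the bracketed JASPAR dialect (``>ID`` header, ``A [ ... ]``
    rows) and a bare 4-row count table. Probabilities are
    ``(count + pseudocount) / (column total + 4 * pseudocount)``.
    """
    with open(path) as fh:
        text = fh.read()
    pwm_id = "pfm"
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        pwm_id = lines[0][1:].split()[0]
        try:
            motif = bio_motifs.read(io.StringIO(text), "jaspar")
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse JASPAR PFM ({exc})") from None
        counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    else:
        rows = []
        for lineno, ln in enumerate(lines, start=1):
            parts = ln.replace("[", " ").replace("]", " ").split()
            if parts and parts[0].upper() in "ACGT" and len(parts[0]) == 1:
                parts = parts[1:]
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric count") from None
        if len(rows) != 4:
            raise FormatError(f"{path}: expected 4 count rows, got {len(rows)}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"{path}: ragged count rows (lengths {sorted(widths)})")
        counts = np.array(rows, dtype=float)
    if (counts < 0).any():
        raise FormatError(f"{path}: negative counts")
    return PWM.from_counts(pwm_id, motif_class, counts, pseudocount)


def write_jaspar_pfm(pwm_id: str, counts: np.ndarray, path, description: str = "") -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{pwm_id} {description}".rstrip() + "\n")
        for base, row in zip("ACGT", counts):
            cells = " ".join(f"{v:6g}" for v in row)
            fh.write(f"{base} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def parse_sample_sheet(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "cell_type", "condition", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return samples


def parse_counts_table(path, metadata: pd.DataFrame) -> CountMatrix:
    """Read a genes x samples TSV of integer counts, validated against metadata.

    The first column holds gene ids; remaining columns must exactly match the
    ``sample`` column of ``metadata`` (order taken from the metadata).
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    table_cols = set(table.columns)
    meta_cols = set(metadata["sample"])
    extra = sorted(table_cols - meta_cols)
    absent = sorted(meta_cols - table_cols)
    if extra or absent:
        raise FormatError(
            f"{path}: column/metadata mismatch (not in metadata: {extra}; "
            f"missing from table: {absent})"
        )
    table = table[list(metadata["sample"])]
    if table.isna().any().any():
        raise FormatError(f"{path}: missing values are not allowed")
    values = table.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise FormatError(f"{path}: non-integer counts present")
    if (values < 0).any():
        raise FormatError(f"{path}: negative counts present")
    return CountMatrix(table.astype(np.int64), metadata)


def write_counts_table(cm: CountMatrix, counts_path, samples_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(samples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Binned tag coverage
# ---------------------------------------------------------------------------

@dataclass
class Coverage:
    """Per-chromosome tag counts in fixed-width bins (one ChIP sample).

    ``values[chrom][i]`` is the tag count in ``[i * bin_size, (i+1) * bin_size)``.
    """

    bin_size: int
    values: dict[str, np.ndarray]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Total tags in bins overlapping ``[start, end)`` on ``chrom``."""
        arr = self.values.get(chrom)
        if arr is None:
            return 0.0
        lo = max(0, start // self.bin_size)
        hi = min(len(arr), -(-end // self.bin_size))
        return float(arr[lo:hi].sum())

    def to_bedgraph_records(self):
        for chrom, arr in self.values.items():
            for i, v in enumerate(arr):
                if v:
                    yield (chrom, i * self.bin_size, (i + 1) * self.bin_size, float(v))

    @classmethod
    def from_bedgraph_records(cls, records, bin_size: int, lengths: dict[str, int]) -> "Coverage":
        values = {
            chrom: np.zeros(-(-length // bin_size)) for chrom, length in lengths.items()
        }
        for chrom, start, end, value in records:
            if (end - start) != bin_size and start // bin_size != (end - 1) // bin_size:
                raise ValueError("bedGraph intervals must respect the bin grid")
            values[chrom][start // bin_size] += value
        return cls(bin_size, values)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def parse_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file into ``{name: (description, members)}``."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = (desc, members)
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def parse_bedgraph(path) -> list[tuple[str, int, int, float]]:
    """Read a bedGraph into (chrom, start, end, value) tuples, half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: empty interval")
            out.append((chrom, start, end, value))
    return out


def write_bedgraph(records, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
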