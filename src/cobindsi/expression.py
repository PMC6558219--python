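"""Expression pipeline: normalization, fold changes, commonality and synergy.

The flow mirrors a standard bulk RNA-seq comparison design: median-of-ratios
size factors, an expressed-signal filter (normalized replicate mean > 8 in at
least one condition of a cell type), per-condition fold changes against the
cell type's control, up-regulated gene lists (FC >= 2 by default), three-way
Venn commonality across cell types, and the signal-integration (SI) statistic

    SI  <=>  FC(IFN + LPS)  >  FC(IFN) + FC(LPS)        (strict)

which flags genes whose combined-treatment response is super-additive.

Two overlap percentages are provided because the published figures use two
different denominators: ``jaccard`` = 100 * |A∩B| / |A∪B| and
``sum`` = 100 * |A∩B| / (|A| + |B|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import COMBO_PARTS, CONDITIONS, CountMatrix

TREATED_CONDITIONS = tuple(c for c in CONDITIONS if c != "control")


@dataclass(frozen=True)
class ExpressionRecord:
    """Per gene x cell type: normalized means, fold changes, up flags."""

    gene_id: str
    cell_type: str
    means: dict  # condition -> normalized replicate mean
    fc: dict  # treated condition -> FC vs control
    expressed: bool
    up: dict  # treated condition -> bool

    def log2fc(self, condition: str) -> float:
        return float(np.log2(self.fc[condition]))


@dataclass(frozen=True)
class SIRecord:
    gene_id: str
    cell_type: str
    combo: str
    fc_combo: float
    fc_ifn: float
    fc_lps: float

    @property
    def si_flag(self) -> bool:
        return self.fc_combo > self.fc_ifn + self.fc_lps


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization statistic).

    ``factor_j = median_i( count_ij / geomean_i )`` over genes with strictly
    positive counts in every sample. Identical columns yield all-ones.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; cannot form the "
            "reference (pseudo-reference fallback is off)"
        )
    ref = counts[all_positive]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geomean, axis=0))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def normalize_and_filter(
    cm: CountMatrix, factors: pd.Series, cutoff: float = 8.0
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Divide counts by size factors and apply the expressed-signal filter.

    A gene counts as expressed in a cell type iff its normalized replicate
    mean exceeds ``cutoff`` (strictly) in at least one condition of that cell
    type.
    """
    normalized = cm.counts / factors
    expressed: dict[str, set[str]] = {}
    for ct in cm.cell_types:
        passing: set[str] = set()
        for cond in CONDITIONS:
            cols = cm.columns_for(ct, cond)
            if not cols:
                continue
            means = normalized[cols].mean(axis=1)
            passing |= set(normalized.index[means > cutoff])
        expressed[ct] = passing
    return normalized, expressed


def fold_changes(
    cm: CountMatrix,
    normalized: pd.DataFrame,
    expressed: dict[str, set[str]],
    pseudocount: float = 0.5,
    fc_cutoff: float = 2.0,
    strict_boundary: bool = False,
) -> list[ExpressionRecord]:
    """Per-condition fold changes vs the cell type's control.

    ``FC = (mean_treated + eps) / (mean_control + eps)`` with a symmetric
    pseudocount so that induced-from-zero genes remain finite. A gene is "up"
    in a condition iff it passed the expressed filter and FC >= ``fc_cutoff``
    (or strictly greater when ``strict_boundary``).
    """
    records: list[ExpressionRecord] = []
    for ct in cm.cell_types:
        cond_means: dict[str, pd.Series] = {}
        for cond in CONDITIONS:
            cols = cm.columns_for(ct, cond)
            if not cols:
                raise ValueError(f"missing condition {cond!r} for cell type {ct!r}")
            cond_means[cond] = normalized[cols].mean(axis=1)
        control = cond_means["control"]
        for gene_id in normalized.index:
            means = {c: float(cond_means[c][gene_id]) for c in CONDITIONS}
            fc = {
                c: (means[c] + pseudocount) / (means["control"] + pseudocount)
                for c in TREATED_CONDITIONS
            }
            is_expressed = gene_id in expressed.get(ct, set())
            up = {
                c: is_expressed
                and (fc[c] > fc_cutoff if strict_boundary else fc[c] >= fc_cutoff)
                for c in TREATED_CONDITIONS
            }
            records.append(ExpressionRecord(gene_id, ct, means, fc, is_expressed, up))
    return records


def up_regulated_lists(records: list[ExpressionRecord]) -> dict[tuple[str, str], list[str]]:
    """Genes flagged up per (cell type, condition), sorted by descending FC."""
    lists: dict[tuple[str, str], list[tuple[float, str]]] = {}
    for rec in records:
        for cond in TREATED_CONDITIONS:
            if rec.up[cond]:
                lists.setdefault((rec.cell_type, cond), []).append((rec.fc[cond], rec.gene_id))
    return {
        key: [g for _, g in sorted(vals, key=lambda t: (-t[0], t[1]))]
        for key, vals in lists.items()
    }


def common_genes(lists: dict[str, list[str]] | list[list[str]]):
    """Triple intersection plus the full 7-region Venn partition.

    Returns ``(common_set, venn_counts)`` where ``venn_counts`` maps a
    membership key like ``"110"`` (in list 1 and 2, not 3) to a count; the
    counts partition the union exactly.
    """
    if isinstance(lists, dict):
        sets = [set(v) for v in lists.values()]
    else:
        sets = [set(v) for v in lists]
    if len(sets) != 3:
        raise ValueError("common_genes expects exactly three lists")
    a, b, c = sets
    venn: dict[str, int] = {}
    for gene in a | b | c:
        key = f"{int(gene in a)}{int(gene in b)}{int(gene in c)}"
        venn[key] = venn.get(key, 0) + 1
    for key in ("100", "010", "001", "110", "101", "011", "111"):
        venn.setdefault(key, 0)
    return a & b & c, venn


def si_flags(records: list[ExpressionRecord]) -> list[SIRecord]:
    """Signal-integration flags for both combined conditions."""
    out: list[SIRecord] = []
    for rec in records:
        for combo, (ifn, lps) in COMBO_PARTS.items():
            out.append(
                SIRecord(rec.gene_id, rec.cell_type, combo,
                         rec.fc[combo], rec.fc[ifn], rec.fc[lps])
            )
    return out


def si_flags_from_fc(table: pd.DataFrame) -> pd.Series:
    """Apply the SI statistic to a table with fc_ifn/fc_lps/fc_combo columns."""
    return table["fc_combo"] > table["fc_ifn"] + table["fc_lps"]


def pairwise_overlap(list_a, list_b, method: str = "jaccard") -> float:
    """Percentage overlap of two gene lists.

    ``jaccard``: 100 * |A∩B| / |A∪B|; ``sum``: 100 * |A∩B| / (|A| + |B|).
    Empty inputs yield 0.
    """
    a, b = set(list_a), set(list_b)
    inter = len(a & b)
    if method == "jaccard":
        denom = len(a | b)
    elif method == "sum":
        denom = len(a) + len(b)
    else:
        raise ValueError(f"unknown overlap method {method!r}")
    return 100.0 * inter / denom if denom else 0.0


def enrich_gene_sets(
    gene_list, universe, gene_sets: dict[str, tuple[str, list[str]]], alpha: float = 0.05
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_list`` over ``gene_sets``.

    ``p = P(X >= overlap)`` for X hypergeometric with population ``|universe|``,
    successes ``|set ∩ universe|`` and draws ``|gene_list|``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_list)
    if genes - universe:
        raise ValueError("gene list is not a subset of the universe")
    rows = []
    for name, (desc, members) in gene_sets.items():
        in_universe = set(members) & universe
        overlap = len(in_universe & genes)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(in_universe), len(genes)))
        rows.append(
            {"set": name, "description": desc, "set_size": len(in_universe),
             "overlap": overlap, "p_value": p, "significant": p < alpha}
        )
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)


def expression_summary(
    records: list[ExpressionRecord], gene_subset, cell_type: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2 FC matrix (genes x treated conditions) plus per-condition quartiles.

    Quartiles use linear interpolation, matching the usual box-plot
    convention (median and first/third quartiles).
    """
    subset = set(gene_subset)
    rows = {
        rec.gene_id: {c: rec.log2fc(c) for c in TREATED_CONDITIONS}
        for rec in records
        if rec.cell_type == cell_type and rec.gene_id in subset
    }
    missing = subset - set(rows)
    if missing:
        raise ValueError(f"genes absent from records: {sorted(missing)[:5]}")
    matrix = pd.DataFrame.from_dict(rows, orient="index")[list(TREATED_CONDITIONS)]
    quartiles = matrix.quantile([0.25, 0.5, 0.75], interpolation="linear")
    quartiles.index = ["q1", "median", "q3"]
    return matrix, quartiles
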