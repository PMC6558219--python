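# Methods

This note documents the statistical model, the simulator, the numerical
choices and the known limitations of `cobindsi`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Coordinate and sequence conventions

All genomic intervals are 0-based half-open (BED convention); 1-based
coordinates never enter the data model. The TSS of a minus-strand gene is
the last base of its span (`end − 1`), a point coordinate, so nearest-TSS
distances behave identically on both strands. Sequences are upper-case over
`{A, C, G, T, N}`; `N` scores as background in both scanning dialects
(zero log-odds contribution; probability 0.25 under the similarity dialect)
rather than raising, so masked regions degrade scores instead of failing.

## Expression model

**Normalization.** Size factors are median-of-ratios: for genes with
strictly positive counts in every sample, `factor_j = median_i(c_ij / g_i)`
with `g_i` the per-gene geometric mean. There is no pseudo-reference
fallback; a matrix with no all-positive gene raises. This estimator assumes
a mostly unchanged transcriptome, which shapes the simulator defaults (see
below).

**Expressed filter.** A gene is expressed in a cell type iff its normalized
replicate-mean exceeds 8 (strictly) in at least one condition of that cell
type. The permissive "any condition" reading retains genes induced from
zero baseline — exactly the genes the SI analysis is about.

**Fold change.** `FC = (mean_treated + ε) / (mean_control + ε)` with
symmetric pseudocount ε = 0.5 (default). The symmetric ε keeps FC ordering
intact and keeps induced-from-zero genes finite. The up-regulation boundary
is `FC ≥ 2` by default; the strict `>` variant is config-exposed
(`strict_fc_boundary`) because both conventions circulate in practice.

**Signal integration.** `SI ⇔ FC(combo) > FC(IFN) + FC(LPS)`, strict. This
linear-scale super-additivity test is deliberately simple: it uses no
replicate variance and therefore needs no dispersion model. The packaged
published top-30 fold-change tables are a standing regression fixture for
it: the statistic must reproduce their synergy marks exactly (25/30 and
26/30 flagged).

**Overlap percentages.** Two denominators are provided because both appear
in published figures of this kind: `jaccard = 100·|A∩B|/|A∪B|` (used for
comparing the two combined-treatment common-gene lists) and
`sum = 100·|A∩B|/(|A|+|B|)` (used for per-mode overlaps). Back-solving the
printed percentages from the printed list sizes identifies which
denominator each figure used; both back-solutions are packaged and checked.

**Enrichment.** Upper-tail hypergeometric (`scipy.stats.hypergeom.sf`)
of the overlap between a gene list and each GMT set restricted to the
universe; sets with p < 0.05 are flagged. No multiplicity correction is
applied, matching the single-threshold convention of the source analysis
style; users can correct downstream.

## Motif scanning dialects

**Log-odds (genome-wide).** Score of window *w* is
`Σ_i ln(p(b_i, i) / q(b_i))` with uniform background by default. Natural
log is the default because the per-class Motif Score Thresholds (GAS 6,
ISRE 6, NFκB 7) are calibrated against that convention in the common
HOMER-style tooling; the base is config-exposed. Probabilities are
regularized as `(p + 1e-3)/(1 + 4·1e-3)` before the log so zero-count
columns cannot produce −∞ while consensus scores stay within ~1% of the
closed form (`L·ln 4` for a probability-1 matrix). Both strands are scanned
and reverse hits are reported in forward coordinates. All overlapping hits
are reported — downstream occupancy only needs presence/absence, so greedy
pruning would add a tie-break rule without changing any result.

**Matrix similarity (promoter).** `raw(w) = Σ_i p(b_i, i)`,
`similarity = (raw − raw_min)/(raw_max − raw_min)` with per-column
extremes. The published promoter analysis used a web tool whose exact
normalization is not public; this min–max dialect is adopted because it
reproduces the [0, 1] score semantics, gives the consensus similarity 1 for
any non-degenerate matrix, and is affine-invariant in the raw score.
Thresholds: 0.85 (GAS/ISRE), 0.90 (NFκB). The promoter window is −950/+50
relative to the TSS; on the minus strand the window is mirrored around the
TSS point coordinate (forward interval `[tss−hi+1, tss−lo+1)`), clipped to
the chromosome. A class is present for a gene if **any** matrix of that
class has at least one hit in the window (the "any matrix" reading; the
alternative "all matrices" reading is stricter than any published count
suggests).

## ChIP integration

**Occupancy.** A GAS/ISRE hit is occupied iff fully contained in a STAT1
peak of the same condition; NFκB requires a p65 peak. Full containment (not
mere overlap) avoids crediting hits that straddle peak edges. Same-condition
matching is used — motif hits are compared against peaks called under the
condition being analyzed, not pooled across conditions.

**Annotation.** Site midpoint to nearest TSS by absolute distance, sign
flipped for minus-strand genes (positive = downstream), dropped beyond
±100 kb. Ties break lexicographically on gene id (documented, deterministic).

**Genomic categories.** Precedence promoter/TSS (−1 kb..+100 bp) > TTS
(±100 bp; the window mirrors the promoter's +100 bp by symmetry) > 5′UTR >
3′UTR > exon > intron > intergenic. The precedence is fixed so categories
partition sites exactly; UTRs derive from the BED12 thick (CDS) span.

**Modes.** One mode per gene per condition pair: the set of motif classes
with ≥1 occupied annotated site. Mode assignment uses the combined-treatment
peak sets of both factors; single-treatment peak sets feed descriptive
outputs only. A gene with several co-binding regions contributes the union
of its sites to a single gene-level mode.

**Summit distances.** For each STAT1 summit, the signed distance (p65 −
STAT1, genome orientation) to the closest p65 summit on the same
chromosome; histogram over [−1000, 1000) in 25-bp bins, out-of-range
distances retained in the list.

**Occupancy clustering.** RPKM =
`reads_in_region / ((len/1000)·(total/10^6))` per merged region per sample;
k-means (k = 10 default) on `log2(RPKM+1)` rows. scikit-learn's KMeans with
a fixed `random_state` (k-means++ init, `n_init=10`) is used: it is
deterministic under a fixed seed and is the estimator practitioners reach
for; a bespoke farthest-point initialization was considered and rejected as
re-implementing a solved problem. The RD (read-density) matrix holds
depth-normalized tag counts in 25-bp bins over ±1 kb around region centers.

## The simulator

The generator emulates the statistical structure the analysis assumes, not
sequencing artefacts.

* **Genome.** i.i.d. uniform background (order-0), chosen so scanner
  false-positive rates are analytically predictable. Genes are placed on a
  fixed grid of non-overlapping slots wide enough that every planted motif
  annotates to its own gene; strand is random. Default: 4 chromosomes ×
  600 kb, 160 genes.
* **Modes.** Each gene draws one of 8 modes. Default fractions: 65% `none`,
  5% each of the 7 motif-bearing modes. The majority-null default matters:
  median-of-ratios normalization assumes most genes unchanged, as in a real
  transcriptome where a few hundred of ~20k genes respond; a
  mostly-responsive gene set would distort size factors in the combined
  conditions and is not a realistic study condition.
* **Motifs.** Planted as PWM consensus strings (argmax per column), so they
  are detectable at the stated thresholds by construction, in the promoter
  window (probability 0.5) or at a distal offset (1.5–5 kb). Composite
  modes place motifs with adjacent midpoint spacings drawn uniformly from
  `[38, 264/(k−1)]` bp so that *every pairwise* spacing stays inside the
  38–264 bp band observed for composite sites.
* **Expression.** Negative binomial via gamma–Poisson, mean
  `base_mean · FC`, dispersion 0.05 (typical for replicated bulk RNA-seq),
  3 replicates. STAT1-class genes respond to both IFNs (log2 FC 3), NFκB
  genes to LPS (log2 FC 3). SI genes (50% of motif-bearing genes) get
  combined-condition mean `(FC_IFN + FC_LPS)·2^bonus` (bonus 2 log2 units);
  non-SI genes saturate at `max(FC_IFN, FC_LPS)`, which is strictly
  sub-additive, so the planted SI labels are unambiguous under the SI
  statistic's own definition. 80% of genes share effects across all three
  cell types; the rest respond in one.
* **ChIP.** STAT1 peaks (200 bp, summit at the motif midpoint, jitter 0 by
  default) cover GAS/ISRE motifs under IFN and IFN+LPS; p65 peaks cover
  NFκB motifs under LPS and IFN+LPS and — when the `sequential_recruitment`
  flag is on (default) — under IFN alone at composite sites only, so tests
  can probe the classifier with and without that biological behaviour.
  Coverage is Poisson per 25-bp bin, background rate set by `tag_depth`,
  20× enrichment under peaks.
* **Determinism.** Every stage draws from a named substream of the single
  seed; identical seeds give byte-identical FASTA, count tables, peak files
  and summary JSON.

**What the simulator does not emulate** — and hence what passing recovery
tests do not establish about real data: mappability and GC biases, peak
irreproducibility between replicates, non-consensus (weak) motif instances,
correlated background (real genomes are far from order-0 uniform),
cell-type-specific chromatin, and read-level artefacts. Recovery results
certify the pipeline's correctness on its stated model, not discovery
performance on GEO-scale data; genome-scale published counts (Venn totals,
absolute mode counts, cluster identities) require raw-read alignment and
peak calling, which are out of scope.

## Problem sizes

Default simulated runs use 160 genes on a 2.4 Mb genome with 54 RNA samples
and 12 ChIP samples — large enough that every mode is populated and
recovery rates are stable across seeds, small enough that a full pipeline
run takes a couple of seconds. Oracle-equivalence tests run scanners
against exhaustive per-window/per-base re-implementations on randomized
instances up to 2 kb across 100 seeds.

## Known limitations

* The SI statistic compares point estimates of fold change; it has no
  significance test, by design.
* The matrix-similarity dialect is this package's documented reconstruction
  of an unpublished formula; absolute similarity values may differ from the
  original web tool even though thresholds and semantics match.
* Blacklist handling is interval subtraction only; no blacklist ships with
  the package.
* Cluster labels from k-means are arbitrary; only partitions (and their
  agreement with truth) are meaningful.
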