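# Methods

This note records the models, conventions and design choices behind each
stage, in enough detail to reimplement them.

## QC filtering and normalization

Per-cell metrics are total UMI $t$, number of expressed genes $g$
(count > 0) and mitochondrial fraction $m$ (prefix-matched symbols,
case-sensitive, default `MT-`; $m \equiv 0$ for an all-zero cell). The
keep rule is $t \in [u_{\min}, u_{\max}]$ (defaults 800, 20,000),
$g > 500$ (strict) and $m < 0.15$ (strict) — the literal complements of
the usual discard phrasings ("less than 800 or more than 20,000", "no
more than 500", "less than 15%"). Every violated rule is reported per
cell, so rule counts can exceed the number of discarded cells. The rules
are per-cell, so filtering per donor matrix or on the merged matrix gives
identical results.

Normalization is counts-per-10,000 followed by log1p:
$x_{gc} = \ln(1 + c_{gc}\,s / t_c)$ with scale factor $s = 10^4$. Zero
counts map to exactly zero, preserving sparsity. Cells with $t_c = 0$ are
rejected (filter first).

Duplicate gene symbols are made unique by appending `.1`, `.2`, … in file
order; duplicate Matrix Market triplet entries are summed. Matrices are
gene-major (genes × cells), 0-based internally, 1-based on disk.

## Transcriptional noise

The noise statistic is the distribution of within-subset pairwise
Euclidean distances over square-root-transformed, depth-equalized counts
of "stable" genes.

**Downsampling.** "Equal total UMI per subset" is implemented at the
subset level: each subset's pool of individual UMIs — one token per
molecule, attached to its (gene, cell) entry — is sampled uniformly
without replacement down to the minimum subset total $T^\*$. The kept
counts per entry are exactly multivariate hypergeometric (entry mean
$nK/N$), no entry exceeds its original count, and integer counts are
preserved (per-cell rescaling would not preserve them). The sampler draws
one permutation of the subset's token array per subset, subsets in sorted
label order, tokens ordered by gene then barcode. Ordering by barcode
rather than column position makes the draw a function of the cell *set*,
giving exact permutation equivariance; the fixed consumption pattern lets
a naive token-list re-implementation reproduce the draw bit-for-bit from
the same seed, which the test suite exploits as an oracle. A single
seeded draw is the default (an averaged multi-draw mode can be built by
looping over seeds).

**Stable genes.** Computed independently per subset on that subset's
downsampled counts (the procedure is defined within "for each subset").
Genes with zero mean are excluded (CV undefined), the rest ranked by mean
(ties by gene order) and split into `n_bins` = 10 equal-count bins
(`numpy.array_split` semantics; equal-count, not equal-width, for
robustness to heavy-tailed expression). The lowest- and highest-mean bins
are dropped; from each kept bin the `max(1, floor(0.10 · bin))` genes with
lowest population CV are retained (ties by gene order; the floor with a
minimum of one guarantees a non-empty selection).

**Distances.** Square root of the downsampled counts restricted to the
stable genes, then all $n(n-1)/2$ pairwise Euclidean distances per
subset. The full distribution is retained; mean, median and IQR are
reported because subset comparisons are orderings of these distributions
(the mean is used as the default ordering statistic). Subsets with one
cell are skipped with a warning recorded in the result.

## Signature scoring and markers

A signature score is the unweighted per-cell mean of log-normalized
expression over the set's genes (no control-gene-bin subtraction — the
plain mean is the definition used). Absent symbols are dropped with a
warning; a fully absent set is an error. The proinflammatory set (SELE,
SELP, CSF3, CCL14, IL6, ICAM1, HMOX1) ships as a constant; other sets
(e.g. an EC-migration signature) are user-supplied as GMT or two-column
TSV, since no canonical list exists.

Markers are one-vs-rest per subset. Pre-filters: detection fraction
≥ 0.3 in the subset **or** in the rest (standard `min.pct` semantics) and
|log2FC| ≥ 0.4, where log2FC = $\log_2\frac{\overline{\mathrm{expm1}(x_{in})}+1}
{\overline{\mathrm{expm1}(x_{out})}+1}$ — means on the depth-normalized
scale with pseudo-count 1, the convention behind the usual single-cell
toolkits (the thresholds are given by convention; the formula is ours to
fix). Genes passing both are tested with a two-sided Wilcoxon rank-sum
(mid-ranks, tie-corrected normal approximation with continuity
correction; `scipy.stats.mannwhitneyu`), BH-adjusted across the tested
genes within each subset (`statsmodels`). A marker call requires adjusted
p ≤ 0.05. DEG lists additionally require log2FC ≥ 0.4 *positive* and
in-group detection ≥ 0.3, ordered by descending fold change. Note that
`passes_filters` is monotone in the pre-filter thresholds only through
the tested set; because BH renormalizes over the tested genes, the
post-adjustment set is not formally monotone, and the monotonicity
property is asserted on the tested set.

## TF–target networks

Coexpression: Pearson correlation of log-normalized expression within a
cell subset, p-values by the t transform on $n-2$ df, no multiple-testing
correction (the rule is stated per pair). Retention is strict:
r > 0.15 **and** p < 0.05. The rule is literal positive-only — negative
regulation is invisible by design. Zero-variance genes are dropped with a
warning; fewer than 3 cells is an error. By default correlation is
restricted to a supplied universe (TF plus candidate targets) to avoid
the all-pairs quadratic blowup; all-pairs is available by passing no
universe.

Regulon tables use the schema of exported inference output (tf, target,
sign, plus per-regulon contrast statistics); regulon inference itself is
out of scope. Filtering keeps lfc > 0.1 and padj < 10⁻⁵, both strict.
"Combining both methods" is implemented as intersection — a target needs
regulon support *and* coexpression support — with `union` and
`regulon_only` modes for comparison. By construction the edge set is
contained in both evidence sets.

## Synthetic data

Counts are negative binomial with mean
$\mu_{gc} = b_g \cdot f_{s(c),g} \cdot e_{d(c),g} \cdot \ell_{B,c} \cdot L_c$
and inverse-size dispersion $d_{s(c)}$ (variance $\mu + d\mu^2$; $d=0$ is
the Poisson limit, sampled directly), where $b_g$ is a lognormal baseline
scaled to the target library mean, $f$ the subset marker fold, $e$ a
per-donor lognormal batch fold, $\ell_B$ the shared lognormal latent
factor of the TF block (mean-corrected, so block genes gain correlation
without gaining mean), and $L_c$ the cell's lognormal library-size
factor. The latent-factor construction was chosen over a Gaussian copula
because it keeps integer-count fidelity while planting positive pairwise
correlation.

Default study conditions (chosen once): 1,500 genes of which 30
mitochondrial at a 5% expected UMI share; 6 vein-wall subsets
(IL6-high venous EC, venous EC, valvular EC, fibroblast, SMC,
macrophage) × 200 cells with dispersion gradient 0.2–1.0; 3 donors with
small batch shifts (sd 0.05–0.08 log-fold); library sizes lognormal with
mean 4,000 UMI and σ = 0.25 — the ≈4σ margin above the 800-UMI floor
makes un-injected cells pass QC by construction, so truth-vs-filter
agreement is exact rather than probabilistic; marker folds of 6 on
10 genes per subset (the IL6-high EC program reuses the proinflammatory
symbols); a KLF9 block of 15 targets with latent loading 0.6 at ~8 mean
counts. Injected QC-failure cells are constructed to violate exactly one
nominated rule each (e.g. a low-UMI cell still expresses more than the
gene floor), and the constructor verifies this, erroring when the
thresholds make it impossible.

What the generator does **not** emulate: ambient RNA, doublets,
pseudotime structure, ligand–receptor patterning, realistic gene-gene
correlation beyond the planted block, or real vein biology. Passing
recovery tests therefore demonstrates correctness of the computations
under the stated count model, not performance on real tissue.

## Benchmarks and problem sizes

The validation suite (also exposed via `scripts/acceptance.py`) uses:
the default fixture for QC truth recovery; 10×6 matrices for exact oracle
equivalence (tolerance 1e-10); 40 replicates of two 200-cell,
1,500-gene subsets at dispersions 0.1 vs 1.0 for ordering recovery;
2,000 seeded draws of a 1,000-UMI subset downsampled to 600 for
hypergeometric unbiasedness (3 SE criterion); 20 replicates of
400-gene, 2×200-cell data with fold-4 markers for recovery, and 20 label
permutations for the null; 20 replicates of a 200-cell subset with a
15-target TF block plus 50 unrelated genes for network sensitivity and
false-edge rate. These sizes keep the whole suite desk-scale (seconds to
a minute) while leaving the measured rates far from their thresholds.

## Pipeline

`run_pipeline` expands one global seed into per-stage substreams
(`SeedSequence.spawn`), so adding a stage never perturbs another stage's
randomness; identical config + seed give byte-identical artifacts and
manifest checksums. In the synthetic end-to-end run, the regulon table
supplied to the network stage is derived from the planted TF block (with
passing activity statistics), standing in for an external inference run.

## Known limitations

- The all-pairs coexpression mode is quadratic in genes; use a universe.
- The token-based downsampler materializes one index per UMI; at
  atlas-scale totals (10⁸+ UMIs) an entry-level hypergeometric sampler
  would be preferable.
- The exact-enumeration rank-sum check is feasible only at tiny group
  sizes; at realistic sizes the normal approximation is the implementation
  and the hand-coded formula the oracle.
- Distances other than Euclidean and cross-donor noise decomposition are
  out of scope.
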