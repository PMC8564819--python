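# Methods notes

## The traveling-ratio model

Low-input tissue epigenomics (ChIL-seq and relatives) yields, per gene, a
PolII signal profile whose *height* scales with the number of cells engaging
the locus and whose *shape* reflects the pause/release state of the
polymerase. We summarize the shape by the traveling ratio TR = TES/TSS
signal and the height by the TSS-window CPM, and estimate both jointly with
a Poisson GLM per gene and condition:

    y_ij ~ Poisson(λ_ij),  log λ_ij = β0 + β1·s_ij + log M_i

with `s_ij` the TES indicator and `M_i` the replicate's total mapped reads
in millions. The offset term performs CPM normalization inside the
likelihood, so small libraries contribute proportionally less information —
the reason for modeling counts rather than normalized ratios. A plain
Poisson (no dispersion parameter) is an explicit modeling choice: the data
this targets are deduplicated counts in short fixed windows, and keeping the
model saturated gives closed-form estimates

    exp(β0) = S0/ΣM,  tr = S1/S0,  var(β0) = 1/S0,  var(β1) = 1/S0 + 1/S1,
    cov(β0,β1) = −1/S0

(`S0`, `S1` the summed TSS/TES counts). The Fisher information is evaluated
at the MLE, where expected and observed information coincide. Replicates
enter only through the sufficient sums, so pooling replicates (summing
counts and library sizes) provably leaves the point estimates unchanged;
this is covered by a property test. `fit_tr_irls` re-fits the same model
through statsmodels' IRLS path and is used as a numerical oracle and as the
extension point for richer designs (covariates, smooth time effects).

### Degenerate counts

No pseudocounts are added by default. `S0 = 0` leaves both coefficients
undefined (`zero_tss`); `S1 = 0` gives `tr = 0` with infinite log-scale
variance (`zero_tes`). Both statuses are propagated and excluded from Wald
testing; padding them with p = 1 instead would inflate the BH universe.

### Windows

TSS: ±750 bp around the start site (symmetric, hence strand-invariant).
TES: 0 to +1,500 bp from the end site. The direction of the TES window is
not uniquely determined by "0 to +1,500 bp" alone; we read it as downstream
in the direction of transcription and expose offset/length so the
alternative (into the gene body) is one argument away. Coordinates are
0-based half-open everywhere; GTF is converted on load; negative window
coordinates are clipped at zero and flagged. Counting uses the strand-aware
read 5′ end by default — for deduplicated single-end data this is the least
ambiguous unit and prevents a long read from straddling both windows of a
short gene — with a ≥1 bp overlap mode as an option, since it cannot be
established from the data alone which convention upstream pipelines used.

### TR_GB variant

The gene-body variant replaces TES counts with counts in the window strictly
between the TSS and TES windows. Gene bodies vary over orders of magnitude
in length, so GB counts are normalized per kb — implemented through the
exposure (offset: `M_i · len_kb`) rather than by dividing counts, which
would break the integrality the Poisson likelihood assumes. The GB window
definition itself (between-windows) is our choice, configurable via
`build_windows`.

## Contrasts, classification, clusters

Contrasts of independent fits are Gaussian on the log scale with variance
`V_A + V_B`; two-sided p-values throughout (sidedness is a convention, and
symmetric nulls are the default in differential analysis). Thresholds are
applied exactly as reported figures conventionally state them: a measure is
significant iff |log₂FC| > 1 and BH FDR < 0.1, with both thresholds
configurable. The label is read off the TR/TSS significance pair
(TR-only → activation_*, TSS-only → population_*, both, neither). BH runs
within the user-selected gene set after dropping untestable genes, because
correcting over genes that can never reject only dilutes m.

Time-course clusters C1..Ck assign each gene to the index of its
maximal-TR timepoint, ties to the earliest — deliberately simple and fully
deterministic.

## Peak metrics

Hit semantics follow bedtools: recall/precision and the specificity odds
ratio count ≥1 bp overlaps at the peak level (a bp-level mode exists);
the Jaccard index is base-pair level on merged sets. Within-set overlaps are
always merged first, making every metric invariant to redundant input.
The super-enhancer filter keeps candidates ranked in the top 5% of tag
counts (ties kept) in ≥2 replicates and not overlapping any excluded
tissue's SE set; the top-5% cut selects `n − ceil(0.95·n)` candidates, which
is exactly 5% at n = 100 and empty below n = 20 (warned). Degenerate odds
ratios are reported as flagged infinities unless the Haldane 0.5 correction
is requested explicitly.

## Synthetic generator

The generator emulates the count layer of a tissue time-course: cell types
with population trajectories `N_t`, genes with per-cell TSS coefficient
`α` (CPM per cell unit) and true TR per timepoint, replicates with unequal
library sizes (default 1, 2, 4 M so the offset is genuinely exercised), and

    y_TSS ~ Poisson(M·α·N),  y_TES ~ Poisson(M·α·N·TR).

Linearity of signal in population size is an assumption, stated here so
users can substitute saturating or mixed relationships via custom
trajectories. Default scenario parameters: activation TR 0.3→1.2 at the
second timepoint with population fixed at 2,000 cells; migration population
1,000→4,000 with TR fixed at 0.6; α = 0.05, so expected TSS counts per
condition stay ≥ 200 even in the low-population arm. `expectation` mode
emits round-half-up Poisson means (deterministic, exact recovery of truth by
the fitter); `poisson` mode draws from per-gene streams seeded by
`(root seed, crc32(gene_id))`, so enlarging a design never perturbs existing
genes. The read-level simulator places read 5′ ends uniformly within the
counted window, giving an exact generator→counter round trip.

What the generator does **not** emulate — background reads outside windows,
fragment-length and GC biases, overdispersion from biological replicate
heterogeneity, overlapping gene models — bounds what green tests mean:
they demonstrate correctness and calibration of the estimator and tests
*under the stated model*, not robustness to real-library artifacts. In
particular, real replicate heterogeneity will make the plain-Poisson CIs
anti-conservative to a degree the package does not estimate.

## Problem sizes and numerical choices

Calibration checks use sizes where Monte-Carlo error is well below the
asserted bands: 2,500 genes for CI coverage (binomial SE ≈ 0.4% at 95%),
5,000 genes for the type-I rate, 20 repeats × 2,000 genes for the BH FDR
mixture, 500 genes per scenario for label recovery, and ~10⁵ reads for the
round trip. The three-way fitter agreement (closed form / IRLS / grid
refinement of the separable log-likelihood to width 1e-9) is asserted at
1e-6 on the coefficients; IRLS covariances agree with the closed form only
to ~1e-4 relative, reflecting the GLM convergence tolerance, and that is the
tolerance tested. Output floats are formatted at six significant digits so
pipeline reruns are byte-identical.

## Known limitations

* Per-gene fits are independent; no information sharing across genes, hence
  noisy TR for weakly covered genes (visible in wide CIs, not hidden).
* The TSS level conflates population size with per-cell loading; the
  decomposition is an interpretation layered on the two-parameter fit, valid
  insofar as per-cell signal is roughly constant within a cell type.
* BAM input is out of scope by design (BED intervals are the contract);
  deduplication and mapping-quality filtering are assumed done upstream.
* Peak calling and enhancer-list construction are inputs, not outputs.
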