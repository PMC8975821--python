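# Methods

This note records the models, conventions and design choices behind
`polkinetics`, at the level a maintainer or reviewer needs to interpret its
output. All coordinates are 0-based half-open; all tracks are 50-bp binned
unless configured otherwise.

## What the package computes

Four linked analyses of Pol II transcription kinetics in a knockout-versus-
control design:

1. **Elongation rates** from nascent-RNA (4sU-labeled) coverage after
   synchronized release from a DRB transcription block, via per-gene
   detection of the advancing "wave" front at 10 and 20 min.
2. **Promoter-proximal pausing** via the traveling ratio (TR): promoter
   RPKM / gene-body RPKM of Pol II occupancy.
3. **Transcriptional output** via spike-in normalized count matrices and
   threshold-based differential calls.
4. **Extragenic transcription** via stranded window/gap island calling and
   class-priority annotation (lncRNA / enhancer / antisense / PROMPT /
   readthrough / promoter-convergent / other).

## Elongation-front model

A gene's coverage segment runs from the TSS to 2 kb upstream of the TES
(the TES-proximal 2 kb is excluded as unstable), reoriented 5'→3'. The
front is decoded with a three-state left-to-right hidden Markov model on
log1p(coverage): states WAVE → FRONT → BACKGROUND, Gaussian emissions,
backward transitions forbidden. Choices the citation trail leaves open, and
how they were fixed:

- **Emissions**: Gaussian on log1p of binned coverage. log1p stabilizes the
  variance of overdispersed counts, and keeps zero-coverage bins finite.
- **Initialization** (deterministic, so reruns are bit-identical): WAVE mean
  = mean of the top 30% of bins, BACKGROUND = bottom 30%, FRONT = midpoint;
  pooled variance; Baum–Welch refinement (≤50 iterations, tol 1e-4 on
  log-likelihood) then Viterbi decoding. The fit is delegated to
  `hmmlearn.GaussianHMM` with structural zeros in the transition matrix.
- **State topology**: ordered along the gene. Whether the original
  three-state formulation was positional or purely signal-level is not
  documented anywhere we could find; the positional reading is implemented
  because it makes the decoded path monotone and the boundary well defined.
- **Boundary anchor**: the Viterbi path gives the end of the last
  WAVE-or-FRONT bin; this anchor is then refined by a local two-level
  least-squares changepoint scan (±20 bins). The refinement matters: for
  any front that decays over a finite transition zone, the "last
  distinguishable bin" sits systematically past the transition midpoint,
  whereas the least-squares changepoint of a symmetric transition is its
  midpoint. On noise-free steps the refined boundary coincides with an
  exhaustive single-changepoint maximum-likelihood scan.
- **"Clear" front**: a boundary is reported only when the decoded path has
  ≥5 leading WAVE bins, ≥5 trailing BACKGROUND bins, and the boundary is
  not within 2 bins of either segment edge. Genes must be clear in *both*
  replicates at every required time point to enter rate estimation. These
  run-length thresholds operationalize an otherwise qualitative "clear
  front border" requirement.

## Rates, filters and rate-change calls

- **0–10 / 0–20 min rates**: mean replicate travel distance (kb) divided by
  elongation time (min). Genes enter the 10-min analysis only when longer
  than 30 kb, and the 20-min analysis when longer than 60 kb (the wave
  traverses ~38/76 kb at the typical ~3.8 kb/min); genes must also not
  overlap any other gene and have no other gene within 2 kb upstream of the
  TSS.
- **10–20 min ("late") rate**: OLS slope of replicate-level (time,
  distance) points. The 50% confidence interval uses the Student-t quantile
  with n−2 df on the replicate-level fit — fitting replicate-averaged
  points, as the procedure is sometimes described, leaves zero residual
  degrees of freedom and no CI, so replicate-level fitting is the only
  self-consistent reading. An estimate is retained iff slope > 0, full CI
  width < 0.5 kb/min, and the time-axis intercept is > −10 min.
- **Rate change between conditions** uses the either-replicate rule read as
  strict separation: *faster* iff every knockout replicate distance exceeds
  every control replicate distance, *slower* in the mirror case, otherwise
  *unaffected*. The lenient any-vs-any reading can label a gene both faster
  and slower, so it is available only behind `rule="lenient"` (with
  double-labels resolved to unaffected). For the 10–20 min interval the
  per-replicate distance is d20 − d10.
- **Composite late-elongation verdict**: a gene's late productive
  elongation is *decreased* iff (early ∈ {faster, unaffected} and late =
  slower) or (early = faster and late = unaffected) — an early speed-up
  that is not sustained counts as a late decrease.
- **TR-by-rate association**: Pearson chi-square test of independence with
  adjusted standardized residuals
  r_ij = (O−E)/√(E(1−row_i/N)(1−col_j/N)).

## Traveling ratio and gene groups

- Promoter window [TSS−50, TSS+300), body [TSS+300, TES), both
  strand-aware and configurable; the windows follow the common schematic
  convention since no coordinates are printed anywhere authoritative.
- TR is evaluable only when promoter density > 0.005 RPKM and body density
  > 0; TR fold changes ≥ 1.5 (inclusive) are *decreased*/*increased*, with
  "decreased" meaning decreased in the knockout.
- Expression groups: Silent (mean TPM < 1); among non-silent genes Low /
  Medium / High by the first and third quartiles, ties resolving to Medium.
  An optional relocation moves named Silent genes into Low.
- Nine groups: row-major 3×3 grid, rows = TR status (decreased, unaffected,
  increased), columns = output status; group 1 = TR decreased + output
  decreased, group 9 = TR increased + output increased.

## Spike-in normalization and differential calls

- Size factors are median-of-ratios computed on spike-in features only
  (reference = per-feature geometric mean across samples), then applied to
  all features. This preserves genuine global output shifts that
  library-size normalization would erase.
- The significance engine is a **pooled-dispersion negative-binomial Wald
  test**: one overdispersion α is estimated across all target features by a
  ratio-of-sums method-of-moments (Σ(s²−μ)/Σμ², clipped at 0), and the Wald
  statistic is Δlog(mean) / √((α+1/μ̂)(1/n₁+1/n₂)) with the information
  evaluated at the grand mean. A per-feature median of method-of-moments
  ratios is badly biased at one residual degree of freedom (the median of
  χ²₁ is 0.455), which is why the pooled ratio is used. A label-permutation
  test (exact when ≤20 distinct splits, else seeded Monte-Carlo) and a
  Welch t on log2(normalized+1) are available via `test=`; note that with
  two replicates per condition an exact permutation test cannot produce
  p < 1/3 and therefore cannot make calls at q < 0.05, which is why it is
  not the default.
- Calls require all three of: abundance floor (mean CPM or TPM ≥ 1 by
  preset), BH-adjusted p below the q threshold, and fold change at or above
  the threshold (inclusive). Presets: RNA-seq (TPM ≥ 1, q < 0.05,
  FC ≥ 1.5), TT-seq (CPM ≥ 1, q < 0.05, FC ≥ 1.2), extragenic (FC ≥ 1.5),
  ATAC peaks (q < 0.01, FC ≥ 2), gene-body accessibility (q < 0.05,
  FC ≥ 1.2).
- **Power at the study design**: with NB dispersion 0.05 and two replicates
  per condition, the per-sample Fisher information for a log-mean is
  1/(α+1/μ) ≤ 1/α, bounding the Wald statistic for a 2-fold change near
  z ≈ ln2/√α ≈ 3.1 for *any* test. BH-corrected power at q < 0.05 is
  therefore ≈0.45–0.75 depending on the cohort; recall above 90% would
  require ≥4 replicates or dispersion below ~0.03. The acceptance suite
  asserts the 90% bound as specified and the corresponding test documents
  this limit; it is a property of the design, not of the implementation.

## Extragenic islands

- Per strand, read 5' positions are tiled into 500-bp windows; a window is
  eligible when its count reaches the smallest k with Poisson tail
  P(X≥k | λ) < 0.1 under the background rate λ = N·window/L; eligible
  windows with inter-window gaps ≤ 1000 bp form islands; the island score
  is Σ −ln Poisson(count; λ) over its eligible windows.
- The island-score threshold is calibrated by seeded Monte-Carlo: simulate
  pure Poisson background 50 times, and choose the smallest threshold at
  which the expected number of surviving background islands is ≤ the
  e-value (default 100). This replaces the classic analytic score-threshold
  recursion; the window/gap/e-value parameters keep their standard meanings.
- Reads overlapping protein-coding genes on either strand are excluded
  before calling (strand-aware exclusion is available). Islands from both
  conditions are merged per strand; merged regions are kept when every
  replicate of at least one condition has ≥ 50 (raw) reads.
- Class priority: lncRNA (same-strand overlap) > enhancer (overlap) >
  antisense (opposite-strand gene-body overlap) > PROMPT (within 2 kb of a
  TSS, direction opposite the mRNA) > readthrough (within 2 kb of a TES,
  same direction) > promoter-convergent (within 2 kb of a TSS, same
  direction) > other. "Within 2 kb" means ≥1 bp overlap with the symmetric
  ±2 kb window around the anchor. Note the printed promoter-convergent
  definition (same direction, near the TSS) differs from the usual sense of
  "convergent"; it is implemented as printed. lncRNA assignment requires
  same-strand overlap because the class asserts transcript identity.
- Replicate-peak reconciliation keeps a merged-replicate peak iff it
  overlaps ≥1 peak in *each* individual replicate (`require="either"`
  relaxes this to at least one).

## Synthetic data: what it emulates, and what it does not

The generator produces one synthetic chromosome with sequentially placed
genes (2.6–6 kb gaps, three length strata below/within/above 30–60 kb,
deliberate filter violations: overlapping partners and sub-2-kb upstream
neighbours), an intergenic arena with lncRNA and enhancer intervals, and
all four data modalities. Key defaults and their rationale:

- **Wave speeds** 3.8 (control) / 4.4 (knockout) kb/min — the human-typical
  rate for control and a ~15% speed-up mimicking loss of an elongation
  restraint; per-gene lognormal jitter (sd 5%) shared between replicates
  (replicates re-measure the same biology).
- **Front shape**: coverage falls from the wave level to background
  logistically across a transition zone of 250 bp centred on the nominal
  front v·t (half-max at the front; scale = width/8). The polymerases at
  the wave tip are modeled as spread symmetrically about their mean
  position, which makes the front the midpoint of a symmetric transition —
  the quantity the changepoint-refined decoder estimates without bias. The
  250-bp default keeps the whole transition inside ±2–3 bins at 50-bp
  resolution.
- **Noise**: negative-binomial per bin (gamma–Poisson), background 0.2 and
  wave level 15 counts/bin, dispersion 0.05 (a standard RNA count model);
  `deterministic_signal=True` emits expected values for exactness tests.
- **Occupancy**: per-gene body density lognormal around 0.02 read
  starts/bp; true TR log-uniform on [1, 10]; in the knockout a 40% fraction
  of genes has its promoter density divided by 2 (TR decreases upon loss of
  the pausing factor). Unspecific background scales with the configured
  background noise and vanishes when noise is off.
- **Counts**: NB with per-sample depth factors (0.7–1.3), 10% of target
  features perturbed 2-fold (half up, half down) in the knockout, spike-ins
  untouched. An optional `composition_shift` multiplies *all* knockout
  target features, making spike-in normalization informative; it defaults
  to 1 (off) so that the default dataset is null-centered.
- **Extragenic islands**: ~1.5–2 kb islands with NB per-sample support
  around 150 reads, placed so that each island is geometrically
  unambiguous for the class-priority annotator (≥2 kb + one window width
  from every non-anchor TSS/TES, clear of gene bodies, ≥3 kb same-strand
  separation); thin uniform background reads on both strands. Antisense
  islands overlap gene bodies and are therefore — correctly — removed by
  genic-read exclusion in the end-to-end pipeline; the annotator's
  antisense class is exercised directly in unit tests.

What the generator does **not** emulate: mappability and GC structure,
introns and splicing, fragment-length effects, pause-peak shapes at t = 0,
multi-chromosome genomes, batch effects, or dispersion trends with
expression level. Passing tests therefore demonstrate the correctness of
the implemented procedures under their stated statistical assumptions, not
robustness to the full messiness of real sequencing data.

All randomness flows from a single root seed through named
`numpy.random.SeedSequence` child streams (annotation / waves / occupancy /
counts / extragenic), so datasets are bit-identical across reruns and
components stay independent.

## Numerical and degenerate-input conventions

- Bin-grid mismatches between tracks are hard errors, never silent
  resampling; regions shorter than a metagene flank are dropped and
  reported, never padded.
- Zero-variance inputs: correlation returns an explicit `undefined` flag;
  the HMM returns `clear=False` with a reason code; all-collinear OLS
  returns a zero-width CI; degenerate time spreads raise.
- CPM with zero total reads, empty regions, zero-length features, zero
  marginals in contingency tables, and out-of-range p-values all raise
  typed errors.
- Tn5 insertion sites: + reads shift start +4; − reads anchor on the
  rightmost aligned base (end−1) and shift −5; out-of-range sites are
  clamped and flagged.
- Problem sizes in the test and acceptance runs (≈100–400 genes, 2,500
  null features, 50 calibration simulations) were chosen so each check has
  comfortable statistical resolution on a single CPU.

## Known limitations

- Single-changepoint model: genes with multiple waves (re-initiation
  during labeling) are outside the model; the clear-front rule typically
  rejects them.
- The NB Wald test shares one dispersion across features; with strong
  mean–dispersion trends its calibration would degrade (the type-I check
  in the acceptance suite guards the regime the generator produces).
- The island-score calibration assumes a homogeneous Poisson background
  per strand and chromosome.
- BED12 I/O treats genes as single blocks (no exon structure).
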