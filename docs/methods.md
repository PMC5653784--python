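# Methods

## Model and rationale

The package addresses a drug-repositioning question: given expression
time courses of a model organism treated with many compounds, and an
independent disease case/control expression dataset, find compounds whose
transcriptional action coincides with the disease signature — without any
known drug for the disease and without training labels.

Because the two datasets are measured independently, they cannot be
stacked without choosing weights.  Instead every pair (or triple) of
observations sharing a gene is multiplied, giving a product tensor
`x̃[j₁…j_{m−1}, i]` whose entries are large in magnitude exactly where a
gene responds in *both* datasets.  Tucker-form decomposition of this
tensor factorizes it into per-mode orthonormal singular vectors coupled
by a core tensor; combinations of vectors with large core coefficients
are the data-driven "features".  The decomposition used is HOSVD: mode-k
factors are the left singular vectors of the mode-k unfolding.  HOSVD is
deterministic and cheap compared with CP/PARAFAC-style alternating
optimisation, and it does not force one-to-one coupling between modes —
both properties matter here, since useful gene vectors routinely sit
beyond component 100 and several gene vectors typically share one
compound vector.

### Standardization

Each gene-mode fiber is centred and scaled to `∑ᵢ x = 0`,
`∑ᵢ x² = N_gene` *before* multiplication (`standardize="parts"`,
default).  Whether the product should be re-standardized afterwards is
genuinely ambiguous, so it is exposed as a flag
(`"product"`/`"both"`/`"none"`) rather than silently decided.  Constant
fibers (flat probesets occur in real series matrices) standardize to
all-zero fibers instead of raising.

### Selection chain

1. *Time dependence.*  Pearson correlation of each time-mode singular
   vector against the raw day values (0.25, 1, 3, 5 by default; a log-day
   option exists but is off).  The automatic choice is argmax |r|, with a
   manual override at every step because vector choices are sometimes
   made from inspection of the correlation plots.
2. *Class association.*  One-way ANOVA of each sample-mode singular
   vector against the class labels, BH-adjusted across the vectors of
   that mode; all vectors below the threshold (default 0.05) are carried
   forward, not only the best one.
3. *Core ranking.*  Among core entries with the time mode pinned to the
   chosen vector and sample modes restricted to the chosen class vectors,
   the K = 10 of largest |G| are kept (ties broken lexicographically).
   The gene vectors they involve go to gene scoring.  Compound vectors
   are additionally filtered by their share of ∑G² over those entries
   (≥ 50 % of the leading share): when a single compound vector dominates
   all top entries — the typical case — exactly it survives; when several
   contribute comparably, all are kept.  Without this filter, compound
   vectors dragged in by near-noise core entries dilute the distance
   scores and mask the outliers.
4. *Gene scoring.*  `P_i = P_χ²[> ∑_ℓ (u[ℓ,i]/σ_ℓ)²]` with degrees of
   freedom equal to the number of summed vectors, where σ_ℓ is the
   standard deviation of vector ℓ's components over genes — this makes
   each term a squared z-score, matching the χ² reference distribution.
   BH-adjusted P < 0.01 selects genes.
5. *Compound selection.*  Every tested compound is bioactive, so a χ²
   null over compounds is not meaningful; the default instead keeps the
   loading cluster farthest from the origin.  "Cluster" is formalized as
   the largest consecutive gap in the descending score sequence within
   the leading ⌈max_fraction · n⌉ positions (max_fraction = 0.25); the
   ceiling matters so that small panels can still select more than one
   compound.  z-score (mean + 2 sd) and χ²-with-BH alternatives are
   provided, and the method plus parameters are recorded in the output
   because the cluster definition is admittedly arbitrary.

### Evaluation statistics

Predicted target sets are evaluated against reference sets in a 2×2
table over the gene universe, with two-sided Fisher's exact test
(probability-mass rule) and the uncorrected χ² test
(`n(ad−bc)²/∏margins`, Yates available but off).  The headline odds
ratio is the conditional maximum-likelihood estimator under the
noncentral hypergeometric distribution — the estimate printed by standard
exact-test routines, slightly shrunk toward 1 relative to ad/bc — with
the sample odds ratio reported alongside.  Gene-set enrichment is
one-sided hypergeometric over-representation against a GMT library with
BH across sets, replacing a web service so the pipeline runs offline.
Binding energies convert to affinities as
`K_i = exp(−ΔG·4184 / (R·T))` with R = 8.31 J mol⁻¹ K⁻¹, T = 300 K, and
the thermochemical calorie (4184 J/kcal); the formatter prints two
significant figures in the largest unit with mantissa ≥ 0.1.

## Numerical choices

- **On-demand core entries.**  A full core tensor matches the data
  tensor in size (e.g. 355 × 4 × 216 × 3961 ≈ 1.2 × 10⁹ entries) and is
  never materialized; single entries and small constrained blocks are
  computed by contracting the tensor with the chosen singular vectors,
  which is exact.
- **Gene-mode truncation.**  Gene factors are truncated to 200
  components by default; constrained core ranking in practice never
  involves deeper components, and every retained quantity is identical
  to the untruncated computation.
- **SVD route.**  Economy SVD of each unfolding; when a mode is much
  taller than wide (gene modes at genome scale) the factors come from
  the eigendecomposition of the smaller-side Gram matrix, identical up
  to numerically rank-deficient directions.
- **Sign convention.**  Singular-vector signs are arbitrary; each vector
  is flipped so its largest-magnitude entry is positive (first such
  entry on ties), making the decomposition a pure function of its
  input.  All downstream statistics are two-sided, so signs never change
  a selection.
- **Degenerate inputs.**  Zero-variance vectors get r = 0 with a flag
  (never NaN); all-equal compound scores yield an empty selection with a
  flag; zero-margin 2×2 tables report P = 1 with the odds ratio flagged
  undefined; σ_ℓ = 0 in gene scoring is an error.
- **BH step-up** is implemented directly (sort, multiply by n/k,
  cumulative minimum from the largest rank, cap at 1) and cross-checked
  against statsmodels in the test suite.

## Synthetic study conditions

The generator emulates the integrated design: a compound × time × gene
tensor `x = ε + drug_effect · a_{j₁} · τ_{j₂} · s_i` (active-compound
indicator a, centred unit-variance day profile τ, random ±1 gene signs s
on signal genes) and a samples × gene matrix
`x = ε + disease_effect · c_{j₃} · s_i` with the *same* signal genes and
signs — encoding the premise that treatment-responsive alteration is
coincident with disease progression.  Defaults: 30 compounds × 4 time
points (days 0.25, 1, 3, 5) × 2000 genes, 60 signal genes, 4 active
compounds, 20 disease + 20 control samples, unit Gaussian noise, effect
sizes 2.0 (a twofold standardized alteration — strong-responder genes in
a curated toxicogenomic course).  Noise is Gaussian for analytic
tractability; a moment-matched log-normal option mirrors expression
scale.  The planted structure is rank-1 across modes, which HOSVD
provably concentrates into one core entry, so the core-ranking rule is
exercised meaningfully; a `two_factor` variant plants a second, disjoint
signal with a time profile orthogonal to τ to test multi-vector
selection.

What passing recovery tests shows — and does not.  The generator omits
realistic toxicogenomic correlation structure, batch effects, platform
differences, and probe-level noise; recovery of the planted truth
demonstrates the correctness of the machinery (standardization, product
construction, decomposition, ranking, scoring) under the stated
conditions, not expected performance on real GEO series.

Problem sizes in the test suite are scaled to the structure being
exercised: exactness checks run on tensors with extents ≤ 6 against
brute-force oracles; null calibrations use 1000 replicates of reduced
size (e.g. 12 samples × 30 genes); the end-to-end recovery runs at the
full default conditions above.

## Known limitations

- Dense tensors only; a genome-scale product tensor with hundreds of
  samples needs tens of gigabytes and is out of reach for this
  implementation's in-memory path (the factor matrices, not the product,
  are the memory bottleneck that the Gram route addresses).
- The χ² reference for gene scores assumes near-Gaussian singular-vector
  loadings; under heavy-tailed product noise the leading vectors can
  absorb noise structure, so selected genes under a null are not
  guaranteed empty — the class-vector gate, not the gene χ², carries the
  disease specificity.
- Only one-way ANOVA is offered for class association (equivalent to a
  treatment-coded linear model F-test in the balanced case).
- The cluster-farthest-from-origin rule has no unique definition; the
  recorded method/parameters are part of any reported selection.
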