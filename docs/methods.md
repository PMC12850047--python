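# Methods

This note documents the models implemented in `kinnet`, the choices made
where the procedures admitted more than one reasonable reading, and what
the synthetic benchmarks do and do not establish.

## Enzyme kinetics

### Models

All rates are initial rates. Four nested descriptions are used:

* **Initial rate extraction.** An absorbance trace od(t) (NADH depletion
  in a coupled assay, absorbance decreasing) is reduced to |slope| of an
  ordinary-least-squares line over an initial window. The window is the
  longer of (a) the first 10% of the trace duration and (b) the longest
  prefix with linear-fit R² ≥ 0.99 (minimum five points). The dual rule
  keeps the window honest when the trace curves late: rule (a) guarantees
  a floor, rule (b) extends it while linearity genuinely holds. A flat
  trace is perfectly linear with slope 0 by convention.
* **Michaelis–Menten.** v = V_max·S/(K_a + S), where K_a is the
  substrate (PEP) concentration at half-maximal rate. Data with zero rate
  range are flagged non-identifiable (K_a standard error infinite) rather
  than fitted.
* **Activation dose–response.** A(X) = a0 + (a_max − a0)·X^h/(AC50^h +
  X^h). The Hill slope is fixed at h = 1 by default (hyperbolic
  activation, consistent with the Michaelis–Menten treatment of the
  substrate); it can be freed.
* **One-site binding.** y(L) = B_max·L/(K_d + L), for binding-fraction
  vs ligand series with a zero control. Series that are flat, all zero,
  or fully saturated (all points above 0.95·B_max) are rejected as
  non-identifiable.

### Thermodynamic linkage and the coupling constant

Substrate affinity as a function of allosteric-effector concentration X
follows the linked-function form

    K_a(X) = K_ia0 · (K_ix0 + X) / (K_ix0 + Q_ax·X)

with K_ia0 the substrate dissociation constant at zero effector, K_ix0
the effector dissociation constant at zero substrate, and Q_ax the
dimensionless coupling constant. The limits are K_a(0) = K_ia0 and
K_a(∞) = K_ia0/Q_ax, so Q_ax is identically the ratio of the initial to
the final K_a; `coupling_ratio` returns it from those limits and agrees
with the fitted parameter to 1e-9 by construction. Q_ax > 1 means the
effector increases substrate affinity (activation); Q_ax = 1 means no
coupling and a flat K_a(X).

Two fitting modes are provided. `two_stage` (default) fits a
Michaelis–Menten K_a at each effector level, then least-squares fits
K_a(X); this mirrors how such data are analysed at the bench and gives
per-level K_a values for inspection. `global` jointly fits the full
v(S, X) surface with a shared V_max. On noiseless data the two agree to
well under 2%.

All fits are unweighted nonlinear least squares
(`scipy.optimize.curve_fit`) with positivity bounds; initial guesses are
taken from the data (V_max = max rate, K_a = S at half-max, AC50 = X at
half-range, K_d = L at half-signal). Standard errors come from the
Jacobian-based covariance. Unweighted fitting is the default because the
source protocols name no weighting; 1/σ² weighting for multiplicative
noise was evaluated during benchmark design and changes the AC50
dispersion by only a few percent at these noise levels (see
"Benchmark design", below).

### Kinetic generators

Generators draw from exactly the models above. Noise models, which the
protocols do not specify, are: multiplicative Gaussian for rates and
dose–response activities (plate-reader CVs scale with signal), additive
Gaussian for absorbance traces and binding fractions (detector-limited
readouts). One integer seed per call makes outputs bit-identical.

### Benchmark design (study conditions)

The recovery benchmarks in `kinnet.benchmarks` freeze the following
conditions:

* **Linkage.** Truth Q_ax = 11.0 (FBP) and 3.7 (GSH); K_ia0 = 1.5 mM, a
  typical PKM2 PEP affinity without activator. K_ix0 is not printed in
  the source and is set so that the substrate-saturated effector
  affinity K_ix0/Q_ax matches the measured activation midpoints: 1.1 µM
  for FBP (AC50 0.10 µM), 363 µM for GSH (AC50 98.09 µM). Grids: 8
  two-fold-spaced PEP levels (0.05–6.4 mM) bracketing both K_a(0) and
  K_a(∞), and 6 effector levels from 0 to beyond saturation within the
  assayed ranges (FBP 0–2 mM, GSH 0–10 mM on the benchmark grid tail).
  5% CV, 3 replicates (the assays' stated n = 3), 200 seeds, two-stage
  fits, median reported.
* **Binding.** Truth K_d = 1.38 µM; 16-point two-fold dilution from
  550 µM plus a zero control (the thermophoresis design); additive noise
  2% of B_max; 200 seeds.
* **Dose–response.** Truth AC50 = 0.10 µM and 98.09 µM; baseline 1,
  twofold maximal activation; 10 log-spaced doses spanning four decades
  around the truth plus a zero control, in triplicate, 5% CV; 200 seeds.

A limitation worth stating plainly: under the dose–response design the
per-run AC50 dispersion is 15–17% relative. This is the information
limit of the design (efficient weighted and log-space estimators were
measured at the same dispersion), and it matches the ~18–20% relative
uncertainties reported for the measured AC50s themselves. The *median*
across runs is unbiased and stable to ~2%; single-run estimates should
be quoted with that dispersion in mind.

## Co-expression network analysis

### Preprocessing

Expression values are log2(TPM + 1). Genes whose fraction of zero TPM
values is ≥ 0.90 across samples are removed before network construction
(the removal list is reported). Zero-variance genes are dropped at the
correlation step with a warning.

### Adjacency, soft threshold, TOM

Adjacency is a_ij = |cor(g_i, g_j)|^β (unsigned, Pearson — the
conventional defaults; signed mode and the correlation matrix are
configurable), diagonal zero. The soft power β is chosen by scale-free
topology fit: for each candidate power, connectivities k_i = Σ_j a_ij
are binned into 10 equal-count bins and log10 of the connectivity
*density* (bin frequency divided by bin width — with equal-count bins
the raw frequencies are constant by construction, so the density
correction is required) is regressed on log10 mean connectivity. The
signed fit index is −sign(slope)·R². The selected power is the smallest
whose fit reaches 0.7 and lies within 0.02 of the plateau maximum
(parsimony tie-break); if nothing reaches 0.7 — as for a pure-noise
matrix — the argmax is returned with a warning flag.

Topological overlap is

    TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

TOM_ii = 1, symmetric, in [0, 1].

### Module detection

Genes are clustered by average linkage on 1 − TOM. The dendrogram cut is
an adaptive-gap variant of dynamic tree cutting implemented here: merge
heights are sorted, a floor is placed at a deepSplit-mapped fraction of
the height range (deepSplit 0–4 → 0.95, 0.90, 0.80, 0.70, 0.60; default
2), and candidate cut heights are the midpoints of the gaps between
consecutive merge heights above the floor. Among the widest candidate
gaps, the chosen cut is the one that leaves the fewest genes in
sub-minimum clusters, with ties broken toward the wider gap — a raw
widest-gap rule can land inside a module's internal merge region when
strongly coupled modules compress the gap between module completion and
the inter-module merges, fragmenting those modules; the occupancy guard
instead merges such module pairs, which is the faithful reading of their
correlation structure. Larger deepSplit lowers the floor and admits
finer splits. Clusters smaller than min_module_size
(default 5) are relabelled "unassigned"; module labels M1, M2, … are
assigned by decreasing size, and module composition is invariant to gene
ordering. Exact numerical agreement with the reference R implementation
of dynamic tree cut is not claimed; equivalence is established on
planted-module recovery (adjusted Rand index ≥ 0.99 across seeds at the
benchmark conditions below). Degenerate inputs (all-equal dissimilarity)
return a single module with a warning.

## Module–module interaction statistic

For modules A and B, a gene pair (g ∈ A, h ∈ B) is *co-expressed* when
its adjacency weight exceeds τ = 0.01 (the same threshold used for edge
trimming; exposed as a parameter). With m the co-expressed and
n = |A|·|B| the possible A–B pairs, and M, N the co-expressed and
possible pairs between A's genes and all assigned genes outside A
(interior pairs of other modules excluded), the ordered-pair
significance is the hypergeometric upper tail

    p(A→B) = P(X ≥ m),  X ~ Hypergeom(N, M, n),

with the empty-sum convention p = 1 at m = 0, computed via
`scipy.stats.hypergeom.sf` and floored at the smallest positive double
(p-values are never reported as 0). Both orientations are computed; an
undirected edge is significant when either tail is ≤ α = 0.05. The
statistic is exactly the classical over-representation test with A's
global co-expression propensity as the background, so a pair is flagged
only when its bridge density beats A's *own* baseline.

Enrichment of module gene lists against GMT collections uses the same
upper tail over a declared universe with Benjamini–Hochberg FDR.
Subnetwork extraction keeps anchor-gene modules and their neighbors,
then retains only modules ranking in the top k (default 2) by enrichment
p for at least one named pathway (anchors always kept). Gene-network
trimming drops edges with weight ≤ τ and keeps, per node, its 50
heaviest edges; an edge survives if either endpoint nominates it.

### Benchmark conditions and a calibration caveat

The planted-module benchmark simulates 6 modules of 25 genes,
within-module correlation 0.8, 60 samples (15 patients × 3 tumor regions
+ matched normal), and — for the interaction benchmark — a single
coupled module pair with factor correlation 0.9. Networks are built at
β = 17 with τ = 0.01, i.e. a co-expressed pair needs |cor| > 0.763.
This regime matters: at low powers (β = 6, |cor| > 0.46) finite-sample
correlation between nominally independent module factors (n = 60)
produces genuine blocks of spurious co-expressed pairs, which the
statistic correctly flags; single-edge recovery is a property of the
high-power regime, not of the statistic alone. Under a null simulation
with no planted coupling the fraction of ordered pairs with p ≤ 0.05
stays below 0.10, but exact calibration is not expected — pair events
within a block are strongly dependent.

## Regional contrasts

Per gene and tumor region r ∈ {IC, IF, M}, the fold change is
log2((mean TPM_tumor,r + c)/(mean TPM_normal + c)) with pseudocount
c = 1 (matching the log2(TPM+1) normalisation; configurable). Pooled
means are the default; a per-patient mode computes the fold change
within each patient carrying both samples and takes the median across
patients — the source does not state which aggregation was used, so both
are provided. The pooled and per-patient estimates coincide for
patient-homogeneous data and differ under patient heterogeneity.

Module distributions are summarised by five-number statistics
(linear-interpolation quartiles, the boxplot convention). Regions are
compared with a two-sided Wilcoxon signed-rank test pairing member genes
across regions — signed-rank requires pairing, and the gene is the
plotted unit in the violin displays this mirrors. Zero differences are
dropped; the exact null is used for n ≤ 25 pairs, the normal
approximation with continuity correction above. Spearman correlation
uses mid-ranks for ties; its p-value is the exact full-permutation null
for n ≤ 9 without ties and the t approximation otherwise.

## Expression generator

Each planted module shares a latent per-sample factor f; member genes
are x_gs = µ_g + √r·f_s + √(1−r)·ε_gs with per-gene baselines
µ_g ~ N(4, 1) on the log2 scale, so the pairwise within-module
correlation is r. Coupled module pairs share correlated factors
(f_B = c·f_A + √(1−c²)·f'_B). Region shifts are added on the log2 scale
to tumor samples of designated modules only. Values map to the TPM scale
via max(2^x − 1, 0) — the exact inverse of the log2(TPM+1)
normalisation — and zeros are injected uniformly per gene–sample cell
(or at per-gene rates when given) on the TPM scale. The design is one
tumor sample per region plus one matched normal per patient (complete
crossing; 21 patients → 84 samples), an idealisation of cohorts in which
not every patient contributes every region.

What the generator does *not* emulate: count-based mean–variance
coupling, library-size and GC effects, patient-level covariates, and
overlapping module membership. Passing recovery benchmarks therefore
demonstrates correctness of the estimators under the assumed generative
models, not robustness to the full messiness of real RNA-seq.

## Numerical conventions

* All optimisation is bounded to positive parameters; non-convergence
  raises an error carrying the optimizer message rather than returning
  silently bad values.
* Exact symmetry of adjacency and TOM matrices is enforced by averaging
  with the transpose; TOM is clipped to [0, 1].
* Power-selection ties break toward the smaller power; module labels
  order by size with lexical tie-break.
* Problem sizes throughout the test and acceptance protocols (200 seeds
  for kinetic recoveries, 10/50 seeds for network recoveries, 150-gene
  expression studies) were chosen so every benchmark reruns from scratch
  in seconds while keeping Monte-Carlo error well below the decision
  margins.
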