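# Methods

This note documents the statistical model behind `gxephos`, the defaults it
ships with, what the synthetic-data generator does and does not emulate, and
the numerical choices that matter when reproducing results.

## Study design and data model

The pipeline targets factorial in vivo phosphoproteomics cohorts: S inbred
strains × 2 diets (CHOW vs high-fat high-sucrose, HFD) × 2 treatments
(acute insulin vs unstimulated control), with 4–6 biological replicates per
cell. The observed data are log2 phosphopeptide intensities with
substantial missingness (mass-spectrometry data are missing both at random
and preferentially at low abundance) plus, per animal, blood tracer counts
over time and a terminal tissue tracer count.

All inference is on the log2 scale. Fold changes between conditions are
differences of condition *medians*, making them robust to single outliers
at the replicate counts involved.

## Insulin-regulation testing

Only peptides with ≥ `min_per_arm` (3) present values in both treatment
arms in ≥ `min_combinations` (8) of the strain-diet combinations are
tested; below this the per-combination fold changes the later stages need
are unreliable. The insulin main effect is tested in the full three-factor
ANOVA fitted by least squares on whatever samples are present. Because the
data are unbalanced, sums of squares are ambiguous; the default is Type II
for the treatment main effect (conditioning on strain, diet and
strain:diet — order-invariant, and exactly computable by residualising the
treatment indicator within strain-diet cells), with `ss="sequential"`
available for strict emulation of classical sequential fitting in the order
strain, diet, treatment. Degenerate fits (treatment confounded with cells
after missingness) yield a missing p-value rather than a spurious one.

p-values are converted to Storey q-values in a single family: π₀ is
estimated by the smoother method (cubic fit to π₀(λ) on λ = 0.05…0.95,
read off at λ = 0.95, clipped to (0, 1]); with fewer than 20 finite
p-values the estimator is unstable and the code falls back to
Benjamini-Hochberg (π₀ = 1) with a warning. The final call requires
q < 0.05 **and** a largest-magnitude combination fold change above
0.58 log2 units (1.5-fold); the joint gate is what keeps the realised
false-discovery rate of the caller near 1% on reference cohorts even
though the q-threshold alone admits 5%.

## Insulin responses and the magnitude gate

Responses are insulin-stimulated values minus the *unstimulated median* of
the same strain-diet combination, removing baseline-abundance differences
between strains and diets. The strain/diet cascades compare fold changes
through a piecewise-linear gate: candidate y differs meaningfully from
reference x iff y > f(x) or y < g(x), with c = 0.58,

    f(x) = x + c            for x ≥ 2c
         = (5/4)x + c/2     for 0 ≤ x < 2c
         = x + c/2          for −c/2 ≤ x < 0
         = (4/5)x + (2/5)c  for −3c ≤ x < −c/2
         = x + c            for x < −3c

and g(x) = −f(−x). The margin f(x) − x shrinks from c to c/2 for weakly
regulated peptides, so weaker responses need smaller absolute differences
to count. f is continuous and non-decreasing; a published variant of g
whose second piece carries a "+" sign is implemented behind
`printed_g_variant=True` but is discontinuous at both knots of that piece
and is not used: the antisymmetric form is the only one consistent with
the up/down symmetry of the procedure.

Strain effects use CHOW data only: one-way ANOVA of response ~ strain
(Storey q over peptides), Welch two-sided t-tests of each strain against
the reference strain (default `C57Bl6J`; pooled-variance optional) with one
pooled q family over (peptide, strain) pairs, then the gate on CHOW fold
changes. Diet effects use a two-way strain × diet ANOVA on responses;
a significant interaction (q < 0.05) routes to per-strain CHOW-vs-HFD
t-tests plus the gate, else a significant diet main effect routes to the
gate on across-strain mean fold changes. The q families of the regulation,
strain and diet analyses are kept separate.

### Known limitation: interaction inflation from the shared reference median

All insulin responses in one strain-diet combination subtract the *same*
unstimulated median. Its sampling noise therefore acts as a cell-level
random effect (intraclass correlation ≈ 0.2–0.3 at n = 6 regardless of the
noise scale), which the two-way ANOVA — treating responses as independent —
reads as extra between-cell variance. The interaction F is inflated for
*every* peptide (null fraction p < 0.05 ≈ 0.37 at the reference
conditions), so genuinely uniform diet effects are frequently routed into
the interaction branch, where their real (uniform) diet shift passes the
per-strain tests, and they end up classed strain × diet. On reference
cohorts the cascade recovers ~98% of planted strain × diet and strain
effects but only ~15–40% of planted uniform diet effects; the corresponding
acceptance check is deliberately left failing rather than papering over the
behaviour. Scarcity of uniform-diet calls relative to interaction calls is
an expected signature of this procedure, not evidence that uniform effects
are biologically rare. A calibrated alternative would model the shared
reference explicitly (e.g. a mixed model with a combination-level random
intercept); that is out of scope here because the cascade's contract is the
median-referenced procedure.

## Kinase substrate enrichment

Curation keeps edges with in vivo evidence, collapses isoform labels
through an alias table (cycles rejected), removes autophosphorylation edges
(substrate protein = kinase) and removes substrates annotated under ≥ 4
kinases; supplementary substrate lists (e.g. a putative-substrate set for
one kinase) can be appended after the evidence filter but before the
promiscuity rule.

Per sample, peptides with a response value are ranked descending (ties
broken by peptide id, so results are reproducible), and a kinase's score is
the signed maximum deviation of the unweighted running sum: +1/|S| at
substrate positions, −1/(N−|S|) elsewhere; |score| ≤ 1, positive when
substrates concentrate at the top. Significance is empirical: substrate-set
membership is permuted uniformly (1000 draws), and
p = (1 + #{|score_perm| ≥ |score|}) / (n_perm + 1), so p is never 0 and
ties count as exceedances (a 1e−9 tolerance absorbs float differences
between arithmetic paths). A mean-rank z statistic is available via
`method="zscore"` for sensitivity analysis. The peptide universe is
restricted to peptides quantified in ≥ 50% of samples with ≥ 1 response in
every combination; cells with < 5 quantified substrates are undefined, and
kinases qualify for downstream strain/diet ANOVAs only with p < 0.05 in
≥ 5 samples. Each kinase gets an independent child RNG stream, so adding or
removing kinases never changes another kinase's p-values.

## Coregulation subnetworks

Pairwise-complete Pearson correlations of responses (constant rows
excluded) are raised to power 3 as an unsigned adjacency (signed variant
available). Topological overlap,

    TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

measures shared neighbourhood as well as direct similarity; 1 − TOM feeds
average-linkage hierarchical clustering. The tree is cut at a single static
height chosen as the midpoint of the largest gap in merge heights: coherent
modules merge low and join the background high, so the widest gap separates
module formation from background agglomeration. (A cut at a fixed high
quantile of merge heights was tried first and rejected: on planted
two-block data the 0.99 quantile sits above the block-joining merges and
returns a single cluster.) Clusters under 15 peptides dissolve to label 0
(unassigned); no post hoc reassignment is performed. Eigenpeptides are the
first principal component of the standardised member profiles (peptide-mean
imputation of missing entries affects only this extraction), sign-oriented
to correlate positively with the module mean and scaled to unit variance;
module pairs with eigenpeptide dissimilarity 1 − r < 0.25 merge iteratively
(closest pair first; the step is idempotent). Membership (kME) is the
correlation of any peptide with any eigenpeptide. Over-representation of
term sets uses one-sided Fisher exact tests, testing only terms with ≥ 3
overlapping proteins, BH-adjusted within an analysis; fold enrichment is
(overlap/|fg|)/(|term ∩ bg|/|bg|).

## Tracer kinetics and association

Blood clearance is fitted as Cp(t) = Cp0·e^(−Kp·t) by nonlinear least
squares initialised from the log-linear regression of ln Cp on t
(log-linear fitting alone is available but weights early high counts
poorly). The 1-minute sample is dropped iff Cp(1) < Cp(5) and
Cp(5) − Cp(1) > 0.5·(Cp(5) − Cp(7.5)) — an abnormally low first draw
indicates poor tracer diffusion at the sampling site; the event is logged
for review. Uptake is Ki = Ci(t)·Kp/(Cp0·(1 − e^(−Kp·t))) (µL·mg⁻¹·min⁻¹),
which tends to Ci/(Cp0·t) as Kp → 0. Glucose tolerance is summarised by
the baseline-subtracted trapezoid AOC = Σ ((G_{i−1}−G₁)+(G_i−G₁))/2·Δt_i,
invariant to adding a constant to all glucose values.

Association of entity profiles (intensities, responses, kinase scores,
eigenpeptides) with insulin-stimulated uptake uses pairwise-complete
Pearson tests; an entity passes at Storey q < 0.1 and |r| > 0.35. For small
families such as a handful of modules, raw p replaces q (`use_q=False`) —
a q-value over < 10 tests is not meaningful. Intensity-mode association
uses insulin-stimulated samples only. Trait vectors other than uptake
(e.g. body mass) reuse the same routine.

## Synthetic cohorts

`generate_cohort` simulates directly on the log2 scale:
value = baseline (U[18, 30], mimicking MS dynamic range) + per-strain and
per-diet peptide offsets (SD 0.5 / 0.3) + per-sample loading shift
(SD 0.2) + planted insulin effect (insulin-treated samples only) + Gaussian
replicate noise. Defaults plant 10% of peptides as insulin-regulated at
±2.0 log2 units with replicate SD 0.25 and n = 6 per cell; of the regulated
set, 50% carry a strain effect (one non-reference strain's effect removed
on both diets), 25% a strain × diet interaction (one strain's HFD effect
removed) and 2.5% a uniform diet effect (all strains' HFD effects shifted
additively by half the effect size), mirroring the relative prevalence of
these classes in vivo; strain effects overlap the diet classes
independently. Missingness is the union of a completely-random mask (rate
0.15) and a logistic left-censoring mask in the true intensity (midpoint
21.5, slope 0.9), ≈ 40% total at the defaults. Per-peptide variance
heterogeneity is available through a gamma option on the replicate SD
(`replicate_sd_shape`); it defaults off because a scalar SD is the
transparent reference condition.

What the generator does **not** emulate: peptide sequences or spectra,
correlated peptides from the same protein, inter-tissue heterogeneity,
batch structure beyond per-sample shifts, and heavy-tailed noise. Recovery
results on synthetic cohorts therefore demonstrate the pipeline's
statistical behaviour under its own model assumptions, not performance on
any particular real dataset.

Kinase annotations are generated with planted "signal" kinases whose
substrates are up-regulated peptides carrying the full effect in every
combination (so their enrichment should reach the permutation floor in
every insulin-stimulated sample) plus curation traps: isoform duplicates,
an autophosphorylation edge, a site annotated under four kinases and an
in-vitro-only edge. Phenotypes are a weighted driver-response mean plus
Gaussian noise scaled to a target population correlation; drivers must be
mutually correlated (as coregulated peptides are) for their *individual*
correlations with the phenotype to approach the target.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.default_rng`; identical seeds
give bit-identical outputs, and the pipeline driver expands one global seed
into per-stage seeds so stages can be rerun in isolation. Benchmarks in
`gxephos.benchmarks` (shared by the test suite and
`scripts/acceptance.py`) use 20 cohorts of 2000 peptides for regulation and
classification recovery, 100 draws for tracer Monte-Carlo, a 90-peptide
planted-block design for subnetworks and 20 replicates of a 500 × 50
association null — sizes chosen so the complete validation runs in a few
minutes on one CPU while keeping Monte-Carlo error well below the margins
being tested. Sensitivity is reported over planted peptides that pass the
quantification filter; peptides too sparsely quantified to test are
unassessable by construction.
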