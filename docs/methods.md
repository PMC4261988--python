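# Methods

This note records the models, conventions and numerical choices behind
`ecotypeabc`, in enough detail to reimplement or audit any stage.

## Demographic models

All four models describe 2 ecotypes × 2 localities sampled in the
present, read backward in time as a sequence of migration epochs and
merge/resize events.  Parameters, units and default priors:

| symbol | meaning | unit | default prior |
|---|---|---|---|
| *N*<sub>l</sub> | local deme size | diploid individuals | log-uniform [10², 10⁷] |
| *N*<sub>g</sub> | ghost/ancestral size (within-region) | diploid individuals | log-uniform [10², 10⁷] |
| APS | ancestral size relative to *N*<sub>l</sub> (between-region) | — | log-uniform [0.1, 100] |
| *T*<sub>lg</sub>, *T*<sub>wc</sub>, *T*<sub>x</sub>, *T*<sub>mig</sub> | split / end-of-allopatry times | generations | log-uniform [10², 10⁷] (oldest time drawn; others derived) |
| PROPT, PROPTlg, PROPTx, PROPmig | log-scale time proportions | — | uniform (0, 1) |
| *M*<sub>lg</sub>, *M*<sub>wc</sub>, *M*<sub>x</sub> | per-generation migration probabilities | per lineage | log-uniform [10⁻⁹, 10⁻³] |
| MU, AFLPMU | nuclear / AFLP mutation rates | per base per generation | uniform [1.5 × 10⁻⁹, 1.5 × 10⁻⁸] |

These prior ranges are the package's own defaults, chosen to bracket
the posterior medians reported for this study system (local sizes
~10⁴, ghost sizes ~10⁶, colonisation times ~10⁵ generations, migration
10⁻⁸–10⁻⁵); every bound is configurable.

Derived times act on the natural-log scale, the literal reading of
"log(Twc)/log(Tlg)": in the parallel models the oldest time is drawn
and *T*<sub>wc</sub> = exp(PROPT · ln *T*<sub>lg</sub>) (so
*T*<sub>wc</sub> < *T*<sub>lg</sub> automatically); in the old-divergence
models the ecotype split *T*<sub>wc</sub> is oldest and the colonisation
and end-of-allopatry times are derived, with draws rejected until
PROPmig > PROPTlg (equivalently *T*<sub>mig</sub> > *T*<sub>lg</sub>;
analogously with *T*<sub>x</sub> between regions).

Open topology choices, fixed here: the within-region old-divergence
model uses one ghost deme per ecotype, each of size *N*<sub>g</sub>,
with local demes attached to their own-ecotype ghost, and the
post-merge ancestral deme also has size *N*<sub>g</sub>; between-region
migration *M*<sub>x</sub> connects same-ecotype demes across regions
only; both ecotype merges happen at the same instant *T*<sub>wc</sub>.
The between-region builders accept an optional resize at ecotype
formation (population expansion), off by default.

## Coalescent simulation

Genealogies follow a continuous-time Gillespie walk: within a deme of
diploid size *N*, each lineage pair coalesces at rate 1/(2*N*·s) per
generation, where s is a per-locus scale (0.25 for mtDNA: haploid and
maternally inherited); each lineage migrates i→j at the epoch's
probability m<sub>ij</sub> treated as a rate (valid for m ≪ 1, which the
priors guarantee).  Epoch boundaries and merge/resize events interrupt
the walk; the simulation errors out if lineages remain with zero total
rate and no event ahead, or after 5 × 10⁷ events.  Per-deme membership
lists make each event O(1); the kernel is numba-compiled.

Sequences evolve by dropping Poisson(μ · length · branch length)
mutations per branch, each at a uniform site, transition with
probability `ts_fraction` (0.91 mtDNA, 0.33 = unbiased for nuclear and
AFLP) else one of the two transversions; the root sequence is uniform
over {A,C,G,T}.  Bases are encoded A=0, C=1, G=2, T=3 so a substitution
is a transition iff `a ^ b == 2`.

Sampling: one sequence per individual for mtDNA (females) and nuclear
loci (one allele kept per individual), two 20-bp haplotypes per
individual for AFLP.  The default marker panel is the study's: mtDNA
2004 bp, introns 376/270/341 bp (the middle intron pre-pruned of its
recombining 5' segment), 462 AFLP loci.  AFLP conversion: per locus one
haplotype drawn uniformly from the distinct haplotypes present becomes
the "1" allele; individuals are consecutive haplotype pairs; phenotype
1 iff ≥ 1 copy.  Because the allele is chosen among haplotypes present,
an all-absent locus cannot arise; the removal rule for unobservable
loci is retained as a guard.

Not modelled: recombination within loci, indels, scoring or sequencing
error, selection, continuous space, more than two localities.

## Summary statistics

Per sequence locus and group: Tajima's *D* (raw difference counts,
standard variance coefficients, 0 when S = 0) and π as the mean pairwise
Kimura 2-parameter distance, d = −½ln(1 − 2P − Q) − ¼ln(1 − 2Q);
saturated pairs are NaN and excluded.  Per locus and group pair:
Φ<sub>ST</sub> from a two-group AMOVA on squared K2P distances (σ²ₐ/σ²ₜ;
negative values retained; NaN distances replaced by the mean finite
squared distance of the relevant pair set).

AFLP allele frequencies use the square-root method (q̂ = √f₀ under
Hardy–Weinberg).  Per-locus *F*<sub>ST</sub> = (H<sub>T</sub> −
H<sub>S</sub>)/H<sub>T</sub> with the numerator (p̂₁−p̂₂)²/2 corrected by
the delta-method sampling variance of each frequency estimate,
var(q̂) ≈ (1 − q̂²)/(4n) (zero at the boundaries): without the
correction the estimator has an O(1/n) positive bias under panmixia
that would swamp weak real differentiation.  The residual bias decays
as 1/n and is below 0.01 at the study's 26 individuals per group.
Jaccard distances average 1 − |shared bands|/|bands in either| over
between-group individual pairs.

Layout: 4 loci × 4 groups × (D, π) = 32, plus 4 × 6 Φ<sub>ST</sub> = 24
(56 sequence values); 4 H + 6 mean *F*<sub>ST</sub> + 6 SD + 6 Jaccard =
22 AFLP values; 78 combined, asserted at build time.  Pair statistics
that are undefined because the marker panel is monomorphic for that
pair map to 0 in the assembled vector (a monomorphic panel carries no
differentiation signal); dropping those simulations instead would
condition the prior on polymorphism.  Remaining NaN sentinels are
filtered from simulation tables.

## ABC engine

**PLS.** Each statistic is shifted positive (1 − training minimum),
Box-Cox transformed (per-statistic ML λ, clipped to [−5, 5]),
standardised, then a PLS regression of the estimation-scale parameters
(ln for log-uniform priors) on the statistics is fitted on a 70%
training split, separately per model.  The component count is chosen
where the held-out root-mean-squared error of prediction levels off
(within 1% of its minimum), capped at 20.  Constant columns are dropped
with a warning.

**Rejection.** Euclidean distance in PLS component space; the k nearest
rows are retained with ties broken by simulation index (stable sort).
Defaults mirror the study's retention counts out of 10⁶ simulations: 1%
combined, 2% AFLP-only, 0.5% sequence-only — with a floor of 200
retained so the 78-dimensional comparison GLM stays identified at
desk-scale table sizes.

**GLM adjustment.**  On the retained set the statistics are modelled as
s = c₀ + Cθ + ε with ε ~ N(0, Σ) estimated from the regression
residuals (Ledoit–Wolf shrinkage when k < 3p, plus a 10⁻³·tr(Σ)/p
spectral floor: after rejection the leading components are nearly
constant and Σ would otherwise be numerically singular).  On the
estimation scale every prior is flat and the retained parameter draws
are a sample from the prior truncated to the retained region, so the
posterior ∝ truncated-prior × N(s_obs; c₀ + Cθ, Σ) is realised by
weighting the retained draws with their GLM likelihoods; the marginal
density of the observed statistics is the mean likelihood over that
sample.  This form is exact in both limit cases: with noiseless linear
statistics the weights collapse onto the preimage, and with
uninformative statistics (Σ → ∞) the posterior returns the truncated
prior.  Per-parameter densities are weighted Gaussian KDEs (Silverman
bandwidth, boundary reflection at the truncation box) on 1024-point
grids, normalised by the trapezoid rule.

For parameter estimation the GLM conditions on PLS components.  For
model comparison it conditions on the full statistic set, Box-Cox
normalised through the model's transform — raw summary statistics are
heavy-tailed and a Gaussian GLM on them is dominated by single extreme
entries — and the marginal density is mapped back to the raw-statistic
scale through the transform Jacobians, which makes densities comparable
across models even though each model normalises with its own constants.
Bayes factors and posterior probabilities are computed in log space.

**Goodness of fit.** The p-value is the fraction of retained
simulations whose best-fitting GLM likelihood (residual after
projection onto the GLM mean space, in the Σ metric) is at most the
observed vector's.

**Summaries.** Median and mode come from the gridded density; the 95%
HPD is the smallest-density region of mass 0.95, returned as a union of
intervals, with density ties resolved towards the posterior median (so
a flat posterior yields the centred interval).  Log-scale parameters
are reported after exponentiation.

## Validation

PODs are full simulations from the inference priors (rows with sentinel
statistics redrawn, matching table construction).  Model choice: each
POD is classified with the same reference tables, retention and PLS
settings as the real analysis; a model is supported when its posterior
probability exceeds 0.95, otherwise the POD is undecided; fractions are
pooled over the PODs of both generating models.  Calibration: the
posterior CDF at the true value, per parameter, is tested against
uniform(0, 1) by Kolmogorov–Smirnov.

## Outlier scan

The neutral null is a symmetric two-deme island coalescent of dominant
20-bp loci at the observed sample sizes (reference deme size 5000,
θ = 1 per locus; only 4Nm matters for the F_ST null).  4Nm is tuned by
stochastic bisection on log₁₀(4Nm) until the simulated mean
*F*<sub>ST</sub> matches the 30%-trimmed observed mean within 0.005,
with one secant refinement; when the target lies at or below the
estimator's small-sample bias floor the maximal-migration (most
conservative) null is used with a warning.  Observed loci are ranked
within 20 equal-count heterozygosity bins of the null (sparse bins
merged; ≥ 100 loci per bin), and flagged above the 0.95 quantile.
Because dominant-marker *F*<sub>ST</sub> sits on a discrete grid, ties
are broken by a vanishing random jitter (10⁻⁹ of the null spread),
giving the rule its exact nominal size.  Outliers from any pairwise
comparison are removed before demographic inference, and simulation
tables then use the post-filter locus count.  Expected shared outliers
between analyses are n₁n₂/L under independence, with region-level
counts formed as distinct unions (n_a + n_b − shared).

## Scar-frequency G-tests

2×2 morph-by-scar tables use G = 2ΣO ln(O/E) divided by the Williams
correction q = 1 + (N/r₁ + N/r₂ − 1)(N/c₁ + N/c₂ − 1)/(6N), df = 1,
χ² p-values.  The hierarchical decomposition reports, per region, the
pooled table, each locality, and a between-localities heterogeneity
term computed as Σ corrected locality G − corrected pooled G, floored
at zero (corrections break exact additivity and can drive the
difference slightly negative); analogously between regions with df =
regions − 1.  This convention reproduces the published values at one
decimal in 13 of 14 cells; the remaining cell (Sweden pooled, printed
17.4) matches neither the corrected (17.3) nor uncorrected (17.5)
recomputation and the package reports its own value.

## Problem sizes

The full study design (16 sequences and 26 AFLP individuals per group,
462 AFLP loci, 10⁶ simulations per model, 1000 PODs) is reachable
through configuration.  The test suite and the acceptance script use a
scaled design — identical structure with 8 sequences and 8 individuals
per group and 50 AFLP loci — with 2 × 10³-simulation tables for
model-choice smoke runs, 10⁴–2 × 10⁴ tables for coverage checks, and
30–50 PODs, the package's desk-scale defaults for iterating on the
method.  Model-choice accuracy at that scale (correct ≈ 65–70%, wrong
≈ 20–28% at the PP > 0.95 rule) brackets the full-scale study's
reported discrimination and is a sign-level, not numerical,
reproduction.

## Limitations

Synthetic data share the generative family of the inference models, so
passing tests demonstrate internal consistency and calibration, not
robustness to model misspecification (real AFLP scoring error,
recombination, selection at linked sites, or more complex geography).
The GLM goodness-of-fit p-value is a heuristic and can sit at 0 for
individual datasets even under the generating model at desk-scale
retention.  Dominant-marker allele frequencies use the square-root
method throughout; only internal consistency between observed and
simulated data matters for the ABC, but absolute F_ST levels inherit
its small-sample bias.
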