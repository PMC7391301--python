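# Methods

## Hub disruption scanning

The statistic for a hub *h* with usable partners *P'* is the mean absolute
difference of hub–partner Pearson correlations between the two conditions,
S = (1/|P'|) Σ |r_A − r_B|, bounded in [0, 2].  Partners absent from the
expression matrix, identical to the hub, or with zero variance in either
condition are dropped from the mean and the retained count is reported; a
hub with no usable partner carries an undefined (NaN) score and is excluded
downstream rather than silently scored 0.

**Permutation null.**  The null distribution of S is generated by permuting
condition labels across samples while preserving group sizes — the standard
exchangeable null for a two-condition correlation-difference statistic.  The
p-value uses add-one smoothing, p = (1 + #{S_perm ≥ S_obs})/(1 + n_perm), so
it is never zero and is valid as an exact test level.  Because S is
symmetric under complementing the sample split, permuted splits are drawn at
the smaller group's size; this samples the identical null and makes the
p-value exactly invariant to which condition is labelled "A".  Within a scan
run all hubs share one set of permuted splits: the correlations for all
partners and all permutations reduce to a handful of mask matrix products,
which keeps 100 hubs × 1000 permutations around a second of compute.

**Consensus.**  A scan run draws a stratified subsample per condition with
ceiling rounding (two-thirds of 21 tumors and 12 normals gives 14 + 8),
computes every hub's permutation p on it, and marks hubs at p ≤ α (default
α = 0.05, configurable — the per-run level is a free parameter of the
procedure).  The disrupted set is the intersection over runs (default 3).
The intersection is what controls false positives: a null hub significant by
chance in one subsample rarely repeats in two more, while a genuinely
disrupted hub is significant in all of them.  Raising α can only grow each
run's set and hence the intersection (monotonicity).

**Skeleton and hubs.**  The skeleton keeps the top ⌈f·|E|⌉ edges by edge
betweenness centrality (ties broken by sorted edge name for determinism),
then removes degree-0 nodes; f = 1 is the identity on edges minus
pre-existing singletons.  The default retention f = 0.2 is a configuration
choice — betweenness-based skeletons preserve the modular backbone at a wide
range of f.  Hubs are nodes with more than 4 partners (degree ≥ 5),
identified on the skeleton after singleton removal.  Cross-species
confirmation intersects disrupted sets through an ortholog map filtered to
one-to-one pairs (many-to-many pairs are dropped and logged).

## Screen scoring

Counts are normalised by per-sample total to 10^7 reads (total-count scaling
is the simplest method consistent with "normalized reads"; the target is
configurable) and log10-transformed with pseudocount 0.1, chosen so that
reported read values as low as 0.1 remain representable and zeros map to −1.
Base 10 is used throughout; it makes the fivefold-depletion cutoff
log10(1/5) ≈ −0.70, consistent with the −0.69 threshold applied verbatim in
the cutoff mode.

**Robust-Z outlier masking.**  Within each (shRNA, cell line), tumor
replicates are scored by robust Z = (x − median)/(1.4826·MAD).  When MAD = 0
with all values equal there are no outliers; when MAD = 0 with unequal
values the scale falls back to 1.2533 × mean absolute deviation (both
constants are the consistency factors for a normal distribution).
Replicates with |Z| > 5 are flagged and at most 2 of 6 excluded — never
leaving fewer than 4 — taking the largest |Z| first with ties broken by
sample order, so the masking is deterministic.  Note that with 6 replicates
the MAD breaks down at 3 simultaneous outliers (50% contamination), so the
exclusion cap is almost never binding in practice; the cap logic is
exercised with 8-replicate fixtures.

**Dropout calls.**  Per shRNA and line, the mean of retained tumor
replicates over the T0 count (pseudocount added to both) is
log10-transformed and standardised across all shRNAs within the line;
dropout ⇔ Z < −1.96 (two-tailed 5%).  A degenerate screen (zero across-shRNA
SD) is an error, not a silent pass.  The omnibus skewness–kurtosis normality
check on the log ratios is advisory: it warns rather than aborts, because
the Z threshold only needs approximate normality and the appropriate remedy
(the cutoff mode) is a design choice, not an automatic fallback.  The
cutoff mode scores shRNAs at log ratio ≤ −0.69, calls gene hits at ≥ 2
scoring shRNAs, and tiers them high/medium/low by ≥3/2/1 scoring cell lines
in the 4-line design.  Fisher's exact test uses the two-sided
probability-mass convention (sum over tables with probability ≤ observed),
which reproduces the screen-validation p of 0.0002 for the 15/3 vs 3/15
table; a zero margin returns p = 1 with a warning.

## Median-effect synergy

Fraction affected for growth is fa = 1 − X_treated/X_control; apoptotic
index is accepted directly as a fraction.  Fits are OLS on
log10(fa/(1−fa)) ~ log10(D); only fa values at or beyond the [0, 1]
boundaries are clamped (to 0.005 / 0.995) and flagged — values strictly
inside the interval are used untouched, so noiseless data reproduce (m, Dm)
to round-off with r_fit = 1.  A non-positive fitted slope (response not
increasing with dose) is an error.  CI defaults to the mutually exclusive
(no cross-term) form, which reproduces the published in vivo worked example
(combo 3 + 0.001 µg against equivalents 16 + 0.24 µg → CI 0.19); the
non-exclusive third term is available behind a flag.  DRI = Dx/D.  Reported
CIs are conventionally rounded to 2 decimals and DRIs to 2 significant
figures; raw values are retained.  For three drugs, a fixed-ratio pair is
fitted as one entity whose dose is the sum of component doses (ratio drift
beyond 1% is an error), then combined with the third drug as a two-term CI.
The potent-synergy call requires, in every varied-drug orientation, at least
one point with Fa > 0.7 and CI < 0.7.  In vivo growth series are normalised
to day 0 per replicate before averaging; treated vs vehicle at a matched day
feeds fa.

## Synthetic data

*Expression.*  One-factor hub blocks: the hub's latent signal z_h is
standard normal per sample; each partner is r·z_h + √(1−r²)·ε, so the
generating Pearson correlation is exactly r (r_normal in normals and in
tumors for intact hubs; r_tumor_disrupted in tumors for disrupted hubs).
Values are baseline + noise_sd·z with gene-specific baselines uniform on
[6, 12] (log2-microarray-like); noise_sd is a pure scale and must be
positive — zero would give a variance-free, degenerate matrix.  Defaults
mirror the 21-tumor/12-normal design.  The generator does not emulate
probe-level noise, batch effects, or correlation between different hubs'
blocks, so recovery results speak to the statistic's behaviour under clean
block structure, not to microarray preprocessing.

*Screen counts.*  A Poisson-gamma hierarchy: per-shRNA abundance
λ ~ Gamma(shape = dispersion, mean = mean_t0_count) shared between T0 and
tumor samples, counts Poisson(λ) (T0) and Poisson(λ·f) (tumors), with f the
depletion factor for depleted genes and 1 otherwise.  Marginally T0 counts
are negative binomial with the requested mean and dispersion, and sharing λ
makes tumor/T0 ratios tight around f — mimicking a pool where representation
varies but each shRNA's baseline is common to all animals.  Defaults: 6
tumor replicates, mean 1000 reads, dispersion 10.  Outliers multiply chosen
(shRNA, replicate) cells by outlier_factor and are recorded as truth.  The
model omits sequencing-depth differences beyond normalisation's reach,
transduction bottlenecks, and inter-animal graft variability beyond Poisson
noise.

*Dose response.*  Single-drug rows follow fa/(1−fa) = (D/Dm)^m exactly, with
optional multiplicative noise of coefficient of variation cv_noise on the
measured cell number.  Combination rows at constant ratio solve
Σ Dᵢ/Dxᵢ(fa) = 1/α for fa by bracketed root finding (failure to bracket —
doses far outside the response range, e.g. a steep curve sampled well below
Dm — is an error), so the ground-truth CI is 1/α by construction and
recovery tests are analytic.

## Problem sizes and numerical choices

Simulated analyses use study-scale designs: 100 hubs × 5 partners at
21 + 12 (analysis scripts) or 60 + 60 samples (power checks), 1000
permutations and 3 consensus runs; screens of 400–10,000 shRNAs with 6
tumor replicates; dose grids of 5 doses × 3 replicates.  These sizes give
stable statistics while keeping any script or the full test suite in the
tens of seconds.  Correlation denominators below 1e−12 yield r = 0 in
permuted splits (zero-variance subsets are measure-zero for continuous
data); root finding uses `brentq` at 1e−14 tolerance; all randomness flows
from explicit integer seeds through `numpy.random.Generator`
(`SeedSequence.spawn` for per-run streams), so every generator and scan is a
pure function of its inputs.

## Known limitations

The per-run significance level, skeleton retention fraction and
normalisation target are procedure parameters, not published constants;
defaults are stated above and exposed in configuration.  The hub scan's
consensus false-positive control is empirical, not a formal FWER guarantee.
The published genome-scale results (specific disrupted-hub identities, exact
screen hit lists) depend on the study's unreleased expression and screen
data and are out of reach of the simulations here; the recomputation hooks
for the published per-shRNA supplementary tables are present but require
the user to supply those tables.
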