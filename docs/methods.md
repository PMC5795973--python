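# Methods

## The quantification model

Relative qPCR quantification compares transcript abundance between
experimental groups without absolute copy numbers.  Each well reports a
quantification cycle Cp; with per-cycle amplification factor E (estimated per
assay from standard-curve dilution series, E = 2 meaning perfect doubling)
the initial template amount is proportional to E^-Cp.  The package works on

    y = -log2(E^-Cp) = Cp * log2(E),

computed in the product form to avoid underflow at large Cp.  y lives on the
log2 scale whatever the assay efficiency, and larger y means lower
expression.

All genes — 13 lipid-metabolism targets and the endogenous controls — enter
one joint linear mixed model:

    y_gijklr = TG_gi + P_gj + B_gk + A_gl + D_ijkl + e_gijklr

with a fixed mean TG_gi per gene x treatment cell (the 2 breeds x 2 diets x
2 feeding statuses give 8 cells) and zero-mean independent random effects
for plate-within-gene (P), housing-box-within-gene (B), animal-within-gene
(A), biopsy sample shared across genes (D), and well residual (e).  One
variance is estimated per grouping, shared across genes: the model notation
carries a single symbol per grouping, and gene-specific variances would add
~60 weakly identified parameters at this design size.  Technical replicates
enter as individual wells; the residual captures well noise.

### REML estimation

Variance components maximize the restricted likelihood.  The implementation
profiles out both the fixed effects and the residual variance and optimizes
the variance ratios gamma_k = sigma2_k / sigma2_e by L-BFGS-B with an
analytic gradient, restarting from alternative points when the first start
does not converge cleanly; a Nelder-Mead polish runs on small problems and
whenever the quasi-Newton path ends abnormally.  All algebra is carried out
in the random-effect level space through M0 = I + S Z'Z S (S the square
roots of the expanded ratios), so one iteration costs a single Cholesky of a
q x q matrix (q = total random levels; about 1 200 at full study size) and
the optimizer typically needs 15–30 iterations.  Ratios below 1e-8 are
pinned to exactly zero, which handles boundary optima; convergence requires
a relative criterion change below 1e-8 or a gradient norm below 1e-6, and
exceeding the iteration cap (500) raises an error carrying the last
iterate.  A perfect-interpolation shortcut returns the OLS solution when the
residual sum of squares is numerically zero, so noise-free fixtures are
handled exactly.  The exact restricted log-likelihood at arbitrary candidate
components is exposed (`reml_loglik`) so tests can grid-search the surface
independently of the optimizer; the test suite verifies the optimizer
against a dense-matrix grid-plus-polish maximizer to 1e-6 on all small
instances.

### Contrasts, normalization and fold changes

Effects are tested as zero-sum contrasts over the cell means: main effects
average the first-named class's four cells against the other four
(Iberian - Duroc, fed - fasting, HO - CH), interactions are differences of
differences.  With reference normalization on (the default), the contrast
applied to a target gene is its own cell contrast minus the mean of the
same contrast over the reference genes, so reference instability propagates
into the standard error through the combined weight vector; with it off,
the sample-shared random effect D alone absorbs loading differences.

Each contrast diff gets se = sqrt(w' C w) from the fixed-effect covariance
and denominator degrees of freedom gamma by the Satterthwaite approximation
2 g^2 / Var(g), with Var(g) propagated from the observed information of the
variance parameters (numerical Hessian of the restricted likelihood;
boundary components held fixed).  Containment df are available as a config
alternative.  Because y is negative log2 expression, estimates
back-transform as

    FC = 2^-diff,   SE(FC) = 2^-SE,
    95 % CI = [2^-(diff + t(gamma, 0.975) SE), 2^-(diff - t(gamma, 0.975) SE)],

so FC > 1 always means higher expression in the first-named class and the
CI is asymmetric on the ratio scale with sqrt(lo * hi) = FC exactly.  Under
the simulator's default noise levels the Satterthwaite df range over roughly
two orders of magnitude across contrasts (animal-limited breed contrasts
versus replicate-rich within-animal status contrasts); designs with fewer
boxes or stronger box variance push the lower end down further.

### Multiple testing

Within each effect family the p-values are adjusted by Benjamini–Hochberg
step-up in which the test count is replaced by the effective number of
tests from the eigenvalue dispersion of the inter-gene correlation matrix
(Cheverud–Nyholt):

    m_eff = 1 + (M - 1)(1 - Var(lambda) / M),

Var with denominator M - 1, clipped to [1, M].  The correlation matrix is
Pearson correlation across biopsy samples of per-sample gene means after
subtracting each sample's reference-gene mean; which matrix the original
analysis used is not recorded, so this choice is the package's own and is
documented rather than asserted.  Adjusted p-values are floored at the
nominal value, preserving monotonicity in the nominal ranks.

## Reference-gene stability

Wells are collapsed to one value per gene per biopsy sample before
stability analysis — stability is a property of biological samples, not
technical replicates.  The geNorm-style M value of gene j is the mean over
other candidates k of the SD across samples of y_j - y_k; ranking excludes
the worst gene iteratively (ties broken lexicographically) until two
survive.  The NormFinder-style value centers each sample at its across-gene
mean and combines between-group deviation with the sampling noise of the
group mean, mean_j sqrt(d_gj^2 + s2_gj / n_j); with a single group it is
special-cased to the SD of the centered values.  The reference set of size
n (the study fixed n = 2) minimizes the mean of the two ranks.  geNorm's
pairwise-variation criterion for choosing n is deliberately out of scope.
The sample grouping handed to the NormFinder measure is a required argument
with no default, because the original choice is not recorded.

## Fatty-acid composition

Indices are sums of member FA percentages.  The default memberships are

* SFA: C14:0, C16:0, C17:0, C18:0, C20:0
* MUFA: C16:1n-9, C16:1n-7, C18:1n-9, C18:1n-7, C20:1n-9
* PUFA: C18:2n-6, C18:3n-3, C18:4n-3, C20:4n-6, C20:3n-3, C22:4n-6,
  C22:5n-3, C22:6n-3
* n-6: C18:2n-6, C20:4n-6, C22:4n-6; n-3: the five n-3 PUFAs above

C17:1 is excluded from MUFA and C20:2 from PUFA: these are the only
memberships that reproduce the published index rows exactly, and both
exclusions are flagged in the report; all sets are overridable.  The
n-6/n-3 ratio is computed per sample and then modeled — the published ratio
rows are not ratios of the published sums, so the per-sample route is the
only arithmetic consistent with them.

Each FA or index is modeled separately with fixed breed, diet and
breed x diet cell means and random litter and box effects through the same
REML engine.  LS means of a factor level average the cell means over the
other factor; groupings with a single level are dropped with a warning.
Family-wise adjustment reuses the BH-with-m_eff machinery with m_eff from
the inter-response correlation.  A preliminary screen fits fat layer and
layer x diet within each breed and reports those p-values only.

## Synthetic data

The qPCR generator reads the joint model generatively at the emulated trial
design: 30 Iberian + 19 Duroc animals (HO/CH split 17/13 and 10/9), both
feeding statuses per animal, 13 targets + 2 references with the trial's
published amplification efficiencies, triplicate wells, gene-balanced
plates of ~4 animals each, 10 boxes nested in breed x diet, 19 litters
allocated round-robin within breed.  Real plate and box layouts are
unknown; these defaults are declared assumptions chosen to keep all
variance components identifiable.  Treatment effects are injected per gene
as named effect sizes on the -log2 scale via the orthogonal sign pattern of
the 2x2x2 design, so every named contrast recovers exactly its injected
value.  Default variance components (squared log2 units) are plate 0.02,
box 0.005, animal 0.04, sample 0.04, residual 0.02 — i.e. ~0.14-cycle
technical well noise and ~0.2 log2-unit biological animal/sample variation,
a well-run study with moderate biological scatter.  All random components
are normal on the log2 scale, matching the linear-model assumptions under
test; heavy-tailed alternatives are deferred.

The FA generator perturbs per-cell mean composition vectors on the log
scale with litter (SD 0.05), box (SD 0.03) and residual (SD 0.08) noise and
closes every sample to exactly 100 %.  Default cell means are built
additively from the published diet and breed margins (cell = breed + diet -
grand mean, clipped at zero).  Mean vectors summing below 100 are padded
with an explicit `other` component (unreported minor fatty acids), so a
noiseless sample reproduces its stated mean vector exactly; printed margins
that already exceed 100 (a possibility for LS means of a composition) are
closed multiplicatively instead.  Zero entries never gain mass.  The two
generators draw from independently spawned streams of the config seed, so
one simulator's output never depends on the other's seed.

What the generators do not emulate: amplification-curve shape, primer
kinetics, Cp-calling artifacts, missing wells, heavy-tailed or skewed
biological variation, and any real correlation structure between genes
beyond the shared sample effect.  Passing recovery and calibration tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to their violation.

## Numerical and scope choices

* Two-sided t tests throughout; signed fold changes carry the direction.
* The raw well-level data of the emulated trial are not deposited, so its
  expression tables cannot be recomputed from source; printed rows are
  instead checked for internal consistency (CI geometric means, index sums)
  and the machinery is validated on synthetic truth.
* Test problem sizes: the brute-force REML audit runs on instances of at
  most 40 observations; null calibration uses 13 full-size simulated
  studies (1 014 contrast draws); effect recovery and CI coverage use 150
  replicates of a 4-gene variant of the full design (two targets carrying
  the injected effects plus both references); stability selection uses 200
  seeds.  These sizes keep the suite fast while leaving the binomial noise
  of each check well inside its acceptance band.
* No Kenward–Roger correction, no heterogeneous residual variances, no
  covariances between random groupings, no parsing of proprietary
  thermocycler exports, no chromatogram processing, and no growth/carcass
  phenotype analysis.
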