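# Methods

This note documents the models, estimators, numerical choices and known
limitations of `stratext`, in the spirit of a statistical appendix.

## Stratigraphic conventions

Heights are metres, positive up, from an arbitrary datum; at a
Meishan-style section the datum is the base of bed 27c (the
biostratigraphic Permian/Triassic boundary). Beds tile the column with
half-open spans [base, top): a sample exactly at a bed top belongs to
the bed above. Bed labels order by (numeric part, letter suffix), so
24a < 24e < 25. FADs and LADs are placed at the **midpoint** of their
bed: sub-bed membership is the data's real resolution, and midpoints
avoid spurious zero-length gaps between adjacent sub-beds. Range-through
richness (count of taxa whose FAD–LAD interval spans a bed) is the
default diversity metric; sampled-in-bin counting is available. The
per-bed extinction rate is LAD count divided by range-through richness,
with 0/0 defined as 0 and no edge correction at the window's top bed —
the simplest rate consistent with per-bed resolution; per-capita
alternatives would need an explicit time model the bed grid does not
provide.

## Occurrence vetting

Freshwater and palynomorph records are removed; names are mapped through
a flat acyclic synonym table; exact (taxon, bed) duplicates collapse.
Open-nomenclature occurrences ("", ?, aff., cf., informal) are retained
because ranges should use every placement that is stratigraphically
constrained, even when the identification is hedged. Records not
resolvable to a single current sub-bed (older literature using superseded
bed schemes) are excluded — their extinction timing is unconstrained.
Vetting is idempotent by construction.

## Range confidence intervals

The classical uniform-recovery form: if a taxon's H observed horizons
are uniform over its true range, the range extends above the LAD by
`r·((1−C)^(−1/(H−1)) − 1)` at confidence C. The default C is 0.95,
configurable; the formula is isolated in one function and swappable
should a non-uniform recovery model be preferred. Undefined for
singletons (H < 2). A Monte-Carlo study (10,000 simulated taxa)
confirms that the C = 0.5 extension brackets the true extinction height
50% ± 3% of the time.

## Extinction-pulse inference

**Observation model.** Each window bed b has a recovery probability
p_b — the chance a taxon living through b is actually found in it. A
taxon with true extinction bed P and observed LAD bed l ≤ P contributes

    log L = log p_l + Σ_{l < b ≤ P} log(1 − p_b).

For a k-pulse model every non-singleton taxon is assigned to one of k
pulse horizons at-or-above its LAD; the likelihood-optimal assignment is
the nearest such pulse (each skipped bed multiplies by 1 − p_b ≤ 1), so
assignment is profiled out analytically. Candidate pulse horizons are
the observed LAD beds: the likelihood is piecewise constant between
LADs, so nothing is lost, and the search becomes an exhaustive scan over
subsets (vectorized; exact, verified against brute force). For the
interval model (k = 0) the true extinction bed is uniform over [lo, hi]
on the bed grid and the per-taxon likelihood averages over it; interval
bounds are profiled over all bed pairs. The tail sums span hundreds of
orders of magnitude and are accumulated with log-sum-exp.

**Numerical floor.** Both Bernoulli factors are floored at ε inside the
likelihood: p_b < ε is lifted to ε *and* survival 1 − p_b < ε is lifted
to ε (ε defaults to 1/(2·n_taxa)). The second floor matters: an
empirical recovery estimate of exactly 1.0 in a well-sampled bed —
common with tens of taxa — would otherwise make any model in which a
taxon was missed there strictly impossible and push selection toward
spurious extra pulses.

**Recovery estimation.** p̂_b is the fraction of range-through taxa
actually sampled in bed b, clipped to [ε, 1]. This plug-in estimate is
noisy and *overconfident* at small clade sizes; when the sampling regime
is known (synthetic data; fixed-probability field protocols) the profile
should be supplied explicitly, and the pipeline accepts one. The
validation studies pass the generating profile, so they measure the
pulse machinery, not the recovery estimator.

**Model selection.** Models k = 0 (interval, 2 parameters) and
k = 1..K_max (k parameters) are compared by BIC with n = number of
non-singleton taxa. Because BIC alone can prefer one pulse too many on
noisy recovery profiles, a BIC choice of k ≥ 2 must additionally
survive a parametric-bootstrap likelihood-ratio test against k − 1:
datasets are simulated from the smaller fitted model (LADs drawn from
the conditional missed-sampling distribution), both models refit, and
the larger model kept only if the observed LR exceeds the bootstrap
95th percentile. The interval-vs-pulse decision rests on BIC alone —
those models are not nested, so an LR calibration against the smaller
model is not available. Ties in the placement scan prefer fewer pulses,
then lower horizons (parsimony and reproducibility). All stochastic
steps take explicit seeds.

**Uncertainty.** Pulse-position CIs are percentile bootstrap over taxa
(resample with replacement, refit positions at fixed k).

**Per-clade analysis.** Clades with fewer than `min_richness`
(default 10) non-singleton species are reported as "insufficient"
rather than fitted; with a handful of LADs any pulse-count decision is
noise.

**Validation (simulation studies, 200 replicates each).** With 60 taxa,
20 beds and recovery 0.7, a single pulse is selected in ≈98% of
replicates with zero mean position bias; two pulses 8 beds apart with
40 taxa each are both recovered in ≈99%; a uniform 15-bed extinction
interval is preferred over pulse models in ≈94%. The fitter agrees
exactly with an exhaustive placement scan on every small instance
tested.

## Segmented regression

Mean function `b0 + b1·x + Σ d_j (x − ψ_j)₊`, continuous at the
breakpoints. Estimation is the iterative-linearization scheme
underlying the standard segmented-regression literature: refit with
hinge terms U_j = (x − ψ_j)₊ and indicator terms V_j = −1{x > ψ_j},
update ψ_j ← ψ_j + γ_j/δ_j, iterate to tolerance 1e-8 of the x-range
(max 50 iterations). Ten restarts (quantile-spaced plus uniform draws
plus the best coarse-grid placement) guard against local optima; each
converged solution is refit exactly at its final breakpoints and the
lowest-SSE solution kept. Segments must contain ≥ 3 points
(identifiability). Breakpoint count is selected by BIC with
2 + 2k parameters; inside the BIC the SSE is floored at numerical
precision relative to the data range so that exactly-interpolating fits
compare by parameter count rather than floating-point noise. BIC was
chosen over sequential hypothesis testing for determinism and
simplicity; the recovery simulations below validate the choice.

Anomaly (spike) flagging: residuals beyond 3 robust scales
(1.4826·MAD) of the fit. If the MAD degenerates to zero while residuals
are not all zero — a single spike on an otherwise perfect fit — the
residual SD is used instead; identically-zero residuals yield no flags.
Spikes and state shifts are deliberately separate outputs: volcanism
tracers are expected to spike, climate proxies to shift.

**Validation.** With 100 samples over 6 m, a break at 3.0 m, slopes
0 → 2 and noise at 10% of the signal range, the fitted breakpoint lands
within ±0.5 m in ≈100% of replicates (the estimator's intrinsic SD
under these conditions is ≈0.15 m ≈ 2.5 inter-sample spacings — no
estimator can localize the break to a fraction of one spacing at this
noise level). On pure lines with the same relative noise, BIC keeps
k = 0 in ≈97% of replicates.

## Proxy handling

One dataset per proxy: the loader rejects a proxy mixing references
unless told to merge, because datasets from different studies of the
same beds carry inter-laboratory offsets. Bed-referenced samples sit at
bed midpoints (unbiased under uniform within-bed deposition). Core
samples map onto the outcrop height scale by piecewise-linear
interpolation through monotone tie points, extrapolating terminal
segments with a warning. Bed-level aggregation is the arithmetic mean of
samples in [base, top); empty beds are imputed from the proxy's fitted
segmented curve at the bed midpoint, tagged `imputed`, and observed
values are never altered.

## Association models

All bed-level analyses run on the window where fossil and proxy coverage
overlap (beds 22–29a at Meishan-style input; configurable, endpoints
inclusive). The correlation screen reports Pearson and Spearman r with
two-sided p per proxy pair. VIF_j = 1/(1 − R²_j) with R² from OLS of
column j on the rest; columns above the threshold (default 10, the
common rule of thumb) are dropped highest-first with a full audit
trail, and forced drops (e.g. a proxy excluded for coarse sampling
resolution) are honored first. When two focal proxies are too collinear
to share a model, two GLMs are run on the same post-VIF column set, one
excluding each, and compared by AIC. GLMs are log-link Poisson fit by
IRLS (statsmodels) to tolerance 1e-8; the default richness response is
range-through counts with observed proxy values preferred over imputed
ones.

Partial dbRDA follows the capscale construction: Gower double-centering
of −d²/2, residualization of both the centred matrix and the constraint
columns on the conditioning variables, projection onto the constraint
span, and eigendecomposition of the constrained and residual parts.
Negative eigenvalues (Jaccard is not Euclidean-embeddable) are reported
as-is by default; a square-root distance transform option restores
Euclidean embeddability. Permutation inference permutes rows of the
(residualized) constraint matrix — residual permutation under
conditioning — and recomputes the constrained-inertia pseudo-F;
p = (1 + #{F* ≥ F}) / (1 + n_perm), with drop-one marginal tests per
term under the same scheme. Significance is read at α = 0.05 wherever a
single decision is needed, with **no multiple-testing correction**
anywhere — worth remembering when screening 18 proxies.

**Validation.** The unconstrained model reproduces classical PCoA
eigenvalues to 1e-8 (cross-checked against scikit-bio); the permutation
test's type-I error over 1,000 null simulations at 199 permutations is
≈0.04–0.05.

The quadratic trend helper (for body-size-versus-proxy scatters) is
plain polynomial least squares with R².

## Synthetic data

Generators are pure functions of (config, seed) and return ground truth
alongside the data. Occurrences: each taxon gets a true extinction bed
(its pulse, or uniform over the interval), an origination bed uniform
at-or-below it (the simplest model producing non-trivial range-through
structure), and a Bernoulli(p_b) record in each lived-through bed; taxa
never recovered are dropped and counted. Proxies: piecewise-linear
means plus Gaussian noise at given heights. Richness: Poisson counts
with a log-linear link on bed-level proxies. Default study conditions —
60 taxa, 20 half-metre beds, recovery 0.7, one pulse three-quarters up
the column — represent a well-sampled invertebrate record through a
single extinction event.

What the generators do **not** emulate: lithology-dependent
preservation, sequence-stratigraphic truncation and hiatuses,
abundance structure (everything is presence/absence), taxonomic error,
or autocorrelated proxy noise. Passing the validation studies therefore
shows the estimators work *under the stated sampling model*; it does
not certify them against facies-controlled preservation or correlated
noise, which at real sections (lithological boundaries coinciding with
extinction horizons) remain confounders that no purely statistical
treatment removes.

## The bundled fixture

`fixture_mini_meishan()`: 12 half-metre beds, 40 taxa, two pulses at
beds 6 and 11 under recovery 0.9, four proxies (one genuine state shift
at the first pulse horizon, one pure trend, one flat series with an
implanted spike, one noisy flat series), built from a fixed internal
seed and byte-stable across platforms. The pooled pulse model on the
fixture recovers k = 2 at the constructed beds; breakpoint selection
finds exactly one shift on the shifted proxy.

## Known limitations

- Recovery probabilities are treated as known or plug-in estimated;
  no hierarchical uncertainty in p̂_b propagates into pulse CIs.
- The pulse model is discrete-bed; no continuous-time age model.
- The interval model's uniform density is a convention; clustered
  extinction within an interval will bias its bounds inward.
- dbRDA biplot scores are correlations with site scores (scaling-2
  style); other scalings are not implemented.
- The bootstrap LRT calibrates adjacent pulse counts only; k vs k+2
  comparisons rest on BIC.
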