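# Methods

This note documents the models and procedures implemented in `statescape`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Binarization

Network signals are thresholded into ±1 patterns. The default threshold is
the *per-timepoint* mean across the N node signals (the global-signal
threshold), which balances active and inactive counts at every timepoint;
a per-node temporal-mean mode is provided for sensitivity analyses. Ties
(signal exactly at threshold) map to −1: deterministic, and a
measure-zero event for real-valued data. A fit on fewer than 2^(N−1)
timepoints triggers a warning — below that, the 2^N-cell pattern
histogram is too sparse for a trustworthy pairwise fit.

## Pairwise maximum-entropy model

The fitted distribution is the Ising/Boltzmann family
`P(V) ∝ exp(Σ h_i σ_i + ½ Σ J_ij σ_i σ_j)`, the least-structured
distribution matching first and second moments. Fitting is plain gradient
ascent on the log-likelihood from a zero start: each iteration moves
`h_i` by `ε(⟨σ_i⟩ − ⟨σ_i⟩_m)` and `J_ij` by `ε(⟨σ_iσ_j⟩ − ⟨σ_iσ_j⟩_m)`,
with model moments recomputed by exhaustive enumeration (guarded at
N ≤ 20). Defaults: `ε = 0.2`, tolerance `1e-8` on the largest absolute
moment gap, 5·10^5 iteration cap. The log-likelihood is concave, so the
only failure mode is slow convergence; non-convergence is reported in the
diagnostics, never raised. The pipeline uses a looser `1e-6` tolerance for
empirical fits, where sampling error in the moments is orders of
magnitude larger than either tolerance.

Fit accuracy is `(D1 − D2)/D1` with `D1`/`D2` the KL divergences of the
empirical pattern distribution from the first-order and pairwise models.
KL is taken in the direction empirical‖model (natural logs); the
first-order model is closed-form, `h_i = atanh(⟨σ_i⟩)` with means clamped
to 1 − 1e-9. When `D1` is below 1e-12 the ratio is reported as undefined
rather than 0/0.

Pattern codes fix node 0 as the least-significant bit with −1 ↦ 0,
+1 ↦ 1; every exported vector indexed by pattern code uses this order.

## Landscape structure

Two patterns are adjacent iff they differ at one node (the N-hypercube).
Local minima are strict: energy below *all* N neighbours. Basins are
assigned by steepest descent — move to the neighbour with the largest
energy drop, ties broken by lowest pattern code, equal-energy neighbours
treated as non-descending. Steepest descent with a deterministic
tie-break was chosen over "first smaller neighbour found" because it is
order-independent and reproducible; patterns where two or more neighbours
tie for the steepest drop are flagged saddle-ambiguous (they sit on basin
boundaries), and state classification can drop them. Patterns with no
strictly smaller neighbour that are not strict minima (exact-tie
plateaus) remain unassigned; they cannot occur for generic real-valued
parameters.

The disconnectivity tree is built by inserting patterns in ascending
energy into a union-find structure and uniting each with its
already-inserted neighbours; when two components that each contain a
minimum unite, an internal node is recorded at the inserting pattern's
energy. This is an equivalent, O(2^N α(2^N) N) reformulation of the
textbook descending-threshold procedure (remove all patterns above a
threshold, test which minima remain connected, lower the threshold); the
test suite checks exact agreement of all pairwise merge energies against
a literal implementation of that loop.

## Brain-state dynamics

The Metropolis–Hastings walk proposes one of the N single-flip neighbours
uniformly and accepts with `min[1, exp(E(current) − E(proposed))]`;
rejected proposals repeat the current pattern and count toward dwell
time (standard MCMC semantics). Default walk: 10^5 steps, first 100
discarded, leaving 99,900 entries. Detailed balance against the Boltzmann
distribution holds analytically and is asserted pair-by-pair in the
tests.

Trajectories (simulated, or empirical binarized data classified through
the basin map) are summarized by run-length dwell times, a K×K transition
count matrix over consecutive distinct states, and indirect-path counts.
Frequencies are normalized per step of the *uncompressed* sequence so
that short empirical recordings (~10^2 timepoints) and long simulated
walks (10^5 steps) are on one scale. Subject boundaries are never
spanned: each subject's sequence is counted separately.

An indirect-path template `X|B1|…|Bk|Y` matches a segment running from an
X run to the next endpoint run (Y), whose interior decomposes exactly
into one nonempty run-group per block, in order (reversed when traversed
Y→X); both directions are counted, overlapping matches share at most
their endpoint runs, and a direct X→Y step never matches. This ordered
reading is the strictest one consistent with the bracketed notation.
A `~`-prefixed template selects the configurable unordered variant: the
interior must stay within the union of the blocks and visit every block
at least once, in any interleaving. Template strings are
pipe-delimited: `A|C,D|B`, `A|C,D|E,F|B`, `~A|C,D|E,F|B`.

## Intrinsic neural timescale

The biased (n-denominator) sample ACF is used — bounded by 1 and the
standard choice for timescale work. INT is `TR × Σ_{k=1}^{k*−1} acf(k)`
where `k*` is the first lag with `acf ≤ 0` ("hits zero" read as at-or-
below); it is 0 when `acf(1) ≤ 0`. Lag 0 is excluded by default since its
contribution is the constant 1 and only offsets every unit equally; an
`include_lag0` flag exists for sensitivity checks. Default maximum lag is
`min(T−1, 200)`. At fMRI-scale T (~175 timepoints) the estimator is
noticeably biased downward — ACF estimation noise produces early zero
crossings — which compresses between-subject differences; this is a
property of the estimator on short recordings, not of the
implementation, and the synthetic study's effect sizes were chosen with
it in mind. Spatial smoothing of voxel maps is out of scope at node
resolution.

## Group statistics

- Two-sample t: pooled variance, df = n_a + n_b − 2, Cohen's d with
  pooled SD — matching the df convention of clinical reports.
- Two-way ANOVA: the 2×2 interaction with type-II sums of squares
  (robust to unbalanced cells), partial η² = SS_int/(SS_int + SS_err).
  Factor coding (e.g. diagnosis × diagnosis for four groups) is the
  caller's choice.
- Partial correlation: Pearson correlation of OLS residuals after
  regressing both variables on the controls; p from t on df = n − k − 2.
- Multiple comparisons: Benjamini–Hochberg step-up for node/voxel-wise
  families, Bonferroni elsewhere (both via statsmodels).
- Mediation: OLS paths α (x→m), γ (total), γ′ and β (y ~ x + m); the OLS
  identity γ = γ′ + αβ is verified on every fit to 1e-10. Uncertainty by
  percentile case-resampling bootstrap (default 5000 resamples, seeded);
  percentile rather than bias-corrected intervals, as the simplest
  defensible default. The indirect effect is "significant" when the
  α×β interval excludes zero.

## Synthetic cohorts and what they establish

The generator produces the study conditions used throughout validation:
four groups × 30 subjects × 175 timepoints × 7 nodes.

Group models are Hebbian attractor models: three stored ±1 patterns give
`J = (c/N) Σ ξ_μ ξ_μᵀ`, so all groups share six local minima (the stored
patterns and their global flips) organised as three pairs — two deep
states (A, B), two shallow (C, D), two unstable (E, F). A fixed
symmetry-breaking field keeps the six energies distinct, with the same
pair structure in every group and wide gaps at the pair boundaries so the
state sets survive sampling noise in the pooled fits. Groups differ only
by overall scale (inverse temperature) and a mild weakening of one target
node: `deepened` (×1.3) has an overly stable landscape, `flattened`
(×0.5, target node ×0.85) an unstable one with frequent indirect
transitions, `mixed` (×0.8) sits between, `control` is the reference.

Per subject, binary patterns are drawn by the Metropolis–Hastings walk
recording every 4th update (one TR ≈ 4 elementary updates; with every
update recorded, 175-sample chains are so autocorrelated that pooled
group fits lose the shallowest minima and per-subject indirect-path
counts are ≈0.3, too sparse to carry any feature). Continuous signals are
pattern + AR(1) Gaussian noise (baseline φ = 0.8, SD 1/snr per node);
the AR(1)-around-±1 form is a fixture convention — no generative noise
model for rsfMRI is claimed.

Planted effects with known ground truth:

- a latent per-subject instability factor u ~ N(0,1) (truncated at ±2) in
  the `flattened` group scales the whole model by `exp(−0.6u)` and
  shortens the target node's noise timescale
  (`φ_node = clip(0.2 − 0.3u, 0.05, 0.55)`), creating a true
  local-timescale → global-dynamics chain;
- symptom scores are slope·(realized feature) + Gaussian noise, the
  feature being the subject's actual indirect-path frequency or node
  INT — so correlation analyses have exact ground truth;
- an optional pure regression chain (x, m, y) with coefficients
  (α, β, γ′) for calibrating the mediation bootstrap in isolation.

Passing tests on these cohorts establish that the pipeline recovers
effects of realistic size from data with realistic sampling noise,
temporal autocorrelation and measurement noise. They do not establish
anything about hemodynamics, preprocessing artifacts, motion, or the
adequacy of the pairwise model for real BOLD signals — the synthetic
truth *is* a pairwise model, so fit accuracy is high by construction
there, and the >97.5% figure is a property of this setting, not a claim
about any empirical dataset.

## Numerical choices and degenerate inputs

Boltzmann normalization uses log-sum-exp. Enumeration is guarded at
N ≤ 20. Constant signals raise in ACF estimation and are flagged NaN in
timescale maps (an all-constant matrix raises). Zero pooled variance,
zero residual variance, rank-deficient controls and x–m collinearity
raise ValueError; a constant ANOVA response returns an undefined-flagged
result. The pipeline excludes failing subjects with a logged reason and
aborts a group that loses half its subjects. All randomness flows from
explicit seeds; per-subject and per-group streams are split with
`numpy.random.SeedSequence.spawn`, so cohorts and full study runs are
bit-reproducible.

## Cross-group state matching

Fitted landscapes' minima are matched to a reference group's by greedy
maximum Pearson similarity between the ±1 minima patterns (falling back
to sign agreement for zero-variance patterns), reporting the similarity
of every matched pair and any unmatched minima, and the matched states
inherit the reference group's canonical letters before any cross-group
comparison. Correspondence is reported, never assumed: a group with a
missing or extra minimum keeps fresh letters for the unmatched states and
simply contributes no counts to templates that reference absent states.

## Known limitations

- Exact enumeration limits N to ~20 nodes; there is no pseudolikelihood
  or mean-field path for larger parcellations.
- The INT estimator's small-sample bias (above) makes absolute INT values
  at T ≈ 175 systematically short; between-group comparisons remain valid
  because the bias is shared.
- Greedy state matching is not guaranteed optimal for ≥7 minima (tests
  bound it against the exhaustive assignment for ≤6).
- The default study's mediation uses observed features on both sides;
  measurement error in the mediator can leak a small spurious direct
  effect (γ′), which is why the end-to-end check centres on the indirect
  path.
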