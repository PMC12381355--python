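# Methods

This note documents the statistical machinery in `swimmetab`: the models,
their assumptions, the defaults and why, the numerical choices, and what the
synthetic data do and do not establish.

## Study design the package assumes

A repeated-measures design: each participant swims three standardized
trials — moderate (below critical speed), heavy (at CS), severe (above CS)
— with a capillary plasma sample immediately before and after each trial.
Features come in three platform strata: NMR lipoprotein subfractions and
NMR small molecules (absolute concentrations) and LC–MS lipids
(semi-quantitative ion counts). Pooled-plasma QC injections interleaved
through the LC–MS sequence measure analytical precision only.

## Synthetic cohorts (`synthio`)

Abundances are generated on the natural-log scale and exponentiated, so
values are strictly positive and fold-change semantics are exact: a planted
log₂ fold-change effect `d` adds `d·ln 2` to the post-sample log abundance.
The generative model per cell is

    log x = baseline_feature + u_participant + [post] · d(class, trial)·ln2
            + ε,   ε ~ N(0, σ_trial²)

Defaults encode the study conditions: 16 participants (9 male / 7 female),
1000 features (40 FFA, 12 glycolytic, 112 lipoprotein, 836 inert),
participant-intercept SD 0.3, residual SDs (0.2, 0.2, 0.4) for
(moderate, heavy, severe) — the severe trial is noisiest within participant
— baseline log-mean 10 (≈ 2·10⁴ counts, comfortably above the 5000-count
intensity floor), 5% missing cells, 10 QC injections at 10% target RSD.
Planted effects follow the reported physiology: FFA log₂FC
(+1.0, +0.7, 0.0) across (moderate, heavy, severe); glycolytic
(+0.2, +0.8, +1.5); lipoprotein (0, +0.05, +0.1); inert 0. Males get an
additional −0.5 shift on FFA log₂FC in the severe trial only (the
sex-modulated FFA response). Within a class all features share the planted
mean — real panels have heterogeneous per-feature effects, which is why the
demonstration analysis finds many moderately-important features rather than
a few dominant ones. The true within-trial variance ratios are free
parameters of the design, not observable constraints; the defaults above
are what we consider realistic for paired exercise metabolomics and are
fixed once here.

Missingness mechanisms: `mcar` blanks exactly `round(rate · n_cells)`
uniformly chosen study cells; `low-intensity` draws the same count with
rank-based weights `exp(−3·rank/n)` favouring the lowest-abundance cells
(left-censoring). QC rows are never blanked. QC injections are i.i.d.
normal draws around the pooled study mean with CV = target RSD; no
injection-order drift is simulated because the analysis uses QCs only for
RSD filtering.

What passing tests on these data show: the pipeline recovers known planted
structure under the assumed noise model. What they do not show: robustness
to batch drift, retention-time misalignment, non-normal heavy-tailed noise,
or informative missingness beyond the simple intensity mechanism.

## QC filtering and imputation (`qcfilter`)

RSD = 100 · sd(QC values, ddof = 1)/mean(QC values), undefined (NaN) with
fewer than two QC observations or a zero mean; undefined-RSD features are
retained but reported. All three filters use strict inequalities (> 30%,
> 50% of QCs below 5000, > 70% missing), so boundary cases are kept. The
precision filters apply only to the LC–MS stratum — NMR quantities are
concentrations, not counts. Missingness is computed over study samples
only. Each rule is evaluated on the input dataset and the union removed,
which makes the filter idempotent and the report additive
(n_input = n_retained + |union of removals|).

Imputation is the iterative random-forest scheme: per platform stratum, on
natural-log abundances (multiplicative error), features initialized at
observed means and swept in increasing-missingness order, each incomplete
feature regressed on all others (scikit-learn forests, 100 trees, seeded);
iteration stops when the mean squared change of the imputed values
increases — returning the previous sweep — or after 10 sweeps. QC rows are
excluded from training and imputation, and observed cells are never
altered.

## Fold changes and scaling (`foldchange`)

log₂FC = log₂(post/pre) per participant × trial; pairs lacking exactly one
pre and one post sample are dropped with a logged warning; nonpositive
abundances are a hard error naming the sample and feature. Autoscaling
(mean 0, unit variance per column) uses the population SD (ddof = 0); the
convention is documented because R²X shifts slightly with it. Zero-variance
columns are centered, left at zero and flagged. Fitted scaling parameters
are stored so projected/held-out data are always scaled with training
parameters.

## OPLS-DA (`opls`)

For a two-class response y coded {0, 1} and centered, with autoscaled X:

1. Predictive weight `w ∝ Xᵀy`, unit norm (computed once, from the
   undeflated matrix).
2. For each orthogonal component: `t = Xw`, `p = Xᵀt/tᵀt`,
   `w_o ∝ p − (wᵀp)w` normalized, `t_o = X w_o`, `p_o = Xᵀt_o/t_oᵀt_o`,
   deflate `X ← X − t_o p_oᵀ`.
3. Final predictive component on the deflated matrix: `t = Xw`,
   `p = Xᵀt/tᵀt`, `c = yᵀt/tᵀt`.

Orthogonal scores are exactly orthogonal to the deflated column space, so
|corr(t, t_o)| < 1e−8 on training data by construction. Statistics:
R²Y = 1 − SS_res(y)/SS_tot(y); R²X(cum) = Σ_a ‖t_a p_aᵀ‖²_F / ‖X‖²_F over
all components; RMSEE = √(SS_res/(n − 1 − n_components)). VIP over the
single predictive component reduces to √p·|w_j|, so ΣVIP² = p exactly.

Numerical conventions: every weight vector is sign-fixed (largest-magnitude
element positive) because NIPALS leaves the sign undetermined — repeat fits
are bit-identical. If X carries no covariance with y at all (‖Xᵀy‖ < 1e−12,
e.g. duplicated rows across classes), the fit degenerates gracefully to a
flat weight vector and R²Y ≈ 0 instead of dividing by zero.

Cross-validation: stratified k-fold (default 8), folds dealt round-robin
after a seeded shuffle (n mod k extras land in the first folds); scaling is
refit inside each training fold; Q² = 1 − PRESS/SS_tot. Permutation test:
the class vector is shuffled and the full fit + CV pipeline rerun n_perm
times (default 50); p = (1 + #{perm ≥ observed})/n_perm, giving the
attainable floor 1/50 = 0.02. Three-class comparisons are never fit as
three-class models: the model is fit on two classes and the third projected
through the stored scaling and orthogonal filters (no refit). Class margin
for projected samples is `t·c + ȳ − 0.5` on the {0,1} coding.

Component counts default to 1 predictive + 1 orthogonal; an optional
Q²-guided auto-selection adds orthogonal components while CV Q² improves by
more than 0.01, capped at 5.

## Effect sizes (`effects`)

Cliff's delta is computed by binary search against the sorted second sample
(O((n+m) log m)); the pairwise-enumeration oracle lives in the test suite
and the two agree exhaustively on all small-vector pairs. The per-feature
p-values feeding the eruption table come from Welch's t-test on the two
groups' fold-change values (configurable to a rank-sum test); the choice is
documented rather than principled because any reasonable univariate test
serves the same screening role. BH adjustment is the standard step-up
procedure, cross-checked against statsmodels.

Key features require VIP > 3 **and BH-adjusted p < 0.05**. The adjusted p
is a deliberate design choice: VIP and the raw univariate p are computed
from essentially the same group separation, so under a global null the
feature with a chance 3σ weight concentration (VIP > 3) is exactly the
feature whose raw p is small — the raw-p conjunction flags a false key
feature in roughly a fifth of null datasets at 100–1000 features, while the
FDR-adjusted rule is calibrated (null runs are clean ≥ 95% of the time,
which the acceptance suite verifies). The plot colouring still uses
−log₁₀ of the raw p.

## Mixed models (`lmm`)

Per metabolite, on log₂ abundance:

    y = β₀ + time + trial + time×trial + sex + u_participant + ε
    u ~ N(0, σ_p²),  ε ~ N(0, σ²_trial)   (heteroscedastic form)

Treatment coding with reference levels (pre, moderate, female). Estimation
is REML: fixed effects are profiled out by GLS over per-participant blocks
and the restricted likelihood maximized over log-variances (Nelder-Mead;
log-parameterization keeps variances positive; bounds at e^±15..30 guard
degenerate zero-noise data, where β remains exact by GLS regardless).
Balanced designs use a batched Cholesky over the stacked participant
blocks. Both residual-variance forms are fitted and the lower-AIC form
kept (AIC = −2ℓ_REML + 2·(n_varparams + p_fixed); the fixed-effect design
is identical across forms, so REML AICs are comparable) — heterogeneous
level-1 variance is retained only where it improves the fit. A participant
variance collapsing below 1e−10 of the residual scale is pinned to 0 and
flagged.

Contrasts are differences in the pre→post change between trial pairs
(moderate−heavy, moderate−severe, heavy−severe), i.e. interaction contrasts
on the time×trial surface. Inference is Wald z — not Satterthwaite or
Kenward–Roger degrees of freedom; with 16 participants × 6 observations the
difference is small and the simpler method is exactly reproducible. BH is
applied within the per-metabolite family of three contrasts; FDR across
metabolites is handled separately in the eruption table. Confidence
intervals: Wald by default; the nonparametric alternative is a cluster
bootstrap resampling participants with replacement (preserving
within-participant correlation), refitting each replicate with the
full-data variance form, percentile 2.5/97.5 bounds, failed replicates
dropped (> 50% failures is an error). A second entry point fits the
per-participant log₂FC table directly (trial + sex + random intercept); on
balanced data its trial contrasts equal the full model's interaction
contrasts, and the test suite asserts that equality. A sex×trial
interaction is deliberately not in the default model (the sex-specific FFA
pattern is treated descriptively); the fold-change entry point can be
extended with it if a study is powered for that question.

## Critical speed (`critspeed`)

From 12 × 25 m maximal efforts with 5 s rests: peak speed = 25/t₁ₐₚ₁;
CS = mean speed of the slowest two efforts among the final four (ties
resolved by sorting times descending — the outcome depends only on values);
drop-off % = 100·(peak − CS)/peak, with CS > peak producing a warning and a
negative value as a pacing-quality signal rather than an error. The
speed–time model S(t) = a·e^{bt} + c is fit by Levenberg–Marquardt least
squares on lap speeds at cumulative swim-time midpoints — rests are
excluded because the model describes swimming time; a flag includes them
for sensitivity analysis. Initialization (a, b, c) = (S₁ − S₁₂, −1/t₁,
S₁₂).

D′ is defined here as the distance capacity expressed above CS during the
test:

    D′ = ∫₀^{t_u} (a·e^{bt} + c − CS) dt
       = (a/b)(e^{b·t_u} − 1) + (c − CS)·t_u,
    t_u = min(t₁, t*),  t* = ln((CS − c)/a)/b  (the CS crossing, if any)

requiring a decaying fit (b < 0). A discrete lap-wise variant
Σ max(speed − CS, 0)·lap_time is provided as a cross-check; the two agree
to within one lap's discretization on smooth profiles. The closed form is
verified against split-interval numerical quadrature to 1e−6 relative on
random parameter draws.

## Pipeline (`pipeline`)

Stage order: QC filters → imputation → per-trial pre/post OPLS-DA on
autoscaled log₂ abundances → trial-comparison OPLS-DA on log₂ fold changes
(default moderate vs severe) → projection of the held-out trial (default
heavy) → eruption table → mixed-model follow-up. Every stage's seed is
`sha256(config.seed, stage_name) mod 2³¹`, so adding a stage never perturbs
earlier stages' randomness and identical configs give checksum-identical
results bundles (provenance timing is excluded from the manifest). The
mixed-model stage defaults to following up key features only — mirroring
the workflow of univariate follow-up on the top multivariate hits — with
`lmm_scope="all"` available. CSV loading normalizes factor labels
(strip/lowercase, logged), validates levels with row locations, and
supports a column-mapping block for nonstandard headers.

## Problem sizes

The test and acceptance suites run at deliberately compact sizes chosen to
give stable statistics: cohorts of 16 participants with 20–250 features;
parameter-recovery simulations use 200 datasets (fixed-effect recovery and
CI coverage), 100 replicates (heteroscedastic model selection), 20 runs
(null calibration and permutation-floor checks); bootstrap coverage is
checked at B = 60 with 12 outer replicates, with B = 200–1000 used in the
analysis drivers. The demonstration analysis under `analysis/` uses 250
features.

## Known limitations

- One predictive component only (two-class discrimination); no multi-block
  or kernel variants.
- Welch p-values in the eruption table are a screening default, not a
  claim about the optimal univariate test; the mixed-model contrasts are
  the confirmatory analysis.
- The missForest stopping rule compares successive sweeps globally, not per
  stratum; very small strata may stop early.
- Wald inference in small samples is slightly anti-conservative relative to
  Kenward–Roger; coverage at the default design (16 × 6) measures within
  [90%, 99%] in simulation.
- The speed–time model's b is unidentifiable on constant-speed profiles
  (a ≈ 0); the fit degenerates to the plateau and D′ falls back to the
  discrete variant when the curve does not decay.
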