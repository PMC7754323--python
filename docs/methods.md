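# Methods

## Pseudo-data construction

For one study arm with reported sample size $n$, baseline mean/SD
$(\bar Y_B, s_B)$, follow-up mean/SD $(\bar Y_F, s_F)$ and baseline/follow-up
correlation $r$, the generator:

1. draws two independent $n$-vectors from a base distribution
   (standard normal by default);
2. standardises each to *sample* mean 0 and *sample* SD 1 ($n-1$
   denominator); call them $Y_1^*$, $Y_2^*$ and their sample correlation
   $r^*$;
3. regresses $Y_2^*$ on $Y_1^*$; the residuals
   $\hat\varepsilon = Y_2^* - r^* Y_1^*$ are orthogonal to $Y_1^*$ with
   sample variance $1 - r^{*2}$;
4. forms $Y_3^* = r\,Y_1^* + \hat\varepsilon\sqrt{(1-r^2)/(1-r^{*2})}$,
   which has sample SD 1 and sample correlation exactly $r$ with $Y_1^*$
   (this is the unique variance-consistent recombination);
5. returns baseline $Y_1^* s_B + \bar Y_B$ and follow-up
   $Y_3^* s_F + \bar Y_F$.

All standardisations subtract the *realised* sample mean and divide by the
realised sample SD — this, not the population parameters, is what makes the
matching exact. The $n-1$ convention is used throughout because published
SDs are computed that way; any single consistent convention would do.

Since the per-arm means, SDs and correlation are the sufficient statistics
of the ANCOVA linear mixed model, every likelihood-based quantity (fixed
effects, their covariance, variance components, the REML deviance) is a
function of the data only through these moments. Consequently the fits are
provably invariant to the generation seed and to the base distribution; a
uniform or exponential base gives different records but identical
inference, and the package exposes those options mainly so the invariance
can be demonstrated.

Degenerate base draws (sample correlation within $10^{-12}$ of $\pm 1$, or
zero variance) are redrawn up to 10 times and then raise; for $n \ge 3$ a
retry is essentially never needed. Correlations with $|r| \ge 1-10^{-9}$
are rejected at validation rather than clipped: clipping would silently
change the analysis, and the recombination step needs $|r|<1$.

Per-arm random substreams are keyed on (master seed, study id, arm label),
so adding or removing a study never perturbs the other arms' records.

## Correlation recovery

When $r$ is not reported it is recovered from the change-score SD,
$r = (s_B^2 + s_F^2 - s_{change}^2)/(2 s_B s_F)$, applied per arm, or — when
only the standard error of the between-group difference in mean change is
available — from the arm-shared inversion

$r = \dfrac{s_{BT}^2/n_T + s_{FT}^2/n_T + s_{BC}^2/n_C + s_{FC}^2/n_C - se_{diff}^2}
           {2 s_{BT} s_{FT}/n_T + 2 s_{BC} s_{FC}/n_C},$

which assumes equal correlation in the two arms and assigns the result to
both. When both routes are computable and disagree, neither is
auto-selected: both functions are public and the reader decides. Recovered
values outside $(-1, 1)$ mean the reported SDs are mutually inconsistent
and raise an error. Missing follow-up SDs are not imputed — imputation
schemes for summary data are a literature of their own and out of scope
here; absence is a hard error.

## One-stage models

The stratified-study ANCOVA regresses the follow-up value on per-study
intercepts, treatment, and per-study slopes on the study-mean-centred
baseline, with a random treatment effect ($\tau_1^2$). The random-study
variant replaces stratified intercepts/slopes with random effects
(independent covariance by default). Interaction models add the
within-trial term $(\beta_3 + b_{3i})(Y_B - \bar Y_{Bi})X$ and a single
across-trial coefficient on $\bar Y_{Bi} X$; centring on the observed study
mean and keeping the across-trial column separate is what protects
$\beta_3$ from ecological bias, and `include_across_trial=False` exposes
the biased merged estimand for comparison. For the stratified interaction
model the $(b_1, b_3)$ covariance defaults to unstructured; random-study
models default to independent random effects with the treatment indicator
centred at 0.5 inside the random-effect columns only (both defaults are
overridable via `ModelSpec`).

Residual variances follow one of four structures: free per study-arm cell,
per study, per arm, or pooled. These are nested, which the tests exploit
as a deviance inequality.

### REML on sufficient statistics

Within a (study, arm) cell every design column is affine in the baseline
value, so all Gram matrices needed for the restricted likelihood reduce to
the per-cell counts and first/second moments of (baseline, follow-up).
The engine compiles the records once into per-cell cross-products and then
evaluates the likelihood with Woodbury/Schur identities per study block —
cost independent of the number of subjects and linear in the number of
studies. Nothing ever forms an $N\times N$ covariance.

Variance parameters are optimised on a log-SD scale (Cholesky factors with
log diagonals for unstructured blocks), bounded at $e^{\pm 20}$;
a diagonal element below $10^{-10}$ on the natural scale is reported as a
boundary (zero) estimate with a flag. Optimisation runs L-BFGS-B followed
by a damped-Newton (Levenberg) polish. All gradients are exact: the
likelihood evaluation is holomorphic in the parameters, so complex-step
differentiation gives machine-precision derivatives, and the Hessian is
obtained by central differences of that gradient. Near the optimum the
objective is flat to floating-point resolution along weakly identified
directions; the polish therefore also accepts steps that shrink the exact
gradient norm, and declares convergence only on an (almost) undamped
Newton step below $10^{-8}$. This tightness is what makes the pseudo/true
and seed-invariance properties hold to $10^{-6}$ and better in practice.

### Likelihood constant and AIC

`minus2_reml` includes every normalising constant of the restricted
likelihood: $\log|V| + \log|X'V^{-1}X| + r'V^{-1}r + (n-p)\log 2\pi$. The
value of $p$ in the constant is a convention: full-rank designs (nlme,
lme4) use the rank of $X$; software with overparameterized classification
coding (SAS PROC MIXED) effectively uses the factor-expanded column count,
which is larger by the number of aliased columns (2 here: one from the
intercept/study expansion, one from the two-level treatment factor). The
package defaults to the overparameterized convention
(`ModelSpec.reml_constant="overparameterized"`) so AIC values are directly
comparable with the published SAS-based tables; `"rank"` matches nlme and
is what the dense-matrix oracle in the tests uses. The choice shifts the
deviance by a data-independent constant and affects nothing else.
`aic = minus2_reml + 2 q` with $q$ the number of variance-covariance
parameters only.

### Degrees of freedom

Between-within (default): fixed effects carrying a study-level random
component (the treatment effect; the within-trial interaction when its
random effect is present) get the between-study df $N-1$; purely
within-study effects get the residual df $n - p$. With 10 studies this
reproduces the conventional $t_{9}$ intervals. Satterthwaite: df
$= 2\,\mathrm{Var}(\hat c)^2 / (g'\Sigma g)$ with $g$ the exact gradient of
the effect variance in the variance parameters and
$\Sigma = 2H^{-1}$ from the REML Hessian. On the packaged data the
Satterthwaite df is smaller than $N-1$, i.e. those intervals are somewhat
wider — the conservative direction.

## Two-stage analysis and comparators

Stage one fits ordinary least squares ANCOVA per study (equal residual
variance within a study — the analogue of the by-study structure), with the
interaction coefficient on the study-mean-centred baseline so that it is
comparable with the one-stage estimand. Stage two pools with
inverse-variance random-effects meta-analysis. The high-level wrappers
default to iterative REML estimation of $\tau^2$ with $t_{k-1}$ intervals,
mirroring the likelihood-based pooling that makes the two-stage results
agree with the one-stage stratified fit on large trials; the
DerSimonian-Laird moment estimator is available everywhere
(`method="DL"`) and is the generic default of the low-level `pool`.

The aggregate-data comparators need no IPD: change-score meta-analysis
(effect $=$ difference in mean change, variance
$s^2_{change,T}/n_T + s^2_{change,C}/n_C$ with change-SDs derived from the
correlations), final-value and baseline mean-difference meta-analyses, and
random-effects meta-regression (weighted least squares with additive
between-study variance by a moment estimator or REML). The change-score
comparator is exactly invariant under treated-arm baseline shifts — which
is precisely why it cannot adjust for baseline imbalance, the phenomenon
the ANCOVA approach addresses. The meta-regression response defaults to
the change-score difference, with a final-value option; its slope is the
across-trial interaction analogue and is exercised in tests only through
sign and null behaviour, since it is confounded by design.

## Synthetic true-IPD generator

`simulate_ipd` draws baselines $N(\mu_i, \sigma_{Bi}^2)$ and builds
follow-ups from the generative ANCOVA with chosen coefficients,
heterogeneity variances and residual structure. Generative centring uses
the true $\mu_i$ while the fitting modules centre on observed means —
deliberate, since that is all an analyst can do. The generator emulates
normally distributed outcomes with linear baseline effects and two-arm
parallel-group designs; it does not emulate non-normal outcomes, missing
data, repeated measures, or informative arm sizes. Passing equivalence
tests therefore shows that pseudo-data inference equals true-data
inference *given the model family*, not that the ANCOVA model is correct
for any particular real dataset.

The packaged hypertension table (10 trials, 28,580 patients as printed per
arm) is the worked dataset; the imbalanced variant subtracts 5 mmHg from
the treated-arm baseline and follow-up means of trials ATMH and HEP,
20 mmHg for HDFP and MRC-1, and 10 mmHg for MRC-2, leaving every SD,
correlation, sample size and per-arm mean change untouched.

## Problem sizes and tolerances in the test suite

Moment matching is asserted at relative $10^{-8}$ (realised accuracy is
near machine precision). Seed/base-distribution invariance and
pseudo-vs-true equivalence are asserted at $10^{-6}$ on every fitted
quantity; the equivalence sweep uses 20 random scenarios of 2–5 studies
with 15–50 subjects per arm across all residual structures and both model
levels, with interaction models fitted where at least 3 studies make them
stably identifiable. Parameter recovery uses 200 replicates of a fixed
4-study scenario and a 3-standard-error Monte-Carlo band. Comparisons with
published numbers use half a unit in the last printed digit for directly
printed quantities, 0.016 for confidence limits (propagating the rounding
of the printed estimate and SE), and 0.5 for AIC.

## Known limitations

- The random-study model family matches nlme under every centring variant
  tried, but published random-study results for the worked dataset were
  produced by an unpublished SAS specification that we could not
  reconstruct; stratified-model results reproduce published values
  exactly.
- Only two timepoints per subject; no repeated-measures, network or
  cross-over extensions.
- Missing summary statistics are never imputed.
- REML only; no ML or Bayesian fitting.
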