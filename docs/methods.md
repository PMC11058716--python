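# Methods

`protgrn` analyses two-condition time-series proteomics (control vs
treatment, one abundance measurement per protein per day) to identify the
proteins and regulatory interactions a treatment targets. This note
describes the statistical models, the synthetic data that stands in for
laboratory measurements, the numerical choices, and the limitations a user
should know about.

## Study design and data model

The pipeline assumes the frame of a 21-day time course: measurements on
days 1, 2, 3, 4, 7, 8, 9, 10, 11, 14 and 21, one sample per day per
condition, on the order of two thousand proteins before filtering. Two
response phases are analysed: short-term (days 1–11, 9 time points) and
long-term (all 11 time points). Abundances are log2-transformed,
median-normalized per sample against the global median, filtered to
proteins with at most 50 % missing values, and imputed.

Two imputers mirror the two missingness mechanisms the field distinguishes:

* **KNN** (`ProteinKNNImputer`): assumes missingness at random; a missing
  cell is the average of that sample's values over the k = 10 nearest
  proteins (Euclidean distance on co-observed cells, rescaled by overlap,
  with a two-sample overlap floor and a protein-mean fallback).
* **MinProb** (`MinProbImputer`): assumes left-censoring; missing cells are
  drawn from a Gaussian centred at the sample's 1 % quantile with SD equal
  to the median protein-wise observed SD.

Imputation runs within each condition separately so no treatment signal
leaks across groups. Which imputer is "right" is not decided a priori —
the model-selection stage arbitrates, mirroring the reasoning that real
missingness mixes both mechanisms. On mechanism-matched synthetic data the
matched imputer wins in truth-RMSE (tested).

## Differential-expression screen

Per protein, log2 abundance is modelled by natural cubic regression splines
over day (3 degrees of freedom; interior knots at day quantiles, boundary
knots at the extremes — the same construction as R's `splines::ns`, verified
against it to 1e-10 in span). The two-group design has 2(1+3) = 8 columns:
intercept, group offset, shared basis, and group x basis interactions. The
group-difference columns (offset + interactions) are tested jointly with an
empirical-Bayes moderated F-statistic: residual variances are shrunk toward
a common prior estimated by moment matching on log variances (trigamma
inversion), the canonical hierarchical-model construction; our
implementation reproduces limma's `lmFit`/`eBayes` F-statistics to nine
significant digits on frozen fixtures. P-values are Benjamini–Hochberg
adjusted; the screen selects proteins at adjusted p < 0.05 and falls back to
nominal p-values when nothing passes, logging the fallback.

With one replicate per time point the residual df is n − 8 = 14 (long term);
moderation borrows strength across the protein ensemble. Under a Gaussian
null the p-values are uniform (KS-tested) and the type-I rate is ~5 %.

## Network inference

Both engine families produce a directed weight matrix over the selected
proteins (regulator x target, zero diagonal).

**Regression engines (Ridge, random forest).** Protein dynamics are modelled
as dx_i/dt = F_i(x) − α_i x_i with per-protein decay α_i. Discretizing on
the measurement grid turns each target into a regression problem with
response (x_i(t_{k+1}) − x_i(t_k))/(t_{k+1} − t_k) + α_i x_i(t_k) and the
other proteins' expressions at t_k as features, honouring the uneven day
gaps (1,1,1,3,1,1,1,1,3,7). The decay rate and the learner hyperparameter
(ridge penalty; RF `max_features`) are tuned jointly per target: ridge by
exact leave-one-out PRESS Q² (closed form via SVD, verified against explicit
refits), RF by out-of-bag R² averaged over ten seeded refits. Ties break
toward stronger regularization, then smaller decay. Importances are
|coefficients| (ridge) or mean impurity decrease averaged over ten seeded
forests (RF), normalized per target to sum to one. Regression models face an
R² gate at model selection: median per-target cross-validation R² must beat
the mean predictor (zero) in both conditions.

**Precision-matrix engine.** Time points are treated as exchangeable
samples. The chain is: per-protein Yeo–Johnson power transform (with a
D'Agostino–Pearson omnibus normality check, reported but not gating);
shrinkage covariance (1−λ)S + λ·mean(diag S)·I with λ = 0.8 by default —
heavy shrinkage is unavoidable with ~11 samples and tens of proteins;
inversion and partial-correlation scoring ρ_ij = −P_ij/√(P_ii P_jj); then a
correction step: absolute scores are z-scored row- and column-wise
(averaged) to remove per-protein expression biases, squashed into (0,1) by
the standard normal CDF (a fixed monotone map — unlike min–max rescaling it
does not couple every entry to the extremes), and each regulator's outgoing
scores are multiplied by its out-coefficient centrality from one ridge
regression per target, which breaks the symmetry of partial correlations
and yields a directed network. The exact form of this correction is a
documented interpretation, isolated in `correct_and_direct` so it can be
swapped.

## Model selection

Models are named `{Phase}-{Imputation}-{Method}` (e.g. LongTerm-KNN-Portia).
Continuous weights are compared against a known-links reference (an
undirected, STRING-like edge list) by Early Precision: the percentage of
reference links (restricted to the model's proteins) recovered among the
top-ranked links, averaged over ten equally spaced percentile cuts from the
75th to the 90th. EP is computed on unordered-pair scores (a pair's score is
the larger of its two directed weights). This choice matters: thresholding
*directed* weights at a percentile lets an asymmetric random matrix retain
about twice as many distinct pairs as a near-symmetric one, so
precision-route models would lose to random baselines mechanically,
regardless of signal. Pair-level scoring makes models and baselines
commensurable. EPR divides a model's EP by the mean EP of 1000 i.i.d.
Uniform(0,1) weight matrices; the percentile rank is the fraction of random
models scoring at least as well. A random-regulator-set control rebuilds the
network for 100 random protein subsets (size 50) and reports the DE-based
model's percentile among them (midranks for ties).

## Robustness ensembles and downstream analyses

Measurement uncertainty is modelled by perturbing the (imputed) expression
matrix with additive Gaussian noise (x* = x + N(0, σ_a), σ_a = 0.1) or
multiplicative Gaussian noise (x* = x·N(1, σ_m), σ_m = 0.05) and re-running
inference, 50 replicates per condition by default, with replicate noise
fields paired across conditions. Noise is applied after imputation, so the
ensembles isolate measurement sensitivity from imputer variance.

**Protein role analysis (Vester sensitivity analysis).** The top 75 % of
links form the impact matrix; each protein's active sum (AS, outgoing
weight) and passive sum (PS, incoming weight) place it in a role quadrant
split at the per-condition 75th percentiles: critical (both high), active,
reactive, neutral. Role changes are tested per protein with Welch t-tests on
the ensemble AS and PS distributions (per noise kind, min-p over the two
axes doubled for multiplicity); only proteins significant under both AGN and
MGN count as robust. The role-change magnitude is the Euclidean distance
between condition-mean (AS, PS) coordinates.

**Regulatory divergence analysis.** Per directed link, the treatment-minus-
control weight difference on the unperturbed networks ranks links; the top
10 % by |delta| are flagged. The Jensen–Shannon divergence between the
link's control and treatment ensemble distributions (shared
Freedman–Diaconis histogram, floor of 8 bins, epsilon smoothing, base-2
logs, squared to the divergence in [0,1]) quantifies how robustly it
diverges. A flagged link is *significant* when |delta| additionally exceeds
the pooled ensemble SD of that link — this gate is what keeps the
significant set empty under a null treatment; thresholding on rank alone
cannot (with n proteins, random top-decile flags give each protein an
expected incidence of ~0.2(n−1), so "four or more flagged links" is common
by chance). The gate is calibrated to the premise that the ensemble noise
scale is at least the data's measurement noise — the same premise that
motivates the σ values; if the data are noisier than the ensembles, the gate
loses its null protection. Proteins incident to ≥ 4 significant links are
regulatory hubs.

**Target integration.** Candidate effectors are PRA-significant proteins
plus proteins incident to significant divergent links. Principal targets
satisfy at least one of: (a) regulatory hub; (b) PRA-significant and a
divergence-network member; (c) PRA-significant critical-role transition.
Each clause is individually toggleable.

## Synthetic data

No generative model exists for the real measurements, so the package ships
generators that realize, separately, each idealization the analysis stages
assume. Passing tests on them shows the machinery is correct and calibrated
under its own assumptions — not that any real dataset satisfies them.

* **Regulatory ODE trajectories** (`simulate_timeseries`): dx_i/dt = b_i +
  Σ_j w_ji x_j − α_i x_i on the log2 scale, integrated by fixed-step RK4
  (0.05-day steps, overflow guard), with intrinsic process noise (0.3
  log2-units/√day, Euler–Maruyama increments, realization shared between
  conditions so a zero effect gives identical conditions) and multiplicative
  log-normal observation noise. Weights have uniform magnitudes on
  [0.2, 1.0] with random signs; decay rates are uniform on [0.3, 1.5]/day;
  the adjacency is rescaled when the drift matrix is unstable. Used for
  dynamical sanity checks (closed-form decay, fine-step integration oracle,
  analytic fixed points) and the DE power property.
* **Exactly discrete dynamics** (`simulate_discrete_timeseries`): the same
  model advanced by x(t_{k+1}) = x(t_k) + Δt(b + W'x − αx) + noise — the
  regression engines' exact model class, so hyperparameter (decay) and
  support recovery can be assessed without conflating discretization error.
* **Graphical-model snapshots** (`sample_ggm_expression`): i.i.d. samples
  from a Gaussian whose precision matrix is supported exactly on the
  (symmetrized) network skeleton — the idealization under which time points
  are exchangeable and conditional independence equals the regulatory
  skeleton. This is the right benchmark for the precision engine: the
  stationary distribution of a *directed* linear system does not have its
  conditional-independence graph on the adjacency, so trajectory data
  cannot test precision-route recovery even in the large-sample limit (we
  verified that pooling more trajectory samples makes recovery worse).
  Sampling maps shared standard-normal draws through the symmetric
  eigendecomposition square root of each condition's covariance; a Cholesky
  factor must not be used here, because its ordering artifact spreads a
  local covariance change across all later-indexed variables and destroys
  the localization the divergence benchmarks measure. Scale and diagonal
  are shared between conditions so a treatment perturbation changes exactly
  the precision entries it touches.
* **Study-shaped fixture** (`make_study_fixture`): 2229 protein rows on the
  11-day grid, one sample per day per condition. Expression is a hybrid:
  per-protein baseline (log2 uniform on [4, 8]) + a smooth shared day trend
  + a constant treatment level-shift of 1.0–1.8 log2 units on proteins
  incident to the condition effect (a level shift carries full DE signal
  while leaving covariance untouched) + graphical-model fluctuations (SD
  0.3) over a 150-protein regulated core (background proteins fluctuate
  independently) + 5 % multiplicative observation noise. The condition
  effect rewires ~4.5 % of core edges so the responder set lands in the
  study's 40–60 DE band. Missingness mixes MCAR dropout (6 %, tripled on
  days 8, 9 and 14) and abundance-dependent MNAR dropout (10 %, ramping up
  below the 25th abundance percentile), capped at 80 % per protein so the
  50 % filter has both survivors and casualties; pre-masking values are
  retained for imputation benchmarking.

## Numerical choices

* One root seed per run, deterministically split per stage (CRC-keyed
  `SeedSequence`); a manifest fully determines outputs, tested
  byte-for-byte.
* Ridge LOO uses the closed-form PRESS residual e_i/(1 − h_ii) with the
  intercept's 1/n leverage; Q² = 1 − PRESS/SST over pooled leave-one-out
  predictions (a per-fold R² is undefined for single left-out samples).
* Default grids: decay 8 points log-spaced on [0.1, 1.5]; ridge penalty
  10^−3..10^2 (6 points); RF max_features {0.1, 0.3, 0.5, 1.0} with 100
  trees and 10 repeats. Negative R² is allowed and reported; the selection
  gate compares against the zero (mean-predictor) line.
* Degenerate inputs: all-equal weights binarize to "keep everything"
  (logged); zero-variance score rows stay zero; constant protein columns
  pass through the power transform centred; a failed normality check warns
  but does not stop the run; identical-distribution JS is exactly 0 and the
  divergence is clipped to [0, 1] by construction.
* JS estimation uses at most 512 shared bins; ε-smoothing 1e-10.

## Benchmark scales

The verification suite runs at desk scale: recovery benchmarks use 6–12
protein networks with 25–50 seed replicates, ensembles of 10–25 replicates,
and 100–1000 random-network baselines; the study-shaped fixture is analysed
end-to-end at its full 2229-protein frame with 50-replicate ensembles.
These sizes are the package's chosen trade-off between statistical
resolution and a test suite a laptop can run.

## Known limitations

* With 11 samples per condition the precision route's EP/EPR on ~50-protein
  networks carries large seed-to-seed variance; EPR values near 1 with
  middling percentile ranks are the expected regime, and single runs can
  dip below 1.
* Marginalizing a larger regulated core down to the DE subset breaks exact
  conditional-independence correspondence (hidden-variable confounding), so
  study-scale EP understates what the engine achieves on closed small
  networks.
* When a treatment rewires many edges at once, precision estimation spreads
  the change diffusely across the inferred weights; the per-link
  significance gate then flags most top-decile links and hub lists
  saturate. These flagged links are treatment-caused but not
  edge-localized. Localized effects (the benchmark regime) are recovered
  cleanly; interpreting hub lists under broad effects requires caution.
* The dual-noise role-change gate is conservative by construction; its
  power depends on the ensemble noise scale matching the data's measurement
  noise.
* The generators are idealizations: linear regulation, Gaussian
  fluctuations, no batch effects, no peptide-level artifacts. Results on
  them bound what the pipeline can do when its assumptions hold; they are
  not evidence about any particular real dataset.
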