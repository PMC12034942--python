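# Methods

This note documents the statistical models, the estimation machinery, the
synthetic-data generator, and the numerical and design choices behind
`metfa`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

Plot yields across t trials are stacked trial-major, with plots ordered as
rows within columns inside each trial, and modeled as

y = Xτ + Z_g u_g + Z_o u_o + e,

with mutually independent Gaussian random terms:

* **G×E effects** u_g (length mt, genotype fastest within trial):
  var(u_g) = G_e ⊗ I_m. Genotypes are treated as unrelated (no pedigree);
  no separate genotype main effect is fitted — G_e absorbs the main-effect
  covariance between trials. G_e is diagonal in the combined baseline and
  factor-analytic, G_e = ΛΛ′ + diag(Ψ), in the FA models.
* **Non-genetic effects** u_o: per-trial replicate blocks, plus iid random
  column and row effects where the spatial selection retains them. Each
  sub-vector has its own variance; sub-vectors are independent.
* **Residual** e: block-diagonal over trials,
  R_j = σ²_j Σ_c(ρ_c_j) ⊗ Σ_r(ρ_r_j) with AR1 correlations
  (corr = ρ^|lag|) in either or both field directions. Missing plots are
  handled by observation selection: the correlation is evaluated at the
  true grid distances of the observed plots, never re-indexed, so holes in
  the grid do not distort neighbor relationships.

Fixed effects are an intercept plus trial main effects (aliased columns
removed by pivoted QR and reported) and, where retained, centered linear
trend covariates lcol = c − (n_c+1)/2 and lrow = r − (n_r+1)/2 per trial.
Centering keeps the intercept interpretable; the trend coefficients are in
t/ha per column (row).

## REML estimation

The residual log-likelihood is the Patterson–Thompson criterion

ℓ_R(θ) = −½[log|H| + log|X′H⁻¹X| − log|X′X| + y′Py + (n−p) log 2π],

with H = ΣZGZ′ + R and P the usual REML projection. The −log|X′X| term
normalizes ℓ_R so it is invariant under any invertible reparameterization
of X; likelihood *differences* between models sharing a fixed structure
(all REMLRTs here) are unaffected by this convention.

Updates are Newton steps using the average-information matrix
AI_ij = ½(Py)′ dH_i P dH_j (Py) on transformed parameters — log for
variances, Fisher-z (atanh) for AR1 correlations, unconstrained loadings —
with step-halving so the accepted likelihood trace is monotone. If an AI
step (with escalating ridge) fails to improve, a diagonally scaled
gradient step is tried; a fit that still has not met the tolerances after
100 iterations is polished by L-BFGS-B using the analytic score. This
gradient-based rescue plays the role usually given to EM fallbacks: it is
uniform across all variance structures and preserves monotonicity.
Convergence requires |Δℓ_R| < 1e−6 and max |score| < 1e−4 (boundary
parameters excluded).

Variances are bounded below at 1e−8 × var(y) and *pinned* when they sit at
that floor with a negative score; pinned parameters are flagged
(`at_boundary`) and excluded from the score test. A trial whose genetic
variance pins in the combined diagonal fit is reported as having no
genetic variance and excluded from the FA sequence. Heywood cases (FA
specific variances driven to zero) are handled by the same floor and flag.

BLUEs, BLUPs and prediction-error-variance (PEV) blocks come from the
converged fit: û = GZ′Py, PEV = G − G(Z′PZ)G. Design matrices for the
factor terms are never materialized: every random factor here loads each
observation on exactly one effect, so H-assembly and the Z′PZ/Z′Py
aggregations use integer code vectors, and FA derivative products use the
t×t block structure of G_e ⊗ I_m. Dense n×n algebra is used throughout —
MET models at desk scale (n up to a few hundred per dataset) never justify
sparse machinery.

### Identifiability and starting values

FA-k uses the upper-triangle rotation constraint λ_jh = 0 for j < h
(k(k−1)/2 constraints), giving tk − k(k−1)/2 free loadings + t specific
variances. FA likelihoods are multimodal: FA-1 is started from the
diagonal combined fit with a 50/50 split of each genetic variance between
common and specific parts, and FA-(h+1) from FA-h plus a new column
0.1·√(mean Ψ) with a deterministic alternating sign pattern. `reml_fit`
also exposes a seeded multi-start option (perturbed starts, best
likelihood kept, recorded in the trace) used where a single fit must reach
the global optimum (e.g. the unstructured-equivalence check). Candidate
models in the spatial sequence are warm-started from the current fit with
any *new* variance initialized near zero, so each candidate begins at
(essentially) the incumbent's likelihood and monotone ascent cannot end
below it.

### Tests

* REMLRT: statistic 2(ℓ₁−ℓ₀) clipped at zero, df = difference in variance
  parameters; statistics below −0.01 raise (a converged superset model may
  not be worse than its null). For a single variance tested at its
  boundary the reference is the ½χ²_{df−1} + ½χ²_df mixture. FA-h vs
  FA-(h+1) comparisons use the plain χ² with df = t−h (the parameter-count
  difference under the rotation constraint); the boundary mixture is not
  applied because loadings are unbounded.
* Wald: τ̂_s′V_s⁻¹τ̂_s against χ²_df for fixed sub-vectors (used for the
  global trends). No Kenward–Roger small-sample adjustment is provided.

## Spatial selection sequence

Per trial: RCB baseline (random replicate + variety, iid residual), then

1. **local** — fit ar1:id, id:ar1, ar1:ar1; keep the most complex variant
   whose every AR1 parameter is individually supported by a df-1 REMLRT at
   α, ties broken by likelihood;
2. **extraneous** — add random Column, then random Row, each kept if the
   boundary-mixture REMLRT has p ≤ α (terms on degenerate geometry, e.g. a
   single column, are skipped and logged);
3. **global** — add centered lcol and lrow, keep those with Wald p ≤ α;
4. one **re-check pass**: every retained term is re-tested in the final
   model and dropped if it loses significance (configurable off). A single
   pass, rather than an exhaustive search, mirrors the staged narrative
   and bounds runtime.

α defaults to 0.05 for both gates. Replicate and variety effects are never
candidates for removal.

## Combined model and FA sequence

The combined model concatenates the per-trial selected models: trial main
effects (+ retained trends) fixed; G×E effects with diagonal genetic
variance; retained per-trial random terms; residual ⊕_j R_j with retained
AR1 structures. The FA sequence fits FA-1…FA-k_max (k_max ≤ t−1; default 3
in the analysis scripts), warm-started order to order, recording ℓ_R,
%var = 100·tr(ΛΛ′)/tr(G_e) and the REMLRT against the previous order, and
stops early after two successive likelihood gains < 0.05. The final order
is the largest with p ≤ α; if its %var is below 65 and the next order adds
≥ 15 points, that next order can be accepted only under an explicit,
logged override flag. The trace-based %var definition is the convention of
the FA-MET literature (it yields 100% exactly when Ψ → 0); a per-trial
mean variant is available (`percent_var_by_trial`).

Cullis heritability uses A_j = mean over genotype pairs of
PEV_ii + PEV_i′i′ − 2PEV_ii′ from the trial's block of the u_g PEV. Under
the diagonal genetic model only genotypes observed in trial j enter the
average (others have no linkage); under FA every genotype linked through
G_e enters. H² is clipped to [0,1]; a trial with pinned genetic variance
returns NaN.

## Two-stage comparator

Stage one computes per-trial least-squares genotype means (cell-means
genotype coding with sum-to-zero replicate effects; arithmetic means for
complete balanced trials). Stage two: AMMI double-centers the table and
decomposes the interaction by SVD; GGE centers by environment means only.
Missing cells are refused by default — preserving the known limitation of
the two-stage path — with EM-style iterative-SVD imputation behind an
explicit flag. SVD sign ambiguity is fixed by making each axis's
largest-magnitude environment score positive.

## Correlation summaries

Genetic correlations are D^{−1/2} G_e D^{−1/2}. Trial clustering uses the
dissimilarity d = 1 − r (so r = 0.5 maps to the 0.5 cut; the (1−r)/2
variant is available), average-linkage agglomeration by default
(single/complete selectable), and a deterministic cut. The correlation
heat map uses a diverging palette anchored at r = 0.

## Synthetic-data generator

`generate_met` draws data from exactly the model above: u_g by the factor
construction (Λ⊗I)f + ξ (avoiding mt×mt matrices and matching the FA
covariance identity by construction), per-trial residuals from the
Cholesky factor of σ²Σ_c⊗Σ_r on the full grid, iid normal column/row/block
effects, and linear trends on centered indices. Replicate blocks tile the
grid as contiguous column-major bands of m plots (block geometry is not
observable in the emulated trial summaries; bands are the simplest
layout consistent with column-dominant field operations) and genotypes are
randomized within blocks. Entry subsets per trial are explicit
(`concurrence_plan`), so incomplete concurrence is simulated with exact
truth bookkeeping. Identical seeds give byte-identical CSV output.

What the generator emulates: the trial dimensions, entry counts, replicate
counts and concurrence patterns of national-variety-trial series; AR1
spatial correlation; extraneous and global column/row structure;
FA-structured between-trial genetic covariance. What it does not emulate:
non-Gaussian yields, nonlinear spatial surfaces (splines, fertility
patches), measurement-error nuggets, weather/soil covariates, or
informative missingness. Passing tests therefore demonstrate correctness
of the estimators and selection machinery under the stated model, not
robustness to real-data violations of it.

Default magnitudes in the analysis scripts and acceptance run were chosen
once to match the scale of national-variety-trial yield data (yields
~3.5–4.5 t/ha; genetic variances ~0.05–0.3; error variances ~0.1–0.3;
positive AR1 correlations ~0.3–0.6): nine 4×12 trials, 16 entries, 3
replicates, ρ_c = 0.40, extraneous column variance 0.05 in alternating
trials, a 0.08 t/ha-per-column trend in every third trial, FA-2 loadings
giving between-trial correlations from ~0.3 to ~0.9.

## Problem sizes in the test suite

Simulation-based checks are sized for a single-CPU desk run: 200
replicates for single-trial spatial parameter recovery; 500 for test
calibration; 50 per positive selection scenario and 60 null runs; 20 for
FA order recovery (t=8, m=30, 2 replicates); 20 for the three-level
variance/heritability ordering. The full suite runs in roughly a quarter
hour.

Two scenario designs deserve comment. The null-calibration trial is
20 columns × 5 rows with 5 replicates and zero block variance: the
boundary-mixture REMLRT for a variance component is conservative in
finite samples (its point mass at zero exceeds ½ when the tested factor
has few levels — the fixed-levels effect of Crainiceanu & Ruppert), and
column-band replicate blocks confound the trend contrast, so the clean
null uses many columns and no block noise. The trend-detection scenario
(slope 0.05 t/ha per column) uses a 15×8 grid with 4 replicates, σ² = 0.10
and genetic variance 0.10, chosen by an a-priori Wald power calculation
(se(slope) ≈ √(σ²_eff/Σc²) ≈ 0.01, giving power well above the 80%
retention threshold); on short 5-column grids a linear trend is nearly
confounded with AR1 correlation and random column effects and no test can
separate them reliably.

The three-level comparison scenario (error variance and heritability
across RCB → spatial → spatial + G×E) carries extraneous column/row
variation and a global column trend in every trial but no local AR1
correlation. The reason is a point about the comparison itself: under a
separable AR1 residual, σ²_j is the *marginal* variance of the correlated
process, which can legitimately exceed the iid residual variance of the
RCB fit for the same trial — retaining a true AR1 term does not promise a
smaller printed error variance, only a better model. The reduction the
comparison demonstrates comes from variance that spatial terms *remove*
from the residual (extraneous effects, trends), so the scenario is built
from those structures, with strongly correlated (r ≈ 0.9) FA-1 genetic
effects so the combined analysis has real strength to borrow.

## Known limitations

* Dense-matrix algebra bounds practical problem size to a few thousand
  plots per combined fit.
* The FA likelihood surface is multimodal; the warm-start ladder and
  seeded multi-start mitigate but cannot guarantee the global optimum.
* Wald tests are asymptotic and mildly anti-conservative in small trials;
  no Kenward–Roger adjustment is implemented.
* The spatial search is the staged sequence with one re-check pass, not an
  exhaustive model search; strongly confounded structures (trend vs AR1 on
  few columns) resolve in favor of whichever term enters first.
* Two-stage AMMI/GGE requires a complete genotype × trial table unless
  imputation is explicitly enabled.
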