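# Methods

This note records the models implemented in `turnoverlab`, the defaults
and the reasoning behind the genuinely open design choices. Everything
quantitative stated here is computed by the test suite or the acceptance
script; nothing is quoted from external data.

## Flux states

**FBA/pFBA.** Both are linear programs over `{v : S v = 0, lb ≤ v ≤ ub}`
solved with HiGHS (feasibility tolerance 1e-9). pFBA pins the growth
optimum (relative slack 1e-9) and minimizes Σ|v| with the standard
split-variable linearization. Because degenerate optimal faces admit
multiple flux vectors, an optional lexicographic pass fixes Σ|v| and then
minimizes each |v_i| in reaction-index order, making the full vector
reproducible; it costs one LP per reaction, so the environment-averaging
loop leaves it off (HiGHS is deterministic for identical inputs, and the
averaged feature only needs objective-level reproducibility). Every
returned flux vector satisfies ‖S·v‖∞ ≤ 1e-6.

**Growth environments.** A draw opens oxygen with probability ½ and, for
each element C/N/S/P, one uniformly chosen source plus k ~ Binomial(2, ½)
extra sources drawn without replacement (truncated to the candidate pool;
the binomial is drawn per element). Exchanges of biomass products are
sinks, never nutrient candidates. Carbon-containing sources get lower
bound −base/n_C with base = 60 mmol carbon·gDW⁻¹·h⁻¹ (so a hexose gets
−10, the common FBA default); non-carbon sources and oxygen are opened to
−1000, i.e. effectively unconstrained. Non-growing draws are rejected and
redrawn without counting, with a configurable attempt cap (default
10,000). The flux feature is the arithmetic mean of pFBA fluxes over the
accepted environments.

**MFA-constrained states.** Three stages: (1) least-squares projection of
measured fluxes onto the steady-state polytope (QP); (2) measured
reactions pinned at their projected values (±1e-6 to avoid numerical
infeasibility) and ATP maintenance maximized (LP); (3) ATPM additionally
pinned and ‖v‖₂ minimized (QP) — an L2 parsimony, kept deliberately
distinct from pFBA's L1. The QPs run SLSQP on an orthonormal (SVD)
reduction of the steady-state rows; redundant stoichiometric rows
otherwise make the SQP subproblems singular. The L2 objective zeroes any
futile cycle not touched by the pins.

## Thermodynamic efficiency

For a reaction with signed stoichiometry S_i over concentrations x_i (M):
Q = Π x_i^{S_i}, ΔG = RT·ln(Q/K_eq) (kJ·mol⁻¹, natural log,
R = 8.314 J·mol⁻¹·K⁻¹), and η_rev = 1 − exp(ΔG/RT) = 1 − Q/K_eq — 0 at
equilibrium, → 1 at perfect forward drive, negative when the reaction runs
in reverse of its written direction. The RT factor multiplies *both* log
terms; any formulation omitting it on one term is dimensionally
inconsistent and breaks the η_rev identity, which the tests enforce
to 1e-12.

Uncertainty handling: per condition, log-concentration and log-K_eq
vectors are sampled uniformly over their bounding boxes subject to
sign(ΔG) opposing the flux direction for every reaction with
|v| > 0.1 mmol·gDW⁻¹·h⁻¹. These constraints are linear in log space, so
the feasible set is a convex polytope; a hit-and-run walk (default 1,000
samples after 100 burn-in, started from a max-slack LP point) samples it
uniformly — the sampler choice, burn-in and counts are config-exposed
because only "convex sampling" is fixed by the method, not the algorithm.
Sampling is uniform in log space because concentrations span decades.
Unmeasured concentrations default to 1e-6–1e-1 M, a standard physiological
range. Reactions below the flux threshold are evaluated but not
constrained. η_rev is averaged over samples, then over conditions. This
feasibility-constrained box sampling is a deliberate surrogate for full
thermodynamic FBA with direction binaries, which is out of scope.

## Feature assembly

* **Generalist**: max over the reaction's genes of the number of *other*
  reactions using that gene — a single-purpose enzyme scores 0.
* **Substrate count**: distinct reactant-side metabolites for the given
  direction (negative coefficients for forward), excluding water and
  protons matched by elemental formula, not id.
* **Gene→reaction summarization**: AND (complex) nodes sum molecular
  weight and average other features; OR (isozyme) nodes average
  everything; applied recursively over the GPR tree, skipping genes
  without data. These per-feature rules are the package's own defaults and
  the most likely point of divergence from any specific published
  pipeline's per-feature table; they are centralized in one function.
* **Linearization**: flux, molecular weight, K_m, concentrations and
  turnover numbers are log₁₀-transformed (log10 everywhere outside
  thermodynamics, which uses natural log); non-positive values are masked
  missing with a warning rather than becoming −∞; assay temperature (°C)
  becomes 1/T (K⁻¹). The transform round-trips to 1e-12.

## Imputation

Chained equations with predictive mean matching: each incomplete column is
regressed on the others (current imputations as predictors), and a missing
cell receives the observed value of a donor drawn from the k = 5 nearest
neighbours in prediction space; binary columns use logistic draws,
multi-category columns multinomial draws; columns cycle until stable or 10
iterations. Four strategies — none, labelled rows only, unlabelled
(prediction) rows only, all — match the four ensemble variants. The
response column is never a predictor and never imputed, so imputation
cannot leak the output into the features; the null-response CV test
(median R² ≤ 0.05 on permuted responses) guards this end to end.

## Turnover regression

Responses are log₁₀ s⁻¹ throughout. Hyperparameters minimize mean CV RMSE
over an explicit grid (elastic net, random forest, PLS) or a 50-draw
random search (MLP); the CV protocol is 5-fold with 5 repeats (25
validation scores), one repeat for the MLP since it is the costly member.
R² is 1 − SSE/SST on each validation fold and may be negative. An optional
20% held-out split, stratified by response quantile, reports a test R²
that never feeds selection. The deep network of large-scale pipelines is
deliberately replaced by a small scikit-learn MLP with a modest random
search: at a few hundred observations the extra capacity buys nothing and
the desk-scale budget matters.

The 12-member ensemble is {elastic net, random forest, MLP} × {four
imputation strategies}. Each member records the median of its successful
training-set predictions; at prediction time an incomplete row receives
that member's median (the "within-member" reading of the fallback rule —
the alternative, a within-row median across members, is coherent too, but
per-member medians keep each member a total function and are what is
implemented). The ensemble output is the arithmetic mean of the 12 log₁₀
values, exponentiated. Linear and PLS models exist for comparison figures
but never enter the ensemble.

**Permutation importance** uses an explicitly bagged forest (scikit-learn
trees, own bootstrap bookkeeping) because per-tree out-of-bag errors are
not exposed by stock random-forest implementations: importance = mean
over trees of the OOB MSE increase after permuting the feature, divided by
the SD of that increase across trees (features whose permutation changes
nothing score ≤ 0). Significance comes from refitting the forest on
permuted responses — default 500 permutations, p = (1 + #{perm ≥ obs}) /
(1 + B) ∈ (0, 1]. With B chosen so that 0.05·(B+1) is an integer (e.g.
79), the test is exactly calibrated under the null, which the acceptance
suite checks within a binomial 3σ band over 40 null replicates.

## MOMENT

Maximize growth subject to S v = 0, bounds, per-direction enzyme coupling
v ≤ 3600·k_eff·Σ_j u_j over the GPR's DNF alternatives (each complex
alternative j gets its own usage variable; every subunit of a complex
contributes ≥ the complex usage and pays its own mass), and the budget
Σ MW_g·E_g ≤ C = 0.32 g·gDW⁻¹. The 3600 s·h⁻¹ factor converting per-second
rates to per-hour fluxes is explicit. Membrane-flagged reactions always
use the 65 s⁻¹ default (they are outside the regression's scope), and
uptake bounds of −1000 leave substrate supply effectively unconstrained so
growth is enzyme-limited — at the optimum the budget is tight (positive
shadow price) and coupling rows of flux-carrying reactions are saturated,
which is exactly why k_app,max computed from a zero-noise synthetic
proteome returns the planted rates to machine precision.

Proteome comparison: genes enter when predicted fraction > 0 and measured
abundance > 0 copies/cell; genes outside the prediction scope can be
excluded; the matched set may be intersected across parameterizations so
RMSEs are comparable; both sides are renormalized over the final matched
set (matched-set normalization — normalizing over all detected metabolic
genes is a defensible alternative; the matched-set choice makes the two
vectors sum to one over the same support). The score is the RMSE of log₁₀
mass fractions.

## Spearman correlation

rho = 1 − 6S/(n(n²−1)) for tie-free ranks (midrank Pearson otherwise,
so behaviour under ties is defined even though the intended inputs are
tie-free importance scores). Two-sided p: exact enumeration of the S null
distribution for n ≤ 9 (cached per n); for larger n an Edgeworth series
approximation of the S tail — the classical AS 89 approach — evaluated on
the (S−1)-shifted standardized statistic, with the two-sided value
2·min(upper, lower) capped at 1. The series is accurate to a few 1e-4 in
the distribution body but frays in extreme tails at small n, where only
the exact path is used anyway. Reported correlations round to 2 decimals.

## Synthetic data: what it emulates and what it does not

The toy network generator emits mass-balanced (C/N/S/P) networks with
tagged nutrient exchanges, membrane-flagged transporters, a catabolic
chain with a branch, single-gene/complex/isozyme GPRs, a shared
"generalist" gene, an optional blocked reaction, and a balanced biomass
pseudo-metabolite that is exported — so exchange validation, sampling,
summarization and MOMENT all find realistic structure. Gene molecular
weights are lognormal around 40 g·mmol⁻¹ (kDa-scale enzymes).

The planted turnover model is log-linear in the linearized features with
Gaussian log₁₀ noise. Default signs encode the expected biology: turnover
rises with flux and falls with active-site depth, solvent exposure and the
generalist property. Feature marginals are fixed, documented distributions
drawn independently, so the population R² implied by coefficients, the
realized design covariance and σ² is available in closed form; specifying
`target_r2` solves σ from the realized signal variance, making recovery
tests exact by construction. Proteomics are MOMENT solutions converted to
copies/cell (Avogadro scaling with a fixed 1e12 cells·gDW⁻¹-equivalent
constant — cosmetic, since only relative fractions matter downstream)
times lognormal noise.

What passing these tests does **not** show: real feature marginals are
correlated and heavy-tailed, real missingness is not (block-)random, real
turnover data carry cross-database and assay heterogeneity far beyond the
planted decoys, and a toy chain network has none of the redundancy of a
genome-scale reconstruction. The synthetic results validate the machinery
and its statistical calibration, not real-data performance levels.

## Problem sizes

The default test and benchmark sizes are chosen as the smallest that make
the statistics decisive: planted-R² recovery at n = 300 rows × 20 seeds;
importance calibration at 40 null replicates × 8 features with a 40-tree
forest and 79 response permutations; sampler frequencies at 10,000 draws
(binomial 3σ = 0.015); the proteome benchmark on ~20-internal-reaction
networks with 4 carbon-source conditions × 20 seeds, using
fixed-hyperparameter ensemble specs. Larger sizes sharpen nothing
qualitatively.

## Known limitations

* Unweighted Σ|v| parsimony (no molecular-weight weighting) — the common
  formulation where the variant is unspecified.
* Hit-and-run thermodynamic sampling has no formal mixing diagnostics;
  the grid-quadrature test covers low dimensions only.
* The curation conflict comparator (in-vivo-like window pH 6–8 / 25–42 °C,
  then recency, then median agreement, then record id) is a deterministic
  stand-in for what is, in real curation practice, a manual judgement.
* MOMENT here does not model expression machinery, growth-rate-dependent
  dilution, or an unmodelled-protein fraction; those belong to full
  metabolism-and-expression models, which are out of scope.
* Reverse-direction k_eff defaults to the forward value unless supplied.
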