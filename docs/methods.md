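# Methods

`treeace` implements the ACE (autocorrelation–competition–error) approach
to analysing individual-tree traits in forest genetics trials: a REML
mixed model that partitions phenotypic variation into additive genetic
effects, a positively autocorrelated site field, an explicit inter-tree
competition term (negative autocorrelation), and independent error. The
package also contains everything needed to exercise that model without
field data: a trial simulator with known truth, a canopy-height-model
(CHM) processing chain producing crown metrics, and Hegyi-type
competition indices built from those metrics.

## The model

For a trait vector **y** over the trees of a trial,

    y = Xb + Zu + e

with fixed effects **b** (overall mean, a control-vs-tested factor and,
in the default competition mode, the standardized competition covariate)
and random effects **u**. Four model families are supported:

| family | random / residual structure |
|--------|-----------------------------|
| B      | pedigree + replicate + iblock:replicate + iid residual |
| BA     | pedigree + units (nugget) + AR1×AR1 correlated residual |
| BC     | B + competition |
| BAC (ACE) | BA + competition |

The AR1×AR1 residual is the separable field with correlation
ρ_row^|Δr| · ρ_col^|Δc| between planting-grid cells, distances measured
in grid steps. Trees with missing phenotypes are dropped from **y**
while their grid cells stay in the index set, which is algebraically
identical to completing the grid with missing values (verified against a
build-full-then-delete oracle). The pedigree term uses the numerator
relationship matrix **A** from the tabular method; the simulator draws
additive values by gene dropping, so the two routes are independent.

Estimation maximises the REML log-likelihood

    -2LL = log|V| + log|X'V⁻¹X| + y'Py + (n − p) log 2π

over log-variances and atanh-correlations (|ρ| ≤ 0.999), using
Nelder–Mead followed by an L-BFGS-B refinement, one moment-based start
by default with perturbed restarts on non-convergence (`n_starts` turns
on true multi-starts). The convergence tolerance is 1e-8 on −2LL.
Standard errors come from the numerical Hessian at the optimum, mapped
back to the natural scale by the delta method; at boundary optima
(a variance estimated at ~0) the Hessian can be singular and the
affected standard errors are reported as NaN rather than fabricated.
A non-positive-definite covariance during the search returns a large
penalised value to the optimizer instead of raising.

Narrow-sense heritability is h² = σ²_A / (σ²_A + σ²_E), where σ²_E is
the iid residual for B/BC and the **units** (nugget) component for
BA/BAC; the spatially correlated component and the design variances are
excluded from the denominator. Its standard error is by the delta
method from the variance-parameter covariance.

### Competition term: fixed or random

The competition covariate (a standardized index, mean 0, unit sample SD
over the phenotyped trial trees) is fitted as a **fixed** regression by
default: a covariate with an unknown slope is the identifiable,
conventional treatment. REML log-likelihoods are only comparable across
models with identical fixed effects, so whenever the four families are
ranked by LL (the study-plan/report path and the ranking calibration
study) the term is instead fitted as a **one-column random regression**
with its own variance (`competition: random`), keeping "mean + control"
as the only fixed effects in every family. Both modes are exposed; the
reports state which was used.

### Model comparison

D = 2(LL_M − LL_B) against the base model, with p-values from the
boundary chi-square mixture (equal weights on χ²₀ … χ²_q; the familiar
50:50 mixture at q = 1). q counts the variance parameters present in
the test model but absent from the base model, treating the iid
residual and the units/nugget as the same role — so adding an AR1 term
counts its variance and both correlations (q = 3), which keeps the
test honest although correlations unidentified at the boundary still
make it somewhat anti-conservative on small grids. A negative D
is reported with a warning and p = 1. AIC = −2LL + 2t. Two BIC
conventions are available: the package default `printed` uses
−2LL + 2t·log ν (ν = n − p, natural log) and `standard` uses
−2LL + t·log ν; rankings in the reports use LL, so the choice does not
affect orderings. Percentage improvements over the base model are
Δh²% = 100(h²_M − h²_B)/h²_B and Δε% analogously on the independent
residual variance.

The study plan fits B and BA once per trait and the BC/BAC pair per
trait × competition-metric combination. `StudyPlan.runs` lists every
individual fit; `StudyPlan.n_runs` counts runs the way trial reports
conventionally tally them — one run per base fit plus one per
trait × metric evaluation — giving 280 for five traits and 54 metrics.

## The synthetic trial

The generator emulates a 2.8 ha progeny trial: 75 blocks (25 replicates
× 3 incomplete blocks) of 6×6 single-tree plots on a 3.2 m grid, 96
open-pollinated half-sib families of which 6 controls appear in every
block and the other 90 are partitioned (fresh per replicate) across the
incomplete blocks; a 50 m buffer stand at 786 stems/ha surrounds the
trial, rendered as a Poisson-thinned continuation of the lattice.
Replicates tile a near-square arrangement (5×5 of 3-block stacks by
default, a 90×30 tree grid). The mating design is configurable
(half-sib default, full-sib available) since open-pollinated families
are the norm in radiata programs.

Phenotypes follow the BAC generative model exactly: trait =
μ + control + rep + iblock + a + β_c·CI* + ξ + η, with the AR1×AR1 site
field ξ simulated exactly via its Kronecker-structured Cholesky factors
and a drawn by gene dropping on the pedigree. Mortality flags trees
dead independently (default rate 0.10, in line with an age-7 trial that
lost trees to mortality and thinning); dead trees keep their grid cell
and lose their trait values.

**Competition is single-pass and exogenous.** Baseline sizes are drawn
first — independently of the trait's own effects, as
N(baseline_mean, σ²_A + σ²_ξ + σ²_η) — the standardized CIA index of
neighbours' baselines (20-neighbour radius, buffer trees included, dead
trees excluded) is computed, and the trait is penalised by β_c per
standardized unit. Independence makes the covariate exogenous, so the
true β_c and the variance components are recoverable by the fitted
model; real ALS-derived indices are built from observed sizes and are
therefore partially endogenous — a limitation the simulator
deliberately does not reproduce, and a reason recovery results here do
not certify unbiasedness on real data. No growth dynamics are iterated.

Five traits are produced with independently drawn effects (no genetic
correlations): height H (m), diameter DBH (cm), stem volume V derived
deterministically from DBH and H via the V182 equation
V = DBH^1.79068 (H²/(H−1.4))^1.07473 e^−10.03201, Dothistroma needle
loss D38 simulated as a latent Gaussian with strong spatial
correlation, clipped to [0, 100] and rounded to 5% steps, and stress
wave velocity A (km/s). Magnitudes are set to plausible age-7 radiata
values; D38 has only spatial correlation, not an epidemic process.

The synthetic CHM renders each live tree (trial and buffer) as a
generalized cone — height profile H(1 − (d/r)^1.5), crown radius
0.22·H clipped to [0.6, 2.6] m — composited by per-cell maximum at
0.25 m resolution, with optional additive noise and random single-cell
pits. It does not simulate a point cloud, scan geometry or terrain; the
gully-driven site effects of real trials are emulated only through the
AR1 field.

## CHM processing and crown metrics

Pits are removed by grayscale morphological closing (square element,
default 3×3). Growing spaces come from marker-controlled watershed on
the inverted, Gaussian-smoothed CHM (σ = 1.5 cells by default); markers
are either known stem positions or local maxima that dominate a 1.5 m
window and stand at least 2 m tall. Every valid cell is assigned to
exactly one segment, so segment areas tile the analysis window. The
crown inside each growing space is the 4-connected component containing
the apex of cells at or above max(1.0 m, 0.3 × apex height); both
thresholds are configurable, as the delineation rule used with
operator-calibrated tools is not standardised. Detected apices are
matched one-to-one to planted stems by optimal bipartite assignment on
squared distance, gated at 1.6 m; on synthetic stands at 3.2 m spacing
the default settings detect ≥ 95% of stems.

Nine crown metrics are computed per tree: GA_P and CA_P (projected
growing-space and crown areas), CR = √(CA_P/π), A_CG = CA_P/GA_P, CL
(apex height minus mean crown-boundary height, boundary = crown cells
4-adjacent to non-crown), CV_F (volume under the crown surface to the
ground) and CV_P (to the crown base = mean boundary height), and two
triangulated surface areas: CS_T on the raw crown surface and CS_C on
the Gaussian-smoothed surface (same σ as segmentation). The
triangulation interpolates cell-corner heights from crown cells only,
so a flat crown of K cells has surface exactly K × cell-area; CS_C is
defined here as the smoothed-surface analogue of CS_T because no
standard definition distinguishes them in the literature the metric
set follows.

## Competition indices

Three distance-weighted formulations over a neighbourhood N(i):
CIA = Σ (c_j/c_i)/L_ij, CIB = Σ (c_j/c_i)/L_ij², CIC = Σ (c_j/c_i)²/L_ij.
With c = DBH and the area neighbourhood, CIA is the classic Hegyi
index. Neighbourhoods: N_A, all trees within a fixed radius — by
default r = spacing·√((k+1)/π) with k = 20, i.e. 8.273 m at 3.2 m
spacing, the radius whose circle holds on average the subject tree plus
20 neighbours on the grid; and N_B, trees whose watershed segments
share a boundary (4-adjacency default, 8 by flag; the choice is not
standardised). Dead trees are excluded from neighbour sums (their gaps
genuinely lower local competition); buffer trees compete but never
enter the standardization statistics or the model rows; empty
neighbourhoods yield CI = 0 (logged) so design matrices stay complete.
9 metrics × 3 formulations × 2 neighbourhoods = 54 index
configurations.

## Calibration studies and problem sizes

Three studies exercise the whole workflow (`treeace.harness`); their
defaults are sized for a desk machine while keeping estimator behaviour
representative:

- **Recovery** (default 20 simulations of a 24-block, 864-tree trial):
  truth σ²_A = σ²_ξ = σ²_η = 1, ρ_row = ρ_col = 0.6, β_c = −0.3, 10%
  mortality, no replicate/iblock variance (the BAC family carries no
  such terms, so including them would measure confounding, not
  recovery). Reports per-component mean bias, ±2 SE coverage pooled
  over the five variance parameters (20 draws per component is too
  granular for a per-component band), and the paired h² comparison
  against the base model. At this size mean biases are a few percent;
  at 12 blocks (432 trees) the σ²_ξ/σ²_η split is weakly identified and
  its skew alone produces ~25% apparent bias, which is why the smaller
  grid is not used for bias measurement.
- **Ranking** (10 seeds, 12-block trials): fits all four families with
  the competition term random and checks the LL order
  BAC > {BC, BA} > B.
- **Type-I** (20 replicates, 24-block trials): simulates the null
  (no spatial field, no competition, no block variance — the setting in
  which B and BA genuinely tie) and counts boundary-mixture LRT
  rejections of the AR1 term at 5%.

All three studies are Monte-Carlo experiments at 10–20 replicates:
their summary numbers (a mean bias, a rejection rate over 20 trials)
carry sampling error of their own — roughly five percentage points on a
component's mean bias and one twentieth on a rate — and will vary from
seed to seed. They characterise the workflow; they are not constants.

## Numerical and degenerate-input choices

- Variances are optimised on the log scale; exact zeros are therefore
  approached but never hit — a component estimated at ~1e-10 should be
  read as zero, and its SE as undefined.
- Duplicate coordinates are an error in neighbourhood construction
  (zero distance is undefined in every CI formulation).
- Constant inputs to `standardize` are an error, not silently zero.
- `ar1_corr` requires |ρ| < 1; the fit bounds ρ at ±0.999.
- Ties in the watershed are resolved by scikit-image's deterministic
  flooding order; identical seeds give bit-identical pipelines.

## Known limitations

- Absolute log-likelihood values are convention-dependent; only
  differences between models fitted here are meaningful.
- The simulator's trait effects are independent across traits; no
  genetic or environmental correlations, no epidemic dynamics for D38.
- Dense-matrix REML: costs grow cubically with tree count; the
  full-size 2700-tree trial is feasible for single fits but the
  280-run plan at that size is a batch job, not an interactive one.
- Crown delineation uses a simple height-threshold rule in place of
  operator calibration; segmentation quality on real CHMs with complex
  canopies will be lower than on the synthetic stands used in tests.
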