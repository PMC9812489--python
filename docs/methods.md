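# Methods

## Model

The additive genetic model is y = Xθ + Zu + e, where y is the n-vector of
(standardized) phenotypes, X the n-vector of ones carrying the single fixed
effect θ, Z the n × m matrix of standardized allele dosages, u the m-vector
of marker effects, and e ~ N(0, Iσe²). Heritability is
h² = σg²/(σg² + σe²) on the scale of the genomic relationship matrix
G = ZZ′/m.

### Genotype standardization

Raw dosages x ∈ {0,1,2} are centered by the observed column mean and scaled
by the observed column standard deviation with **divisor n** (not n−1).
This makes each column of Z have sum of squares exactly n, hence
tr(G) = n as an identity — the moment system below uses it exactly, and the
test suite asserts it to 1e−8 rather than treating it as an approximation.
Observed (training-set) allele frequencies are used, not the F2 expectation
p = 1/2; candidate individuals are always standardized with the training
means and scales, because marker effects estimated on the training scale
must be applied on that same scale. Phenotypes are standardized to mean 0
and unit variance (divisor n−1) by default; the raw mean/SD are retained so
predictions are returned on the raw phenotype scale.

## Randomized Haseman–Elston regression

Regressing the n² products y_i y_j on the relatedness entries ω_ij = z_i′z_j/m
(plus the diagonal indicator) has the normal equations

    [ tr(G²)  tr(G) ] [σ̂g²]   [ y′Gy ]
    [ tr(G)     n   ] [σ̂e²] = [ y′y  ],

solved in closed form. The only O(n²m) quantity, tr(G²), is replaced by the
Hutchinson estimator (1/S) Σ_s ‖Z(Z′w_s)‖²/m², w_s ~ N(0, I_n), which is
unbiased and needs two matrix–vector products per probe. **S defaults
to 5**; the trace-probe RNG is a named substream of the global seed so the
estimate is reproducible independently of simulation draws. y′Gy = ‖Z′y‖²/m
is computed exactly (one O(nm) pass — randomizing it would save nothing).

Method-of-moments estimates can leave the parameter space: σ̂g² is clamped
to [0, σ̂y²] and ĥ² to [0.001, 0.999], keeping the downstream ridge
λ = σ̂e²/σ̂g² finite and nonzero. A fit at the clamp boundary triggers a
warning, since the variance components are then uninformative. A design
whose randomized trace lands on tr(G²) = tr(G)²/n (G proportional to I,
e.g. unrelated individuals) makes the 2×2 system singular and raises a
degenerate-relatedness error.

## Mixed-model equations and PCG

The marker block is scaled as Z* = Z/√m with λ = σ̂e²/σ̂g². This choice
makes SNP-BLUP algebraically identical to GBLUP with G = ZZ′/m and variance
ratio σe²/σg² — the natural reading when σg² is estimated on the G scale —
and the equivalence is enforced by an oracle test (candidate predictions
agree to 1e−6) instead of being assumed. The equivalent formulation keeps
Z unscaled with ridge mλ.

The solver is the textbook preconditioned conjugate gradient with
M = diag(A): diag(X′X) = n and diag(Z*′Z*)_j = (Σ_i z_ij²)/m + λ, computed
in one vectorized column pass (n/m + λ exactly for training designs).
The coefficient matrix is applied as factored products with X and Z only;
a structural test asserts the module never assembles A, Z′Z, or ZZ′.
Numerical choices:

- start vector x₀ = 0; convergence when ‖b − Ax‖/‖b‖ ≤ 1e−8;
- the recurred residual is replaced by the true residual every 50
  iterations to guard against drift, and the final reported residual is
  always the true one;
- max_iter defaults to 10(m+1); a non-positive curvature p′Ap ≤ 0 raises a
  numerical error naming the iteration (the operator is SPD for λ > 0, so
  this only fires on misuse);
- the preconditioner can be disabled (`jacobi=False`) for measurement; on
  standardized training designs all marker diagonals are equal, so Jacobi
  matters mainly for the intercept row and for externally supplied,
  unevenly scaled designs.

## GBLUP baseline

REML is implemented as a 1-D profile restricted likelihood over h² in the
eigenbasis of G: for each h² the total variance σp² and the GLS intercept
have closed forms, and Brent's bounded method maximizes over
h² ∈ [1e−4, 1−1e−4] (xatol 1e−8). One eigendecomposition per fit — the
cubic cost the conventional method pays. A flat restricted likelihood
(G ≈ I, h² unidentifiable) or an optimum at the search boundary sets a
boundary flag. A cross-implementation test checks the profile optimum
against a generic two-parameter REML optimizer to 1e−4 in h².

Candidate prediction uses the train–candidate relationship block:
ĝ_cand = G_ct (G_t + λI)⁻¹ (y − 1θ̂) + θ̂ with G_ct = Z_cand Z_train′/m,
solved in the cached eigenbasis. The GBLUP comparisons use the REML (not
RHE) heritability.

## F2 simulator

One chromosome, m = 2,000 markers by default. Adjacent markers recombine
with constant fraction c = 0.01 per interval, applied as a first-order
Markov chain along the chromosome with no interference (at 1 cM spacing the
map distance and recombination fraction agree to first order, so 2,000
markers span the 2,000 cM chromosome; no map-function conversion is
applied). Each gamete starts from a Bernoulli(1/2) allele; each F2
individual is the dosage sum of two independent gametes, giving allele
frequency 1/2 and genotype frequencies 1:2:1 at every marker, verified by
χ² tests at n = 10,000.

Every marker is a QTL with effect β_j ~ N(0,1). Genetic values are
g = Z_cohort β on the centered/scaled cohort design, so the simulated
additive variance lives on the same G scale the estimators report and
"estimated ĥ² vs true h²" is a like-for-like comparison. The residual
variance is calibrated to the **empirical** variance of g in each replicate,
σe² = Var(g)(1−h²)/h², so the realized signal fraction matches the target
per replicate rather than only in expectation. Replicate r uses seed
base + r; gamete, effect, and noise draws come from one named stream in a
fixed order, so identical seed and configuration give bit-identical
populations.

What the simulator does **not** emulate: multiple chromosomes, minor-allele-
frequency spectra and LD patterns of natural populations, dominance or
epistasis, genotyping error or missingness, and selection. Passing tests
therefore demonstrate correctness of the estimators under the idealized F2
design, not calibration on real breeding data (real genotype/phenotype
files are supported as inputs, but no claims are tested on them).

## Evaluation protocol

Prediction accuracy is the squared Pearson correlation r² between candidate
**phenotypes** (not true genetic values) and predicted genotypic values —
the noisier but field-standard definition; the correlation against true
genetic values is emitted as a supplementary column. Summary tables report
mean ± SE across replicates with SE = SD(divisor reps−1)/√reps. At large
training sizes mean r² approaches but does not exceed h², its asymptotic
upper bound, which the suite checks at n = 2,000, h² = 0.65.

Replicated scenarios in the test suite are run at the study's population
sizes (training 1,000–2,000, 10 replicates) where those checks are the
point, and at reduced sizes (m = 300–400, training 150–1,000) for
property-style checks such as consistency and the accuracy-vs-training-size
uptrend, keeping the default suite in the minutes range.

## Known limitations

- The RHE heritability estimate is noticeably noisier than REML at S = 5
  probes (SD ≈ 0.25 at n = 600, m = 300, h² = 0.5, shrinking with n and m);
  at high true h² individual replicates can clamp at the 0.999 ceiling.
- Profile REML here is unbiased under the simulated model; published
  REML-based baselines implemented differently can sit measurably higher
  on the same design, so heritability comparisons across implementations
  should be read with that in mind.
- Only a single intercept fixed effect is supported; no covariate matrices,
  multi-trait or gene–environment extensions, and no APY-style sparse
  inverses.
- Jackknife or likelihood-based standard errors for ĥ² are not provided;
  uncertainty is reported across simulation replicates only.
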