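# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer should know
about.

## Detection

**Frequency ratio.** The descriptive ratio
ρ = ((f_A+κ)/PT_A) / ((f_B+κ)/PT_B) with κ = 10 keeps zero-count codes
finite and is symmetric under site swap (ρ → 1/ρ). κ is descriptive
only; no inferential test uses it.

**Per-code test.** "Weighted two-sample t-test adjusting for person-time
and baseline characteristics" is operationalized as weighted least
squares of the per-patient coding rate (count / person-time) on a site
indicator plus covariates (age, sex, insulin use, Elixhauser index,
person-time), with person-time weights and an HC1 sandwich variance.
Per-patient rates are zero-inflated and heavily right-skewed, so the
model-based OLS variance would be badly miscalibrated; the sandwich
variance restores nominal levels at cohort sizes of a few hundred per
site (verified empirically: all three tests reject in [0.03, 0.07] at
α = 0.05 under the null scenario with 1000 replicates, 500
patients/site). A numerically exact fit (zero residuals, e.g. a constant
column) returns p = 1 rather than a 0/0 t-statistic.

**Group tests.** The null model is a maximum-likelihood logistic
regression of the site indicator on an intercept plus covariates, fit by
IRLS to a gradient-norm tolerance of 1e-10. With r = y − μ and
D = diag(μ(1−μ)), the burden statistic for a group matrix G (per-patient
counts of member codes; flat weights w = 1 by default since the genomic
minor-allele-frequency weighting has no analog here) is S = r′Gw with
variance v = w′[G′DG − G′DX(X′DX)⁻¹X′DG]w and S²/v ~ χ²₁. SKAT uses
Q = r′GW²G′r with null distribution Σλᵢχ²₁, λ the eigenvalues of the
projected information W G′(D − DX(X′DX)⁻¹X′D)G W. Burden is powered
against common-direction shifts; SKAT against mixed directions — the
within-group substitution pattern whose group total is unchanged.

**Chi-square mixture tail.** P(Σλᵢχ²₁ > q) is computed by numerical
inversion of the characteristic function (Imhof's formula, the quantity
Davies' algorithm evaluates). The integrand oscillates with an almost
constant frequency and a polynomially decaying envelope, so generic
adaptive quadrature on [0, ∞) fails; instead the integral is evaluated
with composite 12-point Gauss–Legendre panels no wider than half an
oscillation period, truncated at a point U where (i) the phase derivative
is within 10% of its asymptote −q/2 and (ii) the next-order
integration-by-parts term is below 1e-9, with the first-order
integration-by-parts term added for the tail beyond U. Agreement with
10⁶-draw Monte Carlo mixtures is well within Monte-Carlo error across
eigenvalue shapes. When the inversion cannot resolve the tail
(p < 1e-9) the Liu–Tang–Zhang moment-matched noncentral-chi-square
approximation (kurtosis-matched variant) substitutes; at that depth only
the order of magnitude is meaningful. Liu agrees with the inversion
within ~10% relative error for p ≥ 1e-3 but can deviate by tens of
percent at p ≈ 1e-6 — a known limitation of fourth-moment matching, which
is why it is never used where the inversion succeeds.

**Federated computation.** Both the IRLS null fit and the group score
tests are linear in per-site cross-products: each Newton step needs only
the summed X′WX and X′Wz̃, and the tests need only the summed G′r, G′DG,
G′DX and X′DX evaluated at the converged coefficients. The in-process
`SiteDataHolder` exchanges exactly these aggregates (payload shapes are
recorded in an audit log) and reproduces the pooled trajectory
identically, so federated and pooled results agree to solver precision
(~1e-14 observed, 1e-8 asserted). Bonferroni correction uses the number
of tests actually performed per family; codes and groups are separate
families.

## Synthetic two-site generator

Both sites share latent clinical event processes: for each condition c
and patient i, episodes arrive as a Poisson process with rate
λ_c·exp(z_i′β_c) per person-year, where z_i collects standardized age,
centered sex and insulin indicators, and standardized Elixhauser count.
Covariate defaults (age 63 ± 10, 49% female, 21% insulin, Elixhauser mean
3.5) follow the published two-site diabetes cohort's baseline table;
person-time is uniform on (L/8, L] with study length L = 4 years.

Coding is the only cross-site difference. An episode emits the patient's
**style** code — substitutable sibling codes are assigned once per
patient, modeling provider/network coding preference, so siblings are
mutually exclusive within a patient — plus each episode-level entry
(e.g. an accompanying procedure marker) independently, all dated within
the co-emission window (30 days) of the episode date, as a clinical
encounter generates several codes together. Per-patient style choice is
what makes substitution a *between-site* phenomenon: if each episode
re-rolled the code choice, sibling codes would co-occur within patients
and their site-specific embeddings would become individually
identifiable, which real substituted codes are not. Expected endorsement
rates have closed forms (products of covariate moment-generating
functions), so scenario properties such as "the planted group's expected
ratio is exactly 1 while a member's expected ratio exceeds 2" are
asserted analytically, not by simulation.

Scenarios: `null` (identical channels; type-I-error harness; ground truth
is identity), `substitution` (one planted group mixing two site-exclusive
sibling pairs and two shared specific/unspecified pairs with swapped
preferences, plus shared per-condition markers, five null groups and two
site-B-only local codes), `granularity` (three laterality codes at one
site vs one unspecified code at the other, equal total intensity).
Ground truth is defined at **condition resolution**: a source code's
correct targets are the reference codes emitted by the same condition
within the same clinical group, weighted by reference emission intensity.
Style siblings are statistically exchangeable views of the same episodes
(distinguishable only by frequency), so a finer truth would be
unidentifiable in principle.

What the generator does **not** emulate: real marginal code frequencies
or vocabulary sizes (tens of codes, not tens of thousands), irregular
enrollment and censoring, covariate missingness (rejected at the door —
the published cohort's differential missingness is out of scope), coding
drift over time, and cross-vocabulary structure (ICD↔CPT mappings beyond
shared groups). Passing tests therefore demonstrate correctness of the
machinery and the qualitative phenomenology of coding heterogeneity, not
performance at production scale or under real-data artifacts.

## Embedding

Co-occurrence counts event pairs: C_ij is the number of pairs of events
with distinct codes i ≠ j for the same patient at most w = 30 days apart
(each unordered pair once; C_ii = 0). Event-pair counting preserves
frequency information that patient-level binary co-occurrence would
discard. The association matrix is pointwise mutual information,
PMI_ij = log[(C_ij/N)/((n_i/N)(n_j/N))] with n_i the pair participation
and N the unordered pair total; unobserved pairs stay exactly 0, and no
rows are zeroed for high-frequency codes. SPPMI (max(PMI − log s, 0)) is
available behind a flag, with `zeroed_rows` reporting how many codes a
shift silences.

Embeddings factorize the **positive-semidefinite part**: V = U_d√σ_d over
the d largest positive eigenvalues, signs fixed so each column's
largest-magnitude entry is positive. The positive-spectrum restriction is
deliberate: a symmetric PMI matrix with a structurally zero diagonal has
paired negative eigenvalues (a two-code block [[0,a],[a,0]] has spectrum
±a), and a √|σ| factorization lets those components contribute with the
wrong sign to inner products — in development this demonstrably corrupted
cosine-based mapping (systematic sibling swaps) that the PSD part
resolves. The default d = 20 truncates further to each site's positive
rank (~10 at desk scale); the two sites are then cut to their common
dimension before alignment. Keeping d well below the anchor count also
matters: an orthogonal transform has d(d−1)/2 free parameters, and when
that approaches (anchors × d) the Procrustes fit partially interpolates
anchors onto their same-named counterparts, leaking code identity into
the similarity instead of condition structure.

## Alignment and mapping

Anchors are the vocabulary intersection in lexicographic order. Rotation
alignment solves orthogonal Procrustes on unit-normalized anchor rows
(closed form via the SVD of X_A′X_B); unit normalization makes the fit
robust to scale differences between site embeddings, and orthogonality
preserves all within-site angles. Projection alignment is the ridge
regression T = (X_A′X_A + λI)⁻¹X_A′X_B (λ = 1e-6 default, for
conditioning). The reference site is never transformed.

Candidates for a source code are the reference codes of its own clinical
group; ungrouped codes are candidates only for themselves. Directional
similarity is the cosine in the common space; regression similarity is
the per-source-code ridge coefficient vector against all candidates
jointly (the per-source direction was chosen over per-target; both are
defensible). Frequency refinement multiplies by
exp(−γ|log(rate_src,i/rate_ref,j)|) on κ-smoothed rates — an exponential
kernel chosen for sign preservation, monotone damping in the rate gap,
and exact neutrality at γ = 0; default γ = 0.5, which halves similarity
per ~1.4 e-folds of rate discrepancy. Refinement is what resolves the
rate-mismatched shared pairs: sibling codes have nearly identical
co-occurrence geometry, so frequency is the only signal that can route a
dominant specific code onto the reference site's dominant unspecified
sibling (the observed SPC↔UNS swap in the worked example).

Selection is top-K (ties broken by higher reference frequency, then
code) or a global threshold chosen by cross-validation to minimize
|AUC − 0.5|, directly instantiating the domain-confusion success
criterion; the smallest tied threshold wins, and the fold split is
seeded. The harmonization operator weights selected candidates by
max(σ, 0) normalized to row sums of 1; unmapped codes carry to their
identically named reference code when it exists, else drop (both
logged). Default pipeline: RADS (rotation + directional similarity) with
γ = 0.5 refinement and top-1 selection.

## Validation

The site classifier is an L2 logistic regression (C = 1 fixed — tuning it
would confound AUC differences with hyperparameter search) on
standardized log1p counts, stratified 5-fold, with the AUC computed on
pooled out-of-fold scores and a DeLong asymptotic confidence interval
(midranks for ties). The validation universe is the reference codes whose
group contains at least one source code — the harmonizable portion of the
vocabulary, analogous to restricting to condition-related predictors;
site-exclusive ungrouped local codes would trivially identify their site
and measure nothing about mapping quality. The baseline uses the codes
endorsed at both sites over the same universe, with no mapping. Under the
null scenario both AUCs sit near 0.5 (cross-validated AUC under the null
is biased slightly *below* 0.5 at small n; the check uses 1000
patients/site).

## Study sizes used by the test suite

Chosen as the smallest sizes at which the asymptotic approximations and
Monte-Carlo bands are comfortably stable: federated-vs-pooled exactness
on 20 seeds at 150 patients/site (the equality is algebraic, so size is
immaterial); type-I calibration with 1000 replicates at 500/site;
substitution power with 100 replicates at 500/site; mapping recovery and
domain confusion on 20 seeds at 1000/site (the embedding stage is the
size-sensitive one: co-occurrence counts grow quadratically in per-code
frequency, and 1000 patients give stable condition signatures at desk
scale).

## Known limitations

- Liu's approximation degrades in the far tail (documented above); deep
  SKAT tails are reported at order-of-magnitude accuracy.
- The within-group similarity diagnostic averages group-wise then across
  groups; it is used comparatively (before vs after alignment), not as an
  absolute quantity.
- Mapping is directional (source → reference); reference codes can remain
  unmapped. Bi-directional mapping is a separate run with roles swapped.
- The generator's repeat endorsements of one emission all carry the same
  code; same-day repeat endorsements count multiply throughout (the
  alternative — counting once per day — is a documented open choice).
- Separation in the logistic null fit raises an error rather than
  falling back to penalized estimation.
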