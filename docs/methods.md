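# Methods

## The model

Within one imaging voxel, water diffusion is modeled as an ensemble of
microscopic Gaussian compartments, each described by a 3x3 symmetric
positive-semidefinite diffusion tensor D (um^2/ms).  The voxel-scale
diffusion tensor distribution (DTD) is taken to be a **constrained normal
tensor-variate distribution (CNTVD)**: the 6-vector of tensor components
d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) follows a 6-D Gaussian
N(D̄, Ω), truncated to the cone of positive-semidefinite tensors,

    p(D) ∝ exp(-1/2 (d - D̄)ᵀ Ω⁻¹ (d - D̄)) · 1[D ⪰ 0].

D̄ is the mean tensor (what DTI estimates) and Ω the fourth-order
covariance tensor stored as a symmetric 6x6 matrix whose entries are raw
component covariances; the factor of two for off-diagonal components
lives in the b-vector, b = (bxx, byy, bzz, 2bxy, 2bxz, 2byz) (ms/um^2),
so that b·d is the full double contraction.  The reported (D̄, Ω) are the
parameters of the *untruncated* Gaussian, not the moments of the
truncated law — the natural convention for a draw-then-filter sampler;
the two coincide as truncation vanishes.

The magnitude MR signal for a b-matrix B is the Laplace transform of the
DTD, evaluated by Monte Carlo with a positive-semidefiniteness filter:

    S(b) = S0 · E[exp(-b·d)] ≈ S0 · Σᵢ exp(-b·dᵢ) 1[Dᵢ ⪰ 0] / Σᵢ 1[Dᵢ ⪰ 0].

Being a mixture of decaying exponentials, S is bounded by S0 and is
monotonically non-increasing along any b-matrix ray — unlike the
second-order cumulant expansion ln(S/S0) = -b·D̄ + 1/2 bᵀΩb and the
kurtosis model (the cumulant form with Ω replaced by its fully
symmetrized part), both of which eventually grow with b.  The kurtosis
signal equation is a convention of this package: the kurtosis tensor
K = sym(C)·3/tr(D̄)² retains only the fully symmetric part of the
covariance, so the comparator isolates exactly what that symmetrization
discards.

## Sampling and the PSD filter

Proposals are d = D̄ + L z with z ~ N(0, I₆) and L an
eigenvalue-clipped symmetric square root of Ω (singular covariances are
first-class: an emulsion has rank-1 Ω).  The filter evaluates the
characteristic-polynomial invariants of the 3x3 form (trace, second
invariant, determinant), which are all non-negative exactly when the
eigenvalues are — no per-sample eigendecomposition.  Acceptance below
5% warns; below 10⁻⁴ it is an error ("mass almost entirely outside the
cone").  The CNTVD density uses the Gaussian normalizer times the
MC-estimated cone acceptance; for singular Ω it is evaluated on the
support subspace (pseudo-inverse/pseudo-determinant) behind an explicit
`allow_singular` flag, and the differential entropy of a zero-covariance
DTD is reported as -inf (a point mass).

## Experimental design

The acquisition is a compressed-sensing-style random set of rank-1 and
rank-2 b-matrices (default 216 including one exact b = 0 anchor, default
trace range 0-5 ms/um^2, 50/50 rank mix): traces uniform over the
b-range, rank-2 eigenvalue ratios uniform on (0, 1], orientations from
uniform Euler angles with randomized rotation order (a flag switches to
exactly Haar-uniform rotations).  Rank-1 measurements alone probe only
the fully symmetric 15-dimensional part of covariance space; mixing in
rank-2 spans all 21 dimensions, which `audit_design` verifies by the
rank of the quadratic design matrix.

## Covariance symmetry classes

The nested covariance submodels are the classical symmetry classes of
fourth-order tensors: isotropic (2), cubic (3), hexagonal /
transversely isotropic (5), trigonal (6/7), tetragonal (6/7),
orthorhombic (9), monoclinic (13), triclinic (21).  Rather than
transcribing elasticity tables, each class is *computed* as the
fixed-point space of its generating rotations acting on symmetric 6x6
matrices in the Mandel basis (a C_n axis with n ≥ 5 pins the same space
as the full axial group for degree-4 tensors); the dimensions are
asserted against the counts above at build time.  Two Mandel-basis facts
carry the estimator:

* classes are closed under matrix products, so each class's PSD cone is
  exactly `{A² : A symmetric, A in class}` — the fit parameterizes the
  in-class symmetric square root and PSD holds by construction;
* rotations act orthogonally, so frames rotate cleanly.

**Frame convention.** Covariance templates are defined with their
symmetry axis on template axis 1 and rotated so that axis lands on the
*principal* (largest-eigenvalue) eigenvector of the current mean tensor;
frame columns are ordered by descending eigenvalue, and the isotropic
mean class uses the identity frame.  With the minor-axis convention
instead, the exact two-point covariance of a 90-degree crossing is
tetragonal about the oblate mean's minor axis and the selector would
report tetragonal; the principal-axis convention reproduces the
orthorhombic structure reported for crossings and the hexagonal
structure for shape-heterogeneous and fiber-emulsion motifs.  Synthetic
motifs put their distinguished axis on x̂ for the same reason.

## Estimation

Stage 1 fits the four mean submodels (noise 1, isotropic 2,
prolate/oblate 5, general 7 parameters including S0) with Ω = 0; stage 2
augments the winner with each covariance class (plus the zero-covariance
baseline), refitting mean and covariance jointly — joint refitting
matters because degenerate mean eigenvalues leave frame angles that only
the covariance term identifies.  Selection uses the Gaussian BIC with
the residual variance profiled out, n·ln(rss/n) + k·ln(n), under the
parsimony rule: the model with fewest parameters wins unless a richer
model improves BIC by more than 2.

The least-squares objective evaluates the MC forward model with **common
random numbers** — one standard-normal block per fit, reused at every
iterate — making the objective deterministic and piecewise smooth; an
analytic Jacobian (treating the PSD mask as locally constant) reduces a
Jacobian evaluation to two matrix products, and scipy's trust-region
reflective solver does the minimization (ftol 1e-10, up to 3 jittered
restarts; parameters are unconstrained via log/softplus transforms).
Initialization is data-driven: a weighted log-linear DTI fit for the
mean and a low-b cumulant (quadratic log-linear) fit projected onto each
class for the covariance.

Two numerical devices make zero-noise model selection well-posed:

* **Resolution floor.**  The PSD mask is discrete: moving one sample
  across the cone boundary steps each signal by ~S0/n_accepted, so no
  fit is meaningfully better than rss ≈ n_obs·(4·S_max/n_mc)².  Fits
  below this floor tie in the BIC and parsimony decides.  (Deterministic
  zero-covariance fits floor at machine-level n_obs·(1e-6·S_max)².)
* **Nesting-consistency sweep.**  The classes form a partial order by
  group containment (isotropic ⊂ hexagonal ⊂ tetragonal ⊂ orthorhombic
  ⊂ monoclinic ⊂ triclinic, etc.).  A class comparable with the current
  best-fitting class that lags it in rss is refit from the best
  solution's projection — a superset must be able to match its subset's
  fit, and a subset inherits a good basin.  Up to two sweeps run.

When synthesis and inversion share the standard-normal block (matched
n_mc and seed — the benchmark default), the true model interpolates the
data exactly and the selected class is the most parsimonious one
containing the truth; with independent streams the residual floor is MC
resampling noise, which richer classes would otherwise overfit.

## Microstructural stains and glyphs

* `v_size` = sqrt of the mean of the upper 3x3 block of Ω — the SD of
  the mean apparent diffusion coefficient (scalar-projection identity
  with c = (1,1,1,0,0,0)/3); um^2/ms.
* `v_shape` = sqrt(Var(λ2/λ1) + Var(λ3/λ2)) over micro-tensors with
  eigenvalues sorted descending; degenerate ratios with λ2 = 0 are
  defined as 1 (shape-identical), an all-zero tensor as spherical.
* `v_orient` = min over the three eigenvector families of
  sqrt((β2+β3)/(2β1)), where β are eigenvalues of the family's mean
  dyadic; 0 for coherent, 1 for uniformly random orientations.
* `mu_fa`, entropy (-log density) and ODF entropy are PSD-filtered
  ensemble averages of per-tensor functions.

Eigenvector families are labelled by sorted eigenvalues.  Two
consequences are documented rather than hidden: (i) under exact
eigenvalue degeneracy the labels are eigensolver-arbitrary (a warning
fires), which biases `v_orient` for randomly rotated *prolates*;
(ii) for an isotropic-mean shape-heterogeneous mixture a coherent family
is impossible in principle — the family of largest eigenvalues would pin
the largest marginal mean — so `v_orient` of the prolate/oblate/sphere
triplet is not zero.  The stain-selectivity demonstration therefore uses
motifs with unambiguous families: size = isotropic emulsion, shape =
prolate aspect-ratio spread at fixed trace (`shape_mode="aspect"`, no
eigenvalue crossing), orientation = randomly rotated triaxial
(1.7, 0.4, 0.1) tensors.  The isotropic-mean triplet remains the
estimation-benchmark shape motif, and the mu-FA comparison (mu-FA
exceeds FA of the mean only under shape/orientation heterogeneity) is
made on the isotropic-mean motifs.

Sphere integrals (ODF normalization, entropies) use a Gauss-Legendre
(cos θ) x uniform-φ product grid, 48 x 96 by default — spectrally
accurate for these smooth integrands; glyph meshes use a regular 64 x
128 latitude-longitude grid triangulated and written as PLY/OBJ.
Covariance glyph radii are rᵢrⱼrₖrₗ C_ijkl = Var(rᵀDr) ≥ 0; macro/micro
ODF glyphs use the single-tensor ODF 1/(4π√|D| (rᵀD⁻¹r)^{3/2}) and its
ensemble average.

## Synthetic motifs (the study conditions)

Defaults are brain-plausible and fixed once: mean diffusivity
0.8 um^2/ms, prolate template (1.7, 0.2, 0.2) um^2/ms, coefficient of
variation 0.25 for emulsions.  The isotropic-mean shape triplet is
derived in closed form: with equal thirds and shared trace 3·md, writing
the prolate transverse eigenvalue q·md fixes the oblate at
md·(2q-1, 2-q, 2-q); q = 0.6.  The 90-degree crossing is two equal
populations of identical prolates along x̂ and ŷ (other angles generate
with a warning: they are outside CNTVD representability).  Ground-truth
parameters are the empirical moments (denominator n-1) of the motif
ensemble, and benchmark signals are synthesized *from the CNTVD those
moments define* — the motif constructions specify (D̄, Ω); the DTD
itself is the CNTVD.

What the generator does **not** emulate: restricted/time-dependent
diffusion, exchange, multiple T2 compartments, noise correlations, and
DTDs outside the CNTVD family (powder patterns, non-orthogonal
crossings).  Passing tests therefore demonstrate correct inversion of
the model's own forward problem and robustness to Rician noise, not
tissue realism.

## Noise

Gaussian noise is added on real and imaginary channels and the magnitude
taken (Rician data).  The channel SD is the mean noiseless signal over
the b-matrices in the top 5% of trace divided by the requested SNR
("SNR at the largest b-value").  Fitting is least squares on magnitudes
with a Gaussian likelihood even for Rician data; the resulting bias at
SNR ≈ 5 is accepted and visible in the benchmark's low-SNR cells.

## Problem sizes

Default fitting uses n_mc = 20,000 MC samples with a config escalation
to 200,000 for final forward simulations (the forward default).  The
test suite runs the recovery and selection studies at fit n_mc = 20,000,
SNR ∈ {∞, 10}, 2 noise replicates and 10 selection seeds per motif; the
acceptance script runs the zero-noise study at n_mc = 20,000 with 5
seeds per motif on the 216-measurement design.  The fit n_mc matters for
zero-noise selection: the mask-discretization plateau shrinks as
1/n_mc² and at 20,000 samples it falls below the BIC resolution floor,
making the parsimony tie-break effective.  At these sizes the
class-selection study is reproducible seed-for-seed and covariance
errors stay in the single-digit-percent range at SNR = ∞.

## Known limitations

* Class selection at zero noise relies on the matched-stream convention;
  with independent generation noise the BIC floor must cover the MC
  resampling level or richer classes creep in.
* Rician bias is uncorrected (by design, matching the estimation model).
* `v_orient` inherits the eigenvector-labeling ambiguity described
  above; results on DTDs with frequent eigenvalue crossings should be
  read with the emitted warning in mind.
* Single-voxel scope: no image volumes, no NIfTI output, no mixtures of
  multiple CNTVDs.
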