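# Methods

## Model

`finslermri` models the directional apparent diffusion coefficient (ADC)
profile of each voxel with a totally symmetric 4th-order tensor. For a
gradient direction y the profile is the homogeneous quartic form

    Q(y) = D_ijkl y^i y^j y^k y^l,

with 15 unique components `D_ijkl` (mm^2/s on unit vectors). The Finsler
norm is `F(y) = Q(y)^(1/4)` and the direction-dependent Finsler metric is
the half-Hessian of `F^2 = sqrt(Q)` in the direction argument,

    g_ij(y) = 1/2 * d^2 sqrt(Q) / dy_i dy_j
            = Q^(-1/2) [ 3 M(y) - 2 q(y) q(y)^T / Q ],

where `M(y)_ij = D_ijkl y^k y^l` and `q(y)_i = D_ijkl y^j y^k y^l`. g is
zero-homogeneous in y, so only the direction matters. Finsler fractional
anisotropy (FFA) is the standard FA of the eigenvalues of the mean metric,
the unweighted arithmetic average of `g` over a set of unit directions
(one representative per antipodal pair, since diffusion signals are even in
the gradient). With a single averaging direction the mean metric is the
local metric, which is what the directional FFA maps exploit.

For a Gaussian (single-tensor) voxel whose quartic is the symmetrized
square of a 3x3 SPD matrix `D2`, i.e. `Q(y) = (y^T D2 y)^2`, the metric
reduces exactly to `g = D2` for every direction and FFA reduces to the
classical FA of `D2`. This Riemannian reduction is used as an exact oracle
throughout the test suite, alongside a central-finite-difference Hessian
oracle for the general case.

## Estimation

Per voxel the 15 coefficients are estimated by linear least squares of the
quartic form against ADC samples `-ln(S/S0)/b`, through the design matrix
whose row for direction v is `mult_m * v^(a,b,c)` (the 15 monomials with
their multinomial multiplicities). An optional Tikhonov term adds an
identity (ridge) penalty `lambda * ||d||^2` on the raw coefficient vector;
no column scaling is applied. With `lambda = 0` and a full-rank design this
is ordinary least squares; a rank-deficient design then raises rather than
silently pseudo-inverting. ADC-domain fitting was chosen because it is the
standard linear approach for higher-order tensors and admits a closed-form
solve; nonlinear signal-domain fitting would change estimates only at high
noise. Signals that are nonpositive after noise are floored at `1e-6 * S0`
before the log.

Noisy fits can produce quartics that go nonpositive along some directions.
The norm floors `Q` at `clamp_epsilon * ||y||^4` (default 1e-12) before the
fourth root; map-level code floors and flags such voxels in a companion
degenerate-voxel mask, while the scalar `finsler_metric` raises, so silent
NaNs cannot propagate. FA is computed on the raw eigenvalues of the mean
metric and clipped to [0, 1]; no PSD projection is invented.

## Direction sampling

Synthetic work uses a deterministic spherical-Fibonacci lattice: 2n points
on the full sphere, upper hemisphere kept, giving exactly n antipodally
deduplicated directions (default n = 81). The same set serves as the
gradient scheme (b = 1500 s/mm^2) and as the metric-averaging set. In vivo
data use the acquisition's own b-vectors.

A structural property of the descriptor follows from this choice and is
worth stating plainly: the map `y -> g(y)` is rotation-equivariant, so for
a voxel whose profile has cubic symmetry (three orthogonal fibers of equal
weight) the average of `g` over a near-uniform direction set is forced to
be near-isotropic — the only 3x3 symmetric matrices invariant under the
octahedral group are multiples of the identity. FFA of such a voxel is
therefore close to the isotropic value, separated from it only by residual
sampling anisotropy that vanishes as the direction count grows. The test
suite and acceptance script measure this honestly; see "Limitations".

## Synthetic data

Multi-fiber voxels are equal-volume-fraction Gaussian mixtures: each of the
K fibers contributes `exp(-b g^T D_k g)/K`, with per-fiber eigenvalues
axial 1.7e-3 and radial 0.2e-3 mm^2/s (typical deep-white-matter values);
K = 0 is isotropic diffusion at their mean, 0.7e-3 mm^2/s. S0 is normalized
to 1 and kept noise-free. Rician noise adds independent N(0, sigma^2) to
real and imaginary channels and takes the magnitude; SNR = S0/sigma, with
sigma in {0, 0.01, 0.05, 0.09} covering SNR infinity to ~11. Group
ensembles apply 50 uniform random joint rotations (unit-quaternion method),
preserving crossing angles exactly.

The 2D field phantom combines a horizontal x-fiber band, a vertical y-fiber
band (each a quarter of the grid wide, crossing at the center) and a
tangential circular fiber annulus placed inside the crossing so that all
four region classes (isotropic / 1 / 2 / 3 fibers) have at least 50 voxels
at the default 64x64 grid. Its three-fiber voxels are in-plane crossings.
What the generator does not emulate: restricted/non-Gaussian compartments,
partial-volume with CSF/gray matter, spatially correlated noise, eddy/motion
artifacts — so passing tests demonstrate correctness of the estimator and
descriptor on the stated mixture model, not in vivo performance.

## Validation studies and problem sizes

- Four-group protocol: 50 rotation instances per group, 81 directions.
- Pairwise statistics: Welch two-sample t-test (the variance-equality
  assumption is not defensible across groups) and Wilcoxon signed-rank
  paired by rotation index; a degenerate all-zero difference reports p = 1
  with a flag.
- Stability: N in {50, 200, 500, 1000, 2000, 3000} directions, sigma in
  {0, 0.05}, 30 independent noise realizations of the canonical (unrotated)
  configuration per condition; relative error of the mean versus the
  N = 3000 reference, `|m(N) - m(Nref)|/|m(Nref)| * 100`, defined as 0 when
  both means are below 1e-9.
- Regularization: relative Frobenius RMSE of the 15 coefficients and of the
  mean metric against the noise-free unregularized fit of the same
  configuration at the same N (this isolates noise error from quartic model
  error), 30 realizations, lambda in {0, 0.01}.
- Classification: fixed FFA ranges one [0.70, 1.00], two [0.40, 0.70),
  three [0.20, 0.40), isotropic [0.00, 0.20), with left-closed boundaries.

These sizes keep every study comfortably within a single-CPU run while
leaving Monte-Carlo error well below the tolerances asserted.

## Numerical choices

- Monomial order and multiplicities are fixed and written into every
  coefficient dump header.
- Eigenvalues are reported in descending order; FA of an all-zero matrix
  is 0.
- GA maps the population variance V of the mean-normalized profile through
  `1 - 1/(1 + (250 V)^eps)`, `eps = 1 + 1/(1 + 5000 V)`; GFA uses the
  sample-std/rms form `sqrt(n * sum((psi - mean)^2) / ((n-1) * sum(psi^2)))`
  on the quartic ADC profile (not an ODF), so all scalars share one fitted
  model. Both are clipped to [0, 1].
- All randomness flows through numpy `SeedSequence` spawns of a single user
  seed; every dataset and study is bit-reproducible from (parameters, seed).

## Limitations

- The arithmetic-mean aggregation makes FFA of highly symmetric crossings
  (three orthogonal fibers) nearly indistinguishable from isotropic voxels
  in the noise-free limit, for the symmetry reason given above. Contrast
  between those two classes in this implementation is therefore weak, and
  statistical separation of the isotropic and three-fiber groups under
  noise is not expected. The fixed classification ranges should be read
  with this in mind.
- Because noise-induced FFA of near-isotropic voxels decays roughly like
  N^(-1/2) with the direction count, its *relative* convergence error
  between two large N values does not go to zero the way it does for
  strongly anisotropic voxels.
- No positivity-constrained fitting; strongly noisy voxels rely on the
  clamp-and-flag path.
- 6th/8th-order profiles, spherical-weighted averaging and Finsler
  tractography are out of scope.
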