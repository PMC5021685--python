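# Methods

## The conversion model

Generalized q-sampling imaging (GQI) relates the measured diffusion
signals `w` of a voxel linearly to its spin distribution function (SDF)
`Ψ`, the density of diffusing spins per orientation:

    Ψ = A · w,      A[j, i] = sinc( σ · √(6 D b_i) · ⟨b̂_i, û_j⟩ )

with `b_i` (s/mm²) and `b̂_i` the weighting and gradient direction of
volume *i*, `û_j` the ODF sampling directions, `σ` the dimensionless
length ratio setting the displacement detection radius, and `D` (mm²/s)
the free-water diffusivity. `sinc` is the unnormalized `sin(x)/x` with
`sinc(0) = 1` — **not** `numpy.sinc`'s normalized convention; the
implementation calls `np.sinc(x/π)`.

Because the relation is linear for any sampling scheme (single-shell
HARDI, multi-shell, or a DSI q-space grid), signals acquired under one
scheme can be re-expressed under another by equalizing SDFs: with `A`
built from the acquired b-table and `A_h` from the desired HARDI
b-table,

    A_h · w_h = A · w,    w_h ≥ 0,

is solved per voxel for the HARDI representation `w_h`. The ODF
sampling over-determines the system (default 321 directions versus
252–256 unknowns) and the regularized solution is

    w_h ≈ (A_hᵀ A_h + λ I)⁻¹ A_hᵀ A · w.

Strict non-negativity is available as an optional per-voxel NNLS
refinement (`scipy.optimize.nnls`); by default only the prevalence of
negative entries is reported (`positivity_fraction`), mirroring how the
method is used in practice.

### Choosing λ

`λ` is either fixed (default 0.05, the value used in the published
phantom and in-vivo conversions) or selected automatically as the
smallest value on a logarithmic grid for which more than 99% of the
converted entries inside the mask are non-negative. The default grid is
`1e-4 … 1e3` in quarter-decade steps: in the normal equations λ competes
with the diagonal of `A_hᵀA_h`, which is `O(n_odf · E[sinc²]) ≈ 50–60`
for the default 321-direction sampling, so useful regularization
strengths extend well past 1. If no grid value qualifies the grid
maximum is used and the result is flagged (`grid_exhausted`).

### What the conversion cannot do

The SDF carries no radial (b-value) information, so the conversion
cannot recover how signal is distributed between the b0 and the
diffusion-weighted volumes: converted datasets show a systematic
scale/offset bias relative to directly acquired targets, which is why
the published comparisons (and this package's evaluation) apply a
global mean-scale equalization and report correlations rather than
absolute errors. Per-direction accuracy is high for moderately
anisotropic profiles and degrades at the lowest-signal directions of
strongly anisotropic voxels, where sinc-basis ringing dominates the
tiny true signal. For the same reason an *identity* conversion (source
= target table) reproduces physical signals only up to the ridge
attenuation of the weakest basis modes: at λ=1e-8 the per-voxel
norm-relative error is ≲1e-4 on a 64-direction shell, while a
256-direction single-shell system is rank-deficient (the sinc kernel is
band-limited) and individual signal values are not identifiable at all.

### Gradient nonlinearity

When a per-voxel 3×3 gradient-deviation matrix `G` is supplied (HCP
`grad_dev` convention, 9-component row-major NIfTI), the *source* basis
is built per voxel from the effective weighting `|G b̂|² b` along
`G b̂ / |G b̂|`. The target basis stays voxel-independent: the conversion
targets an idealized scheme, whereas `G` describes distortions of the
acquired data.

### b0 handling and masking

Multiple source b0 volumes are averaged into one effective b0 column
before conversion (b < 50 s/mm² counts as b0, since scanner tables
often carry small nonzero values there). The target's b0 value is
estimated by the same linear solve through its all-ones column, with no
special casing. Voxels outside the mask are returned as zeros.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| σ (length ratio) | 1.25 | — | detection radius of the sinc kernel; larger → sharper SDF, more ringing |
| D (free-water diffusivity) | 2.5e-3 | mm²/s | sets the kernel length scale √(6Db) |
| ODF subdivision | 8 (321 hemisphere dirs) | — | icosphere subdivision; over-determines 252/256-direction targets |
| λ (fixed mode) | 0.05 | — | ridge strength of the published experiments |
| λ grid (auto mode) | 1e-4…1e3, ¼-decade | — | candidates for the 99%-positivity rule |
| positivity threshold | 0.99 | fraction | auto-selection rule |
| peak `min_separation` | 25 | degrees | greedy peak filter |
| peak `amplitude_fraction` | 0.3 | fraction of (max−floor) | peaks measured above the per-voxel ODF floor |
| b0 threshold | 50 | s/mm² | volumes below it are treated as b=0 |

σ and D are the conventional GQI reconstruction defaults (body-
temperature free water); both are exposed everywhere they matter.
Peak amplitudes are measured above the per-voxel ODF minimum because
the SDF rides on a large isotropic baseline; a threshold on raw
amplitude would filter nothing.

## ODF sampling

Directions are the hemisphere vertices of a k-fold edge-subdivided
icosahedron (full sphere `10k²+2` vertices; the icosahedron is
centrally symmetric, so vertices pair antipodally and the hemisphere
keeps `5k²+1`, canonical representative z>0 / z=0,y>0 / z=y=0,x>0).
Mesh edges define the adjacency used for peak finding, with antipodal
neighbourhoods folded onto the hemisphere. At the default k=8 the mesh
edge is ≤ 9.4°, which bounds the angular quantization of peak
directions.

## Acquisition schemes

Shell direction sets are generated by spherical-Fibonacci
initialisation followed by 120 iterations of electrostatic repulsion
with antipodal symmetry (deterministic given the seed; a seeded random
rotation decorrelates independently generated sets). The DSI generator
enumerates integer q-space lattice points with squared norm up to
`n_max = round(radius²)` — shells carry integer squared norms, so the
cutoff is the nearest integer shell — assigning `b = b_max·|q|²/n_max`;
`half_sphere` keeps one representative per antipodal pair. `radius 5`
(half sphere) reproduces the 257-gradient grid and `radius 3.6` (full
sphere) the 202-gradient grid of the published acquisitions.

## Synthetic data

The physical crossing-fiber phantom is emulated with a multi-tensor
Gaussian model: `S(b,ĝ) = S0 Σ_k f_k exp(−b ĝᵀD_k ĝ)`. Defaults: stick
eigenvalues (1.7, 0.2, 0.2)·10⁻³ mm²/s, 90° crossing, S0 = 100, free
water 2.5·10⁻³ mm²/s (matching the kernel's D so the free-water region
is exactly the kernel's reference medium). The phantom is a 32×16×1
slab holding a straight bundle along x, a crossing block, a free-water
block and empty background; the analysis ROIs are fixed by construction
at 29 voxels (straight) and 20 voxels (crossing). The brain-like
generator draws voxels with uniformly random fiber orientations, one or
two fibers (50/50, crossing angle uniform in 45–90°), and a free-water
fraction uniform in a configurable range (default 0–0.2).

Noise is Rician: `S' = √((S+n₁)² + n₂²)`, `n₁,n₂ ~ N(0, σ²)` with
`σ = S0/SNR`, optionally per voxel. Every stochastic operation takes an
explicit seed; there is no global random state.

What the generator does *not* emulate: restriction and exchange
(signals are multi-Gaussian, so there is no b-value-dependent kurtosis),
spatial correlations of noise, susceptibility/eddy distortions, fiber
dispersion, and the yarn microstructure of the physical phantom.
Passing synthetic benchmarks therefore demonstrates the correctness and
stability of the conversion pipeline, not scanner-level fidelity; on
real data the b-value-dependence of tissue contrast adds biases of the
kind the published in-vivo regressions show.

## Evaluation metrics

* **DTI fit** — log-linear least squares `ln S = ln S0 − b ĝᵀDĝ` (a
  single shared design matrix, solved for all voxels at once); voxels
  with non-positive signals are flagged invalid rather than fatal. FA
  is clipped to [0,1]; MD offers `trace` (λ̄) and `axial_radial_mean`
  ((λ₁+(λ₂+λ₃)/2)/2) modes, defaulting to `trace`.
* **GFA** — `√(n Σ(Ψj−Ψ̄)² / ((n−1) ΣΨj²))` on the SDF samples.
* **SNR** — mean b0 over σ, with σ either known (simulations) or
  estimated from a background region via the Rayleigh mean
  `E|bg| = σ√(π/2)`.
* **Peaks / angular error** — mesh-adjacency local maxima, floor-
  subtracted amplitude threshold, greedy 25° separation; the angular
  error is `arccos|⟨p_a,p_b⟩|` between primary peaks (antipodally
  invariant), aggregated as mean with quartiles, stratified by SNR
  (default edge at 5).
* **Regression** — OLS slope/intercept and Pearson r
  (`scipy.stats.linregress`).

Peak extraction for the benchmark studies operates on GQI SDFs of both
datasets. The published angular-error analysis used spherical-
deconvolution fODFs from an external tool; spherical deconvolution is
out of scope here, so the SDF-peak analog is the self-contained
substitute and its errors are, as expected for clean synthetic
geometry, below the in-vivo figure.

## Benchmark studies (`qconvert.experiments`)

Problem sizes were chosen to run on a laptop-class single core in
seconds: the phantom studies use the full 257-volume HARDI / 95-volume
multi-shell / 258-volume DSI schemes on the 151-voxel phantom mask, and
the brain-like studies use 2000 voxels. All four studies derive their
sub-seeds from one integer seed.

## Known limitations

* The conversion is one-way; nothing here attempts HARDI → multi-shell.
* λ auto-selection solves the full grid once per dataset; for very
  large volumes a subsampled mask would be the natural optimization.
* Per-voxel gradient-deviation correction rebuilds the source basis
  voxel by voxel (a Python loop); adequate at desk scale, the obvious
  target for vectorization on full brains.
* The NNLS refinement calls `scipy.optimize.nnls` per voxel and is
  correspondingly slower than the ridge path.
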