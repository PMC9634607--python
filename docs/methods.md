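# Methods

## Model

A limited-resolution map is the true model density convolved with the
point-atom image δᵈ(r; D) = (4π/3)D⁻³ G(r/D), where G is the 3D interference
function — the inverse Fourier transform of the indicator of the reciprocal
ball |s| ≤ 1/D (s = 1/d, in Å⁻¹). Isotropic positional disorder is a second
convolution, with the normalized Gaussian g(r; B). All closed forms use the
crystallographic convention

    g(r; B) = (4π/B)^{3/2} exp(−4π² r²/B)  ⇔  ĝ(s) = exp(−B s²/4),

so that B is the standard PDB B-factor (Å²), blurring parameters add under
convolution, and the multi-Gaussian scattering coefficients bₖ sit on the
same scale. The source equations do not fix a convention; this one is pinned
in tests by the requirement that the forward transform of g equal
exp(−B s²/4) and that the point-atom image match a 3D FFT of the reciprocal
ball indicator.

The interference function has no closed-form convolution with a Gaussian, so
it is approximated by a shell decomposition G(x) ≈ Σ κₘ Ω(x; μₘ, νₘ), where
Ω(x; μ, ν) is the unit-mass uniform distribution on a sphere of radius μ
convolved with g(·; ν):

    Ω(x; μ, ν) = (4π/ν)^{3/2} exp(−4π²(x²+μ²)/ν) · sinh(t)/t,   t = 8π²μx/ν.

Ω is evaluated by this product form for t ≤ 30 (with the series of sinh(t)/t
below t = 10⁻⁶, so the origin and the μ → 0 Gaussian limit are exact) and as
the explicit difference of two exponentials for larger t, where sinh would
overflow; both branches are exact rearrangements of the same formula.
Normalization (∫Ω d³x = 1), the transfer identity Ω(·;μ,ν) ∗ g(·;B) =
Ω(·;μ,ν+B) and the rescaling rule D⁻³ Ω(r/D; μ, ν) = Ω(r; μD, νD²) are
verified against radial-quadrature and FFT oracles in the tests.

Everything downstream is bookkeeping: decompositions of G are stored
dimensionless and converted to physical units only when rescaled to a
resolution D (μ → μD, ν → νD², κ → κ·4π/3); an atom's map contribution is
the double sum over its scattering Gaussians (aₖ, bₖ) and the shell terms,
with ν → νD² + bₖ + B.

## Fitting shell decompositions

The fit minimizes the residual between a target radial profile (G, or a
numerically computed atomic image) and Σ κₘ Ω(r; μₘ, νₘ) on a uniform grid:

* **Seeding.** Term 1 is pinned to μ = 0 (the central peak); when M ≥ 3 a
  second, low-weight term is placed inside the central peak; the remaining
  terms sit on successive ripple extrema, with ν from each extremum's
  half-width and κ from its signed amplitude. If a target shows fewer ripples
  than requested terms (the 12-term carbon fit over r ≤ 8 Å has ~8 visible
  extrema), extra terms are inserted at the widest gaps between placed
  shells; a ripple-free profile can seed at most two terms.
* **Optimizer.** Bound-constrained trust-region least squares
  (`scipy.optimize.least_squares`, ν ≥ 10⁻³, μ ≥ 0) with analytic partial
  derivatives of Ω, plus seeded random restarts. A Lawson-style reweighting
  loop (12 rounds, weights ∝ sqrt of the running residual) then pulls the
  least-squares solution toward the equal-ripple minimax optimum, since the
  quoted accuracy metric is max |residual| relative to the target's origin
  value. Fits are deterministic given the config (all restart noise derives
  from the config seed).
* **Tail anchoring.** The fit grid extends a `tail_fraction` beyond the
  domain (default 0.3). This matters when a fitted image decomposition is
  later ν-shifted by B: blurring pulls values from past the domain boundary
  back inside it, so an unconstrained tail would contaminate the blurred
  image. With a 30% tail the B = 30 Å² carbon transfer deviates by ~10⁻⁷ of
  the central value; with 10% it degrades by three orders of magnitude. Fits
  of the dimensionless G itself (never ν-shifted directly) use 0.1, which is
  three times faster at identical accuracy.
* **Uniform weighting.** Residuals are equally weighted in r (not by shell
  volume 4πr²); the accuracy metric of record is the unweighted maximum.
* **Nested M-sweeps.** `nested_fits` produces fits with growing M by warm
  starting each fit from the previous solution plus one term seeded at the
  largest remaining residual, so the achieved residual is non-increasing in
  M by construction (a plain independent fit per M occasionally lands in a
  worse local minimum).

Measured accuracies (recomputed by the tests and `scripts/acceptance.py`):
M = 21 on G over [0, 10]: 6×10⁻⁵ of G(0); M = 12 on the immobile carbon
image at D = 2 Å over r ≤ 8 Å: 2.3×10⁻⁵ of the central value; M = 7 over
r ≤ 4 Å: 1.6×10⁻⁵. A reference 21-term table (coefficients rounded to three
decimals, residual ≈ 2.4×10⁻⁴) ships with the package.

## Scattering factors and the image oracle

Packaged coefficients (in-repo CSV): Peng 5-Gaussian elastic electron
scattering factors (default) and International Tables 4-Gaussian + constant
X-ray factors, for H, C, N, O, P, S. The X-ray constant term is folded in as
a Gaussian with b = 0.01 Å² to stay within the Gaussian formalism — an
approximation, adequate at the resolutions considered. The accuracy figures
quoted above measure decomposition fidelity, not the table; they are
insensitive to which published table is used.

The reference for every image-level claim is `numeric_atom_image`: the
truncated radial Fourier synthesis 4π ∫₀^{1/D} s² f(s) e^{−Bs²/4}
sinc(2πsr) ds, computed by Gauss–Legendre quadrature with node doubling
until successive evaluations agree to 10⁻⁹ of the central value. The
integrand is entire, so Gauss–Legendre converges geometrically; node counts
start at ~16 oscillations per r_max/D and at most six doublings are allowed.

## The map engine

The closed-form map is evaluated on an orthorhombic P1 grid (values at voxel
corners, origin at the cell origin) in a single pass. Every atomic image is
spherically symmetric, so atoms sharing (element, D, B) are evaluated once
on a dense radial grid (step 0.005 Å) and mapped onto voxels through a cubic
spline — the interpolation error (~10⁻⁹ of the peak) is orders below the
decomposition error. Each atom is truncated at max over terms of
μ + cutoff_sigma·sqrt(ν/8π²) (default cutoff_sigma = 5, changing the map by
< 10⁻⁵ of its peak versus larger cutoffs) and summed over every periodic
image whose truncation sphere intersects the box. Grid spacing coarser than
min(Dₙ)/2 is a hard error (aliasing); coarser than min(Dₙ)/3 warns.
Accumulation is plain float64; with ≤ a few hundred atoms per voxel the
summation-order effects sit at ~10⁻¹⁵ relative, far below every stated
tolerance. Occupancy scales an atom's whole contribution.

The Fourier reference computes F(h) = Σ occₙ fₙ(s) e^{−Bₙs²/4} e^{2πi h·xₙ}
by direct summation over all lattice points with |s| ≤ 1/D (strict,
inclusive: boundary reflexes carry full weight, which is also what the
continuous-convolution model implies), then inverse-FFTs onto the grid. The
reference is never computed as the FFT of a sampled density, so it carries
no sampling bias of its own. Parseval consistency and the shift theorem are
tested.

## What map-level agreement does and does not show

In a periodic cell the Fourier map contains ripples from *all* periodic
images of every atom — a slowly decaying, conditionally convergent ripple
field that persists far from the molecule. A decomposition fitted over
|x| ≤ 10 truncates every atomic image at r = 10·D, so voxels further than
that from the nearest atoms (box corners, or points equidistant from many
atoms where distant ripples add coherently) keep a genuine discrepancy of
order 1% of the map peak that no amount of fit accuracy removes; extending
the fit domain pushes the boundary out but the far field converges only
slowly. Within the molecular region the agreement is at the propagated
fit-error level. The shipped tests therefore assert, on a 100-atom toy body
at D = 2 Å: correlation > 0.998 and global max discrepancy < 2.5% of peak
for the 21-term fit; a strictly monotone decrease of the max discrepancy as
M grows 1 → 6 (nested fits); and, for a model with two separated groups at
D = 2 and 5 Å, per-region agreement with the matching constant-D Fourier map
to < 5% of the local peak while the wrong-D map disagrees by more than ten
times that.

## Synthetic test bodies

No structures are downloaded. The canonical body is the `helix` preset: a
solenoid of backbone-like N/C/C/O atoms with ~1.5 Å bonded spacing, wound
compactly (minor radius 2.3 Å on a major circle sized to the chain length)
inside the box, with B drawn uniformly from [5, 60] Å² — a realistic
macromolecular range. A `blob` preset gives random packings with ≥ 0.8 Å
separation. These models have protein-like geometry and scattering but no
stereochemistry, no solvent, no experimental noise and no dataset
incompleteness, so passing tests demonstrate the mathematics of the map
model, not agreement with real micrographs. Per-atom resolutions for the
inhomogeneous demo vary linearly with distance from the center of geometry
between the stated center and edge values (2 → 5 Å).

## Numerical choices and edge cases

* G uses its Taylor expansion for 2πx < 10⁻³ (G(0) = 1 exactly).
* Quadrature oracle tolerance: 10⁻⁹ of the central value.
* Fit grid step defaults to domain/500; the reference fits use 0.002 (G)
  and 0.004 Å (carbon), with residuals always re-measured on a grid twice
  as fine.
* Degenerate inputs rejected with explicit errors: negative radii, ν ≤ 0,
  B < 0 (de-blurring), D ≤ 0, non-orthorhombic or non-P1 cells, grids that
  alias, sidecars with duplicate ids.
* Map I/O is CCP4/MRC mode 2 via gemmi; coefficient JSON round-trips at full
  float precision.

## Known limitations

Isotropic B only (no anisotropic displacement or scattering); orthorhombic
P1 cells only; no bulk solvent; no dataset-incompleteness modeling; the
inverse problem — refining Dₙ, Bₙ, rₙ against an experimental map — and
analytic score-function gradients are out of scope. The X-ray constant-term
fold-in (b = 0.01 Å²) is an approximation. Global Ω-map/Fourier-map
agreement in periodic cells is limited by the decomposition domain, as
described above.
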