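# Methods

## Model

A monolayer domain of ordered (L_C) phase in a disordered (L_E) matrix
carries two competing energies: the boundary line tension λ
(energy/length) and the dipolar self-energy of the excess
surface-normal dipole density μ (so μ² also has units of
energy/length).  Everything observable about equilibrium shape depends
only on the dimensionless ratio λ/μ² (the inverse Bond number) and a
molecular cutoff δ below which the continuum dipole integral is
regularised; δ defaults to 1 nm throughout.

Internal lengths are nanometres.  The image layer speaks micrometres
(and μm/px); conversions happen only at those boundaries.  Energies
are reported in units of μ² unless the user supplies absolute λ and μ²
in `BondParameters`, in which case a consistency check (relative
1e-12) ties the pair to the ratio.

### Circular domains

F/N = (2a₀/r)[λ − μ² ln(4r/(e²δ))].  Setting ∂(F/N)/∂r = 0 gives
r₀ = (e³δ/4)exp(λ/μ²) exactly; the argument of the logarithm is fixed
by requiring precisely this (the two renderings "2.714"/"2.718" of the
exponential constant in common sources are both read as the true e).
The stability window (r₀/e, e^{1/3}r₀) brackets r₀ with the
parameter-free ratio e^{4/3}.

### Rectangle free energy and the width equation

For a rectangle of sides w ≤ l, area A = lw, h = √(w²+l²):

F/(2μ²) = [c + ln(e²δ/A) + ln(w+h)]w + [c + ln(e²δ/A) + ln(l+h)]l − 2h,

with c = λ/μ².  The constant ln(e²δ/A) is the unique choice for which
the analytic w-derivative at fixed A reproduces the width equation

R(w,A) = A ln((A+S)/(Aw)) − w² ln((w²+S)/(Aw)) + (A−w²) ln(δe^{1+c}),
S = √(A²+w⁴),

via d(F/2μ²)/dw = −R/w² (derived by hand; asserted numerically by
central differences in the test suite).  The width equation, not the
energy expression, is treated as the authoritative statement of the
model, because it is independently verifiable: R vanishes identically
on the square locus w² = A, and its large-A root is the limiting
width below.

### Branch structure and constants

Scaling by the critical width w_c = δ(1+√2)e^{√2+c} collapses R to a
parameter-free equation in w̄ = w/w_c, Ā = A/w_c², whose third term is
−(Ā−w̄²)ln((1+√2)e^{√2−1}); the sign follows from scaling R directly
(the printed sign in some renderings is ambiguous; this choice is the
one consistent with the derivative check above).  Three constants tie
the reconstruction together and are each pinned by an independent
numerical oracle in the tests:

* (1+√2)e^{√2} = 9.9306 ("≈10"): recovered by locating the area where
  the rectangular root merges with the square branch (double-root
  condition of R, found by bracketed search on the finite-difference
  ∂R/∂w along w = √A — no use of the closed form);
* 2e^{1−√2}/(1+√2) = 0.5475 ("0.547"): the large-Ā limit of the
  numerically traced rectangular branch;
* their product 2e = 5.4366 ("≈5.5"): the unscaled root of R at
  A = 10⁶δ².

### Numerical choices

Rectangular-branch roots are found by scanning the gap variable
t = 1 − w̄/√Ā on a 4000-point log grid (t from 1e-9), which resolves
roots arbitrarily close to the bifurcation, followed by Brent's method
at relative tolerance 1e-12.  The square point is itself always a
root, so the first interior sign change is the rectangular root.
Branch tracing toward Ā → 1⁺ uses the previous root as a continuation
seed; the merge point is obtained by extrapolating the squared gap
(which closes linearly in Ā, the merge being pitchfork-like) to zero,
giving Ā* = 1 to ~1e-7.

The width → λ/μ² inversion ln(w/(5.5δ)) keeps the conventional
rounded prefactor 5.5 as its default so that published-style tables
reproduce; the exact prefactor 2e is exposed alongside
(`EXACT_WIDTH_PREFACTOR`), and the two differ by ln(5.5/2e) = 0.0116
in the recovered ratio.  Widths at or below the prefactor times δ are
rejected (they would imply λ/μ² ≤ 0 — the resolution floor of the
method).  w always denotes the full stripe width.

### Lever-rule stoichiometry

The DChol term in the expanded-phase area, j(b+1)/(1−j)·N·a_c, treats
j as the DChol fraction of *all* molecules including DChol itself
(N_chol = j/(1−j)·(b+1)N); this is the only reading in which the term
is combinatorially coherent, and it reduces correctly to zero at
j = 0.  Default molecular areas (nm²): a_HD = 0.2, a_DC = 0.45,
a_DL = 0.75, a_c = 0.25.  The trace fluorescent dye (~0.75 mol%) is
ignored.  The stoichiometry fit minimises the unweighted SSE by
default — error-bar weighting is a flag, since either convention is
defensible for three-point data — and ties break toward smaller n.
Candidates violating b ≥ n are excluded with a warning rather than an
error, so a single low-b observation does not abort a fit.

### Growth instability

k₀ = 1/√(2 l_C l_D), k* = k₀/√3, d = 1/k* = √(6 l_C l_D).  The
spacing convention is the reciprocal wavenumber (d ~ 1/k*, **not**
2π/k*).  For diffusive growth of a cylindrical crystal, the cylinder
radius R replaces l_D.  No dispersion relation beyond k₀ and k* is
modelled, and no values of D_L, α_L, ΔΓ or v are bundled — the module
is exercised on synthetic parameters and scaling laws
(d(a·l_C, l_D/a) invariance, k* < k₀, agreement of the two algebraic
forms of k₀).

## Synthetic data

The generators emulate binarised confocal morphologies:

* **stripes** — parallel bands of set width/period, optional uniform
  curvature (concentric arcs) and band-limited boundary noise (a
  cubic-spline Gaussian displacement of the continuous boundary with
  ~2 μm correlation length, applied before rasterisation, so
  boundaries stay smooth like micrographs);
* **domains** — non-overlapping discs with lognormal/uniform/fixed
  radii, greedy largest-first rejection packing with a hard
  minimum-separation and a failure cap (`PackingError`), and an
  optional single wedge notch per domain standing in for the boundary
  cusp of tilt-textured domains (removed sector area is exact in the
  ground truth);
* **fingers** — a disc with radial rectangular fingers at fixed arc
  spacing, one- or two-sided.

Rasterisation uses the pixel-centre convention (a pixel is foreground
iff its centre is inside the continuous shape), which makes the
quantisation error of any measured fraction bounded by
perimeter_px/total_px.  The stripe ground-truth area fraction is
evaluated on a 4× supersampled grid of the same continuous shape,
because frame truncation and curvature make the in-frame fraction
deviate from the nominal duty cycle.  Default pixel size is
0.2 μm/px, safely below the ~0.5 μm optical resolution the images
emulate.  All generators are deterministic under their seed
(byte-identical rasters).

What the generators do *not* emulate: fluorescence intensity and dye
photophysics, chiral spiral textures, domain-domain electrostatic
interactions, or time evolution.  Passing round-trip tests therefore
demonstrates correctness of the measurement/inversion chain on clean
geometry, not robustness to every artefact of real micrographs.

## Morphometrics

* Area fraction is the foreground pixel fraction.
* Domains are 8-connected components; perimeters use the
  chain-code-weighted contour estimator rather than boundary-pixel
  counts (which would be biased high by ~1.27×).
* Stripe width: per elongated component (major/minor axis ≥ 3), the
  skeleton is sampled and each retained skeleton pixel contributes
  2 × EDT px.  Samples within one mean width of a skeleton endpoint
  are discarded (one iteration), and samples below half the component
  median are dropped — both guard against the low-biased medial radius
  at stripe tips and in the oblique wedges where the frame cuts a
  stripe.  Accuracy on clean synthetics is ~0.5 px.
* Stripe period/orientation: Hann-windowed, 4× zero-padded 2-D power
  spectrum; the fundamental is the strongest non-DC peak, refined by
  log-parabolic interpolation.  A peak must beat 25× the median
  spectral power *and* 20× the power at the same |f| rotated 90°
  (stripe spectra are anisotropic; compact-domain spectra are
  ring-like) or the image is declared non-periodic.  Harmonics are
  counted as orders k ≤ 6 whose local power exceeds 1% of the
  fundamental — orders whose Fourier coefficient vanishes for a given
  duty cycle (e.g. k = 3 at duty 1/3) simply do not count.
* Finger spacing: the maximal-radius profile r(θ) about the EDT
  maximum (the core centre — the centroid would be dragged toward
  one-sided fingers), detrended and autocorrelated; the first
  prominent lag converts to arc length at the median (trough) radius,
  which finger tips do not inflate.
* Automatic grayscale thresholding (`binarize`, Li/Otsu) is provided
  for users bringing 8-bit micrographs but bypassed for the
  already-binary synthetic inputs.

Manual width protocols (e.g. "15 measurements per stripe") are
emulated by the pooled medial-axis sampling, not reproduced
placement-by-placement.

## End-to-end recovery study

`run_recovery_experiment` generates stripe images at the limiting
width 5.5δe^{λ/μ²} for λ/μ² ∈ {5, 6, 7} (0.82–6.0 μm at the default
0.2 μm/px), measures them, and inverts.  The generation uses the same
rounded 5.5 prefactor as the inversion so the chain isolates
measurement error from the documented prefactor rounding.  With three
images per value at 512² px the bias in recovered λ/μ² is below 0.01
and the RMSE ~0.03; problem sizes were chosen so the whole study runs
in a few seconds.

## Known limitations

* Only the ratio λ/μ² is identifiable from widths; λ and μ²
  separately require external information.
* The rectangle model ignores interacting stripes, fingered
  intermediate shapes, and the dipolar softening of the effective
  line tension; circular-domain results ignore interdomain repulsion
  and ripening kinetics.
* The asymptotic five-term series is quoted for Ā ≥ 1.75; below that
  the package warns and the numeric branch should be used.
* The width inversion saturates near w ≈ 5.5δ; widths below the
  optical resolution of real imaging (~0.5 μm) are outside the
  generator's guard (≥ 3 px) as well.
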