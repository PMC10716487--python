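# Methods

`spffs` analyses photon event lists from a SPAD-array laser-scanning
microscope and ships a Brownian-dynamics photon simulator that generates
streams with the statistical structure those analyses assume. This note
records the models, the numerical choices, and what the synthetic data can
and cannot demonstrate.

## Data model

A measurement is a list of photons, each carrying a detector channel
(0–24 for the 5×5 array, row-major, centre = 12; 25 for the auxiliary
single-element detector), an absolute time (integer nanoseconds from the
experiment start) and, in lifetime mode, a microtime — the start–stop delay
from the preceding excitation pulse, stored on disk as unsigned 32-bit
picosecond ticks. Integer time storage avoids floating-point drift over
minutes-long acquisitions. The on-disk container is a small HDF5 layout
(columns `channel`/`t_abs`/`microtime`, metadata as JSON attributes) and is
versioned in its header.

Channel merging defines the three nested virtual detection volumes used by
spot-variation FCS — the central element, the inner 3×3 block, and the full
5×5 array — with calibrated 1/e² lateral waists ω₀ = 276, 330 and 390 nm
and axial elongations k = 4.5 (central) and 4.1 (sums); the PSF is modelled
as a 3D Gaussian of 1/e² half-height k·ω₀. The single-element detector is
treated as a 330 nm volume, matching the inner 3×3 in size. The laser
repetition period defaults to 25 ns (40 MHz), configurable; the Gaussian
IRF defaults to σ = 0.1 ns centred at 2 ns.

## Simulator

Emitters perform 3D Brownian motion in a periodic box (default 8 µm per
side, ≥ 20× the largest waist, so that the periodic images of the
detection volume do not overlap). Free motion draws Gaussian increments
with variance 2·D·dt per axis. Two confined-motion classes are available:

* **trap** — spherical domains on a cubic lattice; a free emitter inside a
  domain is captured at rate `trap_rate_s`, then diffuses with `D_in`
  reflected at the domain boundary until a Poisson escape event;
* **hop** — mesh planes every `mesh_size_nm` per axis; a displacement
  crossing a plane is accepted with probability `hop_probability`, else
  reflected.

These parameterizations are constructions of this package; only their
diffusion-law signatures (sign of the intercept, confinement-strength
regime) are meaningful, not their microscopic parameters. The meshwork
signature (negative intercept, S_conf > 1) emerges only when the mesh is
comparable to or larger than the beam, so that the smallest volume probes
mostly intra-compartment motion; a mesh far below the diffraction limit
just rescales the apparent diffusion coefficient uniformly. For strongly
confined motion the correlation decay is no longer 1-component and the
fitted "diffusion times" are effective values — the signatures' signs are
robust, their magnitudes are not.

The time step must satisfy √(2·D·dt) < ω₀/5 (enforced); emission uses the
position at the step start with photon times uniform in the step, which
flattens the correlation only below ≈ 2·dt — fits therefore start at
4·dt. Photon counts per step are Poisson at the local detection rate;
microtimes are Exponential(τ_F) plus the Gaussian IRF, folded by the
repetition period.

**Detection, nested-volume mode (point/circular FCS).** The three merged
volumes are generated as *exact* 3D Gaussians at the calibrated waists:
photons are drawn from the sum-5×5 profile and assigned inward by
hierarchical thinning with probability W_inner(r)/W_outer(r) (well-defined
because the lateral and axial extents are nested), then spread uniformly
over the corresponding channel groups. Relative peak rates are 0.85 : 0.95
: 1.0 (central : sum3×3 : sum5×5). This mirrors measurement practice —
analyses use *calibrated* effective volumes, not volumes derived from the
detector pitch — and makes the 1-component fit model exact, so parameter
recovery tests probe the pipeline rather than a geometry mismatch.

**Detection, element mode (raster imaging).** Each array element detects
through its own Gaussian offset by the projected pitch (default 138 nm ≈
ω₀/2 per element step), multiplied by the excitation Gaussian at the scan
position. The product is a Gaussian of waist ω₀/√2 centred halfway to the
element offset, so each channel image is the object shifted by −o_e/2 and
weighted exp(−|o_e|²/ω₀²) — the property pixel reassignment inverts, and
the origin of the ≈√2 ISM resolution gain. Raster phantoms are brightness
and lifetime maps; per-pixel lifetimes are blurred by the same detection
kernel (brightness-weighted), an intended idealization.

Dual-color studies share one trajectory set: a `co_diffusing_fraction` of
emitter pairs emits in both colors (green via the array, red via the
single-element channel); the rest are independent per color.

**What the generator does not emulate:** photophysics (blinking,
bleaching, saturation), detector dark counts/afterpulsing/crosstalk,
per-element IRF delays, refractive-index aberrations, and any real
cellular heterogeneity. Passing recovery tests therefore demonstrates the
correctness of the analysis chain under its stated model, not robustness
to those instrument or sample effects.

**Study-condition defaults** (chosen once, before any recovery was run,
and used by the validation suite): 2000 emitters in the 8 µm box
(≈ 6.5 nM, occupancy ≈ 2 in the central volume) for diffusion-law studies
— concentration sets the particle-number statistics that dominate the
intercept's standard error, and this value brings it to ≈ 0.02–0.03 ms
over a 60 s acquisition; peak detected rate 5×10⁵ cps per emitter for the
sum-5×5 volume; dt = 20 µs for D = 10 µm²/s and 8–10 µs for the fast
regimes (all within the dt precondition, and fine enough that the
step-emission smear leaves the fitted τ_D unbiased at the fit window's
lower bound of 4·dt).

## Correlator

Correlations are computed from the photon absolute times: the stream is
binned at a 1 µs base resolution and G(τ) = ⟨δI_a(t)δI_b(t+τ)⟩/(⟨I_a⟩⟨I_b⟩)
evaluated on a quasi-logarithmic grid (8 points per decade, 1 µs–1 s),
with the bin width doubling whenever the lag exceeds 16 bins (multi-tau
coarsening) and symmetric normalization — the means are taken over the two
overlapping segments at each lag, which suppresses slow-drift bias. On
small instances the result equals a brute-force binned-trace correlation
to floating precision (tested).

Long acquisitions are split into 10 s (or 5 s) chunks, correlated
independently, and averaged after automated quality control: a chunk is
rejected when its mean intensity deviates more than 25 % from the median
chunk intensity, or when its correlation at the three smallest lags is
more than 5 robust standard deviations from the replicate median. These
thresholds are a deterministic stand-in for visual curation and are
configurable; replicates are retained for per-lag error bars.

## FCS fitting and derived statistics

The 1-component 3D-Gaussian model is

    G(τ) = offset + (1/N)·(1 + τ/τ_D)⁻¹·(1 + τ/(k²τ_D))^(−1/2)

with the geometric γ factor folded into N (so occupancy comparisons are
internally consistent). The 2-component variant is the fraction-weighted
sum with shared geometry; it uses three perturbed starts with best-χ²
selection and orders components τ_fast < τ_slow. Initialization takes τ_D
from the half-plateau lag and N from the plateau amplitude; weights are
inverse replicate SEM when chunk replicates exist. D = ω₀²/(4τ_D).

The circular-scanning calibration model multiplies G by
exp(−4R²·sin²(πτ/T)/(ω₀²(1+τ/τ_D))) with the scan radius R and period T
fixed, which makes the fitted waist independent of any assumed D.

**Fit window.** Fits run from 4·dt of the generating simulation (below
which emission discretization flattens G) up to L²/(400·D) — 1 % of the
box diffusion time. Beyond that lag the periodic box visibly accelerates
the correlation decay relative to the open-space model (measured directly:
the deficit grows from ≈ 1 % at 10 ms to ≈ 25 % at 40 ms for an 8 µm box
at D = 10 µm²/s, and appears proportionally earlier in a 4 µm box), so
including it would bias τ_D downward, more strongly for larger volumes.
For measured data with no surrounding box the window is free; both bounds
are arguments.

The diffusion law regresses τ_D on ω₀² by ordinary least squares; the
intercept t₀ classifies the motion at z = 1.96: free if |t₀| ≤ z·SE,
hop/domain if t₀ > z·SE, meshwork if t₀ < −z·SE (an intercept numerically
negligible against the diffusion times is always "free", covering the
exact-line case). Confinement strength is S_conf = D_central/D_sum5×5 with
first-order error propagation; for 2-component fits the slow
(condensate-bound) component is the default, selectable. Relative FCCS
amplitudes are G_x(0)/G_red(0) and G_x(0)/G_green(0) with amplitudes taken
as fitted, offset-subtracted zero-lag values. The Stokes–Einstein diameter
is d = k_B·T/(3πηD).

## Lifetime and phasors

Decay histograms use 256 bins over one repetition period by default;
microtimes are folded modulo the period first. The tail fit
A·exp(−t/τ) + B starts 0.5 ns after the histogram peak (excluding the
IRF-dominated rise); full IRF reconvolution is out of scope. Per-pixel
lifetime maps use the maximum-likelihood estimator for an exponential
truncated to the tail window, inverted from the mean excess arrival time
by Newton iteration — unlike a log-linear regression it is unbiased at the
low per-pixel counts typical of imaging.

Phasors are first-harmonic cosine/sine summations over the folded
histogram; a mono-exponential lands on the universal semicircle at
(g, s) = (1/(1+(ωτ)²), ωτ/(1+(ωτ)²)). Calibration against a reference dye
of known lifetime is a rotation plus modulation scale; points carry a
`calibrated` flag so the transform cannot be applied twice. Phasor images
threshold pixels below 10 % of the maximum count (configurable).
Segmentation splits the cloud by the vertical line through its centroid —
left (smaller g) = longer lifetime — and back-projects the two sides into
image masks; a cloud with negligible g-spread is returned as a single
label with a degenerate flag. The centroid split is exact only for
well-separated, comparably weighted populations; strongly unbalanced
mixtures shift the centroid toward the majority class.

## ISM / FLISM

Raster streams are histogrammed into a (channel, y, x, Δt) stack, with
pixel indices derived from the absolute times and the pixel dwell
(row-major unidirectional raster assumed). Registration of each
Δt-integrated channel image against the central element uses
phase correlation with upsampled-DFT sub-pixel refinement; channels with
too few photons or a weak peak fall back to a 2D linear model of shift
versus element position fitted over the confident channels (the
fingerprint of a symmetric PSF is linear in the element coordinates).
One fingerprint per frame is reused for all Δt bins. Reconstruction
shifts each channel (bilinear interpolation by default, Fourier shifting
optional) and sums; edges are cropped by the ceiling of the largest shift,
so photons are conserved up to that documented crop (exactly for integer
shifts, to ≤ 0.5 % for sub-pixel shifts). FLISM passes each reassigned
pixel's Δt histogram to the tail estimator above.

## Condensate statistics

Particle analysis labels 8-connected components and measures perimeter
and area on the sub-pixel marching-squares contour after a light circular
moving average of its vertices (window 5) — the raw staircase contour
overestimates a smooth boundary's length by ≈ 5 %, and with smoothing an
ideal disc reaches circularity 4π·area/perimeter² = 1 within 1 % while
straight-edged shapes stay within ≈ 3 % of their exact values;
border-touching particles are flagged. K-means clustering
(z-scored features by default, since D, S_conf and τ_fl carry different
units; 10 restarts, fixed seed) selects k by the elbow criterion — the
point of maximum perpendicular distance of the inertia curve to its end
chord — with a guard: if splitting into two reduces inertia by less than
half, the data are a single cluster (splitting one Gaussian blob always
buys the generic geometric factor ≈ 0.64, so the elbow alone cannot
identify k = 1). Covariance confidence ellipses scale the eigen-axes by
√(χ²₂(level)·λᵢ) and report Pearson's r. Group comparisons use Welch's
unequal-variance t-test at the 0.95 level, with p = 1 by convention for
two zero-variance samples with equal means.

## Validation problem sizes

The validation suite (tests and `scripts/acceptance.py`) runs entirely on
simulated streams: a 60 s free-diffusion acquisition at D = 10 µm²/s for
the diffusion law and confinement strength; 30 s at D = 17.7 µm²/s on a
500 nm/1 ms circle for the waist calibration; 30 s at D = 130 µm²/s for
the fast-monomer regime; 10⁵ microtimes for the lifetime recovery. These
sizes put the statistical error of each recovered quantity a factor ≈ 2
below its acceptance tolerance.

## Known limitations

* The correlator operates on binned photon times (1 µs base); true
  photon-pair correlation below 1 µs (antibunching/afterpulsing scales) is
  out of scope.
* The box-artifact fit bound assumes the simulator's periodic geometry;
  it is not applied automatically to imported data.
* One global phasor calibration; per-element microtime delays are
  accepted as a configurable vector but no per-element calibration
  routine is provided.
* Bidirectional raster de-interleaving, Fourier-reweighted ISM variants,
  FLCS and lifetime-gated correlation are not implemented.
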