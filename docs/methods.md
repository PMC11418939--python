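# Methods

`epighost` simulates the full signal chain behind low-spatial-frequency
odd–even ghosting ("fuzzy ripple" artifacts) in ramp-sampled echo-planar
imaging (EPI), and implements dual-polarity complex averaging as the
mitigation. This note documents the models, the parameters that matter, the
numerical choices, and the limits of what the synthetic experiments show.

## Readout waveform model

The readout train is a sequence of alternating-sign trapezoidal gradient
lobes, one lobe per echo spacing *esp*; a full waveform period is two lobes,
so the train's harmonics sit at `f_n = n / (2 esp)` and, because the train
is half-wave antisymmetric, only odd `n` carry energy. The design rule:
the ramp time is the smallest raster multiple (raster 10 µs) for which the
required ADC gradient area — `matrix_read / fov` cycles/m at
γ = 42.576 MHz/T — fits within the slew and amplitude limits; the flat top
fills the remainder of the lobe and the amplitude is solved exactly from the
area constraint. Minimising the amplitude maximises the ADC duration
(lowest bandwidth), which is why ramp sampling is used at all. The ADC
window is symmetric about the lobe center and excluded from the lowest 10 %
of the ramp amplitude, where the k-space velocity is too small to be useful.
Readout oversampling ×2 (standard scanner practice) doubles the number of
ADC samples; the oversampled read margin is cropped after reconstruction,
which keeps gridding edge effects out of the imaged FOV. All trapezoid
corners fall on raster points, so the raster samples describe the
continuous piecewise-linear waveform exactly and gradient first moments are
computed in closed form.

Phase-encode blips are ideal and instantaneous: the artifact under study is
specific to the readout axis.

## Hardware response (GIRF)

The actual gradient is the commanded waveform convolved with a parametric
impulse response: a (possibly fractional-raster) delay, multi-exponential
eddy-current decays `a_i, τ_i`, and damped-sinusoid resonance terms
`A_j, f_j, ζ_j` that emulate inductive coupling between the gradient and a
high-order shim circuit. Each decaying term is paired with a compensating
delta so that the *discrete DC gain is exactly one*: hardware is calibrated
to reproduce steady gradients, and the residual error is the switching
transient localized at the trapezoid corners. The convolution is a
trapezoid-rule discretization on the raster with zero-padded (causal)
edges; the delay is realised as a two-tap linear-interpolation shift, exact
for whole-raster delays.

Sixteen lead-in lobes (no ADC) run before the excitation so the response to
the periodic train has reached steady state when the first line is
acquired; k and all sample times are referenced to the excitation instant.
Without the lead-in, the startup transient of the long-ringing resonance
breaks the exact odd/even role swap between polarities that makes
dual-polarity averaging a second-order-accurate cancellation.

The default `shim_coupled` preset — delay 2 µs, eddy (a = 0.02,
τ = 250 µs), resonance (A = 0.008, 1100 Hz, ζ = 0.05) — is a simulator
parameter set, not a measurement. It was calibrated once against two fixed
phenomenological constraints: the single-polarity artifact's largest
connected blob spans 5–15 % of the FOV at the default protocol, and the
artifact is in the visibly-fuzzy (envelope-dominated) regime where its
ghost-band energy is predominantly low-spatial-frequency. This places the
artifact deliberately in the *strong* regime; consequences for the
averaging residual are discussed below. `shim_disconnected` is the same
model with the resonance circuit open.

## Study conditions

Defaults emulate the encoding-limited high-resolution regime in which the
artifact is reported: 96 × 96 matrix over a 0.1 m FOV (≈1 mm pixels), echo
spacing 1.0 ms, gmax 80 mT/m, slew 200 T/m/s, giving ramp-sampling
fractions of ≈25–50 % depending on the echo spacing. Off-resonance scales
are chosen so that `Δf · N_lines · esp` (the phase-encode displacement in
pixels) matches in-vivo protocols whose effective echo trains are about
three times shorter than this simulator's full-Fourier 96-line train: the
well-shimmed field is a smooth low-order ≤5 Hz map and the degraded shim
adds a 45 Hz rim just inside the upper object boundary (an air–tissue
interface analogue). The rim's displacement stays inside the object, so
the ghost band outside the object carries the thin, high-spatial-frequency
edge ghosts that off-resonance produces, rather than displacement lumps.

The phantom is a deterministic, seed-jittered ellipse composite (head
outline ≈37 % of the FOV plus internal structures of ≥7 mm scale) with a
smooth complex phase, Gaussian-lobe coil sensitivities with distinct smooth
phases, and a T2* map of 30–50 ms inside the object. Sub-centimeter bright
features are deliberately absent: they would stamp broadband edges onto
every ghost replica and mask the spectral distinction between fuzzy
(trajectory) and edge (off-resonance) ghosting that the experiments probe.

## Forward model

Each sample is a direct, deliberately slow DFT over the scene:

    s(c, l, i) = Σ_r C_c(r) m(r) e^{−t_i/T2*(r)} e^{−2πi ΔB0(r) t_i}
                 e^{−2πi (kx_i x + ky_l y)} + n,   n ~ CN(0, 2σ²)

evaluated at the *actual* (perturbed) read coordinates and the true ADC
sample times (t = 0 at excitation, k-space-center line at TE). No FFT
shortcuts are used, so the forward model remains an oracle independent of
the reconstruction's gridding approximations. GRAPPA sampling acquires
every R-th ky line; the reference (ACS) block is a separate noiseless pass
whose trajectory is *nominal* by default, emulating the clean
FLASH/segmented reference scans vendors use — a kernel trained on
corruption-matched ACS partially compensates the ghost and hides the
GRAPPA amplification seen in practice (`acs_ideal=False` restores the
matched variant). A three-line ky = 0 navigator with polarities (+, −, +)
is simulated with each frame. All noise streams derive from a single
integer seed.

## Reconstruction

The scanner-style pipeline is: per-line least-squares sinc regridding onto
the uniform (oversampled) read grid using *nominal* coordinates — the
mismatch with the actual trajectory is the ghost source — then the
two-parameter odd/even phase correction, GRAPPA filling of skipped lines,
centered 2-D inverse FFT, read-margin crop, and coil combination with the
ground-truth maps (phase-preserving `Σ conj(C) I / Σ |C|²`, or a
map-normalized root-sum-of-squares that discards phase). The regridding
solves a Tikhonov-stabilized system; the default weight (1e−5 of the Gram
trace) bounds the operator norm at the ramp-corner-clustered sample
positions, where a near-interpolating solve would amplify
trajectory-inconsistent data pathologically. The phase correction is
estimated from the navigator as a magnitude-weighted linear fit to the
unwrapped odd/even projection-phase difference and applied as
`exp(i(φ0 + φ1 ξ))` to negative-polarity lines in the hybrid (x, line)
domain; it exactly annihilates constant-plus-linear odd/even phase errors
and provably cannot remove kx-dependent (ramp-corner) errors. The entire
pipeline is linear in the k-space data once the data-dependent calibration
(φ0, φ1, GRAPPA weights) is frozen, which is what makes averaging commute
with reconstruction.

`reconstruct_with_actual_trajectory` runs the identical pipeline fed the
true coordinates. On the decay- and off-resonance-free scene variant it
drives the ghost-to-signal ratio below 1e−5 while the nominal-trajectory
recon ghosts at several per cent — the in-package proof that the artifact
is caused by the trajectory mismatch. The clean variant is essential here:
with finite T2*, within-line decay makes the data inconsistent with any
single per-line object and limits even the informed recon at roughly the
1e−2 level, which would say nothing about trajectories.

## Ghost metrics

The artifact image is `A = |recon| − |reference|` with a pipeline-matched
reference. The ghost region is the complement of the 3-pixel-dilated object
support restricted to the object's read-direction column span (EPI ghosts
displace along phase encode; the read-flanking zones contain read-axis
distortion tails, not ghosts). Reported quantities:

- **gsr** — mean of the brightest 2 % of ghost-region |A| divided by the
  mean object |recon|; a peak-ghost intensity that is insensitive to how
  much of the band the artifact covers and reads ≈0.1 for an injected test
  blob of amplitude 0.1 × the object mean.
- **low_freq_fraction** — fraction of the ghost-region artifact's spectral
  energy below matrix/8 cycles per FOV (DC excluded); separates fuzzy-cloud
  scales from half-FOV edge-ghost content.
- **artifact_extent_fov_fraction** — equivalent diameter of the largest
  connected blob of ghost-region pixels with |A| above 3 × the robust
  (1.4826·MAD) SD, as a FOV fraction.

In the condition-matrix experiment each condition's reference isolates its
distinguishing corruption: trajectory conditions are referenced against the
properly shimmed scene through ideal hardware (including the averaging step
for dual-polarity conditions), and the degraded-shim condition against the
*same* corrupted hardware with a proper shim. A single zero-B0 reference
would floor every condition at the common off-resonance footprint and
obscure the contrasts of interest.

## Dual-polarity averaging

Reversing the readout train exactly negates the k-space deviation (a
consequence of the linearity of convolution and integration, asserted to
1e−10). Within a frame the odd/even-line ghost therefore flips sign between
the two polarities while consistent distortions do not, so the complex
average cancels the ghost to first order in the hardware amplitude: the
single-polarity ghost level scales as ε and the averaged residual as ε²
(measured log-log slopes ≈0.99 and ≈1.98). Two caveats, both deliberate:

- The scaling experiment reconstructs with the navigator correction off.
  The correction removes ~97 % of the single-polarity ghost, and its
  residual interacts with the polarity classes at first order, which hides
  the averaging law without changing it.
- At the default (strong) preset the averaged residual is dominated by the
  ε² term and sits near 30 % of the single-polarity ghost; the ≥5×
  first-order cancellation is exhibited at perturbative amplitudes
  (quarter preset and below).

For time series, pair members acquired one repetition apart differ by the
drift-induced, spatially smooth B0 phase; `align_phase=True` removes a
Gaussian low-pass of the voxelwise cross-product phase before averaging
(the analogue of dynamic off-resonance correction in complex-valued fMRI
preprocessing) while the ghost's rapidly varying phase passes through
untouched. The tSNR comparison reports the ghost-*affected* region — object
voxels overlapped by the half-FOV replica — because in the empty band a
stable ghost trivially has high tSNR and cancelling it lowers the mean
there.

## Echo-spacing sweep

For each echo spacing the sweep runs coupled single-polarity, coupled
dual-averaged, and resonance-disconnected single-polarity conditions. The
resonance-attributable ghost (coupled minus disconnected) peaks at the echo
spacing whose *odd* waveform harmonic lands nearest the 1100 Hz resonance —
1.26 ms on the default grid, whose third harmonic sits at 1190 Hz. Even
harmonics carry no energy for a symmetric alternating train, so proximity
is evaluated on odd harmonics only. At off-peak spacings the weak resonance
term can interfere destructively with the delay/eddy ghost by a few 1e−3 in
gsr, so "disconnecting never hurts" is asserted at the resonance-overlap
spacing, not elementwise.

## Numerical conventions

DC sits at index N/2 on both k-space axes; the centered transforms are
`fftshift(fft(ifftshift(·)))` pairs; images are indexed [y, x] with pixel
centers on the integer grid; matrices are assumed divisible by four.
Trajectory integration evaluates the running integral of the
piecewise-linear raster waveform exactly (piecewise quadratic in time) at
the off-raster ADC instants. The per-line k reference subtracts the nominal
window-center value, so nominal lines span [−N/2fov, +N/2fov) and constant
per-line deviations (the delay signature) survive as artifact drivers; a
small corner-discretization offset common to all lines carries no odd/even
information. Gridding matrices are cached per unique coordinate vector.
GRAPPA uses the fixed 2-source-line × 5-tap kernel with Tikhonov weight
1e−4 of the Gram trace; calibration raises a conditioning error when
`n_coils < R` or when the training residual exceeds 0.5 (duplicated or
uninformative coils). Its held-out self-consistency is ~1.5–2 % for
realistically smooth sensitivities — the sensitivity tail beyond one line
spacing sets the floor, not the EPI chain.

## What the synthetic experiments do and do not show

The generator emulates single-slice 2-D physics with ground-truth coil
maps, ideal blips, no motion, no physiological noise beyond a sinusoidal
respiration-like B0 mode, and hardware imperfections confined to the
readout axis. Passing tests therefore demonstrate the *mechanism* —
corner-localized trajectory errors under ramp sampling produce
low-spatial-frequency odd/even ghosts that two-parameter correction cannot
remove, that GRAPPA amplifies, and that dual-polarity complex averaging
cancels to first order — under controlled conditions. They do not
demonstrate in-vivo effect sizes, interactions with motion or with
estimated (rather than known) coil maps, 3-D/multiband excitation effects,
or the behaviour of vendor reconstructions beyond the idealized pipeline
modeled here. Reported quantities at other matrix sizes scale with the
protocol (ramp fraction, train length), so numbers quoted in the README
refer to the default study conditions.
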