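# Methods

This note documents the model behind `spatialsim`, the choices that were
genuinely open, and what the synthetic studies do and do not establish.

## Imaging model

A 3D-SIM acquisition records, for each of 3 pattern orientations and 5
phase steps, a z-stack of the sample under laterally sinusoidal excitation

    E_i(r) = I0 [ 1 + a1 cos(psi(r) + phi_i) + a2 cos(2 psi(r) + 2 phi_i) ],

with total pattern phase `psi(r) = 2 pi p . r + phase0`, wavevector `p`
(cycles per raw pixel), first/second-harmonic modulation depths `a1, a2`,
and equally spaced steps `phi_i = 2 pi i / 5`. The detected image is the
excited fluorophore density blurred by the 3D incoherent PSF. Writing the
phase series as a sum of harmonics `m = -2..+2`, each band `s_m` carries a
copy of the object spectrum displaced by `m p`; the unmodulated `m = 0`
band is the widefield image and carries essentially all of the defocused
background (the missing cone of the 3D OTF).

No axial pattern modulation is simulated or assumed: the harmonics are
purely lateral, consistent with the two-harmonic mixing model above.
Axial resolution improvement from true three-beam axial modulation is
therefore outside this package's model (a documented limitation).

## Spatial-domain reconstruction

1. **Zero-order removal.** Per angle, the per-pixel mean over the 5 phases
   is subtracted. Any phase-independent additive term — in particular the
   defocused background — cancels exactly.
2. **Per-pixel recombination.** Each zero-mean phase image is Fourier
   zero-padded to a 2x lateral grid (the carriers' second harmonic would
   alias on the raw grid), multiplied by an analytic coefficient field
   built from `cos/sin(psi)` and `cos/sin(2 psi)` mixed by the inverse of
   the trigonometric phase-step design, and summed over phases and angles.
   This plants every band at its true frequency position without explicit
   band separation or spectrum shifting. Harmonic contributions are
   divided by `max(a_m, 0.05)` (Wiener-style gain limiting).
   The full 5x5 design `[1, cos phi_i, sin phi_i, cos 2phi_i, sin 2phi_i]`
   is inverted and the DC row discarded; treating the (already removed) DC
   as an explicit nuisance makes every coefficient row sum exactly to zero
   for arbitrary distinct steps, not only equally spaced ones.
3. **Frequency optimization.** One 3D FFT, then: a Gaussian notch
   (width 0.01 cycles/px, depth 0.95) at the residual illumination peaks
   +-p, +-2p (all axial frequencies; DC is untouched); a two-step low-SNR
   filter — Wiener-style gain `|H|/(|H|^2 + w)` with `w = 0.1` against the
   coverage-summed transfer (the 1/a-weighted |OTF| footprints at the band
   positions, max-normalized), followed by zeroing outside the extended
   support; and a triangular apodization to 1.8x the widefield lateral
   cutoff and 2x the axial cutoff. Stacks are padded axially before the
   FFT (8 mirrored planes when z >= 8, else edge-replicated — a zero pad
   would put a sharp axial edge next to thin stacks and leak along kz).
   With every filter disabled the stage is an exact identity.
4. **Optical section and fusion.** See below; the final volume is
   `SR2 = SR1 + w_os * OS`, clamped at zero after the sum. The pipeline
   default `w_os` equalizes the two volumes' spectral magnitude over a
   mid-frequency crossover annulus (0.15-0.25 of Nyquist on the shared
   grid, central plane), so the section's low frequencies hand over to the
   reconstruction's band without rescaling either. A DC-matching weight
   (section sum equals the removed zero-order sum) is also provided, but
   when the section is widefield-bright it swamps the high-resolution
   band — measured on the point study it degraded the fused resolution
   from 130 nm to 184 nm, which is why it is not the default.

The reconstruction is purely per-plane up to stage SR0_minus, so
limited-layer stacks (down to a single plane) recombine identically to
the same planes of a deep stack; only the 3D frequency filters couple
planes, weakly.

## Optical sectioning

The section combines, per angle and plane, the low-pass of a structured
image with the high-pass of the 5-phase mean (high frequencies are
inherently optically sectioned), then averages the three angles to even
out illumination differences. Lo and Hi are a complementary Gaussian pair
(`Lo + Hi = 1`); the Lo sigma defaults to |p|/4, the conventional HiLo
crossover. Two inputs to the Lo branch are provided:

* **literal** — the raw first-phase image. With complementary filters an
  unmodulated acquisition reproduces the widefield image to machine
  precision. However, a smooth phase-independent background passes Lo
  unattenuated, so this variant does not section such backgrounds at all
  (measured on the ring study: OS SBR 2.95 dB vs widefield 2.96 dB). It
  is the default for a bare `optical_section` call.
* **amplitude** (pipeline default) — the per-pixel first-harmonic
  magnitude `|(2/5) sum_i D_i e^{-i phi_i}| / a1`, the classic OS-SIM
  section: only in-focus content is pattern-modulated, so the
  low-frequency part of the section is genuinely background-free. The
  magnitude operation rectifies noise across the whole sampling band, so
  this variant is band-limited to the detection support (cosine edge from
  0.85x to 1.0x the widefield cutoff). On the ring-plus-background study
  this raises the reconstruction's SBR gain over widefield from ~0.4 dB
  to ~6 dB.

The choice exists because the two desirable properties — an exact
widefield limit and genuine sectioning of smooth backgrounds — cannot be
had from a single Lo input; both behaviors are tested.

## Parameter estimation (prior knowledge)

Estimation runs once per dataset; deep stacks use their 9 central planes
(the parameters do not depend on z).

* **Wavevector.** The pixelwise product of the first-order and zero-order
  bands is a carrier phasor at `p`. Its 2D spectrum (pooled over z) gives
  the integer-bin peak; sub-pixel refinement is a four-stage shrinking
  grid search of the correlation DTFT magnitude (final grid 0.01 bins).
  A phase-slope refinement was tried first and discarded: the correlation
  field's envelope has structure-dependent phase (blur does not commute
  with the carrier), which collapses slope estimates on structured
  objects. Detection requires the first-order band to carry at least
  1e-3 of the zero-order energy and the spectral peak to exceed 8x the
  median (score threshold); otherwise "pattern not detected".
* **Phase and depths.** Each order-m band is demodulated by its own
  carrier in real space, which brings the band's off-grid frequency comb
  exactly onto the sampling grid:
  `X_m(k) = (a_m/2) e^{i m phase0} V(k) OTF(k + m p)` holds bin-by-bin.
  (The opposite ordering — shifting the on-grid zero band off grid —
  suffers Dirichlet leakage on broadband objects and was discarded.) The
  object spectrum is read off the zero band over the OTF-supported
  overlap (threshold 0.02 on both the native and displaced OTF; the
  displaced OTF is sampled on a 2x grid and cropped, because `2|p|` can
  exceed the raw Nyquist frequency where a raw-grid evaluation aliases).
  The complex scale is solved by least squares with an
  errors-in-variables correction: the regressor is built from the noisy
  zero band, whose noise power (measured from far out-of-band bins)
  otherwise attenuates the estimate at low photon counts.

Measured accuracy at the default study conditions (dense point scatter,
256 x 256 x 9, 500 peak photons, 10 seeds): median wavevector error well
below 0.005 cycles/px, median phase error ~0.01 rad, a1 within ~1% and
a2 within ~10% (median absolute relative error).

## Frequency-domain reference engine

The classical reconstruction — per-angle band separation with the 5x5
phase matrix, 2x Fourier upsampling, exact sub-pixel band shifting by
real-space phase ramps, generalized Wiener combination
`sum_b H_b S_b / (sum_b H_b^2 + w)` with `w = 0.05`, then apodization —
serves as the independent comparator and as a correctness oracle: with
the zero order excluded, Wiener weighting off and the same 1/a band
weights, its spectrum must reproduce the spatial recombination's spectrum
exactly (measured relative L2 ~ 5e-16; the release gate asserts < 1e-6).
The Wiener band-weight fields use nearest-bin displaced |OTF| copies
(the weights are smooth; sub-bin placement is immaterial there).

## Synthetic acquisitions

The simulator generates what the reconstruction assumes, plus the
nuisances under study: two-harmonic lateral sinusoidal excitation,
scalar-diffraction 3D blur (hard circular pupil, angular-spectrum
defocus, immersion index 1.518), an optional defocused background (the
widefield volume smoothed by a wide Gaussian — an effective heavily
widened PSF — added identically to every phase), then Poisson shot noise
scaled to a peak photon budget and additive Gaussian read noise.
Modulation and blur run on a 2x fine grid and are Fourier-cropped to the
camera grid; raw-grid generation would alias the second-harmonic carrier.
Detected intensities are clamped at zero (interpolation ringing of
delta-like phantoms and read-noise undershoot).

Default study conditions, chosen once and frozen: NA 1.25, emission
525 nm, lateral pixel 62.5 nm, axial step 125 nm (41 layers for the
headline study), |p| = 0.8x the lateral cutoff at orientations 5/65/125
degrees, a1 = 0.9, a2 = 0.45, 500 peak photons, read sigma 2. The NA was
calibrated so that the *widefield* decorrelation resolution of the point
phantom lands near 237 nm — the simulation optics behind that reference
value are not otherwise pinned — and the apodization default (1.8x
cutoff) sets the package's reconstruction operating point in the ~1.8x
improvement regime typical of linear SIM. At these defaults the headline
point study measures 245.1 nm (widefield), 135.9 nm (full
reconstruction) and 133.0 nm (frequency-domain reference) with an
improvement ratio of 1.80. Default wavevectors are snapped
to integer cycles per field of view so the patterns are continuous across
the periodic boundary; off-grid carriers would leak the boundary phase
jump into every frequency bin of the simulated data.

What the simulator does **not** emulate: vectorial/polarization effects,
aberrations, axial pattern modulation, sCMOS fixed-pattern noise, sample
motion, and real instruments' non-periodic fields of view. Passing tests
therefore establish internal consistency and noise robustness of the
algorithms under the stated model, not instrument-level performance.

## Quality metrics

* `SBR(dB) = 10 log10(mean_signal / mean_background)` on the min-max
  normalized image; `SNR(dB) = 10 log10((mean_signal - mean_noise) /
  std_noise)` on the raw image. A non-positive log argument is reported
  as an undefined-metric error, never a complex logarithm.
* Image-decorrelation resolution: the image spectrum is correlated with
  its phase-only version restricted to growing frequency disks; the
  highest peak frequency across the unfiltered curve and 10 Gaussian
  high-pass variants (100 radius samples) gives `kc` (Nyquist units) and
  resolution `2 px / kc`. The method needs both structure and noise; a
  structureless or peak-free input raises an undefined-metric error.
  Edges are cosine-tapered (border = size/16) before the FFT.

## Numerical choices

* Single precision on large volumes (the headline study peaks at
  ~3.7 GB); double precision below 2e7 voxels, which covers every
  equivalence assertion.
* All carriers are evaluated analytically from (p, phase0) on 0-based
  pixel coordinates; frequency arrays are DC-centered; one shared
  Nyquist-splitting Fourier upsampler is used by both engines so they are
  comparable to machine precision.
* Problem sizes in the test-suite studies (512^2 x 41 headline, 256^2 x
  22 limited-layer, 256^2 x 9 recovery/background) were chosen as the
  smallest grids at which the decorrelation metric's granularity
  (~2% per radius step) stops dominating the comparisons.

## Known limitations

* Lateral-only carriers: no axial super-resolution claim is made or
  tested.
* The literal HiLo variant does not section smooth backgrounds (see
  above); the amplitude variant's magnitude is a biased (Rician)
  estimator at very low SNR.
* Modulation-depth estimation assumes the background is weak during
  estimation (a strong unmodulated background inflates the zero band and
  biases a1 downward); estimate on a low-background acquisition when
  possible.
* Real acquisitions are not periodic; estimation on real data would
  benefit from edge windowing, which is not applied by default.
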