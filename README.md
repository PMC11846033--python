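# spatialsim

Spatial-domain reconstruction for three-dimensional structured-illumination
microscopy (3D-SIM), with optical sectioning.

3D-SIM acquires, per z plane, 15 raw images — 3 illumination orientations x
5 phase steps of a sinusoidal excitation pattern — and reconstructs a
volume with roughly doubled lateral resolution. The classical route
separates the raw phase series into frequency bands, shifts each band to
its true position and merges them with a generalized Wiener filter; it is
memory-hungry, needs many z planes, and is sensitive to defocused
background. This package implements the fast spatial-domain alternative:

1. subtract the per-pixel mean over the 5 phases (the unmodulated zero
   order, which carries the defocused background),
2. recombine the zero-mean phase images per pixel,
   `SR0-(r, z) = sum_theta sum_i c_theta,i(r) D_theta,i(r, z)`, where the
   coefficients are analytic carrier phasors `cos/sin(2 pi p.r + phase0)`
   and their second harmonics on a 2x output grid — this plants every band
   at its true frequency position without any explicit band shifting,
3. optimize the spectrum (notch at the residual illumination peaks, a
   two-step Wiener/out-of-band filter, apodization) to form `SR1`,
4. compute a HiLo optical section
   `OS = mean_theta { Lo[structured] + Hi[widefield] }` from the same raw
   data, and
5. fuse: `SR2 = SR1 + w * OS`, restoring in-focus low-frequency content.

Because the zero order is removed before recombination, the defocused
background is suppressed without notching the center band, and the method
reconstructs faithfully from as few as 2-3 z planes. Without the zero
order, the recombined spectrum is mathematically identical to the
classical frequency-domain result — the package ships both engines and
asserts their equivalence to 1e-6 as a release gate.

Also included: a synthetic 3D-SIM acquisition simulator (scalar 3D PSF,
two-harmonic excitation, defocused background, shot + read noise) with
ground truth; illumination-parameter estimation by cross-correlation
(wavevector, starting phase, modulation depths); and quantitative metrics
(SBR, SNR, image-decorrelation resolution).

## Worked example

```sh
$ spatialsim simulate raw.tif --size 256 --layers 9 --seed 1
wrote raw.tif ((3, 5, 9, 256, 256), seed=1)

$ spatialsim estimate raw.tif params.txt
angle0: p=(+0.01952, +0.23823) cyc/px phase0=+0.048 rad a1=0.910 a2=0.603
angle1: p=(+0.21478, +0.10154) cyc/px phase0=+1.069 rad a1=0.929 a2=0.583
angle2: p=(+0.19525, -0.13670) cyc/px phase0=+2.033 rad a1=0.924 a2=0.574

$ spatialsim reconstruct raw.tif sr2.tif --params params.txt
wrote sr2.tif (stage SR2)

$ spatialsim evaluate sr2.tif sr2.wf.tif
image                                      res_nm   sbr_db   snr_db
sr2.tif                                     156.2        -        -
sr2.wf.tif                                  240.4        -        -
```

The simulated sample is a field of point pairs 150 nm apart at NA 1.25 /
525 nm emission. `estimate` recovers each orientation's pattern
wavevector (ground truth for angle 0: (+0.01953, +0.23828) cycles/px),
starting phase and modulation depths from the raw data alone; the depth
`a2` is overestimated here because delta-like samples clip at zero
(see `docs/methods.md`). `reconstruct` writes the fused volume plus the
widefield and optical-section companions and a JSON run report;
`evaluate` prints each image's decorrelation resolution — 240 nm for the
widefield versus 156 nm for the reconstruction on this small demo grid.
`--engine reference` runs the classical frequency-domain reconstruction
instead, and `--os-only` emits the optical section alone.

The same flow is available as a library:

```python
from spatialsim import (make_phantom, make_otf3d, simulate_acquisition,
                        run_pipeline)
from spatialsim.simulator import default_illumination, NoiseModel

shape = (9, 256, 256)  # (z, y, x)
phantom = make_phantom("point", shape, spacing_nm=150.0, rng_seed=1)
otf = make_otf3d(1.25, 525.0, 62.5, 125.0, shape)
params = default_illumination(otf)
stack = simulate_acquisition(phantom, params, otf,
                             noise=NoiseModel(500, 2), rng_seed=1)
volumes, report = run_pipeline(stack, params, otf)
# volumes["SR2"], volumes["SR1"], volumes["OS"], volumes["WF"], ...
```

## Layout

- `src/spatialsim/simulator.py` — phantoms, 3D OTF/PSF, acquisition model
- `src/spatialsim/params.py` — illumination-parameter estimation
- `src/spatialsim/spatial.py` — zero-order removal and recombination
- `src/spatialsim/freqopt.py` — notch / two-step / apodization filters
- `src/spatialsim/hilo.py`, `fuse.py` — optical section and fusion
- `src/spatialsim/oracle.py` — classical frequency-domain engine
- `src/spatialsim/metrics.py` — SBR, SNR, decorrelation resolution
- `src/spatialsim/io.py`, `cli.py`, `pipeline.py` — TIFF/config I/O, CLI
- `docs/methods.md` — model, parameter defaults, design notes, limits
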