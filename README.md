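# flpaint

Analysis toolkit for **fluorescence-lifetime DNA-PAINT (FL-PAINT)**:
multiplexed single-molecule super-resolution imaging in which several
targets are imaged *simultaneously* with spectrally similar dyes and told
apart by the **fluorescence lifetime** of each binding event, instead of by
sequential imager exchange.

It is written for microscopists and method developers who work with
time-resolved single-molecule data — either wide-field photon-event streams
from a lifetime camera or TCSPC-tagged confocal scans — and who want a
scriptable, testable pipeline from raw photons to lifetime-coloured
super-resolution images, plus a simulator that generates the same data with
known ground truth.

## The method

In DNA-PAINT, dye-labelled imager strands bind transiently to docking
strands on the target; every binding event produces a localizable burst of
photons. With time-resolved detection each photon also carries a TCSPC
delay (micro-time), so each event yields a decay histogram. The pipeline:

1. **Binning** — photons are binned into frames: 8×8 detector pixels × 500 ms
   for wide-field (24 nm raw pixels → 192 nm virtual pixels), or groups of 8
   scanned frames for confocal (0.8 s for a 20 µm × 20 µm raster at 100 nm
   pixels and 2.5 µs dwell).
2. **Localization** — candidate spots from a Gaussian matched filter, then
   a **pixel-integrated Gaussian MLE** fit per spot:
   `µ_px = N·[Φ((x+1−x₀)/σ)−Φ((x−x₀)/σ)]·[Φ((y+1−y₀)/σ)−Φ((y−y₀)/σ)] + b`
   under a Poisson likelihood; the precision is the CRLB from the Fisher
   information at the fit. Localizations with PSF width above 345 nm
   (wide-field) or 180 nm (confocal), or fewer than 100 photons, are
   rejected; single-frame detections are discarded by event linking.
3. **Lifetime** — per event, the photon delays past the TCSPC peak (first
   0.1 ns after the maximum discarded) are fitted with a mono-exponential
   by maximum likelihood, `p(t|τ) ∝ e^{−(t−a)/τ}` truncated to the fit
   window; only lifetimes within 0.5–5.0 ns are kept.
4. **Classification** — the lifetime histogram of all events is fitted with
   a K-component Gaussian mixture; minimum-error thresholds between
   components assign events to targets, and the expected crosstalk matrix
   follows from Gaussian interval masses. Alternatively, Bayesian **pattern
   matching** compares each event's delay histogram with single-target
   reference decays under a multinomial likelihood.
5. **Post-processing** — redundant cross-correlation drift correction,
   per-target and lifetime-coloured renders (2D and z-stack), localization
   precision (CRLB + NeNA) and Fourier-ring-correlation resolution maps.

The dye set used throughout the examples is the orange-emitting trio
Alexa 555, Cy3b, and Atto 550, with lifetimes of 1.7, 2.8, and 3.7 ns on
DNA.

## Worked example

Simulate a two-target sample (peroxisome-like rings labelled at 1.7 ns,
a second ring set at 3.7 ns) and run the full pipeline:

```python
from flpaint import simkit, photonio
from flpaint.pipeline import PipelineConfig, run_pipeline

cfg = simkit.multi_target_scenario(
    lifetimes=(1.7, 3.7), names=("peroxisomes", "mitochondria"),
    rings_per_target=6, movie_duration=180.0, seed=11,
)
rng = cfg.rng()
events = simkit.simulate_binding_events(cfg.targets, cfg.movie_duration, rng)
stream = simkit.simulate_photons_widefield(events, cfg, seed=rng)
photonio.write_photon_stream(stream, "demo_stream.h5")

result = run_pipeline(PipelineConfig(mode="widefield", n_targets=2,
                                     output_dir="demo_out"), "demo_stream.h5")
```

Output (exact numbers for this seed):

```
simulated 364 binding events -> 3171165 photons
1194 localizations -> 205 binding events
mixture means (ns): [1.68  3.684]  sigmas: [0.031 0.086]  weights: [0.483 0.517]
threshold (ns): [2.215]
analytic crosstalk matrix:
 [[1. 0.]
 [0. 1.]]
mean event precision (nm): 2.4
```

The two mixture components recover the simulated dye lifetimes to within
~1%, the minimum-error threshold lands between them at 2.22 ns, and at this
separation the expected crosstalk between the two targets is numerically
zero. `demo_out/` then holds the localization and event CSVs, per-target
and lifetime-coloured TIFFs, the crosstalk matrix and a `metrics.json`
with full provenance (config hash, package version).

The same stages are available from the shell:

```bash
flpaint simulate sim.yaml --out stream.h5 --truth truth.csv
flpaint run stream.h5 -k 2 --out-dir out/
flpaint metrics out/events.csv --out metrics.json
```

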