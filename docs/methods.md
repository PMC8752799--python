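# Methods

This note documents the models, estimators and numerical conventions the
package implements, the assumptions behind its synthetic-data generator,
and the design decisions taken where more than one reasonable choice
existed.

## Signal model

A binding event is the transient hybridization of a dye-labelled imager
strand to a docking strand. While bound, the dye emits photons at an
approximately constant rate; unbinding ends emission. We model no
intra-event photophysics (no blinking, no intersystem crossing, no
photobleaching kinetics): the signal is binding-limited, which is the
standard operating regime of DNA-PAINT.

Each detected photon carries

* a transverse position (detector pixel for the wide-field event camera,
  scan pixel for the confocal raster), blurred by a Gaussian PSF of width
  `psf_sigma` (default 150 nm) and quantized by the detector grid;
* a macro arrival time (s);
* a TCSPC delay (micro-time, ns): `Exp(τ) + N(t₀, σ_IRF)` folded modulo
  the laser period and quantized to the TCSPC resolution.

### TCSPC conventions

* **Window**: 12.5 ns by default (80 MHz excitation, the common rep rate
  for these dyes; configurable).
* **Resolution**: 50 ps for the wide-field camera (configurable), fixed
  16 ps for the confocal TCSPC electronics.
* **Quantization** snaps delays to **bin centres** `(k + ½)Δ`. With
  left-edge quantization every continuous-likelihood fit on quantized data
  would inherit a −Δ/2 bias (~1.5% of τ at Δ = 50 ps, τ = 1.7 ns); bin
  centres make the discretization error `O(Δ²/τ)`, negligible at both
  resolutions.
* **IRF**: Gaussian, FWHM 0.25 ns, centred at t₀ = 0.5 ns. Placing the
  rising edge inside the window matters: the *decay* folding is harmless —
  by memorylessness the folded exponential restricted to `[0, T)` is again
  `∝ e^{−t/τ}` — but a rising edge wrapped from negative times would
  deposit IRF-shaped counts at the end of the window, inside the fit range.
* **Background** photons are uniform in position, macro-time and delay.
  Uniform delay is the worst case for lifetime classification; real
  backgrounds are a mixture with some correlated component, so
  classification on real data should only be easier in this respect.

## Binding kinetics (simulator)

Per docking site, event starts form a Poisson process with rate
`event_rate_per_site` (default 0.03 /s in the benchmark scenario); bright
times are exponential with mean `mean_event_duration` (default 1.5 s, so a
typical event spans ~3 of the 500 ms wide-field time bins). Events are
truncated at the movie end and the photon budget is Poisson with mean
`photons_per_event_mean` scaled by the surviving fraction of the bright
time. The per-event photon budget default is 5000 in the benchmark
scenario (bright orange dyes integrated over second-scale events); this is
a repository choice — the number of photons per binding event is
instrument- and dye-specific, and the pipeline's filters (≥100 photons per
localization, ≥50 tail photons per event fit) define what the analysis
actually requires.

The confocal simulator emits a photon only while the beam dwells on a
pixel overlapping the emitter PSF during an active event: the event's
photon budget is distributed multinomially over its eligible dwell slots,
weighted by the pixel-integrated PSF and the dwell's overlap with the
bright interval. For z-stacks the budget is thinned by a Gaussian axial
detection profile (σ = 400 nm) around the imaged plane; planes are 500 nm
apart by default.

Stage drift is constant-velocity by default (the simplest model whose
recovery is exactly checkable); the drift estimator itself makes no such
assumption.

## Localization

Frames are searched with a **zero-mean Gaussian matched filter**. The
filter response scales with spot brightness, so a threshold in units of
the robust (MAD) noise of the correlation image is meaningful photon
statistics. The default threshold is 5.0 robust σ: measured on Poisson
background of 1 count/pixel, 3.5 σ admits several false maxima per 64×64
frame (the MAD underestimates the heavy Poisson tail), while detection of
the weakest admissible spots (100 photons — the filtering cut) is still
100% at 5.5 σ. Candidates whose surrounding window holds fewer than 30
photons are rejected outright — a normalized score is scale-free and a
lone photon on an empty frame would otherwise correlate perfectly.

Each candidate is refined on a 7×7 virtual-pixel ROI by maximizing the
Poisson likelihood of the pixel-integrated Gaussian model (parameters
x₀, y₀, N, b, σ; analytic gradients; L-BFGS-B with bounds; centroid
initialization). The reported precision is the CRLB on x₀ from the Fisher
information `I_ij = Σ_px ∂_i µ ∂_j µ / µ` at the fit. On simulation at
N = 1000, σ = 150 nm, b = 2/px the position RMSE sits within a few percent
of this bound (the acceptance suite checks 20%).

Linking is greedy nearest-neighbour across frames: maximum displacement 2
virtual pixels, at most 1 skipped frame. Single-frame events are
discarded. Event positions are photon-weighted means of their member
localizations.

## Lifetime estimation

The per-event lifetime is the MLE of a mono-exponential fitted to the
**tail** of the event's delay distribution: delays in
`[t_peak + 0.1 ns, T]`, where `t_peak` is the centre of the maximum
histogram bin (50 ps search bins) and T the window end. The tail density is
the truncated exponential

    p(t|τ) = e^{−(t−a)/τ} / (τ (1 − e^{−(b−a)/τ})),  t ∈ [a, b],

which — again by memorylessness — is *exact* for the folded decay,
wrap-around included. The 1-D likelihood is maximized by bounded scalar
minimization (`xatol` 10⁻⁷ ns; a brute-force 1 ps grid scan agrees to
<1 ps in the tests); the standard error comes from the numerical second
derivative of the log-likelihood at the optimum. Fits run on unbinned
delays when available; a binned path over histogram bin centres agrees to
<0.5% at 16 ps bins and exists for parity with histogram-based workflows.

Events with fewer than 50 tail photons are flagged rather than fitted:
below that the statistical error approaches the ~1 ns spacing between the
dyes and the value is useless for classification.

Two residual biases are worth knowing about. First, the IRF shoulder: with
a 0.25 ns FWHM IRF the region just past the peak is not yet purely
exponential, which depresses the estimate by ~1% at τ = 1.7 ns (less for
longer lifetimes); this is inherent to the 0.1 ns tail offset and well
inside the 3% recovery tolerance the acceptance suite enforces. Second,
background admixture: photons collected around a spot include uniform-delay
background, which *raises* the fitted lifetime. The pipeline therefore (a)
collects event photons in a tight window (2 virtual pixels) around the
fitted position, and (b) by default extends the tail density with a
uniform component, `p = (1−f)·trunc_exp + f/(b−a)`, with the fraction f
estimated per event from the fitted per-pixel background b of its
localizations. The pure mono-exponential remains the
`fit_lifetime_tail` default and the pipeline flag can be switched off.

Only lifetimes in the inclusive range 0.5–5.0 ns enter classification.

## Target classification

**Threshold mode.** Fitted lifetimes of all events are modelled as a
K-component 1-D Gaussian mixture, fitted by EM (scikit-learn backend) with
deterministic quantile initialization — component k starts at the
(k+½)/K quantile, width = sample SD / K, uniform weights, σ floor 0.02 ns
(re-initialized once with a doubled floor on collapse). Decision
boundaries are the points between adjacent means where the weighted
densities are equal — the minimum-error rule — found by bracketed root
finding with a midpoint fallback when the densities do not cross. The
expected crosstalk matrix is `C_ij = ∫_interval_j w_i N(τ; µ_i, σ_i) dτ /
w_i`, i.e. Gaussian interval masses per component; on the Alexa 555 /
Atto 550 pair with realistic widths the off-diagonals are below 1%, and
truth-label misclassification on simulation at 500 photons/event is
numerically zero.

**Pattern mode.** Reference decay patterns are pooled, normalized delay
histograms of single-target measurements. Pooling happens on the **raw
TCSPC axis**: the instrument response pins the decay's position in the
window, so reference and event histograms are aligned by construction.
(Registering each event's histogram by its own empirical peak was tried
and rejected: at a few hundred photons the peak estimate jitters by
several bins and the registration noise overwhelmed the extra information,
making pattern matching *worse* than thresholding. The pooled-histogram
peak is recorded for instruments that need a one-off channel-offset
shift.) An event's posterior is the multinomial likelihood of its delay
histogram under each pattern times the prior, computed in log space with a
10⁻⁹ floor for empty pattern bins. Because pattern matching uses every
photon rather than a scalar summary, it is at least as accurate as the
threshold on paired simulations (strictly better in the overlapping
2.8 vs 3.7 ns regime), at the cost of requiring reference measurements.
Events whose best posterior falls below 0.5 are left unassigned.

## Drift correction

Redundant cross-correlation: localizations are split into time segments
(default movie/10; segments with <100 localizations merge into their
successor), each segment is rendered as a 30 nm histogram image and lightly
smoothed (1 px Gaussian), and shifts between **all** segment pairs are
measured by cross-correlation with 50× Fourier upsampling. Plain — not
phase-normalized — correlation is used deliberately: spectral whitening
amplifies shot noise on sparse reconstructions and produced occasional
gross peak-locking failures in testing. The over-determined pairwise
system is solved by least squares with the first segment anchored at zero;
the trajectory is interpolated linearly between segment centres and
extrapolated linearly beyond them (the anchor-to-endpoint extrapolation
matters: clamping would truncate half a segment of real drift). Applying a
trajectory and then subtracting it restores coordinates exactly; a 50 nm
linear drift over 10⁵ localizations is recovered to well under 5 nm at the
movie end.

## Rendering and quality metrics

Rendering accumulates localizations on a configurable grid (default
20 nm) either as counts or as unit-mass Gaussians of each localization's
precision; a parallel channel carries the intensity-weighted mean lifetime
per pixel and drives the lifetime→hue colormap (limits default to the
accepted lifetime range and are stored in the image metadata). Z-stacks
are rendered per plane and projected with height encoded as hue.

Precision is reported two ways: the mean per-fit CRLB, and NeNA — from
displacements d between consecutive-frame localizations of the same event,
which are Rayleigh with scale σ√2, so `σ_NeNA = sqrt(mean d² / 4)`
(flagged undefined without repeats).

FRC resolution splits events (not localizations — intra-event repeats are
correlated and would inflate the estimate) randomly into two half-sets,
renders both, and takes the Fourier ring correlation of the mean-subtracted,
Hann-windowed images; the resolution is the inverse frequency of the first
crossing below 1/7, after a 3-ring moving average (independent noise images
then correctly report "unresolved" instead of a spurious low-frequency
crossing). Mean subtraction precedes windowing because the window envelope
itself correlates even independent images at the lowest rings. The
resolution map repeats this per 64×64-render-pixel block, leaving blocks
with fewer than 2000 localizations undefined; the report carries the block
mean and minimum.

## Benchmark scenario and problem sizes

`simkit.multi_target_scenario` is the package's standard phantom: ring
structures with diameters drawn from 100–300 nm (peroxisome-scale — small
enough to be unresolvable in diffraction-limited imaging), six sites per
ring, ring centres placed on a jittered 2 µm grid with disjoint cells per
target. The grid placement is deliberate: with uniform random placement,
rings of different targets occasionally land within a PSF width of each
other, and the photons of two dyes genuinely mix — the resulting
"misclassifications" are a property of the phantom, not of the classifier.
Defaults are a 12.3 µm field (the 512×512 camera at 24 nm/px), 180 s
movie, 0.03 events/site/s, 5000 photons per event and a background of 50
photons/s/µm² (~0.9 counts per virtual pixel per 500 ms bin). At these
sizes the full three-target pipeline runs in tens of seconds on one core
and yields ~200 classified events, enough for a stable three-component
mixture (the fit requires 50·K events).

What passing these simulations does **not** show about real data: dye
lifetime heterogeneity within a population (the simulator draws every
event of a target at exactly its nominal τ, so mixture widths on real data
are larger), detector count-rate nonlinearity near the camera's ceiling
(simulated only as a warning), non-uniform and partially correlated
background, and cell-scale structure density. The in-cell crosstalk
reported for real multi-target samples (a few percent) is accordingly
larger than the sub-percent values these phantoms produce.

## Known limitations

* Mono-exponential lifetimes only; multi-exponential decays and phasor
  analysis are out of scope.
* Confocal 3D comes from discrete z-planes, not from PSF-shape (astigmatic)
  fitting.
* The greedy linker does not split two events that overlap in time within
  one PSF width; on dense samples such merges set the effective event
  rate ceiling.
* No parsers for proprietary vendor TTTR formats; streams enter through
  the documented HDF5 container or the generic time-tag CSV shim.
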