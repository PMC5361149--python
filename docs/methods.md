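# Methods

## Signal model

All computation assumes the single-scattering model of OCT intensity:
for a homogeneous medium with surface at z₀,

    I_oct(z) = A · μ_bs · h(z) · exp(−2 μ_ext (z − z₀)),  z ≥ z₀,

on **linear** intensity (readers convert dB-domain data on load). The
factor 2 in the exponent accounts for the round trip of the probe
light; it is a single shared constant (`signal_model.ROUND_TRIP`) so
the simulator and all three estimators cannot drift apart on the
convention. The beam focus function h(z) is represented as a tabulated
positive vector, not a parametric confocal formula: reference
normalization cancels it exactly, so its shape matters only as a
simulator knob for testing that cancellation.

Normalization divides the sample A-line by a laterally averaged
reference-phantom A-line, each re-indexed to start at its own surface
pixel. The reference is collapsed to one averaged profile per run (the
phantom is homogeneous); the known μ_ext,r is added back to the fitted
relative attenuation at the end. Surfaces use 0-based indices, the
surface index is the first pixel at or below the surface, and all
windows are half-open `[start, start + n)`.

## The FD estimator

For a sampled exponential I(n) = a·xⁿ with x = exp(−2 μ_rel Δz), the
DFT coefficient moduli follow the geometric-series closed form
|F(m)| = a·|1 − x^N| / |1 − x·e^(−i2πm/N)|. The ratio of any two
harmonic moduli is therefore a function of x alone. With the default
(0, 1) pair,

    r = |F(0)| / |F(1)| = |1 − x e^(−i2π/N)| / (1 − x),

squaring gives the quadratic (r²−1)x² − 2(r²−cos(2π/N))x + (r²−1) = 0
whose roots are reciprocal; the root in [0, 1) is the physical decay
and μ_rel = −ln(x)/(2Δz). This **exact discrete inversion** is the
default because it is unbiased on sampled exponentials at any N. The
continuum-limit formula μ_rel = (π/L)/√(r²−1) (L = NΔz) is available as
`inversion="continuum"`; the two differ by O(1/N). Any harmonic pair
m_lo < m_hi is accepted; the inversion generalizes with
b = r²cos(2πm_lo/N) − cos(2πm_hi/N).

Numerical edges: |F(m_hi)| below 1e-12·|F(m_lo)| is treated as a
constant signal (μ_rel = 0, flat-signal diagnostic). For non-negative
data r ≥ 1 always holds (triangle inequality); r numerically below 1
is clamped and flagged with a quality warning rather than raised. No
spectral window/taper is applied before the DFT — the decay itself is
the signal and tapering would bias r.

**Sign blindness.** The DFT moduli of a decaying exponential and of its
time-reversed (growing) counterpart coincide — the quadratic's two
roots x and 1/x. The FD estimator therefore returns |μ_rel|; it cannot
flag a sample *less* attenuating than the reference. In practice the
reference phantom is chosen weakly attenuating (dilute silica), keeping
μ_rel > 0 for tissue. LF and EF are sign-aware and report negative
estimates verbatim (never clipped), which is what exposes
surface-detection failures in diagnostic maps.

## LF and EF baselines

LF fits ln I(z) by ordinary least squares using the four running sums
Σz, Σy, Σzy, Σz² (the same four accumulations a streaming/GPU
implementation would keep) and reports μ_rel = −slope/2 with slope,
intercept and R² diagnostics. It requires strictly positive values and
names the first offending pixel otherwise.

EF fits a·exp(−2μz) by trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method "trf", analytic Jacobian),
with μ bounded in [−50, 50] mm⁻¹ (configurable), step/function/gradient
tolerances 1e-10 and at most 200 function evaluations. It is
initialized from the LF solution (fast and usually close), falling
back to (a = I(0), μ = 1 mm⁻¹) when LF is unusable; non-convergence is
reported through a diagnostic flag, never an exception.

On noiseless single exponentials all three agree with the true μ_rel
to better than 1e-6 mm⁻¹ across μ ∈ [0.5, 10] mm⁻¹ and windows of
0.35–1.05 mm (verified in the test suite, FD additionally against a
brute-force grid search over μ with step 1e-4).

## Preprocessing

Lateral averaging: arithmetic mean of linear intensities over sliding
windows of 330 A-lines (default) advancing by 13, computed with a
cumulative sum; partial trailing windows are dropped rather than
zero-padded (padding would bias the mean). Intensities are averaged
*first*, then normalized, then fitted. Averaging is along x within a
frame only; frames are not mixed.

Surface detection (the literature leaves the algorithm open; this is
our choice): the averaged profile is median-smoothed (width 5 px), the
noise floor and SD are estimated from the shallowest 50 px, and the
surface is the first index whose smoothed intensity exceeds
floor + 4·SD. Confidence is the detected edge strength normalized by
the profile's peak excess over the floor. Columns with no
super-threshold pixel return index −1 and are masked downstream. The
detector is O(N), robust to fully developed speckle after 300-line
averaging (within ±3 px on seeded simulations — our working tolerance,
not an external requirement), and pluggable should a max-gradient
variant be preferred.

Window extraction takes ⌊data_length/Δz⌋ samples from the surface;
windows that overflow the depth range raise and the cell is masked.

## Simulator

The generator emulates the acquisition geometry of a swept-source
system (1.8 mm depth at 2048 px → Δz ≈ 0.88 μm; 2×2 mm lateral field),
scaled down in A-lines/frames for desk-size runs, with:

- **speckle**: per-pixel intensity drawn from an exponential
  distribution with the local mean (fully developed speckle; SD equals
  the mean). Correlated speckle is not modelled.
- **few-scattering tail**: a second, slower exponential carrying a
  fraction c of the power at rate α·μ, the simplest contamination
  consistent with multiply-scattered light surviving at depth.
  Defaults c = 0.15, α = 0.3 put the LF long-window bias at μ = 7 mm⁻¹
  in the tens of percent; this is a modelling choice, not measured
  tissue physics, so only bias *orderings* (EF least, LF most, FD
  between) transfer to real data, never percentages.
- **surface errors**: `misdetect_surfaces` applies systematic or
  seeded-random pixel offsets to a detected surface map; negative
  offsets open the fitting window on pre-surface noise pixels, which
  breaks LF and EF (down to negative μ) but barely moves FD.
- **noise floor**: an additive positive constant (default 1e-3 of the
  surface signal, ~30 dB down); may be set to 0 for the exact
  noiseless limit, in which simulate → estimate is the identity on μ
  to 1e-6 for all three methods.
- the reference profile is generated with the same h(z), μ = μ_ext,r
  (default 1.0 mm⁻¹, a plausible dilute-silica value; real runs must
  supply their phantom's value), flat surface at z₀ = 0, speckle
  averaged over 2000 draws.

A fixed seed makes every volume, map and CSV byte-identical between
runs; the generator refuses volumes over 2³¹ samples.

What passing these tests shows — and does not. The simulator draws
from the same single-exponential family the estimators assume, so
exactness results validate the *inversion algebra*, not the model's
fit to tissue; the speckle, tail and misdetection studies validate
robustness *orderings* under controlled violations. Real tissue adds
heterogeneity within the window, correlated speckle, depth-dependent
μ_bs and detector roll-off, none of which are modelled.

## Mapping and classification

One μ_ext,s per (lateral window, frame) cell; cells whose surface is
missing, whose window overflows, or whose fit fails/diverges are
masked, never interpolated. Classification against the diagnostic
threshold (default 5.5 mm⁻¹, from prior brain-margin work) labels
below-threshold cells high-cancer-density; ties go to "above"
(conservative toward non-cancer) and are configurable. Maps render
red→yellow→green (matplotlib RdYlGn) over a configurable μ range with
masked cells gray (distinguishable from low-signal black); the exact
colour breakpoints are a convention, not a reproduction of any
published colour bar. Cell coordinates are window centres in mm. CSV
grids carry (x_mm, y_mm, mu_mm1, label, mask) at 6 significant digits.

## Study sizes

The bundled studies run at sizes chosen to make each effect decisive
on one CPU: 100 seeded runs for the surface-offset study (binary
FD-wins rate, margin ~100%), 40 for the tail-bias ordering (gaps of
0.6–1.8 mm⁻¹ against standard errors below 0.01), 200 replicates for
the speckle-averaging SD ratio (√6 expected between 50- and 300-line
averaging; observed within a few percent), and 10⁴ signals for the
throughput comparison (EF is two orders of magnitude slower than the
closed-form FD/LF batch paths, far beyond the 5× ordering asserted).

## Known limitations

- FD sign blindness (above): choose μ_ext,r below the tissue range.
- One μ per window: no depth-resolved (per-pixel) attenuation profile.
- The tail model is phenomenological; absolute bias percentages are
  not transferable to tissue.
- Surface detection is per-column; no 2-D regularization across
  columns.
- CPU only; the FD/LF batch paths are vectorized but no GPU kernels
  are provided, so absolute throughput is host-dependent and only
  relative timings are meaningful.
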