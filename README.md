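# octatten

Estimation and en-face mapping of optical attenuation coefficients from
OCT intensity data, built around a fast, surface-robust
**frequency-domain (FD)** estimator with the classical **log-and-fit
(LF)** and **exponential-fit (EF)** methods as baselines, plus a
synthetic OCT simulator used to validate every robustness claim.

## The problem

The optical attenuation (extinction) coefficient μ_ext — absorption plus
scattering, in mm⁻¹ — is a quantitative tissue property that can be
read out of OCT intensity images. It is clinically useful where
structural images carry no visible landmarks: infiltrative brain-cancer
margins, for instance, show *reduced* attenuation relative to healthy
white matter, so a 2-D "en-face" map of μ_ext over the scanned surface
can delineate cancer in real time during surgery. The catch is that
per-window exponential fitting must be fast, robust to speckle, to
multiply-scattered light, and — critically for in vivo use — to errors
in locating the tissue surface.

## The model and the estimators

Under the single-scattering approximation, the depth-dependent OCT
intensity of a homogeneous sample is

    I_oct(z) = A · μ_bs · h(z) · exp(−2 μ_ext (z − z₀)),   z ≥ z₀,

with system constant A, back-scattering coefficient μ_bs, beam focus
function h(z), and the round-trip factor 2. Dividing a sample A-line by
the A-line of a reference phantom of known attenuation μ_ext,r (both
re-indexed to their own surface) cancels A and h(z), leaving a pure
exponential in the **relative** attenuation μ_rel = μ_ext,s − μ_ext,r:

    I(z) = I_s(z) / I_r(z) ∝ exp(−2 μ_rel z).

Three estimators recover μ_rel from the windowed, normalized signal:

- **FD** — computes the moduli of two DFT coefficients of the window
  (by default the DC term |F(0)| and first harmonic |F(1)|). For a
  sampled exponential I(n) = a·xⁿ, |F(m)| = a·|1−x^N| / |1−x·e^(−i2πm/N)|,
  so the ratio r = |F(0)|/|F(1)| depends only on the per-pixel decay
  x = exp(−2 μ_rel Δz). The package inverts r exactly (a quadratic in x
  with reciprocal roots) and also offers the continuum-limit formula
  μ_rel = (π/L)/√(r²−1). Because a global scale — including the scale
  change produced by windowing a pure exponential early or late —
  cancels in the ratio, FD is nearly immune to mis-detected surfaces.
- **LF** — ordinary least squares of ln I(z) on z; μ_rel = −slope/2.
  Fast, but log-weighting makes the (noisy, multiply-scattered) tail as
  influential as the strong early signal.
- **EF** — trust-region nonlinear least squares of a·exp(−2μz) in the
  linear domain. Slowest (iterative), but most robust to tail
  contamination since the fit weight sits on the large early samples.

The mapping pipeline averages ~330 neighbouring A-lines (speckle
suppression), detects the surface per averaged column, cuts a fixed
data length (~350 or ~700 μm) below it, normalizes, estimates, and
assembles μ_ext,s = μ_rel + μ_ext,r into an en-face grid that is
classified against a diagnostic threshold (default 5.5 mm⁻¹) and
rendered red (low attenuation, high cancer density) → green (high
attenuation, mostly white matter).

## Worked example

```python
import octatten as ot

dz = 1.8 / 2048
reference = ot.ReferenceProfile(
    ot.forward_model(z0=0.0, A=2.0, mu_bs=1.0, mu_ext=1.0, psf=None, dz=dz, n=1400),
    mu_ref=1.0,
)
sample = ot.forward_model(z0=0.0, A=1.0, mu_bs=0.7, mu_ext=3.5, psf=None, dz=dz, n=1400)
signal = ot.normalize(sample, reference, sample_surface=0, window_mm=0.35)
for method in ("FD", "LF", "EF"):
    res = ot.estimate(signal, method, reference_mu=reference.mu_ref)
    print(f"{method}: mu_rel = {res.mu_rel:+.6f} /mm, mu_sample = {res.mu_sample:.6f} /mm")
```

prints

```
FD: mu_rel = +2.500000 /mm, mu_sample = 3.500000 /mm
LF: mu_rel = +2.500000 /mm, mu_sample = 3.500000 /mm
EF: mu_rel = +2.500000 /mm, mu_sample = 3.500000 /mm
```

the sample/reference ratio decays at 2·μ_rel = 2·2.5 /mm, and adding
the known reference attenuation (1.0 /mm) recovers the sample's
μ_ext,s = 3.5 /mm exactly — on noiseless data all three estimators are
unbiased to numerical precision. The scripts in `examples/` walk
through the other capabilities (en-face mapping of a two-region sample,
surface-misdetection robustness, few-scattering bias); e.g.
`examples/03_surface_misdetection.py` prints

```
offset   +0 px:  FD  +2.99 +/- 0.02  LF  +2.99 +/- 0.01  EF  +2.99 +/- 0.02 /mm
offset  -30 px:  FD  +3.11 +/- 0.02  LF  -1.18 +/- 0.01  EF  +1.85 +/- 0.01 /mm
offset  -60 px:  FD  +3.50 +/- 0.02  LF  -4.78 +/- 0.01  EF  +1.09 +/- 0.01 /mm
```

— when the fitting window starts before the true surface, LF and EF
collapse (LF to negative values) while FD stays near the true 3 /mm.

## Command line

```sh
octatten simulate --config sim.yaml     # synthetic volume + reference + truth
octatten map --config run.yaml          # en-face maps, comparisons, manifest
octatten compare out/map_FD.csv out/map_LF.csv
octatten benchmark --n-signals 10000    # relative FD/LF/EF throughput
```

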