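"""Build an en-face attenuation map of a two-region synthetic sample.

Simulates a speckled volume whose attenuation steps from 3 to 7 /mm at
x = 0.25 mm, runs the full pipeline (lateral averaging, surface
detection, normalization, FD estimation) and prints the map row.  The
printed attenuations should cluster near 3 on the left and 7 on the
right of the step, localizing the boundary within one averaging
window.
"""

import octatten as ot

cfg = ot.SimulationConfig(
    n_depth=900, n_alines=512, n_frames=1,
    mu_field=lambda x, y: 3.0 if x < 0.25 else 7.0,
    surface_height=0.05, speckle=True, noise_floor=1e-3, seed=1,
)
volume, reference, truth = ot.simulate_volume(cfg)

amap = ot.build_map(
    volume, reference,
    ot.MapConfig(method="FD", data_length_mm=0.35,
                 averaging=ot.AveragingSpec(window_alines=128, step_alines=32)),
)
for x, mu in zip(amap.x_mm, amap.mu[0]):
    print(f"x = {x:.3f} mm  mu = {mu:5.2f} /mm")

labels = ot.classify(amap, ot.ClassificationRule(threshold_mm1=5.5))
print("labels:", list(labels[0]))
# cells below 5.5 /mm would read as high cancer density in tissue;
# here they simply mark the weakly attenuating left region.
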