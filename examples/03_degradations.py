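"""Image degradations used in the sensitivity studies.

Applies the additive Gaussian noise model at the suite's SNR levels
(sigma_n = sigma_i / SNR over the whole volume) and the uniform intensity
reductions to a phantom template, and prints the realized statistics.
The realized sigma_i/sigma_n should match each requested SNR, and scaled
volumes should have mean and standard deviation scaled by (1 - f).
"""

from warpstrain import (
    NoiseSpec,
    PhantomSpec,
    add_noise,
    intensity_stats,
    render_image,
    scale_intensity,
)

template = render_image(PhantomSpec().full_grid())
mean0, sd0, _, _ = intensity_stats(template)
print(f"clean template: {template.voxels.size} voxels, "
      f"mean {mean0:.2f}, sd {sd0:.2f}")

print("\nadditive noise (realized sigma_i / sigma_n):")
for snr in (8.0, 4.0, 1.0, 0.5, 0.1):
    _, noise = add_noise(template, NoiseSpec(snr=snr, seed=0))
    print(f"  requested SNR {snr:4g} -> realized {sd0 / noise.voxels.std():6.3f}")

print("\nintensity reduction (mean scales by 1 - f):")
for pct in (10, 20, 40):
    m, s, _, _ = intensity_stats(scale_intensity(template, pct / 100))
    print(f"  -{pct}% -> mean {m:.2f} (x{m / mean0:.2f}), sd {s:.2f}")
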