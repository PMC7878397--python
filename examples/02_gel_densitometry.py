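"""Quantify band areas from a gel image: profile, baseline, integration.

Renders a synthetic blot (two LC3 bands plus a loading control on a smooth
background), then runs the lane-profile workflow and compares the recovered
areas with the generator's ground truth.
"""

from autoflux.quantification import (
    SyntheticBand,
    extract_profile,
    integrate_bands,
    integration_intervals,
    make_synthetic_gel,
    subtract_baseline,
)

bands = [
    SyntheticBand("lane1", "LC3-I", center=30, sigma=2.0, total_intensity=3000),
    SyntheticBand("lane1", "LC3-II", center=60, sigma=2.0, total_intensity=6000),
    SyntheticBand("lane1", "loading_control", center=95, sigma=2.0, total_intensity=8000),
]
image, truth, rois = make_synthetic_gel(
    bands, lanes={"lane1": (2, 10)}, shape=(120, 12),
    background="smooth", background_scale=4.0, noise_sd=0.3, seed=0,
)

profile = extract_profile(image, rois[0])
profile = subtract_baseline(profile, method="rolling-ball", window=15)
calls = integrate_bands(profile, integration_intervals(truth)["lane1"])

print(f"{'band':>16} {'recovered (au)':>15} {'true (au)':>10} {'error':>7}")
for call, band in zip(calls, truth):
    err = call.area / band.total_intensity - 1
    print(f"{call.band_label:>16} {call.area:15.1f} {band.total_intensity:10.1f} {err:+7.2%}")
print()
print("Each area is the baseline-subtracted profile summed over the band window;")
print("errors of a percent or two come from background removal and pixel noise.")
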