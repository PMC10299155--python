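"""From TIRF movie to trajectories: spot detection and trace extraction.

Renders a synthetic movie of diffraction-limited spots (stably bound
fluorophores at peak-pixel SNR 5), detects them on a band-pass-filtered
average image, extracts background-subtracted intensity traces, and
compares recovered spot positions and intensities with the ground truth.
"""
import numpy as np
from scipy.spatial import cKDTree

from smg4 import BindingModel, detect_spots, extract_trace, simulate_movie

PSF_SIGMA = 1.2  # px
model = BindingModel.two_state(
    1e-4, 0.0, n_frames=50, pre_frames=0,
    state_intensities=(0.0, 500.0), noise_sd=0.0,
)
peak = 500.0 / (2 * np.pi * PSF_SIGMA**2)
movie = simulate_movie(
    model, n_spots=30, field_size=256, psf_sigma=PSF_SIGMA,
    noise_sd=peak / 5, start_state=1, seed=9,
)

spots = detect_spots(movie.stack, detect_frames=slice(0, 10),
                     threshold_sigmas=5.0)
dists, idx = cKDTree(movie.centers).query([s.center for s in spots])
print(f"placed {len(movie.centers)} spots, detected {len(spots)}, "
      f"{int((dists < 1).sum())} matched within 1 px "
      f"(median offset {np.median(dists):.2f} px)")

traces = [extract_trace(movie.stack, s) for s in spots[:3]]
for spot, trace in zip(spots, traces):
    print(f"spot at ({spot.center[0]:6.1f}, {spot.center[1]:6.1f}): "
          f"mean extracted intensity {trace.intensities.mean():7.1f} AU")
print("(window sum minus annulus background; compare with the injected "
      "per-frame intensity of 500 AU, minus the PSF tail outside the "
      "3 px window)")
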