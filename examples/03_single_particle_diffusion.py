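"""Single-particle MSD and diffusion-coefficient estimation.

Simulates a membrane particle population that is half freely diffusing
(D = 0.05 µm²/s) and half immobile, computes the ensemble MSD of each
class and fits the short-lag line whose slope/4 is D.
"""

import numpy as np

from memclust import compute_msd, fit_diffusion
from memclust.synthetic import TrajectoryFieldSpec, generate_trajectories

spec = TrajectoryFieldSpec(
    n_tracks=200, n_frames=60, frame_interval=0.1,  # 6 s at 0.1 s interval
    D_free=0.05, immobile_fraction=0.5, localization_sd=0.02, seed=3)
tracks = generate_trajectories(spec)

for label in ("free", "immobile"):
    subset = [t for t in tracks if t.label == label]
    curve = compute_msd(subset, max_lag=4)
    est = fit_diffusion(curve, n_fit_lags=4)
    print(f"{label:8s}: D = {est.D:.4f} µm²/s, intercept = {est.intercept:.5f} µm² "
          f"(r² = {est.r_squared:.3f})")

print(f"true D_free = {spec.D_free} µm²/s; localization offset 4σ² = "
      f"{4 * spec.localization_sd**2:.5f} µm²")
print("-> the free population recovers D from the MSD slope/4; the immobile")
print("   population's apparent D collapses to ~0, with only the static")
print("   localization-noise offset left in the intercept.")
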