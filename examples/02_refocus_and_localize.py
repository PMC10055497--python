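"""Shift-and-add refocusing localises a point source in depth.

Renders a synthetic PSF at z = +125 um, extracts the 9 lenslet views and
refocuses them over the 24-slice grid.  The slice whose peak is maximal is
where the parallax of the 9 views cancels -- the source's true depth.
"""
import numpy as np

import sbrnet as sn

config = sn.OpticsConfig().desk(grid_px=96, view_px=32, lenslet_pitch_px=30,
                                fov_diameter_um=100.0)
disparity = sn.DisparityModel.from_config(config,
                                          slope_magnitude_px_per_um=0.02)

z_true = 125.0
frame = sn.synth_psf_plane(config, disparity, z_true)
views = sn.extract_views(frame, config, disparity)
vol = sn.refocus(views, disparity, config.recon_z_um)

peaks = vol.slices.max(axis=(1, 2))
best = int(np.argmax(peaks))
print(f"true source depth     : {z_true:+.0f} um")
print(f"sharpest slice        : z = {config.recon_z_um[best]:+.0f} um")
print(f"peak ratio best/worst : {peaks.max() / peaks.min():.2f}")
print()
print("Refocusing shifts each view against its depth-dependent parallax and")
print("averages; only at the source depth do all 9 spots align, so the peak")
print("identifies the emitter's axial position to within one 25 um slice.")
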