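"""Train a small reconstruction network and score it against the baseline.

Generates a few desk-scale scattering pairs, trains a reduced dual-branch
network for a handful of epochs (enough to show learning, far short of a
converged model), then reconstructs a held-out attenuated phantom and
compares detection F1 with the background-removal + refocus + threshold
baseline.  Expect modest absolute numbers at this tiny scale; the point is
the relative behaviour and the mechanics of the full loop.
"""
import numpy as np

import sbrnet as sn
from sbrnet.volume import emitter_voxel_coords

sim = sn.SimulationConfig.desk(n_pairs=8, seed=3, density_mean=2000)
pairs = sn.generate_pairs(sim)
print(f"generated {len(pairs)} pairs, SBR in "
      f"[{min(p['meta']['sbr'] for p in pairs):.2f}, "
      f"{max(p['meta']['sbr'] for p in pairs):.2f}]")

model = sn.build_network(sn.NetworkSpec.desk(2, 8), seed=0)
config = sn.TrainConfig(epochs=10, patch_px=32, batch=4, seed=0, lr=3e-3,
                        target="binarized", steps_per_epoch=10,
                        schedule_period=10)
model, history = sn.train(model, pairs, config)
stats = history["stats"]
print(f"train loss {history['train_loss'][0]:.3f} -> "
      f"{history['train_loss'][-1]:.3f}; "
      f"best val {history['best_val_loss']:.3f}")

# held-out attenuated phantom at a fixed SBR
oc = sim.optics
disp = sn.DisparityModel.from_config(oc)
psf = sn.synth_psf_stack(oc, disp)
rng = np.random.default_rng(99)
pair = sn.generate_pair(sim, psf, disp, rng, density_mean=2000,
                        attenuation=sn.AttenuationParams(160.0),
                        add_noise=True, sbr=2.0)
gt = emitter_voxel_coords(pair["emitters"], oc)
gt[:, 1:] -= oc.grid_px // 2 - oc.view_px // 2
gt = gt[((gt[:, 1:] >= 0) & (gt[:, 1:] < oc.view_px)).all(axis=1)]

vol = sn.reconstruct(model, pair["views"], pair["refocused"], stats)
net = sn.match_detections(sn.detect_emitters(vol, 0.5), gt, 24)

frame = sn.remove_background(pair["frame"])
views = sn.extract_views(frame, oc, disp)
ref = sn.refocus(views, disp, oc.recon_z_um)
base_vol = ref.slices / max(ref.slices.max(), 1e-12)
base = sn.match_detections(sn.detect_emitters(base_vol, 0.5), gt, 24)

print(f"network  : P={net.precision:.2f} R={net.recall:.2f} F1={net.f1:.2f}")
print(f"baseline : P={base.precision:.2f} R={base.recall:.2f} F1={base.f1:.2f}")
print()
print("F1 counts an emitter as recovered only if a detection lands within")
print("2 px laterally and 1 slice axially of its true position.  At these")
print("few epochs the network may still trail the baseline; the acceptance")
print("suite trains ~20x longer, where the ordering reverses.")
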