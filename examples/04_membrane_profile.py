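"""Local vs bulk membrane structure around a barrel protein.

Generates five replicas of a synthetic coarse-grained bilayer with 12 A
of thinning and increased chain disorder imposed at the barrel's seam
residue (808), then profiles phosphate thickness and per-bond order
parameters for the seam annulus, the opposite side of the barrel (613),
and bulk lipid.
"""

from foldkit import profile_trajectories
from foldkit.synthetic import BilayerSpec, generate_bilayer_trajectories

spec = BilayerSpec(chain_beads=4, thinning_depth=12.0,
                   cone_angle_seam_deg=50.0, n_frames=30, n_replicas=5,
                   seed=11)
trajectories, truth = generate_bilayer_trajectories(spec)
profile = profile_trajectories(trajectories, anchors=[808, 613],
                               burn_in_fraction=1 / 6)

print(f"{spec.n_replicas} replicas x {spec.n_frames} frames, "
      f"{trajectories[0].frames[0].n_lipids} lipids, "
      f"ground truth: bulk {truth.bulk_thickness:.1f} A, "
      f"seam {truth.seam_thickness:.1f} A")
for name, label in (("near_808", "seam (808)"), ("near_613", "opposite (613)"),
                    ("bulk", "bulk (>30 A)")):
    sel = profile.selections[name]
    orders = ", ".join(f"{b}: {m:.2f}" for b, m in sel.order_mean.items())
    print(f"{label:15s} thickness {sel.thickness_mean:5.1f} +/- "
          f"{sel.thickness_sd:.2f} A | S: {orders}")
print("Thinning and lower order parameters at the seam, absent on the "
      "opposite side, reproduce the local membrane perturbation a barrel's "
      "lateral gate imposes.")
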