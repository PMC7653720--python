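"""Pairwise Bhattacharyya overlap of home ranges and the spatial network.

Computes AKDE home ranges for a few birds per group, the full pairwise
Bhattacharyya coefficient matrix (0 = disjoint ranges, 1 = identical),
and summarises within- vs between-group overlap — the clustering that
shows relocated birds sitting between the two resident groups.
"""

import colonyforage as cf

cfg = cf.SimulationConfig(
    seed=5, n_birds_per_group={"zb_zb": 3, "vl_vl": 3, "zb_vl": 3},
    n_days=8)
ds = cf.simulate_tracks(cfg)

fits, hrs = {}, {}
for bird, traj in ds.fixes.groupby("bird_id"):
    fits[bird] = cf.fit_ou(traj)
    hrs[bird] = cf.akde(fits[bird], cell_km=1.0)

ov = cf.pairwise_overlap(hrs)
print(f"{len(ov)} pairwise overlaps among {len(hrs)} birds")
print()
print("mean Bhattacharyya coefficient by group pair:")
print(cf.clustering_summary(ov, ds.birds).round(3).to_string(index=False))
print()
print("Residents of the two colonies barely overlap; relocated birds "
      "(zb_vl) share\nground with both — the intermediate position seen "
      "in the overlap network.")
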