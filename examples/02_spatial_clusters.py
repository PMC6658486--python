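"""Spatial Gaussian-mixture clustering with AIC model selection.

Samples individuals from blobs along a short coastline, fits mixtures with
4, 5 and 6 initial components (10 seeded runs each) and keeps the
minimum-AIC model, as one would for geo-referenced field collections.
"""

import numpy as np

import patchkin as pk

rng = np.random.default_rng(0)
centers = np.arange(6)[:, None] * np.array([300.0, 250.0])  # meters, SW->NE
xy = np.vstack([c + rng.normal(0, 30.0, size=(80, 2)) for c in centers])
lon = 2.80 + np.degrees(xy[:, 0] / (6_371_000 * np.cos(np.radians(41.67))))
lat = 41.67 + np.degrees(xy[:, 1] / 6_371_000)

points = pk.project_coordinates([f"fish{k}" for k in range(len(xy))], lon, lat)
clustering = pk.select_clustering(points, K_list=(4, 5, 6), runs_per_K=10, seed=7)

print(f"chosen model: {clustering.n_clusters} effective components, "
      f"AIC = {clustering.fit.aic:.1f}")
print("cluster sizes (labels ordered SW->NE):",
      np.bincount(clustering.labels)[1:].tolist())
print("\nall candidates (K_init, best AIC):")
best = clustering.candidates.groupby("K_init")["aic"].min()
for k, aic in best.items():
    print(f"  K={k}: {aic:.1f}")
print("the 6-component model wins because the data contain 6 planted blobs.")
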