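"""Fit cohort confidence ellipses on the published per-line medians and
classify an undiagnosed line.

Run:  python examples/cohort_clustering.py
"""

from cilioscope import assign_cluster, ellipses_overlap, fit_cohort_model, plot_cohort
from cilioscope.reference import reference_lines

df = reference_lines()
df = df[df["group"].isin(["control", "ATD", "CED"])]
groups = {g: sub[["length_um", "ift_um2"]].to_numpy(float)
          for g, sub in df.groupby("group")}

model = fit_cohort_model(groups)
for name, g in model.groups.items():
    print(f"{name:8s} centroid ({g.centroid[0]:.2f} µm, {g.centroid[1]:.2f} µm²), "
          f"n = {g.n_lines}")
print("ATD and CED 0.9 ellipses overlap:",
      ellipses_overlap(model, "ATD", "CED", 0.9))

# an undiagnosed line with short cilia and a large IFT88 accumulation
point = (2.60, 0.95)
res = assign_cluster(point, model)
print(f"\nnew line at {point}: assigned to {res.label}")
for g, d in res.distances.items():
    inside = "inside" if res.inside_09[g] else "outside"
    print(f"  {g:8s} Mahalanobis {d:6.2f}  ({inside} the 0.9 ellipse)")

plot_cohort(model, groups, "cohort_clusters.png",
            extra={"new line": point})
print("\nwrote cohort_clusters.png (dots = per-line medians, "
      "ellipses = 0.5 and 0.9 confidence regions)")
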