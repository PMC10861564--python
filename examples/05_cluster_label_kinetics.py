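"""Cluster compounds by their label-enrichment kinetics.

Fifteen synthetic compounds label with first-order rates 1.0, 0.3 or
0.05 per hour.  k-means on the nmol-labeled trajectories recovers the three
kinetic groups exactly; PCA gives the 2-D overview.
"""

from sklearn.metrics import adjusted_rand_score

from isoscope.clustering import build_trajectories, kmeans_cluster, pca_project
from isoscope.synthetic import three_group_trajectories

metrics, truth = three_group_trajectories(
    n_per_group=5, rates_per_h=(1.0, 0.3, 0.05), seed=0
)
traj = build_trajectories(metrics, metric="nmol_labeled")
km = kmeans_cluster(traj, k=3, seed=0)
pca = pca_project(traj)

ari = adjusted_rand_score(truth[traj.compounds], km.labels)
print(f"k-means (k=3) on {len(traj.compounds)} compounds: ARI vs truth = {ari:.1f}")
print(f"silhouette = {km.silhouette:.3f}; PC1 explains "
      f"{pca.explained_variance_ratio[0]*100:.1f}% of variance\n")

print("cluster centroids (nmol labeled, cluster 0 = fastest):")
print(km.centroids.round(2).to_string())
print("\nmembership:")
for c in range(km.k):
    members = [name for name, lab in km.labels.items() if lab == c]
    print(f"  cluster {c}: {', '.join(members)}")
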