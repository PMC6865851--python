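"""Principal component analysis of binary clinical phenotype profiles.

41 antibody-negative patients x 36 binary clinical features, with three
latent groups of sizes 6 / 14 / 21. PCA on the scaled matrix separates the
groups; held-out patients are placed by projecting into the trained space.
"""

import numpy as np

from chemoclass import assign_clusters, fit_pca, loadings_table, project
from chemoclass.synth import PhenotypeConfig, generate_binary_phenotypes

matrix, truth = generate_binary_phenotypes(PhenotypeConfig(seed=3))
model = fit_pca(matrix, n_components=2)

print(f"Phenotype matrix: {matrix.values.shape[0]} patients x "
      f"{matrix.values.shape[1]} binary features")
print(f"PC1 / PC2 explain {model.explained_variance_fraction[0]:.1%} / "
      f"{model.explained_variance_fraction[1]:.1%} of the variance")

top = loadings_table(model).query("component == 1").head(3)
print("Features driving PC1:",
      ", ".join(f"{r.feature_name} ({r.loading:+.2f})" for r in top.itertuples()))

clusters = assign_clusters(model.scores, k=3, seed=0)
print(f"k-means on the score plane recovers groups of sizes "
      f"{sorted(np.bincount(clusters).tolist(), reverse=True)} (true: [21, 14, 6])")

new, new_truth = generate_binary_phenotypes(
    PhenotypeConfig(cluster_sizes=(5, 5, 5), seed=4)
)
proj = project(model, new)
centroids = np.vstack([model.scores[truth == c].mean(0) for c in range(3)])
nearest = np.argmin(((proj[:, None] - centroids[None]) ** 2).sum(-1), axis=1)
print(f"Held-out patients land nearest their own group centroid "
      f"{(nearest == new_truth).mean():.0%} of the time")
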