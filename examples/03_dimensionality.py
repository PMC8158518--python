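"""How many principal components carry signal rather than noise?

After the square-root transform and autoscaling, the eigenvalues of the
sample correlation matrix are tested sequentially against the Tracy-Widom
null for the largest eigenvalue of a white Wishart matrix (alpha = 0.001).
The count of significant components estimates the data's dimensionality.
"""

import liponet as lp
from liponet.preprocess import preprocess_matrix

table = lp.generate_cohort(seed=7)
X = preprocess_matrix(table).to_numpy()
model = lp.fit_pca(X)
report = lp.tracy_widom_count(model.eigenvalues, n=X.shape[0], m=X.shape[1],
                              alpha=0.001)

print(f"top five eigenvalues: {model.eigenvalues[:5].round(2)}")
print(f"significant components at alpha=0.001: {report.n_significant}")
print("(the class-block correlation structure of the synthetic cohort puts "
      "most of the variance on a handful of components; the count says how "
      "many eigenvalues exceed what uncorrelated variables could produce)")
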