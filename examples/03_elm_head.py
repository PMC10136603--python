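"""Fit the extreme learning machine and compare with shallow heads.

The ELM draws one random hidden projection and solves its output weights
in closed form by ridge regression — no gradient descent.
"""

import numpy as np

from eegcube.heads import (GridSearchSpec, elm_fit, elm_predict, fit_shallow,
                           grid_search, predict_shallow)

rng = np.random.default_rng(0)
n = 300
x = np.vstack([rng.normal(0, 1, (n // 2, 8)), rng.normal(2.5, 1, (n // 2, 8))])
y = np.repeat([0, 1], n // 2)

model = elm_fit(x, y, hidden_width=200, ridge=1e-3, seed=0)
labels, scores = elm_predict(model, x)
print(f"ELM (L=200, lambda=1e-3): training accuracy {(labels == y).mean():.3f}")
print(f"beta solves (H'H + lambda I) beta = H'Y; shape {model.beta.shape}")

for kind in ("knn", "svm", "rf", "xgb"):
    head = fit_shallow(kind, x, y, seed=0)
    acc = (predict_shallow(head, x) == y).mean()
    print(f"{kind:4s} training accuracy {acc:.3f}")

res = grid_search(GridSearchSpec("knn", {"n_neighbors": [1, 5, 25]}, seed=0), x, y)
print(f"grid search over k: best {res.best_params} "
      f"(validation accuracy {res.best_score:.3f})")
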