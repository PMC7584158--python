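"""Synthetic minority oversampling (SMOTE family) for training folds.

Synthetic rows are convex combinations ``x + u * (x' - x)`` of a minority
sample ``x`` and one of its k nearest minority neighbours ``x'`` with
``u ~ U(0, 1)``, generated until every class matches the majority count.
The SVM variant seeds interpolation only from minority samples that lie on
the decision boundary (support vectors of an SVC fit on the training
fold), concentrating synthesis where classes meet.

Oversampling is a training-only transform: callers must never pass test
rows through it.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = ["oversample"]


def oversample(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "smote",
    k_neighbors: int = 5,
    random_state: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by appending synthetic minority rows.

    Parameters
    ----------
    X, y
        Training feature matrix and labels.  Returned untouched (same
        array content, originals first) with synthetic rows appended.
    method
        "none" (identity), "smote", or "svmsmote".
    k_neighbors
        Neighbourhood size for interpolation; shrunk with a log message
        when a minority class is smaller.
    """
    if method == "none":
        return X, y
    if method not in {"smote", "svmsmote"}:
        raise ValueError(f"unknown oversampling method {method!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires at least 2 classes")
    rng = (random_state if isinstance(random_state, np.random.Generator)
           else np.random.default_rng(random_state))
    target = counts.max()

    sv_mask = None
    if method == "svmsmote":
        svc = SVC(kernel="rbf", random_state=0)
        svc.fit(X, y)
        sv_mask = np.zeros(len(y), dtype=bool)
        sv_mask[svc.support_] = True

    new_X: list[np.ndarray] = []
    new_y: list[np.ndarray] = []
    for cls, count in zip(classes, counts):
        n_new = int(target - count)
        if n_new == 0:
            continue
        idx = np.flatnonzero(y == cls)
        Xc = X[idx]
        if len(Xc) == 1:
            logger.info("class %r has a single sample; replicating it", cls)
            new_X.append(np.repeat(Xc, n_new, axis=0))
            new_y.append(np.repeat(cls, n_new))
            continue
        k = min(k_neighbors, len(Xc) - 1)
        if k < k_neighbors:
            logger.info("class %r: neighbourhood shrunk from %d to %d",
                        cls, k_neighbors, k)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, neigh = nn.kneighbors(Xc)  # column 0 is the point itself
        if method == "svmsmote":
            seed_pool = np.flatnonzero(sv_mask[idx])
            if len(seed_pool) == 0:
                logger.info("class %r: no support vectors; seeding from all rows", cls)
                seed_pool = np.arange(len(Xc))
        else:
            seed_pool = np.arange(len(Xc))
        seeds = rng.choice(seed_pool, size=n_new, replace=True)
        picks = rng.integers(1, k + 1, size=n_new)
        partners = neigh[seeds, picks]
        u = rng.random(n_new)[:, None]
        synth = Xc[seeds] + u * (Xc[partners] - Xc[seeds])
        new_X.append(synth)
        new_y.append(np.repeat(cls, n_new))

    if not new_X:
        return X, y
    return np.vstack([X, *new_X]), np.concatenate([y, *new_y])
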