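"""Correlation-matrix PCA of water-chemistry variables.

Water-quality variables are measured in incompatible units (conductivity in
uS/cm, ions in mg/L, pH unitless), so the default analysis standardises
each variable (correlation PCA); eigenvalues then sum to the number of
variables and "percent variance" has its usual meaning.  The decomposition
is computed by singular-value decomposition of the standardised data
matrix.  Loading signs are fixed so the largest-magnitude loading of each
component is positive, making reported loadings reproducible (the sign of
an eigenvector is otherwise arbitrary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PCAError(ValueError):
    pass


@dataclass
class PCAResult:
    variables: list[str]
    eigenvalues: np.ndarray  # descending
    percent_variance: np.ndarray
    loadings: np.ndarray  # (n_variables, n_components), orthonormal columns
    scores: np.ndarray  # (n_samples, n_components)
    sample_index: list  # row labels of retained samples
    centroids: dict = field(default_factory=dict)  # group -> (n_components,)


def run_pca(
    data: pd.DataFrame,
    variables: list[str] | None = None,
    center: bool = True,
    scale: bool = True,
) -> PCAResult:
    """PCA of a samples x variables matrix.

    Rows with missing values are dropped (with a logged count).  With
    ``scale=True`` each variable is divided by its sample standard deviation
    (ddof=1), so eigenvalues are those of the correlation matrix and sum to
    the number of variables.
    """
    if variables is None:
        variables = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    if len(variables) < 2:
        raise PCAError("need at least 2 variables")
    X = data[variables]
    keep = ~X.isna().any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("run_pca: dropped %d rows with missing values", dropped)
    X = X.loc[keep]
    if X.shape[0] < 2:
        raise PCAError("need at least 2 complete samples")
    M = X.to_numpy(dtype=float)
    n = M.shape[0]
    if center:
        M = M - M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=1)
        zero = [v for v, s in zip(variables, sd) if s == 0]
        if zero:
            raise PCAError(f"zero-variance variables with scale=True: {zero}")
        M = M / sd
    _u, s, vt = np.linalg.svd(M, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T
    scores = M @ loadings
    # sign convention: largest-magnitude loading per component is positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total = eigenvalues.sum()
    percent = 100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return PCAResult(
        variables=list(variables),
        eigenvalues=eigenvalues,
        percent_variance=percent,
        loadings=loadings,
        scores=scores,
        sample_index=list(X.index),
    )


def group_separation(result: PCAResult, grouping) -> dict:
    """Group centroids and pairwise per-axis centroid distances.

    *grouping* maps each retained sample label to a group key (e.g.
    ``(site, epoch)``).  Returns ``{"centroids": {group: vector},
    "distances": {(g1, g2): |centroid difference| per component}}``.  No
    significance test is attached.
    """
    labels = [grouping[i] for i in result.sample_index]
    groups = sorted(set(labels), key=repr)
    centroids = {}
    for g in groups:
        mask = np.array([lab == g for lab in labels])
        if not mask.any():
            raise PCAError(f"group {g!r} has no samples")
        centroids[g] = result.scores[mask].mean(axis=0)
    distances = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            distances[(g1, g2)] = np.abs(centroids[g1] - centroids[g2])
    result.centroids = centroids
    return {"centroids": centroids, "distances": distances}
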