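"""PCA of spot volumes with gels as observations.

Used to check whether replicate gels cluster by group when only the
differentially abundant spots are considered.  Missing entries are imputed
as 0 before decomposition: absence of a spot is informative (group-unique
spots are strong separators), and 0 is the natural volume of an undetected
spot.  Columns are always mean-centered; unit-variance scaling (PCA on the
correlation rather than covariance matrix) is optional and off by default.
Component signs are fixed by forcing the largest-magnitude loading of each
component to be positive, making results reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import ExperimentDesign, SpotVolumeTable
from .errors import ValidationError


@dataclass
class PCAResult:
    """Scores (gels x components), loadings (spots x components), variance."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    mean_: np.ndarray
    scale_: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def variance_first_two(self) -> float:
        """Fraction of total variance carried by PC1+PC2 (in [0, 1])."""
        return float(self.variance_fraction[: min(2, self.n_components)].sum())


def run_pca(
    table: SpotVolumeTable,
    design: ExperimentDesign | None = None,
    scale: bool = False,
    n_components: int | None = None,
) -> PCAResult:
    """Singular-value decomposition PCA of the gels x spots matrix.

    ``table`` is typically restricted to the significant spots beforehand.
    With ``n_components=None`` all components are kept and the variance
    fractions sum to 1.
    """
    if table.n_gels < 2:
        raise ValidationError("PCA needs at least 2 observations (gels)")
    if design is not None:
        design.check_table(table)
    X = table.volumes.T.fillna(0.0).to_numpy(dtype=float)
    scale_ = None
    if scale:
        sd = X.std(axis=0, ddof=1)
        scale_ = np.where(sd > 0, sd, 1.0)
        X = X / scale_
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.gel_ids, columns=comps),
        loadings=pd.DataFrame(loadings, index=table.spot_ids, columns=comps),
        variance_fraction=pca.explained_variance_ratio_.copy(),
        mean_=pca.mean_.copy(),
        scale_=scale_,
    )


def group_silhouette(result: PCAResult, design: ExperimentDesign,
                     n_components: int = 2) -> float:
    """Mean silhouette of the gel scores grouped by design label.

    Positive values mean replicate gels sit closer to their own group than
    to other groups in the first ``n_components`` score dimensions.
    """
    from sklearn.metrics import silhouette_score

    labels = design.assignment.loc[result.scores.index, "group"].to_numpy()
    k = min(n_components, result.n_components)
    return float(silhouette_score(result.scores.iloc[:, :k], labels))
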