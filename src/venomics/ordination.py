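"""PCA of toxin feature matrices: scores, loadings, and driver masses.

The decomposition is a plain SVD of the (optionally centred and unit-scaled)
samples × features matrix, with a deterministic sign convention: within each
component, the loading of largest magnitude is made positive. Loadings
identify which toxin masses drive each component, and a simple separation
statistic (mean between-group minus mean within-group pairwise distance in
score space) quantifies the clustering that ordination plots show visually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import GroupingError, ValidationError
from .feature_matrix import FeatureMatrix

__all__ = [
    "OrdinationResult",
    "run_pca",
    "top_loading_features",
    "cluster_separation",
]


@dataclass
class OrdinationResult:
    """PCA output: scores (samples × PCs), loadings (features × PCs), variance."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    preprocessing: dict
    feature_meta: pd.DataFrame | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def write_csv(self, outdir: str | Path, prefix: str = "pca") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(outdir / f"{prefix}_scores.csv")
        self.loadings.to_csv(outdir / f"{prefix}_loadings.csv")
        pd.DataFrame(
            {
                "component": list(self.scores.columns),
                "explained_variance_ratio": self.explained_variance_ratio,
            }
        ).to_csv(outdir / f"{prefix}_variance.csv", index=False)


def run_pca(
    matrix: FeatureMatrix,
    n_components: int = 2,
    center: bool = True,
    scale: bool = False,
) -> OrdinationResult:
    """Principal component analysis of a feature matrix by SVD.

    Parameters
    ----------
    matrix
        Feature matrix; samples become observations (matrix columns), toxin
        features become variables.
    n_components
        Number of components to retain (clipped to the available rank bound,
        ``min(samples − 1, features)`` when centred).
    center, scale
        Subtract feature means / divide by feature standard deviations.
        Scaling a zero-variance feature is refused with an error naming the
        constant features.
    """
    X = matrix.values.to_numpy().T.astype(float)  # samples x features
    sample_ids = list(matrix.values.columns)
    feature_ids = list(matrix.values.index)
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise ValidationError("PCA requires at least 2 samples")
    if n_features < 1:
        raise ValidationError("PCA requires at least 1 feature")

    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        constant = [feature_ids[i] for i in np.flatnonzero(sd == 0)]
        if constant:
            raise ValidationError(
                f"cannot unit-scale zero-variance features: {constant}"
            )
        X = X / sd

    rank_bound = min(n_samples - 1 if center else n_samples, n_features)
    k = max(1, min(n_components, rank_bound))

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    s = s[:rank_bound]
    U = U[:, :rank_bound]
    Vt = Vt[:rank_bound]

    total = float((s**2).sum())
    evr = (s**2 / total) if total > 0 else np.zeros_like(s)

    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(rank_bound):
        pivot = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]

    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    comp_labels = [f"PC{j + 1}" for j in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=sample_ids, columns=comp_labels),
        loadings=pd.DataFrame(loadings, index=feature_ids, columns=comp_labels),
        explained_variance_ratio=evr[:k],
        preprocessing={"transform": matrix.transform, "center": center, "scale": scale},
        feature_meta=matrix.features.set_index("feature_id"),
    )


def top_loading_features(result: OrdinationResult, component: int = 1, k: int = 10) -> pd.DataFrame:
    """The k features with the largest |loading| on a component (1-based).

    Ties in |loading| are broken toward the lower consensus mass, keeping the
    ranking deterministic. Returns a frame with feature_id, loading, and the
    consensus mass when available.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not 1 <= component <= result.n_components:
        raise IndexError(
            f"component {component} out of range 1..{result.n_components}"
        )
    col = f"PC{component}"
    df = pd.DataFrame(
        {
            "feature_id": result.loadings.index,
            "loading": result.loadings[col].to_numpy(),
        }
    )
    if result.feature_meta is not None and "consensus_mass_da" in result.feature_meta:
        df["consensus_mass_da"] = result.feature_meta.loc[
            df["feature_id"], "consensus_mass_da"
        ].to_numpy()
    else:
        df["consensus_mass_da"] = np.nan
    df["abs_loading"] = df["loading"].abs()
    df = df.sort_values(
        ["abs_loading", "consensus_mass_da"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df.head(k).drop(columns="abs_loading")


def cluster_separation(
    result: OrdinationResult,
    grouping: Mapping[str, str] | pd.Series,
) -> float:
    """Mean between-group minus mean within-group pairwise distance in score space.

    Distances are Euclidean over the first two components (or one, if only
    one was retained). Positive values mean the grouping is separated. With
    no within-group pair at all (all singleton groups) the within term is 0.
    """
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_dict()
    sample_ids = list(result.scores.index)
    missing = [s for s in sample_ids if s not in grouping]
    if missing:
        raise GroupingError(f"grouping missing samples: {missing}")
    labels = np.array([grouping[s] for s in sample_ids])
    if len(set(labels)) < 2:
        raise GroupingError("cluster separation requires at least two groups")
    k = min(2, result.n_components)
    S = result.scores.to_numpy()[:, :k]
    diff = S[:, None, :] - S[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(sample_ids), k=1)
    within = dist[iu][same[iu]]
    between = dist[iu][~same[iu]]
    within_mean = float(within.mean()) if within.size else 0.0
    between_mean = float(between.mean()) if between.size else 0.0
    return between_mean - within_mean
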