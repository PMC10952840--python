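"""Nonmetric multidimensional scaling of the distance matrix and diagnostics.

The morphospace is visualized by 2-D nMDS: a configuration whose inter-point
distances best preserve the rank order of the observed mean character
differences, found by majorization (SMACOF) with isotonic regression from
multiple random starts. Fit is summarized by Kruskal stress-1 and by the
Shepard-plot r-squared values (nonmetric fit 1 - stress^2; linear fit: squared
correlation between configuration distances and observed dissimilarities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .distance import DistanceMatrix

__all__ = [
    "Ordination",
    "nmds",
    "kruskal_stress",
    "shepard",
    "group_centroid",
    "hull_coverage",
]


@dataclass
class Ordination:
    ids: list[str]
    coordinates: np.ndarray  # (n, k)
    stress: float  # Kruskal stress-1
    k: int
    n_starts: int
    seed: int
    converged: bool = True

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def _monotone_fit(observed: np.ndarray, config_d: np.ndarray) -> np.ndarray:
    """Isotonic (primary-ties) regression of configuration distances on D."""
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    return iso.fit_transform(observed, config_d)


def kruskal_stress(observed: np.ndarray, config_d: np.ndarray) -> float:
    """Kruskal stress-1: sqrt(sum (d - dhat)^2 / sum d^2) over all pairs."""
    dhat = _monotone_fit(observed, config_d)
    denom = float(np.sum(config_d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((config_d - dhat) ** 2) / denom))


def _standardize(coords: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes, and fix signs.

    Sign convention: on each axis the point with the largest absolute
    coordinate is made positive, so output is comparable across runs up to
    the rigid motions nMDS cannot determine.
    """
    x = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for a in range(x.shape[1]):
        i = int(np.argmax(np.abs(x[:, a])))
        if x[i, a] < 0:
            x[:, a] = -x[:, a]
    return x


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-6,
) -> Ordination:
    """Best-of-``n_starts`` nonmetric MDS of a fully defined distance matrix.

    Runs SMACOF with isotonic regression from ``n_starts`` random initial
    configurations and keeps the lowest-stress solution, then standardizes
    the configuration (centered, principal-axis rotated, signed).
    Deterministic given ``seed``.
    """
    from sklearn.manifold import MDS

    if not dm.is_fully_defined:
        raise ValueError("distance matrix has undefined entries; drop taxa first")
    if dm.n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} taxa for a k-D embedding")
    observed = dm.condensed()
    if np.all(observed == 0):
        raise ValueError("degenerate all-zero distance matrix")
    mds = MDS(
        n_components=k,
        metric=False,
        n_init=n_starts,
        max_iter=max_iter,
        eps=eps,
        dissimilarity="precomputed",
        random_state=int(seed) % (2**32),
        normalized_stress=True,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = mds.fit_transform(dm.values)
    coords = _standardize(coords)
    stress = kruskal_stress(observed, pdist(coords))
    converged = bool(getattr(mds, "n_iter_", max_iter) < max_iter)
    if not converged:
        warnings.warn("nMDS did not converge in any start; returning best found")
    return Ordination(
        ids=list(dm.ids),
        coordinates=coords,
        stress=stress,
        k=k,
        n_starts=n_starts,
        seed=seed,
        converged=converged,
    )


def shepard(dm: DistanceMatrix, ordination: Ordination) -> tuple[float, float]:
    """Shepard-diagram fit statistics ``(nonmetric_r2, linear_r2)``.

    Nonmetric r^2 = 1 - (residual SS of the monotone fit) / (total SS of the
    configuration distances, uncentered) = 1 - stress-1 squared. Linear r^2 is
    the squared Pearson correlation between configuration distances and the
    observed dissimilarities.
    """
    if ordination.ids != dm.ids:
        raise ValueError("ordination does not match distance matrix")
    observed = dm.condensed()
    config_d = pdist(ordination.coordinates)
    stress = kruskal_stress(observed, config_d)
    nonmetric_r2 = 1.0 - stress**2
    r = np.corrcoef(observed, config_d)[0, 1]
    return float(nonmetric_r2), float(r**2)


def group_centroid(ordination: Ordination, groups: pd.Series) -> pd.DataFrame:
    """Arithmetic per-axis mean of member coordinates, per group."""
    df = ordination.to_dataframe()
    labels = [groups.get(name) for name in df.index]
    df = df.assign(_group=labels).dropna(subset=["_group"])
    if df.empty:
        raise ValueError("no ordinated taxon carries a group label")
    return df.groupby("_group").mean().rename_axis("group")


def hull_coverage(
    ordination: Ordination,
    subset: list[str],
    reference_subset: list[str] | None = None,
) -> float:
    """Convex-hull area of ``subset`` over the hull area of the reference.

    The reference defaults to all ordinated points (the total morphospace).
    Collinear subsets yield area 0 with a warning.
    """
    if ordination.k != 2:
        raise ValueError("hull coverage is defined for 2-D ordinations")
    coords = ordination.to_dataframe()
    if reference_subset is None:
        reference_subset = list(ordination.ids)

    def _area(names: list[str]) -> float:
        if len(names) < 3:
            raise ValueError("hull needs >= 3 points")
        pts = coords.loc[names].to_numpy()
        try:
            return float(ConvexHull(pts).volume)  # 2-D: volume == area
        except QhullError:
            warnings.warn("collinear point subset; hull area is 0")
            return 0.0

    ref_area = _area(reference_subset)
    if ref_area == 0:
        raise ValueError("reference subset is collinear (zero hull area)")
    return _area(list(subset)) / ref_area
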