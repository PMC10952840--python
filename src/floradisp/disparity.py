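"""Disparity metrics per group and disparity-through-time binning.

Metrics, all derived from the pairwise mean character difference D:

* ``meanD`` — mean of the within-group pairwise distances (density of a group
  in the morphospace), with its standard deviation over the same pair set;
* ``maxD`` (the range R) — maximum within-group pairwise distance;
* rarefied ``meanD``/``R`` — the metric recomputed on repeated equal-size
  subsamples to remove sample-size sensitivity;
* ``Ddelta`` — a group's contribution to total disparity, the change in the
  whole-dataset meanD attributable to including the group;
* eccentricity — a taxon's mean distance to all other taxa; large values mark
  morphological outliers at the edge of the occupied morphospace.

Fossils are pooled into stratigraphic time bins (e.g. Early Cretaceous
145-100.5 Ma) by the midpoint of their age range; extant taxa form the
"present" bin; fossils whose midpoint falls outside every bin (e.g. Neogene)
are flagged excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characters import TaxonRecord, TraitMatrix
from .distance import DistanceMatrix, build_distance_matrix

__all__ = [
    "TimeBin",
    "PAPER_TIME_BINS",
    "PRESENT_BIN",
    "EXCLUDED",
    "assign_time_bins",
    "group_disparity",
    "rarefy",
    "ddelta",
    "eccentricity",
]

PRESENT_BIN = "present"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class TimeBin:
    name: str
    max_Ma: float
    min_Ma: float

    def __post_init__(self) -> None:
        if not (self.max_Ma > self.min_Ma >= 0):
            raise ValueError(f"bin {self.name!r}: need max_Ma > min_Ma >= 0")

    def contains(self, age: float) -> bool:
        # half-open (min, max] so adjacent bins do not overlap at shared edges
        return self.min_Ma < age <= self.max_Ma


#: The standard disparity-through-time bins (Ma): Neogene (23.03-0) is absent
#: on purpose, so Neogene-midpoint fossils come out flagged ``excluded``.
PAPER_TIME_BINS = (
    TimeBin("Early Cretaceous", 145.0, 100.5),
    TimeBin("Late Cretaceous", 100.5, 66.0),
    TimeBin("Paleogene", 66.0, 23.03),
)


def assign_time_bins(
    taxa: list[TaxonRecord], bins: tuple[TimeBin, ...] = PAPER_TIME_BINS
) -> pd.Series:
    """Assign each taxon to a time bin (fossils by age-range midpoint).

    Extant taxa map to :data:`PRESENT_BIN`; fossils whose midpoint falls in no
    bin map to :data:`EXCLUDED`; theoretical/ancestor rows map to ``None``.
    """
    for a in bins:
        for b in bins:
            if a is not b and a.contains((b.max_Ma + b.min_Ma) / 2):
                raise ValueError(f"overlapping bins {a.name!r} and {b.name!r}")
    labels: dict[str, str | None] = {}
    for t in taxa:
        if t.status == "extant":
            labels[t.name] = PRESENT_BIN
        elif t.status == "fossil":
            if t.age_range is None:
                raise ValueError(f"fossil {t.name!r} has no age range")
            mid = (t.age_range[0] + t.age_range[1]) / 2
            hit = next((b.name for b in bins if b.contains(mid)), EXCLUDED)
            labels[t.name] = hit
        else:
            labels[t.name] = None
    return pd.Series(labels, name="time_bin")


def _within_pairs(dm: DistanceMatrix, idx: list[int]) -> np.ndarray:
    sub = dm.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return sub[iu]


def _group_indices(dm: DistanceMatrix, groups: pd.Series) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i, name in enumerate(dm.ids):
        g = groups.get(name)
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        out.setdefault(str(g), []).append(i)
    return out


def group_disparity(dm: DistanceMatrix, groups: pd.Series) -> pd.DataFrame:
    """Per-group n, meanD, sdD and maxD over within-group pairwise distances.

    ``groups`` maps taxon name -> group label; taxa absent from the mapping
    (or labelled None) are ignored. Every group must have >= 2 members in the
    distance matrix. SD is the sample standard deviation over the C(n, 2)
    pairwise values (a single pair yields SD 0).
    """
    rows = []
    for g, idx in sorted(_group_indices(dm, groups).items()):
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 taxa in the matrix")
        pairs = _within_pairs(dm, idx)
        if np.any(np.isnan(pairs)):
            raise ValueError(f"group {g!r} contains undefined distances")
        rows.append(
            {
                "group": g,
                "n": len(idx),
                "meanD": float(pairs.mean()),
                "sdD": float(pairs.std(ddof=1)) if pairs.size > 1 else 0.0,
                "maxD": float(pairs.max()),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def rarefy(
    matrix: TraitMatrix,
    groups: pd.Series,
    metric: str = "meanD",
    reps: int = 1000,
    seed: int = 0,
    n: int | None = None,
) -> pd.DataFrame:
    """Rarefied per-group metric distributions.

    Per replicate and group, ``n`` taxa (default: smallest group size minus
    one) are sampled without replacement, the distance matrix is recomputed on
    the subsample, and the metric (``"meanD"`` or ``"R"``/``"maxD"``) is taken
    over the defined within-group pairs. Returns a long-format frame
    (group, replicate, value). Deterministic given ``seed``.
    """
    if metric not in ("meanD", "R", "maxD"):
        raise ValueError(f"unknown metric {metric!r}")
    members: dict[str, list[str]] = {}
    for name in matrix.taxon_names:
        g = groups.get(name)
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        members.setdefault(str(g), []).append(name)
    sizes = {g: len(v) for g, v in members.items()}
    smallest = min(sizes.values())
    if n is None:
        n = smallest - 1
    if n < 2:
        raise ValueError("rarefaction needs subsample size >= 2 (smallest group >= 3)")
    if n > smallest:
        raise ValueError(f"subsample size {n} exceeds smallest group ({smallest})")
    rng = np.random.default_rng(seed)
    records = []
    for g in sorted(members):
        names = members[g]
        for rep in range(reps):
            take = list(rng.choice(names, size=n, replace=False)) if n < len(names) else list(names)
            sub = matrix.subset(take)
            dm = build_distance_matrix(sub, drop_policy="none")
            pairs = dm.condensed()
            pairs = pairs[~np.isnan(pairs)]
            if pairs.size == 0:
                value = np.nan
            elif metric == "meanD":
                value = float(pairs.mean())
            else:
                value = float(pairs.max())
            records.append({"group": g, "replicate": rep, "value": value})
    return pd.DataFrame(records)


def ddelta(dm: DistanceMatrix, groups: pd.Series, target_group: str) -> float:
    """Contribution of ``target_group`` to total disparity.

    Computed as ``Dtot - meanD(dataset without the group)``: positive values
    mean the group's presence raises the whole-dataset mean pairwise
    distance. ``Dtot`` is the meanD over all labelled taxa.
    """
    by_group = _group_indices(dm, groups)
    if target_group not in by_group:
        raise KeyError(target_group)
    labelled = sorted(i for idx in by_group.values() for i in idx)
    rest = sorted(set(labelled) - set(by_group[target_group]))
    if len(rest) < 2:
        raise ValueError("removing the group leaves fewer than 2 taxa")
    d_tot = float(np.nanmean(_within_pairs(dm, labelled)))
    d_without = float(np.nanmean(_within_pairs(dm, rest)))
    return d_tot - d_without


def eccentricity(dm: DistanceMatrix, reference: list[str] | None = None) -> pd.DataFrame:
    """Per-taxon mean distance to all other taxa of the reference set.

    Equivalent to averaging each row of the (reference-restricted) distance
    matrix, excluding the self-distance. Sorted descending; ``rank`` 1 is the
    most eccentric taxon.
    """
    names = reference if reference is not None else list(dm.ids)
    if len(names) < 2:
        raise ValueError("reference set needs >= 2 taxa")
    sub = dm.submatrix(list(names))
    vals = sub.values.copy()
    np.fill_diagonal(vals, np.nan)
    ecc = np.nanmean(vals, axis=1)
    df = (
        pd.DataFrame({"taxon": sub.ids, "eccentricity": ecc})
        .sort_values(["eccentricity", "taxon"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df
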