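"""Mean character difference between taxa on categorical matrices.

The pairwise dissimilarity is a Gower-type index for mixed ordered/unordered
categorical characters: per character, unordered states contribute 0/1 and
ordered states contribute ``|code_i - code_j| / (k - 1)``; the taxon-pair
distance D is the average over the characters observed in *both* taxa. D is
undefined for pairs with no comparable character; such pairs are eliminated by
greedily dropping the taxa involved in the most undefined pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .characters import Cell, CharacterDef, TraitMatrix

__all__ = [
    "DistanceMatrix",
    "char_distance",
    "mean_character_difference",
    "build_distance_matrix",
]

NOT_COMPARABLE = None


@dataclass
class DistanceMatrix:
    """Symmetric taxon x taxon matrix of mean character differences.

    ``values`` uses ``nan`` for undefined entries (no comparable characters);
    ``comparable_counts[i, j]`` is the number of characters compared for the
    pair, zero exactly where the entry is undefined. ``dropped`` logs taxa
    removed to complete the matrix, as ``(name, reason)`` pairs.
    """

    ids: list[str]
    values: np.ndarray
    comparable_counts: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.comparable_counts = np.asarray(self.comparable_counts, dtype=np.int32)
        n = len(self.ids)
        if self.values.shape != (n, n) or self.comparable_counts.shape != (n, n):
            raise ValueError("shape mismatch between ids and matrices")
        if not np.allclose(np.diag(self.values), 0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        vals = self.values
        both = ~np.isnan(vals)
        if not np.array_equal(vals[both], vals.T[both]) or not np.array_equal(
            np.isnan(vals), np.isnan(vals.T)
        ):
            raise ValueError("matrix must be symmetric")
        defined = ~np.isnan(vals)
        if np.any(vals[defined] < -1e-12) or np.any(vals[defined] > 1 + 1e-12):
            raise ValueError("defined distances must lie in [0, 1]")
        off = ~np.eye(n, dtype=bool)
        bad = ((self.comparable_counts == 0) != np.isnan(vals)) & off
        if np.any(bad):
            raise ValueError("comparable_counts == 0 must coincide with undefined D")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_fully_defined(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return not np.any(np.isnan(self.values[off]))

    def index(self, name: str) -> int:
        return self.ids.index(name)

    def submatrix(self, names: list[str]) -> "DistanceMatrix":
        idx = [self.index(n) for n in names]
        return DistanceMatrix(
            [self.ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.comparable_counts[np.ix_(idx, idx)],
            list(self.dropped),
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle (scipy condensed) vector of distances."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "taxon"
        df.to_csv(path)

    def write_drop_log(self, path: str | Path) -> None:
        pd.DataFrame(self.dropped, columns=["taxon", "reason"]).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        counts = np.where(np.isnan(values), 0, 1).astype(np.int32)
        np.fill_diagonal(counts, 0)
        return cls(list(df.index.astype(str)), values, counts)


def char_distance(cell_i: Cell, cell_j: Cell, chardef: CharacterDef) -> float | None:
    """Per-character dissimilarity in [0, 1], or None when not comparable.

    Missing or inapplicable on either side makes the pair not comparable for
    this character. Polymorphic cells must be resolved before distances.
    """
    if cell_i.is_polymorphic or cell_j.is_polymorphic:
        raise ValueError("polymorphic cell reached char_distance; resolve first")
    if cell_i.kind != "observed" or cell_j.kind != "observed":
        return NOT_COMPARABLE
    (a,) = cell_i.states
    (b,) = cell_j.states
    if chardef.ordered:
        return abs(a - b) / (chardef.k - 1)
    return 0.0 if a == b else 1.0


def mean_character_difference(row_i, row_j, character_set) -> float | None:
    """Mean character difference D between two rows of cells.

    ``row_i``/``row_j`` are sequences of :class:`Cell` aligned with
    ``character_set``. Returns None when no character is comparable.
    """
    total = 0.0
    n = 0
    for ci, cj, chardef in zip(row_i, row_j, character_set):
        d = char_distance(ci, cj, chardef)
        if d is not None:
            total += d
            n += 1
    if n == 0:
        return None
    return total / n


def _pairwise(matrix: TraitMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized all-pairs D and comparable counts for a resolved matrix."""
    codes = matrix.codes
    n = matrix.n_taxa
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int32)
    for j, char in enumerate(matrix.character_set):
        v = codes[:, j].astype(np.int32)
        obs = v >= 0
        comparable = obs[:, None] & obs[None, :]
        if char.ordered:
            d = np.abs(v[:, None] - v[None, :]) / (char.k - 1)
        else:
            d = (v[:, None] != v[None, :]).astype(float)
        sums += np.where(comparable, d, 0.0)
        counts += comparable
    with np.errstate(invalid="ignore"):
        values = sums / counts
    values[counts == 0] = np.nan
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(counts, 0)
    return values, counts


def build_distance_matrix(
    matrix: TraitMatrix, drop_policy: str = "greedy_undefined"
) -> DistanceMatrix:
    """All-pairs mean character difference with undefined-entry handling.

    Polymorphism must already be resolved. Under ``drop_policy ==
    "greedy_undefined"``, taxa are removed one at a time — always the taxon
    participating in the most undefined pairs, ties broken alphabetically —
    until every remaining pair is defined; removals are logged. Under
    ``"none"`` undefined entries are kept as ``nan``.
    """
    if matrix.has_polymorphic:
        raise ValueError("resolve polymorphism before building the distance matrix")
    if drop_policy not in ("greedy_undefined", "none"):
        raise ValueError(f"unknown drop policy {drop_policy!r}")
    values, counts = _pairwise(matrix)
    ids = list(matrix.taxon_names)
    dropped: list[tuple[str, str]] = []
    if drop_policy == "greedy_undefined":
        keep = list(range(len(ids)))
        undef = np.isnan(values)
        np.fill_diagonal(undef, False)
        while True:
            sub = undef[np.ix_(keep, keep)]
            per_taxon = sub.sum(axis=1)
            if per_taxon.max(initial=0) == 0:
                break
            worst = per_taxon.max()
            candidates = [keep[i] for i in np.flatnonzero(per_taxon == worst)]
            victim = min(candidates, key=lambda i: ids[i])
            dropped.append(
                (ids[victim], f"undefined D with {int(worst)} other taxa")
            )
            keep.remove(victim)
        if len(keep) < 2:
            raise ValueError("fewer than 2 taxa remain after dropping undefined pairs")
        values = values[np.ix_(keep, keep)]
        counts = counts[np.ix_(keep, keep)]
        ids = [ids[i] for i in keep]
    return DistanceMatrix(ids, values, counts, dropped)
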