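"""Theoretical morphospace: exact counting and constrained random sampling.

The theoretical morphospace of a categorical schema is the set of all state
combinations; its size is the product of per-character state counts (an exact
big integer — for the default 30-character floral schema,
2^17 x 3^8 x 4^3 x 5^2 = 1,375,941,427,200). A random background of distinct
combinations is drawn for ordination; combinations violating applicability
rules never occur because triggered consequence characters are set
inapplicable (and treated as missing downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .characters import (
    INAPPLICABLE,
    CharacterSet,
    TaxonRecord,
    TraitMatrix,
    apply_constraints,
)

__all__ = ["TheoreticalSample", "count_combinations", "sample_theoretical"]


@dataclass
class TheoreticalSample:
    """A without-replacement sample of theoretical state combinations."""

    rows: TraitMatrix
    requested_n: int
    seed: int


def count_combinations(character_set: CharacterSet) -> int:
    """Exact number of unconstrained state combinations (arbitrary precision)."""
    if len(character_set) == 0:
        raise ValueError("empty character set")
    return math.prod(int(c.k) for c in character_set)


def sample_theoretical(
    character_set: CharacterSet, n: int, seed: int
) -> TheoreticalSample:
    """Draw ``n`` distinct theoretical combinations.

    Each character's state is drawn uniformly; rows triggering a constraint
    rule get the consequence characters set inapplicable; duplicate rows
    (after constraint masking) are rejected, so the sample is without
    replacement over constrained combinations. Uniformity is over raw
    pre-masking combinations. Deterministic given ``seed``.

    Raises if the request apparently exceeds the constrained space size
    (detected by a rejection-rate watchdog).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ks = np.array([c.k for c in character_set], dtype=np.int64)
    seen: set[bytes] = set()
    rows: list[np.ndarray] = []
    attempts = 0
    max_attempts = max(10_000, 200 * n)
    batch = max(64, n)
    while len(rows) < n:
        if attempts > max_attempts:
            raise ValueError(
                f"could not draw {n} distinct combinations after {attempts} attempts; "
                "the constrained space is likely smaller than n"
            )
        draw = np.empty((batch, len(ks)), dtype=np.int16)
        for j, k in enumerate(ks):
            draw[:, j] = rng.integers(0, k, size=batch)
        draw = apply_constraints(character_set, draw)
        for row in draw:
            attempts += 1
            key = row.tobytes()
            if key in seen:
                continue
            seen.add(key)
            rows.append(row)
            if len(rows) == n:
                break
    codes = np.vstack(rows)
    taxa = [
        TaxonRecord(name=f"theoretical_{i + 1:04d}", status="theoretical")
        for i in range(n)
    ]
    tm = TraitMatrix(taxa, character_set, codes, {})
    return TheoreticalSample(rows=tm, requested_n=n, seed=seed)
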