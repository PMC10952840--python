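import numpy as np
import pandas as pd
import pytest

from floradisp.characters import (
    CharacterDef,
    CharacterSet,
    TaxonRecord,
    TraitMatrix,
    resolve_polymorphism,
)
from floradisp.distance import build_distance_matrix
from floradisp.synth import SynthConfig, generate_matrix


@pytest.fixture(scope="session")
def toy_schema() -> CharacterSet:
    """Two unordered binaries, one ordered three-state, one unordered three-state."""
    return CharacterSet(
        (
            CharacterDef("c1", states=(0, 1)),
            CharacterDef("c2", states=(0, 1)),
            CharacterDef("c3", states=(0, 1, 2), ordered=True),
            CharacterDef("c4", states=(0, 1, 2)),
        )
    )


def make_matrix(tokens: list[list[str]], schema: CharacterSet, names=None,
                taxa=None) -> TraitMatrix:
    """Build a TraitMatrix from token strings (test helper)."""
    from floradisp.characters import _matrix_from_tokens

    names = names or [f"t{i + 1}" for i in range(len(tokens))]
    df = pd.DataFrame(tokens, index=names, columns=schema.ids)
    return _matrix_from_tokens(df, schema, taxa)


@pytest.fixture(scope="session")
def synthetic_matrix():
    matrix, truth = generate_matrix(SynthConfig(seed=11))
    return matrix, truth


@pytest.fixture(scope="session")
def synthetic_distance(synthetic_matrix):
    matrix, _ = synthetic_matrix
    resolved = resolve_polymorphism(matrix, seed=7)
    dm = build_distance_matrix(resolved)
    groups = pd.Series({t.name: t.group for t in matrix.taxa})
    return resolved, dm, groups
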