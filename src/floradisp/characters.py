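"""Data model and I/O for categorical trait matrices.

A trait matrix is a taxon x character grid of categorical cells. Cells may be
observed (one or several states), missing, or inapplicable. Characters are
defined by a small schema (state codes, ordered flag, organ block) and may be
linked by applicability constraints ("perianth absent" forces the perianth
detail characters to be inapplicable).

Cell token dialect (CSV):

* an integer state code, e.g. ``"2"``;
* ``"?"`` for missing;
* ``"-"`` for inapplicable;
* ``"&"``-joined codes for polymorphism, e.g. ``"0&2"``.

Internally states are stored as an integer code array; the sentinels
:data:`MISSING`, :data:`INAPPLICABLE` and :data:`POLYMORPHIC` mark non-singleton
cells, with polymorphic state sets kept in a side table until they are resolved
by :func:`resolve_polymorphism`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "POLYMORPHIC",
    "ORGAN_BLOCKS",
    "CharacterDef",
    "ConstraintRule",
    "CharacterSet",
    "Cell",
    "TaxonRecord",
    "TraitMatrix",
    "read_matrix",
    "write_matrix",
    "read_nexus",
    "read_groups",
    "read_schema",
    "write_schema",
    "resolve_polymorphism",
    "audit_missing",
    "load_constraints",
    "default_constraints",
    "angiosperm_flower_schema",
]

MISSING = -1
INAPPLICABLE = -2
POLYMORPHIC = -3

ORGAN_BLOCKS = ("flower", "perianth", "androecium", "gynoecium", "pollen")

TAXON_STATUSES = ("extant", "fossil", "theoretical", "ancestor")


@dataclass(frozen=True)
class CharacterDef:
    """Definition of one categorical character.

    State codes must be the contiguous integers ``0..k-1``. For ordered
    characters the code doubles as the rank used in distance scaling.
    """

    id: str
    label: str = ""
    states: tuple[int, ...] = (0, 1)
    state_labels: tuple[str, ...] = ()
    ordered: bool = False
    organ_block: str = "flower"

    def __post_init__(self) -> None:
        k = len(self.states)
        if k < 2:
            raise ValueError(f"character {self.id!r}: needs >= 2 states, got {k}")
        if tuple(self.states) != tuple(range(k)):
            raise ValueError(
                f"character {self.id!r}: state codes must be contiguous 0..k-1, "
                f"got {self.states}"
            )
        if self.state_labels and len(self.state_labels) != k:
            raise ValueError(f"character {self.id!r}: state label count != k")
        if self.organ_block not in ORGAN_BLOCKS:
            raise ValueError(
                f"character {self.id!r}: unknown organ block {self.organ_block!r}"
            )

    @property
    def k(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class ConstraintRule:
    """When ``trigger_char`` takes ``trigger_state``, the ``consequences``
    characters are inapplicable (e.g. no perianth => no perianth merism)."""

    trigger_char: str
    trigger_state: int
    consequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.trigger_char in self.consequences:
            raise ValueError(
                f"constraint on {self.trigger_char!r} cannot force itself inapplicable"
            )
        if not self.consequences:
            raise ValueError("constraint rule with empty consequence list")


@dataclass(frozen=True)
class CharacterSet:
    """An ordered collection of character definitions plus constraint rules."""

    characters: tuple[CharacterDef, ...]
    constraints: tuple[ConstraintRule, ...] = ()

    def __post_init__(self) -> None:
        ids = [c.id for c in self.characters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate character ids")
        known = set(ids)
        for rule in self.constraints:
            if rule.trigger_char not in known:
                raise ValueError(f"constraint trigger {rule.trigger_char!r} unknown")
            for cid in rule.consequences:
                if cid not in known:
                    raise ValueError(f"constraint consequence {cid!r} unknown")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # trigger -> consequence edges must not cycle (DFS, 3-colour)
        edges: dict[str, set[str]] = {}
        for rule in self.constraints:
            edges.setdefault(rule.trigger_char, set()).update(rule.consequences)
        state: dict[str, int] = {}

        def visit(u: str) -> None:
            state[u] = 1
            for v in edges.get(u, ()):
                if state.get(v) == 1:
                    raise ValueError(f"cyclic constraint triggering via {u!r} -> {v!r}")
                if state.get(v, 0) == 0:
                    visit(v)
            state[u] = 2

        for u in list(edges):
            if state.get(u, 0) == 0:
                visit(u)

    def __len__(self) -> int:
        return len(self.characters)

    def __iter__(self):
        return iter(self.characters)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.characters]

    def index(self, char_id: str) -> int:
        for i, c in enumerate(self.characters):
            if c.id == char_id:
                return i
        raise KeyError(char_id)

    def __getitem__(self, char_id: str) -> CharacterDef:
        return self.characters[self.index(char_id)]

    def state_counts(self) -> list[int]:
        return [c.k for c in self.characters]

    def with_constraints(self, constraints: Sequence[ConstraintRule]) -> "CharacterSet":
        return CharacterSet(self.characters, tuple(constraints))


@dataclass(frozen=True)
class Cell:
    """One matrix cell: observed (>= 1 state), missing, or inapplicable."""

    kind: str  # "observed" | "missing" | "inapplicable"
    states: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.kind == "observed":
            if not self.states:
                raise ValueError("observed cell with empty state set")
        elif self.kind in ("missing", "inapplicable"):
            if self.states:
                raise ValueError(f"{self.kind} cell with non-empty state set")
        else:
            raise ValueError(f"unknown cell kind {self.kind!r}")

    @property
    def is_polymorphic(self) -> bool:
        return self.kind == "observed" and len(self.states) > 1


@dataclass(frozen=True)
class TaxonRecord:
    name: str
    status: str = "extant"
    group: str | None = None
    age_range: tuple[float, float] | None = None  # (max_Ma, min_Ma)

    def __post_init__(self) -> None:
        if self.status not in TAXON_STATUSES:
            raise ValueError(f"taxon {self.name!r}: unknown status {self.status!r}")
        if self.status == "fossil":
            if self.age_range is None:
                raise ValueError(f"fossil {self.name!r} lacks an age range")
        if self.age_range is not None:
            hi, lo = self.age_range
            if not (hi >= lo >= 0):
                raise ValueError(
                    f"taxon {self.name!r}: age range must satisfy max >= min >= 0"
                )


class TraitMatrix:
    """Taxon x character grid of categorical cells.

    Parameters
    ----------
    taxa:
        One :class:`TaxonRecord` per row; names must be unique.
    character_set:
        Column schema.
    codes:
        ``(n_taxa, n_characters)`` integer array. Non-negative entries are
        observed monomorphic state codes; ``MISSING``/``INAPPLICABLE`` mark
        empty cells and ``POLYMORPHIC`` marks cells whose state sets live in
        ``polymorphic``.
    polymorphic:
        Mapping ``(row, col) -> tuple of state codes`` for polymorphic cells.
    """

    def __init__(
        self,
        taxa: Sequence[TaxonRecord],
        character_set: CharacterSet,
        codes: np.ndarray,
        polymorphic: Mapping[tuple[int, int], tuple[int, ...]] | None = None,
    ) -> None:
        self.taxa = list(taxa)
        self.character_set = character_set
        self.codes = np.asarray(codes, dtype=np.int16)
        self.polymorphic = dict(polymorphic or {})
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate taxon names: {dupes}")
        n, m = self.codes.shape
        if n != len(self.taxa) or m != len(self.character_set):
            raise ValueError(
                f"grid shape {self.codes.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.character_set)} characters"
            )
        for j, char in enumerate(self.character_set):
            col = self.codes[:, j]
            bad = col[(col >= char.k)]
            if bad.size:
                raise ValueError(
                    f"character {char.id!r}: state code {int(bad[0])} outside 0..{char.k - 1}"
                )
            if np.any((col < 0) & ~np.isin(col, (MISSING, INAPPLICABLE, POLYMORPHIC))):
                raise ValueError(f"character {char.id!r}: unknown sentinel code")
        for (i, j), states in self.polymorphic.items():
            if self.codes[i, j] != POLYMORPHIC:
                raise ValueError(f"polymorphic table entry at ({i},{j}) not flagged in grid")
            if len(states) < 2 or len(set(states)) != len(states):
                raise ValueError(f"polymorphic cell ({i},{j}) needs >= 2 distinct states")
            k = self.character_set.characters[j].k
            if any(not (0 <= s < k) for s in states):
                raise ValueError(f"polymorphic cell ({i},{j}) has out-of-range state")
        n_flagged = int(np.sum(self.codes == POLYMORPHIC))
        if n_flagged != len(self.polymorphic):
            raise ValueError("polymorphic flags and side table disagree")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.character_set)

    @property
    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    @property
    def has_polymorphic(self) -> bool:
        return bool(self.polymorphic)

    def cell(self, i: int, j: int) -> Cell:
        code = int(self.codes[i, j])
        if code == MISSING:
            return Cell("missing")
        if code == INAPPLICABLE:
            return Cell("inapplicable")
        if code == POLYMORPHIC:
            return Cell("observed", frozenset(self.polymorphic[(i, j)]))
        return Cell("observed", frozenset((code,)))

    def taxon_index(self, name: str) -> int:
        for i, t in enumerate(self.taxa):
            if t.name == name:
                return i
        raise KeyError(name)

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(
            list(self.taxa), self.character_set, self.codes.copy(), dict(self.polymorphic)
        )

    def subset(self, names: Iterable[str]) -> "TraitMatrix":
        """Row subset in the given order."""
        idx = [self.taxon_index(n) for n in names]
        codes = self.codes[idx, :]
        poly = {}
        for new_i, old_i in enumerate(idx):
            for (i, j), states in self.polymorphic.items():
                if i == old_i:
                    poly[(new_i, j)] = states
        return TraitMatrix([self.taxa[i] for i in idx], self.character_set, codes, poly)

    def concat(self, other: "TraitMatrix") -> "TraitMatrix":
        """Stack rows of two matrices sharing a character set."""
        if other.character_set.ids != self.character_set.ids:
            raise ValueError("character sets differ")
        codes = np.vstack([self.codes, other.codes])
        poly = dict(self.polymorphic)
        for (i, j), states in other.polymorphic.items():
            poly[(i + self.n_taxa, j)] = states
        return TraitMatrix(self.taxa + other.taxa, self.character_set, codes, poly)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.character_set.ids == other.character_set.ids
            and np.array_equal(self.codes, other.codes)
            and {k: tuple(sorted(v)) for k, v in self.polymorphic.items()}
            == {k: tuple(sorted(v)) for k, v in other.polymorphic.items()}
        )

    # -- serialization ------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Token representation (see module docstring for the dialect)."""
        tokens = np.empty(self.codes.shape, dtype=object)
        tokens[self.codes >= 0] = self.codes[self.codes >= 0]
        tokens = np.where(self.codes >= 0, self.codes.astype(str), tokens)
        tokens[self.codes == MISSING] = "?"
        tokens[self.codes == INAPPLICABLE] = "-"
        for (i, j), states in self.polymorphic.items():
            tokens[i, j] = "&".join(str(s) for s in sorted(states))
        return pd.DataFrame(
            tokens, index=pd.Index(self.taxon_names, name="taxon"), columns=self.character_set.ids
        )


# ---------------------------------------------------------------------------
# token parsing


def _parse_token(token: str, char: CharacterDef) -> tuple[int, tuple[int, ...] | None]:
    token = str(token).strip()
    if token in ("?", "", "nan"):
        return MISSING, None
    if token in ("-", "N/A", "NA"):
        return INAPPLICABLE, None
    parts = token.split("&")
    try:
        states = tuple(sorted({int(p) for p in parts}))
    except ValueError as exc:
        raise ValueError(f"character {char.id!r}: cannot parse token {token!r}") from exc
    for s in states:
        if not (0 <= s < char.k):
            raise ValueError(
                f"character {char.id!r}: state {s} outside declared set 0..{char.k - 1}"
            )
    if len(states) == 1:
        return states[0], None
    return POLYMORPHIC, states


def _matrix_from_tokens(
    tokens: pd.DataFrame,
    character_set: CharacterSet,
    taxa: Sequence[TaxonRecord] | None = None,
) -> TraitMatrix:
    if list(tokens.columns) != character_set.ids:
        if len(tokens.columns) != len(character_set):
            raise ValueError(
                f"matrix has {len(tokens.columns)} characters, schema declares "
                f"{len(character_set)}"
            )
        raise ValueError("matrix column names do not match schema character ids")
    names = [str(n) for n in tokens.index]
    if taxa is None:
        taxa = [TaxonRecord(name) for name in names]
    codes = np.empty(tokens.shape, dtype=np.int16)
    poly: dict[tuple[int, int], tuple[int, ...]] = {}
    for j, char in enumerate(character_set):
        for i, token in enumerate(tokens.iloc[:, j]):
            code, states = _parse_token(token, char)
            codes[i, j] = code
            if states is not None:
                poly[(i, j)] = states
    return TraitMatrix(taxa, character_set, codes, poly)


# ---------------------------------------------------------------------------
# CSV I/O


def read_schema(path: str | Path) -> CharacterSet:
    """Read a character schema CSV (id, label, ordered, states, organ_block).

    ``states`` is a ``;``-separated list of ``code`` or ``code:label`` items.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    chars = []
    for _, row in df.iterrows():
        items = [s for s in str(row["states"]).split(";") if s != ""]
        codes, labels = [], []
        for item in items:
            if ":" in item:
                code, label = item.split(":", 1)
            else:
                code, label = item, ""
            codes.append(int(code))
            labels.append(label)
        chars.append(
            CharacterDef(
                id=row["id"],
                label=row.get("label", ""),
                states=tuple(codes),
                state_labels=tuple(labels) if any(labels) else (),
                ordered=str(row["ordered"]).strip().lower() in ("1", "true", "yes"),
                organ_block=row["organ_block"],
            )
        )
    return CharacterSet(tuple(chars))


def write_schema(character_set: CharacterSet, path: str | Path) -> None:
    rows = []
    for c in character_set:
        if c.state_labels:
            states = ";".join(f"{s}:{l}" for s, l in zip(c.states, c.state_labels))
        else:
            states = ";".join(str(s) for s in c.states)
        rows.append(
            {
                "id": c.id,
                "label": c.label,
                "ordered": c.ordered,
                "states": states,
                "organ_block": c.organ_block,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_groups(path: str | Path) -> list[TaxonRecord]:
    """Read a taxon metadata CSV (taxon, group, status, max_Ma, min_Ma)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        age = None
        if "max_Ma" in df.columns and pd.notna(row.get("max_Ma")):
            age = (float(row["max_Ma"]), float(row["min_Ma"]))
        group = row.get("group")
        records.append(
            TaxonRecord(
                name=str(row["taxon"]),
                status=str(row.get("status", "extant")),
                group=None if pd.isna(group) else str(group),
                age_range=age,
            )
        )
    return records


def read_matrix(
    matrix_file: str | Path,
    schema_file: str | Path,
    groups_file: str | Path | None = None,
) -> TraitMatrix:
    """Read and validate a trait matrix CSV against its schema CSV."""
    character_set = read_schema(schema_file)
    tokens = pd.read_csv(matrix_file, index_col=0, dtype=str).fillna("?")
    names = [str(n) for n in tokens.index]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate taxon names in matrix file: {dupes}")
    taxa: Sequence[TaxonRecord] | None = None
    if groups_file is not None:
        by_name = {t.name: t for t in read_groups(groups_file)}
        taxa = [by_name.get(n, TaxonRecord(n)) for n in names]
    return _matrix_from_tokens(tokens, character_set, taxa)


def write_matrix(matrix: TraitMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path)


def read_nexus(path: str | Path, character_set: CharacterSet | None = None) -> TraitMatrix:
    """Read a NEXUS standard (morphology) matrix, read-only.

    NEXUS ``missing`` maps to missing, ``gap`` to inapplicable, and state
    multisets to polymorphic cells. If no schema is given, an unordered
    schema is inferred with k = (max observed code) + 1 per character.
    """
    import dendropy

    cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    names = [t.label for t in cm.taxon_namespace]
    n_chars = max(len(cm[t]) for t in cm.taxon_namespace)
    max_code = [1] * n_chars

    # dendropy state identities: use the state's member symbols
    parsed: list[list[tuple[int, tuple[int, ...] | None]]] = []
    for t in cm.taxon_namespace:
        prow = []
        for j, state in enumerate(cm[t]):
            if state.is_gap_state:
                prow.append((INAPPLICABLE, None))
            elif state.symbol == "?":
                prow.append((MISSING, None))
            else:
                syms = sorted(int(s.symbol) for s in state.fundamental_states)
                if len(syms) == 1:
                    prow.append((syms[0], None))
                    max_code[j] = max(max_code[j], syms[0])
                else:
                    prow.append((POLYMORPHIC, tuple(syms)))
                    max_code[j] = max(max_code[j], max(syms))
        parsed.append(prow)

    if character_set is None:
        chars = tuple(
            CharacterDef(id=f"char_{j + 1}", states=tuple(range(max(2, mc + 1))))
            for j, mc in enumerate(max_code)
        )
        character_set = CharacterSet(chars)
    codes = np.empty((len(names), n_chars), dtype=np.int16)
    poly: dict[tuple[int, int], tuple[int, ...]] = {}
    for i, prow in enumerate(parsed):
        for j, (code, states) in enumerate(prow):
            codes[i, j] = code
            if states is not None:
                poly[(i, j)] = states
    taxa = [TaxonRecord(n) for n in names]
    return TraitMatrix(taxa, character_set, codes, poly)


# ---------------------------------------------------------------------------
# operations


def resolve_polymorphism(matrix: TraitMatrix, seed: int) -> TraitMatrix:
    """Collapse each polymorphic cell to one of its states, uniformly at random.

    Monomorphic, missing and inapplicable cells are untouched. Deterministic
    given ``seed``; cells are visited in row-major order so results do not
    depend on dict insertion history.
    """
    rng = np.random.default_rng(seed)
    codes = matrix.codes.copy()
    for (i, j) in sorted(matrix.polymorphic):
        states = matrix.polymorphic[(i, j)]
        codes[i, j] = states[rng.integers(len(states))]
    return TraitMatrix(list(matrix.taxa), matrix.character_set, codes, {})


def audit_missing(matrix: TraitMatrix, status: str | Sequence[str] | None = None) -> dict:
    """Count missing+inapplicable (pooled) and polymorphic cells.

    Parameters
    ----------
    status:
        Optional taxon-status filter (e.g. ``"extant"`` or ``("fossil",)``).

    Returns
    -------
    dict with total cells, counts and exact proportions.
    """
    if status is None:
        idx = list(range(matrix.n_taxa))
    else:
        wanted = {status} if isinstance(status, str) else set(status)
        idx = [i for i, t in enumerate(matrix.taxa) if t.status in wanted]
    if not idx:
        raise ValueError("empty taxon subset in audit")
    sub = matrix.codes[idx, :]
    total = sub.size
    n_missing = int(np.sum(sub == MISSING))
    n_inapplicable = int(np.sum(sub == INAPPLICABLE))
    n_poly = int(np.sum(sub == POLYMORPHIC))
    pooled = n_missing + n_inapplicable
    return {
        "n_taxa": len(idx),
        "n_characters": matrix.n_characters,
        "n_cells": total,
        "missing_cells": n_missing,
        "inapplicable_cells": n_inapplicable,
        "missing_or_inapplicable_cells": pooled,
        "missing_or_inapplicable_proportion": pooled / total,
        "polymorphic_cells": n_poly,
        "polymorphic_proportion": n_poly / total,
        "observed_cells": total - pooled,
    }


def write_audit(audit: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(audit, indent=2))


# ---------------------------------------------------------------------------
# constraint rules


def load_constraints(path: str | Path, character_set: CharacterSet) -> CharacterSet:
    """Attach constraint rules from a YAML file to a character set.

    YAML layout::

        rules:
          - trigger: {character: perianth_presence, state: 0}
            inapplicable: [perianth_merism, perianth_phyllotaxis]
    """
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    rules = []
    for item in doc.get("rules", []):
        rules.append(
            ConstraintRule(
                trigger_char=item["trigger"]["character"],
                trigger_state=int(item["trigger"]["state"]),
                consequences=tuple(item["inapplicable"]),
            )
        )
    return character_set.with_constraints(rules)


def apply_constraints(
    character_set: CharacterSet, codes: np.ndarray
) -> np.ndarray:
    """Set consequence characters inapplicable wherever a rule triggers.

    Rules are applied iteratively until a fixed point so that chained rules
    (A=0 forces B off; B=0 would force C off) behave predictably: a rule only
    fires while its trigger character is still observed at the trigger state.
    """
    codes = np.array(codes, dtype=np.int16, copy=True)
    single = codes.ndim == 1
    if single:
        codes = codes[None, :]
    col = {cid: j for j, cid in enumerate(character_set.ids)}
    changed = True
    while changed:
        changed = False
        for rule in character_set.constraints:
            tj = col[rule.trigger_char]
            hit = codes[:, tj] == rule.trigger_state
            if not np.any(hit):
                continue
            for cid in rule.consequences:
                cj = col[cid]
                target = hit & (codes[:, cj] != INAPPLICABLE)
                if np.any(target):
                    codes[target, cj] = INAPPLICABLE
                    changed = True
    return codes[0] if single else codes


# ---------------------------------------------------------------------------
# default 30-character floral schema

# Organ-block composition: 1 whole-flower, 8 perianth, 11 androecium,
# 8 gynoecium, 2 pollen characters; state-count profile 17 binary, 8
# three-state, 3 four-state, 2 five-state. The concrete character list is the
# package's default instance of that schema shape.
_FLOWER_SCHEMA: tuple[tuple[str, str, int, bool, str], ...] = (
    ("flower_sex", "flower", 2, False, "bisexual/unisexual"),
    ("perianth_presence", "perianth", 2, False, "absent/present"),
    ("perianth_phyllotaxis", "perianth", 3, False, "spiral/whorled/irregular"),
    ("perianth_merism", "perianth", 5, True, "dimerous..polymerous"),
    ("perianth_whorls", "perianth", 4, True, "1/2/3/more whorls"),
    ("perianth_differentiation", "perianth", 3, False, "undiff/sepals+petals/other"),
    ("perianth_fusion", "perianth", 2, False, "free/fused"),
    ("perianth_symmetry", "perianth", 3, False, "actinomorphic/zygomorphic/asymmetric"),
    ("perianth_spurs", "perianth", 2, False, "absent/present"),
    ("stamen_number", "androecium", 5, True, "1/2-3/4-5/6-10/>10"),
    ("androecium_phyllotaxis", "androecium", 3, False, "spiral/whorled/irregular"),
    ("androecium_whorls", "androecium", 4, True, "1/2/3/more whorls"),
    ("stamen_fusion", "androecium", 2, False, "free/fused"),
    ("anther_attachment", "androecium", 3, False, "basifixed/dorsifixed/other"),
    ("anther_dehiscence", "androecium", 4, False, "longitudinal/valvate/poricidal/transverse"),
    ("staminodes", "androecium", 2, False, "absent/present"),
    ("anther_orientation", "androecium", 2, False, "introrse/extrorse"),
    ("filament_differentiation", "androecium", 2, False, "undifferentiated/differentiated"),
    ("androecium_perianth_fusion", "androecium", 2, False, "free/fused"),
    ("pollen_sac_number", "androecium", 2, False, "two/four"),
    ("carpel_number", "gynoecium", 3, True, "1/2-5/>5"),
    ("carpel_fusion", "gynoecium", 3, False, "apocarpous/syncarpous/other"),
    ("ovary_position", "gynoecium", 3, True, "superior/half-inferior/inferior"),
    ("style_differentiation", "gynoecium", 2, False, "undifferentiated/differentiated"),
    ("stigma_lobation", "gynoecium", 2, False, "unlobed/lobed"),
    ("ovules_per_carpel", "gynoecium", 2, False, "one/several"),
    ("placentation_axile", "gynoecium", 2, False, "axile/other"),
    ("nectary_presence", "gynoecium", 2, False, "absent/present"),
    ("pollen_aperture_number", "pollen", 2, False, "one/several"),
    ("pollen_aperture_shape", "pollen", 2, False, "colpate/porate"),
)


def angiosperm_flower_schema(with_constraints: bool = True) -> CharacterSet:
    """The default 30-character floral organization schema.

    17 binary + 8 three-state + 3 four-state + 2 five-state characters split
    over the five organ blocks (1 flower, 8 perianth, 11 androecium, 8
    gynoecium, 2 pollen). With ``with_constraints`` the default applicability
    rules (see :func:`default_constraints`) are attached.
    """
    chars = tuple(
        CharacterDef(
            id=cid,
            label=label,
            states=tuple(range(k)),
            ordered=ordered,
            organ_block=block,
        )
        for cid, block, k, ordered, label in _FLOWER_SCHEMA
    )
    cs = CharacterSet(chars)
    if with_constraints:
        cs = cs.with_constraints(default_constraints())
    return cs


def default_constraints() -> tuple[ConstraintRule, ...]:
    """Default applicability rules for the floral schema.

    These mirror the standard logical dependencies of floral organization:
    organ-detail characters are meaningless when the organ is absent or
    undifferentiated.
    """
    return (
        ConstraintRule(
            "perianth_presence",
            0,
            (
                "perianth_phyllotaxis",
                "perianth_merism",
                "perianth_whorls",
                "perianth_differentiation",
                "perianth_fusion",
                "perianth_spurs",
                "androecium_perianth_fusion",
            ),
        ),
        ConstraintRule("perianth_differentiation", 0, ("perianth_spurs",)),
        ConstraintRule("carpel_number", 0, ("carpel_fusion",)),
        ConstraintRule("stamen_number", 0, ("stamen_fusion", "androecium_whorls")),
    )
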