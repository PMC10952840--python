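"""Nonparametric group comparisons and correlation tests.

* Kruskal-Wallis rank test (tie-corrected H, reported as chi-squared) with
  Siegel-Castellan style post hoc mean-rank comparisons summarized as a
  compact letter display;
* PERMANOVA (npMANOVA) on a distance matrix: pseudo-F from sums of squared
  inter-point distances with a label-permutation p-value, plus pairwise tests
  with Bonferroni correction;
* Pearson correlation tests (r, t, df, two-sided p).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distance import DistanceMatrix

__all__ = [
    "KWResult",
    "PermanovaResult",
    "PearsonResult",
    "kruskal_wallis",
    "permanova",
    "pairwise_permanova",
    "pearson_test",
]


@dataclass
class KWResult:
    H: float  # tie-corrected statistic, chi-squared distributed under H0
    df: int
    p: float
    mean_ranks: dict[str, float]
    posthoc: pd.DataFrame  # pairwise |mean-rank difference| vs critical value
    letters: dict[str, str]


@dataclass
class PermanovaResult:
    pseudo_F: float
    r2: float
    p: float
    n_permutations: int
    df_between: int
    df_within: int
    pairwise: pd.DataFrame | None = None


@dataclass
class PearsonResult:
    r: float
    t: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _posthoc_mean_ranks(
    values: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[dict[str, float], pd.DataFrame]:
    """Pairwise mean-rank comparisons with a normal critical difference.

    The critical difference for groups i, j is
    ``z_{alpha / (k (k - 1))} * sqrt(N (N + 1) / 12 * (1 / n_i + 1 / n_j))``
    (two-sided Bonferroni over the k(k-1)/2 pairs).
    """
    names = sorted(values)
    pooled = np.concatenate([values[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for g in names:
        n_g = len(values[g])
        mean_ranks[g] = float(ranks[start : start + n_g].mean())
        start += n_g
    k = len(names)
    z = stats.norm.ppf(1 - alpha / (k * (k - 1))) if k > 1 else np.inf
    rows = []
    for a, b in itertools.combinations(names, 2):
        diff = abs(mean_ranks[a] - mean_ranks[b])
        crit = z * np.sqrt(
            n_total * (n_total + 1) / 12 * (1 / len(values[a]) + 1 / len(values[b]))
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_rank_diff": diff,
                "critical_diff": float(crit),
                "significant": bool(diff > crit),
            }
        )
    return mean_ranks, pd.DataFrame(rows)


def _letter_display(names: list[str], posthoc: pd.DataFrame, mean_ranks: dict[str, float]) -> dict[str, str]:
    """Compact letter display: greedy clique cover of the non-significant graph.

    Groups are visited by descending mean rank (alphabetical tie-break); each
    group joins every existing letter-clique it is compatible with, else opens
    a new letter. Groups sharing a letter are not significantly different.
    """
    nonsig = {frozenset((r.group_a, r.group_b)) for r in posthoc.itertuples() if not r.significant}

    def compatible(g: str, clique: set[str]) -> bool:
        return all(frozenset((g, h)) in nonsig for h in clique)

    order = sorted(names, key=lambda g: (-mean_ranks[g], g))
    cliques: list[set[str]] = []
    for g in order:
        placed = False
        for clique in cliques:
            if compatible(g, clique):
                clique.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    # absorb cliques fully contained in another
    cliques = [c for i, c in enumerate(cliques) if not any(c < d for j, d in enumerate(cliques) if i != j)]
    letters = {g: "" for g in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in sorted(clique):
            letters[g] += letter
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def kruskal_wallis(values: dict[str, np.ndarray | list[float]], alpha: float = 0.05) -> KWResult:
    """Kruskal-Wallis test across groups of values with post hoc letters.

    In the disparity pipeline the group values are the within-group pairwise
    distances D (the procedure behind the published chi-squared statistics,
    reported as-is despite the non-independence of pairwise values).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} has no values")
    names = sorted(groups)
    if np.ptp(np.concatenate(list(groups.values()))) == 0:
        h, p = 0.0, 1.0  # all values tied; scipy refuses this degenerate case
    else:
        h, p = stats.kruskal(*(groups[g] for g in names))
    mean_ranks, posthoc = _posthoc_mean_ranks(groups, alpha=alpha)
    letters = _letter_display(names, posthoc, mean_ranks)
    return KWResult(
        H=float(h), df=len(names) - 1, p=float(p),
        mean_ranks=mean_ranks, posthoc=posthoc, letters=letters,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and r^2 from squared distances and integer group codes.

    SS_total = sum_{i<j} d2_ij / N ; SS_within = sum_g sum_{i<j in g} d2 / n_g.
    """
    n = len(codes)
    ss_total = d2.sum() / (2 * n)  # full matrix double-counts pairs
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), float(ss_between / ss_total)


def permanova(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_permutations: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against group labels.

    Taxa without a label are excluded. The p-value is
    ``(count of permuted F >= observed + 1) / (n_permutations + 1)``.
    Deterministic given ``seed``.
    """
    labelled = [(i, str(groups.get(name))) for i, name in enumerate(dm.ids)
                if groups.get(name) is not None and not (isinstance(groups.get(name), float) and np.isnan(groups.get(name)))]
    idx = [i for i, _ in labelled]
    labels = [g for _, g in labelled]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    counts = {g: labels.count(g) for g in uniq}
    if min(counts.values()) < 2:
        small = [g for g, c in counts.items() if c < 2]
        raise ValueError(f"groups of size 1 not allowed: {small}")
    codes = np.array([uniq.index(g) for g in labels])
    vals = dm.values[np.ix_(idx, idx)]
    if np.any(np.isnan(vals)):
        raise ValueError("undefined distances among labelled taxa")
    d2 = vals**2
    f_obs, r2 = _permanova_f(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = _permanova_f(d2, rng.permutation(codes), len(uniq))
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_F=f_obs,
        r2=r2,
        p=float(p),
        n_permutations=n_permutations,
        df_between=len(uniq) - 1,
        df_within=len(idx) - len(uniq),
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_permutations: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise PERMANOVAs with Bonferroni-adjusted p-values.

    The adjustment multiplier is the number of pairs tested;
    ``p_adj = min(1, p_raw * n_pairs)``.
    """
    labels = {name: groups.get(name) for name in dm.ids}
    uniq = sorted({str(g) for g in labels.values() if g is not None and not (isinstance(g, float) and np.isnan(g))})
    pairs = list(itertools.combinations(uniq, 2))
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        sub_names = [n for n in dm.ids if str(labels.get(n)) in (a, b)]
        sub = dm.submatrix(sub_names)
        res = permanova(sub, groups, n_permutations=n_permutations,
                        seed=int(rng.integers(2**31)))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_F": res.pseudo_F,
                "r2": res.r2,
                "p_raw": res.p,
                "p_adjusted": min(1.0, res.p * len(pairs)),
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_adjusted"] < 0.05
    return out


# ---------------------------------------------------------------------------
# Pearson


def pearson_test(x, y) -> PearsonResult:
    """Pearson correlation with t statistic, df = n - 2, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    df = len(x) - 2
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt(df / (1 - r**2))
    return PearsonResult(r=r, t=float(t), df=df, p=float(res.pvalue))
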