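"""Mk-model ancestral-state reconstruction on dated trees.

Per character: tips with missing, inapplicable or polymorphic cells are
dropped from the tree; an Mk model (ER: one rate; ARD: k(k-1) free rates) is
fitted by maximum likelihood via Felsenstein pruning; the AIC-preferred model
drives stochastic character mapping (conditional node draws plus
uniformization path sampling), whose node-state frequencies give ancestral
state probabilities. Argmax states across all characters form the most
probable ancestral combination, which can be appended to a trait matrix as an
``ancestor`` row for morphospace placement.

The root prior is uniform (1/k) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .characters import MISSING, CharacterSet, TaxonRecord, TraitMatrix

__all__ = [
    "MkFit",
    "ASRResult",
    "read_tree",
    "prune_for_character",
    "build_q",
    "mk_loglik",
    "fit_mk",
    "marginal_ancestral_states",
    "stochastic_map",
    "ancestral_combination",
    "reconstruct_all_characters",
]


# ---------------------------------------------------------------------------
# tree plumbing


def read_tree(path: str) -> dendropy.Tree:
    """Read a Newick tree with branch lengths; node labels are honored."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def prune_for_character(
    tree: dendropy.Tree, matrix: TraitMatrix, char_id: str
) -> tuple[dendropy.Tree, dict[str, int]]:
    """Drop tips unusable for one character; return (pruned tree, tip states).

    Unusable = missing, inapplicable, or polymorphic cell. Unbranched internal
    nodes created by the pruning are suppressed with branch lengths summed, so
    root-to-tip path lengths of surviving tips are preserved.
    """
    j = matrix.character_set.index(char_id)
    usable: dict[str, int] = {}
    for i, taxon in enumerate(matrix.taxa):
        code = int(matrix.codes[i, j])
        if code >= 0:
            usable[taxon.name] = code
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    keep = sorted(tip_labels & usable.keys())
    if len(keep) < 2:
        raise ValueError(f"character {char_id!r}: fewer than 2 usable tips")
    pruned = tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    return pruned, {name: usable[name] for name in keep}


class _TreeArrays:
    """Flat postorder arrays for likelihood computations on a dendropy tree."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.nodes = nodes
        self.index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(len(nodes), -1, dtype=int)
        self.edge_len = np.zeros(len(nodes))
        self.children: list[list[int]] = [[] for _ in nodes]
        self.tip_label: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = self.index[id(nd.parent_node)]
                self.children[self.parent[i]].append(i)
                self.edge_len[i] = nd.edge.length or 0.0
            if nd.is_leaf():
                self.tip_label[i] = nd.taxon.label
        self.root = self.index[id(tree.seed_node)]
        self.n = len(nodes)

    def node_labels(self) -> dict[int, str]:
        out = {}
        for i, nd in enumerate(self.nodes):
            if not nd.is_leaf() and nd.label:
                out[i] = nd.label
        return out


# ---------------------------------------------------------------------------
# Mk generator and transition probabilities


def build_q(model: str, rates: np.ndarray | list[float], k: int) -> np.ndarray:
    """Mk generator matrix (rows sum to zero).

    ER takes one rate (all off-diagonal entries equal); ARD takes k(k-1)
    rates filling the off-diagonal row-wise.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    q = np.zeros((k, k))
    if model == "ER":
        if rates.size != 1:
            raise ValueError("ER expects a single rate")
        q[:] = rates[0]
    elif model == "ARD":
        if rates.size != k * (k - 1):
            raise ValueError(f"ARD expects {k * (k - 1)} rates")
        it = iter(rates)
        for i in range(k):
            for j in range(k):
                if i != j:
                    q[i, j] = next(it)
    else:
        raise ValueError(f"unknown model {model!r}")
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _transition_mats(q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """P(t) = exp(Q t) for every branch length, batched via eigendecomposition.

    Falls back to scipy's expm branch-by-branch if Q is (near-)defective.
    """
    k = q.shape[0]
    try:
        lam, u = np.linalg.eig(q)
        uinv = np.linalg.inv(u)
        if np.linalg.cond(u) > 1e8:
            raise np.linalg.LinAlgError
        e = np.exp(np.multiply.outer(ts, lam))  # (b, k)
        p = np.einsum("ij,bj,jl->bil", u, e, uinv).real
    except np.linalg.LinAlgError:
        p = np.stack([expm(q * t) for t in ts])
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=2, keepdims=True)
    if not np.all(np.isfinite(p)):
        raise FloatingPointError("non-finite transition probabilities")
    return p


# ---------------------------------------------------------------------------
# likelihood


def _partials(
    ta: _TreeArrays, tip_states: dict[str, int], k: int, p_mats: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Postorder conditional likelihoods with per-node log scaling.

    Returns (partials (n, k), log_scale (n,)): partials[v, s] is proportional
    to P(data below v | state(v) = s), with sum of logs of the scalers.
    """
    part = np.zeros((ta.n, k))
    log_scale = np.zeros(ta.n)
    for i in range(ta.n):  # postorder by construction
        if i in ta.tip_label:
            part[i, tip_states[ta.tip_label[i]]] = 1.0
            continue
        vec = np.ones(k)
        acc = 0.0
        for c in ta.children[i]:
            msg = p_mats[c] @ part[c]
            vec *= msg
            acc += log_scale[c]
        scale = vec.max()
        if scale <= 0:
            raise FloatingPointError("zero likelihood at an internal node")
        part[i] = vec / scale
        log_scale[i] = acc + np.log(scale)
    return part, log_scale


def mk_loglik(
    tree: dendropy.Tree,
    tip_states: dict[str, int],
    model: str,
    rates: np.ndarray | list[float],
    k: int | None = None,
    root_prior: np.ndarray | None = None,
) -> float:
    """Log-likelihood of tip states under an Mk model (Felsenstein pruning)."""
    if k is None:
        k = max(tip_states.values()) + 1
    ta = _TreeArrays(tree)
    q = build_q(model, rates, k)
    return _loglik_arrays(ta, tip_states, q, root_prior)


def _loglik_arrays(
    ta: _TreeArrays,
    tip_states: dict[str, int],
    q: np.ndarray,
    root_prior: np.ndarray | None = None,
) -> float:
    k = q.shape[0]
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
    p_mats = _transition_mats(q, ta.edge_len)
    part, log_scale = _partials(ta, tip_states, k, p_mats)
    like = float(prior @ part[ta.root])
    if like <= 0:
        return -np.inf
    return np.log(like) + float(log_scale[ta.root])


@dataclass
class MkFit:
    model: str  # "ER" | "ARD"
    rates: np.ndarray
    logL: float
    AIC: float
    k: int
    degenerate: bool = False

    @property
    def n_params(self) -> int:
        return 1 if self.model == "ER" else self.k * (self.k - 1)

    @property
    def q(self) -> np.ndarray:
        return build_q(self.model, self.rates, self.k)


def _fit_one(
    ta: _TreeArrays, tip_states: dict[str, int], k: int, model: str, starts: list[np.ndarray]
) -> MkFit:
    n_par = 1 if model == "ER" else k * (k - 1)

    def negll(log_rates: np.ndarray) -> float:
        ll = _loglik_arrays(ta, tip_states, build_q(model, np.exp(log_rates), k))
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for x0 in starts:
        res = minimize(
            negll, np.log(np.maximum(x0, 1e-10)), method="L-BFGS-B",
            bounds=[(-23, 6)] * n_par,
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"{model} optimization failed in all starts")
    rates = np.exp(best.x)
    logl = -float(best.fun)
    return MkFit(model=model, rates=rates, logL=logl,
                 AIC=2 * n_par - 2 * logl, k=k)


def fit_mk(
    tree: dendropy.Tree,
    tip_states: dict[str, int],
    k: int | None = None,
    models: tuple[str, ...] = ("ER", "ARD"),
) -> tuple[MkFit, dict[str, MkFit]]:
    """Fit ER and ARD by bounded multi-start ML; return (AIC-best, all fits).

    A constant character (single observed tip state) is degenerate: the rate
    sits at the lower boundary and the fit is flagged; only ER is reported.
    """
    if k is None:
        k = max(tip_states.values()) + 1
    ta = _TreeArrays(tree)
    tree_len = float(ta.edge_len.sum())
    scale = max(tree_len, 1e-6)
    if len(set(tip_states.values())) < 2:
        q0 = 1e-10
        logl = _loglik_arrays(ta, tip_states, build_q("ER", [q0], k))
        fit = MkFit("ER", np.array([q0]), logl, 2 - 2 * logl, k, degenerate=True)
        return fit, {"ER": fit}
    base = np.array([0.5, 2.0, 10.0]) * len(tip_states) / scale
    fits: dict[str, MkFit] = {}
    if "ER" in models:
        starts = [np.array([b]) for b in base]
        fits["ER"] = _fit_one(ta, tip_states, k, "ER", starts)
    if "ARD" in models:
        n_par = k * (k - 1)
        anchor = fits["ER"].rates[0] if "ER" in fits else base[0]
        rng = np.random.default_rng(12345)
        starts = [np.full(n_par, anchor)]
        starts += [anchor * np.exp(rng.normal(0, 0.5, size=n_par)) for _ in range(2)]
        fits["ARD"] = _fit_one(ta, tip_states, k, "ARD", starts)
        if "ER" in fits and fits["ARD"].logL < fits["ER"].logL - 1e-6:
            # nested models: ARD must not fall below ER; retry from ER solution
            retry = _fit_one(ta, tip_states, k, "ARD",
                             [np.full(n_par, fits["ER"].rates[0]) * f for f in (1.0, 0.999)])
            if retry.logL > fits["ARD"].logL:
                fits["ARD"] = retry
    best = min(fits.values(), key=lambda f: (f.AIC, f.n_params))
    return best, fits


# ---------------------------------------------------------------------------
# marginal reconstruction and stochastic mapping


def _above_partials(
    ta: _TreeArrays, part: np.ndarray, p_mats: np.ndarray, prior: np.ndarray
) -> np.ndarray:
    """Preorder 'outside' partials; marginal(v) ~ above(v) * part(v)."""
    k = part.shape[1]
    above = np.zeros_like(part)
    order = list(reversed(range(ta.n)))  # preorder (reverse postorder)
    above[ta.root] = prior
    msgs = np.zeros((ta.n, k))  # child -> parent likelihood messages
    for c in range(ta.n):
        if ta.parent[c] >= 0:
            msgs[c] = p_mats[c] @ part[c]
    for v in order:
        for c in ta.children[v]:
            sib = np.ones(k)
            for s in ta.children[v]:
                if s != c:
                    sib *= msgs[s]
            combined = above[v] * sib
            above[c] = combined @ p_mats[c]
            tot = above[c].sum()
            if tot > 0:
                above[c] /= tot
    return above


def marginal_ancestral_states(
    tree: dendropy.Tree, tip_states: dict[str, int], fit: MkFit,
    root_prior: np.ndarray | None = None,
) -> pd.DataFrame:
    """Marginal (rerooting-equivalent) state probabilities per internal node.

    Indexed by the postorder node id; node labels, when present, are in the
    ``label`` column.
    """
    ta = _TreeArrays(tree)
    k = fit.k
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
    p_mats = _transition_mats(fit.q, ta.edge_len)
    part, _ = _partials(ta, tip_states, k, p_mats)
    above = _above_partials(ta, part, p_mats, prior)
    rows = []
    labels = {i: (ta.nodes[i].label or "") for i in range(ta.n)}
    for v in range(ta.n):
        if v in ta.tip_label:
            continue
        post = above[v] * part[v]
        post /= post.sum()
        rows.append({"node": v, "label": labels[v], **{f"p{s}": post[s] for s in range(k)}})
    return pd.DataFrame(rows).set_index("node")


def _sample_path(
    a: int, b: int, t: float, q: np.ndarray, p_ab: float, rng: np.random.Generator
) -> list[tuple[float, int]]:
    """Sample a state path on a branch conditional on endpoints (uniformization).

    Returns the jump chain as (time, new_state) events. The number of virtual
    jumps is drawn from its conditional distribution, then the bridge of
    uniformized-chain states is sampled transition by transition.
    """
    from scipy.stats import poisson

    k = q.shape[0]
    mu = float(np.max(-np.diag(q)))
    if mu == 0 or t == 0:
        return []
    r = np.eye(k) + q / mu
    # number of virtual jumps: P(N = n | a, b) ~ Poisson(mu t; n) * R^n[a, b],
    # normalized by P_ab(t); sampled by CDF inversion
    rn = [np.eye(k)]
    n = 0
    target = rng.random() * p_ab
    acc = 0.0
    while True:
        if n >= len(rn):
            rn.append(rn[-1] @ r)
        acc += poisson.pmf(n, mu * t) * rn[n][a, b]
        if acc >= target - 1e-15 or n > 100 + int(10 * mu * t):
            break
        n += 1
    # sample the n uniformized transitions as a bridge from a to b
    states = [a]
    for i in range(1, n + 1):
        prev = states[-1]
        weights = r[prev, :] * rn[n - i][:, b]
        s = weights.sum()
        if s <= 0:
            states.append(b)
            continue
        states.append(int(rng.choice(k, p=weights / s)))
    times = np.sort(rng.random(n)) * t
    events = []
    cur = a
    for i in range(n):
        nxt = states[i + 1]
        if nxt != cur:
            events.append((float(times[i]), int(nxt)))
            cur = nxt
    return events


@dataclass
class ASRResult:
    """Stochastic-mapping summary for one character."""

    char_id: str
    fit: MkFit
    n_simulations: int
    node_probabilities: pd.DataFrame  # node id x state probability columns
    node_labels: dict[int, str]
    mean_changes: float  # mean number of state changes per simulated history

    def most_probable_state(self, node: int) -> tuple[int | None, float]:
        row = self.node_probabilities.loc[node]
        probs = row[[c for c in row.index if str(c).startswith("p")]].to_numpy(dtype=float)
        order = np.argsort(probs)[::-1]
        if len(order) > 1 and abs(probs[order[0]] - probs[order[1]]) < 1e-9:
            return None, float(probs[order[0]])  # tie
        return int(order[0]), float(probs[order[0]])


def stochastic_map(
    tree: dendropy.Tree,
    tip_states: dict[str, int],
    fit: MkFit,
    n_sims: int = 500,
    seed: int = 0,
    char_id: str = "",
    sample_paths: bool = True,
) -> ASRResult:
    """Stochastic character mapping: node-state frequencies over simulations.

    Histories are sampled conditional on the tip data: the root state from the
    posterior at the root, then each child given its parent by
    ``P(child = b | parent = a, data) ~ P_ab(t) * L_child(b)`` in preorder;
    branch paths by uniformization (used for the change-count summary).
    Deterministic given ``seed``.
    """
    ta = _TreeArrays(tree)
    k = fit.k
    prior = np.full(k, 1.0 / k)
    p_mats = _transition_mats(fit.q, ta.edge_len)
    part, _ = _partials(ta, tip_states, k, p_mats)
    rng = np.random.default_rng(seed)
    counts = np.zeros((ta.n, k))
    order = list(reversed(range(ta.n)))  # preorder
    root_post = prior * part[ta.root]
    root_post /= root_post.sum()
    n_changes = 0
    states = np.zeros(ta.n, dtype=int)
    for _ in range(n_sims):
        states[ta.root] = rng.choice(k, p=root_post)
        for v in order:
            for c in ta.children[v]:
                w = p_mats[c][states[v], :] * part[c]
                w_sum = w.sum()
                states[c] = int(rng.choice(k, p=w / w_sum))
                if sample_paths:
                    events = _sample_path(
                        int(states[v]), int(states[c]), float(ta.edge_len[c]),
                        fit.q, float(p_mats[c][states[v], states[c]]), rng,
                    )
                    n_changes += len(events)
                elif states[c] != states[v]:
                    n_changes += 1
        counts[np.arange(ta.n), states] += 1
    probs = counts / n_sims
    rows = []
    for v in range(ta.n):
        if v in ta.tip_label:
            continue
        rows.append({"node": v, **{f"p{s}": probs[v, s] for s in range(k)}})
    node_probs = pd.DataFrame(rows).set_index("node")
    return ASRResult(
        char_id=char_id,
        fit=fit,
        n_simulations=n_sims,
        node_probabilities=node_probs,
        node_labels=ta.node_labels(),
        mean_changes=n_changes / n_sims,
    )


# ---------------------------------------------------------------------------
# whole-matrix reconstruction and ancestor rows


def _mrca_index(tree: dendropy.Tree, labels: set[str]) -> int | None:
    """Postorder index of the MRCA of the given tip labels, if >= 2 survive."""
    present = [l for l in (leaf.taxon.label for leaf in tree.leaf_node_iter()) if l in labels]
    if len(present) < 2:
        return None
    mrca = tree.mrca(taxon_labels=present)
    ta = _TreeArrays(tree)
    return ta.index[id(mrca)]


def reconstruct_all_characters(
    tree: dendropy.Tree,
    matrix: TraitMatrix,
    clades: dict[str, list[str]],
    n_sims: int = 500,
    seed: int = 0,
) -> dict[str, dict[str, tuple[int | None, float]]]:
    """Per character, reconstruct the state at each named clade's crown node.

    ``clades`` maps a clade name to its member tip labels; per character the
    crown node is the MRCA of the members surviving that character's pruning.
    Returns ``{clade: {char_id: (argmax state or None, probability)}}``;
    missing entries mean the node vanished from the pruned tree or the
    character was unusable.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, tuple[int | None, float]]] = {c: {} for c in clades}
    for char in matrix.character_set:
        try:
            pruned, tip_states = prune_for_character(tree, matrix, char.id)
        except ValueError:
            continue
        fit, _ = fit_mk(pruned, tip_states, k=char.k)
        asr = stochastic_map(
            pruned, tip_states, fit, n_sims=n_sims,
            seed=int(rng.integers(2**31)), char_id=char.id, sample_paths=False,
        )
        for clade, members in clades.items():
            node = _mrca_index(pruned, set(members))
            if node is None or node not in asr.node_probabilities.index:
                continue
            out[clade][char.id] = asr.most_probable_state(node)
    return out


def ancestral_combination(
    reconstruction: dict[str, tuple[int | None, float]],
    character_set: CharacterSet,
    name: str,
) -> tuple[TraitMatrix, list[str]]:
    """Assemble one ancestor row from per-character argmax states.

    Characters absent from the reconstruction, or tied at the argmax, become
    missing cells; ties are logged. Returns a one-row matrix with
    ``status="ancestor"`` ready to concatenate before distance computation.
    """
    codes = np.full((1, len(character_set)), MISSING, dtype=np.int16)
    tie_log: list[str] = []
    for j, char in enumerate(character_set):
        if char.id not in reconstruction:
            continue
        state, prob = reconstruction[char.id]
        if state is None:
            tie_log.append(f"{name}:{char.id} tied at p={prob:.3f}; set missing")
            continue
        codes[0, j] = state
    tm = TraitMatrix([TaxonRecord(name, status="ancestor")], character_set, codes, {})
    return tm, tie_log
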