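"""Configuration-driven orchestration of the three standard analyses.

A run executes, in order: polymorphism resolution -> distance matrix (with
greedy dropping of taxa in undefined pairs) -> per-group disparity (+
rarefaction, Ddelta, eccentricity) -> nMDS ordination (optionally against a
theoretical background) -> group statistics (Kruskal-Wallis on within-group
pairwise D, PERMANOVA on the distance matrix). Every random step takes its
seed from the run config and all seeds, drop logs, and row counts land in the
manifest, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characters import TraitMatrix, audit_missing, read_matrix, resolve_polymorphism
from .disparity import (
    PAPER_TIME_BINS,
    PRESENT_BIN,
    EXCLUDED,
    TimeBin,
    assign_time_bins,
    ddelta,
    eccentricity,
    group_disparity,
    rarefy,
)
from .distance import build_distance_matrix
from .groupstats import kruskal_wallis, pairwise_permanova, permanova
from .ordination import group_centroid, nmds, shepard
from .theospace import sample_theoretical

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    matrix_file: str | None = None
    schema_file: str | None = None
    groups_file: str | None = None
    out_dir: str = "floradisp_out"
    analysis: str = "groups"  # "dtt" | "groups"
    grouping: str | None = None  # None: dtt -> time bins, groups -> group labels
    time_bins: tuple[TimeBin, ...] = PAPER_TIME_BINS
    excluded_groups: tuple[str, ...] = ()
    excluded_taxa: tuple[str, ...] = ()
    theoretical_n: int = 2000
    include_theoretical: bool = True
    rarefaction_reps: int = 1000
    n_permutations: int = 9999
    nmds_starts: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "time_bins" in doc:
            doc["time_bins"] = tuple(
                TimeBin(b["name"], float(b["max_Ma"]), float(b["min_Ma"]))
                for b in doc["time_bins"]
            )
        for key in ("excluded_groups", "excluded_taxa"):
            if key in doc:
                doc[key] = tuple(doc[key])
        cfg = cls(**doc)
        for name in ("matrix_file", "schema_file"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        return cfg


def _group_labels(matrix: TraitMatrix, cfg: RunConfig) -> pd.Series:
    if cfg.analysis == "dtt":
        bins = assign_time_bins(matrix.taxa, cfg.time_bins)
        return bins.where(bins != EXCLUDED)
    labels = {t.name: t.group for t in matrix.taxa if t.status in ("extant", "fossil")}
    return pd.Series(labels, dtype=object)


def run(cfg: RunConfig, matrix: TraitMatrix | None = None) -> dict:
    """Execute one analysis; write all artifacts; return the result bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "analysis": cfg.analysis,
        "stages": [],
    }
    rng = np.random.default_rng(cfg.seed)

    if matrix is None:
        if cfg.matrix_file is None or cfg.schema_file is None:
            raise ValueError("need matrix_file and schema_file (or an in-memory matrix)")
        matrix = read_matrix(cfg.matrix_file, cfg.schema_file, cfg.groups_file)
    manifest["stages"].append({"stage": "load", "n_taxa": matrix.n_taxa,
                               "n_characters": matrix.n_characters})

    if cfg.excluded_taxa:
        keep = [n for n in matrix.taxon_names if n not in set(cfg.excluded_taxa)]
        matrix = matrix.subset(keep)
    groups = _group_labels(matrix, cfg)
    if cfg.excluded_groups:
        groups = groups.where(~groups.isin(set(cfg.excluded_groups)))
    manifest["excluded_taxa"] = list(cfg.excluded_taxa)
    manifest["excluded_groups"] = list(cfg.excluded_groups)

    audit = audit_missing(matrix)
    (out / "audit.json").write_text(json.dumps(audit, indent=2))

    poly_seed = int(rng.integers(2**31))
    resolved = resolve_polymorphism(matrix, seed=poly_seed)
    manifest["stages"].append({"stage": "resolve_polymorphism", "seed": poly_seed,
                               "cells_resolved": len(matrix.polymorphic)})

    dm = build_distance_matrix(resolved, drop_policy="greedy_undefined")
    dm.write_csv(out / "distance.csv")
    dm.write_drop_log(out / "drop_log.csv")
    manifest["stages"].append({"stage": "distance", "n_before": matrix.n_taxa,
                               "n_after": dm.n, "dropped": dm.dropped})

    groups = groups[groups.index.isin(dm.ids)]
    sizes = groups.value_counts()
    usable = set(sizes[sizes >= 2].index)
    groups_stat = groups.where(groups.isin(usable))

    disparity_df = group_disparity(dm, groups_stat)
    d_deltas = {g: ddelta(dm, groups_stat, g) for g in disparity_df.index}
    disparity_df["Ddelta"] = pd.Series(d_deltas)
    disparity_df.to_csv(out / "disparity.csv")

    rare_seed = int(rng.integers(2**31))
    smallest = int(sizes[sizes >= 2].min()) if len(usable) else 0
    rarefaction = None
    if smallest >= 3 and cfg.rarefaction_reps > 0:
        resolved_kept = resolved.subset(dm.ids)
        rarefaction = rarefy(
            resolved_kept, groups_stat, metric="meanD",
            reps=cfg.rarefaction_reps, seed=rare_seed,
        )
        rarefaction.to_csv(out / "rarefaction.csv", index=False)
    manifest["stages"].append({"stage": "disparity", "groups": sorted(usable),
                               "rarefaction_seed": rare_seed,
                               "rarefaction_reps": cfg.rarefaction_reps})

    empirical_names = [n for n in dm.ids]
    ecc = eccentricity(dm, empirical_names)
    ecc.to_csv(out / "eccentricity.csv", index=False)

    # ordination, optionally on empirical + theoretical rows
    theo_seed = int(rng.integers(2**31))
    ord_input = resolved.subset(dm.ids)
    if cfg.include_theoretical and cfg.theoretical_n > 0:
        theo = sample_theoretical(matrix.character_set, cfg.theoretical_n, seed=theo_seed)
        ord_input = ord_input.concat(theo.rows)
    ord_dm = build_distance_matrix(ord_input, drop_policy="greedy_undefined")
    nmds_seed = int(rng.integers(2**31))
    ordination = nmds(ord_dm, k=2, n_starts=cfg.nmds_starts, seed=nmds_seed)
    nonmetric_r2, linear_r2 = shepard(ord_dm, ordination)
    coords = ordination.to_dataframe()
    status = {t.name: t.status for t in ord_input.taxa}
    coords["status"] = [status.get(n, "") for n in coords.index]
    coords["group"] = [groups.get(n) for n in coords.index]
    coords.rename_axis("taxon").to_csv(out / "coordinates.csv")
    centroids = group_centroid(ordination, groups_stat)
    centroids.to_csv(out / "centroids.csv")
    diagnostics = {
        "stress": ordination.stress,
        "shepard_nonmetric_r2": nonmetric_r2,
        "shepard_linear_r2": linear_r2,
        "k": ordination.k,
        "n_starts": cfg.nmds_starts,
        "seed": nmds_seed,
        "n_points": ord_dm.n,
    }
    (out / "ordination.json").write_text(json.dumps(diagnostics, indent=2))
    manifest["stages"].append({"stage": "ordination", "seed": nmds_seed,
                               "theoretical_seed": theo_seed,
                               "n_points": ord_dm.n, "stress": ordination.stress})

    # group statistics on within-group pairwise D and on the distance matrix
    kw_values = {}
    for g in disparity_df.index:
        idx = [i for i, n in enumerate(dm.ids) if groups_stat.get(n) == g]
        sub = dm.values[np.ix_(idx, idx)]
        kw_values[g] = sub[np.triu_indices(len(idx), k=1)]
    kw = kruskal_wallis(kw_values)
    perm_seed = int(rng.integers(2**31))
    perm = permanova(dm, groups_stat, n_permutations=cfg.n_permutations, seed=perm_seed)
    pairwise = pairwise_permanova(dm, groups_stat,
                                  n_permutations=min(cfg.n_permutations, 999),
                                  seed=perm_seed)
    pairwise.to_csv(out / "pairwise_permanova.csv", index=False)
    stats_doc = {
        "kruskal_wallis": {"chi2": kw.H, "df": kw.df, "p": kw.p, "letters": kw.letters},
        "permanova": {"F": perm.pseudo_F, "r2": perm.r2, "p": perm.p,
                      "n_permutations": perm.n_permutations, "seed": perm_seed},
    }
    (out / "stats.json").write_text(json.dumps(stats_doc, indent=2))
    manifest["stages"].append({"stage": "stats", "permanova_seed": perm_seed})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "matrix": matrix,
        "distance": dm,
        "groups": groups_stat,
        "disparity": disparity_df,
        "rarefaction": rarefaction,
        "eccentricity": ecc,
        "ordination": ordination,
        "diagnostics": diagnostics,
        "kruskal_wallis": kw,
        "permanova": perm,
        "pairwise_permanova": pairwise,
        "manifest": manifest,
    }
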