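"""End-to-end orchestration: full analysis runs, reference-list replay, and
the synthetic parameter-recovery benchmark.

``run_full`` executes the complete chain on an indicator table:

    screen -> standardize per theme -> elbow (recorded) -> k-means per theme
    -> risk-order labels -> pairwise Jaccard matrices -> match worst clusters
    -> late-integrate (Venn) -> per-variable contribution table,

writing all outputs plus a run manifest that echoes the configuration and
per-stage dimensions, so a rerun with the same config reproduces the bundle
bit-for-bit.

``run_fixture_replay`` recomputes every set-arithmetic summary (worst-cluster
Jaccards, Venn region sizes and percentages, cluster-size tables) from the
packaged membership lists alone and compares them with the published values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .clustering import ClusterModel, elbow_curve, kmeans_fit, rank_clusters_by_risk, silhouette
from .data_io import (
    IndicatorTable,
    load_membership_fixture,
    write_assignments,
    write_contributions,
    write_regions,
    write_similarity,
)
from .errors import ConfigurationError
from .inference import contribution_table
from .metrics import ari_from_mappings
from .multiview import late_integrate, match_high_risk, round_half_up, similarity_matrix
from .preprocessing import screen_completeness, standardize
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)

#: Published values the replay is checked against: worst-cluster Jaccards,
#: Venn region sizes, and per-theme cluster sizes.
PUBLISHED = {
    "jaccard_worst": {("NAD", "HAD"): 0.72, ("NAD", "HALE"): 0.71, ("HAD", "HALE"): 0.84},
    "union_size": 69,
    "triple_intersection": 45,
    "triple_intersection_pct": 65.2,
    "nad_only": 11,
    "nad_only_pct": 15.9,
    "nad_had_only": 5,
    "nad_had_only_pct": 7.2,
    "nad_hale_only": 4,
    "nad_hale_only_pct": 5.8,
    "cluster_sizes": {"NAD": (61, 42, 65), "HAD": (45, 69, 54), "HALE": (27, 88, 53)},
}


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config echo, seeds, version,
    per-stage shapes, and accumulated warnings."""

    config: dict[str, Any]
    version: str = __version__
    stages: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def digest(self) -> str:
        payload = json.dumps(
            {"config": self.config, "version": self.version, "stages": self.stages},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def write(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "version": self.version,
            "stages": self.stages,
            "warnings": self.warnings,
            "digest": self.digest(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=str) + "\n")


def run_full(
    table: IndicatorTable,
    directions: Mapping[str, int],
    k: int = 3,
    seed: int = 0,
    restarts: int = 50,
    standardize_mode: str = "zscore",
    k_range: tuple[int, int] = (1, 6),
    out_dir: str | Path | None = None,
    config_echo: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Run the full multiview pipeline on an indicator table.

    Returns a bundle dict with the fitted models, similarity matrices,
    matched triple, Venn partition, contribution rows, elbow curves, and
    manifest; when ``out_dir`` is given all outputs are also written there.
    """
    missing_dirs = [v for t in table.themes for v in t.variables if v not in directions]
    if missing_dirs:
        raise ConfigurationError(f"no severity direction configured for: {missing_dirs}")

    manifest = RunManifest(
        config=dict(
            config_echo or {},
            k=k, seed=seed, restarts=restarts,
            standardize_mode=standardize_mode, k_range=list(k_range),
        )
    )
    screened, report = screen_completeness(table)
    manifest.stages["screen"] = {
        "n_input": report.n_input, "n_retained": report.n_retained,
        "dropped": [c for c, _ in report.dropped],
    }
    scaled = standardize(screened, mode=standardize_mode)

    models: dict[str, ClusterModel] = {}
    elbows: dict[str, Any] = {}
    silhouettes: dict[str, float] = {}
    for spec in table.themes:
        X = scaled.theme_matrix(spec.name).to_numpy(float)
        elbows[spec.name] = elbow_curve(X, *k_range, seed=seed, restarts=restarts)
        model = kmeans_fit(X, k, seed=seed, restarts=restarts, theme=spec.name)
        model = rank_clusters_by_risk(model, screened, dict(directions))
        models[spec.name] = model
        silhouettes[spec.name] = silhouette(X, model.assignments) if k >= 2 else float("nan")
        manifest.stages[f"cluster_{spec.name}"] = {
            "k": k, "wss": model.wss, "n": len(model.assignments),
            "elbow_chosen_k": elbows[spec.name].chosen_k,
            "silhouette": silhouettes[spec.name],
        }

    countries = screened.countries
    assignments = {
        name: {c: int(lbl) for c, lbl in zip(countries, m.assignments)}
        for name, m in models.items()
    }
    names = [t.name for t in table.themes]
    sims = {
        (a, b): similarity_matrix(assignments[a], assignments[b], theme_pair=(a, b))
        for i, a in enumerate(names) for b in names[i + 1:]
    }
    (ab, ac, bc) = (
        sims[(names[0], names[1])], sims[(names[0], names[2])], sims[(names[1], names[2])],
    )
    triple, is_worst = match_high_risk(ab, ac, bc)
    worst_triple = (models[names[0]].k, models[names[1]].k, models[names[2]].k)
    if not is_worst:
        manifest.warnings.append(
            f"max-similarity triple {triple} is not the worst-risk triple {worst_triple}"
        )
    # Late integration targets the highest-risk clusters; the max-similarity
    # match is reported alongside as a concordance diagnostic.
    worst_sets = [
        models[name].members(label, countries) for name, label in zip(names, worst_triple)
    ]
    partition = late_integrate(*worst_sets, names=tuple(names))
    manifest.stages["late_integration"] = {
        "worst_triple": list(worst_triple), "matched_triple": list(triple),
        "union_size": partition.union_size,
        "region_sizes": {k_: len(v) for k_, v in partition.regions.items()},
    }
    contributions = contribution_table(screened, assignments)

    bundle = {
        "models": models, "assignments": assignments, "elbows": elbows,
        "silhouettes": silhouettes, "similarities": sims,
        "matched_triple": triple, "worst_triple": worst_triple,
        "partition": partition, "contributions": contributions,
        "manifest": manifest, "screen_report": report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_assignments(assignments, out / "assignments.csv")
        write_similarity(sims.values(), out / "similarity.csv")
        write_regions(partition, out / "regions.json")
        write_contributions(contributions, out / "contributions.csv")
        pd.DataFrame(
            [
                (t, k_, w)
                for t, e in elbows.items()
                for k_, w in zip(e.k_values, e.wss_values)
            ],
            columns=["theme", "k", "wss"],
        ).to_csv(out / "elbow.csv", index=False)
        manifest.write(out / "manifest.json")
    return bundle


# ---------------------------------------------------------------------------
# Reference replay
# ---------------------------------------------------------------------------


def run_fixture_replay() -> dict[str, Any]:
    """Recompute all set-arithmetic summaries from the packaged membership
    lists and compare them with the published values.

    Returns a report dict with the recomputed quantities, per-check
    pass/fail, and an overall ``all_match`` flag.
    """
    fx = load_membership_fixture()
    worst = {t: fx.cluster(t, 3) for t in ("NAD", "HAD", "HALE")}
    jac = {
        pair: round_half_up(
            len(worst[pair[0]] & worst[pair[1]]) / len(worst[pair[0]] | worst[pair[1]]), 2
        )
        for pair in (("NAD", "HAD"), ("NAD", "HALE"), ("HAD", "HALE"))
    }
    partition = late_integrate(
        worst["NAD"], worst["HAD"], worst["HALE"], names=("NAD", "HAD", "HALE")
    )
    pct = partition.percentages()
    computed = {
        "jaccard_worst": jac,
        "union_size": partition.union_size,
        "triple_intersection": len(partition.regions["NAD&HAD&HALE"]),
        "triple_intersection_pct": pct["NAD&HAD&HALE"],
        "nad_only": len(partition.regions["NAD_only"]),
        "nad_only_pct": pct["NAD_only"],
        "nad_had_only": len(partition.regions["NAD&HAD_only"]),
        "nad_had_only_pct": pct["NAD&HAD_only"],
        "nad_hale_only": len(partition.regions["NAD&HALE_only"]),
        "nad_hale_only_pct": pct["NAD&HALE_only"],
        "cluster_sizes": {t: fx.sizes(t) for t in ("NAD", "HAD", "HALE")},
    }
    checks = {key: computed[key] == PUBLISHED[key] for key in PUBLISHED}
    return {
        "computed": computed,
        "expected": PUBLISHED,
        "checks": checks,
        "all_match": all(checks.values()),
        "partition": partition,
    }


# ---------------------------------------------------------------------------
# Synthetic benchmark
# ---------------------------------------------------------------------------


def run_benchmark(
    separations: tuple[float, ...] = (0.0, 3.0, 6.0, 8.0),
    discordances: tuple[float, ...] = (0.0, 0.1, 0.2),
    n_countries: int = 200,
    n_replicates: int = 5,
    seed: int = 0,
    restarts: int = 20,
    k_range: tuple[int, int] = (1, 6),
) -> pd.DataFrame:
    """Parameter-recovery study over a separation x discordance grid.

    Per cell and replicate: generate a synthetic dataset, cluster each theme
    at k = n_tiers, and score per-theme ARI against the planted tiers, the
    recovered cross-theme worst-cluster Jaccards, and the elbow-chosen k.
    Deterministic: replicate r of cell (i, j) uses its own derived seed.
    """
    rows = []
    for si, sep in enumerate(separations):
        for di, disc in enumerate(discordances):
            for rep in range(n_replicates):
                ds_seed = seed + 100_000 * si + 1_000 * di + rep
                ds = generate(
                    SyntheticConfig(
                        n_countries=n_countries, tier_separation=sep,
                        discordance=disc, seed=ds_seed,
                    )
                )
                bundle = run_full(
                    ds.table, ds.directions, k=ds.config.n_tiers,
                    seed=ds_seed, restarts=restarts, k_range=k_range,
                )
                names = [t.name for t in ds.table.themes]
                aris = {
                    t: ari_from_mappings(bundle["assignments"][t], dict(ds.true_tiers[t]))
                    for t in names
                }
                worst_jac = {
                    (a, b): bundle["similarities"][(a, b)].entry(3, 3)
                    for i, a in enumerate(names) for b in names[i + 1:]
                }
                rows.append({
                    "separation": sep, "discordance": disc, "replicate": rep,
                    "seed": ds_seed,
                    **{f"ari_{t}": aris[t] for t in names},
                    **{f"jaccard_{a}_{b}": v for (a, b), v in worst_jac.items()},
                    **{f"elbow_k_{t}": bundle["elbows"][t].chosen_k for t in names},
                })
    return pd.DataFrame(rows)
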