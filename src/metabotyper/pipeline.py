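"""End-to-end metabotyping workflow and its report bundle.

Stages, in order: read or simulate the 11-metabolite table -> aggregate to
aglycone sums -> pre-treatment grid with the PCA quality report (24 rows)
-> clustering (final consensus over the nine algorithms, k-means, EM, and
the two PC-score rules) -> one PLS-DA model per clustering method per
dataset (10 models) -> univariate summary per method -> sulfate/
glucuronide ratio report.  Every stochastic stage takes its seed from the
run config; two runs with the same config and seed write identical CSVs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import data_model as dm
from . import plsda as pls
from . import synthetic as syn
from . import univariate as uni
from .pca import fit_pca, pca_grid_report
from .pretreatment import PretreatmentSpec, pretreat

logger = logging.getLogger(__name__)

# clustering methods carried into PLS-DA / univariate reporting
DEFAULT_METHODS = ("final-consensus", "kmeans", "em", "pc-score-2", "pc-score-3")


@dataclass
class RunConfig:
    """Configuration of one workflow run; echoed verbatim to the output dir."""

    input_path: str | None = None  # None -> simulate the default cohort
    out_dir: str = "metabotyper_out"
    seed: int = 0
    n_components: int = 2
    folds: int = 7
    n_perm: int = 99
    k: int | None = None  # None -> choose by index voting
    k_range: tuple[int, int] = (2, 10)
    repeats: int = 5
    algorithms: tuple[str, ...] = cl.ALGORITHMS
    methods: tuple[str, ...] = DEFAULT_METHODS
    run_grid: bool = True
    run_clustering: bool = True
    run_select_k: bool = True
    index_panel: list[str] | None = None


def _autoscaled(values: pd.DataFrame) -> np.ndarray:
    spec = PretreatmentSpec(transform="none", scaling="center+UV")
    scaled, _ = pretreat(values.to_numpy(float), spec)
    return scaled


def _clustering_partitions(
    x: np.ndarray, k: int, methods: tuple[str, ...], algorithms: tuple[str, ...], seed: int
) -> tuple[dict[str, cl.Partition], cl.ConsensusResult | None]:
    """Build the requested method partitions on autoscaled data."""
    parts: dict[str, cl.Partition] = {}
    consensus = None
    if "final-consensus" in methods:
        runs = [cl.run_algorithm(x, alg, k, seed) for alg in algorithms]
        aligned = [runs[0]] + [cl.align_labels(runs[0], p) for p in runs[1:]]
        consensus = cl.final_consensus(aligned)
        parts["final-consensus"] = consensus.partition
    for m in methods:
        if m in cl.ALGORITHMS:
            parts[m] = cl.run_algorithm(x, m, k, seed)
    if "pc-score-2" in methods or "pc-score-3" in methods:
        scores = fit_pca(x, 2).scores
        if "pc-score-2" in methods:
            parts["pc-score-2"] = cl.pc_score_clusters(scores, "2-group")
        if "pc-score-3" in methods:
            parts["pc-score-3"] = cl.pc_score_clusters(scores, "3-group")
    return parts, consensus


def run_full(config: RunConfig) -> dict:
    """Execute the full workflow; returns the bundle of in-memory results
    and writes all reports as CSV (plus a JSON run log) under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": []}
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2, default=list))
    results: dict = {}

    stage = "input"
    try:
        if config.input_path is None:
            sim = syn.simulate(syn.default_spec(), seed=config.seed)
            table = sim.table
            syn.write_truth(sim, out / "truth_labels.csv")
            results["simulation"] = sim
        else:
            table = dm.read_metabolite_table(config.input_path)
        results["table"] = table
        dm.write_metabolite_table(table, out / "individual_metabolites.csv")

        stage = "aggregate"
        sums = dm.aggregate_to_aglycones(table)
        results["sums"] = sums
        dm.write_metabolite_table(sums, out / "aglycone_sums.csv")

        stage = "pca-grid"
        if config.run_grid:
            grid = pca_grid_report(
                table.values.to_numpy(float),
                sums.values.to_numpy(float),
                config.n_components,
                config.folds,
            )
            grid.to_csv(out / "pca_grid_report.csv", index=False)
            results["pca_grid"] = grid
        log["stages"].append("pca-grid")

        if not config.run_clustering:
            (out / "run_log.json").write_text(json.dumps(log, indent=2))
            return results

        stage = "clustering"
        datasets = {"individual": table.values, "sums": sums.values}
        partitions: dict[tuple[str, str], cl.Partition] = {}
        for ds_name, values in datasets.items():
            x = _autoscaled(values)
            if config.k is not None:
                k = config.k
            elif config.run_select_k:
                sel = cl.select_k(
                    x,
                    config.algorithms,
                    config.k_range,
                    config.repeats,
                    config.seed,
                    config.index_panel,
                )
                results[f"k_selection_{ds_name}"] = sel
                sel.votes.to_csv(out / f"k_votes_{ds_name}.csv", index=False)
                k = sel.best_k
            else:
                k = 2
            log["stages"].append(f"select-k:{ds_name}:k={k}")
            parts, consensus = _clustering_partitions(
                x, k, config.methods, config.algorithms, config.seed
            )
            for m, p in parts.items():
                partitions[(ds_name, m)] = p
            if consensus is not None:
                vt = consensus.vote_table.copy()
                vt.insert(0, "sample_id", table.values.index)
                vt["consensus_label"] = consensus.partition.labels
                vt.to_csv(out / f"consensus_votes_{ds_name}.csv", index=False)
            label_df = pd.DataFrame(
                {m: p.labels for m, p in parts.items()}, index=table.values.index
            )
            label_df.to_csv(out / f"cluster_labels_{ds_name}.csv")
            pca = fit_pca(x, config.n_components)
            pd.DataFrame(
                pca.scores,
                index=table.values.index,
                columns=[f"PC{a + 1}" for a in range(config.n_components)],
            ).to_csv(out / f"pca_scores_{ds_name}.csv")
            pd.DataFrame(
                pca.loadings,
                index=values.columns,
                columns=[f"PC{a + 1}" for a in range(config.n_components)],
            ).to_csv(out / f"pca_loadings_{ds_name}.csv")
        results["partitions"] = partitions

        stage = "plsda"
        model_rows = []
        vip_rows = []
        for (ds_name, m), part in partitions.items():
            x_raw = datasets[ds_name].to_numpy(float)
            complete = ~np.isnan(x_raw).any(axis=1)
            xr, lab = x_raw[complete], part.labels[complete]
            model = pls.fit_plsda(xr, lab, config.n_components)
            q2 = pls.q2_cv_plsda(xr, lab, config.n_components, config.folds, config.seed)
            anova = pls.cv_anova(xr, lab, config.n_components, config.folds, config.seed)
            perm = pls.permutation_test(
                xr, lab, config.n_components, config.n_perm, config.seed, config.folds
            )
            model_rows.append(
                {
                    "clustering_method": m,
                    "dataset": ds_name,
                    "r2x_cum": model.r2x_cum,
                    "q2_cum": q2,
                    "cv_anova_p": anova.p_value,
                    "permutation_p": perm.p_value,
                }
            )
            vips = pls.vip_scores(model)
            for j, var in enumerate(datasets[ds_name].columns):
                vip_rows.append(
                    {
                        "clustering_method": m,
                        "dataset": ds_name,
                        "variable": var,
                        "vip": vips.vip[j],
                        "selected": bool(vips.vip[j] > 1.0),
                    }
                )
        plsda_report = pd.DataFrame(model_rows)
        plsda_report.to_csv(out / "plsda_models.csv", index=False)
        pd.DataFrame(vip_rows).to_csv(out / "vip_scores.csv", index=False)
        results["plsda_report"] = plsda_report

        stage = "univariate"
        for m in config.methods:
            key = ("individual", m)
            if key not in partitions:
                continue
            rep = uni.cluster_summary(table, partitions[key])
            rep.to_csv(out / f"univariate_{m}.csv", index=False)
            results[f"univariate_{m}"] = rep

        stage = "ratios"
        ratio = dm.sulfate_glucuronide_ratios(table)
        ratio_out = ratio.ratios.copy()
        ratio_out["sulfate_dominant"] = ratio.sulfate_dominant
        ratio_out.to_csv(out / "sulfate_glucuronide_ratios.csv")
        ratio.correlations.rename("pearson_r_vs_overall").to_csv(
            out / "ratio_correlations.csv"
        )
        results["ratios"] = ratio
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (config at {out / 'config.json'})"
        ) from exc

    log["stages"].append("done")
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return results
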