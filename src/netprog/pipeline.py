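"""Top-level pipeline driver: simulate -> score -> connect -> graph -> progress -> predict.

Each stage reads/writes plain-text artifacts in an output directory and every
run records provenance (configuration hash, seed, package version).  Stages
are toggleable; reruns with an identical configuration produce byte-identical
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from . import __version__
from .cohort import CohortConfig, default_anatomy, example_planted_edges, generate_cohort
from .connectivity import bootstrap_adjacency, detect_connection_changes, permutation_dr_threshold
from .expression import gmr_normalize, score_profiles
from .graphs import DEFAULT_GRID, compare_metrics, metric_sweep
from .longitudinal import bland_altman_rm_corr, fit_igm
from .phenoconversion import (
    PredictorConfig,
    dat_percent_normal,
    dat_sor,
    predict_conversion_time,
    summarize_predictions,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for one end-to-end run."""

    out_dir: str = "netprog_out"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    plant_example_edges: bool = True
    stages: tuple[str, ...] = ("simulate", "score", "connect", "graph", "progress", "predict")
    tau_r: float = 0.6
    tau_dr: float = 0.4
    B: int = 100
    n_permutations: int = 1000
    grid: tuple[float, ...] = DEFAULT_GRID
    n_null: int = 10
    graph_iterates: int = 25
    predictor: PredictorConfig = field(default_factory=PredictorConfig)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True, default_flow_style=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the toggled stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        k: int(np.random.default_rng(c).integers(2**31))
        for k, c in zip(["connect", "perm", "graph"], ss.spawn(3))
    }

    cohort_cfg = config.cohort
    if config.plant_example_edges and not (
        cohort_cfg.planted_gains or cohort_cfg.planted_losses
    ):
        from .cohort import generate_patterns

        pdrp, pdcp = generate_patterns(
            cohort_cfg.n_regions, cohort_cfg.overlap_fraction, seed=cohort_cfg.seed
        )
        gains, losses = example_planted_edges(pdrp, pdcp, seed=cohort_cfg.seed)
        cohort_cfg = dataclasses.replace(
            cohort_cfg, planted_gains=gains, planted_losses=losses
        )

    cohort = generate_cohort(cohort_cfg)
    anatomy = default_anatomy(
        cohort_cfg.n_regions,
        (*cohort_cfg.planted_gains, *cohort_cfg.planted_losses),
    )
    pdrp, pdcp = cohort.patterns["PDRP"], cohort.patterns["PDCP"]

    if "simulate" in config.stages:
        nio.write_profiles(cohort.hc_profiles, out / "profiles_hc.tsv")
        for k, ps in enumerate(cohort.case_profiles_by_timepoint):
            nio.write_profiles(ps, out / f"profiles_case_tp{k}.tsv")
        labels = cohort.hc_profiles.region_labels
        nio.write_pattern(pdrp, out / "pdrp.tsv", labels)
        nio.write_pattern(pdcp, out / "pdcp.tsv", labels)
        cohort.trajectories.to_csv(out / "trajectories.csv", index=False)
        cohort.dat_counts.to_csv(out / "dat_counts.csv", index=False)
        cohort.hc2_dat_counts.to_csv(out / "dat_counts_hc2.csv", index=False)
        nio.write_anatomy(anatomy, out / "anatomy.tsv")
        nio.write_json(cohort.truth, out / "truth.json")
        nio.write_cohort_config(cohort_cfg, out / "cohort.yaml")

    score_sets = None
    if "score" in config.stages:
        all_scores = []
        for pattern in (pdrp, pdcp):
            case_z, hc_z, _ = score_profiles(
                cohort.case_profiles_by_timepoint, cohort.hc_profiles, pattern
            )
            all_scores.extend(case_z)
            all_scores.append(hc_z)
        nio.write_scores(all_scores, out / "scores.csv")
        score_sets = all_scores

    if "connect" in config.stages:
        hc_norm = gmr_normalize(cohort.hc_profiles)
        null = permutation_dr_threshold(
            hc_norm, P=config.n_permutations, seed=seeds["perm"]
        )
        changes_all, tables = [], []
        for k, ps in enumerate(cohort.case_profiles_by_timepoint):
            changes, table = detect_connection_changes(
                gmr_normalize(ps),
                hc_norm,
                pdrp,
                pdcp,
                anatomy_edges=anatomy,
                tau_r=config.tau_r,
                tau_dr=config.tau_dr,
                B=config.B,
                seed=seeds["connect"] + k,
            )
            changes_all.extend(changes)
            tables.append(table)
        nio.write_changes(changes_all, out / "changes.csv")
        pd.concat(tables, ignore_index=True).to_csv(out / "change_categories.csv", index=False)
        nio.write_json(
            {"permutation_threshold": null.threshold, "alpha": null.alpha,
             "n_permutations": null.n_permutations},
            out / "permutation_null.json",
        )

    if "graph" in config.stages:
        rows = []
        comparisons = []
        hc_norm = gmr_normalize(cohort.hc_profiles)
        adj_hc = bootstrap_adjacency(
            hc_norm, B=config.graph_iterates, seed=seeds["graph"], keep_iterates=True
        )
        hc_set = metric_sweep(
            adj_hc, grid=config.grid, n_null=config.n_null, seed=seeds["graph"]
        )
        rows.append(hc_set.summarize().assign(group="HC"))
        for k, ps in enumerate(cohort.case_profiles_by_timepoint):
            adj = bootstrap_adjacency(
                gmr_normalize(ps),
                B=config.graph_iterates,
                seed=seeds["graph"] + 1 + k,
                keep_iterates=True,
            )
            case_set = metric_sweep(
                adj, grid=config.grid, n_null=config.n_null, seed=seeds["graph"] + 1 + k
            )
            rows.append(case_set.summarize().assign(group=f"case_tp{k}"))
            comparisons.append(
                compare_metrics(case_set, hc_set).assign(contrast=f"case_tp{k}-vs-HC")
            )
        pd.concat(rows, ignore_index=True).to_csv(out / "graph_metrics.csv", index=False)
        pd.concat(comparisons, ignore_index=True).to_csv(
            out / "graph_comparisons.csv", index=False
        )

    report = {}
    if "progress" in config.stages:
        tr = cohort.trajectories
        for measure in ("PDRP_z", "PDCP_z", "putamen_pct", "caudate_pct"):
            sub = tr[tr["measure"] == measure]
            est = fit_igm(sub.rename(columns={"timepoint_years": "time"}))
            report[measure] = dataclasses.asdict(est)
        pr = tr[tr["measure"] == "PDRP_z"].set_index(["subject", "timepoint_years"])["value"]
        pc = tr[tr["measure"] == "PDCP_z"].set_index(["subject", "timepoint_years"])["value"]
        joined = pd.concat([pr.rename("x"), pc.rename("y")], axis=1).dropna().reset_index()
        r, p = bland_altman_rm_corr(joined["x"], joined["y"], joined["subject"])
        report["pdrp_pdcp_rm_corr"] = {"r": r, "p": p}
        nio.write_json(report, out / "progression_report.json")

    if "predict" in config.stages:
        # final available DAT scan per subject -> % of HC2 normal mean
        hc2 = cohort.hc2_dat_counts
        hc_mean_put = float(
            np.mean([dat_sor(s, o) for s, o in zip(hc2["putamen_counts"], hc2["occipital_counts"])])
        )
        dc = cohort.dat_counts.sort_values("timepoint_years").groupby("subject").tail(1)
        tr = cohort.trajectories
        preds = []
        for _, row in dc.iterrows():
            sor = dat_sor(row["putamen_counts"], row["occipital_counts"])
            pct = dat_percent_normal(sor, hc_mean_put)
            zrows = tr[(tr["subject"] == row["subject"]) & (tr["measure"] == "PDRP_z")]
            z = float(zrows.sort_values("timepoint_years")["value"].iloc[-1])
            preds.append(
                dataclasses.asdict(
                    predict_conversion_time(z, pct, config.predictor, subject_id=row["subject"])
                )
            )
        pred_df = pd.DataFrame(preds)
        pred_df.to_csv(out / "predictions.csv", index=False)
        nio.write_json(
            summarize_predictions(pred_df["t_predicted"].to_numpy()),
            out / "prediction_summary.json",
        )

    nio.write_json(
        {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "netprog_version": __version__,
            "stages": list(config.stages),
        },
        out / "provenance.json",
    )
    return out
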