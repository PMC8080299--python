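"""End-to-end orchestration: simulate -> QC -> features -> EHR scoring ->
cohort -> classification grid -> distribution report, with every stage
output persisted and a manifest for byte-identical reruns."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import models, synth
from .bouts import PHASES, features_table, occupancy_24h

log = logging.getLogger("actibout")


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run; fully serialisable."""

    population: synth.PopulationConfig = field(default_factory=synth.PopulationConfig)
    gap_tolerance_epochs: int = 60
    qc_min_hours: float = 72.0
    window_before_months: int = 6
    window_after_months: int = 1
    band_thresholds: tuple[float, float] = (0.5, 1.5)
    impute_k: int = 5
    folds: int = 10
    train_fraction: float = 0.8
    holdout: bool = True
    algorithms: tuple[str, ...] = models.ALGORITHMS
    feature_sets: tuple[str, ...] = models.FEATURE_SETS
    seed: int = 0
    histogram_bins: int = 30

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_thresholds"] = list(self.band_thresholds)
        d["algorithms"] = list(self.algorithms)
        d["feature_sets"] = list(self.feature_sets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pop = d.pop("population", {})
        cfg = cls(population=synth.PopulationConfig(**pop))
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            if key in ("band_thresholds", "algorithms", "feature_sets"):
                val = tuple(val)
            setattr(cfg, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def sleep_summary_24h(features: pd.DataFrame, phase_map: dict) -> pd.DataFrame:
    """Per-participant daily-average sleep summaries aggregated to 24 h:
    percentage of the day asleep, number of sleep bouts, mean sleep-bout
    length (epochs)."""
    rows = {}
    for pid, phases in phase_map.items():
        feats = features.loc[pid]
        occ = occupancy_24h(feats, phases)
        n_bouts = sum(feats[f"sleep_{p}_n_bouts"] for p in PHASES)
        total_epochs = sum(
            feats[f"sleep_{p}_n_bouts"] * feats[f"sleep_{p}_mean_bout_len"] for p in PHASES
        )
        rows[pid] = {
            "sleep_pct_24h": occ["sleep"],
            "sleep_n_bouts_24h": n_bouts,
            "sleep_mean_bout_len_24h": total_epochs / n_bouts if n_bouts else 0.0,
        }
    df = pd.DataFrame(rows).T
    df.index.name = "participant_id"
    return df


def occupancy_table(features: pd.DataFrame, phase_map: dict) -> pd.DataFrame:
    """24-h occupancy (%) per activity class per participant."""
    rows = {pid: occupancy_24h(features.loc[pid], phase_map[pid]) for pid in phase_map}
    df = pd.DataFrame(rows).T
    df.index.name = "participant_id"
    return df


def mean_control_occupancy(
    n: int = 200, days: int = 7, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """Population mean 24-h occupancy (%) per activity class for ``n``
    synthetic control participants under the default control profile,
    computed through the full bout-feature pipeline (sleep-window
    detection, phase partition, per-phase percentages aggregated back to
    24 h). Returns (mean occupancy, per-participant table)."""
    profile = synth.default_control_profile()
    ss = np.random.SeedSequence(seed)
    traces = {
        f"P{i:04d}": synth.generate_trace(
            profile, days=days, seed=np.random.default_rng(child), participant_id=f"P{i:04d}"
        )
        for i, child in enumerate(ss.spawn(n))
    }
    feats, phase_map, _ = features_table(traces)
    occ = occupancy_table(feats, phase_map)
    return occ.mean(), occ


def histogram_report(
    values: pd.DataFrame, groups: pd.Series, bins: int = 30
) -> pd.DataFrame:
    """Binned counts per metric and group over shared bin edges."""
    if groups.nunique() < 2:
        raise ValueError("distribution report needs at least two groups")
    out = []
    for col in values.columns:
        v = values[col].dropna()
        edges = np.histogram_bin_edges(v, bins=bins)
        for g, idx in groups.groupby(groups).groups.items():
            sel = values.loc[values.index.intersection(idx), col].dropna()
            if len(sel) == 0:
                raise ValueError(f"empty group {g!r} for metric {col!r}")
            counts, _ = np.histogram(sel, bins=edges)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                out.append(
                    {"metric": col, "group": g, "bin_left": lo, "bin_right": hi, "count": int(c)}
                )
    return pd.DataFrame(out)


def write_distribution_report(
    values: pd.DataFrame,
    groups: pd.Series,
    outdir: str | Path,
    bins: int = 30,
    plot: bool = True,
) -> pd.DataFrame:
    """Histogram CSV (and PNG overlays) of the daily-average sleep metrics
    per group."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hist = histogram_report(values, groups, bins=bins)
    hist.to_csv(outdir / "distributions.csv", index=False)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for col in values.columns:
            fig, ax = plt.subplots(figsize=(6, 4))
            for g in sorted(groups.unique()):
                sub = hist[(hist["metric"] == col) & (hist["group"] == g)]
                centers = (sub["bin_left"] + sub["bin_right"]) / 2
                ax.step(centers, sub["count"], where="mid", label=str(g))
            ax.set_xlabel(col)
            ax.set_ylabel("participants")
            ax.legend()
            fig.tight_layout()
            fig.savefig(outdir / f"hist_{col}.png", dpi=100)
            plt.close(fig)
    return hist


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline into ``outdir``; see the stage log for
    Figure-1-style attrition counts. Raises with the stage name on failure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    log.info("stage simulate: generating population (seed=%d)", config.population.seed)
    pop = synth.generate_population(config.population)
    pop.demographics.to_csv(outdir / "demographics.csv", index=False)
    pop.ehr.to_csv(outdir / "ehr.csv", index=False)
    pop.selfreport.to_csv(outdir / "selfreport.csv", index=False)
    pop.wear.to_csv(outdir / "wear.csv", index=False)
    pop.labels.to_frame().reset_index().to_csv(outdir / "labels.csv", index=False)
    stages["simulate"] = {"participants": len(pop.labels)}

    log.info("stage features: QC + bout features for %d traces", len(pop.traces))
    feats, phase_map, qc = features_table(
        pop.traces,
        gap_tolerance_epochs=config.gap_tolerance_epochs,
        qc_min_hours=config.qc_min_hours,
    )
    qc.to_csv(outdir / "qc.csv", index=False)
    feats.round(6).to_csv(outdir / "features.csv")
    stages["features"] = {"qc_pass": int(qc["qc_pass"].sum()), "qc_fail": int((~qc["qc_pass"]).sum())}

    log.info("stage cohort: EHR scoring and stratification")
    assignments = cohort_mod.build_cohort(
        pop.selfreport,
        pop.ehr,
        pop.wear,
        window_before_months=config.window_before_months,
        window_after_months=config.window_after_months,
        band_thresholds=config.band_thresholds,
    )
    # participants failing wear-time QC leave the cohort here
    passed = set(qc.loc[qc["qc_pass"], "participant_id"])
    assignments.loc[~assignments["participant_id"].isin(passed), "label"] = (
        cohort_mod.LABEL_EXCLUDED
    )
    assignments.loc[
        ~assignments["participant_id"].isin(passed), "exclusion_reason"
    ] = "wear-time-qc"
    assignments.to_csv(outdir / "cohort.csv", index=False)
    stages["cohort"] = assignments["label"].value_counts().to_dict()

    try:
        ts1, ts2 = cohort_mod.build_training_sets(assignments, seed=config.seed)
    except ValueError as exc:
        raise RuntimeError(f"stage cohort failed: {exc}") from exc
    ts1.table.to_csv(outdir / "training_set_1.csv", index=False)
    ts2.table.to_csv(outdir / "training_set_2.csv", index=False)

    log.info("stage impute: kNN imputation (k=%d)", config.impute_k)
    demo_imputed = models.impute_knn(pop.demographics, k=config.impute_k)
    demo_imputed.to_csv(outdir / "demographics_imputed.csv", index=False)

    log.info("stage grid: %d x %d x 2 models, %d-fold CV",
             len(config.algorithms), len(config.feature_sets), config.folds)
    results = models.run_grid(
        (ts1, ts2),
        feats,
        demo_imputed,
        algorithms=config.algorithms,
        feature_sets=config.feature_sets,
        folds=config.folds,
        seed=config.seed,
        holdout=config.holdout,
        train_fraction=config.train_fraction,
    )
    table = models.results_table(results)
    table.round(6).to_csv(outdir / "results_full.csv", index=False)
    models.auc_pivot(results).round(4).to_csv(outdir / "results_auc.csv")
    f1 = table[table["mode"] == "cv"].melt(
        id_vars=["algorithm", "feature_set", "training_set"],
        value_vars=["f1_pos", "f1_neg"],
        var_name="class",
        value_name="f1",
    )
    f1.round(6).to_csv(outdir / "results_f1.csv", index=False)
    roc_dir = outdir / "roc"
    roc_dir.mkdir(exist_ok=True)
    for r in results:
        if r.mode != "cv":
            continue
        tag = f"{r.training_set}_{r.feature_set}_{r.algorithm}"
        pd.DataFrame({"fpr": r.roc[0], "tpr": r.roc[1]}).round(6).to_csv(
            roc_dir / f"roc_{tag}.csv", index=False
        )
    stages["grid"] = {"models_cv": sum(r.mode == "cv" for r in results)}

    log.info("stage report: distribution histograms")
    summary = sleep_summary_24h(feats, phase_map)
    grp = pop.labels.reindex(summary.index)
    grp = grp.replace({"impaired_control": "control"})
    write_distribution_report(summary, grp, outdir / "report", bins=config.histogram_bins)
    occupancy_table(feats, phase_map).round(6).to_csv(outdir / "occupancy_24h.csv")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir
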