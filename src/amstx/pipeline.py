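"""End-to-end orchestration: simulate/load -> preprocess -> differential
expression -> cross-cohort biomarkers -> classifier panels.

``run_all`` executes every stage from a single :class:`RunConfig`, writes
TSV artifacts per stage plus a JSON manifest (parameters, seed, stage
outputs, sample/gene counts), and is byte-reproducible for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import biomarkers, io, panel, preprocess, simulate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; ``simulate`` may be overridden by input paths."""

    out_dir: str = "amstx_run"
    seed: int = 0
    # inputs: either explicit tables, or a simulation
    counts_paths: dict[str, str] | None = None  # cohort -> counts TSV
    meta_path: str | None = None
    sim: simulate.SimConfig | None = None
    # preprocessing
    low_threshold: int = 10
    max_low_fraction: float = 0.2
    knn_k: int = 5
    trim_M: float = 0.30
    trim_A: float = 0.05
    # differential expression / DEG calling
    prior_df: float = 10.0
    p_max: float = 0.05
    lfc_min: float = 0.7
    # panel selection
    n_trees: int = panel.DEFAULT_N_TREES
    svm_C: float = 1.0
    max_k: int | None = None
    categories: tuple[str, ...] = field(
        default_factory=lambda: biomarkers.CATEGORIES
    )

    def __post_init__(self) -> None:
        if not (0 < self.p_max <= 1) and self.p_max != 0:
            raise ValueError("p_max must lie in [0, 1]")
        if self.lfc_min < 0 or self.prior_df <= 0 or self.n_trees < 1:
            raise ValueError("invalid DE/panel parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "cohorts" in sim_raw:
                sim_raw["cohorts"] = tuple(
                    simulate.CohortSpec(
                        **{
                            **c,
                            "attrition": tuple(
                                (int(i), tp) for i, tp in c.get("attrition", [])
                            ),
                        }
                    )
                    for c in sim_raw["cohorts"]
                )
            if "signal_sets" in sim_raw:
                sim_raw["signal_sets"] = {
                    k: simulate.SignalSpec(**v) for k, v in sim_raw["signal_sets"].items()
                }
            raw["sim"] = simulate.SimConfig(**sim_raw)
        if "categories" in raw:
            raw["categories"] = tuple(raw["categories"])
        return cls(**raw)


def _preprocess_cohort(counts: pd.DataFrame, cfg: RunConfig):
    counts_int, factors, logcpm = preprocess.prepare_counts(
        counts, cfg.low_threshold, cfg.max_low_fraction, cfg.knn_k,
        cfg.trim_M, cfg.trim_A,
    )
    pca = preprocess.pca_outlier_check(logcpm)
    return counts_int, factors, logcpm, pca


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": _jsonable(asdict(config)),
        "stages": [],
        "outputs": {},
    }

    # ---- inputs -----------------------------------------------------------
    if config.counts_paths is not None:
        if config.meta_path is None:
            raise ValueError("counts_paths given without meta_path")
        counts = {c: io.read_counts(p) for c, p in config.counts_paths.items()}
        meta = io.read_meta(config.meta_path)
        manifest["inputs"] = {
            c: _sha256(p) for c, p in config.counts_paths.items()
        } | {"meta": _sha256(config.meta_path)}
    else:
        sim_cfg = config.sim or simulate.SimConfig(seed=config.seed)
        study = simulate.generate_study(sim_cfg)
        counts, meta = study.counts, study.meta
        for name, mat in counts.items():
            io.write_counts(mat, out / f"counts_{name}.tsv")
        io.write_meta(meta, out / "meta.tsv")
        manifest["inputs"] = {"simulated": True, "sim_seed": sim_cfg.seed}
    cohort_names = list(counts)
    if len(cohort_names) != 2:
        raise ValueError(f"pipeline expects exactly 2 cohorts, got {cohort_names}")
    manifest["stages"].append("inputs")

    # ---- preprocessing (per cohort, separate sequencing batches) ----------
    prep = {}
    for name in cohort_names:
        try:
            prep[name] = _preprocess_cohort(counts[name], config)
        except ValueError as e:
            raise RuntimeError(f"preprocess failed for cohort {name}: {e}") from e
        counts_int, factors, logcpm, pca = prep[name]
        meta_c = meta[meta["cohort"] == name]
        meta = pd.concat(
            [meta[meta["cohort"] != name], meta_c.loc[meta_c.index.intersection(counts_int.columns)]]
        )
        manifest["outputs"][f"preprocess_{name}"] = {
            "n_genes": int(counts_int.shape[0]),
            "n_samples": int(counts_int.shape[1]),
            "pca_flagged": pca.flagged,
        }
    meta = meta.sort_index()
    manifest["stages"].append("preprocess")

    # ---- differential expression: 4 contrasts x 2 cohorts -----------------
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for category in config.categories:
        spec = biomarkers.ContrastSpec.for_category(category)
        for name in cohort_names:
            counts_int, factors, _, _ = prep[name]
            meta_c = meta[meta["cohort"] == name]
            res = biomarkers.run_contrast(
                counts_int, meta_c, spec, cohort=name,
                prior_df=config.prior_df, offsets=factors,
            )
            results[(category, name)] = res
            path = out / f"de_{category}_{name}.tsv"
            res.drop(columns=["converged"]).to_csv(path, sep="\t", float_format="%.6g")
            up = int(((res["PV"] < config.p_max) & (res["log2FC"] > config.lfc_min)).sum())
            down = int(((res["PV"] < config.p_max) & (res["log2FC"] < -config.lfc_min)).sum())
            log.info("DE %s/%s: %d up, %d down", category, name, up, down)
            manifest["outputs"][f"de_{category}_{name}"] = {
                "n_tested": len(res), "n_up": up, "n_down": down,
                "common_dispersion": res.attrs["common_dispersion"],
            }
    manifest["stages"].append("diffexpr")

    # ---- cross-cohort replication -----------------------------------------
    sets: dict[str, biomarkers.BiomarkerSet] = {}
    a, b = cohort_names
    for category in config.categories:
        bset = biomarkers.common_degs(
            results[(category, a)], results[(category, b)],
            p_max=config.p_max, lfc_min=config.lfc_min,
            category=category, cohorts=(a, b),
        )
        sets[category] = bset
        bset.table.to_csv(out / f"biomarkers_{category}.tsv", sep="\t", float_format="%.6g")
        n_up, n_down = biomarkers.direction_counts(bset)
        manifest["outputs"][f"biomarkers_{category}"] = {
            "n_genes": len(bset), "n_up": n_up, "n_down": n_down,
        }
    if len(sets) >= 2:
        conv = biomarkers.converged_genes(list(sets.values()))
        conv.to_csv(out / "converged_genes.tsv", sep="\t")
        manifest["outputs"]["converged"] = {
            "n_multi_category": int((conv["n_categories"] >= 2).sum())
        }
    incidence = biomarkers.incidence_summary(meta)
    incidence.to_csv(out / "incidence.tsv", sep="\t")
    manifest["outputs"]["incidence"] = {
        c: {"n_severe": int(r["n_severe"]), "n_total": int(r["n_total"]),
            "percent": int(r["percent"])}
        for c, r in incidence.iterrows()
    }
    manifest["stages"].append("biomarkers")

    # ---- classifier panels -------------------------------------------------
    for category, labeler in (
        ("diagnostic", panel.diagnostic_labels),
        ("predictive", panel.predictive_labels),
    ):
        if category not in sets:
            continue
        pool = sets[category].genes
        if not pool:
            log.info("panel %s skipped: empty biomarker pool", category)
            manifest["outputs"][f"panel_{category}"] = {"skipped": "empty pool"}
            continue
        feats = {}
        skip = None
        for name in cohort_names:
            _, _, logcpm, _ = prep[name]
            meta_c = meta[meta["cohort"] == name]
            labels = labeler(meta_c)
            if labels.nunique() < 2:
                skip = f"cohort {name} labels single-class"
                break
            pool_avail = [g for g in pool if g in logcpm.index]
            feats[name] = panel.build_features(logcpm, meta_c, pool_avail, labels, name)
        if skip:
            log.info("panel %s skipped: %s", category, skip)
            manifest["outputs"][f"panel_{category}"] = {"skipped": skip}
            continue
        ranking = panel.gini_rank(feats[a], n_trees=config.n_trees, seed=config.seed)
        traj = panel.forward_trajectory(
            ranking, feats[a], feats[b], max_k=config.max_k, C=config.svm_C
        )
        traj.entries.to_csv(out / f"panel_{category}_trajectory.tsv", sep="\t",
                            index=False, float_format="%.6g")
        best_clf = panel.train_linear_classifier(feats[a], list(traj.best_genes), C=config.svm_C)
        roc = panel.roc_auc(best_clf.decision_scores(feats[b].features), feats[b].labels)
        pd.DataFrame({
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }).to_csv(out / f"panel_{category}_roc.tsv", sep="\t", index=False,
                  float_format="%.6g")
        thr, sens, spec_ = roc.youden()
        manifest["outputs"][f"panel_{category}"] = {
            "pool_size": len(pool),
            "ranking": list(ranking.genes),
            "best_k": traj.best_k,
            "best_genes": list(traj.best_genes),
            "test_auc": traj.best_auc,
            "youden": {"threshold": thr, "sensitivity": sens, "specificity": spec_},
        }
    manifest["stages"].append("panel")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
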