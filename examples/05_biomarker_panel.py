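"""Forward-selected diagnostic classifier panel across cohorts.

Ranks the replicated diagnostic biomarkers by random-forest Gini importance
on the discovery cohort (positives = HA samples of severe subjects), then
grows linear-SVM panels gene by gene and evaluates each on the held-out
validation cohort by ROC AUC, picking the operating threshold by the Youden
index. A reduced forest (1,000 trees instead of the default 10,000) keeps
this example quick; the ranking is already stable at this size.
"""

from amstx import biomarkers, panel, preprocess, simulate
from amstx.simulate import SignalSpec, SimConfig

cfg = SimConfig(seed=7, signal_sets={"diagnostic": SignalSpec(20, 2.0)})
study = simulate.generate_study(cfg)

features, results = {}, {}
spec = biomarkers.ContrastSpec.for_category("diagnostic")
for name in ("PikesPeak", "Chamber"):
    counts, factors, logcpm = preprocess.prepare_counts(study.counts[name])
    meta = study.meta[study.meta["cohort"] == name]
    results[name] = biomarkers.run_contrast(counts, meta, spec, cohort=name, offsets=factors)
    features[name] = (logcpm, meta)

pool = biomarkers.common_degs(results["PikesPeak"], results["Chamber"]).genes
print(f"replicated biomarker pool: {len(pool)} genes")

built = {}
for name, (logcpm, meta) in features.items():
    avail = [g for g in pool if g in logcpm.index]
    labels = panel.diagnostic_labels(meta)
    built[name] = panel.build_features(logcpm, meta, avail, labels, name)
    print(f"  {name}: {int(labels.sum())} AMS+ / {int((1 - labels).sum())} AMS- samples")

ranking = panel.gini_rank(built["PikesPeak"], n_trees=1000, seed=7)
traj = panel.forward_trajectory(ranking, built["PikesPeak"], built["Chamber"])

print("\nforward trajectory (panel size, validation AUC):")
print(traj.entries[["k", "auc", "sensitivity", "specificity"]].head(8).to_string(index=False))
print(f"\nbest panel: k={traj.best_k}, genes={list(traj.best_genes)}, "
      f"validation AUC {traj.best_auc:.3f}")
planted = set(study.planted["diagnostic"])
print(f"planted diagnostic genes in best panel: {len(planted & set(traj.best_genes))}")
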