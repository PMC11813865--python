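"""Run the whole pipeline (simulate -> preprocess -> DE -> biomarkers ->
panels) from one config and read its manifest.

A reduced simulation (600 genes, 500 trees) keeps the example under a
minute; output tables land in ./scratch/pipeline_demo.
"""

from amstx import pipeline, simulate

config = pipeline.RunConfig(
    out_dir="scratch/pipeline_demo",
    seed=3,
    sim=simulate.SimConfig(n_genes=600, seed=3),
    n_trees=500,
)
manifest = pipeline.run_all(config)

print("stages:", " -> ".join(manifest["stages"]))
print("\nDE summaries (category/cohort: up / down DEGs):")
for key, val in manifest["outputs"].items():
    if key.startswith("de_"):
        print(f"  {key[3:]}: {val['n_up']} up, {val['n_down']} down")

print("\nreplicated biomarkers per category:")
for cat in ("diagnostic", "predictive", "pathogenic", "protective"):
    val = manifest["outputs"][f"biomarkers_{cat}"]
    print(f"  {cat}: {val['n_genes']} genes ({val['n_up']} up, {val['n_down']} down)")

diag = manifest["outputs"]["panel_diagnostic"]
if "skipped" not in diag:
    print(f"\ndiagnostic panel: best k={diag['best_k']}, test AUC {diag['test_auc']:.3f}, "
          f"Youden sens {diag['youden']['sensitivity']:.2f} / "
          f"spec {diag['youden']['specificity']:.2f}")
print("\nfull manifest written to scratch/pipeline_demo/manifest.json")
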