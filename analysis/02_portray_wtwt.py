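#!/usr/bin/env python
"""Full SOM portrayal of the wt/wt culture.

Runs QC, normalization, SOM training, spot segmentation, group discovery
and gene-set scoring on the simulated wt/wt culture (run
01_simulate_cultures.py first), persists every intermediate under
results/wtwt_run/ and prints the group/spot inventory.
"""

import json
from pathlib import Path

from somcell.pipeline import PipelineParams, RunConfig, run_pipeline
from somcell.synthetic import preset

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated" / "wtwt"
OUT = ROOT / "results" / "wtwt_run"

cfg = RunConfig(
    matrix_path=str(SIM / "matrix.tsv"),
    out_dir=str(OUT),
    annotation_path=str(SIM / "annotation.tsv"),
    gmt_path=str(SIM / "truth_sets.gmt"),
    params=PipelineParams(seed=preset("wtwt").seed),
)
report = run_pipeline(cfg)

print(f"QC: {report.qc['n_retained']} of {report.qc['n_input_cells']} cells retained")
print(f"groups: {report.n_groups}")
for g, pct in sorted(report.group_percentages.items()):
    print(f"  group {g}: {report.group_sizes[g]} cells ({pct:.1f}%)")
print(f"spots: {len(report.spots)}")
for s in report.spots:
    print(f"  spot {s['label']}: {s['n_units']} units, {s['n_genes']} genes, "
          f"top genes {', '.join(s['top_10_genes'][:5])} ...")
sig = report.enrichment
print(f"significant spot/set enrichments (p < 1e-7): {len(sig)}")
for row in sig[:8]:
    print(f"  spot {row['spot']} ~ {row['set']}: a={row['a']}, p={row['p']:.3g}")
print(f"full report: {OUT / 'report.json'}")

# render the summary portrait alongside the tables
from somcell.som import SOMModel, mean_portrait  # noqa: E402
from somcell.viz import portrait_png  # noqa: E402

model = SOMModel.load(OUT / "som")
fig_dir = OUT / "figures"
fig_dir.mkdir(exist_ok=True)
portrait_png(mean_portrait(model, model.cell_ids), fig_dir / "mean_portrait.png")
print(f"figures under {fig_dir}")
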