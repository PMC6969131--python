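"""Group-level inference on the pipeline outputs.

Hemisphere-mean AUC Welch t-tests (healthy vs IVH), the channel x time-bin
cluster-based permutation test on the 1-Hz-binned HbO responses, and the
mixed ANOVAs on GFP and projection measures (peaks 2-4 x repetition x
group).  Writes results/stats/group_stats.json.
"""

import json
from pathlib import Path

from nvcouple.config import PipelineConfig
from nvcouple.pipeline import run_stats_stage

ROOT = Path(__file__).resolve().parents[1]
report = run_stats_stage(ROOT / "results" / "nirs", ROOT / "results" / "eeg",
                         ROOT / "results" / "stats", PipelineConfig(seed=2026))

for h, c in report["auc_comparison"].items():
    print(f"AUC {h}: healthy median {c['median_a']:.3f} (IQR {c['iqr_a']:.2f}) vs "
          f"IVH {c['median_b']:.3f} (IQR {c['iqr_b']:.2f}); t={c['t']:.2f}, p={c['p']:.4g}")
sig = [c for c in report["clusters"] if c["p_value"] <= 0.05]
print(f"clusters: {len(report['clusters'])} formed, {len(sig)} significant at 0.05")
if sig:
    print(f"largest cluster spans channels {sig[0]['channels']} (p={sig[0]['p_value']:.4g})")
for name in ("gfp_anova", "projection_anova"):
    if name in report:
        print(name + ":")
        for row in report[name]:
            print(f"  {row['effect']:24s} F({row['df_num']},{row['df_den']}) = "
                  f"{row['f']:8.2f}  p = {row['p']:.4g}")
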