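"""Figures: group-mean HbO/Hb block responses and grand-average GFP.

Reads the cohort dataset and pipeline outputs; writes PNGs to
results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from nvcouple import dataset as ds
from nvcouple.config import PipelineConfig
from nvcouple.eeg import compute_gfp, eeg_subject_pipeline
from nvcouple.nirs import nirs_subject_pipeline
from nvcouple.probe import build_probe

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "dataset"
OUT = ROOT / "results" / "figures"
OUT.mkdir(parents=True, exist_ok=True)

manifest = ds.read_manifest(DATA)
layout = build_probe()

hemo = {"healthy": [], "IVH": []}
gfps = {"healthy": [], "IVH": []}
for rec in manifest["subjects"]:
    _, schedule, raw_nirs, raw_eeg = ds.read_subject(DATA, rec["subject_id"])
    resp = nirs_subject_pipeline(raw_nirs, schedule, layout)
    hemo[rec["group"]].append((resp.times(), resp.mean_hbo.mean(0), resp.mean_hb.mean(0)))
    erp = eeg_subject_pipeline(raw_eeg, schedule)
    g = compute_gfp(erp)
    gfps[rec["group"]].append((g.times(), g.gfp))

fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
for ax, group in zip(axes, ("healthy", "IVH")):
    t = hemo[group][0][0]
    hbo = np.mean([h for _, h, _ in hemo[group]], axis=0)
    hb = np.mean([h for _, _, h in hemo[group]], axis=0)
    ax.axvspan(0, 20, color="0.92")
    ax.plot(t, hbo, "r", label="HbO")
    ax.plot(t, hb, "b", label="Hb")
    ax.axvline(0, color="k", lw=0.5)
    ax.set(title=group, xlabel="time from block onset (s)")
axes[0].set_ylabel("Δ concentration (µM)")
axes[0].legend()
fig.tight_layout()
fig.savefig(OUT / "hemodynamic_response.png", dpi=150)

fig, ax = plt.subplots(figsize=(7, 3))
for group, color in (("healthy", "C0"), ("IVH", "C3")):
    t = gfps[group][0][0] * 1e3
    g = np.mean([v for _, v in gfps[group]], axis=0)
    ax.plot(t, g, color=color, label=group)
for onset in (0, 600, 1200, 1800):
    ax.axvline(onset, color="k", ls=":", lw=0.5)
ax.set(xlabel="time from S1 onset (ms)", ylabel="GFP (µV)", xlim=(-200, 2600))
ax.legend()
fig.tight_layout()
fig.savefig(OUT / "gfp_grand_average.png", dpi=150)
print(f"figures -> {OUT}")
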