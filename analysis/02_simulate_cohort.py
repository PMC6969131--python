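"""Simulate the synthetic healthy / IVH cohort.

12 healthy and 7 IVH subjects, 6 blocks each (desk scale), both modalities,
written to scratch/dataset (large raw recordings stay out of results/).
Healthy subjects carry full neurovascular coupling gain on every channel;
IVH subjects have zero gain except a 0.4 residual on one right-temporal
channel, with neural (ERP) parameters identical across groups.
"""

from pathlib import Path

from nvcouple.synthetic import simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "dataset"

manifest = simulate_cohort(n_healthy=12, n_ivh=7, n_blocks=6, seed=2026, out_dir=DATA)
groups = [s["group"] for s in manifest["subjects"]]
print(f"wrote {len(manifest['subjects'])} subjects "
      f"({groups.count('healthy')} healthy, {groups.count('IVH')} IVH) -> {DATA}")
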