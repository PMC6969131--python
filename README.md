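# nvcouple

Neurovascular coupling analysis of syllable-evoked responses in preterm
neonates, combining event-related potentials (EEG) and optical topography
(fNIRS), together with a seeded synthetic-cohort generator that makes every
stage of the analysis verifiable without clinical data.

## The scientific problem

Very preterm neonates with high-grade intraventricular hemorrhage (IVH) may
process sounds normally at the neural level while failing to mount the
hemodynamic response that functional neuroimaging relies on — a decoupling
of the neurovascular unit. Testing this requires measuring, in the same
block-design auditory paradigm (trials of four syllables, SOA 600 ms, 20 s
of stimulation followed by 40 s of silence):

- the **neural response**: syllable-locked ERPs with four components at
  84/244/378/576 ms whose amplitude decreases with syllable repetition
  (habituation), summarized by the global field power
  `GFP(t) = SD over electrodes of V(·, t)` and by the projection of each
  subject's voltage topography onto leave-one-out healthy template maps;
- the **hemodynamic response**: oxy-/deoxy-hemoglobin concentration changes
  from two-wavelength (690/830 nm) intensities through the modified
  Beer-Lambert law, `ΔOD(λ) = (ε_HbO(λ) Δ[HbO] + ε_Hb(λ) Δ[Hb]) · d · DPF`,
  summarized per channel by the area under the mean HbO response
  (`AUC = ∫ Δ[HbO] dt` over the first 10 s of stimulation) and compared
  between groups with hemisphere-mean Welch t-tests and a cluster-based
  permutation test on the 20-channel × 30-time-bin response
  (max-sum cluster mass, max-statistic permutation null).

The package implements both processing chains exactly as specified for this
paradigm — fNIRS: MBLL → z-score block rejection (|z| > 4) → zero-phase
0.03–0.5 Hz Butterworth band-pass → segmentation [−5, +25] s → linear
detrend → baseline correction → averaging; EEG: 1–20 Hz band-pass →
512 Hz → 4-s trial epochs → threshold artifact cascade (50 µV absolute,
30 µV ten-sample jump, 70 % session rule, 15 % trial rule) → subject ERP —
plus the group statistics (Welch t, cluster permutation test, balanced
split-plot ANOVA computed from sums of squares).

Because no raw clinical recordings are distributable, `nvcouple.synthetic`
generates seeded cohorts embedding the structures the analysis assumes:
discontinuous neonatal EEG background (≈10 µV interburst, ≈300 µV bursts
random with respect to stimulation), habituating ERP components, a
gamma-shaped hemodynamic response peaking 7 s after block onset, slow
drifts, a 164 BPM cardiac oscillation, and a group contrast in
neurovascular coupling gain (healthy: 1.0 everywhere; IVH: 0 everywhere
except a 0.4 residual on one right-temporal channel) with identical neural
parameters in both groups.

## Worked example

```bash
python analysis/01_build_paradigm.py
python analysis/02_simulate_cohort.py     # 12 healthy + 7 IVH -> scratch/dataset
python analysis/03_nirs_pipeline.py
python analysis/04_eeg_pipeline.py
python analysis/05_group_stats.py
```

The final step prints (seed 2026, 6 blocks per subject):

```
AUC L: healthy median 2.037 (IQR 0.03) vs IVH -0.025 (IQR 0.03); t=207.28, p=7.18e-21
AUC R: healthy median 2.037 (IQR 0.04) vs IVH 0.068 (IQR 0.03); t=182.47, p=2.832e-28
clusters: 6 formed, 6 significant at 0.05
gfp_anova:
  group                    F(1,17) =     0.00  p = 0.9816
  repetition               F(3,51) =   120.03  p = 4.19e-23
  repetition*group         F(3,51) =     0.26  p = 0.8557
```

Read: the hemodynamic response is abolished in the IVH arm (hemisphere AUC
medians near zero, both hemispheres significant), while the neural response
is preserved — no group effect on GFP, a strong repetition (habituation)
effect, and no repetition × group interaction. This is the dissociation
the analysis is designed to detect.

The same machinery is available as a CLI
(`nvcouple paradigm|simulate|nirs|eeg|stats|run-all`) and as library
functions (`nvcouple.build_paradigm`, `nvcouple.mbll_convert`,
`nvcouple.cluster_permutation_test`, ...).

## Layout

- `src/nvcouple/` — library: `paradigm`, `probe`, `montage`, `synthetic`,
  `nirs`, `eeg`, `stats`, `config`, `dataset`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — models, parameters, numerical choices, limitations
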