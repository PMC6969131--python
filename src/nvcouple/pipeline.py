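"""End-to-end orchestration: simulate -> fNIRS -> EEG -> group statistics.

Each stage writes tidy tables (TSV) and JSON results stamped with the
configuration digest and master seed, and the final report collects
retained-block/trial counts, the hemisphere AUC comparison, the cluster
summary, and the GFP / template-projection ANOVA tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset as ds
from . import eeg as eegmod
from . import nirs as nirsmod
from . import stats as statsmod
from .config import PipelineConfig
from .nirs import compute_sto2
from .probe import ProbeLayout, build_probe, channel_adjacency
from .synthetic import SubjectParams, simulate_cohort


def run_nirs_stage(data_dir, out_dir, config: PipelineConfig) -> pd.DataFrame:
    """Per-subject fNIRS pipeline over a dataset; writes channel AUC table.

    Returns a tidy frame (subject, group, hemisphere, channel, auc, plus the
    whole-stimulation-window AUC and counts)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = ds.read_manifest(data_dir)
    layout = ProbeLayout.from_json(Path(data_dir) / "probe_layout.json")
    hemis = layout.hemisphere_of()
    rows = []
    responses = {}
    for rec in manifest["subjects"]:
        params, schedule, raw, _ = ds.read_subject(data_dir, rec["subject_id"])
        if raw is None:
            continue
        conc = nirsmod.mbll_convert(
            raw, dpf=config.dpf, separation_mm=config.separation_mm
        )
        z = nirsmod.znormalize(conc)
        mask = nirsmod.reject_blocks(
            z, schedule, threshold=config.z_threshold,
            window_s=config.block_window_s, signed=config.z_signed,
        )
        carried = z if config.analyze_in == "z" else conc
        filt = nirsmod.bandpass_nirs(carried, band_hz=config.nirs_band_hz,
                                     order=config.nirs_filter_order)
        epochs = nirsmod.segment_and_correct(
            filt, schedule, mask,
            window_s=config.block_window_s, baseline_s=config.baseline_window_s,
        )
        sto2 = float(
            compute_sto2(params["baseline_hbo_uM"], params["baseline_hb_uM"])
        )
        resp = nirsmod.subject_response(
            epochs, layout=layout, auc_window_s=config.auc_window_s, sto2=sto2
        )
        auc_full = nirsmod._windowed_trapezoid(
            resp.times(), resp.mean_hbo, *config.auc_window_full_s
        )
        responses[rec["subject_id"]] = resp
        for i, cid in enumerate(resp.channel_ids):
            rows.append(
                {
                    "subject": rec["subject_id"],
                    "group": rec["group"],
                    "hemisphere": hemis[cid],
                    "channel": cid,
                    "auc": float(resp.auc_uM_s[i]),
                    "auc_full": float(auc_full[i]),
                    "n_blocks_retained": resp.n_retained,
                    "sto2": sto2,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "channel_auc.tsv", sep="\t", index=False)
    # per-subject mean epochs, downsampled to 1 Hz bins for the cluster test
    binned = {
        sid: statsmod.downsample_epochs(
            r.mean_hbo, r.sampling_rate_hz, window_s=config.block_window_s
        )
        for sid, r in responses.items()
    }
    np.savez(
        out_dir / "binned_hbo.npz",
        **{sid: arr for sid, arr in binned.items()},
    )
    return table


def run_eeg_stage(data_dir, out_dir, config: PipelineConfig):
    """Per-subject EEG pipeline; writes GFP and projection coefficient tables."""
    from .montage import default_montage

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = ds.read_manifest(data_dir)
    montage = default_montage()

    erps, ids, groups = [], [], []
    gfp_rows = []
    for rec in manifest["subjects"]:
        _, schedule, _, raw = ds.read_subject(data_dir, rec["subject_id"])
        if raw is None:
            continue
        erp = eegmod.eeg_subject_pipeline(raw, schedule, positions=montage.positions)
        erps.append(erp)
        ids.append(rec["subject_id"])
        groups.append(rec["group"])
        gfp = eegmod.compute_gfp(erp)
        measures = eegmod.gfp_peak_measures(
            gfp, peak_latencies_ms=config.peak_latencies_ms,
            window_ms=config.gfp_peak_window_ms,
        )
        for p in range(measures.shape[0]):
            for s in range(measures.shape[1]):
                gfp_rows.append(
                    {
                        "subject": rec["subject_id"],
                        "group": rec["group"],
                        "peak": f"P{p + 1}",
                        "repetition": s + 1,
                        "value": measures[p, s],
                        "n_trials_retained": erp.n_trials_retained,
                    }
                )
    gfp_table = pd.DataFrame(gfp_rows)
    gfp_table.to_csv(out_dir / "gfp_measures.tsv", sep="\t", index=False)

    # leave-one-out template projection: healthy templates, every subject scored
    healthy = [(e, i) for e, i, g in zip(erps, ids, groups) if g == "healthy"]
    proj_rows = []
    if len(healthy) >= 3:
        for erp, sid, group in zip(erps, ids, groups):
            leave = sid if group == "healthy" else None
            templates = eegmod.build_templates(
                [e for e, _ in healthy], [i for _, i in healthy], leave_out=leave,
                peak_latencies_ms=config.peak_latencies_ms,
                window_ms=config.gfp_peak_window_ms,
            )
            _, coef = eegmod.project_templates(
                erp, templates,
                peak_latencies_ms=config.peak_latencies_ms,
                window_ms=config.proj_peak_window_ms,
            )
            for p in range(coef.shape[0]):
                for s in range(coef.shape[1]):
                    proj_rows.append(
                        {
                            "subject": sid,
                            "group": group,
                            "template": f"P{p + 2}",
                            "repetition": s + 1,
                            "value": coef[p, s],
                        }
                    )
    proj_table = pd.DataFrame(proj_rows)
    proj_table.to_csv(out_dir / "projection_coefficients.tsv", sep="\t", index=False)
    return gfp_table, proj_table


def _anova_frame(values: pd.DataFrame, config) -> list:
    """Pivot a tidy (subject, group, peak, repetition, value) table into the
    subject x peak x repetition array and run the mixed ANOVA (peaks 2-4)."""
    sub = values[values.peak != "P1"] if "peak" in values else values
    key = "peak" if "peak" in values else "template"
    piv = sub.pivot_table(
        index=["subject", "group"], columns=[key, "repetition"], values="value"
    )
    groups = piv.index.get_level_values("group").to_numpy()
    n_a = sub[key].nunique()
    n_b = sub["repetition"].nunique()
    arr = piv.to_numpy().reshape(len(piv), n_a, n_b)
    return statsmod.mixed_anova(arr, groups, within_names=(key, "repetition"))


def run_stats_stage(nirs_dir, eeg_dir, out_dir, config: PipelineConfig) -> dict:
    """Group statistics from the two pipelines' tidy outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_digest": config.digest()}

    nirs_dir = Path(nirs_dir)
    if (nirs_dir / "channel_auc.tsv").exists():
        auc = pd.read_csv(nirs_dir / "channel_auc.tsv", sep="\t")
        hemi_mean = (
            auc.groupby(["subject", "group", "hemisphere"])["auc"].mean().reset_index()
        )
        by = {}
        for g in ("healthy", "IVH"):
            by[g] = {
                h: hemi_mean[
                    (hemi_mean.group == g) & (hemi_mean.hemisphere == h)
                ]["auc"].to_numpy()
                for h in ("L", "R")
            }
        comp = statsmod.compare_auc(by["healthy"], by["IVH"])
        report["auc_comparison"] = {h: asdict(c) for h, c in comp.items()}
        report["auc_note"] = "two hemisphere t-tests reported uncorrected"

        binned = np.load(nirs_dir / "binned_hbo.npz")
        groups = dict(zip(auc.subject, auc.group))
        a = np.stack([binned[s] for s in binned.files if groups[s] == "healthy"])
        b = np.stack([binned[s] for s in binned.files if groups[s] == "IVH"])
        layout = build_probe()
        adj_sets = channel_adjacency(layout, config.adjacency_radius_mm)
        ids = layout.channel_ids
        adj = np.array([[b_ in adj_sets[a_] for b_ in ids] for a_ in ids])
        res = statsmod.cluster_permutation_test(
            a, b, adj, forming_alpha=config.forming_alpha,
            n_perm=config.n_permutations, seed=config.seed,
        )
        report["clusters"] = [
            {
                "mass": c.mass,
                "p_value": c.p_value,
                "n_cells": len(c.members),
                "channels": sorted({ids[ci] for ci, _ in c.members}),
            }
            for c in res.clusters
        ]

    eeg_dir = Path(eeg_dir)
    if (eeg_dir / "gfp_measures.tsv").exists():
        gfp = pd.read_csv(eeg_dir / "gfp_measures.tsv", sep="\t")
        report["gfp_anova"] = [asdict(r) for r in _anova_frame(gfp, config)]
        proj_path = eeg_dir / "projection_coefficients.tsv"
        try:
            proj = pd.read_csv(proj_path, sep="\t")
        except pd.errors.EmptyDataError:
            proj = pd.DataFrame()
        if len(proj):
            report["projection_anova"] = [asdict(r) for r in _anova_frame(proj, config)]

    with open(out_dir / "group_stats.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Simulate a cohort and run everything; returns the final report."""
    out_dir = Path(out_dir)
    data_dir = out_dir / "dataset"
    try:
        manifest = simulate_cohort(
            config.n_healthy, config.n_ivh, config.n_blocks, config.seed, data_dir
        )
        nirs_table = run_nirs_stage(data_dir, out_dir / "nirs", config)
        gfp_table, proj_table = run_eeg_stage(data_dir, out_dir / "eeg", config)
        report = run_stats_stage(out_dir / "nirs", out_dir / "eeg", out_dir / "stats", config)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    report["n_subjects"] = len(manifest["subjects"])
    retained = (
        nirs_table.groupby("subject")["n_blocks_retained"].first().to_dict()
        if len(nirs_table)
        else {}
    )
    report["subjects"] = [
        {
            "subject_id": r["subject_id"],
            "group": r["group"],
            "n_blocks_retained": retained.get(r["subject_id"]),
        }
        for r in manifest["subjects"]
    ]
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
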