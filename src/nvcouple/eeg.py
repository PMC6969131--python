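"""EEG processing: filtering, trial epoching, artifact rejection, ERP
averaging, global field power habituation measures, and spatial-template
projection.

The chain: band-pass 1-20 Hz (zero phase), down-sample to 512 Hz, segment
into 4-s epochs [-0.5, +3.5) s locked to the first syllable of each trial,
baseline-correct on the 200 ms before S1, reject artifacted channels/trials
(50 µV absolute and 30 µV ten-sample-jump thresholds; 70 % session rule;
15 % trial rule), average to a subject ERP.  GFP (spatial SD across
electrodes) is then summarized in 40-ms windows around the four component
peaks (84/244/378/576 ms) after each of the four syllables, and subject
topographies are scored against leave-one-out healthy template maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

EEG_BAND_HZ = (1.0, 20.0)
EEG_TARGET_RATE_HZ = 512.0
EPOCH_WINDOW_S = (-0.5, 3.5)
BASELINE_WINDOW_S = (-0.2, 0.0)
ABS_THRESH_UV = 50.0
JUMP_THRESH_UV = 30.0
JUMP_SPAN = 10
CHAN_FRAC = 0.70
TRIAL_FRAC = 0.15
PEAK_LATENCIES_MS = (84.0, 244.0, 378.0, 576.0)
GFP_PEAK_WINDOW_MS = 40.0
PROJ_PEAK_WINDOW_MS = 100.0
SYLLABLE_ONSETS_MS = (0.0, 600.0, 1200.0, 1800.0)


@dataclass
class ERPEpochSet:
    """Trial x electrode x time epochs with rejection masks."""

    sampling_rate_hz: float
    labels: tuple[str, ...]
    window_s: tuple[float, float]
    trials: np.ndarray  # (n_trials, n_electrodes, n_samples), µV
    channel_reject: np.ndarray | None = None  # (n_trials, n_electrodes) bool
    trial_retained: np.ndarray | None = None  # (n_trials,) bool
    electrode_retained: np.ndarray | None = None  # (n_electrodes,) bool

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def times(self) -> np.ndarray:
        return self.window_s[0] + np.arange(self.trials.shape[-1]) / self.sampling_rate_hz


@dataclass
class SubjectERP:
    """Mean voltage over retained trials; session-rejected electrodes are NaN."""

    sampling_rate_hz: float
    labels: tuple[str, ...]
    window_s: tuple[float, float]
    voltage: np.ndarray  # (n_electrodes, n_samples), µV, NaN where rejected
    n_trials_retained: int
    positions: np.ndarray | None = None  # (n_electrodes, 2)

    def times(self) -> np.ndarray:
        return self.window_s[0] + np.arange(self.voltage.shape[-1]) / self.sampling_rate_hz

    def retained_electrodes(self) -> np.ndarray:
        return ~np.isnan(self.voltage).any(axis=1)


@dataclass
class GFPSeries:
    """Global field power (spatial SD across electrodes) over epoch time."""

    sampling_rate_hz: float
    window_s: tuple[float, float]
    gfp: np.ndarray  # (n_samples,), µV

    def times(self) -> np.ndarray:
        return self.window_s[0] + np.arange(self.gfp.shape[-1]) / self.sampling_rate_hz


@dataclass
class TemplateMap:
    """Unit-norm, electrode-mean-centred spatial template for one peak."""

    peak_id: str  # "P2" | "P3" | "P4"
    labels: tuple[str, ...]
    weights: np.ndarray
    source: str = "full"  # or left-out subject id


def preprocess_eeg(raw, band_hz=EEG_BAND_HZ, target_rate_hz=EEG_TARGET_RATE_HZ):
    """Zero-phase band-pass then integer decimation (2048 -> 512 Hz).

    The 20 Hz cut-off is far below the post-decimation Nyquist (256 Hz), so
    the band-pass doubles as the anti-alias filter.
    """
    factor = raw.sampling_rate_hz / target_rate_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"sampling rate {raw.sampling_rate_hz} not an integer multiple of {target_rate_hz}"
        )
    factor = int(round(factor))
    sos = butter(4, band_hz, btype="bandpass", fs=raw.sampling_rate_hz, output="sos")
    volt = sosfiltfilt(sos, np.asarray(raw.voltage, float), axis=-1)
    volt = volt[:, ::factor]
    from .synthetic import RawEEGRecording

    return RawEEGRecording(
        sampling_rate_hz=target_rate_hz,
        labels=raw.labels,
        voltage=volt,
        t_start_s=raw.t_start_s,
    )


def epoch_trials(
    recording,
    schedule,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
    baseline_s: tuple[float, float] = BASELINE_WINDOW_S,
) -> ERPEpochSet:
    """One epoch per trial, locked to its first syllable, baseline-corrected
    on the 200 ms before S1.  Out-of-bounds trials are skipped with a warning."""
    import warnings

    fs = recording.sampling_rate_hz
    n_epoch = int(round((window_s[1] - window_s[0]) * fs))
    t_rel = window_s[0] + np.arange(n_epoch) / fs
    base_sel = (t_rel >= baseline_s[0]) & (t_rel < baseline_s[1])
    volt = np.asarray(recording.voltage, float)

    epochs = []
    for onset in schedule.trial_onsets_s():
        start = int(round((onset + window_s[0] - recording.t_start_s) * fs))
        if start < 0 or start + n_epoch > volt.shape[-1]:
            warnings.warn(f"trial at {onset:.3f} s outside recording; skipped")
            continue
        seg = volt[:, start : start + n_epoch].copy()
        seg -= seg[:, base_sel].mean(axis=1, keepdims=True)
        epochs.append(seg)
    if not epochs:
        raise ValueError("no trial fits inside the recording")
    return ERPEpochSet(
        sampling_rate_hz=fs,
        labels=recording.labels,
        window_s=window_s,
        trials=np.stack(epochs),
    )


def reject_artifacts(
    epochs: ERPEpochSet,
    abs_thresh_uV: float = ABS_THRESH_UV,
    jump_thresh_uV: float = JUMP_THRESH_UV,
    jump_span: int = JUMP_SPAN,
    chan_frac: float = CHAN_FRAC,
    trial_frac: float = TRIAL_FRAC,
) -> ERPEpochSet:
    """Threshold-based artifact cascade, in order:

    1. flag (trial, electrode) if max |V| > 50 µV or any amplitude jump
       across ten successive samples |V[t+9] - V[t]| > 30 µV;
    2. drop an electrode for the session if flagged on > 70 % of trials;
    3. drop a trial if > 15 % of the session-retained electrodes are flagged.
    """
    x = epochs.trials
    flagged = np.abs(x).max(axis=-1) > abs_thresh_uV
    jump = np.abs(x[..., jump_span - 1 :] - x[..., : x.shape[-1] - jump_span + 1])
    flagged |= jump.max(axis=-1) > jump_thresh_uV

    electrode_retained = flagged.mean(axis=0) <= chan_frac
    if not electrode_retained.any():
        raise ValueError("all trials rejected: every electrode failed the session rule")
    frac_bad = flagged[:, electrode_retained].mean(axis=1)
    trial_retained = frac_bad <= trial_frac
    if not trial_retained.any():
        raise ValueError("all trials rejected")
    return ERPEpochSet(
        sampling_rate_hz=epochs.sampling_rate_hz,
        labels=epochs.labels,
        window_s=epochs.window_s,
        trials=epochs.trials,
        channel_reject=flagged,
        trial_retained=trial_retained,
        electrode_retained=electrode_retained,
    )


def average_erp(epochs: ERPEpochSet, positions: np.ndarray | None = None) -> SubjectERP:
    """Mean over retained trials; session-rejected electrodes become NaN."""
    trial_mask = (
        epochs.trial_retained
        if epochs.trial_retained is not None
        else np.ones(epochs.n_trials, bool)
    )
    if not trial_mask.any():
        raise ValueError("no retained trials to average")
    erp = epochs.trials[trial_mask].mean(axis=0)
    if epochs.electrode_retained is not None:
        erp = erp.copy()
        erp[~epochs.electrode_retained] = np.nan
    return SubjectERP(
        sampling_rate_hz=epochs.sampling_rate_hz,
        labels=epochs.labels,
        window_s=epochs.window_s,
        voltage=erp,
        n_trials_retained=int(trial_mask.sum()),
        positions=positions,
    )


def compute_gfp(erp: SubjectERP) -> GFPSeries:
    """Global field power: population SD across retained electrodes at each
    time point (reference-translation invariant)."""
    keep = erp.retained_electrodes()
    if keep.sum() < 2:
        raise ValueError("GFP needs at least 2 retained electrodes")
    gfp = erp.voltage[keep].std(axis=0, ddof=0)
    return GFPSeries(sampling_rate_hz=erp.sampling_rate_hz, window_s=erp.window_s, gfp=gfp)


def _mean_over_window(t_ms: np.ndarray, y: np.ndarray, lo_ms: float, hi_ms: float) -> float:
    sel = (t_ms >= lo_ms) & (t_ms < hi_ms)
    if not sel.any():
        raise ValueError(f"window [{lo_ms}, {hi_ms}) ms holds no samples")
    return float(y[..., sel].mean(axis=-1)) if y.ndim == 1 else y[..., sel].mean(axis=-1)


def gfp_peak_measures(
    gfp: GFPSeries,
    peak_latencies_ms=PEAK_LATENCIES_MS,
    syllable_onsets_ms=SYLLABLE_ONSETS_MS,
    window_ms: float = GFP_PEAK_WINDOW_MS,
) -> np.ndarray:
    """(peak x syllable-position) matrix of GFP means in half-open 40-ms
    windows centred on each component peak after each syllable onset."""
    t_ms = gfp.times() * 1e3
    out = np.empty((len(peak_latencies_ms), len(syllable_onsets_ms)))
    for p, lat in enumerate(peak_latencies_ms):
        for s, onset in enumerate(syllable_onsets_ms):
            centre = onset + lat
            lo, hi = centre - window_ms / 2, centre + window_ms / 2
            if lo < t_ms[0] or hi > t_ms[-1] + 1e-9:
                raise ValueError(f"peak window [{lo}, {hi}) ms outside the epoch")
            out[p, s] = _mean_over_window(t_ms, gfp.gfp, lo, hi)
    return out


def gfp_local_maxima_ms(
    gfp: GFPSeries,
    lo_ms: float = 0.0,
    hi_ms: float = 600.0,
    min_prominence_frac: float = 0.1,
) -> np.ndarray:
    """Latencies (ms) of local GFP maxima in (lo_ms, hi_ms], ascending.

    Maxima with prominence below ``min_prominence_frac`` of the window's GFP
    maximum are ignored — these are filter ripple, not components.
    """
    from scipy.signal import find_peaks

    t_ms = gfp.times() * 1e3
    sel = (t_ms > lo_ms) & (t_ms <= hi_ms)
    idx = np.nonzero(sel)[0]
    y = gfp.gfp[idx]
    peaks, _ = find_peaks(y, prominence=min_prominence_frac * y.max())
    return t_ms[idx[peaks]]


def _common_electrodes(erps) -> np.ndarray:
    keep = None
    for erp in erps:
        k = erp.retained_electrodes()
        keep = k if keep is None else (keep & k)
    return keep


def build_templates(
    healthy_erps: list[SubjectERP],
    subject_ids: list[str] | None = None,
    leave_out: str | None = None,
    peak_latencies_ms=PEAK_LATENCIES_MS,
    window_ms: float = GFP_PEAK_WINDOW_MS,
) -> list[TemplateMap]:
    """Template maps for peaks P2/P3/P4 from the healthy grand average.

    Each template is the grand-average voltage map in the 40-ms window
    centred on the peak after S1, electrode-mean-centred and unit-normalized.
    With ``leave_out``, the named subject is excluded (leave-one-out fold).
    """
    ids = subject_ids or [f"sub{i}" for i in range(len(healthy_erps))]
    sel = [e for e, sid in zip(healthy_erps, ids) if sid != leave_out]
    if len(sel) < 2:
        raise ValueError("need at least 2 healthy subjects after exclusion")
    labels = sel[0].labels
    # templates use the intersection of retained electrodes across subjects
    common = _common_electrodes(sel)
    grand = np.stack([e.voltage for e in sel]).mean(axis=0)
    grand[~common] = np.nan
    t_ms = sel[0].times() * 1e3
    templates = []
    for p, lat in enumerate(peak_latencies_ms):
        if p == 0:
            continue  # P1 overlaps the previous syllable's P4; no template
        w = (t_ms >= lat - window_ms / 2) & (t_ms < lat + window_ms / 2)
        m = grand[:, w].mean(axis=1)
        m = m - np.nanmean(m)
        norm = float(np.sqrt(np.nansum(m**2)))
        if norm == 0:
            raise ValueError("degenerate (all-zero) template map")
        templates.append(
            TemplateMap(
                peak_id=f"P{p + 1}",
                labels=labels,
                weights=m / norm,
                source=leave_out or "full",
            )
        )
    return templates


def project_templates(
    erp: SubjectERP,
    templates: list[TemplateMap],
    peak_latencies_ms=PEAK_LATENCIES_MS,
    syllable_onsets_ms=SYLLABLE_ONSETS_MS,
    window_ms: float = PROJ_PEAK_WINDOW_MS,
    metric: str = "centered-cosine",
) -> tuple[np.ndarray, np.ndarray]:
    """Score the subject's instantaneous maps against each template.

    Returns ``(similarity, coefficients)``: similarity is template x time in
    [-1, 1] (centred cosine, i.e. spatial Pearson r); coefficients average
    the similarity over 100-ms windows centred on each template's peak after
    each of the four syllables (templates x 4 repetitions).
    """
    keep = erp.retained_electrodes()
    sims = []
    for tpl in templates:
        if tuple(tpl.labels) != tuple(erp.labels):
            raise ValueError("template and ERP use different electrode sets")
        tw = tpl.weights.copy()
        overlap = keep & ~np.isnan(tw)
        if overlap.sum() < 0.8 * np.sum(~np.isnan(tpl.weights)):
            raise ValueError("electrode overlap with template below 80%")
        v = erp.voltage[overlap]
        w = tw[overlap]
        if metric == "centered-cosine":
            v = v - v.mean(axis=0, keepdims=True)
            w = w - w.mean()
        wn = w / np.linalg.norm(w)
        denom = np.linalg.norm(v, axis=0)
        denom[denom == 0] = np.inf
        sims.append((wn @ v) / denom)
    similarity = np.asarray(sims)

    t_ms = erp.times() * 1e3
    # template p corresponds to peak p+1 (P2..P4)
    lats = peak_latencies_ms[1 : 1 + len(templates)]
    coef = np.empty((len(templates), len(syllable_onsets_ms)))
    for p, lat in enumerate(lats):
        for s, onset in enumerate(syllable_onsets_ms):
            centre = onset + lat
            sel = (t_ms >= centre - window_ms / 2) & (t_ms < centre + window_ms / 2)
            if not sel.any():
                raise ValueError("projection window outside the epoch")
            coef[p, s] = similarity[p, sel].mean()
    return similarity, coef


def interpolate_map(
    values: np.ndarray,
    positions: np.ndarray,
    grid_n: int = 64,
    radius: float = 0.85,
):
    """Thin-plate-spline interpolation of an electrode map onto a 2-D grid.

    For topographic display only — no statistic consumes interpolated
    values.  Returns (xx, yy, zz) with points outside the head radius NaN.
    """
    from scipy.interpolate import RBFInterpolator

    keep = np.isfinite(values)
    if keep.sum() < 4:
        raise ValueError("need at least 4 finite electrodes to interpolate")
    rbf = RBFInterpolator(positions[keep], values[keep], kernel="thin_plate_spline")
    g = np.linspace(-radius, radius, grid_n)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    zz = rbf(pts).reshape(grid_n, grid_n)
    zz[xx**2 + yy**2 > radius**2] = np.nan
    return xx, yy, zz


def eeg_subject_pipeline(raw, schedule, positions=None):
    """Full per-subject chain: preprocess -> epoch -> reject -> average."""
    pre = preprocess_eeg(raw)
    epochs = epoch_trials(pre, schedule)
    epochs = reject_artifacts(epochs)
    return average_erp(epochs, positions=positions)
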