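"""fNIRS processing: modified Beer-Lambert conversion, z-score artifact
rejection, band-pass filtering, block segmentation and AUC summaries.

Processing order: MBLL -> z-based block rejection -> zero-phase band-pass
[0.03, 0.5] Hz (Butterworth order 6) -> segmentation [-5, +25) s around
block onsets -> linear detrend -> baseline correction on [-5, 0) s ->
averaging over retained blocks -> per-channel AUC of the mean HbO response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .probe import ProbeLayout

#: Molar extinction coefficients, cm^-1 / (mol/L) (Gratzer/Cope compilation).
EXTINCTION_M_CM = {
    690: {"hbo": 276.0, "hb": 2051.96},
    830: {"hbo": 974.0, "hb": 693.04},
}
#: Same table per µmol/L.
EXTINCTION_UM_CM = {
    wl: {k: v * 1e-6 for k, v in row.items()} for wl, row in EXTINCTION_M_CM.items()
}
DPF_DEFAULT = 4.99
NIRS_BAND_HZ = (0.03, 0.5)
Z_THRESHOLD_DEFAULT = 4.0
BLOCK_WINDOW_S = (-5.0, 25.0)
BASELINE_WINDOW_S = (-5.0, 0.0)
AUC_WINDOW_S = (0.0, 10.0)


def forward_intensity(
    hbo_uM: np.ndarray,
    hb_uM: np.ndarray,
    wavelength_nm: int,
    i0: float,
    separation_cm: float,
    dpf: float,
) -> np.ndarray:
    """Forward modified Beer-Lambert model: intensity from concentration
    changes.  Exact inverse of :func:`mbll_convert` with a geometric-mean
    reference and mean-centred inputs."""
    eps = EXTINCTION_UM_CM[wavelength_nm]
    d_od = (eps["hbo"] * np.asarray(hbo_uM) + eps["hb"] * np.asarray(hb_uM)) * (
        separation_cm * dpf
    )
    return i0 * 10.0 ** (-d_od)


@dataclass
class HbTimeSeries:
    """Relative (de)oxy-hemoglobin concentration changes per channel (µM)."""

    sampling_rate_hz: float
    channel_ids: list[str]
    hbo_uM: np.ndarray  # (n_channels, n_samples)
    hb_uM: np.ndarray
    t_start_s: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.hbo_uM.shape[-1]

    def times(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class BlockEpochSet:
    """Block-locked concentration epochs on the canonical [-5, +25) s grid."""

    sampling_rate_hz: float
    channel_ids: list[str]
    window_s: tuple[float, float]
    hbo: np.ndarray  # (n_retained_blocks, n_channels, n_samples)
    hb: np.ndarray
    retained_mask: np.ndarray  # (n_blocks,) over the full schedule

    @property
    def n_retained(self) -> int:
        return self.hbo.shape[0]

    def times(self) -> np.ndarray:
        return self.window_s[0] + np.arange(self.hbo.shape[-1]) / self.sampling_rate_hz


@dataclass
class SubjectHemoResponse:
    """Per-subject block-average response and AUC summaries."""

    channel_ids: list[str]
    sampling_rate_hz: float
    window_s: tuple[float, float]
    mean_hbo: np.ndarray  # (n_channels, n_samples)
    mean_hb: np.ndarray
    auc_uM_s: np.ndarray  # (n_channels,), over auc_window
    auc_window_s: tuple[float, float]
    hemisphere_auc: dict[str, float]
    n_retained: int
    sto2: float | None = None

    def times(self) -> np.ndarray:
        return self.window_s[0] + np.arange(self.mean_hbo.shape[-1]) / self.sampling_rate_hz


def mbll_convert(
    raw,
    extinction_table: dict | None = None,
    dpf: float = DPF_DEFAULT,
    separation_mm: float = 15.0,
    reference: str = "geometric-mean",
) -> HbTimeSeries:
    """Convert raw two-wavelength intensities to Delta[HbO]/Delta[Hb] (µM).

    Optical density change is referenced to each channel's session mean:
    ``reference="geometric-mean"`` (default) uses the geometric temporal
    mean, i.e. the arithmetic mean in the OD domain, which makes the
    conversion the exact inverse of the forward model; ``"mean"`` uses the
    arithmetic mean intensity.  The per-wavelength OD changes are then
    solved channel-wise for the two chromophores through the 2x2 extinction
    system  dOD(lambda) = (eps_HbO dHbO + eps_Hb dHb) * separation * DPF.
    """
    ext = extinction_table or EXTINCTION_UM_CM
    wl = raw.wavelengths_nm
    intens = np.asarray(raw.intensity, float)
    if np.any(intens <= 0):
        ch, w, s = np.argwhere(intens <= 0)[0]
        raise ValueError(
            f"non-positive intensity at channel {raw.channel_ids[ch]}, "
            f"wavelength {wl[w]} nm, sample {s}"
        )
    e = np.array([[ext[w]["hbo"], ext[w]["hb"]] for w in wl])
    if abs(np.linalg.det(e)) < 1e-18:
        raise ValueError("extinction matrix is singular")
    path_cm = (separation_mm / 10.0) * dpf

    log_i = np.log10(intens)
    if reference == "geometric-mean":
        ref_log = log_i.mean(axis=-1, keepdims=True)
    elif reference == "mean":
        ref_log = np.log10(intens.mean(axis=-1, keepdims=True))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    d_od = -(log_i - ref_log)  # (n_channels, 2, n_samples)

    a_inv = np.linalg.inv(e * path_cm)
    conc = np.einsum("kw,cwt->ckt", a_inv, d_od)
    return HbTimeSeries(
        sampling_rate_hz=raw.sampling_rate_hz,
        channel_ids=list(raw.channel_ids),
        hbo_uM=conc[:, 0],
        hb_uM=conc[:, 1],
        t_start_s=raw.t_start_s,
    )


def compute_sto2(hbo_abs_uM, hb_abs_uM):
    """Tissue oxygen saturation StO2 = [HbO] / ([HbO] + [Hb]), elementwise."""
    hbo = np.asarray(hbo_abs_uM, float)
    hb = np.asarray(hb_abs_uM, float)
    if np.any(hbo < 0) or np.any(hb < 0):
        raise ValueError("absolute concentrations must be >= 0")
    total = hbo + hb
    if np.any(total == 0):
        raise ValueError("StO2 undefined where [HbO] + [Hb] = 0")
    return hbo / total


def znormalize(series: HbTimeSeries, sd_floor: float = 1e-12) -> HbTimeSeries:
    """Z-score each channel over the whole recording (mean 0, SD 1)."""

    def _z(x):
        sd = x.std(axis=-1, keepdims=True)
        bad = np.nonzero(sd.ravel() <= sd_floor)[0]
        if bad.size:
            raise ValueError(
                f"degenerate channel (SD <= {sd_floor}): {series.channel_ids[bad[0]]}"
            )
        return (x - x.mean(axis=-1, keepdims=True)) / sd

    return HbTimeSeries(
        sampling_rate_hz=series.sampling_rate_hz,
        channel_ids=list(series.channel_ids),
        hbo_uM=_z(series.hbo_uM),
        hb_uM=_z(series.hb_uM),
        t_start_s=series.t_start_s,
    )


def _window_indices(t_start, fs, n_samples, win_lo, win_hi, n_fixed=None):
    """Sample index range for a half-open [win_lo, win_hi) time window."""
    first = int(np.ceil((win_lo - t_start) * fs - 1e-9))
    if n_fixed is None:
        last = int(np.ceil((win_hi - t_start) * fs - 1e-9))
    else:
        last = first + n_fixed
    if first < 0 or last > n_samples:
        raise ValueError(
            f"window [{win_lo}, {win_hi}) s extends outside the recording"
        )
    return first, last


def reject_blocks(
    z: HbTimeSeries,
    schedule,
    threshold: float = Z_THRESHOLD_DEFAULT,
    window_s: tuple[float, float] = BLOCK_WINDOW_S,
    signed: bool = False,
) -> np.ndarray:
    """Block retention mask from the z-scored signals.

    A block is rejected if |z| (or z, when ``signed``) exceeds ``threshold``
    at any sample of any channel (HbO or Hb) inside its [-5, +25) s window.
    """
    fs = z.sampling_rate_hz
    mask = np.ones(len(schedule.block_onsets_s), bool)
    for b, onset in enumerate(schedule.block_onsets_s):
        lo, hi = _window_indices(
            z.t_start_s, fs, z.n_samples, onset + window_s[0], onset + window_s[1]
        )
        seg = np.concatenate([z.hbo_uM[:, lo:hi], z.hb_uM[:, lo:hi]])
        val = seg.max() if signed else np.abs(seg).max()
        mask[b] = val <= threshold
    return mask


def bandpass_nirs(
    series: HbTimeSeries,
    band_hz: tuple[float, float] = NIRS_BAND_HZ,
    order: int = 6,
) -> HbTimeSeries:
    """Zero-phase Butterworth band-pass (default [0.03, 0.5] Hz, order 6),
    removing slow drifts and the ~164 BPM arterial pulse."""
    fs = series.sampling_rate_hz
    if fs <= 2 * band_hz[1]:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    sos = butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    min_len = 3 * (2 * order + 1)
    if series.n_samples <= min_len:
        raise ValueError(f"series too short to filter ({series.n_samples} samples)")
    return HbTimeSeries(
        sampling_rate_hz=fs,
        channel_ids=list(series.channel_ids),
        hbo_uM=sosfiltfilt(sos, series.hbo_uM, axis=-1),
        hb_uM=sosfiltfilt(sos, series.hb_uM, axis=-1),
        t_start_s=series.t_start_s,
    )


def segment_and_correct(
    filtered: HbTimeSeries,
    schedule,
    retained_mask: np.ndarray | None = None,
    window_s: tuple[float, float] = BLOCK_WINDOW_S,
    baseline_s: tuple[float, float] = BASELINE_WINDOW_S,
) -> BlockEpochSet:
    """Extract [-5, +25) s block epochs, detrend linearly over the full
    segment, then subtract the mean of the [-5, 0) s baseline.

    Epoch length is fixed at floor(window * fs) samples so that every epoch
    shares the canonical time grid ``window[0] + k / fs``.
    """
    fs = filtered.sampling_rate_hz
    onsets = list(schedule.block_onsets_s)
    if retained_mask is None:
        retained_mask = np.ones(len(onsets), bool)
    n_epoch = int(np.floor((window_s[1] - window_s[0]) * fs + 1e-9))
    t_rel = window_s[0] + np.arange(n_epoch) / fs
    base_sel = (t_rel >= baseline_s[0]) & (t_rel < baseline_s[1])

    hbo_ep, hb_ep = [], []
    for b, onset in enumerate(onsets):
        if not retained_mask[b]:
            continue
        lo, _ = _window_indices(
            filtered.t_start_s, fs, filtered.n_samples, onset + window_s[0],
            onset + window_s[1], n_fixed=n_epoch,
        )
        for arr, store in ((filtered.hbo_uM, hbo_ep), (filtered.hb_uM, hb_ep)):
            seg = arr[:, lo : lo + n_epoch].copy()
            # least-squares line over the full segment
            coef = np.polynomial.polynomial.polyfit(t_rel, seg.T, 1)
            seg -= coef[1][:, None] * t_rel + coef[0][:, None]
            seg -= seg[:, base_sel].mean(axis=1, keepdims=True)
            store.append(seg)
    if not hbo_ep:
        raise ValueError("no retained blocks to segment")
    return BlockEpochSet(
        sampling_rate_hz=fs,
        channel_ids=list(filtered.channel_ids),
        window_s=window_s,
        hbo=np.stack(hbo_ep),
        hb=np.stack(hb_ep),
        retained_mask=np.asarray(retained_mask, bool),
    )


def _windowed_trapezoid(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Trapezoidal integral of y(t) over [lo, hi], linearly interpolating the
    window edges onto the sampling grid (y may be 2-D, channels x time)."""
    y = np.atleast_2d(y)
    inner = (t > lo) & (t < hi)
    tt = np.concatenate(([lo], t[inner], [hi]))
    yy = np.column_stack(
        [
            np.array([np.interp(lo, t, row) for row in y]),
            y[:, inner],
            np.array([np.interp(hi, t, row) for row in y]),
        ]
    )
    return np.trapezoid(yy, tt, axis=-1)


def subject_response(
    epochs: BlockEpochSet,
    layout: ProbeLayout | None = None,
    auc_window_s: tuple[float, float] = AUC_WINDOW_S,
    sto2: float | None = None,
) -> SubjectHemoResponse:
    """Average retained epochs and summarize each channel by the time
    integral (AUC, µM·s) of its mean HbO response over ``auc_window_s``."""
    if epochs.n_retained < 1:
        raise ValueError("need at least one retained block")
    t = epochs.times()
    if auc_window_s[0] < epochs.window_s[0] or auc_window_s[1] > epochs.window_s[1]:
        raise ValueError("auc_window must lie inside the epoch window")
    mean_hbo = epochs.hbo.mean(axis=0)
    mean_hb = epochs.hb.mean(axis=0)
    auc = _windowed_trapezoid(t, mean_hbo, *auc_window_s)

    hemi_auc: dict[str, float] = {}
    if layout is not None:
        hemis = layout.hemisphere_of()
        for h in ("L", "R"):
            sel = [i for i, c in enumerate(epochs.channel_ids) if hemis.get(c) == h]
            if sel:
                hemi_auc[h] = float(auc[sel].mean())
    return SubjectHemoResponse(
        channel_ids=list(epochs.channel_ids),
        sampling_rate_hz=epochs.sampling_rate_hz,
        window_s=epochs.window_s,
        mean_hbo=mean_hbo,
        mean_hb=mean_hb,
        auc_uM_s=auc,
        auc_window_s=auc_window_s,
        hemisphere_auc=hemi_auc,
        n_retained=epochs.n_retained,
        sto2=sto2,
    )


def nirs_subject_pipeline(
    raw,
    schedule,
    layout: ProbeLayout,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
    auc_window_s: tuple[float, float] = AUC_WINDOW_S,
) -> SubjectHemoResponse:
    """Full per-subject chain: MBLL -> z rejection -> band-pass ->
    segmentation/detrend/baseline -> averaging -> AUC."""
    conc = mbll_convert(raw)
    z = znormalize(conc)
    mask = reject_blocks(z, schedule, threshold=z_threshold)
    filt = bandpass_nirs(conc)
    epochs = segment_and_correct(filt, schedule, mask)
    return subject_response(epochs, layout=layout, auc_window_s=auc_window_s)
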