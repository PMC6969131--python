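"""Seeded synthetic cohorts: raw two-wavelength fNIRS intensities and raw EEG.

The generator embeds the statistical structure the analysis assumes so that
every pipeline stage can be verified end-to-end without clinical data:

* block-locked hemodynamic responses (HbO up / Hb down, gamma kernel
  peaking ~7 s after block onset) scaled by a per-channel neurovascular
  coupling gain — healthy subjects have full gain everywhere, IVH subjects
  near-zero gain except a residual on one right-temporal channel;
* syllable-locked ERPs with four components at 84/244/378/576 ms whose
  amplitude decays with syllable repetition (habituation), on top of the
  discontinuous neonatal background (low-voltage interburst activity
  interrupted by high-voltage bursts that are random with respect to the
  stimulation);
* physiological and instrumental noise: multiplicative slow intensity
  drifts, a cardiac oscillation at 164 BPM, and white measurement noise.

Intensities are produced by the exact forward modified Beer-Lambert model
that :func:`nvcouple.nirs.mbll_convert` inverts, so the zero-noise round
trip is exact to machine precision.  Because the conversion references each
channel to its session (geometric) mean intensity, the ground-truth
concentration traces returned alongside are expressed relative to their
session mean as well.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .montage import Montage, default_montage
from .nirs import DPF_DEFAULT, forward_intensity
from .paradigm import StimulusSchedule, build_paradigm, write_events
from .probe import ProbeLayout, build_probe, right_temporal_channel

NIRS_RATE_HZ = 9.1912
EEG_RATE_HZ = 2048.0
WAVELENGTHS_NM = (690, 830)
CARDIAC_BPM = 164.0

ERP_LATENCIES_S = (0.084, 0.244, 0.378, 0.576)
ERP_AMPLITUDES_UV = (2.0, 3.0, 2.5, 3.5)
ERP_KERNEL_SIGMA_S = 0.022

#: two-pole (positive, negative) Gaussian centres per ERP component, in
#: montage coordinates — fixed distinct dipolar topographies.
_ERP_POLES = (
    ((0.30, 0.55), (-0.30, -0.55)),
    ((-0.45, 0.30), (0.45, -0.30)),
    ((0.00, 0.60), (0.00, -0.60)),
    ((0.55, 0.10), (-0.55, -0.10)),
)
_ERP_POLE_WIDTH = 0.35


@dataclass
class SubjectParams:
    """Ground-truth generative parameters of one synthetic subject."""

    subject_id: str = "sub-00"
    group: str = "healthy"  # "healthy" | "IVH"
    coupling_gain: dict[str, float] | None = None  # per channel; None -> group default
    ivh_residual_gain: float = 0.4
    hbo_peak_amplitude_uM: float = 0.5
    hb_ratio: float = -1 / 3
    hrf_peak_latency_s: float = 7.0
    hrf_fwhm_s: float = 8.0
    erp_amplitudes_uV: tuple[float, ...] = ERP_AMPLITUDES_UV
    erp_latencies_s: tuple[float, ...] = ERP_LATENCIES_S
    habituation_ratio: float = 0.8
    burst_rate_per_min: float = 6.0
    burst_amplitude_uV: float = 300.0
    interburst_amplitude_uV: float = 10.0
    drift_scale: float = 0.005  # relative slow intensity drift (RMS)
    cardiac_scale: float = 0.1  # cardiac amplitude / HbO response peak
    white_noise_scale: float = 1e-3  # relative white intensity noise (SD)
    baseline_hbo_uM: float = 42.0
    baseline_hb_uM: float = 21.0

    def __post_init__(self):
        if not (0 < self.habituation_ratio <= 1):
            raise ValueError("habituation_ratio must be in (0, 1]")
        if self.hrf_peak_latency_s <= 0:
            raise ValueError("hrf_peak_latency_s must be > 0")
        if self.coupling_gain is not None and any(g < 0 for g in self.coupling_gain.values()):
            raise ValueError("coupling_gain must be >= 0")

    def gains_for(self, layout: ProbeLayout) -> dict[str, float]:
        """Per-channel coupling gain, with group defaults when unset:
        healthy -> 1.0 everywhere; IVH -> 0.0 except the right-temporal
        channel at ``ivh_residual_gain``."""
        if self.coupling_gain is not None:
            return {cid: float(self.coupling_gain.get(cid, 0.0)) for cid in layout.channel_ids}
        if self.group == "IVH":
            gains = {cid: 0.0 for cid in layout.channel_ids}
            gains[right_temporal_channel(layout)] = self.ivh_residual_gain
            return gains
        return {cid: 1.0 for cid in layout.channel_ids}

    def noiseless(self) -> "SubjectParams":
        """Copy with every stochastic nuisance process switched off."""
        p = SubjectParams(**asdict(self))
        p.drift_scale = 0.0
        p.cardiac_scale = 0.0
        p.white_noise_scale = 0.0
        p.burst_rate_per_min = 0.0
        p.interburst_amplitude_uV = 0.0
        return p


@dataclass
class RawIntensityRecording:
    """Two-wavelength raw optical intensities, channel x wavelength x time."""

    sampling_rate_hz: float
    wavelengths_nm: tuple[int, int]
    channel_ids: list[str]
    intensity: np.ndarray  # (n_channels, 2, n_samples), detector units > 0
    t_start_s: float
    ground_truth_hbo_uM: np.ndarray | None = None  # session-mean-centred
    ground_truth_hb_uM: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[-1]

    def times(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class RawEEGRecording:
    """Raw multi-electrode EEG voltages in microvolts."""

    sampling_rate_hz: float
    labels: tuple[str, ...]
    voltage: np.ndarray  # (n_electrodes, n_samples), µV
    t_start_s: float

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[-1]

    def times(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.n_samples) / self.sampling_rate_hz


# --------------------------------------------------------------------------
# hemodynamics


def gamma_hrf(t_s: np.ndarray, peak_latency_s: float = 7.0, fwhm_s: float = 8.0) -> np.ndarray:
    """Gamma-variate hemodynamic kernel, unit peak at ``peak_latency_s``.

    Shape/scale are chosen so the mode sits at the requested latency and the
    width matches ``fwhm_s`` approximately (Gaussian-equivalent relation
    FWHM ~ 2.355 sqrt(k) theta); the kernel has returned to ~0 by 20 s after
    the peak.
    """
    sd = fwhm_s / 2.355
    # mode = (k-1) theta, sd = sqrt(k) theta  ->  solve for k
    # sd^2 = k theta^2 and m = (k-1) theta  ->  theta = (sqrt(m^2+4 sd^2)-m)/2
    theta = (np.sqrt(peak_latency_s**2 + 4 * sd**2) - peak_latency_s) / 2
    k = 1 + peak_latency_s / theta
    t = np.maximum(np.asarray(t_s, float), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_h = (k - 1) * np.log(t / theta) - t / theta
    log_peak = (k - 1) * np.log(peak_latency_s / theta) - peak_latency_s / theta
    h = np.where(t > 0, np.exp(log_h - log_peak), 0.0)
    return h


def evoked_hbo(
    params: SubjectParams, schedule: StimulusSchedule, times_s: np.ndarray
) -> np.ndarray:
    """Block-onset-locked ground-truth Delta[HbO] (µM) for unit coupling gain."""
    out = np.zeros_like(times_s)
    for onset in schedule.block_onsets_s:
        rel = times_s - onset
        mask = (rel > 0) & (rel < params.hrf_peak_latency_s + 25.0)
        out[mask] += gamma_hrf(rel[mask], params.hrf_peak_latency_s, params.hrf_fwhm_s)
    return params.hbo_peak_amplitude_uM * out


def _slow_drift(rng: np.random.Generator, t: np.ndarray, scale: float) -> np.ndarray:
    """Sum of random sinusoids below 0.01 Hz, unit RMS, scaled."""
    if scale == 0:
        return np.zeros_like(t)
    freqs = rng.uniform(0.001, 0.01, size=5)
    phases = rng.uniform(0, 2 * np.pi, size=5)
    amps = rng.uniform(0.5, 1.0, size=5)
    d = np.zeros_like(t)
    for f, ph, a in zip(freqs, phases, amps):
        d += a * np.sin(2 * np.pi * f * t + ph)
    rms = np.sqrt(np.mean(d**2))
    return scale * d / rms


def simulate_nirs(
    params: SubjectParams,
    schedule: StimulusSchedule,
    layout: ProbeLayout,
    seed: int = 0,
    pad_pre_s: float = 10.0,
) -> RawIntensityRecording:
    """Simulate a raw two-wavelength intensity recording.

    The recording starts ``pad_pre_s`` before the first block onset so that
    the [-5, +25] s analysis window of every block lies inside it.
    """
    if not schedule.events:
        raise ValueError("schedule has no events")
    duration = pad_pre_s + schedule.duration_s
    if duration <= 0:
        raise ValueError("schedule duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration * NIRS_RATE_HZ))
    t = -pad_pre_s + np.arange(n) / NIRS_RATE_HZ

    gains = params.gains_for(layout)
    unit_hbo = evoked_hbo(params, schedule, t)
    cardiac = params.cardiac_scale * params.hbo_peak_amplitude_uM * np.sin(
        2 * np.pi * (CARDIAC_BPM / 60.0) * t + rng.uniform(0, 2 * np.pi)
    )

    n_ch = layout.n_channels
    intensity = np.empty((n_ch, 2, n), float)
    gt_hbo = np.empty((n_ch, n), float)
    gt_hb = np.empty((n_ch, n), float)
    for i, c in enumerate(layout.channels):
        hbo = gains[c.channel_id] * unit_hbo
        hb = params.hb_ratio * hbo
        gt_hbo[i] = hbo - hbo.mean()
        gt_hb[i] = hb - hb.mean()
        hbo_n = hbo + cardiac
        hb_n = hb - 0.25 * cardiac
        sep_cm = c.separation_mm / 10.0
        for w, wl in enumerate(WAVELENGTHS_NM):
            i0 = 1e6 * rng.uniform(0.5, 2.0)
            base = forward_intensity(hbo_n, hb_n, wl, i0, sep_cm, DPF_DEFAULT)
            drift = np.exp(_slow_drift(rng, t, params.drift_scale))
            white = 1.0 + params.white_noise_scale * rng.standard_normal(n)
            intensity[i, w] = base * drift * white
    if np.any(intensity <= 0):
        intensity = np.maximum(intensity, 1e-12)

    return RawIntensityRecording(
        sampling_rate_hz=NIRS_RATE_HZ,
        wavelengths_nm=WAVELENGTHS_NM,
        channel_ids=layout.channel_ids,
        intensity=intensity,
        t_start_s=-pad_pre_s,
        ground_truth_hbo_uM=gt_hbo,
        ground_truth_hb_uM=gt_hb,
    )


# --------------------------------------------------------------------------
# EEG


def erp_component_maps(montage: Montage) -> np.ndarray:
    """Fixed dipolar topography per ERP component, (4, n_electrodes),
    unit maximum absolute value."""
    maps = []
    for (pp, pn) in _ERP_POLES:
        d_p = np.linalg.norm(montage.positions - np.asarray(pp), axis=1)
        d_n = np.linalg.norm(montage.positions - np.asarray(pn), axis=1)
        m = np.exp(-(d_p**2) / (2 * _ERP_POLE_WIDTH**2)) - np.exp(
            -(d_n**2) / (2 * _ERP_POLE_WIDTH**2)
        )
        maps.append(m / np.max(np.abs(m)))
    return np.asarray(maps)


def erp_ground_truth(
    params: SubjectParams,
    montage: Montage,
    fs_hz: float,
    window_s: tuple[float, float] = (-0.5, 3.5),
    soa_s: float = 0.6,
    n_syllables: int = 4,
) -> np.ndarray:
    """Noiseless single-trial ERP (electrode x time) on a canonical epoch
    grid time-locked to the first syllable."""
    n = int(round((window_s[1] - window_s[0]) * fs_hz))
    t = window_s[0] + np.arange(n) / fs_hz
    maps = erp_component_maps(montage)
    out = np.zeros((montage.n_electrodes, n))
    for s in range(n_syllables):
        hab = params.habituation_ratio**s
        for p, (lat, amp) in enumerate(zip(params.erp_latencies_s, params.erp_amplitudes_uV)):
            kern = amp * hab * np.exp(
                -((t - s * soa_s - lat) ** 2) / (2 * ERP_KERNEL_SIGMA_S**2)
            )
            out += np.outer(maps[p], kern)
    return out


def _band_noise(rng, n, fs, lo, hi, rms):
    """Band-limited Gaussian noise with the requested RMS."""
    from scipy.signal import butter, sosfiltfilt

    x = rng.standard_normal(n)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, x)
    return rms * x / np.sqrt(np.mean(x**2))


def simulate_eeg(
    params: SubjectParams,
    schedule: StimulusSchedule,
    montage: Montage | None = None,
    seed: int = 0,
    pad_pre_s: float = 2.0,
) -> RawEEGRecording:
    """Simulate a raw EEG recording (µV) at 2048 Hz.

    Voltage = interburst background + randomly timed high-voltage bursts
    (independent of the stimulation) + syllable-locked ERP components with
    habituation across the four syllables of each trial.
    """
    if not schedule.events:
        raise ValueError("schedule has no events")
    montage = montage or default_montage()
    if montage.n_electrodes < 2:
        raise ValueError("montage needs at least 2 electrodes")
    rng = np.random.default_rng(seed)
    duration = pad_pre_s + schedule.duration_s
    n = int(np.ceil(duration * EEG_RATE_HZ))
    t0 = -pad_pre_s
    n_el = montage.n_electrodes
    volt = np.zeros((n_el, n))

    # interburst background: band-limited noise per electrode
    if params.interburst_amplitude_uV > 0:
        rms = params.interburst_amplitude_uV / 2.0
        for e in range(n_el):
            volt[e] += _band_noise(rng, n, EEG_RATE_HZ, 0.5, 25.0, rms)

    # bursts: Poisson arrivals, Hann envelope 1-3 s, shared waveform with a
    # smooth random spatial profile
    if params.burst_rate_per_min > 0 and params.burst_amplitude_uV > 0:
        n_bursts = rng.poisson(params.burst_rate_per_min * duration / 60.0)
        for _ in range(n_bursts):
            onset = rng.uniform(t0, t0 + duration)
            dur = rng.uniform(1.0, 3.0)
            nb = int(dur * EEG_RATE_HZ)
            i0 = int((onset - t0) * EEG_RATE_HZ)
            if i0 < 0 or i0 + nb > n or nb < 8:
                continue
            env = np.hanning(nb)
            content = _band_noise(rng, nb, EEG_RATE_HZ, 1.0, 8.0, 1.0) * env
            content *= params.burst_amplitude_uV / max(np.max(np.abs(content)), 1e-12)
            profile = 0.5 + 0.5 * rng.uniform(0, 1, size=n_el)
            volt[:, i0 : i0 + nb] += np.outer(profile, content)

    # syllable-locked ERP
    maps = erp_component_maps(montage)
    sigma = ERP_KERNEL_SIGMA_S
    for idx, ev in enumerate(schedule.events):
        pos = idx % schedule.n_syllables_per_trial  # events are ordered, 4/trial
        hab = params.habituation_ratio**pos
        for p, (lat, amp) in enumerate(zip(params.erp_latencies_s, params.erp_amplitudes_uV)):
            centre = ev.onset_s + lat
            lo = int((centre - 5 * sigma - t0) * EEG_RATE_HZ)
            hi = int((centre + 5 * sigma - t0) * EEG_RATE_HZ) + 1
            lo, hi = max(lo, 0), min(hi, n)
            if hi <= lo:
                continue
            tt = t0 + np.arange(lo, hi) / EEG_RATE_HZ
            kern = amp * hab * np.exp(-((tt - centre) ** 2) / (2 * sigma**2))
            volt[:, lo:hi] += np.outer(maps[p], kern)

    return RawEEGRecording(
        sampling_rate_hz=EEG_RATE_HZ, labels=montage.labels, voltage=volt, t_start_s=t0
    )


# --------------------------------------------------------------------------
# cohorts


def simulate_cohort(
    n_healthy: int,
    n_ivh: int,
    n_blocks: int,
    seed: int,
    out_dir,
    modalities: tuple[str, ...] = ("nirs", "eeg"),
    params_overrides: dict | None = None,
) -> dict:
    """Simulate and write a full cohort dataset; returns the manifest.

    Per-subject seeds derive deterministically from the master seed.  Healthy
    subjects come first (``sub-h01`` ...), then IVH (``sub-i01`` ...).
    """
    from .dataset import write_subject, write_manifest

    if n_healthy < 0 or n_ivh < 0:
        raise ValueError("cohort counts must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = build_probe()
    montage = default_montage()
    rng = np.random.default_rng(seed)
    n_total = n_healthy + n_ivh
    subject_seeds = rng.integers(0, 2**31, size=max(n_total, 1) * 3)

    subjects = []
    k = 0
    for group, count, tag in (("healthy", n_healthy, "h"), ("IVH", n_ivh, "i")):
        for j in range(count):
            sid = f"sub-{tag}{j + 1:02d}"
            params = SubjectParams(subject_id=sid, group=group)
            for key, val in (params_overrides or {}).items():
                setattr(params, key, val)
            sched_seed = int(subject_seeds[3 * k])
            schedule = build_paradigm(n_blocks, seed=sched_seed)
            rec_nirs = rec_eeg = None
            if "nirs" in modalities:
                rec_nirs = simulate_nirs(params, schedule, layout, seed=int(subject_seeds[3 * k + 1]))
            if "eeg" in modalities:
                rec_eeg = simulate_eeg(params, schedule, montage, seed=int(subject_seeds[3 * k + 2]))
            write_subject(out_dir, sid, params, schedule, rec_nirs, rec_eeg)
            subjects.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "seed": int(subject_seeds[3 * k]),
                    "path": sid,
                }
            )
            k += 1
    manifest = {
        "schema_version": 1,
        "master_seed": int(seed),
        "n_blocks": int(n_blocks),
        "modalities": list(modalities),
        "subjects": subjects,
    }
    write_manifest(out_dir, manifest)
    layout.to_json(out_dir / "probe_layout.json")
    return manifest
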