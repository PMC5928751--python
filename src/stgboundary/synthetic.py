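"""Synthetic audiovisual-speech ECoG and BOLD fMRI data with a planted boundary.

The generator emulates the statistical structure of a dual-modality study of
multisensory speech perception on the superior temporal gyrus (STG):

* a 1-D gyrus model (position in mm from the anterior tip) with an anatomical
  landmark (the posterior margin of Heschl's gyrus) and a planted *functional*
  boundary where the clear-minus-noisy speech contrast crosses zero;
* rapid event-related fMRI runs (160 volumes at TR 1.5 s; 48 three-second
  trials per run, 12 per condition) of four audiovisual conditions
  (auditory clear/noisy x visual clear/blurred);
* multichannel ECoG-like recordings at 2 kHz in which each trial multiplies
  the ongoing 70-110 Hz band power by a condition- and position-dependent
  factor, on top of pink-noise background and 60 Hz line noise;
* voxel time series in raw scanner intensity around a baseline of ~1000 with
  AR(1) noise, slow polynomial drift and small motion-coupled artifacts;
* Bernoulli behavioral responses with condition-specific accuracy.

Anterior cortex prefers clear speech (default high-gamma ~300% vs ~110%
percent change; BOLD ~0.37% vs ~0.24%), posterior cortex prefers noisy
speech, and the generating clear-minus-noisy amplitude profile crosses zero
exactly at the planted boundary, so every downstream analysis stage can be
checked against a known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "CLEAR_CONDITIONS",
    "NOISY_CONDITIONS",
    "GyrusModel",
    "EventSchedule",
    "EcogRecording",
    "BoldSession",
    "SimulationParams",
    "make_gyrus",
    "make_event_schedule",
    "simulate_ecog",
    "simulate_bold",
    "simulate_behavior",
    "simulate_response_table",
    "condition_amplitudes",
]

CONDITIONS = ("AclearVclear", "AclearVblur", "AnoisyVclear", "AnoisyVblur")
CLEAR_CONDITIONS = CONDITIONS[:2]
NOISY_CONDITIONS = CONDITIONS[2:]


# ---------------------------------------------------------------------------
# Gyrus geometry


@dataclass(frozen=True)
class GyrusModel:
    """A 1-D anterior-to-posterior coordinate frame for the STG.

    Positions are millimetres from the anterior tip of the gyrus strip.  The
    affine ``y = standard_offset_mm - position`` maps strip position onto the
    standard-space anterior-posterior (y) axis, where more posterior cortex
    has more negative y.
    """

    length_mm: float = 100.0
    node_spacing_mm: float = 1.0
    anatomical_landmark_mm: float = 70.0
    true_boundary_mm: float = 68.0
    standard_offset_mm: float = 40.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.node_spacing_mm <= 0:
            raise ValueError("node_spacing_mm must be positive")
        if not 0 < self.anatomical_landmark_mm < self.length_mm:
            raise ValueError("anatomical landmark must lie strictly inside the strip")
        if not 0 < self.true_boundary_mm < self.length_mm:
            raise ValueError("true boundary must lie strictly inside the strip")

    @property
    def node_positions(self) -> np.ndarray:
        n = int(np.floor(self.length_mm / self.node_spacing_mm)) + 1
        return np.arange(n) * self.node_spacing_mm

    @property
    def posterior_third_start_mm(self) -> float:
        return 2.0 * self.length_mm / 3.0

    def to_standard_y(self, position_mm):
        """Map strip position (mm from anterior tip) to standard-space y (mm)."""
        return self.standard_offset_mm - np.asarray(position_mm, dtype=float)


def make_gyrus(
    length_mm: float = 100.0,
    anatomical_landmark_mm: float = 70.0,
    true_boundary_mm: float = 68.0,
    standard_offset_mm: float = 40.0,
    node_spacing_mm: float = 1.0,
) -> GyrusModel:
    """Build a gyrus model; defaults map the landmark to y = -30 and the
    planted functional boundary to y = -28 in standard space."""
    return GyrusModel(
        length_mm=length_mm,
        node_spacing_mm=node_spacing_mm,
        anatomical_landmark_mm=anatomical_landmark_mm,
        true_boundary_mm=true_boundary_mm,
        standard_offset_mm=standard_offset_mm,
    )


# ---------------------------------------------------------------------------
# Event schedule


@dataclass(frozen=True)
class EventSchedule:
    """Trial onsets for a rapid event-related session.

    ``trials`` has one row per trial with columns ``run`` (0-based),
    ``onset_s`` (relative to run start, on the TR lattice), ``duration_s``
    and ``condition``.
    """

    trials: pd.DataFrame
    n_runs: int
    tr_s: float = 1.5
    volumes_per_run: int = 160

    @property
    def run_duration_s(self) -> float:
        return self.tr_s * self.volumes_per_run

    @property
    def total_volumes(self) -> int:
        return self.n_runs * self.volumes_per_run

    def baseline_s_per_run(self, run: int = 0) -> float:
        t = self.trials[self.trials["run"] == run]
        return self.run_duration_s - float(t["duration_s"].sum())

    def run_trials(self, run: int) -> pd.DataFrame:
        return self.trials[self.trials["run"] == run].reset_index(drop=True)


def make_event_schedule(
    n_runs: int = 5,
    trials_per_condition_per_run: int = 12,
    tr_s: float = 1.5,
    volumes_per_run: int = 160,
    trial_duration_s: float = 3.0,
    seed: int = 0,
) -> EventSchedule:
    """Randomized non-overlapping trial onsets on the TR lattice.

    Each run is a shuffled sequence of trial tokens (occupying
    ``ceil(duration/TR)`` volumes each) and single-volume baseline tokens, so
    per-run condition counts are exact, trials never overlap, and every trial
    ends before the end of the run.  Deterministic given ``seed``.
    """
    if n_runs < 1 or trials_per_condition_per_run < 0:
        raise ValueError("need n_runs >= 1 and non-negative trial count")
    if tr_s <= 0 or trial_duration_s <= 0:
        raise ValueError("tr_s and trial_duration_s must be positive")
    slots_per_trial = int(np.ceil(trial_duration_s / tr_s))
    n_trials_run = 4 * trials_per_condition_per_run
    if n_trials_run * slots_per_trial > volumes_per_run:
        raise ValueError(
            "infeasible packing: total trial time exceeds run duration"
        )
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for run in range(n_runs):
        conds = np.repeat(CONDITIONS, trials_per_condition_per_run)
        rng.shuffle(conds)
        n_baseline = volumes_per_run - n_trials_run * slots_per_trial
        tokens = np.array([1] * n_trials_run + [0] * n_baseline)
        rng.shuffle(tokens)
        slot = 0
        trial_i = 0
        for tok in tokens:
            if tok == 1:
                rows.append(
                    {
                        "run": run,
                        "onset_s": slot * tr_s,
                        "duration_s": trial_duration_s,
                        "condition": conds[trial_i],
                    }
                )
                trial_i += 1
                slot += slots_per_trial
            else:
                slot += 1
    trials = pd.DataFrame(rows, columns=["run", "onset_s", "duration_s", "condition"])
    return EventSchedule(
        trials=trials, n_runs=n_runs, tr_s=tr_s, volumes_per_run=volumes_per_run
    )


# ---------------------------------------------------------------------------
# Simulation parameters


def _default_ecog_anterior() -> dict:
    return {
        "AclearVclear": 300.0,
        "AclearVblur": 300.0,
        "AnoisyVclear": 110.0,
        "AnoisyVblur": 110.0,
    }


def _default_ecog_posterior() -> dict:
    return {
        "AclearVclear": 110.0,
        "AclearVblur": 110.0,
        "AnoisyVclear": 190.0,
        "AnoisyVblur": 190.0,
    }


def _default_bold_anterior() -> dict:
    return {
        "AclearVclear": 0.37,
        "AclearVblur": 0.37,
        "AnoisyVclear": 0.24,
        "AnoisyVblur": 0.24,
    }


def _default_bold_posterior() -> dict:
    return {
        "AclearVclear": 0.26,
        "AclearVblur": 0.26,
        "AnoisyVclear": 0.33,
        "AnoisyVblur": 0.33,
    }


def _default_accuracy() -> dict:
    return {
        "AclearVclear": 0.99,
        "AclearVblur": 0.99,
        "AnoisyVclear": 0.87,
        "AnoisyVblur": 0.69,
    }


@dataclass(frozen=True)
class SimulationParams:
    """Generating amplitudes, noise levels and behavioral accuracies.

    High-gamma amplitudes are percent change over the pre-stimulus baseline;
    BOLD amplitudes are percent signal change for a single trial.  The
    clear-vs-noisy preference reverses across the planted boundary with a
    sigmoidal transition of width ``transition_width_mm``.
    """

    ecog_anterior_amp: Mapping[str, float] = field(default_factory=_default_ecog_anterior)
    ecog_posterior_amp: Mapping[str, float] = field(default_factory=_default_ecog_posterior)
    bold_anterior_amp: Mapping[str, float] = field(default_factory=_default_bold_anterior)
    bold_posterior_amp: Mapping[str, float] = field(default_factory=_default_bold_posterior)
    transition_width_mm: float = 4.0

    # ECoG noise composition (microvolt-like units)
    ecog_carrier_rms: float = 5.0
    ecog_inband_noise_rms: float = 2.0
    ecog_pink_noise_rms: float = 15.0
    ecog_line_amp: float = 10.0

    # BOLD noise (percent-signal units unless noted)
    bold_noise_sd_pct: float = 0.2
    bold_ar1: float = 0.3
    bold_drift_pct: float = 0.5
    bold_motion_coupling_pct: float = 0.05
    bold_baseline: float = 1000.0

    behavior_accuracy: Mapping[str, float] = field(default_factory=_default_accuracy)

    def __post_init__(self) -> None:
        for amps in (
            self.ecog_anterior_amp,
            self.ecog_posterior_amp,
            self.bold_anterior_amp,
            self.bold_posterior_amp,
        ):
            if set(amps) != set(CONDITIONS):
                raise ValueError("amplitude maps must cover the four conditions")
            if any(v < 0 for v in amps.values()):
                raise ValueError("amplitudes must be non-negative")
        if self.transition_width_mm <= 0:
            raise ValueError("transition width must be positive")
        if set(self.behavior_accuracy) != set(CONDITIONS):
            raise ValueError("accuracy map must cover the four conditions")
        if any(not 0 <= v <= 1 for v in self.behavior_accuracy.values()):
            raise ValueError("accuracies must lie in [0, 1]")

    def with_zero_noise(self) -> "SimulationParams":
        """Copy with every stochastic term switched off (generative identity)."""
        return replace(
            self,
            ecog_inband_noise_rms=0.0,
            ecog_pink_noise_rms=0.0,
            ecog_line_amp=0.0,
            bold_noise_sd_pct=0.0,
            bold_drift_pct=0.0,
            bold_motion_coupling_pct=0.0,
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def condition_amplitudes(
    positions_mm: np.ndarray,
    anterior: Mapping[str, float],
    posterior: Mapping[str, float],
    boundary_mm: float,
    width_mm: float,
) -> dict[str, np.ndarray]:
    """Per-condition response amplitude along the strip.

    Each condition interpolates sigmoidally from its anterior to its posterior
    plateau.  The auditory clear-minus-noisy component is re-centred so that
    the generating contrast ``mean(clear) - mean(noisy)`` crosses zero exactly
    at ``boundary_mm`` (a plain sigmoid blend would cross slightly off-centre
    whenever the anterior and posterior contrast magnitudes differ).
    """
    pos = np.asarray(positions_mm, dtype=float)
    s = _sigmoid((pos - boundary_mm) / width_mm)
    base = {c: anterior[c] + (posterior[c] - anterior[c]) * s for c in CONDITIONS}

    d_ant = (
        anterior["AclearVclear"] + anterior["AclearVblur"]
        - anterior["AnoisyVclear"] - anterior["AnoisyVblur"]
    ) / 2.0
    d_post = (
        posterior["AclearVclear"] + posterior["AclearVblur"]
        - posterior["AnoisyVclear"] - posterior["AnoisyVblur"]
    ) / 2.0
    d_plain = d_ant + (d_post - d_ant) * s
    if d_ant > 0 > d_post:
        q = d_ant / (d_ant - d_post)
        p0 = boundary_mm - width_mm * np.log(q / (1.0 - q))
        d_target = d_ant + (d_post - d_ant) * _sigmoid((pos - p0) / width_mm)
    else:
        d_target = d_plain  # no sign reversal requested; leave profile as-is
    delta = (d_target - d_plain) / 2.0
    out = {}
    for c in CONDITIONS:
        sign = 1.0 if c in CLEAR_CONDITIONS else -1.0
        out[c] = base[c] + sign * delta
    return out


# ---------------------------------------------------------------------------
# ECoG simulation


@dataclass
class EcogRecording:
    """A multichannel ECoG-like recording with a trial event table.

    ``channels`` has one row per channel with ``channel`` (id) and
    ``position_mm`` (strip position; NaN for off-gyrus reference channels,
    which exist so that common average referencing behaves as it does with a
    realistic full electrode montage).  ``events`` holds auditory-onset times
    (``onset_s``, seconds from recording start) and conditions.
    """

    sample_rate_hz: float
    channels: pd.DataFrame
    samples: np.ndarray  # (n_channels, n_samples), float32
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("samples and channel table disagree on channel count")
        dur = self.samples.shape[1] / self.sample_rate_hz
        if len(self.events) and (
            (self.events["onset_s"] < 0).any() or (self.events["onset_s"] > dur).any()
        ):
            raise ValueError("event times must lie within the recording span")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sample_rate_hz

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


def burst_envelope(t_s: np.ndarray) -> np.ndarray:
    """Normalized high-gamma burst envelope, time in s after auditory onset.

    Rises smoothly from 40 ms, reaches its peak of 1 by ~180 ms (onset latency
    under 100 ms, peak around 200 ms), holds a 200 ms plateau, then decays
    exponentially (tau = 120 ms).  The plateau makes the peak of the
    time-smoothed power estimate equal the generating amplitude.
    """
    t = np.asarray(t_s, dtype=float)
    env = np.zeros_like(t)
    rise = (t >= 0.040) & (t < 0.180)
    env[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - 0.040) / 0.140))
    plateau = (t >= 0.180) & (t <= 0.380)
    env[plateau] = 1.0
    decay = t > 0.380
    env[decay] = np.exp(-(t[decay] - 0.380) / 0.120)
    return env


def _fft_band_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    rms: float,
    f_lo: float,
    f_hi: float,
    exclude: tuple[float, float] | None = None,
    pink: bool = True,
) -> np.ndarray:
    """Gaussian noise synthesized in the frequency domain.

    Non-zero spectral content only in [f_lo, f_hi] (optionally excluding a
    band), with 1/f power weighting when ``pink``.  Scaled to the requested
    RMS.  The random draw happens even when rms == 0 so that the stream of
    random numbers (and hence everything downstream) does not depend on the
    noise scale.
    """
    from scipy.fft import irfft, next_fast_len

    n_fast = next_fast_len(n)
    freqs = np.fft.rfftfreq(n_fast, d=1.0 / fs)
    coef = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    if rms == 0.0:
        return np.zeros(n)
    weight = np.zeros(freqs.size)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    if pink:
        with np.errstate(divide="ignore"):
            weight[sel] = 1.0 / np.sqrt(np.maximum(freqs[sel], f_lo))
    else:
        weight[sel] = 1.0
    if exclude is not None:
        weight[(freqs >= exclude[0]) & (freqs <= exclude[1])] = 0.0
    x = irfft(coef * weight, n=n_fast)[:n]
    cur = np.sqrt(np.mean(x**2))
    if cur == 0:
        return np.zeros(n)
    return x * (rms / cur)


def simulate_ecog(
    gyrus: GyrusModel,
    electrode_positions: Sequence[float],
    n_trials_per_condition: int,
    params: SimulationParams | None = None,
    seed: int = 0,
    sample_rate_hz: float = 2000.0,
    n_reference_channels: int = 54,
    iti_s: float = 2.5,
    iti_jitter_s: float = 0.5,
    band: tuple[float, float] = (70.0, 110.0),
    line_hz: float = 60.0,
) -> EcogRecording:
    """Simulate a continuous ECoG recording with band-power trial responses.

    Each strip electrode carries an ongoing 70-110 Hz process (a deterministic
    multi-sine carrier plus, optionally, stochastic band-limited noise) whose
    *amplitude* is multiplied during each trial by
    ``sqrt(1 + (amp%/100) * envelope(t))``, so the in-band power percent
    change follows ``amp% * envelope`` exactly.  Off-band pink noise and a
    60 Hz line component are additive and unmodulated.  Reference channels
    carry noise only.  Deterministic given ``seed``.
    """
    params = params or SimulationParams()
    if n_trials_per_condition < 0:
        raise ValueError("trial count must be non-negative")
    positions = np.asarray(electrode_positions, dtype=float)
    if positions.size and (
        (positions < 0).any() or (positions > gyrus.length_mm).any()
    ):
        raise ValueError("electrode positions must lie on the gyrus strip")

    rng = np.random.default_rng(seed)
    fs = sample_rate_hz

    # Event sequence: shuffled conditions, jittered onsets on the 1 ms grid.
    n_trials = 4 * n_trials_per_condition
    conds = np.repeat(CONDITIONS, n_trials_per_condition)
    rng.shuffle(conds)
    gaps = iti_s + iti_jitter_s * rng.random(n_trials)
    onsets = 2.0 + np.concatenate(([0.0], np.cumsum(gaps[:-1])))
    onsets = np.round(onsets * 1000.0) / 1000.0
    duration = (onsets[-1] if n_trials else 2.0) + 2.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    amp_by_cond = condition_amplitudes(
        positions,
        params.ecog_anterior_amp,
        params.ecog_posterior_amp,
        gyrus.true_boundary_mm,
        params.transition_width_mm,
    )

    # Per-trial envelope train, shared across channels.
    env_train = {}
    for c in CONDITIONS:
        tr = np.zeros(n)
        for onset in onsets[conds == c]:
            i0 = int(round(onset * fs))
            i1 = min(n, i0 + int(1.2 * fs))
            tr[i0:i1] += burst_envelope(t[i0:i1] - onset)
        env_train[c] = tr

    # Single mid-band carrier line per strip electrode: its instantaneous
    # band power is constant, so the planted percent-change profile survives
    # time-averaging exactly (several in-band lines on one channel would beat
    # at their difference frequencies).  Electrodes get slightly offset
    # carrier frequencies -- coherent same-frequency lines across channels
    # would otherwise interfere through the common average reference and add
    # a random per-recording power bias.  Reference channels carry no
    # deterministic in-band line at all.
    bw = band[1] - band[0]
    carrier_amp = params.ecog_carrier_rms * np.sqrt(2.0)

    channel_ids = [f"E{i:02d}" for i in range(positions.size)] + [
        f"R{i:02d}" for i in range(n_reference_channels)
    ]
    ch_pos = np.concatenate([positions, np.full(n_reference_channels, np.nan)])
    samples = np.empty((len(channel_ids), n), dtype=np.float32)

    n_strip = positions.size
    for ci in range(len(channel_ids)):
        phase = rng.uniform(0, 2 * np.pi)
        if ci < n_strip:
            frac = (ci % 8) / 8.0 if n_strip > 1 else 0.5
            f_carrier = band[0] + bw * (0.3 + 0.4 * frac)
            carrier = carrier_amp * np.cos(2 * np.pi * f_carrier * t + phase)
        else:
            carrier = np.zeros(n)
        inband = _fft_band_noise(
            rng, n, fs, params.ecog_inband_noise_rms, band[0], band[1], pink=True
        )
        # Guard margin keeps the unmodulated background out of the analysis
        # band even as seen through the ~10 Hz spectral smoothing of a short
        # analysis window.
        pink = _fft_band_noise(
            rng, n, fs, params.ecog_pink_noise_rms, 0.5, fs / 2.0,
            exclude=(band[0] - 15.0, band[1] + 15.0), pink=True,
        )
        line_phase = rng.uniform(0, 2 * np.pi)
        line = params.ecog_line_amp * np.sin(2 * np.pi * line_hz * t + line_phase)

        if ci < positions.size:
            mod = np.ones(n)
            for c in CONDITIONS:
                mod += (amp_by_cond[c][ci] / 100.0) * env_train[c]
            gain = np.sqrt(np.maximum(mod, 0.0))
        else:
            gain = 1.0
        samples[ci] = ((carrier + inband) * gain + pink + line).astype(np.float32)

    channels = pd.DataFrame({"channel": channel_ids, "position_mm": ch_pos})
    events = pd.DataFrame({"onset_s": onsets, "condition": conds})
    return EcogRecording(
        sample_rate_hz=fs, channels=channels, samples=samples, events=events
    )


# ---------------------------------------------------------------------------
# BOLD simulation


@dataclass
class BoldSession:
    """Voxel time series for one simulated hemisphere/session.

    ``voxels`` maps each voxel to a strip position and a depth index (the
    thickness axis used by volume-to-surface sampling); ``data`` is raw
    scanner-intensity series (n_voxels, n_volumes); ``motion`` holds the six
    nuisance columns per volume.  ``generating_amplitudes`` records the true
    per-voxel, per-condition percent-signal amplitudes used by the generator
    (for parameter-recovery oracles).
    """

    gyrus: GyrusModel
    schedule: EventSchedule
    voxels: pd.DataFrame
    data: np.ndarray
    motion: pd.DataFrame
    tr_s: float
    generating_amplitudes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.shape[1] != self.schedule.total_volumes:
            raise ValueError("series length must equal runs x volumes_per_run")
        if len(self.motion) != self.data.shape[1]:
            raise ValueError("motion table must have one row per volume")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]


def ground_truth_hrf(dt_s: float = 0.1):
    """The generator's hemodynamic impulse response.

    Auditory-cortex responses to brief stimuli peak slightly earlier than the
    canonical kernel used for cross-modal prediction and show their
    post-stimulus undershoot from ~10 s onward: peak 5.75 s, trough 12.75 s,
    peak/undershoot ratio 4 (sharper lobes realize the closer peak-trough
    spacing).  The deconvolved single-trial response then peaks in the 4-6 s
    window and is already negative at the 10.5 s lag, while remaining close
    enough to the canonical kernel that cross-modal predictions correlate in
    the high 0.9s.
    """
    from .forward import make_double_gamma_hrf

    return make_double_gamma_hrf(
        peak_time_s=5.75,
        undershoot_offset_s=7.0,
        ratio=4.0,
        dt_s=dt_s,
        shape=8.0,
    )


def bold_response_kernel(hrf_kernel: np.ndarray, dt_s: float, block_s: float = 2.0):
    """Single-trial BOLD kernel: HRF convolved with a neural boxcar, unit peak."""
    box = np.ones(max(1, int(round(block_s / dt_s))))
    k = np.convolve(box, hrf_kernel) * dt_s
    return k / k.max()


def condition_regressors(
    schedule: EventSchedule,
    kernel: np.ndarray,
    dt_s: float,
    block_s: float = 2.0,
) -> dict[str, np.ndarray]:
    """Unit-peak condition regressors sampled on the TR grid (runs concatenated).

    ``kernel`` is the raw HRF sampled at ``dt_s``; each condition's regressor
    is its boxcar train convolved with the HRF and normalized so an isolated
    trial peaks at 1.
    """
    n_fine = int(round(schedule.run_duration_s / dt_s))
    single = bold_response_kernel(kernel, dt_s, block_s)
    tr_idx = (np.arange(schedule.volumes_per_run) * schedule.tr_s / dt_s).round().astype(int)
    out = {c: [] for c in CONDITIONS}
    box_n = max(1, int(round(block_s / dt_s)))
    for run in range(schedule.n_runs):
        trials = schedule.run_trials(run)
        for c in CONDITIONS:
            stim = np.zeros(n_fine)
            for onset in trials.loc[trials["condition"] == c, "onset_s"]:
                i0 = int(round(onset / dt_s))
                stim[i0 : i0 + box_n] = 1.0
            reg = np.convolve(stim, kernel)[:n_fine] * dt_s
            reg /= (np.convolve(np.ones(box_n), kernel) * dt_s).max()
            out[c].append(reg[tr_idx])
    return {c: np.concatenate(v) for c, v in out.items()}


def simulate_bold(
    gyrus: GyrusModel,
    schedule: EventSchedule,
    params: SimulationParams | None = None,
    seed: int = 0,
    voxel_spacing_mm: float = 1.0,
    n_depth: int = 3,
    hrf_kernel: np.ndarray | None = None,
    hrf_dt_s: float = 0.1,
    neural_block_s: float = 0.6,
) -> BoldSession:
    """Simulate an event-related BOLD session on the gyrus voxel grid.

    Neural amplitudes per condition follow the sigmoidal anterior-to-posterior
    profile (clear-minus-noisy crossing zero at the planted boundary).  Each
    trial drives a brief neural event (default 0.6 s, the duration of a
    single spoken word) convolved with the ground-truth double-gamma HRF,
    scaled about a raw baseline of ~1000, and corrupted with AR(1) noise,
    per-run quadratic drift, and small motion-coupled artifacts.
    Deterministic given ``seed``.
    """
    from .forward import make_double_gamma_hrf  # local import avoids cycle at import time

    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    if hrf_kernel is None:
        hrf = ground_truth_hrf(dt_s=hrf_dt_s)
        hrf_kernel = hrf.kernel

    positions = np.arange(0.0, gyrus.length_mm + 1e-9, voxel_spacing_mm)
    n_pos = positions.size
    vox_pos = np.repeat(positions, n_depth)
    vox_depth = np.tile(np.arange(n_depth), n_pos)
    n_vox = vox_pos.size
    n_t = schedule.total_volumes

    amps = condition_amplitudes(
        vox_pos,
        params.bold_anterior_amp,
        params.bold_posterior_amp,
        gyrus.true_boundary_mm,
        params.transition_width_mm,
    )
    regs = condition_regressors(schedule, hrf_kernel, hrf_dt_s, block_s=neural_block_s)
    signal_pct = np.zeros((n_vox, n_t))
    for c in CONDITIONS:
        signal_pct += np.outer(amps[c], regs[c])

    # AR(1) noise, stationary sd = bold_noise_sd_pct, independent per run.
    rho = params.bold_ar1
    noise = np.zeros((n_vox, n_t))
    vpr = schedule.volumes_per_run
    for run in range(schedule.n_runs):
        w = rng.standard_normal((n_vox, vpr))
        block = np.empty((n_vox, vpr))
        block[:, 0] = w[:, 0]
        for j in range(1, vpr):
            block[:, j] = rho * block[:, j - 1] + np.sqrt(1 - rho**2) * w[:, j]
        noise[:, run * vpr : (run + 1) * vpr] = block
    noise *= params.bold_noise_sd_pct

    # Per-run quadratic drift with random voxel coefficients.
    tau = np.linspace(-1.0, 1.0, vpr)
    drift_basis = np.vstack([tau, tau**2 - np.mean(tau**2)])
    drift = np.zeros((n_vox, n_t))
    for run in range(schedule.n_runs):
        coef = rng.standard_normal((n_vox, 2)) * params.bold_drift_pct / 2.0
        drift[:, run * vpr : (run + 1) * vpr] = coef @ drift_basis

    # Motion: slow random walks, lightly coupled into each voxel.
    steps = rng.standard_normal((n_t, 6)) * 0.02
    motion = np.cumsum(steps, axis=0)
    motion -= motion.mean(axis=0, keepdims=True)
    coupling = rng.standard_normal((n_vox, 6)) * params.bold_motion_coupling_pct
    motion_sig = coupling @ motion.T

    total_pct = signal_pct + noise + drift + motion_sig
    data = params.bold_baseline * (1.0 + total_pct / 100.0)

    voxels = pd.DataFrame(
        {
            "voxel": np.arange(n_vox),
            "position_mm": vox_pos,
            "depth": vox_depth,
        }
    )
    motion_df = pd.DataFrame(motion, columns=[f"motion{i+1}" for i in range(6)])
    gen_amp = pd.DataFrame({c: amps[c] for c in CONDITIONS})
    return BoldSession(
        gyrus=gyrus,
        schedule=schedule,
        voxels=voxels,
        data=data,
        motion=motion_df,
        tr_s=schedule.tr_s,
        generating_amplitudes=gen_amp,
    )


# ---------------------------------------------------------------------------
# Behavior


def simulate_behavior(
    schedule: EventSchedule,
    params: SimulationParams | None = None,
    seed: int = 0,
    participant: str = "P00",
) -> pd.DataFrame:
    """Bernoulli word-identification correctness per trial.

    Returns the trial table with added ``participant`` and ``correct`` columns.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    trials = schedule.trials.copy()
    p = trials["condition"].map(params.behavior_accuracy).to_numpy(dtype=float)
    trials["correct"] = (rng.random(len(trials)) < p).astype(int)
    trials.insert(0, "participant", participant)
    return trials


# ---------------------------------------------------------------------------
# Factorial response tables (for mixed-model recovery and calibration)


def simulate_response_table(
    effects: Mapping[str, float] | None = None,
    n_anterior: int = 16,
    n_posterior: int = 11,
    n_participants: int = 5,
    sigma_e: float = 40.0,
    sigma_b: float = 45.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a unit x condition response table with known fixed effects.

    Each unit (e.g. an electrode) sits at a fixed location and contributes one
    response per auditory x visual cell; participants contribute a shared
    random intercept (sd ``sigma_b``) and each response an independent
    residual (sd ``sigma_e``).  ``effects`` uses treatment coding with
    reference anterior / auditory-clear / visual-clear; keys: ``baseline``,
    ``An``, ``Vb``, ``posterior``, ``An:Vb``, ``posterior:An``,
    ``posterior:Vb``, ``posterior:An:Vb``.  Default effect sizes follow the
    observed high-gamma response structure (strong clear preference
    anteriorly that reverses posteriorly).
    """
    if effects is None:
        effects = {
            "baseline": 183.1,
            "An": -109.6,
            "Vb": 21.6,
            "posterior": -101.0,
            "An:Vb": -13.3,
            "posterior:An": 140.6,
            "posterior:Vb": -8.9,
            "posterior:An:Vb": 3.6,
        }
    rng = np.random.default_rng(seed)
    n_units = n_anterior + n_posterior
    unit_part = np.arange(n_units) % n_participants
    b = rng.standard_normal(n_participants) * sigma_b
    rows = []
    for u in range(n_units):
        post = 1 if u >= n_anterior else 0
        for an in (0, 1):
            for vb in (0, 1):
                mu = (
                    effects["baseline"]
                    + effects["An"] * an
                    + effects["Vb"] * vb
                    + effects["posterior"] * post
                    + effects["An:Vb"] * an * vb
                    + effects["posterior:An"] * post * an
                    + effects["posterior:Vb"] * post * vb
                    + effects["posterior:An:Vb"] * post * an * vb
                )
                rows.append(
                    {
                        "unit": f"u{u:03d}",
                        "participant": f"p{unit_part[u]:02d}",
                        "location": "posterior" if post else "anterior",
                        "auditory": "noisy" if an else "clear",
                        "visual": "blurred" if vb else "clear",
                        "response": mu + b[unit_part[u]] + rng.standard_normal() * sigma_e,
                    }
                )
    return pd.DataFrame(rows)
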