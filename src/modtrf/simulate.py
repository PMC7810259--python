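"""Ground-truth-known synthetic EEG and behavior for validating the pipeline.

The EEG forward model mirrors what the analysis assumes: a component time
course is the convolution of each trial's stimulus envelope with a known
lag-resolved kernel, projected through a fixed unit-norm channel topography,
plus 1/f-amplitude-spectrum Gaussian noise scaled to a configurable response
SNR.  The behavioral observer reports the probe tone with probability given
by a logistic psychometric function of the tone's local SNR at a fixed
integration window, plus a constant false-alarm rate on catch trials.
Everything is a pure function of (config, master seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg import EEGEpochs, bandpass_filter

__all__ = [
    "GroundTruthKernel",
    "SimulationConfig",
    "make_kernels",
    "make_topography",
    "one_over_f_noise",
    "simulate_eeg",
    "simulate_component_trials",
    "simulate_behavior",
]

#: staggered peak latencies (ms) giving mutually dissimilar kernels in
#: "specific" mode; within the 0-500 ms lag window used for TRF estimation
SPECIFIC_PEAKS_MS = (60.0, 95.0, 135.0, 180.0, 230.0, 290.0)


@dataclass(frozen=True)
class GroundTruthKernel:
    am_type: str
    neural_band: str
    peak_ms: float
    width_ms: float
    amplitude: float
    biphasic_ratio: float
    lags_ms: np.ndarray
    kernel: np.ndarray  # sampled on lags_ms


@dataclass(frozen=True)
class SimulationConfig:
    n_channels: int = 32
    n_trials_per_type: int = 50
    response_snr_db: float = 0.0
    noise_exponent: float = 1.0
    fs: float = 500.0
    epoch_span: tuple = (-3.0, 8.0)
    t0: float = 3.0
    stimulus_duration: float = 5.0
    # behavioral observer: near-threshold detection — the tone is reported
    # when it locally stands out of the masker, so the threshold sits well
    # above the -10 dB global SNR and the psychometric function is steep
    psychometric_threshold_db: float = -5.0
    psychometric_slope_db: float = 2.0
    false_alarm_rate: float = 0.1
    integration_window_ms: float = 30.0
    n_participants: int = 19
    master_seed: int = 0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in
                self.__dataclass_fields__.values()}  # type: ignore[attr-defined]


def _gamma_bump(t_ms: np.ndarray, peak_ms: float, width_ms: float) -> np.ndarray:
    """Unit-peak gamma-shaped bump with mode at peak_ms; zero for t <= 0."""
    a = (peak_ms / width_ms) ** 2
    out = np.zeros_like(t_ms, dtype=float)
    pos = t_ms > 0
    tt = t_ms[pos] / peak_ms
    out[pos] = np.exp(a * (np.log(tt) + 1.0 - tt))
    return out


def make_kernels(
    am_types,
    lags_ms: np.ndarray,
    mode: str = "specific",
    neural_band: str = "full",
    amplitude: float = 1.0,
    biphasic_ratio: float = 0.6,
) -> dict:
    """Difference-of-gamma biphasic kernels on the TRF lag grid.

    "shared": one kernel shape for every AM type (pairwise correlations 1).
    "specific": staggered peak latencies and widths per type, designed so
    pairwise kernel correlations stay below 0.5.
    """
    lags_ms = np.asarray(lags_ms, dtype=float)
    kernels = {}
    for i, am_type in enumerate(am_types):
        if mode == "shared":
            peak, width = 100.0, 30.0
        elif mode == "specific":
            peak = SPECIFIC_PEAKS_MS[i % len(SPECIFIC_PEAKS_MS)]
            width = 12.0 + 4.0 * (i % len(SPECIFIC_PEAKS_MS))
        else:
            raise ValueError(f"unknown kernel mode: {mode!r}")
        trough_peak = peak + 2.5 * width
        if trough_peak > lags_ms.max():
            raise ValueError("kernel support exceeds the lag window")
        k = _gamma_bump(lags_ms, peak, width)
        k = k - biphasic_ratio * _gamma_bump(lags_ms, trough_peak, 1.6 * width)
        kernels[am_type] = GroundTruthKernel(
            am_type=am_type, neural_band=neural_band, peak_ms=peak,
            width_ms=width, amplitude=amplitude, biphasic_ratio=biphasic_ratio,
            lags_ms=lags_ms, kernel=amplitude * k,
        )
    return kernels


def make_topography(n_channels: int, seed: int = 0,
                    smooth: int = 5) -> np.ndarray:
    """Smooth random channel weight vector, zero-mean and unit-norm.

    Average-referenced EEG defines spatial patterns only up to the reference,
    i.e., within the zero-mean channel subspace; generating the ground-truth
    topography there keeps the PCA-recovery comparison well-posed.
    """
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n_channels + smooth - 1)
    w = np.convolve(w, np.ones(smooth) / smooth, mode="valid")
    w = w - w.mean()
    return w / np.linalg.norm(w)


def one_over_f_noise(n_samples: int, exponent: float,
                     rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Gaussian noise with amplitude spectrum proportional to f**(-exponent)."""
    freqs = np.fft.rfftfreq(n_samples)
    shape_f = np.zeros_like(freqs)
    shape_f[1:] = freqs[1:] ** (-exponent)
    white = rng.standard_normal((size, len(freqs))) \
        + 1j * rng.standard_normal((size, len(freqs)))
    x = np.fft.irfft(white * shape_f, n=n_samples, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x[0] if size == 1 else x


def _component_response(envelope: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Forward model: convolution of the envelope with the kernel (causal)."""
    return np.convolve(envelope, kernel)[: len(envelope)]


def simulate_eeg(
    envelopes_by_type: dict,
    kernels: dict,
    topography: np.ndarray,
    config: SimulationConfig | None = None,
) -> EEGEpochs:
    """Multi-channel epochs from the forward model plus 1/f channel noise.

    ``envelopes_by_type``: am_type -> list of stimulus envelopes already at
    the EEG rate (config.fs), one per trial, covering the 5-s stimulus.
    Kernel values are indexed by am_type (GroundTruthKernel or bare arrays
    sampled at config.fs).  Noise is scaled so that the variance of the
    noise-free component over the stimulus window, divided by the variance
    of the noise projected onto the topography, matches response_snr_db.
    """
    cfg = config or SimulationConfig()
    if not np.isfinite(cfg.response_snr_db):
        raise ValueError("response SNR must be finite")
    fs = cfg.fs
    n_epoch = int(round((cfg.epoch_span[1] - cfg.epoch_span[0]) * fs))
    i0 = int(round(cfg.t0 * fs))
    rng = np.random.default_rng(np.random.SeedSequence(cfg.master_seed))

    components, types = [], []
    for am_type, envs in envelopes_by_type.items():
        k = kernels[am_type]
        k_arr = k.kernel if isinstance(k, GroundTruthKernel) else np.asarray(k)
        for env in envs:
            env = np.asarray(env, dtype=float)
            comp = np.zeros(n_epoch)
            resp = _component_response(env, k_arr)
            comp[i0 : i0 + len(resp)] = resp
            components.append(comp)
            types.append(am_type)
    components = np.array(components)           # (trials, samples)
    n_trials = len(components)

    stim_mask = np.zeros(n_epoch, dtype=bool)
    stim_mask[i0 : i0 + int(round(cfg.stimulus_duration * fs))] = True
    sig_var = components[:, stim_mask].var()

    noise = one_over_f_noise(n_epoch, cfg.noise_exponent, rng,
                             size=n_trials * cfg.n_channels)
    noise = noise.reshape(n_trials, cfg.n_channels, n_epoch)
    proj = np.tensordot(noise, topography, axes=([1], [0]))
    noise_var = proj[:, stim_mask].var()
    target_noise_var = sig_var * 10.0 ** (-cfg.response_snr_db / 10.0)
    noise *= np.sqrt(target_noise_var / noise_var)

    data = topography[None, :, None] * components[:, None, :] + noise
    meta = pd.DataFrame({"am_type": types})
    channels = tuple(f"ch{i:02d}" for i in range(cfg.n_channels))
    return EEGEpochs(data=data, fs=fs, t0=cfg.t0, trial_meta=meta,
                     channel_names=channels)


def simulate_component_trials(
    envelopes_by_type: dict,
    kernels: dict,
    config: SimulationConfig | None = None,
    band: tuple | None = None,
) -> dict:
    """Component-level (envelope, response) pairs without the channel stage.

    Cheaper than simulate_eeg when the spatial projection is not under test:
    response = conv(envelope, kernel) + 1/f noise at response_snr_db.  If
    ``band`` is given, the envelope is band-passed before convolution.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.master_seed))
    out = {}
    for am_type, envs in envelopes_by_type.items():
        k = kernels[am_type]
        k_arr = k.kernel if isinstance(k, GroundTruthKernel) else np.asarray(k)
        trials = []
        for env in envs:
            env = np.asarray(env, dtype=float)
            drive = bandpass_filter(env, *band, cfg.fs) if band else env
            resp = _component_response(drive, k_arr)
            noise = one_over_f_noise(len(resp), cfg.noise_exponent, rng)
            noise *= resp.std() * 10.0 ** (-cfg.response_snr_db / 20.0)
            trials.append((env, resp + noise))
        out[am_type] = trials
    return out


def simulate_behavior(
    snr_table: pd.DataFrame,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Logistic yes/no observer over the full trial table.

    ``snr_table``: one row per stimulus with columns stimulus_id, am_type and
    local_snr_db (NaN for catch trials without a probe).  Tone trials are
    reported with probability logistic((snr - threshold)/slope); catch trials
    with the fixed false-alarm rate.  Each participant gets an independent
    seeded stream.
    """
    cfg = config or SimulationConfig()
    if cfg.psychometric_slope_db <= 0:
        raise ValueError("psychometric slope must be > 0")
    snr = snr_table["local_snr_db"].to_numpy(dtype=float)
    tone_present = np.isfinite(snr)
    x = (snr - cfg.psychometric_threshold_db) / cfg.psychometric_slope_db
    with np.errstate(over="ignore"):
        p_yes = np.where(tone_present, 1.0 / (1.0 + np.exp(-x)),
                         cfg.false_alarm_rate)
    root = np.random.SeedSequence(cfg.master_seed)
    frames = []
    for p, child in enumerate(root.spawn(cfg.n_participants)):
        rng = np.random.default_rng(child)
        frames.append(pd.DataFrame({
            "participant_id": f"p{p:02d}",
            "stimulus_id": snr_table["stimulus_id"].to_numpy(),
            "am_type": snr_table["am_type"].to_numpy(),
            "tone_present": tone_present,
            "reported_tone": rng.random(len(snr)) < p_yes,
        }))
    return pd.concat(frames, ignore_index=True)
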