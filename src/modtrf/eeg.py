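"""EEG conditioning, PCA auditory-component extraction, band decomposition,
evoked responses, and Morlet induced power.

Epochs are trials x channels x samples at 500 Hz spanning -3 to +8 s around
stimulus onset.  Preprocessing: average reference, zero-phase FIR band-pass
1-45 Hz (applied forward and reverse), and baseline correction over -1 to
0 s.  A single spatial filter — the first principal component of the 0-500 ms
grand-average evoked response — projects all trials onto one auditory
component channel; all downstream analyses run on that component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "EEGEpochs",
    "SpatialFilter",
    "ComponentSignal",
    "InducedPowerResult",
    "NEURAL_BANDS",
    "preprocess_eeg",
    "fit_spatial_filter",
    "apply_spatial_filter",
    "band_decompose",
    "evoked_response",
    "induced_power",
]

#: Conventional EEG frequency bands (Hz); "full" is the whole analysis range.
NEURAL_BANDS: dict = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 45.0),
    "full": (1.0, 45.0),
}


@dataclass(frozen=True)
class EEGEpochs:
    data: np.ndarray          # (trials, channels, samples), microvolts
    fs: float                 # Hz
    t0: float                 # s of stimulus onset within the epoch
    trial_meta: pd.DataFrame  # one row per trial (am_type, ...)
    channel_names: tuple

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[-1]) / self.fs - self.t0

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["fs"] = self.fs
            f.attrs["t0"] = self.t0
            f.attrs["channel_names"] = list(self.channel_names)
            meta = f.create_group("trial_meta")
            for col in self.trial_meta.columns:
                vals = self.trial_meta[col].to_numpy()
                if vals.dtype.kind in "OU":
                    vals = vals.astype("S")
                meta.create_dataset(col, data=vals)

    @classmethod
    def load(cls, path: str | Path) -> "EEGEpochs":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            meta = {}
            for col in f["trial_meta"]:
                vals = f["trial_meta"][col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                meta[col] = vals
            return cls(
                data=data, fs=float(f.attrs["fs"]), t0=float(f.attrs["t0"]),
                trial_meta=pd.DataFrame(meta),
                channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            )


@dataclass(frozen=True)
class SpatialFilter:
    weights: np.ndarray   # one real weight per channel, unit L2 norm
    polarity: int         # +1 or -1
    explained_variance_fraction: float


@dataclass(frozen=True)
class ComponentSignal:
    data: np.ndarray          # (trials, samples)
    fs: float
    t0: float
    trial_meta: pd.DataFrame

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[-1]) / self.fs - self.t0


@dataclass(frozen=True)
class InducedPowerResult:
    freqs: np.ndarray          # Hz, 1..45
    times: np.ndarray          # s relative to stimulus onset
    spectrogram: np.ndarray    # (freqs, times), dB re baseline
    power_spectrum: np.ndarray # per-frequency mean dB over the averaging window
    baseline_window: tuple
    average_window: tuple


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def design_fir_bandpass(l_freq: float, h_freq: float, fs: float,
                        transition_hz: float = 1.0) -> np.ndarray:
    """Linear-phase Hamming-window FIR band-pass; order from the 3.3/df rule."""
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    return signal.firwin(numtaps, [l_freq, h_freq], pass_zero=False, fs=fs)


def _fir_filtfilt(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Forward-reverse application of a linear-phase FIR along the last axis."""
    shape = (1,) * (x.ndim - 1) + (len(b),)
    kernel = b.reshape(shape)
    y = signal.fftconvolve(x, kernel, mode="same", axes=-1)
    return signal.fftconvolve(y[..., ::-1], kernel, mode="same", axes=-1)[..., ::-1]


def _baseline_correct(data: np.ndarray, times: np.ndarray,
                      window: tuple) -> np.ndarray:
    mask = (times >= window[0]) & (times < window[1])
    return data - data[..., mask].mean(axis=-1, keepdims=True)


def preprocess_eeg(
    epochs: EEGEpochs,
    l_freq: float = 1.0,
    h_freq: float = 45.0,
    baseline: tuple = (-1.0, 0.0),
) -> EEGEpochs:
    """Average-reference, zero-phase FIR band-pass, baseline-correct; drop NaN trials."""
    data = epochs.data
    meta = epochs.trial_meta
    good = ~np.isnan(data).any(axis=(1, 2))
    if not good.all():
        logger.info("rejecting %d trial(s) containing NaN samples", int((~good).sum()))
        data = data[good]
        meta = meta.loc[good].reset_index(drop=True)
    data = data - data.mean(axis=1, keepdims=True)  # average reference
    b = design_fir_bandpass(l_freq, h_freq, epochs.fs)
    data = _fir_filtfilt(data, b)
    data = _baseline_correct(data, epochs.times, baseline)
    return replace(epochs, data=data, trial_meta=meta)


# ---------------------------------------------------------------------------
# auditory component extraction
# ---------------------------------------------------------------------------

def fit_spatial_filter(
    epochs: EEGEpochs,
    window: tuple = (0.0, 0.5),
    polarity_window: tuple = (0.15, 0.35),
) -> SpatialFilter:
    """First principal component of the 0-500 ms grand-average evoked response.

    The PCA runs on the channels x time evoked matrix (time points as
    observations).  Sign is fixed deterministically: the overall sign makes
    the largest-magnitude weight positive, and the reported polarity makes
    the mean component value 150-350 ms post-onset positive (automating the
    usual manual polarity check against the positive ~250-ms evoked peak).
    """
    if epochs.data.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    evoked = epochs.data.mean(axis=0)  # (channels, samples)
    times = epochs.times
    seg = evoked[:, (times >= window[0]) & (times < window[1])]
    x = seg.T - seg.T.mean(axis=0, keepdims=True)  # time x channels, centered
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[0] == 0:
        raise ValueError("rank-deficient evoked matrix")
    w = vt[0]
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    evf = float(s[0] ** 2 / np.sum(s**2))
    comp = w @ evoked
    pol_mask = (times >= polarity_window[0]) & (times < polarity_window[1])
    polarity = 1 if comp[pol_mask].mean() >= 0 else -1
    logger.info("spatial filter: EV fraction %.3f, polarity %+d", evf, polarity)
    return SpatialFilter(weights=w, polarity=polarity, explained_variance_fraction=evf)


def apply_spatial_filter(epochs: EEGEpochs, filt: SpatialFilter) -> ComponentSignal:
    if epochs.data.shape[1] != len(filt.weights):
        raise ValueError("channel count does not match the spatial filter")
    comp = filt.polarity * np.tensordot(epochs.data, filt.weights, axes=([1], [0]))
    return ComponentSignal(data=comp, fs=epochs.fs, t0=epochs.t0,
                           trial_meta=epochs.trial_meta)


# ---------------------------------------------------------------------------
# band decomposition
# ---------------------------------------------------------------------------

def band_decompose(
    component: ComponentSignal,
    bands: Mapping[str, tuple] | None = None,
    order: int = 4,
) -> dict:
    """Zero-phase Butterworth band-pass copies (forward-reverse, order `order`)."""
    bands = dict(bands) if bands is not None else dict(NEURAL_BANDS)
    out = {}
    for name, (lo, hi) in bands.items():
        if not (0 < lo < hi < component.fs / 2):
            raise ValueError(f"invalid passband {lo}-{hi} Hz for band {name!r}")
        sos = signal.butter(order, (lo, hi), btype="bandpass", fs=component.fs,
                            output="sos")
        filtered = signal.sosfiltfilt(sos, component.data, axis=-1)
        out[name] = replace(component, data=filtered)
    return out


def bandpass_filter(x: np.ndarray, lo: float, hi: float, fs: float,
                    order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass on a bare array (last axis)."""
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# evoked responses and induced power
# ---------------------------------------------------------------------------

def evoked_response(
    component: ComponentSignal,
    event: str = "onset",
    stimulus_duration: float = 5.0,
    window: tuple = (-0.2, 0.5),
    baseline: tuple = (-0.2, 0.0),
) -> tuple:
    """Trial-average response around stimulus onset or offset.

    Returns (times_relative_to_event, response); baseline over -200..0 ms
    before the event is subtracted.
    """
    if event not in ("onset", "offset"):
        raise ValueError("event must be 'onset' or 'offset'")
    t_event = 0.0 if event == "onset" else stimulus_duration
    fs = component.fs
    n = component.data.shape[-1]
    i_evt = int(round((component.t0 + t_event) * fs))
    i_lo = i_evt + int(round(window[0] * fs))
    i_hi = i_evt + int(round(window[1] * fs))
    if i_lo < 0 or i_hi > n:
        raise ValueError("epoch does not cover the requested window")
    avg = component.data.mean(axis=0)
    resp = avg[i_lo:i_hi]
    b_lo = i_evt + int(round(baseline[0] * fs))
    b_hi = i_evt + int(round(baseline[1] * fs))
    resp = resp - avg[b_lo:b_hi].mean()
    rel = (np.arange(i_lo, i_hi) - i_evt) / fs
    return rel, resp


def induced_power(
    component: ComponentSignal,
    fmin: float = 1.0,
    fmax: float = 45.0,
    baseline: tuple = (-1.0, -0.75),
    average_window: tuple = (0.5, 4.5),
    decim: int = 1,
) -> InducedPowerResult:
    """Morlet induced power, dB-normalized to the prestimulus baseline.

    Per-trial Morlet power (wavelet length rising linearly from 2 cycles at
    1 Hz to 10 cycles at 45 Hz) is averaged across trials, divided by the
    per-frequency mean over the baseline window, and converted to dB; the
    power spectrum averages the dB spectrogram over ``average_window`` to
    stay clear of onset/offset transients.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.arange(fmin, fmax + 1)
    n_cycles = 2.0 + (freqs - 1.0) * 8.0 / 44.0
    times = component.times[::decim]
    bmask = (times >= baseline[0]) & (times < baseline[1])
    if not bmask.any():
        raise ValueError("epoch does not cover the baseline window")
    power = tfr_array_morlet(
        component.data[:, None, :], sfreq=component.fs, freqs=freqs,
        n_cycles=n_cycles, output="power", decim=decim, verbose="error",
    )[:, 0]                                   # (trials, freqs, times)
    mean_power = power.mean(axis=0)
    base = mean_power[:, bmask].mean(axis=1, keepdims=True)
    spectrogram = 10.0 * np.log10(mean_power / base)
    amask = (times >= average_window[0]) & (times <= average_window[1])
    return InducedPowerResult(
        freqs=freqs, times=times, spectrogram=spectrogram,
        power_spectrum=spectrogram[:, amask].mean(axis=1),
        baseline_window=baseline, average_window=average_window,
    )
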