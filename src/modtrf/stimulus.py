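"""Synthesis of amplitude-modulated (AM) noise stimuli with prescribed modulation spectra.

The generative chain: a target modulation *amplitude* spectrum (1/f^chi or
speech-derived) -> random-phase inverse FFT -> Butterworth conditioning
(1 Hz high-pass order 3, 30 Hz low-pass order 6, forward only) -> middle
5 s of a 10-s realization -> min/max normalization to 100% modulation
depth -> multiplication onto a fresh white-noise carrier -> 50-ms
raised-cosine onset/offset ramps -> RMS calibration.  Half of the stimuli
additionally carry a 30-ms 1-kHz probe tone at a fixed global SNR, used
for the tone-detection task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "ModulationSpectrum",
    "AMEnvelope",
    "ToneProbe",
    "AMStimulus",
    "StimulusSet",
    "StimulusConfig",
    "ProbeConfig",
    "make_modulation_spectrum",
    "make_speech_surrogate_envelopes",
    "synthesize_envelope",
    "modulate_noise",
    "insert_tone",
    "probe_waveform",
    "build_stimulus_set",
    "write_stimulus_set",
    "read_manifest",
]

DEFAULT_FS = 20_000
DEFAULT_EXPONENTS = (0.5, 0.75, 1.0, 1.5, 2.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModulationSpectrum:
    """Target modulation amplitude spectrum on the rfft grid of an n_points signal."""

    frequencies: np.ndarray  # Hz, strictly increasing from 0
    amplitudes: np.ndarray   # nonnegative magnitudes, arbitrary units
    kind: str                # "one_over_f" | "speech_derived"
    n_points: int            # time-domain length the spectrum maps onto
    fs: float                # Hz
    exponent: float | None = None  # chi, present iff kind == "one_over_f"

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.amplitudes):
            raise ValueError("frequencies and amplitudes must have equal length")
        if np.any(self.amplitudes < 0):
            raise ValueError("modulation amplitudes must be nonnegative")


@dataclass(frozen=True)
class AMEnvelope:
    samples: np.ndarray
    fs: float
    seed: int
    depth: float = 1.0
    source_spectrum: ModulationSpectrum | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class ToneProbe:
    """Probe tone parameters; the waveform is reconstructible via probe_waveform."""

    frequency: float = 1000.0
    duration: float = 0.030
    onset: float = 0.0          # s within the stimulus
    snr_db: float = -10.0
    ramp: float = 0.010
    amplitude: float = 1.0      # peak gain applied to the unit sine

    def __post_init__(self) -> None:
        if self.ramp > self.duration / 2:
            raise ValueError("probe ramp must not exceed half the probe duration")


@dataclass(frozen=True)
class AMStimulus:
    waveform: np.ndarray
    fs: float
    am_type: str
    envelope: AMEnvelope
    noise_seed: int
    probe: ToneProbe | None = None
    masker: np.ndarray | None = None  # probe-free waveform, kept for local-SNR analysis

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.waveform**2)))

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.fs


@dataclass(frozen=True)
class StimulusSet:
    stimuli: list
    manifest: pd.DataFrame


@dataclass(frozen=True)
class ProbeConfig:
    frequency: float = 1000.0
    duration: float = 0.030
    snr_db: float = -10.0
    onset_lo: float = 0.75
    onset_hi: float = 4.25
    ramp: float = 0.010


@dataclass(frozen=True)
class StimulusConfig:
    fs: float = DEFAULT_FS
    duration_pre_trim: float = 10.0
    duration_final: float = 5.0
    exponents: tuple = DEFAULT_EXPONENTS
    include_speech: bool = True
    n_per_type: int = 60
    ramp_ms: float = 50.0
    target_rms: float = 0.05
    probe: ProbeConfig = field(default_factory=ProbeConfig)

    @property
    def am_types(self) -> list:
        types = [f"e{g:g}" for g in self.exponents]
        if self.include_speech:
            types.append("speech")
        return types

    @property
    def n_points(self) -> int:
        return int(round(self.duration_pre_trim * self.fs))


# ---------------------------------------------------------------------------
# modulation spectra
# ---------------------------------------------------------------------------

def make_modulation_spectrum(
    kind: str,
    exponent: float | None = None,
    reference_envelopes: Sequence[np.ndarray] | None = None,
    n_points: int = 200_000,
    fs: float = DEFAULT_FS,
) -> ModulationSpectrum:
    """Build the a-priori modulation amplitude spectrum.

    one_over_f : amplitude(f) = f**(-exponent) for f > 0; DC bin set to 0
    (the envelope mean is re-imposed later by depth normalization).

    speech_derived : pointwise mean of the rfft magnitudes of the supplied
    broadband envelopes, linearly resampled onto the target frequency grid.
    """
    freqs = np.fft.rfftfreq(n_points, 1.0 / fs)
    if kind == "one_over_f":
        if exponent is None or exponent < 0:
            raise ValueError("one_over_f spectra require exponent >= 0")
        amps = np.zeros_like(freqs)
        amps[1:] = freqs[1:] ** (-exponent)
        return ModulationSpectrum(freqs, amps, kind, n_points, fs, exponent=float(exponent))
    if kind == "speech_derived":
        if not reference_envelopes:
            raise ValueError("speech_derived spectra require at least one reference envelope")
        spectra = []
        for env in reference_envelopes:
            env = np.asarray(env, dtype=float)
            f_ref = np.fft.rfftfreq(len(env), 1.0 / fs)
            spectra.append((f_ref, np.abs(np.fft.rfft(env))))
        n_ref = len(spectra[0][0])
        if any(len(f) != n_ref for f, _ in spectra):
            raise ValueError("reference envelopes must share one length")
        f_ref = spectra[0][0]
        mean_mag = np.mean([m for _, m in spectra], axis=0)
        amps = np.interp(freqs, f_ref, mean_mag)
        amps[0] = 0.0
        return ModulationSpectrum(freqs, amps, kind, n_points, fs)
    raise ValueError(f"unknown spectrum kind: {kind!r}")


def make_speech_surrogate_envelopes(
    n_segments: int = 10,
    segment_duration: float = 60.0,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    peak_hz: float = 4.0,
    exponent: float = 1.5,
) -> list:
    """Synthetic stand-ins for broadband speech envelopes.

    Real connected speech has a low-pass modulation spectrum with a
    syllabic peak near 4 Hz riding on an approximately 1/f^1.5 trend.  Each
    surrogate is a random-phase realization of that analytic curve, shifted
    to be nonnegative so it is a valid amplitude envelope.
    """
    n = int(round(segment_duration * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amps = np.zeros_like(freqs)
    amps[1:] = freqs[1:] ** (-exponent)
    amps *= 1.0 + 3.0 * np.exp(-0.5 * ((freqs - peak_hz) / 1.5) ** 2)
    amps[0] = 0.0
    rng = np.random.default_rng(seed)
    envelopes = []
    for _ in range(n_segments):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
        spec = amps * np.exp(1j * phases)
        spec[0] = 0.0
        x = np.fft.irfft(spec, n=n)
        envelopes.append(x - x.min())
    return envelopes


# ---------------------------------------------------------------------------
# envelope synthesis
# ---------------------------------------------------------------------------

def synthesize_envelope(
    spectrum: ModulationSpectrum,
    seed: int,
    duration_final: float = 5.0,
    hp_hz: float = 1.0,
    lp_hz: float = 30.0,
) -> AMEnvelope:
    """Random-phase inverse-FFT envelope with Butterworth conditioning.

    Phases are uniform on [0, 2pi) per positive-frequency bin with conjugate
    symmetry (guaranteed by irfft).  The 10-s realization is high-pass
    (order 3) and low-pass (order 6) filtered forward-only, the middle
    ``duration_final`` seconds are kept, and the result is min/max
    normalized so depth is exactly 100%.
    """
    n = spectrum.n_points
    fs = spectrum.fs
    n_final = int(round(duration_final * fs))
    if n_final > n:
        raise ValueError("final duration exceeds the synthesis grid")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spectrum.frequencies))
    spec = spectrum.amplitudes * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)

    sos_hp = signal.butter(3, hp_hz, btype="highpass", fs=fs, output="sos")
    sos_lp = signal.butter(6, lp_hz, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfilt(sos_hp, x)
    x = signal.sosfilt(sos_lp, x)

    start = (n - n_final) // 2
    x = x[start : start + n_final]
    x = (x - x.min()) / (x.max() - x.min())
    return AMEnvelope(samples=x, fs=fs, seed=seed, depth=1.0, source_spectrum=spectrum)


# ---------------------------------------------------------------------------
# carrier modulation and probe tones
# ---------------------------------------------------------------------------

def _raised_cosine_ramps(n_samples: int, n_ramp: int) -> np.ndarray:
    """Unit gate with squared-sine on-ramp and squared-cosine off-ramp.

    Sample 0 and the final sample are exactly 0; both ramps are monotone.
    """
    gate = np.ones(n_samples)
    up = np.sin(0.5 * np.pi * np.arange(n_ramp) / n_ramp) ** 2
    down = np.cos(0.5 * np.pi * np.arange(1, n_ramp + 1) / n_ramp) ** 2
    down[-1] = 0.0  # cos(pi/2)**2 is ~1e-33, not exactly 0
    gate[:n_ramp] = up
    gate[-n_ramp:] = down
    return gate


def modulate_noise(
    envelope: AMEnvelope,
    noise_seed: int,
    am_type: str = "am",
    target_rms: float = 0.05,
    ramp_ms: float = 50.0,
) -> AMStimulus:
    """Multiply a fresh standard-normal carrier by the envelope, ramp, and calibrate RMS."""
    rng = np.random.default_rng(noise_seed)
    carrier = rng.standard_normal(len(envelope.samples))
    wave = carrier * envelope.samples
    n_ramp = int(round(ramp_ms / 1000.0 * envelope.fs))
    wave = wave * _raised_cosine_ramps(len(wave), n_ramp)
    rms = np.sqrt(np.mean(wave**2))
    if rms > 0:
        wave = wave * (target_rms / rms)
    return AMStimulus(
        waveform=wave, fs=envelope.fs, am_type=am_type,
        envelope=envelope, noise_seed=noise_seed, masker=wave,
    )


def probe_waveform(probe: ToneProbe, fs: float) -> np.ndarray:
    """Reconstruct the ramped probe tone (its own time base, onset not applied)."""
    n = int(round(probe.duration * fs))
    t = np.arange(n) / fs
    tone = np.sin(2.0 * np.pi * probe.frequency * t)
    n_ramp = int(round(probe.ramp * fs))
    tone *= _raised_cosine_ramps(n, n_ramp)
    return probe.amplitude * tone


def insert_tone(
    stimulus: AMStimulus,
    probe_seed: int,
    config: ProbeConfig | None = None,
) -> AMStimulus:
    """Sum a ramped 1-kHz probe onto the masker at a fixed global SNR.

    The SNR convention: mean-square of the tone over its own duration divided
    by the long-term mean-square of the full 5-s masker equals
    10**(snr_db / 10).  This makes the global SNR identical across stimuli
    regardless of where the probe lands.
    """
    if stimulus.probe is not None:
        raise ValueError("stimulus already carries a probe tone")
    cfg = config or ProbeConfig()
    rng = np.random.default_rng(probe_seed)
    onset = rng.uniform(cfg.onset_lo, cfg.onset_hi)
    probe = ToneProbe(
        frequency=cfg.frequency, duration=cfg.duration, onset=onset,
        snr_db=cfg.snr_db, ramp=cfg.ramp, amplitude=1.0,
    )
    unit = probe_waveform(probe, stimulus.fs)
    masker_ms = np.mean(stimulus.waveform**2)
    target_ms = masker_ms * 10.0 ** (cfg.snr_db / 10.0)
    gain = np.sqrt(target_ms / np.mean(unit**2))
    probe = replace(probe, amplitude=gain)

    wave = stimulus.waveform.copy()
    i0 = int(round(onset * stimulus.fs))
    wave[i0 : i0 + len(unit)] += gain * unit
    return replace(stimulus, waveform=wave, probe=probe, masker=stimulus.waveform)


# ---------------------------------------------------------------------------
# full stimulus set
# ---------------------------------------------------------------------------

def build_stimulus_set(
    config: StimulusConfig | None = None,
    master_seed: int = 0,
    speech_reference_envelopes: Sequence[np.ndarray] | None = None,
) -> StimulusSet:
    """Generate the full set: n_per_type stimuli per AM type, half with probes.

    Everything is a pure function of (config, master_seed): per-stimulus
    envelope, carrier and probe seeds are spawned from one SeedSequence, and
    probe assignment is drawn from the same stream.  For the speech type,
    reference envelopes default to the built-in speech surrogates.
    """
    cfg = config or StimulusConfig()
    root = np.random.SeedSequence(master_seed)
    spectra: dict = {}
    for chi in cfg.exponents:
        spectra[f"e{chi:g}"] = make_modulation_spectrum(
            "one_over_f", exponent=chi, n_points=cfg.n_points, fs=cfg.fs
        )
    if cfg.include_speech:
        refs = speech_reference_envelopes
        if refs is None:
            refs = make_speech_surrogate_envelopes(fs=cfg.fs, seed=master_seed)
        spectra["speech"] = make_modulation_spectrum(
            "speech_derived", reference_envelopes=refs, n_points=cfg.n_points, fs=cfg.fs
        )

    stimuli = []
    rows = []
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    for type_index, (am_type, spectrum) in enumerate(spectra.items()):
        child = np.random.SeedSequence(entropy=master_seed, spawn_key=(type_index + 1,))
        seeds = child.generate_state(3 * cfg.n_per_type, dtype=np.uint32)
        if len(np.unique(seeds)) != len(seeds):
            raise ValueError("duplicate per-stimulus seeds; choose another master_seed")
        probed = np.zeros(cfg.n_per_type, dtype=bool)
        probed[assign_rng.choice(cfg.n_per_type, cfg.n_per_type // 2, replace=False)] = True
        for i in range(cfg.n_per_type):
            env_seed, noise_seed, probe_seed = (int(s) for s in seeds[3 * i : 3 * i + 3])
            env = synthesize_envelope(spectrum, env_seed, duration_final=cfg.duration_final)
            stim = modulate_noise(
                env, noise_seed, am_type=am_type,
                target_rms=cfg.target_rms, ramp_ms=cfg.ramp_ms,
            )
            if probed[i]:
                stim = insert_tone(stim, probe_seed, cfg.probe)
            stimuli.append(stim)
            rows.append({
                "stimulus_id": f"{am_type}_{i:02d}",
                "am_type": am_type,
                "envelope_seed": env_seed,
                "noise_seed": noise_seed,
                "probe_onset_s": round(stim.probe.onset, 6) if stim.probe else np.nan,
                "snr_db": cfg.probe.snr_db if stim.probe else np.nan,
            })
    manifest = pd.DataFrame(rows)
    return StimulusSet(stimuli=stimuli, manifest=manifest)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stimulus_set(stimulus_set: StimulusSet, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stim, (_, row) in zip(stimulus_set.stimuli, stimulus_set.manifest.iterrows()):
        tag = "tone" if stim.probe is not None else "notone"
        idx = row["stimulus_id"].rsplit("_", 1)[1]
        name = f"{stim.am_type}_{idx}_{tag}.wav"
        wavfile.write(out / name, int(stim.fs), stim.waveform.astype(np.float32))
    manifest_path = out / "manifest.tsv"
    stimulus_set.manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
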