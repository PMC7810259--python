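"""Ridge-regression temporal response functions (TRFs) and cross-encoding.

A TRF is a lag-resolved linear kernel mapping a stimulus amplitude envelope
to a neural response: response(t) = sum_lag kernel(lag) * envelope(t - lag).
Kernels are estimated by ridge regression on a lagged (Toeplitz-style)
design matrix, with the ridge parameter lambda selected by cross-validation
(leave-one-out over trials for AM stimuli, 10-fold over segments for
continuous speech).  Prediction accuracy is the Pearson correlation between
predicted and observed responses, Fisher z-transformed before any
averaging.  Cross-encoding applies the TRF (and lambda) trained on one
stimulus class to responses from another class, yielding a train x test
matrix whose diagonal is own-class leave-one-out performance.

Conventions (applied identically at training and scoring time): envelopes
are z-scored per trial, responses are centered per trial, and the intercept
column is unpenalized.  Trials are never concatenated; each trial's design
is zero-padded at its own edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import fisher_z
from .eeg import NEURAL_BANDS, bandpass_filter

__all__ = [
    "TRFModel",
    "EncodingResult",
    "CrossEncodingMatrix",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_WORKING_FS",
    "lag_grid",
    "lagged_design",
    "fit_trf",
    "predict_score",
    "train_with_cv",
    "cross_encode",
    "modulation_band_encode",
    "matched_band_summary",
    "resample_to",
    "standardize_trial",
]

#: log-spaced ridge-parameter grid, 1e-2 .. 1e6
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2, 6, 17))
#: working sample rate for TRF fitting (envelope content is <= 45 Hz)
DEFAULT_WORKING_FS = 128.0


@dataclass(frozen=True)
class TRFModel:
    kernel: np.ndarray        # weight per lag
    intercept: float
    lam: float                # ridge parameter, >= 0
    lags: np.ndarray          # lag positions in samples
    fs: float                 # working sample rate, Hz
    stim_band: str = "broadband"
    neural_band: str = "full"
    train_label: str = ""

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags / self.fs * 1000.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("ridge parameter must be >= 0")
        if len(self.kernel) != len(self.lags):
            raise ValueError("kernel length must equal the number of lags")


@dataclass(frozen=True)
class EncodingResult:
    z: float            # Fisher-z prediction accuracy
    n: int              # folds or trials entering the mean
    lambda_used: float


@dataclass(frozen=True)
class CrossEncodingMatrix:
    values: pd.DataFrame  # train labels (rows) x test labels (columns), mean z
    neural_band: str = "full"

    def diagonal(self) -> pd.Series:
        common = [l for l in self.values.index if l in self.values.columns]
        return pd.Series({l: self.values.loc[l, l] for l in common})


# ---------------------------------------------------------------------------
# design matrices and the ridge solution
# ---------------------------------------------------------------------------

def lag_grid(tmin_ms: float, tmax_ms: float, fs: float) -> np.ndarray:
    """Integer sample lags covering [tmin_ms, tmax_ms] at rate fs."""
    lo = int(round(tmin_ms / 1000.0 * fs))
    hi = int(round(tmax_ms / 1000.0 * fs))
    if hi < lo:
        raise ValueError("tmax_ms must be >= tmin_ms")
    return np.arange(lo, hi + 1)


def lagged_design(envelope: np.ndarray, lags: np.ndarray,
                  intercept: bool = True) -> np.ndarray:
    """Time x lags design matrix; row t holds envelope(t - lag), zero-padded.

    A leading all-ones intercept column is prepended when ``intercept``.
    """
    x = np.asarray(envelope, dtype=float)
    lags = np.asarray(lags, dtype=int)
    n = len(x)
    cols = np.zeros((n, len(lags)))
    for j, lag in enumerate(lags):
        if lag >= 0:
            if lag < n:
                cols[lag:, j] = x[: n - lag]
        else:
            if -lag < n:
                cols[: n + lag, j] = x[-lag:]
    if intercept:
        return np.column_stack([np.ones(n), cols])
    return cols


def fit_trf(
    design: np.ndarray,
    response: np.ndarray,
    lam: float,
    lags: np.ndarray | None = None,
    fs: float = DEFAULT_WORKING_FS,
    intercept: bool = True,
    **labels,
) -> TRFModel:
    """Ridge solution (X'X + lam*M)^-1 X'y with the intercept unpenalized.

    M is the identity with a zero at the intercept position.  With lam = 0 a
    singular Gram matrix raises, advising lam > 0.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if lam < 0:
        raise ValueError("ridge parameter must be >= 0")
    g = x.T @ x
    m = np.eye(g.shape[0])
    if intercept:
        m[0, 0] = 0.0
    try:
        coef = np.linalg.solve(g + lam * m, x.T @ y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular normal equations; use lam > 0"
        ) from err
    if intercept:
        b0, kernel = float(coef[0]), coef[1:]
    else:
        b0, kernel = 0.0, coef
    if lags is None:
        lags = np.arange(len(kernel))
    return TRFModel(kernel=kernel, intercept=b0, lam=float(lam),
                    lags=np.asarray(lags, dtype=int), fs=fs, **labels)


def standardize_trial(envelope: np.ndarray,
                      response: np.ndarray) -> tuple:
    """Per-trial convention: z-score the envelope, center the response."""
    e = np.asarray(envelope, dtype=float)
    r = np.asarray(response, dtype=float)
    sd = e.std()
    if sd == 0:
        raise ValueError("constant envelope cannot be standardized")
    return (e - e.mean()) / sd, r - r.mean()


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling along the last axis."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=float)
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def _predict(model: TRFModel, envelope_std: np.ndarray) -> np.ndarray:
    design = lagged_design(envelope_std, model.lags, intercept=False)
    return model.intercept + design @ model.kernel


def predict_score(model: TRFModel, envelope: np.ndarray,
                  response: np.ndarray) -> EncodingResult:
    """Fisher-z Pearson correlation between predicted and observed response."""
    e, r = standardize_trial(envelope, response)
    pred = _predict(model, e)
    if pred.std() == 0 or r.std() == 0:
        raise ValueError("constant predicted or observed series")
    rho = float(np.corrcoef(pred, r)[0, 1])
    return EncodingResult(z=fisher_z(rho), n=1, lambda_used=model.lam)


# ---------------------------------------------------------------------------
# cross-validated training
# ---------------------------------------------------------------------------

def _prepare(trials: Sequence, lags: np.ndarray) -> tuple:
    """Standardize trials, build per-trial designs and Gram/cross terms."""
    designs, resps, grams, crosses = [], [], [], []
    for env, resp in trials:
        e, r = standardize_trial(env, resp)
        x = lagged_design(e, lags, intercept=True)
        designs.append(x)
        resps.append(r)
        grams.append(x.T @ x)
        crosses.append(x.T @ r)
    return designs, resps, np.array(grams), np.array(crosses)


def _solve(g: np.ndarray, c: np.ndarray, lam: float) -> np.ndarray:
    m = np.eye(g.shape[0])
    m[0, 0] = 0.0
    return np.linalg.solve(g + lam * m, c)


def train_with_cv(
    trials: Sequence,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    scheme: str = "loo",
    lags: np.ndarray | None = None,
    fs: float = DEFAULT_WORKING_FS,
    **labels,
) -> tuple:
    """Select lambda by cross-validation, refit on all trials, report held-out z.

    trials: sequence of (envelope, response) pairs at rate ``fs``.
    scheme: "loo" (one fold per trial) or "kfold10" (ten contiguous folds).
    Returns (TRFModel refit at the optimal lambda, EncodingResult whose z is
    the mean held-out Fisher-z at that lambda).
    """
    if len(lambda_grid) == 0:
        raise ValueError("empty lambda grid")
    if len(trials) < 2:
        raise ValueError("need at least 2 trials or segments")
    if lags is None:
        lags = lag_grid(0.0, 500.0, fs)
    if scheme == "loo":
        folds = [[i] for i in range(len(trials))]
    elif scheme == "kfold10":
        folds = [list(f) for f in np.array_split(np.arange(len(trials)), 10) if len(f)]
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")

    designs, resps, grams, crosses = _prepare(trials, lags)
    g_tot, c_tot = grams.sum(axis=0), crosses.sum(axis=0)

    mean_z = np.empty(len(lambda_grid))
    for li, lam in enumerate(lambda_grid):
        zs = []
        for fold in folds:
            g_train = g_tot - grams[fold].sum(axis=0)
            c_train = c_tot - crosses[fold].sum(axis=0)
            coef = _solve(g_train, c_train, lam)
            for i in fold:
                pred = designs[i] @ coef
                if pred.std() == 0 or resps[i].std() == 0:
                    continue
                zs.append(fisher_z(float(np.corrcoef(pred, resps[i])[0, 1])))
        mean_z[li] = np.mean(zs) if zs else -np.inf
    best = int(np.argmax(mean_z))
    lam = float(lambda_grid[best])
    coef = _solve(g_tot, c_tot, lam)
    model = TRFModel(kernel=coef[1:], intercept=float(coef[0]), lam=lam,
                     lags=lags, fs=fs, **labels)
    return model, EncodingResult(z=float(mean_z[best]), n=len(folds), lambda_used=lam)


# ---------------------------------------------------------------------------
# cross-encoding
# ---------------------------------------------------------------------------

def cross_encode(
    models: Mapping[str, TRFModel],
    test_sets: Mapping[str, Sequence],
    own_performance: Mapping[str, float] | None = None,
    neural_band: str = "full",
) -> CrossEncodingMatrix:
    """Score every trained TRF against every test set; mean z per cell.

    ``own_performance`` (label -> held-out z from train_with_cv) overrides the
    diagonal so it reports cross-validated rather than resubstitution
    accuracy, matching how the matrix is constructed in practice.
    """
    if not models or not test_sets:
        raise ValueError("models and test_sets must both be non-empty")
    train_labels = list(models)
    test_labels = list(test_sets)
    values = pd.DataFrame(index=train_labels, columns=test_labels, dtype=float)
    for tr in train_labels:
        model = models[tr]
        for te in test_labels:
            if tr == te and own_performance is not None and tr in own_performance:
                values.loc[tr, te] = own_performance[tr]
                continue
            trials = test_sets[te]
            if len(trials) == 0:
                raise ValueError(f"empty test set for label {te!r}")
            zs = [predict_score(model, env, resp).z for env, resp in trials]
            values.loc[tr, te] = float(np.mean(zs))
    return CrossEncodingMatrix(values=values, neural_band=neural_band)


# ---------------------------------------------------------------------------
# modulation-band x neural-band encoding
# ---------------------------------------------------------------------------

def default_modulation_bands(lo: float = 1.0, hi: float = 45.0,
                             step: float = 2.0) -> list:
    """Contiguous 2-Hz-wide modulation bands spanning 1-45 Hz (22 bands)."""
    edges = np.arange(lo, hi + 1e-9, step)
    return [(float(a), float(a + step)) for a in edges[:-1]]


def modulation_band_encode(
    trials: Sequence,
    fs: float = DEFAULT_WORKING_FS,
    neural_bands: Mapping[str, tuple] | None = None,
    mod_bands: Sequence[tuple] | None = None,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    scheme: str = "loo",
    lags: np.ndarray | None = None,
) -> pd.DataFrame:
    """Encoding accuracy for every (modulation band, neural band) pair.

    Envelopes are band-passed (Butterworth order 2, two-pass) into each
    modulation band and responses into each neural band (order 4, two-pass);
    train_with_cv runs per pair.  Cells whose filtered envelope is
    numerically constant are left NaN.  Rows are labeled by modulation-band
    center frequency (Hz), columns by neural-band name.
    """
    if neural_bands is None:
        neural_bands = {k: v for k, v in NEURAL_BANDS.items() if k != "full"}
    if mod_bands is None:
        mod_bands = default_modulation_bands()
    nyq = fs / 2.0
    for lo, hi in mod_bands:
        if hi >= nyq:
            raise ValueError(f"modulation band {lo}-{hi} Hz above Nyquist {nyq} Hz")
    centers = [0.5 * (lo + hi) for lo, hi in mod_bands]
    grid = pd.DataFrame(index=pd.Index(centers, name="mod_band_hz"),
                        columns=list(neural_bands), dtype=float)
    envs = [np.asarray(e, dtype=float) for e, _ in trials]
    resps = [np.asarray(r, dtype=float) for _, r in trials]
    for nb_name, (nlo, nhi) in neural_bands.items():
        resp_f = [bandpass_filter(r, nlo, nhi, fs, order=4) for r in resps]
        for center, (mlo, mhi) in zip(centers, mod_bands):
            env_f = [bandpass_filter(e, mlo, mhi, fs, order=2) for e in envs]
            if all(f.std() < 1e-3 * e.std() for f, e in zip(env_f, envs)):
                continue  # band outside the stimulus content: cell stays NaN
            try:
                _, result = train_with_cv(
                    list(zip(env_f, resp_f)), lambda_grid=lambda_grid,
                    scheme=scheme, lags=lags, fs=fs,
                )
            except ValueError:
                continue  # degenerate (zero-variance) band: cell stays NaN
            grid.loc[center, nb_name] = result.z
    return grid


def matched_band_summary(grid: pd.DataFrame,
                         neural_bands: Mapping[str, tuple] | None = None,
                         band_halfwidth: float = 1.0) -> pd.Series:
    """Average each neural band's column over its frequency-matched modulation bands."""
    if neural_bands is None:
        neural_bands = {k: v for k, v in NEURAL_BANDS.items() if k != "full"}
    out = {}
    for name, (lo, hi) in neural_bands.items():
        centers = grid.index.to_numpy(dtype=float)
        overlap = (centers + band_halfwidth > lo) & (centers - band_halfwidth < hi)
        out[name] = float(grid.loc[overlap, name].mean())
    return pd.Series(out, name="matched_band_z")
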