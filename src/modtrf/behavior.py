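"""Tone-detection sensitivity (d') and its correlation with local SNR.

Each AM type yields a 2x2 confusion table over 60 trials (30 with the probe
tone, 30 without).  Sensitivity is d' = Phi^-1(hit rate) - Phi^-1(false-alarm
rate).  A table in which every trial is correct gets half an artificial
incorrect trial added to both error cells so the rates stay off 0 and 1.
Correlations between d' and local SNR across AM types are Fisher
z-transformed per participant before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DPrimeResult",
    "dprime_from_responses",
    "dprime_table",
    "snr_behavior_correlation",
    "fisher_z",
]

_Z_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class DPrimeResult:
    am_type: str
    hits: float
    misses: float
    false_alarms: float
    correct_rejections: float
    dprime: float


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """atanh with |r| clipped just below 1 (warns when clipping engages)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| = 1 clipped before Fisher z-transform", stacklevel=2)
    out = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
    return float(out) if out.ndim == 0 else out


def dprime_from_responses(responses: pd.DataFrame, am_type: str = "",
                          correction: str = "perfect_table") -> DPrimeResult:
    """d' from a trial table with boolean columns tone_present / reported_tone.

    correction="perfect_table" (default): the half-trial correction applies
    only to fully perfect tables (zero misses AND zero false alarms); a table
    perfect on one margin only raises, since its rate of 0 or 1 leaves d'
    undefined.  correction="per_cell": any empty error cell gets the half
    trial, so d' is always finite (the convention the synthetic observer
    pipeline uses, where single-margin-perfect tables do occur).
    """
    if correction not in ("perfect_table", "per_cell"):
        raise ValueError(f"unknown correction: {correction!r}")
    tp = responses["tone_present"].to_numpy(dtype=bool)
    rep = responses["reported_tone"].to_numpy(dtype=bool)
    n_target = int(tp.sum())
    n_noise = int((~tp).sum())
    if n_target < 1 or n_noise < 1:
        raise ValueError("need at least one target and one noise trial")
    hits = float(np.sum(tp & rep))
    misses = float(np.sum(tp & ~rep))
    fas = float(np.sum(~tp & rep))
    crs = float(np.sum(~tp & ~rep))
    perfect_table = misses == 0 and fas == 0
    if perfect_table or (correction == "per_cell" and misses == 0):
        misses, hits = 0.5, n_target - 0.5
    if perfect_table or (correction == "per_cell" and fas == 0):
        fas, crs = 0.5, n_noise - 0.5
    if correction == "per_cell":  # empty correct cells break rates symmetrically
        if hits == 0:
            hits, misses = 0.5, n_target - 0.5
        if crs == 0:
            crs, fas = 0.5, n_noise - 0.5
    hit_rate = hits / n_target
    fa_rate = fas / n_noise
    if hit_rate in (0.0, 1.0) or fa_rate in (0.0, 1.0):
        raise ValueError("degenerate hit or false-alarm rate")
    d = float(norm.ppf(hit_rate) - norm.ppf(fa_rate))
    return DPrimeResult(am_type=am_type, hits=hits, misses=misses,
                        false_alarms=fas, correct_rejections=crs, dprime=d)


def dprime_table(trials: pd.DataFrame,
                 correction: str = "perfect_table") -> pd.DataFrame:
    """Per-participant, per-AM-type d' from a long trial table."""
    rows = []
    for (pid, am_type), grp in trials.groupby(["participant_id", "am_type"]):
        res = dprime_from_responses(grp, am_type=am_type, correction=correction)
        rows.append({"participant_id": pid, "am_type": am_type, "dprime": res.dprime})
    return pd.DataFrame(rows)


def snr_behavior_correlation(
    dprimes: pd.DataFrame,
    snr_by_type: pd.DataFrame,
) -> pd.DataFrame:
    """Fisher-z Pearson correlation between d' and local SNR across AM types.

    dprimes: wide table, participants x am_type.
    snr_by_type: am_type x window-size (ms) mean local SNR over probed stimuli.
    Returns per-window mean z across participants plus the per-participant z.
    """
    types = [t for t in snr_by_type.index if t in dprimes.columns]
    if len(types) < 3:
        raise ValueError("need at least 3 AM types shared between tables")
    d = dprimes[types].to_numpy(dtype=float)
    rows = []
    for w in snr_by_type.columns:
        s = snr_by_type.loc[types, w].to_numpy(dtype=float)
        if np.std(s) == 0:
            raise ValueError(f"zero SNR variance at window {w}")
        for i, pid in enumerate(dprimes.index):
            if np.std(d[i]) == 0:
                raise ValueError(f"zero d' variance for participant {pid}")
            r = float(np.corrcoef(d[i], s)[0, 1])
            rows.append({"participant_id": pid, "window_ms": w, "z": fisher_z(r)})
    per_part = pd.DataFrame(rows)
    mean_z = per_part.groupby("window_ms", sort=False)["z"].mean().rename("mean_z")
    return per_part.merge(mean_z, on="window_ms")
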