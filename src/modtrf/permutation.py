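"""Label-shuffling permutation thresholds for condition-labeled group statistics.

Condition labels are permuted independently within each participant; each
permutation is summarized either as the mean over cells of per-cell medians
across participants (one global threshold) or as per-cell means across
participants (one threshold per cell).  One-sided thresholds are the
ceil((1 - alpha) * n_perm)-th order statistics of the permutation
distribution — conservative and exact for n_perm = 1000.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PermutationNull", "permutation_threshold"]


@dataclass(frozen=True)
class PermutationNull:
    thresholds: dict        # alpha -> scalar (median_summary) or per-cell array
    observed: np.ndarray    # per-cell observed summary statistic
    flags: dict             # alpha -> boolean per-cell exceedance
    n_perm: int
    scheme: str
    cell_labels: tuple


def _order_statistic(sorted_draws: np.ndarray, alpha: float, n_perm: int) -> np.ndarray:
    k = math.ceil((1.0 - alpha) * n_perm)  # 1-indexed order statistic
    return sorted_draws[..., k - 1]


def permutation_threshold(
    data: np.ndarray,
    scheme: str = "median_summary",
    n_perm: int = 1000,
    alphas: Sequence[float] = (0.05, 0.01),
    seed: int = 0,
    cell_labels: Sequence | None = None,
) -> PermutationNull:
    """One-sided permutation thresholds from a participants x cells matrix.

    median_summary: each permutation's statistic is the mean over cells of the
    per-cell median across participants; observed per-cell statistics (medians
    across participants) are compared against the single global threshold.

    mean_summary: each permutation yields per-cell means across participants;
    each cell gets thresholds from its own permutation distribution.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("data must be participants x cells with at least 2 of each")
    for a in alphas:
        if not (0.0 < a < 0.5):
            raise ValueError(f"alpha {a} outside (0, 0.5)")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse thresholds", stacklevel=2)
    n_part, n_cells = data.shape
    labels = tuple(cell_labels) if cell_labels is not None else tuple(range(n_cells))
    if len(labels) != n_cells:
        raise ValueError("cell_labels length mismatch")

    rng = np.random.default_rng(seed)
    # independent within-participant shuffles, vectorized via random-key argsort
    keys = rng.random((n_perm, n_part, n_cells))
    idx = np.argsort(keys, axis=-1)
    permuted = np.take_along_axis(np.broadcast_to(data, keys.shape), idx, axis=-1)

    if scheme == "median_summary":
        draws = np.median(permuted, axis=1).mean(axis=1)     # (n_perm,)
        draws_sorted = np.sort(draws)
        observed = np.median(data, axis=0)
        thresholds = {a: float(_order_statistic(draws_sorted, a, n_perm)) for a in alphas}
        flags = {a: observed > thresholds[a] for a in alphas}
    elif scheme == "mean_summary":
        draws = permuted.mean(axis=1)                         # (n_perm, n_cells)
        draws_sorted = np.sort(draws, axis=0)
        observed = data.mean(axis=0)
        thresholds = {a: _order_statistic(draws_sorted.T, a, n_perm) for a in alphas}
        flags = {a: observed > thresholds[a] for a in alphas}
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")
    return PermutationNull(thresholds=thresholds, observed=observed, flags=flags,
                           n_perm=n_perm, scheme=scheme, cell_labels=labels)
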