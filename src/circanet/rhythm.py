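"""Nonparametric circadian rhythmicity detection (JTK-style scan).

Each gene's time course is compared against a bank of cosine references —
every (period, phase) combination on a grid — via Kendall's tau-b; the
scan statistic is the maximum tau over the bank.  Because the maximum
over many correlated references is not Kendall-distributed, significance
is calibrated against a seeded Monte-Carlo null: random permutations of
the time-course ranks are pushed through the identical scan, and p is the
empirical upper-tail probability of the observed max tau.  This keeps the
null p-value distribution uniform, which a per-reference Kendall tail on
the maximum would not.  q-values are Benjamini–Hochberg across genes.

Being rank-based, the scan is invariant to strictly increasing affine
transforms of each series.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["jtk_scan", "classify_circadian"]


def _pair_signs(values: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Sign of all pairwise differences along the last axis (tau-b kernel)."""
    return np.sign(values[..., j] - values[..., i])


def _reference_bank(
    timepoints: np.ndarray, periods: Sequence[float], phase_step: float
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    refs, meta = [], []
    for period in periods:
        for phase in np.arange(0.0, period, phase_step):
            refs.append(np.cos(2.0 * np.pi * (timepoints - phase) / period))
            meta.append((float(period), float(phase)))
    return np.asarray(refs), meta


def _max_tau(sign_rows: np.ndarray, ref_signs: np.ndarray, ref_nz: np.ndarray):
    """Best tau-b and its reference index for each row of pair signs."""
    S = sign_rows @ ref_signs.T  # concordant minus discordant
    x_nz = (sign_rows != 0).sum(axis=1)
    denom = np.sqrt(np.outer(x_nz, ref_nz))
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(denom > 0, S / denom, np.nan)
    best = np.nanargmax(tau, axis=1)
    return tau[np.arange(tau.shape[0]), best], best


def jtk_scan(
    table: pd.DataFrame,
    periods: Iterable[float] = range(20, 29),
    phase_step: float | None = None,
    n_null: int = 2000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Scan a genes x timepoints table for rhythmicity.

    Columns must be numeric hours.  Returns one row per gene with the
    calibrated p, BH q, best period and phase (hours), the best tau, and
    a ``constant`` flag (constant series get tau undefined and p = 1).

    The default period grid 20–28 h (1 h step) brackets the circadian
    band; the default phase step is the sampling interval.
    """
    timepoints = np.asarray([float(c) for c in table.columns])
    n = timepoints.size
    if n < 8:
        raise ValueError("rhythm scan needs >= 8 timepoints")
    if np.any(np.diff(timepoints) <= 0):
        raise ValueError("timepoint columns must be strictly increasing")
    periods = [float(p) for p in periods]
    span = timepoints[-1] - timepoints[0]
    if max(periods) > span:
        logger.warning("longest scanned period %.1f h exceeds data span %.1f h",
                       max(periods), span)
    if phase_step is None:
        phase_step = float(np.median(np.diff(timepoints)))

    i, j = np.triu_indices(n, k=1)
    refs, meta = _reference_bank(timepoints, periods, phase_step)
    ref_signs = _pair_signs(refs, i, j)
    ref_nz = (ref_signs != 0).sum(axis=1)

    values = table.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        logger.warning("%d constant series: tau undefined, p set to 1", int(constant.sum()))

    genes = list(table.index)
    tau = np.full(len(genes), np.nan)
    best_idx = np.zeros(len(genes), dtype=int)
    active = ~constant
    if active.any():
        sign_rows = _pair_signs(values[active], i, j)
        tau[active], best_idx[active] = _max_tau(sign_rows, ref_signs, ref_nz)

    # Monte-Carlo null of the max-tau statistic, shared across genes
    rng = np.random.default_rng(rng_seed)
    perms = np.argsort(rng.random((n_null, n)), axis=1).astype(float)
    null_tau, _ = _max_tau(_pair_signs(perms, i, j), ref_signs, ref_nz)

    p = np.ones(len(genes))
    if active.any():
        obs = tau[active]
        exceed = (null_tau[None, :] >= obs[:, None] - 1e-12).sum(axis=1)
        p[active] = (1.0 + exceed) / (n_null + 1.0)
    q = bh_fdr(p)

    period = np.array([meta[k][0] for k in best_idx])
    phase = np.array([meta[k][1] for k in best_idx])
    period[constant] = np.nan
    phase[constant] = np.nan
    return pd.DataFrame(
        {
            "gene": genes,
            "p": p,
            "q": q,
            "period": period,
            "phase": phase,
            "tau": tau,
            "constant": constant,
        }
    ).set_index("gene")


def classify_circadian(
    calls: pd.DataFrame, alphas: Iterable[float] = (0.009, 0.05), on: str = "p"
) -> pd.DataFrame:
    """Boolean rhythmicity flags at each significance level.

    ``on`` selects the thresholded column ('p' or 'q'): published
    circadian gene lists mix both policies, so both columns are always
    present in the calls and either can be flagged.
    """
    if on not in ("p", "q"):
        raise ValueError("on must be 'p' or 'q'")
    out = pd.DataFrame(index=calls.index)
    for a in alphas:
        if not (0.0 <= a <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        out[f"{on}<{a:g}"] = calls[on] <= a
    return out
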