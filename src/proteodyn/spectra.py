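"""Spectral read-outs: periodogram PSDs, alpha-band metrics, lobe aggregates.

The retained excitatory signals are turned into one-sided periodogram power
spectral densities (rectangular window, density scaling, so the frequency
grid spacing is 1/retained-duration — 0.1 Hz for a 10 s window).  Alpha-band
metrics are the trapezoidal band integral of the PSD over 8-12 Hz and the
grid frequency of maximal PSD in that band (ties broken toward the lowest
frequency).  Aggregation mirrors the reporting convention of the simulated
E/MEG figures: node -> lobe means first, then mean/std across realizations,
with the single-node brain-stem excluded from lobe rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .connectome import BRAIN_STEM_LOBE, Connectome
from .errors import ValidationError
from .neural_dynamics import TimeSeriesSet

ALPHA_BAND = (8.0, 12.0)


@dataclass
class Spectrum:
    """One-sided PSD per node on a uniform frequency grid (Hz, signal^2/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray  # (n_freqs, n_nodes)

    def __post_init__(self) -> None:
        if self.freqs.size != self.psd.shape[0]:
            raise ValidationError("frequency grid and PSD disagree")
        if np.any(self.psd < 0):
            raise ValidationError("PSD must be nonnegative")


@dataclass
class AlphaMetrics:
    """Per-node alpha-band power (integral of PSD) and peak frequency (Hz)."""

    band_power: np.ndarray
    peak_freq: np.ndarray


def periodogram_psd(ts: TimeSeriesSet) -> Spectrum:
    """Standard one-sided periodogram (rectangular window, density scaling)."""
    if ts.t.size < 2:
        raise ValidationError("need at least two samples")
    freqs, psd = periodogram(
        ts.x, fs=ts.fs, window="boxcar", scaling="density", axis=0, detrend=False
    )
    return Spectrum(freqs, np.atleast_2d(psd.T).T if psd.ndim == 1 else psd)


def alpha_metrics(sp: Spectrum, band: tuple[float, float] = ALPHA_BAND) -> AlphaMetrics:
    """Band power (trapezoid over grid points inside the band) and peak frequency."""
    lo, hi = band
    if sp.freqs[0] > lo or sp.freqs[-1] < hi:
        raise ValidationError(f"frequency grid does not cover the {lo}-{hi} Hz band")
    mask = (sp.freqs >= lo) & (sp.freqs <= hi)
    if mask.sum() < 2:
        raise ValidationError("frequency grid too coarse to resolve the band")
    f = sp.freqs[mask]
    p = sp.psd[mask]
    power = np.trapezoid(p, f, axis=0)
    peak = f[np.argmax(p, axis=0)]  # argmax returns the first (lowest-f) maximum
    return AlphaMetrics(band_power=power, peak_freq=peak)


def aggregate_by_lobe(
    metrics: Sequence[AlphaMetrics], c: Connectome
) -> pd.DataFrame:
    """Mean/std over realizations of lobe-mean alpha metrics.

    Rows: one per lobe (brain-stem excluded) plus a ``global`` row over all
    non-brain-stem nodes.  Columns: power_mean, power_std, peak_mean,
    peak_std, and the bandwidth-normalized power_density_mean.
    """
    if len(metrics) == 0:
        raise ValidationError("need at least one realization")
    lobes = c.lobes
    groups = {
        lobe: np.nonzero(lobes == lobe)[0]
        for lobe in sorted(set(lobes) - {BRAIN_STEM_LOBE})
    }
    groups["global"] = np.nonzero(lobes != BRAIN_STEM_LOBE)[0]
    bandwidth = ALPHA_BAND[1] - ALPHA_BAND[0]

    rows = []
    for lobe, idx in groups.items():
        powers = np.array([m.band_power[idx].mean() for m in metrics])
        peaks = np.array([m.peak_freq[idx].mean() for m in metrics])
        rows.append(
            {
                "lobe": lobe,
                "power_mean": powers.mean(),
                "power_std": powers.std(ddof=0),
                "power_density_mean": powers.mean() / bandwidth,
                "peak_mean": peaks.mean(),
                "peak_std": peaks.std(ddof=0),
            }
        )
    return pd.DataFrame(rows)
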