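"""Spectral preprocessing: raw intensity scans -> smoothed absorbance matrix.

The fixed pipeline order is block_average -> to_absorbance -> moving_average
-> (snv, for the monitoring branch only) -> mean_center.  Ten one-second
intensity scans are averaged into one spectrum (one per ~10 s), converted to
absorbance against the bright/dark references, then smoothed with a causal
75-spectrum moving mean; the first 74 outputs use an expanding window and are
flagged as warm-up.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .types import SpectraSeries

logger = logging.getLogger(__name__)

__all__ = ["block_average", "to_absorbance", "moving_average", "snv", "mean_center",
           "preprocess_pipeline"]

_TRANSMITTANCE_FLOOR = 1.0e-6


def block_average(raw: SpectraSeries, block: int = 10) -> SpectraSeries:
    """Average non-overlapping blocks of ``block`` consecutive intensity scans.

    The output timestamp is the mean of the block's timestamps; a trailing
    partial block is dropped.
    """
    if raw.kind != "intensity":
        raise ValueError("block_average expects intensity spectra")
    if block < 1:
        raise ValueError("block must be >= 1")
    n = raw.n_scans
    if n < block:
        raise ValueError(f"need at least {block} scans, got {n}")
    m = n // block
    vals = raw.values[: m * block].reshape(m, block, -1).mean(axis=1)
    ts = raw.timestamps[: m * block].reshape(m, block).mean(axis=1)
    return raw.copy_with(values=vals, timestamps=ts,
                         meta={**raw.meta, "block": block})


def to_absorbance(avg: SpectraSeries) -> SpectraSeries:
    """Convert intensity to absorbance, A = -log10((I - dark)/(bright - dark)).

    Non-physical transmittances (I <= dark) are clipped at 1e-6 and counted in
    the output metadata rather than silently dropped.
    """
    if avg.kind != "intensity":
        raise ValueError("to_absorbance expects intensity spectra")
    span = avg.bright_ref - avg.dark_ref
    trans = (avg.values - avg.dark_ref) / span
    n_clip = int(np.sum(trans <= _TRANSMITTANCE_FLOOR))
    if n_clip:
        logger.warning("clipped %d non-physical transmittance values", n_clip)
    trans = np.maximum(trans, _TRANSMITTANCE_FLOOR)
    a = -np.log10(trans)
    return avg.copy_with(values=a, kind="absorbance",
                         meta={**avg.meta, "clipped_transmittance": n_clip})


def moving_average(series: SpectraSeries, window: int = 75) -> SpectraSeries:
    """Causal moving mean over the current and ``window - 1`` prior spectra.

    During warm-up (the first ``window - 1`` outputs) the window expands from
    1 to ``window`` so the series keeps its length; those rows are flagged in
    ``meta['warmup_scans']``.
    """
    if series.kind != "absorbance":
        raise ValueError("moving_average expects absorbance spectra")
    if window < 1:
        raise ValueError("window must be >= 1")
    x = series.values
    csum = np.cumsum(x, axis=0)
    n = x.shape[0]
    out = np.empty_like(x)
    k = min(window, n)
    idx = np.arange(n)
    counts = np.minimum(idx + 1, window).astype(float)
    out[:k] = csum[:k] / counts[:k, None]
    if n > window:
        out[window:] = (csum[window:] - csum[:-window]) / window
    return series.copy_with(values=out,
                            meta={**series.meta, "window": window,
                                  "warmup_scans": min(window - 1, n)})


def snv(series: SpectraSeries) -> SpectraSeries:
    """Standard normal variate: centre and unit-scale each spectrum across wavelengths.

    Removes per-spectrum multiplicative scatter and additive offsets; used for
    the monitoring (MSPC) branch only.
    """
    if series.kind != "absorbance":
        raise ValueError("snv expects absorbance spectra")
    x = series.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0.0)
    if zero.size:
        raise ValueError(f"zero-variance spectrum at row(s) {zero[:5].tolist()}")
    return series.copy_with(values=(x - mu) / sd,
                            meta={**series.meta, "snv": True})


def mean_center(x: np.ndarray, mean: Optional[np.ndarray] = None):
    """Subtract the column mean; returns ``(centred, mean_used)``.

    When ``mean`` is supplied (prediction time) it is applied as-is so new
    spectra are centred identically to the training set.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if mean is None:
        mean = x.mean(axis=0)
    else:
        mean = np.asarray(mean, dtype=float)
        if mean.size != x.shape[1]:
            raise ValueError(
                f"mean length {mean.size} does not match {x.shape[1]} columns"
            )
    return x - mean, mean


def preprocess_pipeline(
    raw: SpectraSeries,
    block: int = 10,
    window: int = 75,
    apply_snv: bool = False,
) -> SpectraSeries:
    """The full fixed-order preprocessing chain (without mean-centring).

    Mean-centring is left to the model-fitting stage, which must store the
    training mean to centre prediction-time spectra identically.
    """
    out = block_average(raw, block)
    out = to_absorbance(out)
    out = moving_average(out, window)
    if apply_snv:
        out = snv(out)
    return out
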