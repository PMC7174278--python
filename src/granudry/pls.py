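"""PLS1 moisture calibration on log10 moisture, via the NIPALS algorithm.

The calibration relates preprocessed absorbance spectra X to the mean-centred
base-10 logarithm of the reference (loss-on-drying) moisture y; the log
transform equalises the relative error across the wide moisture range, and
predictions are back-transformed with 10**(.) so an additive error in y is a
relative error in moisture.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .preprocess import mean_center
from .types import PLSModel

logger = logging.getLogger(__name__)

__all__ = [
    "fit_pls_nipals",
    "select_n_lv",
    "predict_moisture",
    "predict_log_moisture",
    "relative_error",
    "calibrate_moisture_model",
    "pair_lod_with_spectra",
]


def fit_pls_nipals(
    x_centred: np.ndarray,
    y_centred: np.ndarray,
    n_lv: int,
    x_mean: Optional[np.ndarray] = None,
    y_mean: float = 0.0,
    wavelength_grid: Optional[np.ndarray] = None,
    tol: float = 1.0e-10,
    max_iter: int = 500,
) -> PLSModel:
    """Classical NIPALS PLS1 with deflation on centred data.

    Each component iterates the weight vector until it changes by less than
    ``tol`` (or 500 iterations); for a single response the loop converges in
    one pass but is kept generic.  The regression vector on the centred scale
    is b = W (P'W)^-1 q, and the intercept b0 = y_mean - x_mean . b expresses
    the model on the uncentred scale.
    """
    x = np.array(x_centred, dtype=float)
    y = np.asarray(y_centred, dtype=float).ravel()
    n, w = x.shape
    if y.size != n:
        raise ValueError("X and y must have the same number of rows")
    if np.allclose(y, 0.0):
        raise ValueError("y has zero variance")
    if n_lv > min(n - 1, w) or n_lv < 1:
        raise ValueError(f"n_lv={n_lv} out of range for a {n}x{w} matrix")
    if x_mean is None:
        x_mean = np.zeros(w)
    if wavelength_grid is None:
        wavelength_grid = np.arange(w, dtype=float)

    weights = np.zeros((w, n_lv))
    p_load = np.zeros((w, n_lv))
    q_load = np.zeros(n_lv)
    xd, yd = x, y.copy()
    for a in range(n_lv):
        wv = xd.T @ yd
        nrm = np.linalg.norm(wv)
        if nrm == 0:
            raise ValueError(f"degenerate deflated data at component {a + 1}")
        wv = wv / nrm
        for _ in range(max_iter):
            t = xd @ wv
            tt = t @ t
            if tt == 0:
                raise ValueError(f"zero-variance score at component {a + 1}")
            q = (yd @ t) / tt
            wv_new = xd.T @ (yd * q)
            wv_new /= np.linalg.norm(wv_new)
            if np.linalg.norm(wv_new - wv) < tol:
                wv = wv_new
                break
            wv = wv_new
        t = xd @ wv
        tt = t @ t
        p = xd.T @ t / tt
        q = (yd @ t) / tt
        xd = xd - np.outer(t, p)
        yd = yd - q * t
        weights[:, a], p_load[:, a], q_load[a] = wv, p, q

    b = weights @ np.linalg.solve(p_load.T @ weights, q_load)
    b0 = float(y_mean - x_mean @ b)
    residuals = y - x @ b
    return PLSModel(
        n_lv=n_lv,
        weights=weights,
        x_loadings=p_load,
        y_loadings=q_load,
        b=b,
        b0=b0,
        x_mean=np.asarray(x_mean, dtype=float),
        y_mean=float(y_mean),
        wavelength_grid=np.asarray(wavelength_grid, dtype=float),
        residuals=residuals,
    )


def select_n_lv(
    x: np.ndarray,
    y: np.ndarray,
    max_lv: int = 5,
    folds: int = 5,
) -> int:
    """Latent-variable count by contiguous-block cross-validation, one-SE rule.

    Folds are contiguous blocks (time order preserved, avoiding leakage
    between adjacent smoothed spectra); the smallest component count whose CV
    RMSE lies within one standard error of the minimum is returned.  Because
    fold RMSEs are strongly correlated across candidate counts, the standard
    error is that of the *paired* fold-wise difference against the best
    candidate, not of the best candidate's RMSE itself.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    rank_cap = min(n - max(n // folds, 1) - 1, x.shape[1])
    if max_lv > rank_cap:
        raise ValueError(f"max_lv={max_lv} exceeds the usable rank {rank_cap}")
    bounds = np.linspace(0, n, folds + 1).astype(int)
    fold_rmse = np.zeros((max_lv, folds))
    for j in range(folds):
        test = np.arange(bounds[j], bounds[j + 1])
        train = np.setdiff1d(np.arange(n), test)
        xt, xm = mean_center(x[train])
        ym = float(np.mean(y[train]))
        yt = y[train] - ym
        for a in range(1, max_lv + 1):
            model = fit_pls_nipals(xt, yt, a, x_mean=xm, y_mean=ym)
            pred = x[test] @ model.b + model.b0
            fold_rmse[a - 1, j] = np.sqrt(np.mean((pred - y[test]) ** 2))
    rmse = fold_rmse.mean(axis=1)
    best = int(np.argmin(rmse))
    diff = fold_rmse - fold_rmse[best]
    se_diff = diff.std(axis=1, ddof=1) / np.sqrt(folds)
    within = rmse - rmse[best] <= se_diff
    chosen = int(np.argmax(within)) + 1
    logger.debug("CV RMSE by LV: %s -> chose %d", np.round(rmse, 5), chosen)
    return chosen


def predict_log_moisture(model: PLSModel, spectra: np.ndarray) -> np.ndarray:
    """Predicted log10 moisture for one spectrum or a stack of spectra."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[1] != model.wavelength_grid.size:
        raise ValueError(
            "wavelength grid mismatch: model covers "
            f"[{model.wavelength_grid[0]}, {model.wavelength_grid[-1]}] nm with "
            f"{model.wavelength_grid.size} points, input has {x.shape[1]} points"
        )
    return x @ model.b + model.b0


def predict_moisture(model: PLSModel, spectrum: np.ndarray):
    """Back-transformed moisture prediction f_w = 10**(yhat).

    Values outside (0, 1) are physically impossible moisture fractions and
    are flagged through the returned ``out_of_range`` mask.
    """
    yhat = predict_log_moisture(model, spectrum)
    f_w = 10.0**yhat
    out_of_range = (f_w <= 0.0) | (f_w >= 1.0)
    if np.asarray(spectrum).ndim == 1:
        return float(f_w[0]), bool(out_of_range[0])
    return f_w, out_of_range


def relative_error(pred, ref) -> float:
    """Root-mean-square relative deviation between predictions and reference, in %.

    e_rel = 100 * sqrt( mean( ((pred - ref)/ref)^2 ) )
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape:
        raise ValueError("pred and ref must have the same shape")
    if np.any(r <= 0):
        raise ValueError("reference moisture values must be positive")
    return float(100.0 * np.sqrt(np.mean(((p - r) / r) ** 2)))


def pair_lod_with_spectra(
    lod_samples: Sequence[tuple[float, float]],
    spectra_times: np.ndarray,
    max_gap: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Match each reference sample to the nearest preprocessed spectrum in time.

    Samples further than ``max_gap`` seconds from any spectrum are dropped.
    Returns (spectrum indices, observed moisture values).
    """
    ts = np.asarray(spectra_times, dtype=float)
    idx, vals = [], []
    for t, v in lod_samples:
        i = int(np.argmin(np.abs(ts - t)))
        if abs(ts[i] - t) <= max_gap:
            idx.append(i)
            vals.append(v)
    return np.asarray(idx, dtype=int), np.asarray(vals, dtype=float)


def calibrate_moisture_model(
    spectra_values: np.ndarray,
    spectra_times: np.ndarray,
    lod_samples: Sequence[tuple[float, float]],
    wavelength_grid: np.ndarray,
    n_lv: Optional[int] = None,
    max_lv: int = 5,
    folds: int = 5,
    max_gap: float = 30.0,
) -> PLSModel:
    """Fit the full moisture calibration from preprocessed spectra + LOD samples.

    Pairs each LOD observation with its nearest spectrum, builds y = log10 f_w,
    optionally selects the component count by cross-validation, and fits NIPALS
    on mean-centred data.
    """
    idx, f_obs = pair_lod_with_spectra(lod_samples, spectra_times, max_gap)
    if idx.size < 4:
        raise ValueError("too few paired calibration samples")
    x = spectra_values[idx]
    y = np.log10(f_obs)
    if n_lv is None:
        n_lv = select_n_lv(x, y, max_lv=max_lv, folds=folds)
    xc, xm = mean_center(x)
    ym = float(np.mean(y))
    model = fit_pls_nipals(xc, y - ym, n_lv, x_mean=xm, y_mean=ym,
                           wavelength_grid=wavelength_grid)
    model.meta["n_calibration_samples"] = int(idx.size)
    return model
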