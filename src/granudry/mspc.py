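"""PCA-based multivariate statistical process control for endpoint detection.

A PCA model of normal-operation *endpoint* spectra (moisture below the 2 wt%
criterion) defines the in-control region; a new spectrum's Q-statistic (SPE)
is the squared norm of its residual off the model plane.  Control limits come
from the Jackson-Mudholkar closed form on the residual eigenvalue moments,
and the batch endpoint is declared when the Q trace stays below the 95% limit
for 10 consecutive observations.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
from scipy.stats import norm

from .types import MSPCModel

logger = logging.getLogger(__name__)

__all__ = ["build_mspc", "select_n_pc", "q_statistic", "jm_limit", "detect_endpoint"]

_EIG_TRUNC = 1.0e-12  # residual eigenvalues below this fraction of the largest are dropped


def _snv_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance spectrum cannot be SNV-normalised")
    return (x - x.mean(axis=1, keepdims=True)) / sd


def select_n_pc(
    x_centred: np.ndarray,
    max_pc: int = 5,
    folds: int = 7,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Component count by row-fold cross-validation with a wavelength split.

    Plain row-held-out PRESS is monotone non-increasing in the component count
    (projection onto a larger subspace can only shrink a residual), so for
    each held-out row the scores are estimated from a random half of the
    wavelengths and the reconstruction error is evaluated on the other half.
    Components beyond the true rank then fit fold-specific noise and PRESS
    rises; the PRESS-minimising count is returned.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(x_centred, dtype=float)
    n, w = x.shape
    max_pc = min(max_pc, n - max(n // folds, 1) - 1, w // 2)
    if max_pc < 1:
        raise ValueError("too few rows for cross-validation")
    perm = rng.permutation(w)
    half_a, half_b = perm[: w // 2], perm[w // 2:]
    bounds = np.linspace(0, n, folds + 1).astype(int)
    press = np.zeros(max_pc)
    for j in range(folds):
        test = np.arange(bounds[j], bounds[j + 1])
        if test.size == 0:
            continue
        train = np.setdiff1d(np.arange(n), test)
        mu = x[train].mean(axis=0)
        _, _, vt = np.linalg.svd(x[train] - mu, full_matrices=False)
        xt = x[test] - mu
        for k in range(1, max_pc + 1):
            p = vt[:k]
            scores, *_ = np.linalg.lstsq(p[:, half_a].T, xt[:, half_a].T, rcond=None)
            recon_b = scores.T @ p[:, half_b]
            press[k - 1] += float(np.sum((xt[:, half_b] - recon_b) ** 2))
    chosen = int(np.argmin(press)) + 1
    logger.debug("PCA CV PRESS: %s -> %d components", np.round(press, 4), chosen)
    return chosen


def build_mspc(
    x_endpoint: np.ndarray,
    n_pc: Union[int, str] = "auto",
    snv: bool = True,
    wavelength_grid: Optional[np.ndarray] = None,
) -> MSPCModel:
    """Build the endpoint PCA model from a stack of preprocessed spectra.

    SNV normalisation (optional, on by default) and mean-centring are applied
    internally and their state stored, so monitoring spectra are transformed
    identically.  PCA is computed by SVD; when ``n_pc='auto'`` the count is
    chosen by cross-validated PRESS over 1-5 components.  The residual
    eigenvalues (beyond the retained components) feed the Jackson-Mudholkar
    control limits at 95% and 99%.
    """
    x = np.atleast_2d(np.asarray(x_endpoint, dtype=float))
    n, w = x.shape
    if snv:
        x = _snv_rows(x)
    mu = x.mean(axis=0)
    xc = x - mu
    if np.allclose(xc, 0.0):
        raise ValueError("degenerate endpoint spectra: no variance after centring")
    if n_pc == "auto":
        k = select_n_pc(xc, max_pc=min(5, n - 2))
    else:
        k = int(n_pc)
        if not 0 < k < n:
            raise ValueError(f"n_pc={k} must lie in (0, {n})")
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    resid_eig = eig[k:]
    resid_eig = resid_eig[resid_eig > _EIG_TRUNC * eig[0]] if eig[0] > 0 else resid_eig
    if resid_eig.size == 0:
        resid_eig = np.array([_EIG_TRUNC * max(eig[0], 1.0)])
    lim95 = jm_limit(resid_eig, 0.95)
    lim99 = jm_limit(resid_eig, 0.99)
    return MSPCModel(
        loadings=vt[:k],
        x_mean=mu,
        n_pc=k,
        residual_eigenvalues=resid_eig,
        limit_95=lim95,
        limit_99=lim99,
        snv_applied=snv,
        wavelength_grid=None if wavelength_grid is None
        else np.asarray(wavelength_grid, dtype=float),
        meta={"n_training_spectra": n},
    )


def q_statistic(model: MSPCModel, x_new: np.ndarray):
    """Q (squared prediction error) of one spectrum or a stack of spectra.

    Applies the model's stored SNV/centring, projects off the retained
    principal-component plane, and returns the squared residual norm.
    """
    x = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x.shape[1] != model.x_mean.size:
        raise ValueError(
            f"wavelength grid mismatch: model has {model.x_mean.size} points, "
            f"input has {x.shape[1]}"
        )
    if model.snv_applied:
        x = _snv_rows(x)
    xc = x - model.x_mean
    resid = xc - (xc @ model.loadings.T) @ model.loadings
    q = np.sum(resid**2, axis=1)
    return float(q[0]) if np.asarray(x_new).ndim == 1 else q


def jm_limit(residual_eigenvalues: np.ndarray, alpha: float = 0.95) -> float:
    """Jackson-Mudholkar control limit for the Q-statistic.

    With theta_i = sum(lambda^i) over the residual eigenvalues and
    h0 = 1 - 2 theta1 theta3 / (3 theta2^2), the limit at confidence alpha is

        theta1 * [ c_a sqrt(2 theta2 h0^2)/theta1 + 1
                   + theta2 h0 (h0 - 1)/theta1^2 ]^(1/h0)

    where c_a is the standard normal quantile.
    """
    lam = np.asarray(residual_eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive residual eigenvalues: no residual space")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    th1, th2, th3 = lam.sum(), np.sum(lam**2), np.sum(lam**3)
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    c = norm.ppf(alpha)
    core = c * np.sqrt(2.0 * th2 * h0**2) / th1 + 1.0 + th2 * h0 * (h0 - 1.0) / th1**2
    return float(th1 * core ** (1.0 / h0))


def detect_endpoint(
    q_trace: np.ndarray,
    limit: float,
    run_length: int = 10,
) -> Optional[int]:
    """First index (0-based) opening a run of ``run_length`` sub-limit Q values.

    Returns ``None`` when no such run exists (an off-specification batch that
    never settles below the limit).  Reports downstream of the API present
    the index 1-based.
    """
    q = np.asarray(q_trace, dtype=float)
    if q.size == 0:
        raise ValueError("empty Q trace")
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    below = q < limit
    count = 0
    for i, b in enumerate(below):
        count = count + 1 if b else 0
        if count >= run_length:
            return i - run_length + 1
    return None
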