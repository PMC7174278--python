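"""Mass-transfer-resistance analysis of fluidised-bed drying.

The drying gas carries water away from wet granules.  The analysis chain
turns an in-line moisture trajectory f_w(t) plus bed-temperature data into a
time-resolved total mass-transfer resistance Omega_tot and a three-parameter
resistance curve:

1. differentiate the water inventory N_w(t) to get the molar drying rate;
2. convert moisture to a water activity a_w through the formulation's
   aggregate GAB sorption isotherm, and combine with the Antoine vapour
   pressure at the bed temperature into the saturation concentration
   C_S* = a_w P*(T) / (R T);
3. compare the measured rate with the thermodynamic maximum
   Ndot_inf = (1 - S_in) C_S* phi_g reached when the outlet gas leaves
   saturated, giving the mass-transfer efficiency f_MTR = Ndot / Ndot_inf;
4. invert the plug-flow bed balance
   f_MTR = 1 - exp(-m_s / (Omega_tot f_s rho_s phi_g)) for Omega_tot;
5. fit Omega_tot(F_w) = Omega_ext + Omega_max exp(-(F_w - F_w_end)/F_w_crit),
   a constant external (gas film) resistance plus an internal granule
   resistance that grows exponentially as the granule dries.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .types import (
    GAS_CONSTANT,
    MOLAR_MASS_WATER,
    DryingRun,
    Formulation,
    GABParams,
    MTRTrace,
    ResistanceFit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "vapor_pressure",
    "gab_content",
    "gab_capacity",
    "water_activity",
    "aggregate_isotherm",
    "fit_gab",
    "moles_of_water",
    "drying_rate",
    "equilibrium_concentration",
    "estimate_inlet_concentration",
    "mtr_fraction",
    "omega_total",
    "fit_resistance",
    "analyze_run",
    "DEFAULT_ACTIVITY_GRID",
]

#: Water-activity grid on which aggregate isotherms are tabulated and fitted.
DEFAULT_ACTIVITY_GRID = np.arange(0.02, 0.9401, 0.02)

#: f_MTR is clipped into this open interval before taking the logarithm.
F_MTR_CLIP = 1.0e-6


def vapor_pressure(temp_c):
    """Saturation vapour pressure of water (Pa) from an Antoine correlation.

    The correlation is anchored at 20 deg C where it returns 2339.1 Pa exactly;
    valid for -50 < T < 150 deg C.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= -50.0) or np.any(t >= 150.0):
        raise ValueError("temperature outside the correlation validity range (-50, 150) C")
    p = 2339.1 * np.exp(-4078.8 * (1.0 / (236.63 + t) - 1.0 / 256.63))
    return p if p.ndim else float(p)


def gab_content(a_w, p: GABParams):
    """Equilibrium dry-basis water content (g/g) at activity ``a_w`` (GAB isotherm)."""
    a = np.asarray(a_w, dtype=float)
    if np.any(a < 0) or np.any(p.k_w * a >= 1.0):
        raise ValueError("require 0 <= a_w < 1/k_w for a finite GAB isotherm")
    u = p.k_w * a
    f = u * p.c_gab * p.m_o / ((1.0 - u) * (1.0 + (p.c_gab - 1.0) * u))
    return f if f.ndim else float(f)


def gab_capacity(p: GABParams) -> float:
    """Maximum adsorbed content (g/g) of the isotherm, i.e. its value at a_w = 1.

    Finite whenever k_w < 1; beyond this content the excess water is free
    surface water and the activity is pinned at 1.
    """
    if p.k_w >= 1.0:
        return np.inf
    u = p.k_w
    return u * p.c_gab * p.m_o / ((1.0 - u) * (1.0 + (p.c_gab - 1.0) * u))


def water_activity(f_w, p: GABParams):
    """Invert the GAB isotherm: activity a_w at dry-basis content ``f_w`` (g/g).

    Solves the quadratic in u = k_w a_w
        -F (C-1) u^2 + (F (C-2) - C m_o) u + F = 0
    and returns the root in (0, 1).  Contents above the isotherm's capacity at
    a_w = 1 are in the free-water regime and return exactly 1.
    """
    f_arr = np.asarray(f_w, dtype=float)
    scalar = f_arr.ndim == 0
    f_arr = np.atleast_1d(f_arr)
    if np.any(f_arr < 0):
        raise ValueError("f_w must be >= 0")
    cap = gab_capacity(p)
    out = np.ones_like(f_arr)
    mask = f_arr < cap
    f = f_arr[mask]
    c, mo, k = p.c_gab, p.m_o, p.k_w
    qa = -f * (c - 1.0)
    qb = f * (c - 2.0) - c * mo
    qc = f
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = qb * qb - 4.0 * qa * qc
        if np.any(disc < 0):
            raise ArithmeticError(
                f"GAB inversion has no real root for f_w={f[disc < 0][:3]} with {p}"
            )
        sq = np.sqrt(disc)
        # stable quadratic roots; pick the one in [0, 1)
        u1 = np.where(qa != 0, (-qb + sq) / (2.0 * np.where(qa != 0, qa, 1.0)), -1.0)
        u2 = np.where(qa != 0, (-qb - sq) / (2.0 * np.where(qa != 0, qa, 1.0)), -1.0)
        u_lin = np.where(qb != 0, -qc / np.where(qb != 0, qb, 1.0), 0.0)
    u = np.where((u1 >= 0) & (u1 < 1.0), u1, u2)
    u = np.where(qa == 0, u_lin, u)
    u = np.where(f == 0, 0.0, u)
    if np.any((u < 0) | (u >= 1.0)):
        bad = f[(u < 0) | (u >= 1.0)]
        raise ArithmeticError(f"no GAB root in (0,1) for f_w={bad[:3]} with {p}")
    out[mask] = u / k
    return float(out[0]) if scalar else out


def aggregate_isotherm(
    formulation: Formulation,
    grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, GABParams]:
    """Construct and fit the formulation's aggregate sorption isotherm.

    Assuming the materials do not interact, the water adsorbed at a common
    activity is the mass-weighted sum over all components; the aggregate
    dry-basis content is that sum divided by the adsorbing mass (the
    structural excipients), so small adsorbers such as mannitol contribute to
    the numerator but not the reference mass.

    Returns the tabulated ``(a_w, F_w)`` pairs (shape (n, 2)) and the GAB
    parameters fitted to the table.
    """
    if grid is None:
        grid = DEFAULT_ACTIVITY_GRID
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 0.95):
        raise ValueError("aggregate grid must lie within [0, 0.95]")
    m_adsorb = formulation.adsorbing_mass
    if m_adsorb <= 0:
        raise ValueError("formulation has an empty adsorbing subset")
    total = np.zeros_like(grid)
    for comp in formulation.components:
        total += comp.mass * gab_content(grid, comp)
    f_values = total / m_adsorb
    fitted = fit_gab(grid, f_values)
    fitted.material_name = "aggregate"
    fitted.mass = m_adsorb
    return np.column_stack([grid, f_values]), fitted


def fit_gab(a_grid, f_values, weights=None) -> GABParams:
    """Least-squares fit of GAB parameters to tabulated isotherm data.

    Multi-start over C in {1, 10, 100} and k in {0.5, 0.8, 0.95} to avoid the
    shallow local minima of the three-parameter surface; unweighted by default.
    """
    a = np.asarray(a_grid, dtype=float)
    f = np.asarray(f_values, dtype=float)
    if a.size != f.size:
        raise ValueError("a_grid and f_values must have the same length")
    if a.size < 3:
        raise ValueError("GAB fit is under-determined with fewer than 3 points")
    if np.any(a >= 1.0):
        raise ValueError("a_grid must be < 1")
    w = np.ones_like(f) if weights is None else np.asarray(weights, dtype=float)

    def resid(theta):
        mo, c, k = np.exp(theta[0]), np.exp(theta[1]), 1.0 / (1.0 + np.exp(-theta[2]))
        u = k * a
        model = u * c * mo / ((1.0 - u) * (1.0 + (c - 1.0) * u))
        return w * (model - f)

    best = None
    mo0 = max(np.interp(0.3, a, f), 1e-6)
    for c0 in (1.0, 10.0, 100.0):
        for k0 in (0.5, 0.8, 0.95):
            x0 = [np.log(mo0), np.log(c0), np.log(k0 / (1.0 - k0))]
            try:
                sol = least_squares(resid, x0, method="lm", max_nfev=5000)
            except Exception:  # pragma: no cover - defensive
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("GAB fit failed to converge from all starts")
    mo, c, k = np.exp(best.x[0]), np.exp(best.x[1]), 1.0 / (1.0 + np.exp(-best.x[2]))
    rms = float(np.sqrt(np.mean(best.fun**2)))
    logger.debug("GAB fit: m_o=%.5g C=%.5g k=%.5g rms=%.3g", mo, c, k, rms)
    return GABParams(m_o=mo, c_gab=c, k_w=min(k, 1.0), material_name="fitted", mass=0.0)


def moles_of_water(f_w, m_s: float):
    """Moles of water in the bed at wet-basis moisture ``f_w`` and dry mass ``m_s`` (kg)."""
    f = np.asarray(f_w, dtype=float)
    if np.any(f < 0) or np.any(f >= 1):
        raise ValueError("f_w must lie in [0, 1)")
    n = m_s * f / ((1.0 - f) * MOLAR_MASS_WATER)
    return n if n.ndim else float(n)


def drying_rate(
    time: np.ndarray,
    f_w: np.ndarray,
    m_s: float,
    half_window: int = 36,
):
    """Molar drying rate by windowed linear regression of the water inventory.

    At each point a straight line is fitted to ``half_window`` samples either
    side (72 points over 720 s at the 10 s post-preprocessing cadence); the
    rate is minus the slope.  Returns ``(ndot, slope_se_rel, low_confidence)``
    where ``slope_se_rel`` is the relative standard error of the slope and
    ``low_confidence`` flags points where the windowed derivative is not
    trustworthy: truncated windows at the series edges, and points where the
    slope changes by more than half its value between the two window halves
    (the linear fit is then a poor local model of the inventory).
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(f_w, dtype=float)
    if t.size != f.size:
        raise ValueError("time and f_w must have the same length")
    if t.size <= 2 * half_window:
        raise ValueError(
            f"series of {t.size} points is too short for half_window={half_window}"
        )
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("drying_rate expects a uniform time grid")
    n_w = moles_of_water(f, m_s)
    n = t.size
    ndot = np.empty(n)
    se_rel = np.empty(n)
    low_conf = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window)
        if hi - lo < 2 * half_window:
            low_conf[i] = True
        tw, yw = t[lo:hi], n_w[lo:hi]
        res = linregress(tw, yw)
        ndot[i] = -res.slope
        if res.slope != 0 and np.isfinite(res.stderr):
            se_rel[i] = abs(res.stderr / res.slope)
        else:
            se_rel[i] = np.inf
        # local-linearity check: the two window halves should agree
        if not low_conf[i] and res.slope != 0:
            mid = i
            s_left = linregress(t[lo:mid + 1], n_w[lo:mid + 1]).slope
            s_right = linregress(t[mid:hi], n_w[mid:hi]).slope
            if abs(s_left - s_right) > 0.5 * abs(res.slope):
                low_conf[i] = True
    return ndot, se_rel, low_conf


def equilibrium_concentration(t_bed_c, a_w):
    """Saturation water concentration C_S* = a_w P*(T) / (R T) in mol/m3."""
    a = np.asarray(a_w, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("a_w must lie in [0, 1]")
    t = np.asarray(t_bed_c, dtype=float)
    c = a * vapor_pressure(t) / (GAS_CONSTANT * (t + 273.15))
    return c if c.ndim else float(c)


def estimate_inlet_concentration(
    time: np.ndarray,
    ndot_w: np.ndarray,
    c_s_star: np.ndarray,
    phi_g: float,
    startup_exclude: float = 300.0,
    smooth_window: int = 5,
) -> tuple[float, int]:
    """Estimate the inlet water concentration assuming a saturated outlet at peak rate.

    The inlet humidity is rarely measured; instead ``C_g,in`` is chosen such
    that the outlet gas is exactly saturated at the reference time ``t0`` of
    maximum (smoothed) drying rate, with the first ``startup_exclude`` seconds
    ignored:  C_g,in = max(0, C_S*(t0) - Ndot_w(t0) / phi_g).

    Only well-posed when the outlet really is near-saturated at t0, i.e. when
    the bed operates close to its thermodynamic maximum rate.  Returns the
    estimate and the index of t0.
    """
    t = np.asarray(time, dtype=float)
    nd = np.asarray(ndot_w, dtype=float)
    cs = np.asarray(c_s_star, dtype=float)
    sel = t >= t[0] + startup_exclude
    if not np.any(sel):
        raise ValueError("no constant-rate region after the startup exclusion")
    k = max(1, smooth_window)
    kernel = np.ones(k) / k
    smooth = np.convolve(nd, kernel, mode="same")
    idx_candidates = np.flatnonzero(sel)
    i0 = idx_candidates[np.argmax(smooth[idx_candidates])]
    c_g_in = cs[i0] - nd[i0] / phi_g
    if c_g_in < 0:
        warnings.warn(
            "apparent drying rate exceeds the saturated-outlet maximum; "
            "inlet concentration clamped to 0",
            stacklevel=2,
        )
        c_g_in = 0.0
    return float(c_g_in), int(i0)


def mtr_fraction(ndot_w, ndot_inf):
    """Mass-transfer efficiency f_MTR = Ndot_w / Ndot_inf, clipped away from {0, 1}.

    The clip (at 1e-6 and 1 - 1e-6) keeps the downstream logarithm finite;
    clipped entries are reported via the second return value so they can be
    excluded from resistance fitting.
    """
    nd = np.asarray(ndot_w, dtype=float)
    ni = np.asarray(ndot_inf, dtype=float)
    if np.any(ni <= 0):
        raise ValueError("Ndot_inf must be positive")
    raw = nd / ni
    clipped = (raw <= F_MTR_CLIP) | (raw >= 1.0 - F_MTR_CLIP)
    if np.any(clipped):
        logger.info("f_MTR clipped at %d of %d points", int(np.sum(clipped)), raw.size)
    f = np.clip(raw, F_MTR_CLIP, 1.0 - F_MTR_CLIP)
    if f.ndim == 0:
        return float(f), bool(clipped)
    return f, clipped


def omega_total(f_mtr, m_s: float, f_s: float, rho_s: float, phi_g: float):
    """Total mass-transfer resistance (s) from the bed balance.

    Omega_tot = -m_s / (ln(1 - f_MTR) f_s rho_s phi_g)
    """
    f = np.asarray(f_mtr, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("f_MTR must lie strictly in (0, 1)")
    om = -m_s / (np.log(1.0 - f) * f_s * rho_s * phi_g)
    return om if om.ndim else float(om)


def _mtr_fraction_from_omega(omega, m_s, f_s, rho_s, phi_g):
    return 1.0 - np.exp(-m_s / (np.asarray(omega, dtype=float) * f_s * rho_s * phi_g))


def fit_resistance(
    f_w_dry: np.ndarray,
    omega_tot: np.ndarray,
    f_w_end: float,
) -> ResistanceFit:
    """Fit Omega_tot(F_w) = Omega_ext + Omega_max exp(-(F_w - F_w_end)/F_w_crit).

    The fit minimises squared residuals of log10(Omega_tot): the observed
    resistance spans roughly two orders of magnitude between the external
    plateau and the dry-granule maximum, and a linear-space fit would ignore
    the plateau entirely.  ``F_w_end`` is held fixed (the run's final observed
    dry-basis moisture).  Approximate standard errors from the Jacobian.
    """
    fw = np.asarray(f_w_dry, dtype=float)
    om = np.asarray(omega_tot, dtype=float)
    if fw.size != om.size:
        raise ValueError("F_w and Omega_tot must have the same length")
    if fw.size < 10:
        raise ValueError("resistance fit needs at least 10 points")
    if np.any(om <= 0):
        raise ValueError("Omega_tot must be positive")
    span = fw.max() - f_w_end
    if span < 0.2:
        raise ValueError("degenerate F_w range: data must extend well above F_w_end")
    logobs = np.log10(om)

    def model(theta, x):
        oe, om_max, fc = np.exp(theta)
        return np.log10(oe + om_max * np.exp(-(x - f_w_end) / fc))

    def resid(theta):
        return model(theta, fw) - logobs

    lo_guess = max(np.percentile(om, 5), 1e-6)
    hi_guess = max(np.percentile(om, 95) - lo_guess, 1e-6)
    best = None
    for fc0 in (0.05, 0.1, 0.2):
        x0 = np.log([lo_guess, hi_guess, fc0])
        sol = least_squares(resid, x0, method="lm", max_nfev=10000)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("resistance fit failed to converge")
    oe, om_max, fc = np.exp(best.x)
    # delta-method SEs on the natural scale
    dof = max(fw.size - 3, 1)
    s2 = 2.0 * best.cost / dof
    try:
        jtj = best.jac.T @ best.jac
        cov_log = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.diag(cov_log)) * np.array([oe, om_max, fc])
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(3, np.nan)
    return ResistanceFit(
        omega_ext=float(oe),
        omega_max=float(om_max),
        f_w_crit=float(fc),
        f_w_end=float(f_w_end),
        omega_ext_se=float(se[0]),
        omega_max_se=float(se[1]),
        f_w_crit_se=float(se[2]),
    )


def analyze_run(
    run: DryingRun,
    formulation: Formulation,
    half_window: int = 36,
    cadence: float = 10.0,
    inlet: str = "estimate",
    aggregate_params: Optional[GABParams] = None,
) -> tuple[MTRTrace, ResistanceFit]:
    """Run the full resistance analysis chain on a drying batch.

    Resamples the moisture/temperature traces to the post-preprocessing
    cadence, estimates the drying rate, evaluates the thermodynamic driving
    force through the aggregate isotherm and Antoine correlation, converts
    rates to resistances and fits the resistance curve.

    ``inlet`` selects how C_g,in is obtained: ``"estimate"`` applies the
    saturated-outlet-at-peak-rate estimator (the plant procedure, well-posed
    only when the outlet is near saturation); ``"known"`` uses the value
    recorded in ``run.bed.inlet_water_conc`` (available for synthetic or
    instrumented batches).
    """
    if inlet not in ("estimate", "known"):
        raise ValueError("inlet must be 'estimate' or 'known'")
    bed = run.bed
    phi = bed.gas_flow_m3s
    if phi <= 0:
        raise ValueError("analysis stage drying_rate: gas flow must be positive")

    t = np.arange(run.time[0], run.time[-1] + cadence / 2, cadence)
    f_w = np.interp(t, run.time, run.moisture_fraction)
    t_bed = np.interp(t, run.time, run.bed_temp)

    ndot, se_rel, low_conf = drying_rate(t, f_w, bed.solids_mass, half_window)

    if aggregate_params is None:
        _, aggregate_params = aggregate_isotherm(formulation)
    fw_dry = (bed.solids_mass / bed.adsorbing_mass) * f_w / (1.0 - f_w)
    a_w = water_activity(fw_dry, aggregate_params)
    p_star = vapor_pressure(t_bed)
    c_s_star = equilibrium_concentration(t_bed, a_w)

    if inlet == "known":
        if bed.inlet_water_conc is None:
            raise ValueError("analysis stage inlet: run has no recorded inlet_water_conc")
        c_g_in = float(bed.inlet_water_conc)
    else:
        c_g_in, _ = estimate_inlet_concentration(t, ndot, c_s_star, phi)

    s_in = np.clip(c_g_in / np.maximum(c_s_star, 1e-12), 0.0, 1.0)
    ndot_inf = np.maximum((1.0 - s_in) * c_s_star * phi, 1e-15)
    f_mtr, clipped = mtr_fraction(np.maximum(ndot, 0.0), ndot_inf)
    omega = omega_total(f_mtr, bed.solids_mass, bed.solids_fraction,
                        bed.skeletal_density, phi)

    trace = MTRTrace(
        time=t, f_w=f_w, F_w=fw_dry, a_w=a_w, p_star=p_star,
        c_s_star=c_s_star, s_in=s_in, ndot_w=ndot, ndot_inf=ndot_inf,
        f_mtr=f_mtr, omega_tot=omega, slope_se=se_rel,
        clipped=clipped, low_confidence=low_conf, c_g_in=c_g_in,
        meta={"half_window": half_window, "cadence": cadence, "inlet": inlet},
    )

    good = ~clipped & ~low_conf & np.isfinite(omega)
    if np.sum(good) < 10:
        raise RuntimeError("analysis stage fit_resistance: too few usable points")
    f_w_end = float(fw_dry[-1])
    fit = fit_resistance(fw_dry[good], omega[good], f_w_end)
    return trace, fit
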