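"""Core data containers shared across the drying-monitor toolkit.

All containers are plain dataclasses with eager validation: invalid physical
configurations fail at construction time, not deep inside a pipeline stage.
Arrays are stored as float64 ``numpy`` arrays; wavelengths in nm, times in
seconds, temperatures in degrees Celsius, concentrations in mol/m3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BedConfig",
    "OpticsConfig",
    "ResistanceFit",
    "GABParams",
    "Formulation",
    "SpectraSeries",
    "DryingRun",
    "PLSModel",
    "MSPCModel",
    "MTRTrace",
    "MOLAR_MASS_WATER",
    "GAS_CONSTANT",
]

#: kg/mol, used to convert between mass and moles of water.
MOLAR_MASS_WATER = 0.018

#: J/(mol K)
GAS_CONSTANT = 8.314


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.size == 0:
        raise ValueError(f"{name} must not be empty")
    return a


@dataclass
class BedConfig:
    """Fluidised-bed configuration for one drying batch.

    Parameters
    ----------
    gas_flow:
        Volumetric gas flowrate in L/min (interpreted at inlet conditions).
    inlet_temp:
        Fluidising-gas inlet temperature, deg C.
    solids_mass:
        Dry-basis mass of solids in the bed, kg.
    solids_fraction:
        Volume fraction of solids in the fluidised bed (dimensionless).
    skeletal_density:
        Skeletal density of the solids, kg/m3.
    adsorbing_mass:
        Combined dry mass of the water-adsorbing excipients, kg.  Dry-basis
        moisture ``F_w`` is expressed per unit of this mass.
    inlet_water_conc:
        Water concentration of the inlet gas ``C_g,in`` in mol/m3, or ``None``
        when it is to be estimated from process data.
    """

    gas_flow: float = 600.0
    inlet_temp: float = 25.0
    solids_mass: float = 0.331
    solids_fraction: float = 0.40
    skeletal_density: float = 1500.0
    adsorbing_mass: float = 0.118
    inlet_water_conc: Optional[float] = 0.36

    def __post_init__(self) -> None:
        if self.gas_flow < 0:
            raise ValueError("gas_flow must be >= 0 L/min")
        if not 0 < self.solids_fraction < 1:
            raise ValueError("solids_fraction must lie in (0, 1)")
        if self.skeletal_density <= 0:
            raise ValueError("skeletal_density must be positive")
        if self.solids_mass <= 0:
            raise ValueError("solids_mass must be positive")
        if self.adsorbing_mass > self.solids_mass:
            raise ValueError("adsorbing_mass cannot exceed solids_mass")
        if self.inlet_water_conc is not None and self.inlet_water_conc < 0:
            raise ValueError("inlet_water_conc must be >= 0")

    @property
    def gas_flow_m3s(self) -> float:
        """Gas flowrate converted to m3/s."""
        return self.gas_flow / 1000.0 / 60.0


@dataclass
class ResistanceFit:
    """Parametrisation of the total mass-transfer resistance.

    Omega_tot(F_w) = omega_ext + omega_max * exp(-(F_w - f_w_end) / f_w_crit)

    with a constant external (gas-film) resistance and an internal granule
    resistance that grows exponentially as the dry-basis moisture ``F_w``
    falls toward its final value ``f_w_end``.  All resistances in seconds.
    """

    omega_ext: float
    omega_max: float
    f_w_crit: float
    f_w_end: float = 0.0
    omega_ext_se: Optional[float] = None
    omega_max_se: Optional[float] = None
    f_w_crit_se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.omega_ext < 0 or self.omega_max < 0 or self.f_w_end < 0:
            raise ValueError("resistances and f_w_end must be >= 0")
        if self.f_w_crit <= 0:
            raise ValueError("f_w_crit must be > 0")

    def total(self, f_w: "np.ndarray | float") -> np.ndarray:
        """Evaluate Omega_tot at dry-basis moisture ``f_w`` (array or scalar)."""
        f_w = np.asarray(f_w, dtype=float)
        return self.omega_ext + self.omega_max * np.exp(
            -(f_w - self.f_w_end) / self.f_w_crit
        )

    def internal_fraction(self, f_w: "np.ndarray | float") -> np.ndarray:
        """Fraction of the maximum internal resistance remaining at ``f_w``."""
        f_w = np.asarray(f_w, dtype=float)
        return np.exp(-(f_w - self.f_w_end) / self.f_w_crit)


@dataclass
class OpticsConfig:
    """Synthetic NIR sensor model: wavelength grid, signal levels and artefacts.

    The artefact model (per-scan lognormal gain, air-gap dropout scans and
    exponentially decaying fouling episodes) is deliberately simple; every
    effect can be switched off individually by zeroing its parameter.
    """

    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.arange(1750.0, 2151.0, 1.0)
    )
    dark_level: float = 500.0
    bright_level: float = 20000.0
    water_band_center: float = 1940.0
    water_band_width: float = 35.0
    absorbance_per_moisture: float = 1.0
    response_ref_moisture: float = 0.005
    baseline_offset: float = 0.20
    baseline_slope: float = 1.0e-4
    scan_noise_sd: float = 100.0
    gain_sd: float = 0.20
    airgap_prob: float = 0.03
    fouling_magnitude: float = 0.03
    fouling_decay: float = 1.0 / 300.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.wavelength_grid = _as_array(self.wavelength_grid, "wavelength_grid")
        if np.any(np.diff(self.wavelength_grid) <= 0):
            raise ValueError("wavelength_grid must be strictly increasing")
        if self.dark_level >= self.bright_level:
            raise ValueError("dark_level must be below bright_level")
        if not 0 <= self.airgap_prob <= 1:
            raise ValueError("airgap_prob must lie in [0, 1]")
        if self.water_band_width <= 0:
            raise ValueError("water_band_width must be positive")
        if self.scan_noise_sd < 0 or self.gain_sd < 0 or self.fouling_magnitude < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.response_ref_moisture < 0:
            raise ValueError("response_ref_moisture must be >= 0 (0 = linear response)")

    def moisture_response(self, f_w):
        """Apparent water-band amplitude (0..1 scale) at moisture ``f_w``.

        Diffuse reflectance from wet granules saturates: the apparent
        absorbance grows concavely with water content (path-length and band
        saturation effects), which is what makes a log-moisture calibration
        linear in practice.  Modelled as log(1 + f/f_ref), normalised to 1 at
        f = 1; ``response_ref_moisture = 0`` degenerates to a linear response.
        """
        import numpy as _np

        f = _np.asarray(f_w, dtype=float)
        r = self.response_ref_moisture
        if r == 0:
            return f
        return _np.log1p(f / r) / _np.log1p(1.0 / r)


@dataclass
class GABParams:
    """Guggenheim-Andersen-de Boer sorption-isotherm parameters for one material.

    ``m_o`` is the monolayer capacity (g water / g solid), ``c_gab`` the
    dimensionless energy constant and ``k_w`` the multilayer constant; the
    isotherm is finite on a_w in [0, 1) only when ``k_w * a_w < 1``.
    """

    m_o: float
    c_gab: float
    k_w: float
    material_name: str = ""
    mass: float = 0.0  # g of material in the formulation

    def __post_init__(self) -> None:
        if self.m_o <= 0:
            raise ValueError("m_o must be positive")
        if self.c_gab <= 0:
            raise ValueError("c_gab must be positive")
        if not 0 < self.k_w <= 1:
            raise ValueError("k_w must lie in (0, 1]")
        if self.mass < 0:
            raise ValueError("mass must be >= 0")


@dataclass
class Formulation:
    """A granule formulation: component isotherms, masses and the adsorbing subset."""

    components: list[GABParams]
    adsorbing_subset: list[str]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("formulation needs at least one component")
        names = {c.material_name for c in self.components}
        missing = set(self.adsorbing_subset) - names
        if missing:
            raise ValueError(f"adsorbing_subset names unknown components: {sorted(missing)}")
        if any(c.mass <= 0 for c in self.components):
            raise ValueError("all component masses must be positive")

    @property
    def adsorbing_mass(self) -> float:
        """Combined mass (g) of the components that count toward m_adsorb."""
        return sum(c.mass for c in self.components if c.material_name in self.adsorbing_subset)


@dataclass
class SpectraSeries:
    """A stack of spectra on a fixed wavelength grid with per-scan timestamps.

    ``kind`` is either ``"intensity"`` (detector counts; bright/dark reference
    spectra required) or ``"absorbance"`` (AU).
    """

    wavelengths: np.ndarray
    timestamps: np.ndarray
    values: np.ndarray
    kind: str = "intensity"
    bright_ref: Optional[np.ndarray] = None
    dark_ref: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = _as_array(self.wavelengths, "wavelengths")
        self.timestamps = _as_array(self.timestamps, "timestamps")
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.kind not in ("intensity", "absorbance"):
            raise ValueError("kind must be 'intensity' or 'absorbance'")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")
        n, w = self.values.shape
        if n != self.timestamps.size:
            raise ValueError("one timestamp per scan required")
        if w != self.wavelengths.size:
            raise ValueError("values width must match the wavelength grid")
        if self.kind == "intensity":
            if self.bright_ref is None or self.dark_ref is None:
                raise ValueError("intensity spectra require bright and dark references")
            self.bright_ref = _as_array(self.bright_ref, "bright_ref")
            self.dark_ref = _as_array(self.dark_ref, "dark_ref")
            if self.bright_ref.size != w or self.dark_ref.size != w:
                raise ValueError("reference spectra must match the wavelength grid")
            if np.any(self.bright_ref <= self.dark_ref):
                raise ValueError("bright_ref must exceed dark_ref elementwise")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def copy_with(self, **kwargs) -> "SpectraSeries":
        return replace(self, **kwargs)


@dataclass
class DryingRun:
    """Fused process record for one drying batch on a uniform time grid."""

    time: np.ndarray
    moisture_fraction: np.ndarray  # wet-basis f_w
    bed_temp: np.ndarray
    inlet_temp: np.ndarray
    bed: BedConfig
    lod_samples: list[tuple[float, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_array(self.time, "time")
        self.moisture_fraction = _as_array(self.moisture_fraction, "moisture_fraction")
        self.bed_temp = _as_array(self.bed_temp, "bed_temp")
        self.inlet_temp = _as_array(self.inlet_temp, "inlet_temp")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        n = self.time.size
        for name in ("moisture_fraction", "bed_temp", "inlet_temp"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must match the time grid")
        f = self.moisture_fraction
        if np.any(f < 0) or np.any(f >= 1):
            raise ValueError("moisture_fraction must lie in [0, 1)")

    @property
    def dry_basis_moisture(self) -> np.ndarray:
        """F_w = m_w / m_adsorb, derived identically from f_w and the bed masses."""
        f = self.moisture_fraction
        return (self.bed.solids_mass / self.bed.adsorbing_mass) * f / (1.0 - f)


@dataclass
class PLSModel:
    """A fitted PLS1 calibration with all state needed to predict new spectra."""

    n_lv: int
    weights: np.ndarray      # W x n_lv
    x_loadings: np.ndarray   # W x n_lv
    y_loadings: np.ndarray   # n_lv
    b: np.ndarray            # W
    b0: float
    x_mean: np.ndarray       # W
    y_mean: float
    wavelength_grid: np.ndarray
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    meta: dict = field(default_factory=dict)


@dataclass
class MSPCModel:
    """A PCA model of endpoint spectra for Q-statistic process monitoring."""

    loadings: np.ndarray             # n_pc x W, orthonormal rows
    x_mean: np.ndarray               # W
    n_pc: int
    residual_eigenvalues: np.ndarray  # eigenvalues of the residual covariance
    limit_95: float
    limit_99: float
    snv_applied: bool = True
    wavelength_grid: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)


@dataclass
class MTRTrace:
    """Time-resolved mass-transfer quantities along a drying batch."""

    time: np.ndarray
    f_w: np.ndarray            # wet basis moisture used for the analysis
    F_w: np.ndarray            # dry basis moisture
    a_w: np.ndarray
    p_star: np.ndarray         # Pa
    c_s_star: np.ndarray       # mol/m3
    s_in: np.ndarray
    ndot_w: np.ndarray         # mol/s (measured)
    ndot_inf: np.ndarray       # mol/s (thermodynamic maximum)
    f_mtr: np.ndarray
    omega_tot: np.ndarray      # s
    slope_se: np.ndarray       # relative SE of the drying-rate slope
    clipped: np.ndarray        # bool: f_MTR was clipped before the log
    low_confidence: np.ndarray  # bool: truncated regression window at edges
    c_g_in: float = 0.0
    meta: dict = field(default_factory=dict)
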