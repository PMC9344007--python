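"""Synthetic SERS spectrum generator.

Stands in for undeposited instrument data: spectra are superpositions of
pseudo-Voigt bands on a smooth fluorescence background with multiplicative
intensity noise, on the instrument's 550-1550 cm^-1 detection axis.

Line-shape model
----------------
A band is the mixture

    V(nu) = theta * alpha * exp(-4 ln2 (nu-omega)^2 / gamma^2)
          + (1-theta) * alpha * gamma^2 / ((nu-omega)^2 + gamma^2)

with mixing coefficient theta in [0,1], peak height alpha, centre omega and
half-width gamma.  Note the two terms use different width conventions
(gamma is the FWHM of the Gaussian term but the HWHM of the Lorentzian
term); the mixture is implemented exactly in this form, so at nu = omega
both terms peak and V(omega) = alpha regardless of theta.

The stand-alone Lorentzian L(v) = (1/pi) gamma_L^2 / ((v-w)^2 + gamma_L^2)
is likewise kept in this form: its maximum is always 1/pi, independent of
gamma_L (it is not unit-area normalised).  The Gaussian
G(v) = (1/gamma_G) sqrt(ln2/pi) exp(-((v-w)/gamma_G)^2 ln2) has gamma_G as
its half-width at half-maximum.

Concentration response
----------------------
Each peak library designates one quantitation band; the concentration-
sensitive peaks are scaled jointly so that the clean (noise-free,
baseline-free) intensity at the quantitation centre equals

    I = calibration_slope * N + calibration_intercept

which reproduces the thiram 1379 cm^-1 response I = 11644 N + 4536.5
(0.1-5.0 ug/mL) under the default configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import Spectrum, SpectrumSet

__all__ = [
    "PeakParams",
    "GeneratorConfig",
    "voigt_profile",
    "lorentz_profile",
    "gauss_profile",
    "generate_spectrum",
    "generate_study",
    "generate_nonlinear_study",
    "thiram_config",
    "r6g_config",
    "fruit_epidermis_config",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class PeakParams:
    """Pseudo-Voigt parameters for one band.

    theta: Gauss-Lorentz mixing coefficient in [0, 1].
    alpha: peak height (a.u.); for concentration-sensitive peaks this is a
        height *relative* to the quantitation band before scaling.
    omega: centre position (cm^-1).
    gamma: half-width parameter (cm^-1), > 0.
    sensitive: whether the band scales with analyte concentration.
    """

    theta: float
    alpha: float
    omega: float
    gamma: float
    sensitive: bool = True

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


def voigt_profile(nu, p: PeakParams) -> np.ndarray:
    """Pseudo-Voigt band evaluated elementwise on ``nu``."""
    nu = np.asarray(nu, dtype=float)
    d2 = (nu - p.omega) ** 2
    g2 = p.gamma**2
    gauss = np.exp(-4.0 * _LN2 * d2 / g2)
    lorentz = g2 / (d2 + g2)
    return p.theta * p.alpha * gauss + (1.0 - p.theta) * p.alpha * lorentz


def lorentz_profile(nu, gamma_l: float, omega: float) -> np.ndarray:
    """Lorentzian contour (1/pi) gamma_L^2 / ((v-w)^2 + gamma_L^2)."""
    if gamma_l <= 0:
        raise ValueError(f"gamma_l must be > 0, got {gamma_l}")
    nu = np.asarray(nu, dtype=float)
    g2 = gamma_l**2
    return (1.0 / math.pi) * g2 / ((nu - omega) ** 2 + g2)


def gauss_profile(nu, gamma_g: float, omega: float) -> np.ndarray:
    """Gaussian contour with gamma_g as half-width at half-maximum."""
    if gamma_g <= 0:
        raise ValueError(f"gamma_g must be > 0, got {gamma_g}")
    nu = np.asarray(nu, dtype=float)
    return (1.0 / gamma_g) * math.sqrt(_LN2 / math.pi) * np.exp(
        -(((nu - omega) / gamma_g) ** 2) * _LN2
    )


# Default thiram library: centres fixed by the analyte's Raman bands; the
# 1379 cm^-1 C-N stretch / CH3 deformation band dominates.  Relative heights
# of the other bands are free parameters of the generator.
_THIRAM_PEAKS = (
    PeakParams(0.7, 0.55, 562.0, 10.0),
    PeakParams(0.7, 0.45, 929.0, 10.0),
    PeakParams(0.7, 0.50, 1146.0, 10.0),
    PeakParams(0.7, 1.00, 1379.0, 10.0),
    PeakParams(0.7, 0.60, 1514.0, 10.0),
)

# R6G probe bands: C-H in-plane bend at 1362 and N-H in-plane bend at 1510.
_R6G_PEAKS = (
    PeakParams(0.7, 0.90, 1362.0, 9.0),
    PeakParams(0.7, 1.00, 1510.0, 9.0),
)

# Fruit-epidermis study: the 750 cm^-1 band tracks residue concentration;
# the remaining bands are fixed epidermis/matrix features.
_FRUIT_PEAKS = (
    PeakParams(0.7, 1.00, 750.0, 10.0),
    PeakParams(0.6, 2500.0, 830.0, 12.0, sensitive=False),
    PeakParams(0.6, 2200.0, 1165.0, 12.0, sensitive=False),
    PeakParams(0.6, 2800.0, 1560.0, 12.0, sensitive=False),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one simulated acquisition campaign.

    The defaults are the thiram study conditions: 550-1550 cm^-1 axis at
    1 cm^-1 steps, quantitation at 1379 cm^-1 with response
    I = 11644 N + 4536.5, a decaying-exponential fluorescence background
    and 1.5% multiplicative intensity noise (the substrate-reproducibility
    RSD regime of 1.4-1.6%).
    """

    axis_start: float = 550.0
    axis_stop: float = 1550.0
    axis_step: float = 1.0
    peak_library: tuple[PeakParams, ...] = _THIRAM_PEAKS
    quantitation_center: float = 1379.0
    calibration_slope: float = 11644.0
    calibration_intercept: float = 4536.5
    baseline_amplitude: float = 3000.0
    baseline_decay: float = 400.0
    baseline_offset: float = 200.0
    noise_rsd: float = 0.015
    additive_noise_sd: float = 0.0
    concentration_unit: str = "ug/mL"
    seed: int = 0

    def __post_init__(self):
        if self.axis_start >= self.axis_stop:
            raise ValueError("axis_start must be < axis_stop")
        if self.axis_step <= 0:
            raise ValueError("axis_step must be > 0")
        if self.noise_rsd < 0:
            raise ValueError("noise_rsd must be >= 0")
        if self.additive_noise_sd < 0:
            raise ValueError("additive_noise_sd must be >= 0")
        if not self.peak_library:
            raise ValueError("peak_library must not be empty")
        object.__setattr__(self, "peak_library", tuple(self.peak_library))

    def axis(self) -> np.ndarray:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)

    def baseline(self, nu: np.ndarray) -> np.ndarray:
        """Fluorescence background: decaying exponential plus offset."""
        return self.baseline_offset + self.baseline_amplitude * np.exp(
            -(nu - self.axis_start) / self.baseline_decay
        )

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        peaks = d.pop("peak_library", None)
        if peaks is not None:
            d["peak_library"] = tuple(
                p if isinstance(p, PeakParams) else PeakParams(**p) for p in peaks
            )
        return cls(**d)


def thiram_config(**overrides) -> GeneratorConfig:
    """Thiram standard-solution study (0.1-5.0 ug/mL on the default axis)."""
    return replace(GeneratorConfig(), **overrides)


def r6g_config(**overrides) -> GeneratorConfig:
    """R6G substrate-uniformity probe: two bands, quantitation at 1510 cm^-1.

    The nominal response is chosen so a 1e-4 mol/L probe gives peak
    intensities on the same raw-count scale as the thiram study.
    """
    cfg = GeneratorConfig(
        peak_library=_R6G_PEAKS,
        quantitation_center=1510.0,
        calibration_slope=2.0e8,
        calibration_intercept=0.0,
        concentration_unit="mol/L",
    )
    return replace(cfg, **overrides)


def fruit_epidermis_config(**overrides) -> GeneratorConfig:
    """Fruit-epidermis residue study: quantitation at 750 cm^-1 in ug/g."""
    cfg = GeneratorConfig(
        peak_library=_FRUIT_PEAKS,
        quantitation_center=750.0,
        calibration_slope=11644.0,
        calibration_intercept=4536.5,
        concentration_unit="ug/g",
    )
    return replace(cfg, **overrides)


def _clean_profile(cfg: GeneratorConfig, nu: np.ndarray, concentration: float):
    """Noise-free band superposition (baseline excluded)."""
    fixed = np.zeros_like(nu)
    sens = np.zeros_like(nu)
    for p in cfg.peak_library:
        prof = voigt_profile(nu, p)
        if p.sensitive:
            sens += prof
        else:
            fixed += prof
    wq = cfg.quantitation_center
    # evaluate both stacks at the quantitation centre itself (not the
    # nearest grid point) so the calibration equation holds exactly
    sens_q = sum(
        float(voigt_profile(np.array([wq]), p)[0]) for p in cfg.peak_library if p.sensitive
    )
    fixed_q = sum(
        float(voigt_profile(np.array([wq]), p)[0])
        for p in cfg.peak_library
        if not p.sensitive
    )
    if sens_q <= 0:
        raise ValueError("no concentration-sensitive intensity at the quantitation centre")
    target = cfg.calibration_slope * concentration + cfg.calibration_intercept
    scale = (target - fixed_q) / sens_q
    if scale < 0:
        raise ValueError(
            "fixed bands already exceed the calibration target at the quantitation centre"
        )
    return fixed + scale * sens


def generate_spectrum(
    cfg: GeneratorConfig,
    concentration: float,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
) -> Spectrum:
    """Simulate one spectrum at the given analyte concentration.

    With ``noise_rsd`` and ``additive_noise_sd`` zero the output is a
    deterministic function of (cfg, concentration).
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    nu = cfg.axis()
    clean = _clean_profile(cfg, nu, concentration) + cfg.baseline(nu)
    inten = clean
    if cfg.noise_rsd > 0:
        inten = clean * (1.0 + cfg.noise_rsd * rng.standard_normal(nu.shape))
    if cfg.additive_noise_sd > 0:
        inten = inten + cfg.additive_noise_sd * rng.standard_normal(nu.shape)
    return Spectrum(nu, inten, sample_id)


def generate_study(
    cfg: GeneratorConfig,
    concentrations,
    replicates: int = 1,
    rng: np.random.Generator | None = None,
) -> SpectrumSet:
    """Simulate a full concentration series with replicates.

    Returns |concentrations| x replicates spectra with concentration and
    replicate-group metadata attached; e.g. the fruit-epidermis design
    {0, 0.1, 0.5, 1.5, 10} ug/g x 4 replicates gives 20 spectra.
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("concentration list must not be empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    spectra, concs, groups = [], [], []
    k = 0
    for ci, c in enumerate(concentrations):
        for _ in range(replicates):
            spectra.append(generate_spectrum(cfg, c, rng, sample_id=f"s{k:03d}"))
            concs.append(c)
            groups.append(f"c{ci}")
            k += 1
    return SpectrumSet.from_spectra(
        spectra, concentrations=np.array(concs), unit=cfg.concentration_unit, groups=groups
    )


def generate_nonlinear_study(
    cfg: GeneratorConfig,
    concentrations,
    replicates: int = 1,
    sqrt_weight: float = 0.7,
    rng: np.random.Generator | None = None,
) -> SpectrumSet:
    """Concentration series whose spectral response is non-linear in N.

    The quantitation band responds to the effective concentration
    ``sqrt_weight * sqrt(N) + (1 - sqrt_weight) * N`` while the metadata
    records the true N, emulating sensor saturation where a linear
    calibration model is mis-specified.
    """
    if not 0.0 <= sqrt_weight <= 1.0:
        raise ValueError("sqrt_weight must lie in [0, 1]")
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("concentration list must not be empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    spectra, concs, groups = [], [], []
    k = 0
    for ci, c in enumerate(concentrations):
        c_eff = sqrt_weight * math.sqrt(c) + (1.0 - sqrt_weight) * c
        for _ in range(replicates):
            spectra.append(generate_spectrum(cfg, c_eff, rng, sample_id=f"s{k:03d}"))
            concs.append(c)
            groups.append(f"c{ci}")
            k += 1
    return SpectrumSet.from_spectra(
        spectra, concentrations=np.array(concs), unit=cfg.concentration_unit, groups=groups
    )
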