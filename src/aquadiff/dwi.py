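"""Diffusion-weighting schemes and ADC estimation.

Two routes to an apparent diffusion coefficient (ADC):

* from simulated walker displacements, via the narrow-pulse attenuation
  estimator E = <cos(gamma*delta*g*x)> with ADC = -ln(E)/b, cross-checked
  against the mean-square-displacement estimator <x^2>/(2*Delta_eff);
* from a measured multi-b decay curve, via the slope of ln(S) versus b.

The pulsed-gradient b-value is b = (gamma*delta*g)^2 * (Delta - delta/3)
and the effective diffusion time is Delta_eff = Delta - delta/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EstimationError, FittingError
from .units import GAMMA_1H

__all__ = [
    "GradientScheme",
    "DecayCurve",
    "ADCResult",
    "effective_diffusion_time",
    "display_diffusion_time",
    "b_value",
    "adc_from_trajectories",
    "adc_from_decay",
]


def effective_diffusion_time(Delta_ms: float, delta_ms: float) -> float:
    """Effective diffusion time Delta_eff = Delta - delta/3 (ms), exact."""
    if delta_ms <= 0:
        raise ConfigurationError("delta must be positive")
    t = Delta_ms - delta_ms / 3.0
    if t <= 0:
        raise ConfigurationError("Delta - delta/3 must be positive")
    return t


def display_diffusion_time(Delta_ms: float, delta_ms: float) -> int:
    """Delta_eff rounded to the nearest ms, as quoted in protocols
    (e.g. Delta=400, delta=7 -> 398 ms)."""
    return int(round(effective_diffusion_time(Delta_ms, delta_ms)))


@dataclass(frozen=True)
class GradientScheme:
    """Pulsed-gradient scheme (stimulated-echo convention).

    Parameters
    ----------
    g_T_per_m : gradient strength in T/m (1 mT/m = 1e-3 T/m).
    delta_ms : gradient pulse duration (default 7 ms).
    Delta_ms : interval between the dephasing and rephasing pulses.
    gamma : gyromagnetic ratio, rad s^-1 T^-1 (default 1H).
    axis : unit vector of the gradient direction.
    """

    g_T_per_m: float
    Delta_ms: float
    delta_ms: float = 7.0
    gamma: float = GAMMA_1H
    axis: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.g_T_per_m < 0:
            raise ConfigurationError("gradient strength must be >= 0")
        effective_diffusion_time(self.Delta_ms, self.delta_ms)  # validates
        a = np.asarray(self.axis, dtype=float)
        if not math.isclose(float(a @ a), 1.0, rel_tol=1e-6):
            raise ConfigurationError("axis must be a unit vector")

    @property
    def delta_eff_ms(self) -> float:
        return effective_diffusion_time(self.Delta_ms, self.delta_ms)

    @property
    def q_rad_per_m(self) -> float:
        """Dephasing wavenumber gamma*delta*g (rad/m)."""
        return self.gamma * self.delta_ms * 1e-3 * self.g_T_per_m

    @property
    def q_factor_s_per_m2(self) -> float:
        """q = (gamma*delta*g)^2 per unit time (rad^2/m^2)."""
        return self.q_rad_per_m**2

    @property
    def b_s_per_mm2(self) -> float:
        return b_value(self)

    @classmethod
    def for_b(
        cls,
        b_s_per_mm2: float,
        Delta_ms: float,
        delta_ms: float = 7.0,
        gamma: float = GAMMA_1H,
        axis: tuple = (1.0, 0.0, 0.0),
    ) -> "GradientScheme":
        """Scheme whose gradient strength realises the requested b-value."""
        if b_s_per_mm2 < 0:
            raise ConfigurationError("b must be >= 0")
        t_s = effective_diffusion_time(Delta_ms, delta_ms) * 1e-3
        b_SI = b_s_per_mm2 * 1e6  # s/m^2
        g = math.sqrt(b_SI / t_s) / (gamma * delta_ms * 1e-3)
        return cls(g_T_per_m=g, Delta_ms=Delta_ms, delta_ms=delta_ms, gamma=gamma, axis=axis)


def b_value(scheme: GradientScheme) -> float:
    """b = (gamma*delta*g)^2 * (Delta - delta/3), in s/mm^2."""
    b_SI = scheme.q_factor_s_per_m2 * scheme.delta_eff_ms * 1e-3  # s/m^2
    return b_SI * 1e-6


@dataclass
class DecayCurve:
    """Signal versus b-value, S(b), with positive signals."""

    b_values: np.ndarray  # s/mm^2
    signals: np.ndarray  # arbitrary units
    noise_sd: float | None = None

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.b_values.shape != self.signals.shape:
            raise ConfigurationError("b_values and signals must have equal length")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"b_s_per_mm2": self.b_values, "signal": self.signals}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DecayCurve":
        df = pd.read_csv(path)
        return cls(df["b_s_per_mm2"].to_numpy(), df["signal"].to_numpy())


@dataclass
class ADCResult:
    """An ADC estimate (um^2/s) with fit/estimator diagnostics.

    For decay-curve fits ``r_squared`` and ``intercept_S0`` describe the
    log-linear regression.  For trajectory estimates ``adc_msd`` carries the
    mean-square-displacement cross-check and ``discrepancy`` the relative
    difference between the two estimators.
    """

    adc: float
    intercept_S0: float | None = None
    r_squared: float | None = None
    standard_error: float = float("nan")
    adc_msd: float | None = None
    discrepancy: float | None = None


def adc_from_trajectories(
    displacements_um: np.ndarray, scheme: GradientScheme
) -> ADCResult:
    """ADC from walker displacements accumulated over the diffusion time.

    ``displacements_um`` are per-walker displacements; either a 1-D array
    already projected on the gradient axis or an (n, 3) array (projected
    internally).  The primary estimator is the narrow-pulse attenuation
    E = <cos(q x)>, ADC = -ln(E)/b; the MSD estimator <x^2>/(2*Delta_eff)
    is reported alongside.  The standard error propagates the Monte Carlo
    error of E.
    """
    x = np.asarray(displacements_um, dtype=float)
    if x.ndim == 2:
        x = x @ np.asarray(scheme.axis, dtype=float)
    n = len(x)
    if n < 100:
        raise EstimationError("need at least 100 walkers for an ADC estimate")
    if scheme.g_T_per_m <= 0:
        raise ConfigurationError("scheme gradient strength must be positive")
    q = scheme.q_rad_per_m  # rad/m
    phase = q * x * 1e-6  # x in um -> m
    cosns = np.cos(phase)
    E = float(np.mean(cosns))
    if E <= 0:
        raise EstimationError(
            "attenuation <= 0: gradient too strong for this ensemble size"
        )
    b_SI = scheme.q_factor_s_per_m2 * scheme.delta_eff_ms * 1e-3  # s/m^2
    adc_SI = -math.log(E) / b_SI  # m^2/s
    adc = adc_SI * 1e12  # um^2/s
    se_E = float(np.std(cosns, ddof=1)) / math.sqrt(n)
    se_adc = se_E / (E * b_SI) * 1e12
    msd = float(np.mean(x**2))  # um^2
    adc_msd = msd / (2.0 * scheme.delta_eff_ms) * 1e3  # um^2/s
    disc = (adc - adc_msd) / adc_msd if adc_msd > 0 else None
    return ADCResult(
        adc=adc,
        standard_error=se_adc,
        adc_msd=adc_msd,
        discrepancy=disc,
    )


def adc_from_decay(curve: DecayCurve) -> ADCResult:
    """ADC from the slope of ln(S) versus b (ordinary least squares).

    Returns the ADC in um^2/s (1e-3 mm^2/s = 1000 um^2/s), the intercept
    back-transformed to S0, the regression R^2 and the slope standard error
    (also in um^2/s).
    """
    b = np.asarray(curve.b_values, dtype=float)
    S = np.asarray(curve.signals, dtype=float)
    if len(np.unique(b)) < 2:
        raise FittingError("need at least 2 distinct b-values")
    if np.any(S <= 0):
        raise FittingError("signals must be positive for log-domain fitting")
    res = stats.linregress(b, np.log(S))
    adc = -res.slope * 1e6  # mm^2/s -> um^2/s
    return ADCResult(
        adc=float(adc),
        intercept_S0=float(math.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
        standard_error=float(res.stderr * 1e6) if res.stderr is not None else float("nan"),
    )
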