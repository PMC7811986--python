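"""Skin-contact modelling for contact-current exposure.

The total body impedance splits into the contact-skin impedance in series with
the internal body impedance, Z_Total = Z_Skin + Z_Intern.  Z_Skin behaves like
a parallel-RC slab: strongly touch-voltage dependent below 1 kHz and dropping
sharply above 10 kHz.  This motivates two body-model variants:

* Total-BM  -- the skin at the contact area is replaced by a 2-mm slice of the
  contact electrode carrying voltage-dependent skin properties (Z_Skin kept);
* Intern-BM -- the slice is removed so the electrode drives the subcutaneous
  tissue directly (Z_Skin neglected).

Which variant applies is a function of frequency and touch voltage
(:func:`select_body_model`); between 1 and 10 kHz at intact-skin voltages the
choice is a case-by-case judgement and is never made silently.

The voltage-dependent slice properties are tabulated at 25/50/100/220 V
(:data:`SKIN_TABLE`) and log-log interpolated in between; extrapolation is
refused because no data exists outside that range.  :func:`fit_skin_properties`
recovers such slice properties from reference |Z_Total|(f) curves.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import EPS0

__all__ = [
    "BodyModelMode",
    "SkinSliceProps",
    "ImpedanceCurve",
    "SKIN_TABLE",
    "select_body_model",
    "skin_props",
    "two_layer_impedance",
    "fit_skin_properties",
    "SkinFit",
]


class BodyModelMode(enum.Enum):
    """Exposure-scenario body-model regime."""

    TOTAL = "TOTAL"
    INTERN = "INTERN"
    CASE_BY_CASE = "CASE_BY_CASE"


@dataclass(frozen=True)
class SkinSliceProps:
    """Electric properties of the 2-mm contact-skin slice at one touch voltage."""

    touch_voltage: float  # V
    sigma: float  # S/m
    eps_r: float  # dimensionless

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.eps_r <= 1:
            raise ValueError(f"eps_r must be > 1, got {self.eps_r}")


#: Slice properties versus touch voltage: (U_t [V], sigma [S/m], eps_r).
SKIN_TABLE: tuple[tuple[float, float, float], ...] = (
    (25.0, 0.14e-3, 2.4e4),
    (50.0, 0.19e-3, 3.9e4),
    (100.0, 0.27e-3, 6.4e4),
    (220.0, 0.85e-3, 13.2e4),
)

_TAB_V = np.array([row[0] for row in SKIN_TABLE])
_TAB_SIGMA = np.array([row[1] for row in SKIN_TABLE])
_TAB_EPS = np.array([row[2] for row in SKIN_TABLE])

#: Valid touch-voltage range for intact-skin contact data, volts.
VOLTAGE_RANGE = (25.0, 220.0)


def select_body_model(frequency: float, touch_voltage: float) -> BodyModelMode:
    """Classify an exposure scenario into a body-model regime.

    Intact skin (U_t <= 220 V): Total-BM up to 1 kHz, case-by-case between
    1 and 10 kHz, Intern-BM above 10 kHz.  Above 220 V the skin breaks down
    and the Intern-BM applies at every frequency.  Interval boundaries are
    closed below and open above (1 kHz -> TOTAL, 10 kHz -> CASE_BY_CASE,
    220 V -> intact-skin row).
    """
    if frequency < 0:
        raise ValueError(f"frequency must be >= 0, got {frequency}")
    if touch_voltage <= 0:
        raise ValueError(f"touch_voltage must be > 0, got {touch_voltage}")
    if touch_voltage < VOLTAGE_RANGE[0]:
        warnings.warn(
            f"touch voltage {touch_voltage} V is below the validated range "
            f"[{VOLTAGE_RANGE[0]}, {VOLTAGE_RANGE[1]}] V; classification is "
            "extrapolated",
            stacklevel=2,
        )
    if touch_voltage > 220.0:
        return BodyModelMode.INTERN
    if frequency <= 1e3:
        return BodyModelMode.TOTAL
    if frequency <= 1e4:
        return BodyModelMode.CASE_BY_CASE
    return BodyModelMode.INTERN


def skin_props(touch_voltage: float) -> SkinSliceProps:
    """Slice properties at ``touch_voltage``; log-log interpolated between
    the tabulated voltages, exact at them, no extrapolation."""
    lo, hi = VOLTAGE_RANGE
    if not lo <= touch_voltage <= hi:
        raise ValueError(
            f"touch voltage {touch_voltage} V outside tabulated range [{lo}, {hi}] V; "
            "extrapolation is not supported"
        )
    logv = np.log(touch_voltage)
    sigma = float(np.exp(np.interp(logv, np.log(_TAB_V), np.log(_TAB_SIGMA))))
    eps_r = float(np.exp(np.interp(logv, np.log(_TAB_V), np.log(_TAB_EPS))))
    # exact at table nodes (avoid interpolation round-off)
    idx = np.nonzero(_TAB_V == touch_voltage)[0]
    if idx.size:
        sigma, eps_r = float(_TAB_SIGMA[idx[0]]), float(_TAB_EPS[idx[0]])
    return SkinSliceProps(touch_voltage=touch_voltage, sigma=sigma, eps_r=eps_r)


def two_layer_impedance(
    skin: SkinSliceProps,
    thickness: float,
    area: float,
    z_intern: complex,
    frequency: float,
) -> complex:
    """Z_Total of the slice-plus-body series circuit.

    The slice is a parallel-RC slab: Z_skin = t / (A * (sigma + j*w*eps0*eps_r))
    with ``thickness`` in mm and ``area`` in m^2.  Returns Z_skin + z_intern.
    """
    if thickness <= 0:
        raise ValueError(f"thickness must be > 0 mm, got {thickness}")
    if area <= 0:
        raise ValueError(f"area must be > 0 m^2, got {area}")
    if frequency < 0:
        raise ValueError(f"frequency must be >= 0, got {frequency}")
    omega = 2.0 * np.pi * frequency
    sigma_star = skin.sigma + 1j * omega * EPS0 * skin.eps_r
    z_skin = (thickness * 1e-3) / (area * sigma_star)
    return z_skin + z_intern


@dataclass(frozen=True)
class SkinFit:
    """Result of fitting slice properties at one touch voltage."""

    props: SkinSliceProps
    residual: float  # RMS relative error over the fitted points
    frequencies: tuple[float, ...]
    residual_profile: tuple[float, ...]  # signed relative error per frequency


@dataclass(frozen=True)
class ImpedanceCurve:
    """Reference |Z_Total| data: (frequency [Hz], touch voltage [V], |Z| [Ohm])."""

    points: tuple[tuple[float, float, float], ...]
    contact: str = ""  # free-text descriptor (current path, contact area)

    def __post_init__(self) -> None:
        for f, v, z in self.points:
            if f < 0:
                raise ValueError(f"negative frequency {f}")
            if z <= 0:
                raise ValueError(f"non-positive impedance magnitude {z}")

    def voltages(self) -> tuple[float, ...]:
        return tuple(sorted({v for _, v, _ in self.points}))

    def at_voltage(self, voltage: float) -> tuple[np.ndarray, np.ndarray]:
        pts = [(f, z) for f, v, z in self.points if v == voltage]
        pts.sort()
        freqs = np.array([p[0] for p in pts])
        mags = np.array([p[1] for p in pts])
        return freqs, mags


def fit_skin_properties(
    reference: ImpedanceCurve,
    z_intern_by_freq,
    thickness: float,
    area: float,
    max_frequency: float = 1e3,
) -> dict[float, SkinFit]:
    """Least-squares recovery of (sigma, eps_r) per touch voltage.

    For each voltage level in ``reference`` the relative error of the modelled
    |Z_Total| against the reference magnitudes is minimised over the points with
    frequency <= ``max_frequency`` (the band where the skin layer dominates).
    ``z_intern_by_freq`` maps frequency -> complex internal impedance (a dict
    or a callable).  The fit is performed in log-parameters so sigma and eps_r
    stay positive.  The signed residual-vs-frequency profile is reported so the
    frequency weighting of the recovered values stays visible.
    """
    if callable(z_intern_by_freq):
        z_intern = z_intern_by_freq
    else:
        table = dict(z_intern_by_freq)

        def z_intern(f: float) -> complex:
            return table[f]

    results: dict[float, SkinFit] = {}
    for voltage in reference.voltages():
        freqs, mags = reference.at_voltage(voltage)
        sel = freqs <= max_frequency
        freqs, mags = freqs[sel], mags[sel]
        if freqs.size < 2:
            raise ValueError(
                f"need >= 2 reference frequencies <= {max_frequency} Hz at "
                f"{voltage} V, got {freqs.size}"
            )
        zint = np.array([z_intern(f) for f in freqs])

        def model_mag(log_params: np.ndarray) -> np.ndarray:
            sigma, eps_r = np.exp(log_params)
            omega = 2.0 * np.pi * freqs
            sigma_star = sigma + 1j * omega * EPS0 * eps_r
            z = (thickness * 1e-3) / (area * sigma_star) + zint
            return np.abs(z)

        def residuals(log_params: np.ndarray) -> np.ndarray:
            return (model_mag(log_params) - mags) / mags

        # initial guess: slab resistance from the lowest-frequency point,
        # permittivity at the table scale
        r0 = max(mags[0] - abs(zint[0]), 1e-6 * mags[0])
        sigma0 = (thickness * 1e-3) / (area * r0)
        x0 = np.log([sigma0, 5e4])
        sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
        if not sol.success:
            raise RuntimeError(
                f"skin-property fit did not converge at {voltage} V: {sol.message} "
                f"(cost {sol.cost:.3e}, final params {np.exp(sol.x)})"
            )
        sigma, eps_r = np.exp(sol.x)
        if sigma <= 0 or not np.isfinite(sigma):
            raise RuntimeError(f"fitted sigma invalid at {voltage} V: {sigma}")
        profile = residuals(sol.x)
        results[voltage] = SkinFit(
            props=SkinSliceProps(touch_voltage=voltage, sigma=float(sigma), eps_r=float(eps_r)),
            residual=float(np.sqrt(np.mean(profile**2))),
            frequencies=tuple(float(f) for f in freqs),
            residual_profile=tuple(float(r) for r in profile),
        )
    return results
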