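"""Dual-density buoyancy assay analysis and seawater density.

In the dual-density method, anesthetized larvae are injected into a
ladder of test tubes, each layering seawater over (or under) a sucrose
solution of known density; a larva that sinks to the bottom of a tube is
denser than that solution.  Scoring every tube gives a daily frequency
distribution of larval body density whose 20 % and 80 % quantiles bound
the cohort's density range.  Buoyancy is the sign of (body density -
seawater density): negative means the inactive larva sinks.

Seawater density comes from the one-atmosphere international equation of
state (EOS-80 polynomial in practical salinity and temperature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import isotonic_regression


class Quantile(NamedTuple):
    """A quantile of the body-density distribution, possibly censored.

    ``censored`` is ``None`` for an interior estimate, ``"below"`` when
    the quantile lies below the lightest tube and ``"above"`` when it
    lies above the densest tube; ``value`` then holds the bounding tube
    density.
    """

    value: float
    censored: str | None = None

    def __str__(self) -> str:
        if self.censored == "below":
            return f"< {self.value:g}"
        if self.censored == "above":
            return f"> {self.value:g}"
        return f"{self.value:g}"


@dataclass
class DensityAssay:
    """Sink counts for one day of the density-gradient tube series."""

    day: float
    densities: np.ndarray  # tube solution densities, kg/m^3, strictly increasing
    n_sunk: np.ndarray
    n_total: np.ndarray
    salinity_psu: float = 38.0
    temperature_c: float = 20.0

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.n_sunk = np.asarray(self.n_sunk, dtype=int)
        self.n_total = np.asarray(self.n_total, dtype=int)
        if not (len(self.densities) == len(self.n_sunk) == len(self.n_total)):
            raise ValueError("densities, n_sunk and n_total must align")
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("tube densities must be strictly increasing")
        if np.any(self.n_sunk < 0) or np.any(self.n_sunk > self.n_total):
            raise ValueError("need 0 <= n_sunk <= n_total in every tube")
        if np.any(self.n_total < 1):
            raise ValueError("every tube must contain at least one larva")


@dataclass
class DensityDistribution:
    """Cumulative body-density distribution for one day, with quantiles."""

    day: float
    densities: np.ndarray
    frac_less_dense: np.ndarray  # monotone non-decreasing in density
    q20: Quantile
    q80: Quantile


def _quantile_from_cdf(
    densities: np.ndarray, cdf: np.ndarray, level: float, method: str = "interp"
) -> Quantile:
    """Locate the density at which ``cdf`` reaches ``level``.

    ``interp`` draws straight lines between adjacent tubes; ``step``
    returns the first tube density whose cumulative fraction reaches the
    level.  Levels outside the observed range are censored at the
    boundary tube.
    """
    if level > cdf[-1]:
        return Quantile(float(densities[-1]), "above")
    idx = int(np.argmax(cdf >= level))  # first tube at or above the level
    if idx == 0:
        if cdf[0] == level:
            return Quantile(float(densities[0]), None)
        return Quantile(float(densities[0]), "below")
    if method == "step":
        return Quantile(float(densities[idx]), None)
    f0, f1 = cdf[idx - 1], cdf[idx]
    d0, d1 = densities[idx - 1], densities[idx]
    frac = (level - f0) / (f1 - f0) if f1 > f0 else 1.0
    return Quantile(float(d0 + frac * (d1 - d0)), None)


def assay_to_distribution(
    assay: DensityAssay, method: str = "interp"
) -> DensityDistribution:
    """Build the daily body-density frequency distribution from an assay.

    The fraction of larvae less dense than each tube is
    ``1 - n_sunk / n_total``.  With only ~20 larvae per tube, counting
    noise can make the empirical fractions non-monotone; they are then
    monotonized by pooled-adjacent-violators (weighted by tube size)
    with a warning rather than rejected.  The 20 % and 80 % quantiles are
    located by linear interpolation between adjacent tube densities
    (``method="step"`` gives the discrete convention) and flagged
    censored when they fall outside the tube range.
    """
    frac = 1.0 - assay.n_sunk / assay.n_total
    if np.any(np.diff(frac) < 0):
        warnings.warn(
            "non-monotone sink fractions monotonized by pooled-adjacent-violators",
            stacklevel=2,
        )
        frac = isotonic_regression(frac, weights=assay.n_total.astype(float),
                                   increasing=True).x
    q20 = _quantile_from_cdf(assay.densities, frac, 0.20, method)
    q80 = _quantile_from_cdf(assay.densities, frac, 0.80, method)
    return DensityDistribution(
        day=assay.day,
        densities=assay.densities.copy(),
        frac_less_dense=np.asarray(frac, dtype=float),
        q20=q20,
        q80=q80,
    )


# EOS-80 one-atmosphere coefficients (UNESCO 1983): pure-water term and
# salinity expansion rho(S,T,0) = rho_w + B*S + C*S^1.5 + d0*S^2.
_RHO_W = (999.842594, 6.793952e-2, -9.095290e-3, 1.001685e-4, -1.120083e-6, 6.536332e-9)
_B = (8.24493e-1, -4.0899e-3, 7.6438e-5, -8.2467e-7, 5.3875e-9)
_C = (-5.72466e-3, 1.0227e-4, -1.6546e-6)
_D0 = 4.8314e-4


def seawater_density(salinity_psu: float, temperature_c: float) -> float:
    """Seawater density (kg/m^3) at one atmosphere from EOS-80.

    Valid for practical salinity 0-42 and temperature 0-40 degC.  The
    standard check value is rho(35, 5) = 1027.67547 kg/m^3.
    """
    s, t = float(salinity_psu), float(temperature_c)
    if not 0.0 <= s <= 42.0:
        raise ValueError("salinity outside the EOS-80 one-atmosphere range 0-42")
    if not 0.0 <= t <= 40.0:
        raise ValueError("temperature outside the EOS-80 one-atmosphere range 0-40 degC")
    rho_w = sum(c * t**i for i, c in enumerate(_RHO_W))
    b = sum(c * t**i for i, c in enumerate(_B))
    cc = sum(c * t**i for i, c in enumerate(_C))
    return rho_w + b * s + cc * s**1.5 + _D0 * s**2


@dataclass
class SeawaterState:
    """Reference seawater conditions for buoyancy classification.

    ``density`` defaults to the EOS-80 value at (salinity, temperature)
    but may be supplied directly to match a lab-measured reference.
    """

    salinity_psu: float = 38.0
    temperature_c: float = 20.0
    density: float | None = None

    def __post_init__(self) -> None:
        if self.density is None:
            self.density = seawater_density(self.salinity_psu, self.temperature_c)


def buoyancy_class(
    body_density: float,
    seawater: SeawaterState | float,
    neutral_tolerance: float = 0.5,
) -> tuple[str, float]:
    """Classify buoyancy from the body-seawater density difference.

    Returns ``(label, margin)`` where margin = body - seawater (kg/m^3).
    ``negative`` buoyancy (larva sinks) when the margin exceeds the
    neutrality tolerance, ``positive`` (floats) when it is below minus
    the tolerance, ``neutral`` otherwise.
    """
    sw = seawater.density if isinstance(seawater, SeawaterState) else float(seawater)
    if not (np.isfinite(body_density) and np.isfinite(sw)):
        raise ValueError("densities must be finite")
    margin = float(body_density - sw)
    if margin > neutral_tolerance:
        return "negative", margin
    if margin < -neutral_tolerance:
        return "positive", margin
    return "neutral", margin
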