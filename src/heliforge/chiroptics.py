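"""Closed-form chiroptical relations.

For an isotropic sample the absorption dissymmetry factor of a transition
is, in terms of the electric (mu) and magnetic (m) transition dipole
moments and the angle theta between them,

    g_abs = 4 |m| |mu| cos(theta) / (|mu|^2 + |m|^2)

bounded by +/-2, with the limit reached only for |mu| = |m| (in consistent
absolute units) and exactly parallel or antiparallel vectors — the pure
left/right circularly polarised absorbing transition. Typical organic
chromophores sit near g ~ 1e-3..1e-4 because |m| is roughly three orders
of magnitude below |mu| once both are expressed in cgs.

Moments are stored in the conventional scaled units in which they are
reported (|mu| in 1e-18 esu cm, |m| in 1e-20 erg/G) and converted to
absolute cgs inside the formula.

Chiroptical quantities of the two enantiomers differ only in sign:
:func:`enantiomer_flip` maps the property record of a P-helicene to that
of its M counterpart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateTransitionError, ValidationError

__all__ = [
    "MU_UNIT",
    "M_UNIT",
    "TransitionMoments",
    "PropertyRecord",
    "PROPERTY_NAMES",
    "g_from_moments",
    "enantiomer_flip",
    "ecd_curve",
]

MU_UNIT = 1e-18  # esu cm per stored unit of |mu|
M_UNIT = 1e-20   # erg/G per stored unit of |m|

#: Column order of the nine modelled properties.
PROPERTY_NAMES: tuple[str, ...] = (
    "R_plus", "R_minus", "R_1",
    "lambda_plus", "lambda_minus", "lambda_1",
    "m_abs", "mu_abs", "g_abs",
)


@dataclass(frozen=True)
class TransitionMoments:
    """(|mu|, |m|, theta) of one electronic transition.

    mu_abs is in 1e-18 esu cm, m_abs in 1e-20 erg/G, theta in radians
    within [0, pi].
    """

    mu_abs: float
    m_abs: float
    theta: float

    def __post_init__(self) -> None:
        if self.mu_abs < 0 or self.m_abs < 0:
            raise ValidationError("moment magnitudes must be non-negative")
        if not 0 <= self.theta <= math.pi + 1e-12:
            raise ValidationError("theta must lie in [0, pi]")


@dataclass(frozen=True)
class PropertyRecord:
    """The nine modelled photophysical/chiroptical quantities.

    R_plus / R_minus are the largest positive and negative rotatory
    strengths across the spectrum (1e-40 esu cm erg/G) at wavelengths
    lambda_plus / lambda_minus (nm); R_1 / lambda_1 describe the
    lowest-energy transition; m_abs / mu_abs are its S0->S1 transition
    moments (scaled units as above); g_abs its dissymmetry factor.
    """

    R_plus: float
    R_minus: float
    R_1: float
    lambda_plus: float
    lambda_minus: float
    lambda_1: float
    m_abs: float
    mu_abs: float
    g_abs: float

    def __post_init__(self) -> None:
        if self.R_plus < 0:
            raise ValidationError("R_plus must be >= 0 (maximum positive R)")
        if self.R_minus > 0:
            raise ValidationError("R_minus must be <= 0 (maximum negative R)")
        for lam in (self.lambda_plus, self.lambda_minus, self.lambda_1):
            if not lam > 0:
                raise ValidationError("wavelengths must be positive")
        if self.m_abs < 0 or self.mu_abs < 0:
            raise ValidationError("moment magnitudes must be non-negative")
        if abs(self.g_abs) > 2 + 1e-9:
            raise ValidationError("|g_abs| cannot exceed 2")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PROPERTY_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PropertyRecord":
        return cls(**dict(zip(PROPERTY_NAMES, map(float, values))))


def g_from_moments(t: TransitionMoments) -> float:
    """Dissymmetry factor 4|m||mu|cos(theta) / (|mu|^2 + |m|^2).

    Both moments are converted to absolute cgs units before combination;
    the result is dimensionless and bounded by +/-2. Raises
    :class:`DegenerateTransitionError` when both magnitudes vanish.
    """
    mu = t.mu_abs * MU_UNIT
    m = t.m_abs * M_UNIT
    if mu == 0.0 and m == 0.0:
        raise DegenerateTransitionError("both transition moments are zero")
    # rescale by max(mu, m) to avoid underflow of mu*m in denormal range
    s = max(mu, m)
    mu, m = mu / s, m / s
    return 4.0 * m * mu * math.cos(t.theta) / (mu * mu + m * m)


def enantiomer_flip(rec: PropertyRecord) -> PropertyRecord:
    """Property record of the opposite helical sense.

    All chiroptical signs invert. Because R_plus / R_minus are defined as
    the spectrum's extreme positive / negative rotatory strengths, the
    sign inversion swaps their roles (and the associated wavelengths):
    the M-enantiomer's strongest positive band sits where the P's
    strongest negative band was. Magnitude-valued fields are unchanged
    and the map is an involution.
    """
    return PropertyRecord(
        R_plus=-rec.R_minus,
        R_minus=-rec.R_plus,
        R_1=-rec.R_1,
        lambda_plus=rec.lambda_minus,
        lambda_minus=rec.lambda_plus,
        lambda_1=rec.lambda_1,
        m_abs=rec.m_abs,
        mu_abs=rec.mu_abs,
        g_abs=-rec.g_abs,
    )


def ecd_curve(
    transitions: Iterable[tuple[float, float]],
    width_nm: float = 15.0,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Broaden discrete transitions into a continuous ECD-style curve.

    Each (wavelength_nm, rotatory_strength) pair contributes a Gaussian
    centred at its wavelength with standard deviation ``width_nm`` and
    amplitude proportional to its rotatory strength; the curve is the
    pointwise sum (hence linear in the transition list). Returns
    ``(grid, curve)``. An empty transition list yields the zero curve.
    """
    if width_nm <= 0:
        raise ValueError("width_nm must be positive")
    trans = [(float(w), float(r)) for w, r in transitions]
    for w, _ in trans:
        if w <= 0:
            raise ValidationError("transition wavelengths must be positive")
    if grid is None:
        if trans:
            lo = min(w for w, _ in trans) - 4 * width_nm
            hi = max(w for w, _ in trans) + 4 * width_nm
        else:
            lo, hi = 200.0, 700.0
        grid = np.linspace(max(lo, 1.0), hi, 2000)
    grid = np.asarray(grid, dtype=float)
    curve = np.zeros_like(grid)
    for w, r in trans:
        curve += r * np.exp(-0.5 * ((grid - w) / width_nm) ** 2)
    return grid, curve


def export_curve_csv(path, grid: np.ndarray, curve: np.ndarray) -> None:
    """Write a broadened curve as two-column CSV (wavelength_nm, signal)."""
    import pandas as pd

    pd.DataFrame(
        {"wavelength_nm": grid, "delta_epsilon_arbitrary": curve}
    ).to_csv(path, index=False)
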