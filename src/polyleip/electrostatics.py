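"""Screened electrostatics for site-site long-range interactions.

Charged sites interact through the Debye-Huckel potential

    phi(d) = (1/ln 10) * (l_B / d) * exp(-kappa * d)

expressed in decimal-log energy units (statistical weight = 10**(-phi)),
with l_B the Bjerrum length (0.7 nm in water at 298 K) and kappa the
inverse Debye screening length, kappa**-1 [nm] = 0.304 / sqrt(I [M]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScreenedPotential", "debye_kappa", "dh_pair", "ConfigurationError"]

LN10 = np.log(10.0)

#: Debye-length prefactor for water at 298 K: kappa^-1 = 0.304/sqrt(I) nm.
DEBYE_PREFACTOR_NM = 0.304


class ConfigurationError(ValueError):
    """Raised when physical input parameters are out of range."""


def debye_kappa(ionic_strength: float) -> float:
    """Inverse Debye length kappa in nm^-1 at ionic strength I (mol/L)."""
    if ionic_strength <= 0:
        raise ConfigurationError(
            f"ionic strength must be positive, got {ionic_strength!r}"
        )
    return float(np.sqrt(ionic_strength) / DEBYE_PREFACTOR_NM)


@dataclass(frozen=True)
class ScreenedPotential:
    """Debye-Huckel pair potential parameters.

    Attributes
    ----------
    bjerrum_length : float
        Bjerrum length in nm (> 0).
    kappa : float
        Inverse Debye screening length in nm^-1 (>= 0); 0 means an
        unscreened Coulomb tail.
    """

    bjerrum_length: float
    kappa: float

    def __post_init__(self) -> None:
        if self.bjerrum_length <= 0:
            raise ConfigurationError("bjerrum_length must be positive")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be non-negative")

    @classmethod
    def from_ionic_strength(
        cls, ionic_strength: float, bjerrum_length: float = 0.7
    ) -> "ScreenedPotential":
        return cls(bjerrum_length=bjerrum_length, kappa=debye_kappa(ionic_strength))


def dh_pair(d, pot: ScreenedPotential):
    """Screened pair interaction phi(d) in decimal-log units.

    Accepts a scalar separation or an array of separations (nm); all must
    be strictly positive (a non-positive distance signals a geometry bug
    upstream and raises).
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise ValueError("pair separation must be strictly positive")
    out = (pot.bjerrum_length / d_arr) * np.exp(-pot.kappa * d_arr) / LN10
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(out)
    return out
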