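"""Unit-cell geometry: reciprocal metric tensor and resolution variables.

The weighting scheme's resolution-dependent terms (the ``q`` factor switched
by parameter *c*, and the additive *e* term) need sin(theta)/lambda per
reflection, which for a triclinic cell is ``s = 1/(2d)`` with
``1/d^2 = h^T G* h`` and ``G*`` the reciprocal metric tensor.

Angles are taken in degrees everywhere in this package (the universal
crystallographic file convention) and converted to radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["UnitCell", "ReciprocalMetric", "reciprocal_metric", "sin_theta_over_lambda"]


@dataclass(frozen=True)
class UnitCell:
    """Direct-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"cell length {name} must be > 0, got {getattr(self, name)}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValidationError(f"cell angle {name} must lie in (0, 180), got {ang}")
        if self._volume_factor_sq() <= 0:
            raise ValidationError("degenerate cell: direct metric tensor is not positive definite")

    def _volume_factor_sq(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        return self.a * self.b * self.c * math.sqrt(self._volume_factor_sq())

    def direct_metric(self) -> np.ndarray:
        """The 3x3 direct metric tensor G (Angstrom^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )


@dataclass(frozen=True)
class ReciprocalMetric:
    """Independent components of the symmetric reciprocal metric tensor G*
    (Angstrom^-2), with ``1/d^2(hkl) = h^T G* h``."""

    g11: float
    g22: float
    g33: float
    g12: float
    g13: float
    g23: float

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.g11, self.g12, self.g13],
                [self.g12, self.g22, self.g23],
                [self.g13, self.g23, self.g33],
            ]
        )

    def inv_d_squared(self, h, k, l) -> np.ndarray | float:
        """Evaluate ``1/d^2 = h^T G* h`` for scalar or array indices."""
        h = np.asarray(h, dtype=float)
        k = np.asarray(k, dtype=float)
        l = np.asarray(l, dtype=float)
        return (
            self.g11 * h * h
            + self.g22 * k * k
            + self.g33 * l * l
            + 2.0 * (self.g12 * h * k + self.g13 * h * l + self.g23 * k * l)
        )


def reciprocal_metric(cell: UnitCell) -> ReciprocalMetric:
    """Reciprocal metric tensor via the closed triclinic formulas.

    Reciprocal lengths: a* = bc sin(alpha)/V (cyclic); reciprocal angle
    cosines: cos(alpha*) = (cos(beta)cos(gamma) - cos(alpha)) /
    (sin(beta)sin(gamma)) (cyclic).  Then G*_11 = a*^2 and
    G*_12 = a* b* cos(gamma*) etc.
    """
    sa, sb, sg = (math.sin(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    vol = cell.volume  # raises via UnitCell validation if degenerate
    a_s = cell.b * cell.c * sa / vol
    b_s = cell.a * cell.c * sb / vol
    c_s = cell.a * cell.b * sg / vol
    cos_as = (cb * cg - ca) / (sb * sg)
    cos_bs = (ca * cg - cb) / (sa * sg)
    cos_gs = (ca * cb - cg) / (sa * sb)
    return ReciprocalMetric(
        g11=a_s * a_s,
        g22=b_s * b_s,
        g33=c_s * c_s,
        g12=a_s * b_s * cos_gs,
        g13=a_s * c_s * cos_bs,
        g23=b_s * c_s * cos_as,
    )


def sin_theta_over_lambda(cell: UnitCell, h: int, k: int, l: int):
    """Resolution variable ``s = sin(theta)/lambda = 1/(2d)`` in inverse
    Angstrom for one reflection or arrays of indices."""
    h_arr = np.asarray(h)
    if np.any((np.asarray(h) == 0) & (np.asarray(k) == 0) & (np.asarray(l) == 0)):
        raise ValidationError("sin(theta)/lambda undefined for the (0,0,0) reflection")
    inv_d2 = reciprocal_metric(cell).inv_d_squared(h, k, l)
    s = 0.5 * np.sqrt(inv_d2)
    return float(s) if np.isscalar(h) or h_arr.ndim == 0 else s
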