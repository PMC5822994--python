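"""Reflection containers.

A :class:`ReflectionSet` holds the per-reflection data of a structure-factor
file (Miller indices, Fo^2, sigma(Fo^2), Fc^2) as parallel numpy arrays on
the file's native refinement scale, together with the optional metadata the
downstream operations need: the unit cell (for resolution cut-offs and the
weighting scheme's resolution terms), the wavelength, and the number of
independent refined parameters ``p``.

Values are never rescaled between Fo^2 and Fc^2; any scale factor is assumed
absorbed by the upstream refinement.  Negative Fo^2 measurements are legal
(weak reflections) and are retained; they are clamped to zero only inside
the composite intensity P and inside |Fo|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .cell import UnitCell, sin_theta_over_lambda
from .errors import ValidationError

__all__ = ["Reflection", "ReflectionSet"]


@dataclass(frozen=True)
class Reflection:
    """One measured reflection on the refinement scale of its file."""

    h: int
    k: int
    l: int
    f_obs_sq: float
    sigma_f_obs_sq: float
    f_calc_sq: float

    def __post_init__(self) -> None:
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValidationError("reflection indices (0,0,0) are not allowed")
        if not self.sigma_f_obs_sq > 0:
            raise ValidationError(
                f"sigma(Fo^2) must be > 0 for ({self.h},{self.k},{self.l}), "
                f"got {self.sigma_f_obs_sq}"
            )
        if self.f_calc_sq < 0:
            raise ValidationError(
                f"Fc^2 must be >= 0 for ({self.h},{self.k},{self.l}), got {self.f_calc_sq}"
            )


class ReflectionSet:
    """Ordered collection of reflections plus refinement metadata.

    Parameters
    ----------
    hkl : (n, 3) integer array of Miller indices.
    f_obs_sq, sigma_f_obs_sq, f_calc_sq : (n,) float arrays.
    cell : optional :class:`UnitCell`; required for resolution quantities.
    wavelength : optional wavelength in Angstrom.
    n_params : optional count of independent refined parameters.
    """

    def __init__(
        self,
        hkl: np.ndarray,
        f_obs_sq: np.ndarray,
        sigma_f_obs_sq: np.ndarray,
        f_calc_sq: np.ndarray,
        cell: Optional[UnitCell] = None,
        wavelength: Optional[float] = None,
        n_params: Optional[int] = None,
    ) -> None:
        hkl = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        f_obs_sq = np.asarray(f_obs_sq, dtype=float)
        sigma_f_obs_sq = np.asarray(sigma_f_obs_sq, dtype=float)
        f_calc_sq = np.asarray(f_calc_sq, dtype=float)
        n = hkl.shape[0]
        if hkl.shape != (n, 3):
            raise ValidationError(f"hkl must be (n, 3), got {hkl.shape}")
        if not (f_obs_sq.shape == sigma_f_obs_sq.shape == f_calc_sq.shape == (n,)):
            raise ValidationError("f_obs_sq, sigma_f_obs_sq, f_calc_sq must all have shape (n,)")
        if n == 0:
            raise ValidationError("a ReflectionSet must contain at least one reflection")
        zero = np.flatnonzero(~hkl.any(axis=1))
        if zero.size:
            raise ValidationError(f"reflection indices (0,0,0) at rows {zero.tolist()}")
        bad_sig = np.flatnonzero(sigma_f_obs_sq <= 0)
        if bad_sig.size:
            idx = [tuple(int(x) for x in hkl[i]) for i in bad_sig[:10]]
            raise ValidationError(f"sigma(Fo^2) <= 0 for reflections {idx}")
        bad_fc = np.flatnonzero(f_calc_sq < 0)
        if bad_fc.size:
            idx = [tuple(int(x) for x in hkl[i]) for i in bad_fc[:10]]
            raise ValidationError(f"Fc^2 < 0 for reflections {idx}")
        uniq = np.unique(hkl, axis=0)
        if uniq.shape[0] != n:
            raise ValidationError("duplicate (h,k,l) triples in reflection set")
        self.hkl = hkl
        self.f_obs_sq = f_obs_sq
        self.sigma_f_obs_sq = sigma_f_obs_sq
        self.f_calc_sq = f_calc_sq
        self._cell = cell
        self.wavelength = wavelength
        self.n_params = n_params
        self._s_cache: Optional[np.ndarray] = None

    # -- metadata -----------------------------------------------------------

    @property
    def cell(self) -> Optional[UnitCell]:
        return self._cell

    @cell.setter
    def cell(self, value: Optional[UnitCell]) -> None:
        # changing the cell invalidates cached resolution values
        self._cell = value
        self._s_cache = None

    @property
    def s(self) -> np.ndarray:
        """sin(theta)/lambda per reflection (inverse Angstrom), cached."""
        if self._s_cache is None:
            if self._cell is None:
                raise ValidationError("resolution requested but no unit cell is set")
            self._s_cache = np.asarray(
                sin_theta_over_lambda(self._cell, self.hkl[:, 0], self.hkl[:, 1], self.hkl[:, 2])
            )
        return self._s_cache

    # -- sequence protocol --------------------------------------------------

    def __len__(self) -> int:
        return self.hkl.shape[0]

    def __getitem__(self, i: int) -> Reflection:
        return Reflection(
            h=int(self.hkl[i, 0]),
            k=int(self.hkl[i, 1]),
            l=int(self.hkl[i, 2]),
            f_obs_sq=float(self.f_obs_sq[i]),
            sigma_f_obs_sq=float(self.sigma_f_obs_sq[i]),
            f_calc_sq=float(self.f_calc_sq[i]),
        )

    def __iter__(self) -> Iterator[Reflection]:
        return (self[i] for i in range(len(self)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReflectionSet):
            return NotImplemented
        return (
            np.array_equal(self.hkl, other.hkl)
            and np.array_equal(self.f_obs_sq, other.f_obs_sq)
            and np.array_equal(self.sigma_f_obs_sq, other.sigma_f_obs_sq)
            and np.array_equal(self.f_calc_sq, other.f_calc_sq)
        )

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_reflections(
        cls,
        reflections: Sequence[Reflection],
        cell: Optional[UnitCell] = None,
        wavelength: Optional[float] = None,
        n_params: Optional[int] = None,
    ) -> "ReflectionSet":
        if not reflections:
            raise ValidationError("empty reflection list")
        hkl = np.array([(r.h, r.k, r.l) for r in reflections], dtype=np.int64)
        return cls(
            hkl=hkl,
            f_obs_sq=np.array([r.f_obs_sq for r in reflections]),
            sigma_f_obs_sq=np.array([r.sigma_f_obs_sq for r in reflections]),
            f_calc_sq=np.array([r.f_calc_sq for r in reflections]),
            cell=cell,
            wavelength=wavelength,
            n_params=n_params,
        )

    def subset(self, mask: np.ndarray) -> "ReflectionSet":
        """Order-preserving subset selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(self),):
            raise ValidationError("mask length must match reflection count")
        if not mask.any():
            raise ValidationError("subset would be empty")
        return ReflectionSet(
            hkl=self.hkl[mask],
            f_obs_sq=self.f_obs_sq[mask],
            sigma_f_obs_sq=self.sigma_f_obs_sq[mask],
            f_calc_sq=self.f_calc_sq[mask],
            cell=self._cell,
            wavelength=self.wavelength,
            n_params=self.n_params,
        )

    def reordered(self, order: np.ndarray) -> "ReflectionSet":
        """Copy with rows permuted by ``order`` (an index array)."""
        order = np.asarray(order)
        return ReflectionSet(
            hkl=self.hkl[order],
            f_obs_sq=self.f_obs_sq[order],
            sigma_f_obs_sq=self.sigma_f_obs_sq[order],
            f_calc_sq=self.f_calc_sq[order],
            cell=self._cell,
            wavelength=self.wavelength,
            n_params=self.n_params,
        )
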