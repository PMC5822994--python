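"""The SHELXL-style weighting scheme and refinement statistics.

For a refinement on F^2 each reflection receives the weight

    w = q / [ sigma^2(Fo^2) + (a P)^2 + b P + d + e * s ]

where ``s = sin(theta)/lambda``, P is the composite intensity

    P = f * max(Fo^2, 0) + (1 - f) * Fc^2

and q is a resolution factor switched by the sign of parameter c:
q = 1 for c = 0, q = exp(c s^2) for c > 0 and q = 1 - exp(c s^2) for
c < 0.  The mixing fraction f defaults to 1/3, the value known to reduce
the bias of weighting on Fc^2 or Fo^2 alone.  With a = b = c = d = e = 0
the scheme reduces exactly to statistical weights w = 1/sigma^2(Fo^2).

The tool optimizes a and b only; c, d and e stay fixed (zero by default).
The resolution term is e * (sin(theta)/lambda) to the first power.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ValidationError
from .reflections import Reflection, ReflectionSet

__all__ = [
    "WeightingScheme",
    "FilterSpec",
    "FilterCounts",
    "RefinementStats",
    "composite_p",
    "q_factor",
    "weight",
    "weight_array",
    "apply_filters",
    "wgoof",
    "goof_statistical",
    "refinement_stats",
]


@dataclass(frozen=True)
class WeightingScheme:
    """The six parameters a-f of the SHELXL-style weight.

    ``a`` and ``b`` scale the quadratic and linear intensity-dependent
    variance inflation; ``c`` switches the resolution factor q; ``d`` is a
    constant variance offset; ``e`` (Angstrom) scales a linear resolution
    term; ``f`` in [0, 1] blends Fo^2 and Fc^2 into P.  The default
    ``a = 0.1`` is a conventional search starting placeholder, not an
    optimized value.
    """

    a: float = 0.1
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 0.0
    f: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValidationError(f"mixing fraction f must lie in [0, 1], got {self.f}")

    def with_ab(self, a: float, b: float) -> "WeightingScheme":
        return replace(self, a=a, b=b)

    @property
    def is_statistical(self) -> bool:
        return self.a == self.b == self.c == self.d == self.e == 0.0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in "abcdef"}


def composite_p(f_obs_sq, f_calc_sq, f: float = 1.0 / 3.0):
    """Composite intensity ``P = f * max(Fo^2, 0) + (1 - f) * Fc^2``.

    Negative Fo^2 measurements are clamped to zero inside P only.
    Accepts scalars or arrays.
    """
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"mixing fraction f must lie in [0, 1], got {f}")
    fo = np.maximum(np.asarray(f_obs_sq, dtype=float), 0.0)
    p = f * fo + (1.0 - f) * np.asarray(f_calc_sq, dtype=float)
    return float(p) if p.ndim == 0 else p


def q_factor(c: float, s):
    """Resolution factor q of the weight, switched by the sign of c.

    q = 1 when c = 0; q = exp(c s^2) when c > 0; q = 1 - exp(c s^2) when
    c < 0 (which vanishes at s = 0, where the weight is undefined).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValidationError("sin(theta)/lambda must be >= 0")
    if c == 0.0:
        q = np.ones_like(s)
    elif c > 0.0:
        q = np.exp(c * s * s)
    else:
        q = 1.0 - np.exp(c * s * s)
        if np.any(q <= 0.0):
            raise ValidationError("q = 0 for c < 0 at s = 0: weight undefined")
    return float(q) if q.ndim == 0 else q


def _denominator(f_obs_sq, sigma_f_obs_sq, f_calc_sq, scheme: WeightingScheme, s):
    p = composite_p(f_obs_sq, f_calc_sq, scheme.f)
    sig = np.asarray(sigma_f_obs_sq, dtype=float)
    den = sig * sig + (scheme.a * p) ** 2 + scheme.b * p + scheme.d
    if scheme.e != 0.0:
        den = den + scheme.e * np.asarray(s, dtype=float)
    return den


def weight(refl: Reflection, scheme: WeightingScheme, s: float = 0.0) -> float:
    """Weight of a single reflection; ``s`` is its sin(theta)/lambda
    (only consulted when c or e is nonzero)."""
    den = _denominator(refl.f_obs_sq, refl.sigma_f_obs_sq, refl.f_calc_sq, scheme, s)
    if den <= 0:
        raise ValidationError(
            f"non-positive weight denominator {den} for reflection "
            f"({refl.h},{refl.k},{refl.l})"
        )
    return float(q_factor(scheme.c, s) / den)


def weight_array(rs: ReflectionSet, scheme: WeightingScheme) -> np.ndarray:
    """Per-reflection weights for a whole set (vectorized).

    The cell is only required when c or e is nonzero (resolution enters the
    weight); otherwise the weight is resolution independent.
    """
    needs_s = scheme.c != 0.0 or scheme.e != 0.0
    s = rs.s if needs_s else np.zeros(len(rs))
    den = _denominator(rs.f_obs_sq, rs.sigma_f_obs_sq, rs.f_calc_sq, scheme, s)
    bad = np.flatnonzero(den <= 0)
    if bad.size:
        idx = [tuple(int(x) for x in rs.hkl[i]) for i in bad[:10]]
        raise ValidationError(f"non-positive weight denominator for reflections {idx}")
    q = q_factor(scheme.c, s) if needs_s else 1.0
    return q / den


# -- data cut-offs ----------------------------------------------------------


@dataclass(frozen=True)
class FilterSpec:
    """Cut-offs on intensity, intensity over standard uncertainty, and
    resolution; an unset field imposes no cut."""

    min_intensity: Optional[float] = None
    min_i_over_sigma: Optional[float] = None
    max_sin_theta_over_lambda: Optional[float] = None


@dataclass(frozen=True)
class FilterCounts:
    """How many reflections each criterion removed (a reflection failing
    several criteria is counted under each)."""

    n_input: int
    n_kept: int
    removed_intensity: int
    removed_i_over_sigma: int
    removed_resolution: int

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed_intensity": self.removed_intensity,
            "removed_i_over_sigma": self.removed_i_over_sigma,
            "removed_resolution": self.removed_resolution,
        }


def apply_filters(
    rs: ReflectionSet, spec: FilterSpec, return_counts: bool = False
):
    """Apply the cut-offs of ``spec``, preserving reflection order.

    A reflection is kept iff Fo^2 >= min_intensity, Fo^2/sigma >=
    min_i_over_sigma and s <= max_sin_theta_over_lambda (for whichever cuts
    are set).  Raises if nothing survives.  With ``return_counts`` the
    per-criterion removal counts are returned alongside the subset.
    """
    n = len(rs)
    keep = np.ones(n, dtype=bool)
    removed_i = removed_ios = removed_res = 0
    if spec.min_intensity is not None:
        ok = rs.f_obs_sq >= spec.min_intensity
        removed_i = int((~ok).sum())
        keep &= ok
    if spec.min_i_over_sigma is not None:
        ok = rs.f_obs_sq / rs.sigma_f_obs_sq >= spec.min_i_over_sigma
        removed_ios = int((~ok).sum())
        keep &= ok
    if spec.max_sin_theta_over_lambda is not None:
        ok = rs.s <= spec.max_sin_theta_over_lambda
        removed_res = int((~ok).sum())
        keep &= ok
    counts = FilterCounts(
        n_input=n,
        n_kept=int(keep.sum()),
        removed_intensity=removed_i,
        removed_i_over_sigma=removed_ios,
        removed_resolution=removed_res,
    )
    if not keep.any():
        raise ValidationError(
            f"filters removed every reflection: {counts.as_dict()}"
        )
    out = rs.subset(keep) if not keep.all() else rs
    return (out, counts) if return_counts else out


# -- refinement statistics --------------------------------------------------


@dataclass(frozen=True)
class RefinementStats:
    """Conventional fit statistics.

    R1 is on |F| (with |Fo| = sqrt(max(Fo^2, 0))); wR2 and wGooF use the
    applied scheme's weights; GooF always uses statistical weights
    1/sigma^2, so the two goodness-of-fit values coincide exactly under a
    statistical scheme.
    """

    r1: float
    wr2: float
    goof: float
    wgoof: float
    n: int
    p: int

    def as_dict(self) -> dict:
        return {
            "r1": self.r1,
            "wr2": self.wr2,
            "goof": self.goof,
            "wgoof": self.wgoof,
            "n": self.n,
            "p": self.p,
        }


def wgoof(rs: ReflectionSet, weights: np.ndarray, p: int) -> float:
    """Weighted goodness of fit sqrt(sum(w * (Fo^2 - Fc^2)^2) / (n - p))."""
    weights = np.asarray(weights, dtype=float)
    n = len(rs)
    if weights.shape != (n,):
        raise ValidationError("need exactly one weight per reflection")
    if np.any(weights <= 0):
        raise ValidationError("weights must be strictly positive")
    if n <= p:
        raise ValidationError(f"need more reflections than parameters (n={n}, p={p})")
    delta = rs.f_obs_sq - rs.f_calc_sq
    return float(np.sqrt(np.sum(weights * delta * delta) / (n - p)))


def goof_statistical(rs: ReflectionSet, p: int) -> float:
    """Goodness of fit under statistical weights w = 1/sigma^2."""
    return wgoof(rs, 1.0 / rs.sigma_f_obs_sq**2, p)


def refinement_stats(rs: ReflectionSet, scheme: WeightingScheme, p: int) -> RefinementStats:
    """R1, wR2, GooF and wGooF for a reflection set under ``scheme``."""
    n = len(rs)
    if n <= p:
        raise ValidationError(f"need more reflections than parameters (n={n}, p={p})")
    w = weight_array(rs, scheme)
    delta = rs.f_obs_sq - rs.f_calc_sq
    f_obs = np.sqrt(np.maximum(rs.f_obs_sq, 0.0))
    f_calc = np.sqrt(rs.f_calc_sq)
    sum_fo = f_obs.sum()
    if sum_fo == 0:
        raise ValidationError("sum of |Fo| is zero; R1 undefined")
    wfo4 = np.sum(w * rs.f_obs_sq**2)
    if wfo4 == 0:
        raise ValidationError("sum of w*(Fo^2)^2 is zero; wR2 undefined")
    return RefinementStats(
        r1=float(np.sum(np.abs(f_obs - f_calc)) / sum_fo),
        wr2=float(np.sqrt(np.sum(w * delta * delta) / wfo4)),
        goof=goof_statistical(rs, p),
        wgoof=wgoof(rs, w, p),
        n=n,
        p=p,
    )
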