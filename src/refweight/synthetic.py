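"""Synthetic structure-factor data with a known variance model.

No curated reflection dataset ships with the package, so correctness of the
optimizer and the diagnostics is demonstrated on generated data whose error
structure is exactly the one the weighting scheme models: the reported
variance of each observation is inflated by the quadratic and linear
intensity terms,

    Var(Fo^2) = sigma^2 + (a_true * P)^2 + b_true * P,

with normally distributed errors, so the generating (a_true, b_true) is a
ground truth the optimizer should recover and statistical weights (a = b =
0) are visibly miscalibrated whenever a_true or b_true is positive.

Model choices: Miller indices are drawn without repetition from the lattice
inside the resolution sphere s <= s_max; true intensities Fc^2 are
exponential with mean ``intensity_scale`` (acentric Wilson statistics);
reported sigmas grow with intensity as sigma_floor * sqrt(1 +
Fc^2/intensity_scale), emulating counting statistics on a baseline.  The
generator's composite intensity is P = Fc^2 (Fo^2 does not exist yet when
the noise is drawn); the analysis side blends the realized Fo^2 into P, a
mild, realistic mismatch — real weights also depend on the data they
model — that parameter-recovery tolerances must absorb.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .cell import UnitCell, reciprocal_metric
from .errors import ValidationError
from .io_formats import write_fcf
from .reflections import ReflectionSet

__all__ = ["SynthSpec", "generate", "write_bundle"]


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters.

    ``intensity_scale`` sets the mean of the exponential Fc^2 distribution
    (arbitrary refinement-scale units); ``sigma_floor`` the baseline
    reported sigma(Fo^2); ``a_true``/``b_true`` the variance inflation;
    ``f`` the mixing fraction (kept for symmetry with the analysis side,
    the generator itself uses P = Fc^2).  ``n_params`` is the refined
    parameter count stamped on the output, a typical small-molecule value.
    """

    n: int = 5000
    seed: int = 0
    cell: UnitCell = UnitCell(10.0, 10.0, 10.0)
    s_max: float = 0.7
    intensity_scale: float = 100.0
    sigma_floor: float = 1.0
    a_true: float = 0.05
    b_true: float = 0.5
    f: float = 1.0 / 3.0
    wavelength: float = 0.71073
    n_params: int = 50

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValidationError(f"n must be >= 20, got {self.n}")
        for name in ("s_max", "intensity_scale", "sigma_floor"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.a_true < 0 or self.b_true < 0:
            raise ValidationError("a_true and b_true must be >= 0")
        if not 0.0 <= self.f <= 1.0:
            raise ValidationError(f"f must lie in [0, 1], got {self.f}")


def _lattice_in_sphere(cell: UnitCell, s_max: float) -> np.ndarray:
    """All (h, k, l) != 0 with sin(theta)/lambda <= s_max, in lexicographic
    order (deterministic)."""
    g = reciprocal_metric(cell)
    # conservative per-axis bound: |h| <= 2 s_max / sqrt(lambda_min(G*));
    # a simple axis bound via the diagonal suffices for sane cells
    hmax = int(np.ceil(2.0 * s_max / np.sqrt(g.g11)))
    kmax = int(np.ceil(2.0 * s_max / np.sqrt(g.g22)))
    lmax = int(np.ceil(2.0 * s_max / np.sqrt(g.g33)))
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[hkl.any(axis=1)]
    s = 0.5 * np.sqrt(g.inv_d_squared(hkl[:, 0], hkl[:, 1], hkl[:, 2]))
    return hkl[s <= s_max]


def generate(spec: SynthSpec) -> ReflectionSet:
    """Draw a reflection set under ``spec``; bit-reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    lattice = _lattice_in_sphere(spec.cell, spec.s_max)
    if lattice.shape[0] < spec.n:
        raise ValidationError(
            f"only {lattice.shape[0]} lattice points inside s <= {spec.s_max}; "
            f"cannot draw {spec.n} distinct reflections"
        )
    pick = rng.choice(lattice.shape[0], size=spec.n, replace=False)
    hkl = lattice[np.sort(pick)]

    f_calc_sq = rng.exponential(scale=spec.intensity_scale, size=spec.n)
    sigma = spec.sigma_floor * np.sqrt(1.0 + f_calc_sq / spec.intensity_scale)
    p_gen = f_calc_sq  # the generator's composite intensity
    total_var = sigma**2 + (spec.a_true * p_gen) ** 2 + spec.b_true * p_gen
    f_obs_sq = f_calc_sq + rng.normal(0.0, np.sqrt(total_var))

    return ReflectionSet(
        hkl=hkl,
        f_obs_sq=f_obs_sq,
        sigma_f_obs_sq=sigma,
        f_calc_sq=f_calc_sq,
        cell=spec.cell,
        wavelength=spec.wavelength,
        n_params=spec.n_params,
    )


def write_bundle(
    rs: ReflectionSet, directory, basename: str = "synthetic"
) -> Dict[str, Path]:
    """Write a synthetic dataset as the file bundle a refinement would leave
    behind: ``.fcf`` (reflections + cell), ``.ins`` (CELL card, statistical
    WGHT) and ``.cif`` (refined-parameter count).  Returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if rs.cell is None or rs.wavelength is None or rs.n_params is None:
        raise ValidationError("bundle needs cell, wavelength and n_params on the set")
    paths = {
        "fcf": directory / f"{basename}.fcf",
        "ins": directory / f"{basename}.ins",
        "cif": directory / f"{basename}.cif",
    }
    write_fcf(rs, paths["fcf"])
    c = rs.cell
    paths["ins"].write_text(
        f"TITL {basename} (synthetic)\n"
        f"CELL {rs.wavelength!r} {c.a!r} {c.b!r} {c.c!r} "
        f"{c.alpha!r} {c.beta!r} {c.gamma!r}\n"
        "WGHT 0.0 0.0\n"
    )
    paths["cif"].write_text(
        f"data_{basename}\n_refine_ls_number_parameters {rs.n_params}\n"
    )
    return paths
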