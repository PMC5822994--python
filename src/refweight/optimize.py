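"""Grid-search optimization of the weighting parameters a and b.

The objective follows the classic recipe: reflections are arranged in
ascending order of Fc and divided into ten equal bins; for a candidate
(a, b) the weighted goodness of fit of each bin is computed and the
variance of the ten per-bin values is the quantity minimized.  A correctly
chosen (a, b) makes the weighted residual variance uniform across the
intensity range, so every bin's goodness of fit agrees and the variance
vanishes.

Correct weights make every bin's goodness of fit equal to one, so the
default objective measures the spread of the per-bin values about that
ideal: the mean squared deviation of the bin wGooF values from 1.  Two
other centrings are available for inspection but are not usable as search
objectives on their own.  The variance about the sample mean of the bins
("variance") is scale blind twice over: inflating a or b without bound
scales every weight down together, shrinking all per-bin values — and
hence their variance — toward zero, so it has no finite minimizer; and
dividing the bin values by the whole-set goodness of fit first
("variance_normalized") restores a finite minimum but leaves a shallow
valley along the weight-rescaling direction (a, b) -> (a sqrt(k), b k)
in which the estimate drifts whenever the intensity-dependent terms
dominate sigma^2.  Deviation-from-one penalizes that direction, which is
also why refinements weighted this way end with a goodness of fit close
to 1.

The search evaluates the objective on a 9 x 9 lattice of incrementally
increasing (a, b) values around the current estimate (centred when the
estimate leaves room, slid up against the a, b >= 0 boundary otherwise, so
each iteration always probes nine distinct non-negative values per axis),
recentres on the lattice minimum, shrinks a step size whenever its axis'
minimum was interior to the lattice (an edge minimum instead lets the
lattice walk), and stops once both step sizes have fallen below their
stopping values.  The search is fully deterministic.

Convergence guard: the initial step sizes are derived from the starting
values, and a computed start can be so small that the derived steps start
below the stopping values, which would prevent the search from running at
all.  By default the initial steps are floored at twice the stopping steps
so the search always runs; ``strict=True`` disables the floors and raises a
configuration error instead, which is the historically observed failure for
multipolar data with the reference stopping points (a_stop = 0.0001,
b_stop = 0.005).  For such data, either smaller stopping points
(a_stop = 1e-7, b_stop = 1e-6 is a known working choice) or larger starting
values resolve it; recommended stopping points for multipolar refinements
are a_stop > 0.00001 and b_stop > 0.0005.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .errors import ConfigurationError, ValidationError
from .reflections import ReflectionSet
from .weights import WeightingScheme, composite_p, q_factor

__all__ = [
    "GridSearchConfig",
    "OptimizationResult",
    "TraceEntry",
    "bin_by_fc",
    "binned_variance_objective",
    "make_objective",
    "shelxl_style_start",
    "minimize_on_grid",
    "grid_search",
    "trace_to_tsv",
]


@dataclass(frozen=True)
class GridSearchConfig:
    """Search geometry and stopping rules.

    ``a_stop``/``b_stop`` are the step sizes below which the search stops
    (both axes must fall below; defaults are the reference values 0.0001
    and 0.005).  ``grid_side`` is the number of candidate values per axis
    per iteration and must be odd so the lattice is centred.  ``strict``
    disables the initial-step floors (see module docstring).  ``dof_mode``
    selects the per-bin goodness-of-fit normalization: ``"pooled"`` scales
    the bin mean of w*Delta^2 by n/(n-p) (so a single whole-set bin
    reproduces the wGooF exactly, and parameter-rich models cannot produce
    negative degrees of freedom), ``"per_bin"`` uses n_k - p/n_bins.
    """

    a_start: Optional[float] = None
    b_start: Optional[float] = None
    a_stop: float = 1e-4
    b_stop: float = 5e-3
    n_bins: int = 10
    grid_side: int = 9
    max_iterations: int = 200
    shrink_factor: float = 0.5
    strict: bool = False
    dof_mode: str = "pooled"

    def __post_init__(self) -> None:
        if not (self.a_stop > 0 and self.b_stop > 0):
            raise ValidationError("a_stop and b_stop must be > 0")
        if self.grid_side < 3 or self.grid_side % 2 == 0:
            raise ValidationError(f"grid_side must be odd and >= 3, got {self.grid_side}")
        if self.n_bins < 2:
            raise ValidationError(f"n_bins must be >= 2, got {self.n_bins}")
        if not 0.0 < self.shrink_factor < 1.0:
            raise ValidationError(f"shrink_factor must lie in (0, 1), got {self.shrink_factor}")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.dof_mode not in ("pooled", "per_bin"):
            raise ValidationError(f"dof_mode must be 'pooled' or 'per_bin', got {self.dof_mode}")
        if self.a_start is not None and self.a_start < 0:
            raise ValidationError("a_start must be >= 0")
        if self.b_start is not None and self.b_start < 0:
            raise ValidationError("b_start must be >= 0")


@dataclass(frozen=True)
class TraceEntry:
    iteration: int
    a_centre: float
    b_centre: float
    step_a: float
    step_b: float
    a_best: float
    b_best: float
    objective: float


@dataclass(frozen=True)
class OptimizationResult:
    a_opt: float
    b_opt: float
    objective: float
    n_iterations: int
    converged: bool
    trace: Tuple[TraceEntry, ...] = field(default=())

    def as_dict(self) -> dict:
        return {
            "a_opt": self.a_opt,
            "b_opt": self.b_opt,
            "objective": self.objective,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


def trace_to_tsv(result: OptimizationResult) -> str:
    """Tab-separated trace (iteration, a, b, step_a, step_b, objective),
    suitable for contour or convergence plots."""
    lines = ["iteration\ta\tb\tstep_a\tstep_b\tobjective"]
    for t in result.trace:
        lines.append(
            f"{t.iteration}\t{t.a_best!r}\t{t.b_best!r}\t{t.step_a!r}\t{t.step_b!r}\t{t.objective!r}"
        )
    return "\n".join(lines) + "\n"


# -- binning and objective --------------------------------------------------


def bin_by_fc(rs: ReflectionSet, n_bins: int = 10) -> np.ndarray:
    """Assign each reflection to one of ``n_bins`` contiguous Fc-ordered bins.

    Reflections are ranked in ascending order of Fc^2 (the same ordering as
    Fc) with a stable sort; bin sizes differ by at most one, with the larger
    bins first.  Returns the bin index per reflection in original order.
    """
    n = len(rs)
    if n < n_bins:
        raise ValidationError(f"cannot form {n_bins} bins from {n} reflections")
    order = np.argsort(rs.f_calc_sq, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=np.int64)
    sizes[:rem] += 1
    sorted_bins = np.repeat(np.arange(n_bins), sizes)
    bins = np.empty(n, dtype=np.int64)
    bins[order] = sorted_bins
    return bins


def make_objective(
    rs: ReflectionSet,
    scheme_base: WeightingScheme,
    p: int,
    n_bins: int = 10,
    dof_mode: str = "pooled",
    kind: str = "deviation",
) -> Callable[[float, float], float]:
    """Build the binned objective as a fast callable of (a, b).

    ``kind`` selects the centring of the spread measure: ``"deviation"``
    (default) is the mean squared deviation of the per-bin wGooF values
    from 1; ``"variance"`` the population variance about their sample
    mean; ``"variance_normalized"`` the same after dividing by the
    whole-set wGooF.  Only the default is a well-posed search objective
    (see the module docstring).  Everything that does not depend on
    (a, b) — the composite intensity P, sigma^2, Delta^2, the q factor and
    the fixed d and e terms of the denominator, and the Fc-ordered bin
    assignment — is precomputed once.
    """
    if kind not in ("deviation", "variance", "variance_normalized"):
        raise ValidationError(f"unknown objective kind {kind!r}")
    n = len(rs)
    if n <= p:
        raise ValidationError(f"need more reflections than parameters (n={n}, p={p})")
    bins = bin_by_fc(rs, n_bins)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    p_comp = composite_p(rs.f_obs_sq, rs.f_calc_sq, scheme_base.f)
    sig2 = rs.sigma_f_obs_sq**2
    delta2 = (rs.f_obs_sq - rs.f_calc_sq) ** 2
    fixed = np.zeros(n)
    if scheme_base.d != 0.0:
        fixed = fixed + scheme_base.d
    if scheme_base.e != 0.0:
        fixed = fixed + scheme_base.e * rs.s
    q = q_factor(scheme_base.c, rs.s) if scheme_base.c != 0.0 else 1.0
    if dof_mode == "pooled":
        dof = np.full(n_bins, float(n - p) / n) * counts
    else:
        dof = counts - p / n_bins
        if np.any(dof <= 0):
            raise ValidationError(
                "per-bin degrees of freedom not positive; use dof_mode='pooled'"
            )

    dof_total = float(n - p)

    def objective(a: float, b: float) -> float:
        den = sig2 + (a * p_comp) ** 2 + b * p_comp + fixed
        if np.any(den <= 0):
            raise ValidationError(f"non-positive weight denominator at (a={a}, b={b})")
        wd2 = q * delta2 / den
        t = np.sqrt(np.bincount(bins, weights=wd2, minlength=n_bins) / dof)
        if kind == "deviation":
            return float(np.mean((t - 1.0) ** 2))
        if kind == "variance_normalized":
            t = t / np.sqrt(np.sum(wd2) / dof_total)
        return float(np.var(t))

    return objective


def binned_variance_objective(
    rs: ReflectionSet,
    scheme: WeightingScheme,
    p: int,
    n_bins: int = 10,
    dof_mode: str = "pooled",
    kind: str = "deviation",
) -> float:
    """Spread of the per-bin weighted goodness of fit under ``scheme``.

    Per bin k the statistic is t_k = sqrt( (n/(n-p)) * mean_k(w Delta^2) )
    (``dof_mode="pooled"``), so over a single whole-set bin t equals the
    wGooF; the objective is, by default, the mean squared deviation of the
    t_k from 1 (divisor ``n_bins``), which vanishes exactly when every bin
    carries unit goodness of fit.  See :func:`make_objective` for the
    alternative centrings.
    """
    return make_objective(rs, scheme, p, n_bins, dof_mode, kind)(scheme.a, scheme.b)


# -- starting values --------------------------------------------------------


def shelxl_style_start(
    rs: ReflectionSet,
    p: int,
    f: float = 1.0 / 3.0,
    floor: float = 0.01,
) -> Tuple[float, float]:
    """Heuristic starting values (a_start, b_start) for the search.

    The median excess of Delta^2 over sigma^2 is attributed to the
    quadratic inflation term (a P)^2, giving
    a_start = sqrt(max(median(Delta^2) - median(sigma^2), 0)) / median(P),
    floored at ``floor``; b_start is 0.  A degenerate instance (perfect fit,
    or vanishing median P) falls back to (0.1, 0).
    """
    delta2 = (rs.f_obs_sq - rs.f_calc_sq) ** 2
    med_p = float(np.median(composite_p(rs.f_obs_sq, rs.f_calc_sq, f)))
    if np.all(delta2 == 0.0) or med_p <= 0.0:
        return 0.1, 0.0
    excess = float(np.median(delta2) - np.median(rs.sigma_f_obs_sq**2))
    a_raw = np.sqrt(max(excess, 0.0)) / med_p
    return max(a_raw, floor), 0.0


# -- the adaptive grid search ----------------------------------------------


def _candidates(centre: float, step: float, side: int) -> np.ndarray:
    # sliding window: centred when room allows, shifted up against the
    # non-negativity boundary otherwise, so every iteration probes exactly
    # ``side`` distinct incrementally increasing values >= 0
    base = max(centre - step * (side // 2), 0.0)
    return base + step * np.arange(side)


def minimize_on_grid(
    objective: Callable[[float, float], float],
    a_start: float,
    b_start: float,
    cfg: GridSearchConfig,
) -> OptimizationResult:
    """Adaptive grid descent of an arbitrary objective(a, b).

    Starting steps are half the starting values, floored at twice the
    stopping steps unless ``cfg.strict`` (a zero starting value always falls
    back to twice its stopping step, since a zero step would freeze the
    axis).  In strict mode an initial step below its stopping step raises a
    :class:`ConfigurationError`.  Recentring requires a strict improvement
    over the current centre; equal-valued grid minima are resolved to the
    lexicographically smallest (a, b).  The result is the best point ever
    evaluated (the start counts), so the objective never increases.
    """
    step_a = a_start / 2.0 if a_start > 0 else 2.0 * cfg.a_stop
    step_b = b_start / 2.0 if b_start > 0 else 2.0 * cfg.b_stop
    if cfg.strict:
        if step_a < cfg.a_stop or step_b < cfg.b_stop:
            raise ConfigurationError(
                f"initial grid steps ({step_a:g}, {step_b:g}) are smaller than the "
                f"stopping steps ({cfg.a_stop:g}, {cfg.b_stop:g}); the grid search "
                "cannot run. Supply larger starting values or smaller stopping "
                "points (for multipolar data a_stop > 1e-05 and b_stop > 0.0005 "
                "are recommended; a_stop = 1e-07 with b_stop = 1e-06 is a known "
                "working choice)."
            )
    else:
        step_a = max(step_a, 2.0 * cfg.a_stop)
        step_b = max(step_b, 2.0 * cfg.b_stop)

    a_c, b_c = max(a_start, 0.0), max(b_start, 0.0)
    f_c = objective(a_c, b_c)
    best_a, best_b, best_f = a_c, b_c, f_c
    trace: List[TraceEntry] = []
    converged = False
    n_iter = 0

    for n_iter in range(1, cfg.max_iterations + 1):
        a_vals = _candidates(a_c, step_a, cfg.grid_side)
        b_vals = _candidates(b_c, step_b, cfg.grid_side)
        # lexicographic scan: first strict minimum is the lexicographically
        # smallest among equal-valued grid minima
        g_a = g_b = None
        g_f = np.inf
        for av in a_vals:
            for bv in b_vals:
                val = objective(float(av), float(bv))
                if val < g_f:
                    g_f, g_a, g_b = val, float(av), float(bv)
        if g_f < best_f:
            best_a, best_b, best_f = g_a, g_b, g_f
        trace.append(
            TraceEntry(
                iteration=n_iter,
                a_centre=a_c,
                b_centre=b_c,
                step_a=step_a,
                step_b=step_b,
                a_best=g_a,
                b_best=g_b,
                objective=g_f,
            )
        )
        if g_f < f_c:
            # move; shrink only the axes whose minimum was interior
            ia = int(np.searchsorted(a_vals, g_a))
            ib = int(np.searchsorted(b_vals, g_b))
            if 0 < ia < len(a_vals) - 1:
                step_a *= cfg.shrink_factor
            if 0 < ib < len(b_vals) - 1:
                step_b *= cfg.shrink_factor
            a_c, b_c, f_c = g_a, g_b, g_f
        else:
            # nothing in the lattice beats the centre: refine both steps
            step_a *= cfg.shrink_factor
            step_b *= cfg.shrink_factor
        if step_a < cfg.a_stop and step_b < cfg.b_stop:
            converged = True
            break

    return OptimizationResult(
        a_opt=best_a,
        b_opt=best_b,
        objective=best_f,
        n_iterations=n_iter,
        converged=converged,
        trace=tuple(trace),
    )


def grid_search(
    rs: ReflectionSet,
    scheme_base: WeightingScheme,
    p: int,
    cfg: GridSearchConfig = GridSearchConfig(),
) -> OptimizationResult:
    """Optimize (a, b) of ``scheme_base`` on ``rs`` by adaptive grid search.

    Missing starting values are computed with :func:`shelxl_style_start`
    (in strict mode without its floor, so a pathologically small computed
    start surfaces as the configuration error rather than being masked).
    The other scheme parameters (c, d, e, f) are taken from ``scheme_base``
    and held fixed.
    """
    a_start, b_start = cfg.a_start, cfg.b_start
    if a_start is None or b_start is None:
        a_comp, b_comp = shelxl_style_start(
            rs, p, f=scheme_base.f, floor=0.0 if cfg.strict else 0.01
        )
        a_start = a_comp if a_start is None else a_start
        b_start = b_comp if b_start is None else b_start
    objective = make_objective(rs, scheme_base, p, cfg.n_bins, cfg.dof_mode)
    return minimize_on_grid(objective, a_start, b_start, cfg)
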