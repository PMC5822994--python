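# Methods

## The weighting model

For refinement on *F*², each reflection's weight is

    w = q / [ σ²(Fo²) + (aP)² + bP + d + e·(sinθ/λ) ]

with the composite intensity `P = f·max(Fo², 0) + (1 − f)·Fc²`.  The
denominator is a variance model: the reported σ² plus a quadratic (`a`) and
a linear (`b`) intensity-dependent inflation, a constant offset (`d`) and a
first-power resolution term (`e`, in Å).  The factor `q` depends on the
sign of `c`: `q = 1` for `c = 0`, `q = exp(c·s²)` for `c > 0` and
`q = 1 − exp(c·s²)` for `c < 0`, with `s = sinθ/λ`; the last branch
vanishes at `s = 0`, where the weight is undefined and reported as such.
The mixing fraction defaults to `f = 1/3`, the value known to reduce the
bias of weighting on observed or calculated intensities alone.  With
`a = b = c = d = e = 0` the scheme reduces exactly to statistical weights
`1/σ²`; this identity is asserted in the tests and anchors the statistics
(GooF is always computed with statistical weights, wGooF with the applied
scheme, so the two coincide under a statistical scheme).

Only `a` and `b` are optimized; `c`, `d`, `e` are carried through the
model, validated, and held fixed (zero by default).  Negative Fo²
measurements are retained and clamped to zero only inside `P` and inside
`|Fo|` for R1; a filter can remove them explicitly.  All quantities stay on
the file's native refinement scale; no rescaling between Fo² and Fc² and no
σ re-estimation is performed.

## The objective

Reflections are sorted by Fc² (stable sort; ties keep file order) and split
into `n_bins = 10` contiguous bins whose sizes differ by at most one,
larger bins first.  Per bin the goodness-of-fit statistic is

    t_k = sqrt( (n/(n−p)) · mean_k( w·Δ² ) ),      Δ = Fo² − Fc²,

which over a single whole-set bin reproduces the wGooF exactly, and which
avoids the negative degrees of freedom that per-bin `n_k − p/n_bins`
normalization produces for parameter-rich multipole models (that
normalization is still available as `dof_mode="per_bin"`).

The default objective is the mean squared deviation of the `t_k` from 1
(divisor `n_bins`).  The centring matters.  The variance of the `t_k`
about their own sample mean is not usable as a search objective: growing
`a` or `b` without bound scales every weight down together, sending all
`t_k` — and hence their variance — to zero, so it has no finite minimizer.
Dividing the `t_k` by the whole-set wGooF first removes that collapse but
leaves a shallow valley along the near-uniform rescaling direction
(a, b) → (a·√k, b·k) in which the estimate drifts whenever the
intensity-dependent terms dominate σ²; on synthetic data this biased `b`
low by tens of percent.  Deviation-from-one penalizes the rescaling
direction and pins the scale where the weights truly describe the residual
variance — which is also why refinements weighted this way characteristically
end with a goodness of fit close to 1.  Both alternative centrings remain
available (`kind="variance"`, `kind="variance_normalized"`) for inspection
and for the toy identities in the tests.

## The grid search

Each iteration evaluates the objective on a 9 × 9 lattice of incrementally
increasing `(a, b)` values: nine distinct non-negative values per axis,
centred on the current estimate when it leaves room, slid up against the
`a, b ≥ 0` boundary otherwise.  The lattice minimum (ties broken to the
lexicographically smallest `(a, b)`, preferring the smaller correction)
becomes the new centre only if it strictly improves on the current centre;
an axis' step is halved (`shrink_factor = 0.5`, applied per axis) when its
minimum coordinate was interior, left unchanged when it was on the edge so
the lattice can walk.  When nothing on the lattice beats the centre, both
steps are halved.  The search stops when both steps fall below their
stopping values (`a_stop`, `b_stop`; both must, the conservative reading),
or at `max_iterations = 200`.  The result is the best point ever evaluated
(the start counts), so the reported objective can never exceed the
objective at the start.  The search contains no randomness: identical
inputs give identical results.

Starting values, when not supplied, come from a median heuristic: the
excess of median(Δ²) over median(σ²) is attributed to the quadratic term,
`a₀ = sqrt(max(median(Δ²) − median(σ²), 0)) / median(P)` floored at 0.01,
with `b₀ = 0`; a perfect fit falls back to (0.1, 0).  This is a documented
stand-in: it lands within a small factor of the truth on strongly inflated
data (asserted in tests), which is all a grid start needs.

Initial steps are half the starting values.  On multipolar data a computed
start can be small enough that the steps begin below the default stopping
values (0.0001 and 0.005), which would stop the search before it runs.
Default behaviour floors each initial step at twice its stopping step (a
zero starting value always falls back to that floor, since a zero step
would freeze its axis); `strict=True` disables the floors and raises a
configuration error instead, naming the remedy — larger starts or smaller
stops (a_stop = 1e−7 with b_stop = 1e−6 is a known working choice;
recommended ranges for multipolar data are a_stop > 1e−5 and
b_stop > 5e−4).

## Normal-probability diagnostics

Weighted deviates `√w·Δ` are sorted ascending and paired with the expected
standard-normal order statistics `Φ⁻¹((i − ½)/n)` — the `(i − ½)/n`
plotting position is a convention choice; alternatives differ well below
the tolerances used anywhere here.  Every reflection contributes one point
(no bin averaging), and points map back to reflection identities through a
rank table export.  The summary line is an ordinary least-squares fit of
observed on expected restricted to ranks `n/4 < i ≤ 3n/4`: membership by
rank, not value, is deterministic under ties and makes the fit provably
insensitive to anything placed in the tails.  Deviates are deliberately
not divided by the overall wGooF: a correctly weighted but poorly fitting
refinement should show its inflated spread as a gradient above 1 rather
than being normalized away.

At n = 10⁴ the interquartile gradient of genuinely standard-normal
deviates has a sampling standard deviation of roughly 0.013, so individual
seeds scatter a couple of percent around 1; calibration checks in the
tests use a fixed seed and a ±0.02 band.

## The synthetic generator

The generator emulates a finished refinement whose observations carry
exactly the variance structure the scheme models.  Miller indices are
drawn without repetition from the lattice inside `s ≤ s_max` (cubic 10 Å
cell by default, `s_max = 0.7 Å⁻¹`); true intensities Fc² are exponential
(acentric Wilson statistics) with mean `intensity_scale = 100`; reported
sigmas grow with intensity as `σ = sigma_floor·sqrt(1 + Fc²/intensity_scale)`
(`sigma_floor = 1`), emulating counting statistics on a baseline; and

    Fo² = Fc² + ε,   ε ~ Normal(0, σ² + (a_true·P)² + b_true·P),   P = Fc².

Defaults `a_true = 0.05`, `b_true = 0.5` make statistical weights visibly
miscalibrated (statistical wGooF ≈ 6, NPP gradient ≈ 4.5) — the situation
the optimizer exists for.  The generator's `P` is Fc² (Fo² does not exist
when the noise is drawn), while the analysis-side `P` blends the realized
Fo²; this mild mismatch mirrors the real circularity — weights depend on
the data they model — and is absorbed by the recovery tolerances (25%
relative on `a` and `b`; observed recovery on the default conditions is
within ~8%).

What the generator does **not** emulate: centric/acentric mixtures and
space-group symmetry, correlated errors between reflections, resolution- or
batch-dependent systematic error, absorption/extinction effects, and model
inadequacy (Fc² is the truth by construction).  Passing tests therefore
demonstrate that the optimizer recovers a known variance structure and
that the diagnostics are calibrated — not that any particular real data
set's σ model is of this form.

## Numerical and interface choices

- Angles are degrees in all file formats, converted internally once;
  resolution values are computed lazily per set and invalidated when the
  cell changes.
- The reciprocal metric uses the closed triclinic formulas; tests check it
  against direct numerical inversion of the direct metric tensor.
- `.fcf` parsing is CIF-tag driven (gemmi), never positional; an
  observed-status column excludes rows not flagged `o` unless `keep_all`.
  Fortran `D` exponents and CIF parenthesised uncertainties are accepted.
  `.fco` sigmas are treated on the same scale convention as `.fcf` sigmas.
- `.fco` column order defaults to `h k l Fc² Fo² σ(Fo²)` with an explicit
  override, since XD versions vary.
- Written `.fcf` files use shortest-round-trip number formatting, so
  read(write(set)) reproduces every field bit-exactly.
- Degenerate inputs fail loudly with the offending tag, line or reflection
  named: σ ≤ 0, duplicate or (0,0,0) indices, non-positive weight
  denominators (possible with negative `d`), n ≤ p, filters that remove
  everything, fewer reflections than bins.

## Known limitations

- `c`, `d`, `e` are modelled but not optimized.
- No symmetry merging, absorption/extinction handling, or raw-intensity
  (hkl) formats; inputs are assumed to come from a completed refinement.
- The start heuristic and the binned objective's exact normalization are
  this package's documented choices; other programs in this lineage may
  differ in detail while sharing the same structure.
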