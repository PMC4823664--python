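# Methods

## Model

A single-odor response is

    F(c) = F_max / (1 + ((1 + c/K) / (η c/K))^n),    c ≥ 0,

with odor-specific Hill coefficient `n > 0`, efficacy `η > 0` and
concentration scale `K > 0` (`s = 1/K`), and a maximal physiological
response `F_max` shared by every odor an OSN type senses in one
analysis.  `F(0) = 0` (taken by continuity for `n < 1`), the curve is
strictly increasing, and the asymptote is `F_max η^n/(1 + η^n)` — it
depends on both the efficacy and the steepness, which is what allows
mixtures to escape the band between the component asymptotes.

The mixture of components `i` at concentrations `c_i` (`x_i = c_i/K_i`)
uses the efficacy-weighted sums `A = Σ n_i η_i x_i`, `B = Σ η_i x_i`,
`C = Σ x_i`:

    F_mix = F_max / (1 + ((1 + C)/B)^(A/B)).

Consequences, all verified by the test suite:

* one component reduces the formula exactly to the single-odor curve;
* the self-mixture identity `F(c, c) = F(2c, 0)` holds exactly;
* with all `n_i` equal, the model coincides with the legacy
  shared-coefficient form (`cruz_lowe` in `models.legacy_*`); both that
  form and the per-odor-asymptote form (`rospars`) keep the mixture
  asymptote between the single-odor asymptotes, so neither can show
  synergy or inhibition near the maximum, while the present model does;
* along a fixed-ratio ray (`c_i = w_i · X`) the mixture is a curve of
  the same family with `s_eff = Σ w_i s_i`,
  `η_eff = Σ w_i η_i s_i / s_eff`, `n_eff = Σ w_i n_i η_i s_i / Σ w_i η_i s_i`.

Assumptions and scope: responses are peak firing responses representable
as sigmoids of concentration; no receptor-kinetic scheme is implied; the
time course within a sniff cycle is out of scope, as are perceptual
claims.

## Behavior classification

Mixture and component curves are compared on a shared concentration
axis under the **total-concentration convention**: the mixture point at
abscissa `c` contains `(r/(1+r))·c` of U and `(1/(1+r))·c` of V, and
each single-odor curve is evaluated at `c`.  This convention was chosen
(over evaluating each component at its own in-mixture concentration)
because under it the analytic synergy bound below holds exactly in
simulation; it also makes relabelling U↔V with r↔1/r an exact symmetry.

Labels, applied pointwise and merged into maximal contiguous regions:
synergy (mixture above both components), inhibition (below both),
suppression (strictly between), and the similarity family when the
mixture is within a band of a component (default 5% of `F_max`,
configurable): hypoadditivity if the matched component is the more
effective one over the region, overshadowing otherwise.  Hypoadditivity
is formally a special case of "similar to one of the components"; the
published composite captions are matched accordingly.  The asymptotic
region defaults to concentrations where all three curves exceed 95% of
their own asymptotes.  Phase maps classify analytically at the
asymptote and default to a zero similarity band, giving the strict
three-way suppression/synergy/inhibition partition used for sweep
figures.

**Synergy feasibility bound.**  Under the fixed-ratio paradigm, no
abscissa below the half-asymptote midpoint of the component with the
lower Hill coefficient can classify as synergy.  The midpoint here is
the true half-asymptote concentration
`K / (η(1 + 2η^{-n})^{1/n} − 1)`, not `K`; with `K` in its place the
bound fails in simulation.  `synergy_feasible` implements the bound and
the classifier respects it over 1000 random parameter draws.

## Odor-response-space algebra

Scaling `α⊙(n, η, s) = (n, η, αs)` is the same odor at `α`-fold
concentration; composition
`(n, η, s)•(n', η', s') = ((nηs + n'η's')/(ηs + η's'), (ηs + η's')/(s + s'), s + s')`
is the equal-concentration mixture.  The embedding
`(n, η, s) ↦ (nηs, ηs, s)` maps composition to addition and scaling to
scalar multiplication, so the space is exactly 3-dimensional.  Basis
validity is a determinant test with tolerance `1e-12` scaled by the
column magnitudes; decomposition is the corresponding linear solve, with
coefficients required positive (negatives beyond `-1e-12` raise a
not-representable error, tinier ones are clamped and flagged).  Coverage
in the `(n, η)` plane is scale-free: a query is covered iff non-negative
simplex weights reproduce `(nη, η)` from the vertices' images — solved
directly for three vertices and as a small linear program otherwise.

For a bounded rectangle `[n_min, n_max] × [η_min, η_max]` all four
corner triples (at a common `s`, default `1e6`) are valid bases;
`canonical_bases` returns the two that share the main diagonal, because
their coverage regions partition the rectangle exactly along the curved
image of that diagonal, so their union covers every in-bounds pair while
neither suffices alone.  Default bounds `n ∈ [0.5, 20]`,
`η ∈ [0.1, 16]` span all published parameter values.  Multi-OSN target
synthesis stacks the per-OSN embedded equations into one least-squares
system, because a single physical mixture must serve every OSN type;
infeasibility reports the worst-matched OSN.

## Fitting

`fit_single_odor` estimates `(n, η, K)` with `F_max` held fixed, using
`scipy.optimize.least_squares` (trust-region reflective, log-parameter
bounds `n ∈ [0.1, 30]`, `η ∈ [1e-3, 1e3]`, `K` within two decades of
the sampled range) and a deterministic multistart: 20 starts drawn by a
seeded permutation from a 4×3×3 coarse log-grid of initial guesses, best
cost kept.  Default residuals are on the logarithm of the response —
i.e. relative error — because the fixture noise model is multiplicative,
making relative residuals the matched estimator; plain absolute
residuals (`loss="absolute"`) markedly inflate the spread of `K` under
multiplicative noise.  Points with zero response are excluded from the
relative objective (and from MAPE, which is reported in percent; they
stay in MSE).

The closed-loop recovery study uses the control odor
`(n=3.6, η=1.7, K=3.16e-4)` on 12 log-spaced points over 3 decades
centered on `K`: zero-noise recovery is exact to ~1e-13 relative, and
with 5% multiplicative noise the median relative error over 100 seeds
stays below 10% for all three parameters.  Identifiability degrades for
very steep curves (`n ≳ 10`) where `n` and `K` trade off — fits there
should be read as curve descriptions, not parameter measurements.

`fit_shift` finds the log10-shift of a predicted curve minimizing the
MSE to observed mixture points (coarse 201-point scan refined by bounded
scalar minimization, default window ±1 decade); the returned delta is
the shift applied to the prediction.

## Synthetic data

`generate_curve` emulates noisy electrophysiology: model responses on a
log grid (default 12 points over 4 decades centered on `K`, resembling
published sampling densities) with multiplicative Gaussian noise of
configurable coefficient of variation, truncated to `[0, F_max]`,
bit-reproducible under a fixed seed.  It reproduces the magnitude and
response-proportional scaling of firing-rate variability but not
adaptation, trial-order effects, correlated errors across
concentrations, or concentration-delivery error (the latter is modelled
separately as the log-shift correction) — so passing tests demonstrate
correctness of the estimation and classification machinery under the
assumed noise model, not robustness to every artifact of real
recordings.  `builtin_parameter_sets` carries the published two-odor
sets verbatim, with the shared default mixing ratio `r = 0.2` where a
set states none.

## Numerical choices

All sigmoids are evaluated in log space via `expit`/`log1p`, so Hill
coefficients of order 20 cannot overflow; `B = 0` (all concentrations
zero) returns 0 by the limit.  Noiseless-identity assertions use
relative tolerance `1e-9` on dense 200-point grids.  Region labels use
plurality with first-appearance tie-break.  Strict monotonicity is
asserted only where double precision can still resolve the distance to
the asymptote.

## Limitations

The model is an empirical heuristic: no biophysical kinetic scheme
derives it, and parameters fitted to steep curves are poorly
identified.  Behavior labels near band edges depend on the similarity
tolerance, and the published composite captions are inherently
qualitative.  Real mixture data may violate the fixed-`F_max`
assumption across odors; the package deliberately fixes `F_max` per
analysis rather than fitting it per odor.
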