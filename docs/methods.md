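# Methods

## The model

`episwitch` models a single self-regulating, monomeric transcription factor
(TF) whose promoter carries bivalent chromatin: H3K4me3 (activating, `q_A`)
and H3K27me3 (repressive, `q_I`) marks that are written and erased by four
enzymes (MLL2/KDM5 on H3K4, EZH2/UTX-KDM6 on H3K27). After a slow–fast
reduction of the underlying Michaelis–Menten network, three variables
remain: the TF concentration `x` (slow) and the two mark concentrations
(faster, by the ratio `eps2 = Omega_S/Omega_T < 1` of the histone-residue
and TF system sizes).

Mean-field dynamics:

```
dx/dtau       = B_x - D_x
eps2 dq_A/dtau = B_A - D_A
eps2 dq_I/dtau = B_I - D_I
```

with

```
B_x = rho [1 + (C1 + C4 q_I) h],   D_x = rho [C2 x + C4 q_I h],
h   = q_A x / (lambda_x q_I + q_A x),
B_A = Lambda_A (rho_A - q_A)(A1 + q_A x)(A3 + q_A x)
      / [(rho_A - q_A)(A1 + q_A x) + B2 + K2 q_A x],
D_A = Lambda_A lambda_A K6 q_A / (q_A + K5),
B_I = Lambda_I (rho_I - q_I)(A7 + q_I)(A9 + q_I)
      / [(rho_I - q_I)(A7 + q_I) + B8 + (K8 x + K9) q_I],
D_I = Lambda_I lambda_I K12 q_I / (q_I + K11).
```

The 16 kinetic constants `theta = (A1, A3, B2, K2, K5, K6, lambda_A,
lambda_x, A7, A9, B8, K8, K9, K11, K12, lambda_I)` are the sampled
parameters; `rho, C1, C2, C4, Lambda_A, Lambda_I, rho_A, rho_I` and the
system sizes are fixed constants. The TF is monomeric (no intrinsic
cooperativity): every nonlinearity beyond a first-order Hill function is
generated by the mark–TF feedback.

A structural identity worth knowing: `B_x - D_x = rho (1 + C1 h - C2 x)`.
The `C4 q_I h` term appears in birth and death alike, so it cancels from the
drift but adds to the fluctuation intensity `B_x + D_x`. Deterministic
behaviour is therefore independent of `C4`, while finite-size (noise-driven)
behaviour is not — this is the mechanism behind the noise-induced class.

## Quasi-steady-state marks and the response curve

For each `x`, `q_A*(x)` and `q_I*(x)` solve `B_J = D_J` on their bounded
domains. Both residuals are sign-definite at the endpoints (positive at 0,
non-positive at the capacity), so a root always exists; root finding is a
512-point sign-change scan per `x` followed by vectorised bisection
(60 halvings, far below solver tolerance). Multiple sign changes at any `x`
flag mark multistability; such `theta` are rejected by the ensemble filter,
matching the model's premise that each mark equation is monostable given
`x`.

The TF production response is `R(x) = rho (1 + C1 h(x))` at QSS marks. Two
effective-cooperativity measures are provided:

* `effective_hill` — the maximum logit slope `d log[h/(1-h)]/d log x`. It is
  exact for true Hill inputs of any order (checked against constructed
  curves giving exactly 1 and 2) and is a sharp local measure, but for
  monotone mark curves it is bounded below by 1.
* `fit_hill_exponent` — an unconstrained least-squares fit of
  `R = rho(1 + C_eff x^n/(lambda_eff + x^n))`, the exponent the Hill-form
  description of `R(x)` itself defines. It relaxes to 1 as the feedback
  flattens and is the right measure for "cooperativity is lost" statements.

Bistability requires the `q_A*`/`q_I*` curves to cross ("X pattern"): below
the crossover repression dominates and above it activation does, which is
what makes `h` ultrasensitive.

## Landscape and classification

The stationary law of the slow variable follows a WKB (large `Omega_T`)
form:

```
phi_x(x) = N exp(-Omega_T U(x, Omega_T)),
U = -S + [log<B_x> + log<D_x>]/(2 Omega_T),
S = \int_0^x log(<B_x>/<D_x>) ds,
```

with `<B_x>, <D_x>` the TF rates at QSS marks. Zeros of
`S' = log(<B_x>/<D_x>)` are the mean-field equilibria; zeros of `U'` are the
modes of `phi_x` at finite size. Classification of a parameter set at a
reference `Omega_T` (default 200):

| S' roots | U' roots | label |
|---|---|---|
| 1 | 1 | `LOW_GE` / `HIGH_GE` (modal point vs `x_THR`) |
| 3 | 3 | `BISTABLE` |
| 1 | 3 | `NOISE_INDUCED` (bimodal only at finite size) |
| 3 | 1 | monostable by `x_*` (mean-field bistability erased by noise) |

The (3, 1) row is not named in the published four-class scheme; we fold it
into the monostable classes because phenotypes are defined by the modes of
`phi_x`. Any other root pattern is `UNCLASSIFIED` (re-tried on a finer grid
first; residual rate ~0 under the shipped calibration).

Numerics: the grid is 400 log-spaced points on `[1e-3, 10 (1+C1)/C2]`
(every equilibrium satisfies `x <= (1+C1)/C2` because `h <= 1`). The
integrand of `S` diverges like `-log(c s)` at 0; the head piece on
`[0, x_min]` is added analytically from that local form. `U'` uses the
analytic `S'` plus a finite-difference derivative of `log(B D)`. Gridded
sign changes are polished by bisection/`brentq`; `S'` roots can be refined
to 1e-12 with the scalar QSS solver (the mean-field ODE reproduces them to
~1e-13). Barriers `dU0`, `dU1` are potential differences between the saddle
and the low/high minimum, via a cubic spline of `U`.

The high/low split threshold `x_THR` defaults to the geometric mean of the
deterministic well scale, `sqrt(1+C1)/C2`; `build_ensemble` replaces it by
the kernel-density minimum of `log10(x_*)` between the two peaks of the
monostable modal distribution, which is the data-driven definition.

The conditional mark densities use the same WKB form per mark,
`phi_J(p|x) ∝ exp(-Omega_S \int_0^p log(D_J/B_J) ds)/sqrt(B_J D_J)`; the
`1/sqrt(B D)` prefactor is the standard sub-leading birth–death factor, and
the implementation is validated against a frozen-`x` Gillespie histogram
(TV < 0.05 at `Omega_S = 100`).

## Stochastic simulation

The master equation is simulated exactly in count space: state
`(n_x, n_A, n_I)`, concentrations `n_x/Omega_T`, `n/Omega_S`, and all six
channels carrying propensity `Omega_T * rate` (the `1/eps2` acceleration of
the mark channels combines with their `Omega_S` prefactor to
`Omega_S/eps2 = Omega_T`). Mark addition vanishes at the carrying capacity,
so counts stay within bounds by construction. The inner loop is
numba-compiled and consumes a seeded numpy `Generator`; identical seeds give
bitwise-identical trajectories. Recording is stride-sampled (equal-time
weights estimate the occupation measure). No tau-leaping is used: exactness
matters for the distribution-level comparisons.

Mode counting zero-pads the histogram (so a boundary mode counts), smooths
with a short moving average, and requires peak prominence of at least 5% of
the maximum.

## Basins of attraction

`estimate_Poff` samples `(x, q_A)` uniformly on `[0, 1.2 x_ON] x [0,
rho_A]`, starts `q_I` at its QSS value `q_I*(x_0)` (the plane the phase
portraits are drawn in; the third coordinate is not specified by the
published procedure, so the QSS start is our documented choice), integrates
the slow–fast ODEs at `eps = 0.1` with LSODA, and classifies ON/OFF by the
terminal `x` against the unstable root, with a `1e-3` "undecided" guard
band (an error if undecided exceeds 5%). Tolerances `rtol = 1e-5`,
`atol = 1e-8` reproduce the decisions of a `rtol = 1e-8` reference run
exactly on spot checks while being ~3x faster. When comparing `P_off`
along a parameter ray, the sampling domain is held fixed at the base
parameters — otherwise the domain itself moves with `x_ON` and the values
are not comparable.

Direction of the repression knobs: raising `B2` (suppresses H3K4me3
addition) or `K11` (weakens H3K27me3 removal) enlarges the OFF basin.
Raising `B8` *suppresses H3K27me3 addition* (`B8` is additive in the `B_I`
denominator), so under the model equations the OFF basin shrinks along a
raw-`B8` ray. Published statements that couple `B8` to the OFF state are
made in a normalised coordinate system in which the `B2` axis is rescaled
per `B8`; that normalisation is deliberately a pass-through hook here, so
the package reports raw-coordinate behaviour.

## Ensembles

`theta` is sampled componentwise from uniform priors and accepted iff both
mark equations are monostable at every `x` on a 64-station reference grid
(512-point scan per station). Accepted sets are classified at the common
`Omega_T`; records carry the modal point(s), barriers, the
`phi_x`-weighted mark averages `<q_J|theta>_x`, enzyme-activity proxies,
and a methylation-status label applying the thresholds (0.05, 0.8, 5) in
sequence: unmarked, K4-dominant, K27-dominant, bivalent (the K27 ratio rule
is applied exactly as published even though its direction reads oddly; the
thresholds are configurable). Persistence is one CSV row per record plus a
JSON metadata sidecar (constants, ranges, seed, threshold), so an ensemble
is exactly reproducible.

Activity proxies: for each flux `J` in `{B_A -> MLL2, D_A -> KDM5, B_I ->
EZH2, D_I -> UTX}`, activity is the maximum over the mark level `q` of the
`phi_x`-average of `J(x, q)`. `D_A` is `x`-free and increasing in `q`, so
its proxy has the closed form `Lambda_A lambda_A K6 rho_A/(rho_A + K5)`,
used as an exact unit-test oracle; the grid maximiser agrees with a
bounded continuous optimiser to 1e-4 on fixtures.

## Perturbation ("therapy") screens

A protocol maps theta components to fold-change rules of a dose-like factor
`nu`: identity, `nu`, or `f(nu) = 2 - nu` for the counter-scaled partner of
a combination. Every rule is the identity at `nu = 1`; a `nu` for which a
fold change would be negative is marked infeasible, never clipped. The
screen rescales each bistable `theta`, re-classifies it with the same
machinery as the ensemble build, and reports the fractions that became
monostable, noise-induced, or stayed bistable (all three are reported so
either reading of "became monostable" is recoverable). The default `nu`
grid is 0.1–1.9 in steps of 0.1.

Statistics: two-sample Kolmogorov–Smirnov p-values per theta component
between sub-ensembles (raw p-values as published; a Benjamini–Hochberg
column is available but off by default), and Pearson correlations with
p-value bands (< 0.05, 0.05–0.5, > 0.5) mirroring the three-colour
presentation; Spearman is available as an option.

## The shipped calibration and what it does (not) show

The fixed constants, prior ranges and exemplar parameter sets in
`episwitch.reference` are a synthetic calibration found by seeded search
(`find_reference_params`), not canonical literature values. They were
chosen once so that:

* the OFF/ON wells sit near `x ~ 0.1` and `x ~ 1` (TF counts of order 20
  and 200 at `Omega_T = 200`), keeping finite-size effects on observable
  scales — `rho = 0.1`, `C1 = 9`, `C2 = 10`, `C4 = 5`;
* mark kinetics are genuinely fast relative to the TF
  (`Lambda_A = 100, Lambda_I = 10`) so the adiabatic reduction holds
  dynamically, and mark occupancies stay away from 0/1 so `Omega_S`-level
  granularity does not dominate;
* all four landscape classes are populated, with noise-induced the rarest
  (a few per thousand accepted).

Exemplars: the `BISTABLE` fixture has shallow, balanced barriers
(`dU0 ~ dU1 ~ 0.007`) so both wells are visited and visible in simulations
at `Omega_T` up to ~600; `BISTABLE_TUNABLE` carries its ultrasensitivity
almost entirely on the repressive mark (activating mark saturated), which
is the regime where scaling `K11` collapses the fitted Hill exponent from
~2.1 to ~1.0 while crossing the saddle-node; the `NOISE_INDUCED` fixture
was selected for the visibility of its second mode at `Omega_T = 200`
(second-peak prominence ~0.2 of the maximum).

Because the calibration is synthetic, quantitative ensemble-level numbers
(class percentages, which specific theta components separate sub-ensembles,
which parameter pairs correlate) are conditional on it and are not expected
to match any particular published table. What the tests do establish:
the exact birth–death limit (TV < 0.02 against Poisson for both the WKB
density and simulation at `Omega_T = 50`); agreement of the three routes to
the stationary behaviour (mean-field roots to 1e-6, simulation vs WKB
density to TV < 0.1 at `Omega_T = 600, Omega_S = 150` on all four classes);
the noise-induced mono-to-bimodal transition as size falls from 800 to 200
(at `eps2 = 0.25` for mark-count resolution); basin monotonicity along
`B2`/`K11` rays (n = 2000); screen identity at `nu = 1` and dominance of the
`K6`–`K12` combination over its single-target components; and 5% type-I
calibration of the KS (n = 500 per sample; smaller samples make the exact
two-sample test visibly conservative) and correlation tests over 1e4 null
replicates.

Problem sizes used by the acceptance pipeline (seeded, recomputed from
scratch each run): simulation spans of 1.5e4–4e4 time units, ensembles of
400 accepted parameter sets, 2000 Monte-Carlo basin samples per estimate,
1e4 calibration replicates.

## Known limitations

* The WKB density is leading-order-plus-correction; at small `Omega_S` the
  point-evaluation of rates at `q*(x)` ignores a Jensen gap of order
  `Var(q)`, which is why distribution-level comparisons are run at
  `Omega_S >= 100`.
* Noise-induced wells are `O(1/Omega_T)` deep by construction, so their
  bimodality is always modest; detection needs long runs and the smoothing
  described above.
* Mean first-passage/escape-rate computations, numerical continuation of
  the saddle-node curves, the unreduced reaction network, and cooperative
  (non-monomeric) TFs are out of scope.
* `P_off` near the saddle-node changes steeply with parameters; values on
  a ray are comparable only under the fixed sampling domain described
  above.
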