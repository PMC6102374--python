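# Methods

`neurouq` propagates parameter uncertainty through a black-box model
`Y = U(t, Q)` whose `d` uncertain parameters `Q = (Q_1, ..., Q_d)` carry a
joint probability density `rho_Q`, and attributes the resulting output
variance to the individual parameters. This note records the models,
estimators, numerical choices and their limitations.

## Uncertainty metrics

For every analyzed output (the raw model and each extracted feature) the
toolbox reports, per output point: the mean `E[Y]`, the variance `V[Y]`, the
5th and 95th percentiles (bounding the 90% prediction interval), the
first-order Sobol indices `S_i = V[E[Y|Q_i]] / V[Y]`, the total-order indices
`S_Ti = 1 - V[E[Y|Q_-i]] / V[Y]`, and the time averages of both index
families. `S_i` measures the variance explained by `Q_i` alone; `S_Ti` adds
all interactions involving `Q_i`. With positive variance, `sum_i S_i <= 1`
and `sum_i S_Ti >= 1`, with equality exactly when the model is additive.
Points with (numerically) zero variance have undefined indices and are
reported as NaN, never fabricated.

## Polynomial chaos expansions

The default engine approximates the model by a truncated expansion
`U ~= sum_n c_n(t) phi_n(Q)` in multivariate polynomials orthonormal under
`rho_Q`, truncated at total degree `p` (default 4), giving
`Np = C(d+p, p)` terms. Univariate families come from the classical
three-term recurrences — Legendre for uniform marginals, probabilists'
Hermite for normal ones — and from the discretized Stieltjes procedure for
any other marginal with an inverse CDF (the measure is discretized through
`E[f(X)] = int_0^1 f(F^-1(u)) du` with a 600-point Gauss-Legendre rule in
`u`). The basis is normalized to `gamma_n = E[phi_n^2] = 1`, which
conditions the regression; multi-indices are ordered graded-lexicographically
so the coefficient layout is deterministic and persistable.

**Point collocation** (default): the expansion is regressed against model
evaluations at `Ns = 2(Np + 1)` nodes, the standard two-fold oversampling
rule. Nodes are Hammersley points of the unit hypercube — first coordinate
the midpoint-shifted equispaced sequence, remaining coordinates radical
inverses in the first primes, indexed from 1 so no node touches the
boundary, where inverse CDFs of unbounded marginals diverge — mapped through
the joint's inverse Rosenblatt transformation. The regression uses Tikhonov
regularization; the penalty is selected by generalized cross-validation over
a logarithmic grid that includes zero. Very large designs (the order-6
reference fit below) use a fixed negligible penalty and accumulate the
normal equations in row chunks so the full design matrix is never held in
memory. Invalid model evaluations are dropped from the regression, which
tolerates them as long as at least `Np` valid rows remain (a warning is
raised below the recommended `2(Np+1)`).

**Pseudo-spectral projection** (on request): coefficients are computed by
quadrature, `c_n = sum_k w_k Y(x_k) phi_n(x_k)`. The rule is a Gaussian
tensor product for `d <= 4` and a Smolyak combination of Gaussian rules for
higher dimensions; "quadrature order" means points per one-dimensional rule
and defaults to `p + 2`. Because every node carries a fixed weight, a single
invalid evaluation invalidates the projection; the implementation refuses to
proceed and points the user to collocation.

From the fitted expansion: `E[Y] = c_0`, `V[Y] = sum_{n>=1} c_n^2`, the
Sobol indices are partial coefficient sums (terms whose multi-index is
nonzero only in coordinate `i` for `S_i`, nonzero at all in `i` for `S_Ti`),
and the percentiles are read off 10^4 Hammersley-sampled surrogate
evaluations. The expansion reproduces any polynomial model of total degree
`<= p` exactly (to solver precision), which the tests exploit as an oracle.

## Quasi-Monte Carlo / Saltelli estimation

With `method="mc"` the toolbox evaluates the model on a Saltelli design of
`Ns = N(d+2)` points (default `N = 10,000`): blocks A and B are the first
and last `d` columns of a scrambled Sobol' sequence in `2d` dimensions, and
block `AB_i` copies A with column `i` replaced from B. Mean, variance
(unbiased, `1/(N-1)`) and percentiles use the A-block only, since the
remaining rows are not mutually independent. First-order indices use the
Saltelli (2010) estimator `S_i = mean(f_B (f_ABi - f_A)) / V` and
total-order indices the Jansen estimator
`S_Ti = mean((f_A - f_ABi)^2) / (2V)`, with `V` the pooled A+B sample
variance; both are verified against closed-form indices in the tests.
Invalid evaluations are replaced by the mean of the valid ones before the
estimators run — the standard workaround, which biases the indices in
proportion to the imputed fraction and therefore warns with the count. More
than 50% invalid evaluations abort the run with guidance to narrow the
parameter distributions.

## Dependent parameters

Dependent joints are specified constructively: coordinate `i` carries a
conditional distribution that may depend on the values drawn for
coordinates `0..i-1`. The Rosenblatt transformation is then exact — the
forward map is the sequence of conditional CDFs — rather than an
approximation fitted to data. When a dependent joint is present, the
polynomial basis is built over an independent *uniform* base on `[0,1]^d`
and nodes are mapped through the inverse Rosenblatt transformation before
the model sees them; the surrogate is a function of the base variables, so
all statistics are unchanged. (An independent normal base would serve
equally; the uniform base keeps nodes bounded and the basis Legendre.)

## Features

A feature set is a shared `preprocess` step plus named feature functions; a
feature that is undefined for a given evaluation (spike width without a
spike) returns `None` and that evaluation is handled by the engine's
invalid-evaluation policy for that feature only.

**Spiking features** operate on spikes detected as contiguous
super-threshold excursions of the voltage trace. The detection threshold is
a configurable absolute voltage (default -30 mV; models in the original
0 mV-resting convention should pass a value above their baseline, e.g.
+20 mV), the spike window extends up to ±5 ms around each peak and is
truncated at midpoints between adjacent peaks. The seven features:
number of spikes in the stimulus interval; firing rate (count / stimulus
duration); latency from stimulus onset to the first spike; accommodation
index (mean of `(ISI_i - ISI_{i-1}) / (ISI_i + ISI_{i-1})` after discarding
the first `k` intervals, `k = 0` below five ISIs and 1 otherwise,
configurable since the protocol-dependent choice is not standardized);
mean peak voltage; mean afterhyperpolarization depth (global trace minimum
between consecutive peaks); and mean AP width at the voltage midway between
onset (threshold crossing) and peak, interpolated linearly on both flanks.

**Network features** operate on sets of spike trains. Per-unit: firing
rate, ISI coefficient of variation, local variation
`3 * mean[(ISI_i - ISI_{i+1})^2 / (ISI_i + ISI_{i+1})^2]`; their
population averages (`average_isi` averages per-unit mean ISIs, matching
"averaged over all recorded neurons"); the Fano factor of per-train spike
counts; an instantaneous population rate in a sliding 10 ms window; a
pooled ISI histogram; and pairwise matrices — Victor-Purpura edit distance
(unit insert/delete cost, move cost 0.2/ms so a 5 ms shift equals a
delete+insert), van Rossum distance (causal exponential kernel, tau = 10 ms,
evaluated in closed form), and Pearson correlation/covariance of the binned
binary trains. The bin width defaults to the spike trains' recorded
resolution (1 ms when unknown). For uncertainty quantification the matrix
features contribute their upper triangle as a fixed-length vector.

**Binary post-processing** converts a spike train to a 0/1 sequence on the
grid `0, dt, ..., floor(end/dt)*dt`; a spike at `s` lands in bin
`round(s/dt)` with half-up tie-breaking.

## Built-in models

*Cooling coffee cup*: `dT/dt = -kappa (T - T_env)`, `T(0) = 95` degC over
200 min on a 150-point grid, solved with LSODA at `rtol = atol = 1e-10`
(the closed form is kept out of the model so it can serve as the test
oracle). Case-study priors `kappa ~ U(0.025, 0.075)` 1/min,
`T_env ~ U(15, 25)` degC. The dependent variant
`dT/dt = -alpha kappa_hat (T - T_env)` draws `alpha ~ U(0.5, 1.5)` (any
zero-free interval works — the choice provably cannot affect the output
statistics) and `kappa_hat | alpha ~ U(0.025/alpha, 0.075/alpha)`, so that
`alpha * kappa_hat` is distributed exactly like `kappa`.

*Hodgkin-Huxley*: the original four-variable squid-axon model in its
original convention (resting potential 0 mV, depolarization positive,
`E_Na = 112`, `E_K = -12`, `E_L = 10.613` mV), with the classical 1952 rate
functions (the `x/(e^x - 1)` removable singularities are series-expanded
near 0). Constant stimulus 140 uA/cm^2 from `t = 0`; fixed-step RK4 at
`dt = 0.01` ms, recorded every fifth step (0.05 ms) and reported on the
5-15 ms window — the first 5 ms are discarded as initial transient, the
simulation itself always starts at 0. Halving the step changes the default
trace by under 0.5 mV sup-norm. All 11 parameters take uniform ±10%
priors around their original values. The integrator is vectorized across
parameter sets (state arrays of shape `(n_nodes,)`), and the runner
dispatches whole node sets to it at once, which is what makes the
65,000-evaluation Saltelli runs routine.

*Recurrent network*: 10,000 excitatory and 2,500 inhibitory leaky
integrate-and-fire neurons with delta synapses, fixed in-degree 1,000
excitatory / 250 inhibitory connections per neuron (connection probability
0.1), `J = 0.1` mV, inhibitory weight `-gJ`. Membrane constants are the
canonical ones for this network (`tau_m = 20` ms, threshold 20 mV, reset
10 mV, refractory 2 ms); the external drive is an independent Poisson
process of total rate `eta * nu_thr * C_E` per neuron with
`nu_thr = theta / (J C_E tau_m)`. Dynamics on a fixed 0.1 ms grid:
exponential membrane decay, delayed inputs via a circular buffer
(`delay >= dt` enforced), threshold crossings recorded at the crossing
step. Connectivity is sampled without replacement via the
smallest-uniforms trick and inverted once into flat out-target lists;
spike propagation is a `bincount` over the targets of the spiking neurons.
The first 20 excitatory units are recorded over [100, 1000] ms (times
reported relative to recording onset, end 900 ms). Uncertain-parameter
ranges: `eta ~ U(1.5, 3.5)`, `delay ~ U(1.5, 3)` ms, and `g ~ U(1, 3)`
(synchronous-regular state) or `g ~ U(5, 8)` (asynchronous-irregular
state).

## The accuracy comparison and its error metric

The PCE-vs-QMC comparison uses the time-averaged absolute relative error
`eps_X = mean_t |X - X_est| / |X|` per quantity, with the first 5 ms of the
Hodgkin-Huxley trace excluded (the reported window already starts at 5 ms).
For the first-order Sobol indices the error is computed per parameter and
averaged over parameters. A parameter whose *reference* index curve never
exceeds 1e-6 on the [0, 1] index scale is excluded from that average: its
relative error divides by what is numerically zero and is undefined, not
informative. In the 11-parameter Hodgkin-Huxley study this excludes the
initial gating states `n0` and `m0`, whose converged indices are ~1e-8.
This exclusion matters: keeping such parameters makes the metric diverge as
1/|reference noise| and report arbitrary values in the tens-to-hundreds for
*any* estimator — the blow-up measures the reference, not the method.

The converged reference is an order-6 point-collocation expansion (24,754
model evaluations, plain least squares via chunked normal equations). An
order-6 reference is practical on a single CPU precisely because of the
vectorized Hodgkin-Huxley integrator; order 4 vs order 5 already agree to
well under 1% on every case-study statistic, so the order-6 fit is
comfortably converged. Measured with these choices, the order-4 expansion
(2,732 evaluations) attains a Sobol-index error of ~0.06, while Saltelli
estimation at 65,000 evaluations attains ~13-27 depending on the
scrambling seed — two to three orders of magnitude worse, the same
qualitative gap the method comparison is designed to exhibit. One caveat
recorded here deliberately: because the Saltelli estimator's *absolute*
error scales with a parameter's actual effect, relative errors for
parameters with small-but-resolved indices (initial voltage, leak
parameters) dominate the QMC average; the number is best read as "QMC
cannot resolve the minor indices at this budget", not as a point estimate
of a stable quantity.

## What the synthetic conditions do and do not show

All inputs are generated by the built-in models under the documented
priors; there is no measured data anywhere. Passing tests therefore
demonstrate the statistical machinery (sampling, expansion, estimators,
feature definitions, persistence) and the documented dynamical properties
of the three models — not that the ±10% uniform priors are realistic
descriptions of biological variability, nor that the feature set captures
what matters in any particular experiment. The network analysis uses
single simulations per state for its regime contrast; a full UQ of the
network (thousands of simulations) is out of desk scale and not attempted.

## Numerical choices and degenerate inputs

- `uniform_pm(0, f>0)` is an error, not a silent point mass: a zero-width
  "uncertain" parameter almost always indicates a bug upstream.
- Hypercube points on the closed boundary are rejected by the Rosenblatt
  maps (inverse CDFs may diverge there); the samplers never produce them.
- Zero-variance output points yield NaN Sobol indices plus finite
  time-averages over the defined points; fully-NaN outputs are skipped with
  a warning.
- Percentile convention: linear interpolation between order statistics
  everywhere (surrogate sampling, QMC, features).
- Interpolation of irregular output: common grid = time axis of the valid
  evaluation with the most points restricted to the intersection of spans
  (no extrapolation); piecewise cubic, linear below 4 points.
- The Saltelli base sample count need not be a power of two; the scrambled
  Sobol' sequence then loses some balance but the estimators remain
  consistent (scipy's warning is silenced at the call site).
- Seeds: one integer seed controls the Sobol' scrambling and the network's
  Poisson drive/connectivity; PCE is fully deterministic (Hammersley nodes,
  direct solves), so identical calls are bit-identical.

## Known limitations

- Expansions beyond ~20 parameters are impractical (`Np` growth), the same
  regime boundary that motivates the QMC fallback.
- The Smolyak spectral path uses non-nested Gaussian rules; node counts are
  larger than nested Leja constructions would give.
- Feature output must be scalar or fixed-length one-dimensional for the UQ;
  matrix features are flattened, and only one-dimensional interpolation is
  supported.
- One-at-a-time screening ignores interactions by construction.
- The LIF network records 20 units of one realization per parameter point;
  trial-to-trial variability of the network statistics is not separated
  from parameter uncertainty.
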