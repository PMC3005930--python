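# Methods

## Model

Each modeled gene *g* follows the sigmoid production/decay rate law

    dx_g/dt = R_g σ(u_g) − λ_g x_g,   u_g = Σ_{g'} T_{gg'} x_{g'} + h_g

with maximum production rate `R_g ≥ 0` (expression units per time),
regulatory weights `T_{gg'}` (per expression unit), bias `h_g`
(dimensionless) and decay rate `λ_g ≥ 0` (per time). Production saturates
at `R_g`; decay is first-order; a gene's trajectory is therefore confined
to `[0, max(x_0, R_g/λ_g)]` for nonnegative inputs. Genes without a
parameter entry are *exogenous*: their levels enter other genes' input sums
but are taken from data (splines) or supplied trajectories, never
integrated.

The sigmoid `σ` must be strictly increasing with limits 0 and 1. The
literature that uses this model class does not pin a unique functional
form, so the package defaults to the logistic `1/(1+e^{−u})` and also
offers the algebraic form `½(u/√(u²+1)+1)`; the choice is recorded in every
serialized model. Numerically, outputs are clamped just inside the open
interval (0, 1) so downstream code can rely on strict bounds even where
float64 saturates.

## Smoothing

Each series (minimum 4 time points) is interpolated per gene with a cubic
spline under the not-a-knot end condition (third derivative continuous
across the second and penultimate knots); natural and clamped variants are
selectable but have only small effects on the interpolant. Interpolation —
not penalized smoothing — is deliberate: the estimator consumes the
spline's *analytic* derivative, obtained by differentiating the polynomial
coefficients, and observation noise is expected to be handled upstream (the
generator default is noiseless) or by the optional centered moving-average
`presmooth` (odd window, edge replication). Evaluation outside `[t_0, t_T]`
is rejected: the error integral is defined over the trajectory's duration
only, and extrapolated derivatives are meaningless for fitting.

Spatially resolved data are represented as independent series, one per
space point (58 for a gap-gene-shaped set); time is the only spline axis.

## Estimation

The derivative-based error of gene *g*,

    E0(θ_g) = Σ_i ∫ ( dŷ_g^i/dt − f_g(ŷ^i(t), θ_g) )² dt,

is approximated by a composite trapezoid rule on a uniform refinement of
each knot interval, 5 quadrature points per interval by default; doubling
the density changes E0 by well under 0.1 % on benchmark fixtures. Because
`θ_g` enters only gene *g*'s equation, the network objective is a sum of
per-gene terms, and each gene is fitted independently — results cannot
depend on the order in which genes are processed.

Each per-gene problem is a bounded minimization over `(R, λ, h, T·)`
solved by L-BFGS-B with analytic gradients, restarted from `n_starts`
points drawn uniformly within the bounds (1000 by default, matching the
regime the method was designed for; 25–50 suffice on the packaged
benchmarks and are what the tests and the acceptance script use). The
restart stream is seeded by `(seed, target gene, regulator set)`, so fits
are deterministic, reproducible gene-by-gene, and identical whether a
subset is fitted directly or inside an enumeration. Ties across starts go
to the lowest start index.

Bounds presets:

* `drosophila` — weights in [−0.1, 0.1], production [0, 25], decay
  [0, 10], bias fixed at −3.5; native 0–255 data scale; autoregulation
  allowed.
* `irma_gnw` — weights in [−0.2, 0.2], production [0, 25], decay [0, 10],
  bias free in [−25, 25]; data rescaled so the global maximum is 100
  (`normalize_to_range`); autoregulation disallowed.

The L1-penalized objective `E1 = E0 + c·Σ|T|` (penalty on regulatory
weights only) is made smooth by the exact split `T = p − m`, `p, m ≥ 0`,
penalty `c(p+m)`, keeping the same optimizer; the per-`c` contract is
best-of-starts at that `c`, with no warm starting. There is no principled
universal choice of `c` for dependent time-series data, so the package
reports the whole path (default grid 0 to 10 in steps of 0.1) and flags
links that survive at the largest `c` as highest-confidence.

Thresholding uses strict comparison: `|T| < 0.006` (on the fitted scale) is
a zero call, otherwise the sign of `T`. The threshold is applied uniformly
across data sets.

## Enumeration

All `2^K` subsets of a gene's candidate regulators are fitted with weights
outside the subset structurally fixed at zero. Subsets are encoded as
bitmasks over the candidate order; error ties break toward the smaller
bitmask. The best-per-size table annotates the regulator whose addition
produced the best size-*k* set when it nests the best size-(k−1) set; the
non-nested case is reported as the full subset. The per-subset restart
budget is configurable separately from the global default because the full
1000-start budget across hundreds of subsets is a cluster-scale job.

## Evaluation

A "link" is a directed (regulator, target) pair over the modeled targets
and candidate regulators; with autoregulation disallowed, diagonal pairs
are excluded from every denominator. CF counts exact −/0/+ agreement;
TP/TN/FP/FN are sign-blind presence/absence counts; PPV = TP/(TP+FP),
Sens = TP/(TP+FN); CSF is the fraction of links nonzero in both networks
with matching sign (denominator TP). Fractions with empty denominators are
reported as undefined (serialized as empty fields), never as 0. The chance
level of CF under uniform random signing is 1/3 regardless of the gold
standard.

## Synthetic data

`generate_benchmark` draws a signed topology (sparse: in-degree 1–2 per
gene; dense: near-full) and parameters *strictly inside* the `irma_gnw`
bounds — production in [8, 20], decay in [0.5, 2] per time unit, bias in
[−2, 2], weight magnitudes in [0.04, 0.1] — so the generating truth is
always attainable by the optimizer, and simulates either

* `varied_initial_conditions` (default): 20 series of 16 points over 4
  time units from initial states uniform in [2, 60]; these ranges place
  trajectories in roughly [0, 80] so sigmoid inputs sweep the responsive
  region rather than saturating; or
* `perturb_relax`: the network is brought to its steady state, one random
  gene's production is transiently boosted, and only the relaxation half is
  returned; the perturbation/relaxation period is max(4, 6/λ_min) so the
  recorded half genuinely returns to rest (residual < 1 % of its initial
  value). Non-relaxing draws are regenerated from the next sub-seed, with
  a retry cap.

Noise is off by default; optional i.i.d. Gaussian noise is added to
observations and clipped at zero.

Two shaped fixtures reproduce the dimensions, value ranges, gene names and
gold topologies of well-known data sets without containing their
measurements (both are labelled synthetic): a gap-gene-shaped set (7 genes
× 8 times × 58 space points = 3248 values in [0, 255]; Hb, Kr, Gt, Kni
modeled with autoregulation, Bcd, Cad, Tll exogenous with quasi-static
spatial profiles) and an IRMA-shaped set (SWI5, CBF1, GAL4, GAL80, ASH1;
5 switch-on series sampled every 20 min over 5 h; canonical 7-edge gold
standard in which GAL80 represses SWI5 at the mRNA level and does not
affect GAL4). Consequently, passing the recovery tests demonstrates
correctness of the pipeline on data generated by the model class itself —
it does not certify performance on real measurements, which carry
observation noise, model mismatch and unmeasured regulators.

All generation is keyed by a single integer seed and reproduces outputs
byte for byte.

## Numerical choices and limitations

* Integrator: adaptive RK45 with rtol 1e−6 / atol 1e−8; a fixed-step
  classic RK4 exists for order-of-convergence checks (terminal error drops
  ≥ 8× on halving the step).
* The derivative-based error never calls the integrator; the
  trajectory-based error solves the ODE once per series and is provided
  for comparison and diagnostics only.
* Multi-start local optimization carries no global-optimality guarantee;
  on the packaged benchmarks 25–50 starts reliably reach or beat the
  generating parameters on the objective, and an 11-point-per-parameter
  grid oracle is used in the tests as an independent floor.
* Regulators whose sigmoid input rarely leaves saturation are weakly
  identifiable — a limitation of the data, not the optimizer; the
  enumeration tables make such cases visible as flat error profiles.
* Delay equations, stochastic kinetics, separate mRNA/protein layers and
  penalized (smoothing) splines are out of scope.
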