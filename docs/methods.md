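# Methods

## Bulk induction kinetics

The bulk model treats a culture's mRNA level as a single deterministic
trajectory: zero until an onset time *x*, then first-order kinetics
dM/dt = α − δM towards the steady state α/δ. The model is linear past the
onset, so the package evaluates the exact solution
M(t) = (α/δ)(1 − e^{−δ(t−x)}) everywhere; a Runge–Kutta integration
(`predict_mrna_numeric`, scipy `solve_ivp` at rtol 1e-12 started exactly at
the onset) is retained purely as a cross-check, which removes integrator
tolerance as a failure mode. The degenerate δ = 0 case returns the linear
accumulation limit α(t − x). The half-steady-state time is the analytic
inversion x + ln2/δ, cross-checked against Brent root-finding on the
trajectory.

**Fitting.** The objective is the RMSD between the model at the measured
times and the replicate-averaged data (per-replicate fitting is available
via `per_replicate=True`; averaging is the default because the replicate
mean is the quantity the phenotype metrics describe). Parameters are
bounded: x ∈ [0, max t], α ∈ [0, 50·max value], δ ∈ [1e-4, 5] per time
unit. Each of `n_starts` (default 50) random starts — onset uniform,
α and δ log-uniform so small rates are reachable — runs L-BFGS-B followed
by a bounded Nelder–Mead polish; the quasi-Newton step descends quickly but
stalls on the kink where the onset crosses a data time, which the
derivative-free polish crosses. Ties within 1e-10 of the best objective
break toward the smallest onset, then lexicographically smallest
parameters, making the result deterministic given the seed. An all-zero
time course returns α = 0 with a warning rather than an error.

Times are carried with an explicit unit (minutes for the bulk convention,
hours for the flow experiments); rates scale inversely when a course is
converted.

## Phenotype metrics and comparison tables

Four metrics per fit: activation time x, steady state α/δ, time to
half-steady-state x + ln2/δ, and the activation-to-half interval ln2/δ
(the last isolates the post-onset transcription rate from the lag).
Comparison tables are percentages rounded to one decimal, half away from
zero, matching the printed convention; full precision is kept internally.
`relative_to_reference` always computes 100·strain/reference within the
same induction condition. When reference and strain values are both zero —
reinduction onsets are all below the time resolution — the ratio is
reported as 100.0; a zero reference against a nonzero value is an error.
`percent_change` computes 100·(secondary − primary)/primary per metric.

## Single-cell accumulation model

Per cell: E_i(t) = x_i(t − t_i)_+ + ε_i with Gamma-distributed induction
time and accumulation rate and Normal background noise. Gamma distributions
keep both quantities non-negative while absorbing unmodelled cell-to-cell
variability (size, cycle stage, age). One (t_i, x_i, ε_i) triple is drawn
per cell and reused across snapshot times, so a simulated population is a
consistent cohort; per-time noise redraw is available behind a flag. The
population mean has the closed form
μ + k_xθ_x·[t·F(t;k_t,θ_t) − k_tθ_t·F(t;k_t+1,θ_t)] (F the Gamma CDF),
used as the simulator's analytic oracle.

**Gating.** The positive gate is the empirical 98.5th percentile of the
uninduced reference — the midpoint of the 1–2% false-positive band —
computed with the next-highest order statistic so the strictly-above
fraction stays inside the band. Negative intensities (possible with small μ
and σ > 0) participate in gating but are excluded from geometric means,
which are undefined for non-positive values. Intensities are arbitrary
"GFP counts"; no instrument calibration is modelled.

## Fitting the single-cell model

Snapshots at different times sample different cells, so per-cell pairing
between model and data is impossible; the objective is a distribution
distance. At each snapshot time the observed replicates are binned on a
common 64-bin grid of asinh-transformed intensity spanning the pooled
observed range (asinh behaves like log at high intensity but tolerates the
negative background values), their normalized frequencies averaged, and the
RMSD against a simulated population's frequencies summed over the snapshot
times. Simulated frequencies are normalized by total cell count so
probability mass escaping the observed range is penalized. A decile-RMSD
mode is provided as an alternative reading.

**Common random numbers.** Every objective evaluation simulates with the
same seed (`config.seed`), making the stochastic objective one fixed
deterministic function. This keeps restarts directly comparable and the
whole fit reproducible; the residual Monte-Carlo bias from one fixed noise
realization is far below the parameter-recovery tolerance at the profile
sizes used.

**Optimization.** Search runs in a transformed space — log coordinates for
shapes and scales (bounds: shapes [0.1, 100], scales [1e-3, 100]), linear
for μ ∈ [−5, 5] and σ² ∈ [0, 25] — so steps are scale-free. Each restart
runs a small real-coded genetic algorithm (tournament selection of size 3,
elitism, extended blend crossover with weights in [−0.25, 1.25], per-gene
Gaussian mutation decaying from 20% to 2% of the coordinate range), then
two rounds of adaptive Nelder–Mead from the GA winner with a fresh initial
simplex (spread 0.4 per coordinate); the restart round escapes premature
simplex collapse on the piecewise-flat stochastic objective. The best
restart wins; per-parameter min–max over the top-k restarts is the
uncertainty range and necessarily brackets the best fit.

Two documented profiles: the full-fidelity profile (200 restarts, 100,000
simulated cells, GA population 60 × 40 generations, top-50 ranges) and a
scaled validation profile (20 restarts, 10,000 cells, GA 30 × 25, top-5)
used by the test suite and the acceptance script. At the scaled profile the
recovered population means (mean activation time k_tθ_t, mean expression
rate k_xθ_x) land within a few percent of truth; individual shape/scale
pairs are less identifiable than their product, which is why the means are
the reported phenotypes.

## Synthetic data

The generator emulates the structure of the real experiments: triplicate
bulk courses sampled every 2 h over 14 h with multiplicative Gaussian noise
(default CV 5%, clipped at zero — expression ratios are positive with
scale-dependent scatter), and triplicate independent single-cell
populations at 0/2/4/6 h. Three presets (wild-type-like, deletion-like,
unacetylatable-like) carry truth parameters reverse-engineered from the
published summary statistics: bulk onset/steady-state/half-lag anchors of
(204.8 min, 0.9, 29.5 min), (214.1, 0.7, 148.3) and (191.3, 0.8, 184.2),
and single-cell means of (4.2 h, 2.2 counts/h), (6.5, 1.3) and (5.5, 2.1)
with Gamma shapes fixed at 4 (cell-to-cell CV of 50%) and background
Normal(0.1, 0.05²). The presets reproduce those printed summaries by
construction and make no claim about the unpublished fitted parameter sets.

What passing on synthetic data does not show: the generator draws from the
same model family the fitters assume, so recovery tests validate the
estimation machinery, not model adequacy for real measurements. Real
cytometry adds autofluorescence structure, instrument nonlinearity and
doublets that the Normal noise term does not capture; real Q-RT PCR adds
amplification-efficiency error beyond multiplicative noise.

## Numerical conventions

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; derived seeds use seed-sequence lists so
replicates and restarts are independent but reproducible, and extending the
number of restarts preserves the earlier ones (the best objective is
monotone in restarts). JSON outputs use fixed key order and 12 significant
digits so reruns diff byte-identically. Report rounding is one decimal,
half away from zero. Known limitations: the bulk model has a single steady
state and no overshoot, so data that overshoot induction equilibrium bias δ
upward; the flow objective's histogram binning ties resolution to the
pooled observed range; and the GA/simplex budget trades global coverage for
runtime at the scaled profile (hence multi-start plus top-k ranges rather
than a single run).
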