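# galinduce

Quantitative analysis of inducible gene expression in budding yeast, built
around the *GAL1* galactose-induction system. The package addresses two
questions a yeast geneticist asks of induction data: **how fast does a
culture turn a gene on** (bulk mRNA time courses), and **is a defect due to
fewer cells inducing or to less expression per induced cell** (single-cell
flow cytometry). It provides the two fitted models, the derived phenotype
metrics and comparison tables, cytometry gating statistics, and a
synthetic-data generator so the whole pipeline is testable end to end.

## Models

**Bulk induction kinetics.** Transcript level M(t) (expression ratio against
a reference gene) follows a three-parameter piecewise ODE:

    dM/dt = 0              for t <  x        (lag before onset)
    dM/dt = α − δ·M(t)     for t ≥  x,  M(0) = 0

with onset time *x*, production rate α and degradation rate δ, all
constrained non-negative. The closed form

    M(t) = (α/δ)·(1 − e^{−δ(t−x)})   for t ≥ x

approaches the steady state α/δ and passes half of it at t = x + ln2/δ.
Fitting minimizes the RMSD between the model and replicate-averaged
measurements from many random starts. Derived phenotypes: activation time
x, steady-state level α/δ, time to half-steady-state x + ln2/δ, and the
activation-to-half interval ln2/δ.

**Single-cell accumulation.** Each cell *i* is silent until its own
induction time t_i, then accumulates Gal1-GFP linearly at its own rate x_i,
on top of Normal background noise ε_i:

    E_i(t) = x_i·(t − t_i)_+ + ε_i,
    t_i ~ Gamma(k_t, θ_t),  x_i ~ Gamma(k_x, θ_x),  ε_i ~ Normal(μ, σ²)

The population's induction phenotype is summarized by the mean activation
time k_t·θ_t (hours) and mean expression rate k_x·θ_x (GFP counts/hour).
The six parameters are fitted to snapshot intensity distributions by
histogram-RMSD minimization with a genetic-algorithm + Nelder–Mead
multi-start; per-parameter ranges over the top-k restarts give an
uncertainty estimate. Gating follows cytometry convention: a threshold set
so 1–2% of an uninduced reference is called positive, and geometric-mean
intensity of gated cells as the expression level.

## Worked example

`examples/01_fit_bulk_timecourse.py` generates a wild-type-like triplicate
time course (2-h sampling over 14 h, 5% noise) and fits it:

```
truth : onset 204.8 min, steady state 0.90
fitted: onset 208.7 min, steady state 0.89, RMSD 0.0235
time to half-steady-state 235.9 min (27.2 min after onset)
```

The fitted onset (the lag before any transcription) lands within 2% of the
generating truth, and the half-time decomposes into onset plus ln2/δ.

`examples/04_fit_single_cell_model.py` fits the six-parameter model to
synthetic snapshots from a truth with mean activation 4.2 h and mean rate
2.2 counts/h:

```
mean activation time : 4.17 h   (truth 4.20)
mean expression rate : 2.25 counts/h (truth 2.20)
```

The other examples show the strain comparison tables
(`02_comparison_tables.py`) and the gating statistics over an induction time
course (`03_simulate_and_gate.py`). A thin CLI wraps the same pipeline:
`galinduce make-synthetic | fit-mrna | derive-metrics | simulate-flow |
fit-flow`.

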