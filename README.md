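# frbayes

Bayesian fitting and comparison of **predator-dependent functional
response models** for prey-depletion feeding experiments — the kind of
trial where one to a few predators (e.g. ladybird beetle larvae,
*Propylea quatuordecimpunctata*) are enclosed with a known number of
prey (e.g. *Aphis fabae* nymphs) for a fixed time and the eaten prey
are counted. It is written for ecologists who want to go beyond the
purely prey-dependent Holling disc equation and ask whether **mutual
interference** between predators measurably lowers the feeding rate.

## The models

Prey are not replaced during a trial, so the observable is the solution
N(t) of a depletion ODE, not an instantaneous feeding rate. With attack
rate *a* (h⁻¹), handling time *T_h* (h), interference magnitude *c* and
interference exponent *m*:

| model | dN/dt |
|---|---|
| Holling type II (H2) | −aNP / (1 + aT_hN) |
| Beddington–DeAngelis (BD) | −aNP / (1 + aT_hN + c(P−1)) |
| Crowley–Martin (CM) | −aNP / (1 + aT_hN + c(P−1) + aT_hcN(P−1)) |
| Hassell–Varley (HV) | −aNP^(1−m) / (1 + aT_hNP^(−m)) |

All four coincide at P = 1. Each ODE has an exact implicit solution
α·ln(N₀/N) + β·(N₀−N) = A·t, solved in closed form via the Lambert W
function.

The observation model is binomial: each prey item is eaten by time *t*
with probability p(t) = (N₀ − N(t))/N₀, so the count eaten is
Ne ~ Binomial(N₀, p(t)). Posteriors are sampled by random-walk
Metropolis with proposal scales tuned to a 25% acceptance rate during
burn-in; models are compared by DIC (D̄ + p_D, with
p_D = D̄ − D(θ̄)). Because the four models are likelihood-equivalent at
any *single* predator density, the interference parameters are
identified through an informative prior: the attack-rate posterior of
the H2 fit is moment-matched to a Gamma distribution and used as the
prior on *a* for BD/CM/HV.

## Worked example

Simulate one experiment (3 predators, Crowley–Martin dynamics at the
reference estimates) and fit it:

```sh
frbayes simulate --scenario CM/P3 --seed 7 --out cm3.csv
frbayes fit --input cm3.csv --iterations 12000 --burn-in 4000 \
            --seed 1 --outdir run_cm3
```

The fit prints a per-density summary such as

```
Predator density P = 3
  Holling type II (H2)
     a: mean 0.264  95% CrI [0.221, 0.318]
    th: mean 0.309  95% CrI [0.282, 0.336]
  Beddington-DeAngelis (BD)
     a: mean 0.279  95% CrI [0.240, 0.326]
    th: mean 0.301  95% CrI [0.274, 0.327]
     c: mean 0.063  95% CrI [0.002, 0.194]
  Crowley-Martin (CM)
     a: mean 0.280  95% CrI [0.238, 0.325]
    th: mean 0.266  95% CrI [0.205, 0.314]
     c: mean 0.069  95% CrI [0.003, 0.184]
  Hassell-Varley (HV)
     a: mean 0.278  95% CrI [0.240, 0.320]
    th: mean 0.302  95% CrI [0.277, 0.329]
     m: mean 0.096  95% CrI [0.003, 0.231]
  DIC ranking (best first): CM, HV, BD, H2
    DIC[H2] = 219.931 (pD = 1.925)
    DIC[BD] = 219.898 (pD = 1.735)
    DIC[CM] = 219.682 (pD = 1.513)
    DIC[HV] = 219.778 (pD = 1.728)
```

Read: handling time ≈ 0.3 h, and the interference magnitude *c* is
small but its credible interval excludes zero; the CM fit recovers the
generating T_h = 0.300 and c = 0.079 within its intervals, and the
interference models edge out plain Holling II by a small DIC margin.
The attack rate illustrates the method's one structural caveat: at a
single predator density the data identify only the *effective* rate
a/(1 + c(P−1)), so the CM attack rate stays anchored near the H2
estimate of this (low-drawn) realization rather than returning to the
generating a = 0.364 (see `docs/methods.md`). Chains, the
summary table and the DIC table are persisted under `run_cm3/`, each
chain with a JSON sidecar (seed, priors, settings) that makes it
regenerable. `frbayes reproduce --outdir out` runs the same workflow
on the built-in synthetic reference data for all four predator
densities, and `frbayes select --rundir out` recomputes DIC from
persisted chains.

Because the study's raw counts are published only as a PDF supplement,
the package ships a **synthetic reference dataset**
(`frbayes.synthetic.reference_datasets()`): the study design simulated
at the published posterior means under a fixed seed. It stands in for
the raw data in examples and validation; refitting it recovers the
generating estimates up to sampling noise.

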