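# commvar

Partitioning **density dependence**, **environmental variability**, and
**demographic stochasticity** in multispecies count time series, with a
two-stage hierarchical Bayesian workflow and a fully specified synthetic
community generator.

The package is aimed at population ecologists with yearly census data for a
handful of co-occurring species at one or more sites — the motivating case
is breeding-pair counts of duck communities surveyed over 20–35 years on
European lakes and North American prairie wetlands — who want to ask: *how
much of the year-to-year fluctuation of each species is pullback toward its
carrying capacity, and how much is a response to a shared, unobserved
environment? And do those shares differ between regions or between
ecological guilds?*

## Model

Stage 1 fits, per site, a multispecies Gompertz state-space model on the
log scale,

```
n[i,t] = n[i,t-1] + r[i] (1 − n[i,t-1]/k[i]) + ε[i,t],   ε[:,t] ~ MVN(0, Σ_t)
Σ_t = D_t + C,        D_t[i,i] = δ[i]² / N[i,t-1]
log Y[i,t] ~ Normal(n[i,t], τ[i]²)
```

by MCMC (inverse-Wishart(df = S, I) prior on the environmental covariance
C, half-normal on growth rates r, data-driven uniform bounds on log
carrying capacities k, Uniform(0, 10) on the SDs τ and δ; 4 chains,
Gelman–Rubin R̂ < 1.1 as the convergence bar). Each species' dynamics are
summarized by the density-dependence index `I = (r/k)² Var(n)`, the
environmental variance `C[i,i]`, and the density-dependent share
`Prop(I) = I / (I + C[i,i])`, each with a full posterior.

Stage 2 compares any of these parameters across continents or guilds with
a Bayesian mixed model on the stage-1 posterior means, using the stage-1
posterior SDs as fixed observation-error scales:

```
π_x = α_z + β c_x + ε_x,     p_x ~ Normal(π_x, σ_p,x²)
```

and reports the posterior of the contrast β together with the sign
probability `p = max(P(β>0), P(β<0))`.

Zero counts are treated as missing observations; species with zeros in half
or more of the surveyed years are dropped before fitting. The descriptive
PV index (mean pairwise proportional difference between years, 0 for a
constant series) is included for variability comparisons that do not lean
on the model.

See `docs/methods.md` for priors, sampler design, simulator assumptions,
and known limitations.

## Worked example

Simulate a two-continent dataset at the study's scale — 8 species, 30
years, 2 sites per continent, with +0.1 added to the environmental
variances of the North American sites — then fit each site and compare:

```sh
commvar simulate -s 8 -t 30 --continent-effect 0.1 --seed 7 -o data
commvar fit data/EU1.csv --chains 4 --iterations 5000 --burn-in 2500 \
        --thin 5 --seed 7 -o EU1.csv
# ... same for EU2, and for NA1/NA2 with --continent NorthAmerica ...
commvar compare all.csv --factor continent --parameter C_ii --seed 7 -o cmp.csv
```

The fit prints its convergence verdict and writes one row per species and
parameter:

```
max R-hat 1.0188 converged=True
site,species,guild,continent,parameter,mean,sd
EU1,sp1,dabbling,Europe,C_ii,0.1117,0.0350
EU1,sp2,dabbling,Europe,C_ii,0.1390,0.0463
```

(posterior mean and SD of each species' environmental variance; the
generating value here is 0.1). The comparison prints

```
continent effect on C_ii: 0.0640 +/- 0.1832 (p = 0.772)
```

a posterior-mean contrast of 0.064 where the generating contrast is 0.1.
The shortfall is expected at this series length: with T = 30 the growth
and observation-error parameters absorb part of the environmental
variance, so group contrasts in C_ii are attenuated and, with only four
communities informing the random intercept, the contrast posterior is
wide — see the limitations section of `docs/methods.md` before reading
sign probabilities as significance tests.

A full pipeline (filter → fit per site → summarize → compare, with logs,
convergence flags, and seed provenance in every artifact) runs from a YAML
config via `commvar pipeline config.yaml`; `commvar pv` computes the PV
table.

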