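# lysolatch

Stochastic modelling of the bacteriophage-lambda lysis–lysogeny decision
under multiple infection.

## The problem

When lambda phage infects *E. coli*, the cell either lyses or becomes a
lysogen. Deterministic models of the decision circuit predict the outcome
should depend on the *viral concentration* — the number of infecting
genomes M divided by the cell volume V — yet single-cell experiments show
that cells with the same M/V but different multiplicity of infection (MOI)
lysogenise at markedly different rates. `lysolatch` is a research package
for exploring the mechanisms behind this direct MOI dependence: intrinsic
gene-expression noise, spatial segregation of phage genomes, and
MOI-dependent host growth.

It provides:

- an exact (direct-method Gillespie, numba-compiled) stochastic simulator
  of a CI/Cro/CII regulatory network in which every infecting genome
  contributes one copy of the lytic promoter PR and the establishment
  promoter PRE, with optional CII tetramerisation, CI self-repression,
  early phage replication, staggered infection times, extrinsic noise, and
  cell-growth couplings (dilution, volume growth, growth-scaled
  transcription);
- the matching deterministic (mean-field ODE) integrator;
- threshold-based lysis/lysogeny classification of trajectories and the
  Gaussian threshold-crossing approximation
  P(lysogeny) = ½(1 − erf((K − μ)/(σ√2)));
- a 1-D compartmentalised reaction–diffusion (RDME) version of the circuit
  for phage-placement and diffusion-rate experiments;
- scripted experiment drivers (threshold sweeps, MOI series, burstiness
  modulation, model variants, global parameter sensitivity, growth and
  growth-media sweeps, infection-timing offsets) emitting tidy TSV tables;
- a synthetic two-frame time-lapse cohort generator with growth-rate and
  division-time estimators.

## The core idea

Bimolecular propensities scale as 1/V, so the *mean-field* dynamics depend
only on the concentration M/V: a cell with MOI=1, V=1 and a cell with
MOI=2, V=2 have identical deterministic CII trajectories. But the second
cell carries twice the molecule numbers, hence less intrinsic noise. With
the decision taken by comparing the time-averaged CII concentration to a
threshold K over a 60-minute window, the Gaussian approximation above
shows what follows: for K above the shared mean, the noisier MOI=1 cell
crosses more often (more lysogeny); for K below the mean, less often. The
rate-vs-threshold curves of the two conditions cross near the mean — a
direct MOI dependence produced purely by copy-number noise.

## Worked example

```python
from lysolatch import CellConfig, build_network, default_parameters, simulate_ssa
from lysolatch.decision import DecisionCriterion, decide
from lysolatch.experiments import moi_series

params = default_parameters()
cfg = CellConfig(moi=1, volume=1.0)
traj = simulate_ssa(build_network(params, cfg), cfg, params, horizon=60.0, seed=42)
outcome = decide(traj, DecisionCriterion(threshold=25.0, window=(0.0, 60.0)))
print(f"mean [CII] over 60 min = {outcome.statistic:.2f} -> {outcome.label}")

table = moi_series(concentration=1.0, moi_list=(1, 2, 3), n=500, seed=7)
print(table[["moi", "mu", "cv", "rate_low", "rate_high"]].round(3).to_string(index=False))
```

prints

```
mean [CII] over 60 min = 26.67 -> lysogeny
 moi     mu    cv  rate_low  rate_high
   1 26.669 0.227     0.762      0.202
   2 26.565 0.156     0.888      0.120
   3 26.654 0.136     0.912      0.104
```

Read it as follows: this particular seed's cell averaged 26.67 CII
concentration units over the hour, above the chosen threshold 25, so it
commits to lysogeny. In the MOI series at fixed concentration 1 (volume
grows with MOI), the ensemble mean `mu` is MOI-independent while the noise
`cv` falls with MOI; at a threshold one pooled SD *below* the mean
(`rate_low`) lysogeny increases with MOI, and one SD *above*
(`rate_high`) it decreases — the threshold–noise interplay in action.

## Command line

```
lysolatch run threshold_sweep --seed 1 --out out/ [--profile ci|full]
lysolatch run {moi_series|noise_sweep|sensitivity|variants|spatial|growth|media|offsets|cohort} ...
```

Every run writes `result.tsv`, `metadata.json` (config digest, seed,
package version, settings) and `run.log`; re-running with the same config
and seed reproduces `result.tsv` byte for byte. Parameters are overridden
through a YAML config (`params:` section with `ParameterSet` field names;
unknown keys are rejected).

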