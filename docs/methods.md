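# Methods

## The question

Classical deterministic treatments of the lambda-phage lysis–lysogeny switch
predict that the decision outcome depends on the *viral concentration*
MOI/V — the number of infecting phage genomes divided by the host cell
volume. Single-cell observations instead show that at a fixed concentration,
cells infected by more phage (higher MOI) lysogenise at different rates than
cells infected by fewer phage in proportionally smaller volumes. `lysolatch`
implements a stochastic model of the early lambda regulatory circuit to
probe three candidate mechanisms for this direct MOI dependence: intrinsic
gene-expression noise, spatial segregation of the infecting genomes, and
MOI-dependent modulation of host growth.

## The circuit model

Three early genes are modelled: CI, Cro and CII, expressed from two
promoters carried by every infecting genome. The lytic promoter PR
transcribes the cro and cII messages constitutively; CI₂ or Cro₂ bound at
PR silence it (CI₂ binding also activates cI transcription at rate
`tx_CI_p1`, the self-activation loop); CII dimers bound at the
establishment promoter PRE activate cI transcription at `tx_CI_p2`.
Messages are translated at a common rate and degrade with a shared
first-order constant; monomers decay; dimers and promoter-bound dimers do
not decay directly (turnover proceeds through dissociation followed by
monomer decay — the simplest closure consistent with having exactly three
protein decay constants; a config switch can enable direct dimer decay
pathways by adding reactions). The baseline network has 14 species and 25
elementary reactions. MOI enters only through the *state*: each genome
infecting at time zero contributes one free PR and one free PRE copy.

Bimolecular rate constants are defined at unit volume and their
propensities scale as 1/V, so the mean-field equations depend on MOI and V
only through MOI/V. This makes the pair (MOI=1, V=1) vs (MOI=2, V=2) an
exact control: identical deterministic concentration trajectories,
different copy numbers, hence different intrinsic noise.

Model variants (independently switchable): CII tetramerisation
(2 CII₂ ⇌ CII₄, PRE activated by the tetramer; tetramerisation reuses the
CII dimerisation constants, which the source model does not pin down); CI
self-repression (a second, ten-fold weaker CI₂ operator on the
CI-transcribing PR configuration that silences `tx_CI_p1` while bound);
early phage replication (genome count doubles every 3 minutes for the
first 15 minutes, implemented as deterministic genome-addition events; with
staggered infections the schedule is computed globally from the first
infection, as no per-genome copying semantics are defined); and extrinsic
noise (per-cell lognormal multipliers of stated CV, drawn independently for
each transcription and translation rate and frozen for the cell's
lifetime).

## Nominal parameters

The nominal kinetic constants are this package's own documented choice,
selected once to place the circuit in the regime the analysis requires and
exposed entirely through the flat YAML config (`model.save_parameters` /
`load_parameters`; unknown keys are hard errors). The regime criteria were:

- deterministic [CII] rises and then plateaus over the 60-minute decision
  window at MOI=1, V=1 (it peaks near 35 concentration units and stays
  within ~15% of the peak);
- low copy numbers (tens, not thousands) so intrinsic noise is a
  first-order effect: mean total CII ≈ 25–30 equivalents at V=1, CV of the
  windowed statistic ≈ 0.2 at MOI=1;
- modest promoter occupancies and dimer fractions, keeping the mean-field
  approximation accurate at the ensemble sizes used for comparison;
- translational burst size ≈ 1 (translation / mRNA decay = 1.2), typical
  of moderately expressed bacterial genes.

Defaults (per minute; bimolecular per molecule per minute at unit volume):
dimerisation 0.01 forward / 0.5 reverse for all three proteins; decay
0.02 (CI), 0.05 (Cro), 0.1 (CII — CII is the least stable of the three);
shared mRNA decay 0.25 (4-minute messages); promoter binding 0.01 /
unbinding 0.5; transcription 2.5 (mCro and mCII from free PR), 1.0
(`tx_CI_p1`), 2.0 (`tx_CI_p2`); translation 0.3. Output interval 0.5 min,
cell width 1 length unit.

## Stochastic simulation

The simulator is a direct-method Gillespie algorithm compiled with numba.
Propensities follow stochastic mass action (k, k·x, (k/V)·x·y,
(k/V)·x(x−1)/2). Time-varying features are handled with piecewise-constant
segments: genome additions (delayed infections, replication) are applied at
their exact times, and under volume growth the bimolecular propensities are
refreshed on an internal 0.1-minute grid (for elongation rates ≤ 0.02/min
the within-segment volume error is < 0.2%, far below sampling noise).
Restarting the exponential clock at a segment boundary is exact by
memorylessness. Propensities are updated through per-reaction dependency
lists and recomputed in full at every checkpoint to cancel floating-point
drift. A next-reaction (heap-based) variant was considered and not needed:
at these network sizes the linear scan is faster in practice.

Growth couplings: dilution adds a first-order loss channel at rate g to
every free cytoplasmic species (promoter states are genome-bound and are
not diluted within a cycle; a config switch can change this); volume growth
makes V(t) = V₀·e^{gt}; transcription coupling multiplies all transcription
rates by a factor interpolated linearly in g between (ln2/90 min⁻¹, 2.0)
and (ln2/30 min⁻¹, 1.0). The orientation — slower growth, stronger
transcription — is the one under which growth modulation *adds* to the
observed MOI dependence; the opposite orientation is configurable and the
experiment tables record which was used.

Randomness: one master seed; per-run seeds derive from a counter-based
splitting scheme (`numpy` SeedSequence), so run i's stream never depends on
how many runs follow. All experiment tables are bit-reproducible from
(config, seed). The burstiness sweep additionally reuses one run-seed
stream across its f points (common random numbers), shrinking the
Monte-Carlo variance of cross-f contrasts.

The deterministic limit integrates the mass-action mean-field ODEs
(promoter occupancies continuous, homodimerisation rate k·x²/2V) with
LSODA at rtol 1e-8 on the same output grid, with genome additions as state
jumps between segments.

## Decision criterion

A run commits to lysogeny when the time-averaged CII concentration over the
window [0, 60] min exceeds a threshold K (ties → lysis; a single-time-point
variant is provided and gives very similar rate curves). The readout counts
total CII protein equivalents — monomer + 2·dimer + 2·bound dimer
(+ 4·tetramer) — divided by the current volume; free-monomer and free-dimer
readouts are config options. Because the absolute CII scale is arbitrary,
thresholds are expressed as offsets from ensemble means in ensemble-SD
units ("high" = mean + 1 SD, "low" = mean − 1 SD) unless a driver documents
an absolute anchor. For the Gaussian approximation, P(lysogeny) =
½(1 − erf((K − μ)/(σ√2))) with (μ, σ) the ensemble moments of the
statistic: the sign of K − μ flips the direction of the noise effect, which
is the entire mechanism of the MOI dependence at equal concentration.

In the burstiness sweep, policy thresholds are anchored at each f's own
ensemble mean with the offset in baseline-SD units: jointly scaling
translation and mRNA decay preserves stationary means exactly, but over a
finite transient window the ensemble mean shifts slightly with f because
the mRNA relaxation time changes; anchoring per-f isolates the noise
effect the sweep is designed to probe.

The phenomenological reference curve is the unanimous-vote form: each of
the m infecting phage votes for lysogeny with Hill probability
c^h/(c^h + K_half^h) in the concentration c = m/V, and lysogeny requires
unanimity, giving [c^h/(c^h+K_half^h)]^m. The constants default to
(K_half, h) = (1, 2) and are free parameters — the printed constants of the
original fit are not available, and the curve is used only as a qualitative
reference column.

## Spatial model

The original study used a 3-D Brownian-dynamics particle method. This
package deliberately substitutes a 1-D compartmentalised
reaction–diffusion master equation (RDME): the phenomenon under test —
diffusion delay between genomes separated along the cell's long axis — is
one-dimensional, and the RDME is exact as a jump process and desk-scale in
cost. Consequences: the particle method's time step, binding radius and
3-D geometry are out of scope, and sub-second protein transport cannot be
resolved (see limitations).

The cell of volume V and width 1 is divided into n equal compartments
(default 11, odd so "centre" is a single compartment) along a length
derived from the spherocylinder formula V = π(w/2)²(L−w) + (4/3)π(w/2)³.
Every cytoplasmic species hops between neighbours at rate D/h², h = L/n,
with reflecting ends; promoter species stay in the compartment of their
genome; bimolecular constants are scaled by n/V so the n=1 case reduces
exactly to the well-mixed model. Diffusion defaults: D_mRNA = 0.2 (axial
traversal L²/2D ≈ 10 min for the unit cell, the slow species that carries
the segregation effect) and D_protein = 1.0 length²/min (traversal one to
a few minutes — an order of magnitude faster than mRNA and fast relative
to the 60-minute decision window, but far slower than the seconds-scale
3-D diffusion of real proteins, which a coarse compartment model cannot
reach: hop events already dominate the simulation at this setting).

The production kernel aggregates hop propensities per species (hops
outnumber reactions by orders of magnitude when transport is fast) and is
cross-validated in the test suite against the generic direct-method SSA
running on the explicitly discretised hop network — two independent
samplers of the same jump process. Ensemble diagnostics of the
fast-diffusion (well-mixed) limit run on a 5-compartment grid over a
30-minute window: the limit property is grid- and horizon-independent, and
this choice keeps three 1000-run placement ensembles at 100× diffusion
within minutes of CPU. Growth couplings are not supported spatially.

## Experiment drivers

Each driver simulates one ensemble per condition and reuses it across all
thresholds (decisions are post-hoc classifications of stored statistics);
ensembles are regenerated across conditions. The global sensitivity scan
perturbs every kinetic constant by an independent log-uniform factor in
[1/c, c] (symmetric on the fold scale), then for each set pools the two
conditions' statistics, places K at the pooled mean + 1 SD, and estimates
both rates from the same ensembles — a deliberate economy; at 200+ sims
per set the coupling between the estimated K and the rates is negligible
compared with the binomial noise. The scaled-down profile (50 sets × 200
sims; the command-line `--profile ci`) is the default; `--profile full`
runs 200 × 500.

## Synthetic cohort

The cohort generator emulates two-frame time-lapse measurements: per cell,
an MOI drawn from a truncated Poisson (the empirical MOI distribution of
the original movies is not available), a first-frame length with 15% CV, an
elongation rate g = max(g₀ − MOI·δg, 0) with an additional explicit
non-growing probability increasing with MOI, a terminal event (division for
uninfected cells after a cycle of ln2/g₀ minutes with 10% lognormal
variability; lysis at the 60-minute decision point; lysogeny after the
cycle plus a configured division delay), and a final length
L₀·e^{gΔt}·(1+ε) with multiplicative measurement noise (default CV 5%; a
linear-elongation generative option exists for robustness checks). The
growth-rate estimator is ln(L_f/L₀)/Δt; the per-MOI summary excludes
flagged non-growers and any cell with estimated rate ≤ 0, mirroring the
original reanalysis. What this generator does *not* emulate: segmentation
error structure, fluorescence-based fate calling, phage-counting errors,
or any correlation between MOI and initial cell size — so passing recovery
tests demonstrates correctness of the estimators and summaries, not
robustness to real imaging artefacts.

Known estimator bias: with multiplicative noise of CV c, E[ln(1+ε)] ≈
−c²/2, biasing each per-cell estimate by about −c²/(2Δt) ≈ −2×10⁻⁵ min⁻¹
at c = 0.05 — an order of magnitude below the per-MOI gradient δg and
within the cohort-level standard errors at the sizes used.

## Problem sizes and numerical choices

Test-suite ensembles: n = 5000 for the focal equal-concentration pair,
n = 2000 for MOI series, burstiness, variant and growth checks, 50 × 200
for sensitivity, n = 1000 per placement for the spatial well-mixed limit,
and 20 000 runs for the stationary-distribution comparison against the
directly solved dimerisation master equation (total-variation distance
< 0.02; the sampling floor of that statistic at these sizes is ≈ 0.012).
The acceptance script uses n = 1000–2000 per condition. Ties at the
threshold classify as lysis; all tolerance constants (ODE rtol 1e-8,
growth refresh 0.1 min) are fixed, not adaptive.

## Limitations

- CII stays high at 60 minutes; the real circuit (via CIII and host
  proteases) shuts CII down on this timescale. The decision statistic is
  therefore a windowed average, not a commitment time.
- A single-gene threshold is a crude fate criterion; joint CI/Cro criteria
  are out of scope.
- The 1-D RDME underestimates how fast real proteins mix (seconds in 3-D);
  conclusions about protein-gradient effects are conservative upper bounds
  on spatial influence.
- Downstream lambda genes (N, Q, CIII), anti-termination and
  operator-occupancy thermodynamics are not modelled.
- Infection-time staggering of more than ~a minute measurably lowers the
  windowed CII statistic under the nominal parameters, because the window
  starts at the first infection; the "no significant effect" regime is
  correspondingly narrow here.
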