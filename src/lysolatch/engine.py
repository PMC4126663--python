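"""Exact stochastic simulation and the matching mean-field integrator.

The stochastic path is a direct-method Gillespie simulation (numba-compiled)
that supports the time-varying features of an infection: delayed infections
and phage replication enter as genome-addition events at exact times, cell
growth enters as exponential volume growth (piecewise-constant refresh of
the bimolecular propensities on a fine internal grid), growth dilution as
first-order removal channels on every non-promoter species, and
growth-coupled transcription as a constant multiplier on the transcription
rates.  The deterministic counterpart integrates the mass-action mean-field
ODEs (promoter occupancies treated as continuous) on the same output grid.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernel
from .model import CellConfig, ParameterSet, ReactionNetwork

__all__ = [
    "GrowthModel",
    "EventSchedule",
    "SystemState",
    "Trajectory",
    "EnsembleSummary",
    "CompiledNetwork",
    "simulate_ssa",
    "integrate_deterministic",
    "run_ensemble",
    "phage_copies",
    "event_schedule",
    "derive_seeds",
    "genome_copies",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
    "write_summary_tsv",
]

LN2 = math.log(2.0)

#: Internal refresh interval (min) for time-varying volume; keeps the
#: piecewise-constant propensity error negligible for growth rates <= 0.02/min.
GROWTH_REFRESH = 0.1


@dataclass(frozen=True)
class GrowthModel:
    """Cell growth and its couplings to the gene-expression machinery.

    ``rate`` is the exponential elongation rate g (per min).  ``dilution``
    adds a first-order loss channel at rate g to every free cytoplasmic
    species (promoter states are genome-bound and are not diluted within a
    cell cycle).  ``volume_growth`` makes bimolecular propensities use
    V(t) = V0 exp(g t).  ``tx_coupling`` multiplies all transcription rates
    by a factor interpolated linearly in g between (g_slow, tx_scale_slow)
    and (g_fast, tx_scale_fast); the default orientation gives slowly growing
    cells a two-fold transcription enhancement.
    """

    rate: float = LN2 / 60.0
    dilution: bool = True
    volume_growth: bool = True
    tx_coupling: bool = False
    tx_scale_slow: float = 2.0
    tx_scale_fast: float = 1.0
    g_slow: float = LN2 / 90.0
    g_fast: float = LN2 / 30.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("growth rate must be >= 0")
        if self.tx_scale_slow <= 0 or self.tx_scale_fast <= 0:
            raise ValueError("transcription multipliers must be > 0")
        if self.g_fast <= self.g_slow:
            raise ValueError("g_fast must exceed g_slow")

    def tx_multiplier(self, g: Optional[float] = None) -> float:
        """Transcription multiplier at growth rate g (clipped interpolation)."""
        if not self.tx_coupling:
            return 1.0
        g = self.rate if g is None else g
        return float(
            np.interp(g, [self.g_slow, self.g_fast], [self.tx_scale_slow, self.tx_scale_fast])
        )


@dataclass(frozen=True)
class EventSchedule:
    """Timed genome additions: (time, genomes added) for infections and replication."""

    infection_events: tuple = ()
    replication_events: tuple = ()

    def merged(self) -> list:
        ev = sorted(list(self.infection_events) + list(self.replication_events))
        if any(t < 0 for t, _ in ev):
            raise ValueError("event times must be >= 0")
        return ev


@dataclass
class SystemState:
    """Instantaneous state of one simulated cell."""

    time: float
    counts: dict
    volume: float
    genome_copies: int


@dataclass
class Trajectory:
    """Time-sampled copy-number state of one simulated cell.

    ``counts`` has one row per sample on the grid 0, dt, ..., T and one
    column per species; ``volumes`` holds the cell volume at each sample.
    """

    species: tuple
    times: np.ndarray
    counts: np.ndarray
    volumes: np.ndarray

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def get(self, name: str) -> np.ndarray:
        return self.counts[:, self.species_index(name)]


@dataclass
class EnsembleSummary:
    """Per-time mean and SD of each species over an ensemble of runs."""

    species: tuple
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int


def phage_copies(
    m0: int, t: float, doubling_period: float = 3.0, duration: float = 15.0
) -> int:
    """Deterministic phage genome count under early replication.

    The genome count doubles every ``doubling_period`` minutes for the first
    ``duration`` minutes and is constant afterwards.
    """
    if doubling_period <= 0 or duration <= 0:
        raise ValueError("periods must be > 0")
    if m0 < 1:
        raise ValueError("m0 must be >= 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    k = min(math.floor(t / doubling_period), math.floor(duration / doubling_period))
    return int(m0 * 2**k)


def event_schedule(
    config: CellConfig, doubling_period: float = 3.0, duration: float = 15.0
) -> EventSchedule:
    """Build the genome-addition schedule for one cell configuration.

    Delayed infections add one genome each at their offset time.  If the
    replication variant is on, the total genome count follows
    :func:`phage_copies` computed from the full MOI and the first-infection
    origin (the model does not track per-genome replication lineages).
    """
    infections = tuple((t, 1) for t in config.infection_offsets if t > 0)
    repl = ()
    if config.variants.phage_replication:
        events = []
        prev = config.moi
        nmax = math.floor(duration / doubling_period)
        for k in range(1, nmax + 1):
            t = k * doubling_period
            now = phage_copies(config.moi, t, doubling_period, duration)
            events.append((t, now - prev))
            prev = now
        repl = tuple(events)
    return EventSchedule(infection_events=infections, replication_events=repl)


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit run seeds from one master seed.

    Uses a counter-based splitting scheme (numpy ``SeedSequence``), so the
    stream for run i never depends on how many later runs are requested.
    """
    ss = np.random.SeedSequence(int(master_seed))
    return (ss.generate_state(n, np.uint32) >> np.uint32(1)).astype(np.int64)


class CompiledNetwork:
    """Flat array representation of a network consumed by the SSA kernel.

    Growth features are baked in here: dilution channels are appended for all
    non-promoter species and the transcription multiplier is folded into the
    transcription rate constants.
    """

    def __init__(self, network: ReactionNetwork, growth: Optional[GrowthModel] = None):
        self.network = network
        self.growth = growth
        species = network.species
        self.species = species
        idx = {sp: i for i, sp in enumerate(species)}
        self.index = idx

        rxns = list(network.reactions)
        categories = [rx.category for rx in rxns]
        rates = [rx.rate for rx in rxns]
        if growth is not None and growth.dilution and growth.rate > 0:
            for sp in species:
                if sp in network.promoter_species:
                    continue
                rxns.append(None)  # placeholder; arrays built directly below
                categories.append("dilution")
                rates.append(growth.rate)
        M = len(rxns)
        S = len(species)
        self.order = np.zeros(M, dtype=np.int64)
        self.s1 = np.zeros(M, dtype=np.int64)
        self.s2 = np.zeros(M, dtype=np.int64)
        self.homo = np.zeros(M, dtype=np.bool_)
        self.vexp = np.zeros(M, dtype=np.int64)
        self.kbase = np.asarray(rates, dtype=np.float64)
        d_indptr = [0]
        d_sp: list[int] = []
        d_val: list[int] = []
        n_real = len(network.reactions)
        dil_species = [sp for sp in species if sp not in network.promoter_species]
        for j in range(M):
            if j < n_real:
                rx = rxns[j]
                self.order[j] = rx.order
                self.vexp[j] = rx.vol_exp
                reac = list(rx.reactants.items())
                if rx.order >= 1:
                    if len(reac) == 1:
                        sp, c = reac[0]
                        self.s1[j] = idx[sp]
                        self.s2[j] = idx[sp]
                        self.homo[j] = c == 2
                    else:
                        self.s1[j] = idx[reac[0][0]]
                        self.s2[j] = idx[reac[1][0]]
                delta: dict[int, int] = {}
                for sp, c in rx.reactants.items():
                    delta[idx[sp]] = delta.get(idx[sp], 0) - c
                for sp, c in rx.products.items():
                    delta[idx[sp]] = delta.get(idx[sp], 0) + c
                for sp_i, dv in sorted(delta.items()):
                    if dv != 0:
                        d_sp.append(sp_i)
                        d_val.append(dv)
            else:
                sp = dil_species[j - n_real]
                self.order[j] = 1
                self.s1[j] = idx[sp]
                self.s2[j] = idx[sp]
                d_sp.append(idx[sp])
                d_val.append(-1)
            d_indptr.append(len(d_sp))
        self.d_indptr = np.asarray(d_indptr, dtype=np.int64)
        self.d_sp = np.asarray(d_sp, dtype=np.int64)
        self.d_val = np.asarray(d_val, dtype=np.int64)
        self.categories = categories

        # Fold a constant transcription multiplier into the rate constants.
        if growth is not None:
            mult = growth.tx_multiplier()
            if mult != 1.0:
                for j, cat in enumerate(categories):
                    if cat == "transcription":
                        self.kbase[j] *= mult

        # Reaction dependency lists: jj depends on j if j changes a reactant of jj.
        reactants_of = [set() for _ in range(M)]
        for j in range(M):
            if self.order[j] >= 1:
                reactants_of[j].add(self.s1[j])
                if self.order[j] == 2:
                    reactants_of[j].add(self.s2[j])
        changed = [set(self.d_sp[self.d_indptr[j]: self.d_indptr[j + 1]]) for j in range(M)]
        dep_indptr = [0]
        dep_dat: list[int] = []
        for j in range(M):
            for jj in range(M):
                if reactants_of[jj] & changed[j]:
                    dep_dat.append(jj)
            dep_indptr.append(len(dep_dat))
        self.dep_indptr = np.asarray(dep_indptr, dtype=np.int64)
        self.dep_dat = np.asarray(dep_dat, dtype=np.int64)

        self.tx_rows = np.asarray(
            [j for j, c in enumerate(categories) if c == "transcription"], dtype=np.int64
        )
        self.tln_rows = np.asarray(
            [j for j, c in enumerate(categories) if c == "translation"], dtype=np.int64
        )
        self.x0 = np.asarray(
            [network.initial_counts.get(sp, 0) for sp in species], dtype=np.int64
        )

        # Dense stoichiometry matrix for the mean-field integrator.
        self.stoich = np.zeros((S, M))
        for j in range(M):
            for p in range(self.d_indptr[j], self.d_indptr[j + 1]):
                self.stoich[self.d_sp[p], j] = self.d_val[p]


def _build_checkpoints(
    config: CellConfig,
    growth: Optional[GrowthModel],
    T: float,
    dt: float,
    schedule: EventSchedule,
    species_index: dict,
):
    n_samples = int(round(T / dt)) + 1
    sample_times = np.arange(n_samples) * dt
    times = set(np.round(sample_times, 9).tolist())
    volume_growth = growth is not None and growth.volume_growth and growth.rate > 0
    if volume_growth:
        fine = np.arange(0.0, T + GROWTH_REFRESH / 2, GROWTH_REFRESH)
        times.update(np.round(fine, 9).tolist())
    events = [(t, m) for t, m in schedule.merged() if t <= T]
    times.update(round(float(t), 9) for t, _ in events)
    ckpt_t = np.array(sorted(times))
    C = len(ckpt_t)
    if volume_growth:
        ckpt_vol = config.volume * np.exp(growth.rate * ckpt_t)
    else:
        ckpt_vol = np.full(C, config.volume)
    sample_of = np.full(C, -1, dtype=np.int64)
    pos = np.searchsorted(ckpt_t, np.round(sample_times, 9))
    for i, p in enumerate(pos):
        sample_of[p] = i
    ev_lists: list[list] = [[] for _ in range(C)]
    if events:
        i_pr = species_index["PR"]
        i_pre = species_index["PRE"]
    for t, m in events:
        p = int(np.searchsorted(ckpt_t, round(float(t), 9)))
        ev_lists[p].append((i_pr, m))
        ev_lists[p].append((i_pre, m))
    ev_indptr = [0]
    ev_sp: list[int] = []
    ev_val: list[int] = []
    for lst in ev_lists:
        for sp, m in lst:
            ev_sp.append(sp)
            ev_val.append(m)
        ev_indptr.append(len(ev_sp))
    return (
        sample_times,
        ckpt_t,
        ckpt_vol,
        np.asarray(ev_indptr, dtype=np.int64),
        np.asarray(ev_sp, dtype=np.int64),
        np.asarray(ev_val, dtype=np.int64),
        sample_of,
    )


def _extrinsic_multipliers(cv: float, rng: np.random.Generator, n_rates: int) -> np.ndarray:
    """Lognormal rate multipliers with unit mean and the stated CV."""
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n_rates)


class _RunPlan:
    """Precomputed per-ensemble assets shared across runs."""

    def __init__(
        self,
        network: ReactionNetwork,
        config: CellConfig,
        params: ParameterSet,
        T: float,
        growth: Optional[GrowthModel],
    ):
        self.config = config
        self.compiled = CompiledNetwork(network, growth)
        self.schedule = event_schedule(config)
        (
            self.sample_times,
            self.ckpt_t,
            self.ckpt_vol,
            self.ev_indptr,
            self.ev_sp,
            self.ev_val,
            self.sample_of,
        ) = _build_checkpoints(
            config, growth, T, params.output_interval, self.schedule, self.compiled.index
        )
        self.sample_vols = np.interp(self.sample_times, self.ckpt_t, self.ckpt_vol)

    def run(self, seed: int, noise_seed: Optional[int] = None) -> Trajectory:
        cn = self.compiled
        kbase = cn.kbase
        cv = self.config.variants.extrinsic_noise_cv
        if cv > 0:
            rng = np.random.default_rng(noise_seed if noise_seed is not None else seed)
            kbase = kbase.copy()
            rows = np.concatenate([cn.tx_rows, cn.tln_rows])
            kbase[rows] *= _extrinsic_multipliers(cv, rng, rows.size)
        out = np.zeros((self.sample_times.size, len(cn.species)), dtype=np.int64)
        status = _kernel.ssa_run(
            np.int64(seed),
            cn.x0,
            cn.order,
            cn.s1,
            cn.s2,
            cn.homo,
            cn.vexp,
            kbase,
            cn.d_indptr,
            cn.d_sp,
            cn.d_val,
            cn.dep_indptr,
            cn.dep_dat,
            self.ckpt_t,
            self.ckpt_vol,
            self.ev_indptr,
            self.ev_sp,
            self.ev_val,
            self.sample_of,
            out,
        )
        if status != 0:
            raise RuntimeError(
                f"SSA produced a negative count (seed={seed}); "
                f"final sampled state: {dict(zip(cn.species, out[-1]))}"
            )
        return Trajectory(
            species=cn.species,
            times=self.sample_times,
            counts=out,
            volumes=self.sample_vols.copy(),
        )


def simulate_ssa(
    network: ReactionNetwork,
    config: CellConfig,
    params: ParameterSet,
    horizon: float,
    seed: int,
    growth: Optional[GrowthModel] = None,
) -> Trajectory:
    """Statistically exact sample path of the infection network.

    Genome-addition events (delayed infections, replication) are applied at
    their exact times; growth features follow ``config.growth`` unless an
    explicit ``growth`` model is passed.  Seeded and bit-reproducible.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    growth = growth if growth is not None else config.growth
    plan = _RunPlan(network, config, params, horizon, growth)
    return plan.run(int(seed))


def run_ensemble(
    network: ReactionNetwork,
    config: CellConfig,
    params: ParameterSet,
    T: float,
    n: int,
    seed: int,
    growth: Optional[GrowthModel] = None,
    keep_trajectories: bool = True,
    reduce: Optional[Callable[[Trajectory], object]] = None,
):
    """Run ``n`` independent seeded realisations and summarise them.

    Returns ``(trajectories, summary)``; with ``reduce`` given, the first
    element is instead the list of reduced values (full trajectories are not
    retained), which keeps large ensembles cheap in memory.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    growth = growth if growth is not None else config.growth
    plan = _RunPlan(network, config, params, T, growth)
    seeds = derive_seeds(seed, 2 * n).reshape(n, 2)
    S = len(plan.compiled.species)
    P = plan.sample_times.size
    total = np.zeros((P, S))
    total2 = np.zeros((P, S))
    kept = []
    for i in range(n):
        traj = plan.run(int(seeds[i, 0]), noise_seed=int(seeds[i, 1]))
        total += traj.counts
        total2 += traj.counts.astype(np.float64) ** 2
        kept.append(reduce(traj) if reduce is not None else (traj if keep_trajectories else None))
    mean = total / n
    var = np.maximum(total2 / n - mean**2, 0.0)
    summary = EnsembleSummary(
        species=plan.compiled.species,
        times=plan.sample_times,
        mean=mean,
        sd=np.sqrt(var),
        n=n,
    )
    if reduce is None and not keep_trajectories:
        kept = []
    return kept, summary


def integrate_deterministic(
    network: ReactionNetwork,
    config: CellConfig,
    params: ParameterSet,
    T: float,
    growth: Optional[GrowthModel] = None,
) -> Trajectory:
    """Mean-field ODE trajectory on the same output grid as the SSA.

    Mass-action rates with continuous promoter occupancies; a homodimeric
    propensity k x(x-1)/2V becomes k x^2 / 2V in the continuum limit.
    Genome additions are exact state jumps between integration segments.
    """
    if T <= 0:
        raise ValueError("horizon must be > 0")
    growth = growth if growth is not None else config.growth
    cn = CompiledNetwork(network, growth)
    schedule = event_schedule(config)
    dt = params.output_interval
    n_samples = int(round(T / dt)) + 1
    sample_times = np.arange(n_samples) * dt
    g = growth.rate if (growth is not None and growth.volume_growth) else 0.0
    V0 = config.volume

    order, s1, s2, homo, vexp, kb = cn.order, cn.s1, cn.s2, cn.homo, cn.vexp, cn.kbase
    W = cn.stoich
    M = order.size
    o0 = order == 0
    o1 = order == 1
    o2h = (order == 2) & cn.homo
    o2x = (order == 2) & ~cn.homo

    def rhs(t, x):
        V = V0 * math.exp(g * t)
        a = np.empty(M)
        a[o0] = kb[o0]
        a[o1] = kb[o1] * x[s1[o1]]
        a[o2h] = kb[o2h] / V * x[s1[o2h]] ** 2 / 2.0
        a[o2x] = kb[o2x] / V * x[s1[o2x]] * x[s2[o2x]]
        return W @ a

    x = cn.x0.astype(np.float64)
    events = [(t, m) for t, m in schedule.merged() if 0 < t <= T]
    if events:
        i_pr = cn.index["PR"]
        i_pre = cn.index["PRE"]
    breakpts = sorted({0.0, T, *[t for t, _ in events]})
    out = np.zeros((n_samples, len(cn.species)))
    out[0] = x
    for t0, t1 in zip(breakpts[:-1], breakpts[1:]):
        mask = (sample_times > t0 + 1e-12) & (sample_times <= t1 + 1e-12)
        t_eval = sample_times[mask]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            x,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=1e-8,
            atol=1e-9,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}")
        if t_eval.size:
            out[mask] = sol.y.T
        x = sol.y[:, -1] if sol.y.size else x
        for t, m in events:
            if abs(t - t1) < 1e-9:
                x = x.copy()
                x[i_pr] += m
                x[i_pre] += m
    vols = V0 * np.exp(g * sample_times)
    return Trajectory(species=cn.species, times=sample_times, counts=out, volumes=vols)


def genome_copies(traj: Trajectory, network: ReactionNetwork) -> np.ndarray:
    """Genome count per sample: total occupancy of the PR promoter states."""
    cols = [traj.species_index(sp) for sp in network.pr_states]
    return traj.counts[:, cols].sum(axis=1)


# ---------------------------------------------------------------------------
# TSV interfaces.

def write_trajectory_tsv(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(traj.species) + "\tvolume\n")
        for i, t in enumerate(traj.times):
            row = "\t".join(f"{v:g}" for v in traj.counts[i])
            fh.write(f"{t:g}\t{row}\t{traj.volumes[i]:g}\n")


def read_trajectory_tsv(path) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        species = tuple(header[1:-1])
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    data = np.asarray(rows, dtype=np.float64)
    counts = data[:, 1:-1]
    if np.allclose(counts, np.round(counts)):
        counts = counts.astype(np.int64)
    return Trajectory(
        species=species, times=data[:, 0], counts=counts, volumes=data[:, -1]
    )


def write_summary_tsv(summary: EnsembleSummary, path) -> None:
    with open(path, "w") as fh:
        cols = [f"mean_{s}" for s in summary.species] + [f"sd_{s}" for s in summary.species]
        fh.write("time\t" + "\t".join(cols) + "\n")
        for i, t in enumerate(summary.times):
            vals = list(summary.mean[i]) + list(summary.sd[i])
            fh.write(f"{t:g}\t" + "\t".join(f"{v:.6g}" for v in vals) + "\n")
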