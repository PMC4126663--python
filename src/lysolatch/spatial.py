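"""1-D compartmentalised reaction-diffusion version of the circuit.

Multiple infecting phage can sit at different positions along the cell axis,
so slowly diffusing viral mRNAs create transient spatial gradients between
genomes.  The cell is discretised into equal compartments along its long
axis; every cytoplasmic species hops between neighbouring compartments at
rate D/h^2 (reflecting ends), promoter species are pinned to the compartment
of their genome, and each compartment runs the well-mixed chemistry at the
compartment volume V/n.  In the fast-diffusion limit this construction
recovers the well-mixed model exactly.

The cell length is derived from the standardised volume through the
spherocylinder geometry unless given explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .engine import CompiledNetwork, Trajectory, derive_seeds
from .model import (
    CellConfig,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    capsule_length,
)

__all__ = [
    "SpatialConfig",
    "place_phages",
    "discretise",
    "traversal_time",
    "simulate_rdme",
    "collapse_compartments",
    "write_spatial_tsv",
]


@dataclass(frozen=True)
class SpatialConfig:
    """Grid geometry, diffusion coefficients and phage placement.

    ``cell_length`` of ``None`` derives the length from the cell volume and
    width via the spherocylinder formula.  ``positions`` (fractions of the
    cell length in [0, 1]) is required in ``explicit`` mode.
    """

    n_compartments: int = 11
    cell_length: Optional[float] = None
    D_mrna: float = 0.2
    D_protein: float = 1.0
    placement_mode: str = "centre"
    positions: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.n_compartments < 1:
            raise ValueError("n_compartments must be >= 1")
        if self.D_mrna < 0 or self.D_protein < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.placement_mode not in ("centre", "quarters", "poles", "explicit"):
            raise ValueError(f"unknown placement mode {self.placement_mode!r}")
        if self.placement_mode == "explicit":
            if self.positions is None:
                raise ValueError("explicit placement requires positions")
            if any(not 0 <= p <= 1 for p in self.positions):
                raise ValueError("positions must be fractions in [0, 1]")

    def resolved_length(self, volume: float, width: float) -> float:
        if self.cell_length is not None:
            return self.cell_length
        return capsule_length(volume, width)


def place_phages(
    mode: str,
    moi: int,
    n_compartments: int,
    positions: Optional[Sequence[float]] = None,
) -> list:
    """Compartment index of each infecting phage genome.

    ``centre`` puts every genome in the compartment containing the midpoint;
    ``quarters`` and ``poles`` (two phage) use the compartments containing
    fractions 0.25/0.75 and the two end compartments respectively.
    """
    nc = n_compartments
    if nc < 1:
        raise ValueError("n_compartments must be >= 1")
    if mode == "explicit":
        if positions is None:
            raise ValueError("explicit placement requires positions")
        if len(positions) != moi:
            raise ValueError("need one position per phage")
        return [min(int(p * nc), nc - 1) for p in positions]
    if mode == "centre":
        if moi not in (1, 2):
            raise ValueError("centre placement supports moi 1 or 2")
        return [min(int(0.5 * nc), nc - 1)] * moi
    if mode == "quarters":
        if moi != 2:
            raise ValueError("quarters placement requires moi == 2")
        return [int(0.25 * nc), min(int(0.75 * nc), nc - 1)]
    if mode == "poles":
        if moi != 2:
            raise ValueError("poles placement requires moi == 2")
        return [0, nc - 1]
    raise ValueError(f"unknown placement mode {mode!r}")


def traversal_time(cell_length: float, D: float) -> float:
    """Characteristic diffusion time L^2 / (2 D) across the cell (min)."""
    if cell_length <= 0 or D <= 0:
        raise ValueError("cell_length and D must be > 0")
    return cell_length**2 / (2.0 * D)


def _diffusion_coefficient(species: str, cfg: SpatialConfig) -> float:
    return cfg.D_mrna if species.startswith("m") else cfg.D_protein


def discretise(
    network: ReactionNetwork,
    spatial_config: SpatialConfig,
    volume: float,
    placement: Optional[Sequence[int]] = None,
) -> tuple:
    """Explicit compartmentalised network: ``(network, compartment_volume)``.

    Species are replicated per compartment (named ``X@c``); hops are
    first-order reactions at rate D/h^2 between neighbours with reflecting
    ends; bimolecular propensities are evaluated at the compartment volume
    V/n (which is why the compartment volume is returned alongside).  With a
    single compartment the original network is returned unchanged.

    This explicit form exists for inspection and cross-validation; large
    ensembles run through :func:`simulate_rdme`, whose kernel aggregates the
    diffusion channels but samples the identical jump process.
    """
    nc = spatial_config.n_compartments
    if nc == 1:
        return network, volume
    L = spatial_config.resolved_length(volume, width=1.0)
    h = L / nc
    comp_vol = volume / nc

    def name(sp: str, c: int) -> str:
        return f"{sp}@{c}"

    species = [name(sp, c) for sp in network.species for c in range(nc)]
    rxns = []
    for c in range(nc):
        for rx in network.reactions:
            rxns.append(
                Reaction(
                    name=f"{rx.name}@{c}",
                    reactants={name(sp, c): v for sp, v in rx.reactants.items()},
                    products={name(sp, c): v for sp, v in rx.products.items()},
                    rate=rx.rate,
                    rate_symbol=rx.rate_symbol,
                    order=rx.order,
                    vol_exp=rx.vol_exp,
                    category=rx.category,
                )
            )
    for sp in network.species:
        if sp in network.promoter_species:
            continue
        D = _diffusion_coefficient(sp, spatial_config)
        if D == 0:
            continue
        hop = D / h**2
        for c in range(nc - 1):
            for a, b in ((c, c + 1), (c + 1, c)):
                rxns.append(
                    Reaction(
                        name=f"hop_{sp}_{a}to{b}",
                        reactants={name(sp, a): 1},
                        products={name(sp, b): 1},
                        rate=hop,
                        rate_symbol=f"D_{sp}/h^2",
                        order=1,
                        vol_exp=0,
                        category="hop",
                    )
                )

    if placement is None:
        n_phage = network.initial_counts.get("PR", 0)
        placement = place_phages(
            spatial_config.placement_mode, max(n_phage, 1), nc, spatial_config.positions
        )
    initial = {sp: 0 for sp in species}
    for sp, count in network.initial_counts.items():
        if count == 0:
            continue
        if sp in ("PR", "PRE"):
            for c in placement:
                initial[name(sp, c)] += 1
        else:
            initial[name(sp, 0)] = count
    spatial_net = ReactionNetwork(
        species=tuple(species),
        reactions=tuple(rxns),
        initial_counts=initial,
        promoter_species=tuple(
            name(sp, c) for sp in network.promoter_species for c in range(nc)
        ),
        pr_states=tuple(name(sp, c) for sp in network.pr_states for c in range(nc)),
        pre_states=tuple(name(sp, c) for sp in network.pre_states for c in range(nc)),
    )
    spatial_net.validate()
    return spatial_net, comp_vol


def simulate_rdme(
    network: ReactionNetwork,
    config: CellConfig,
    params: ParameterSet,
    spatial_config: SpatialConfig,
    horizon: float,
    seed: int,
    diffusion_scale: float = 1.0,
) -> Trajectory:
    """Exact SSA sample path of the compartmentalised network.

    ``network`` is the well-mixed network (the kernel performs its own
    spatial layout).  ``diffusion_scale`` multiplies both diffusion
    coefficients, which is how the fast-diffusion (well-mixed) limit is
    probed.  Growth couplings are not supported spatially.
    """
    if config.growth is not None and getattr(config.growth, "rate", 0) > 0:
        raise ValueError("spatial simulation does not support cell growth")
    if any(t != 0 for t in config.infection_offsets) or config.variants.phage_replication:
        raise ValueError("spatial simulation requires synchronous, non-replicating infection")
    nc = spatial_config.n_compartments
    cn = CompiledNetwork(network, None)
    placement = place_phages(
        spatial_config.placement_mode, config.moi, nc, spatial_config.positions
    )
    L = spatial_config.resolved_length(config.volume, params.cell_width)
    h = L / nc
    comp_vol = config.volume / nc

    keff = cn.kbase.copy()
    keff[cn.vexp != 0] /= comp_vol

    S = len(cn.species)
    diffusible = [
        i for i, sp in enumerate(cn.species) if sp not in network.promoter_species
    ]
    sdiff = np.asarray(diffusible, dtype=np.int64)
    rdiff = np.asarray(
        [
            diffusion_scale * _diffusion_coefficient(cn.species[i], spatial_config) / h**2
            for i in diffusible
        ]
    )
    if nc == 1:
        rdiff = np.zeros_like(rdiff)
    diff_of_species = np.full(S, -1, dtype=np.int64)
    for k, i in enumerate(diffusible):
        diff_of_species[i] = k

    # Species -> reactions that consume it (for hop-event propensity updates).
    spdep_indptr = [0]
    spdep_dat: list = []
    M = cn.order.size
    for s in range(S):
        for j in range(M):
            if cn.order[j] >= 1 and (cn.s1[j] == s or (cn.order[j] == 2 and cn.s2[j] == s)):
                spdep_dat.append(j)
        spdep_indptr.append(len(spdep_dat))

    x0 = np.zeros(S * nc, dtype=np.int64)
    i_pr, i_pre = cn.index["PR"], cn.index["PRE"]
    for c in placement:
        x0[i_pr * nc + c] += 1
        x0[i_pre * nc + c] += 1
    for sp, count in network.initial_counts.items():
        if count and sp not in ("PR", "PRE"):
            x0[cn.index[sp] * nc + 0] = count

    dt = params.output_interval
    n_samples = int(round(horizon / dt)) + 1
    sample_t = np.arange(n_samples) * dt
    out = np.zeros((n_samples, S * nc), dtype=np.int64)
    status = _kernel.rdme_run(
        np.int64(seed),
        x0,
        cn.order,
        cn.s1,
        cn.s2,
        cn.homo,
        keff,
        cn.d_indptr,
        cn.d_sp,
        cn.d_val,
        cn.dep_indptr,
        cn.dep_dat,
        np.asarray(spdep_indptr, dtype=np.int64),
        np.asarray(spdep_dat, dtype=np.int64),
        sdiff,
        rdiff,
        diff_of_species,
        nc,
        sample_t,
        out,
    )
    if status != 0:
        raise RuntimeError(f"spatial SSA produced a negative count (seed={seed})")
    species = tuple(f"{sp}@{c}" for sp in cn.species for c in range(nc))
    return Trajectory(
        species=species,
        times=sample_t,
        counts=out,
        volumes=np.full(n_samples, config.volume),
    )


def collapse_compartments(traj: Trajectory) -> Trajectory:
    """Sum compartment copies into whole-cell totals (well-mixed style)."""
    base: dict[str, list] = {}
    for i, sp in enumerate(traj.species):
        name = sp.split("@")[0]
        base.setdefault(name, []).append(i)
    species = tuple(base)
    counts = np.stack([traj.counts[:, cols].sum(axis=1) for cols in base.values()], axis=1)
    return Trajectory(
        species=species, times=traj.times, counts=counts, volumes=traj.volumes
    )


def write_spatial_tsv(traj: Trajectory, path, metadata: Optional[dict] = None) -> None:
    """Spatial trajectory TSV with species-by-compartment columns."""
    with open(path, "w") as fh:
        if metadata:
            for k, v in metadata.items():
                fh.write(f"# {k}: {v}\n")
        fh.write("time\t" + "\t".join(traj.species) + "\tvolume\n")
        for i, t in enumerate(traj.times):
            row = "\t".join(str(v) for v in traj.counts[i])
            fh.write(f"{t:g}\t{row}\t{traj.volumes[i]:g}\n")
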