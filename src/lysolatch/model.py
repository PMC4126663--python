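"""Kinetic parameters and the CI/Cro/CII reaction network.

The circuit couples three early phage genes.  The lytic promoter PR
constitutively transcribes the cro and cII messages; CII dimers activate the
establishment promoter PRE, which transcribes cI; CI dimers bound at PR both
self-activate cI transcription and silence the lytic messages, while Cro
dimers bound at PR silence everything.  Each infecting phage genome carries
one copy of PR and one of PRE, so multiplicity of infection (MOI) sets the
promoter copy number and thereby the intrinsic-noise level of the circuit.

All bimolecular rate constants are expressed at unit cell volume; their
propensities scale as 1/V so that the deterministic (mean-field) dynamics
depend on gene *concentration* MOI/V only.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "VariantFlags",
    "CellConfig",
    "Reaction",
    "ReactionNetwork",
    "KINETIC_FIELDS",
    "default_parameters",
    "build_network",
    "propensity",
    "apply_noise_scaling",
    "perturb_parameters",
    "capsule_volume",
    "capsule_length",
    "load_parameters",
    "save_parameters",
    "network_to_tsv",
]


@dataclass(frozen=True)
class ParameterSet:
    """All kinetic rate constants and simulation controls (units: per min).

    Bimolecular constants (``dim_fwd_*``, ``bind_*``) are per molecule per
    minute at unit volume.  ``output_interval`` is the trajectory sampling
    interval in minutes and ``cell_width`` the cell diameter used for
    spherocylinder geometry corrections (arbitrary length units).
    """

    dim_fwd_CI: float = 0.01
    dim_fwd_Cro: float = 0.01
    dim_fwd_CII: float = 0.01
    dim_rev_CI: float = 0.5
    dim_rev_Cro: float = 0.5
    dim_rev_CII: float = 0.5
    decay_CI: float = 0.02
    decay_Cro: float = 0.05
    decay_CII: float = 0.1
    mrna_decay: float = 0.25
    bind_CI: float = 0.01
    bind_Cro: float = 0.01
    bind_CII: float = 0.01
    unbind_CI: float = 0.5
    unbind_Cro: float = 0.5
    unbind_CII: float = 0.5
    tx_CI_p1: float = 1.0
    tx_CI_p2: float = 2.0
    tx_Cro: float = 2.5
    tx_CII: float = 2.5
    translation: float = 0.3
    output_interval: float = 0.5
    cell_width: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        if self.output_interval <= 0:
            raise ValueError("output_interval must be > 0")
        if self.cell_width <= 0:
            raise ValueError("cell_width must be > 0")

    def replace(self, **kwargs: float) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(d))


#: Fields subject to kinetic perturbation (everything except simulation controls).
KINETIC_FIELDS: tuple = tuple(
    f.name
    for f in dataclasses.fields(ParameterSet)
    if f.name not in ("output_interval", "cell_width")
)

#: Fields scaled by the burstiness / noise-modulation transformation.
NOISE_SCALED_FIELDS = ("translation", "mrna_decay")

TRANSCRIPTION_FIELDS = ("tx_CI_p1", "tx_CI_p2", "tx_Cro", "tx_CII")


def default_parameters() -> ParameterSet:
    """Return the package's nominal kinetic parameter set.

    The values are the documented defaults of this package (see
    ``docs/methods.md``); they place the circuit in a low-copy, weakly
    nonlinear regime in which deterministic [CII] rises and then plateaus
    over the 60-minute decision window at MOI=1, V=1.
    """
    return ParameterSet()


@dataclass(frozen=True)
class VariantFlags:
    """Optional model refinements, independent and freely combinable."""

    cii_tetramer: bool = False
    phage_replication: bool = False
    ci_self_repression: bool = False
    extrinsic_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.extrinsic_noise_cv < 0:
            raise ValueError("extrinsic_noise_cv must be >= 0")


@dataclass(frozen=True)
class CellConfig:
    """One infected cell: MOI, volume and per-phage infection timing.

    ``volume`` is in standardised units (V=1 is the unit cell).
    ``infection_offsets`` holds each phage's infection time relative to the
    first infection (minutes); the earliest offset must be zero, which fixes
    the time origin.  ``growth`` is an ``engine.GrowthModel`` or ``None``.
    """

    moi: int = 1
    volume: float = 1.0
    infection_offsets: tuple = None  # type: ignore[assignment]
    growth: object = None
    variants: VariantFlags = field(default_factory=VariantFlags)

    def __post_init__(self) -> None:
        if int(self.moi) != self.moi or self.moi < 1:
            raise ValueError("moi must be a positive integer")
        object.__setattr__(self, "moi", int(self.moi))
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        offs = self.infection_offsets
        if offs is None:
            offs = (0.0,) * self.moi
        offs = tuple(float(t) for t in offs)
        if len(offs) != self.moi:
            raise ValueError("len(infection_offsets) must equal moi")
        if any(t < 0 for t in offs):
            raise ValueError("infection offsets must be >= 0")
        if min(offs) != 0.0:
            raise ValueError("earliest infection offset must be 0 (time origin)")
        object.__setattr__(self, "infection_offsets", offs)


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: stoichiometry, rate constant and metadata.

    ``order`` is the kinetic order (0, 1 or 2); ``vol_exp`` the volume-scaling
    exponent of the propensity (-1 exactly for bimolecular reactions, else 0).
    ``category`` tags the reaction class (transcription, translation, ...) so
    that downstream transformations (growth coupling, extrinsic noise,
    dilution) can target the right channels.
    """

    name: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate: float
    rate_symbol: str
    order: int
    vol_exp: int
    category: str

    def __post_init__(self) -> None:
        for stoich in (self.reactants, self.products):
            for sp, c in stoich.items():
                if int(c) != c or c < 0:
                    raise ValueError(f"stoichiometry for {sp} must be a nonnegative integer")
        expected = -1 if self.order == 2 else 0
        if self.vol_exp != expected:
            raise ValueError(
                f"reaction {self.name}: vol_exp must be {expected} for order {self.order}"
            )
        if self.rate < 0:
            raise ValueError(f"reaction {self.name}: negative rate")


MONOMERS = ("CI", "Cro", "CII")
DIMERS = ("CI2", "Cro2", "CII2")
MRNAS = ("mCI", "mCro", "mCII")
PR_STATES_BASE = ("PR", "PR_CI2", "PR_Cro2")
PRE_STATES_BASE = ("PRE", "PRE_CII2")

#: CII protein equivalents carried by each species that contains CII.
CII_WEIGHTS = {"CII": 1, "CII2": 2, "PRE_CII2": 2, "CII4": 4, "PRE_CII4": 4}


@dataclass(frozen=True)
class ReactionNetwork:
    """Species list, reaction list and initial condition for one cell."""

    species: tuple
    reactions: tuple
    initial_counts: Mapping[str, int]
    promoter_species: tuple  # species pinned to a phage genome (not diluted, not diffusing)
    pr_states: tuple
    pre_states: tuple

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def validate(self) -> None:
        """Check stoichiometric invariants (promoter-copy conservation)."""
        for rx in self.reactions:
            for states in (self.pr_states, self.pre_states):
                delta = sum(rx.products.get(s, 0) - rx.reactants.get(s, 0) for s in states)
                if delta != 0:
                    raise ValueError(f"reaction {rx.name} does not conserve promoter copies")
            for sp in list(rx.reactants) + list(rx.products):
                if sp not in self.species:
                    raise ValueError(f"reaction {rx.name} references unknown species {sp}")


def _rx(name, reactants, products, rate, symbol, category):
    order = sum(reactants.values())
    return Reaction(
        name=name,
        reactants=dict(reactants),
        products=dict(products),
        rate=rate,
        rate_symbol=symbol,
        order=order,
        vol_exp=-1 if order == 2 else 0,
        category=category,
    )


def build_network(
    params: ParameterSet,
    config: CellConfig,
    *,
    cro_at_pre: bool = False,
) -> ReactionNetwork:
    """Assemble the reaction network for one infected cell.

    The baseline network has 14 species and 25 reactions: three reversible
    dimerisations, three monomer decays, three mRNA decays, three
    translations, reversible binding of CI2 and Cro2 at PR and of the CII
    multimer at PRE, constitutive transcription of mCro and mCII from free
    PR, and activated transcription of mCI from CI2-bound PR (``tx_CI_p1``)
    and CII-bound PRE (``tx_CI_p2``).

    Variant flags extend it: ``cii_tetramer`` routes PRE activation through a
    CII tetramer (2 CII2 <-> CII4); ``ci_self_repression`` adds a second,
    weaker CI2 operator on the CI-transcribing PR configuration that silences
    ``tx_CI_p1`` while occupied.  Phage replication is an event-schedule
    feature handled by the engine, not a reaction.  ``cro_at_pre`` optionally
    lets Cro2 repress PRE (off by default).

    Promoter copies are *state*, not reactions: the initial condition holds
    one free PR and one free PRE per phage infecting at time zero; later
    infections and replication add copies through engine events.
    """
    if config.moi < 1:
        raise ValueError("moi must be >= 1")
    p = params
    v = config.variants

    pr_states = list(PR_STATES_BASE)
    pre_states = list(PRE_STATES_BASE)
    species = list(MONOMERS) + list(DIMERS) + list(MRNAS)
    rxns: list[Reaction] = []

    # Reversible dimerisation of the three monomers.
    for mono, dim in zip(MONOMERS, DIMERS):
        rxns.append(
            _rx(f"dim_{mono}", {mono: 2}, {dim: 1}, getattr(p, f"dim_fwd_{mono}"),
                f"dim_fwd_{mono}", "dimerisation")
        )
        rxns.append(
            _rx(f"undim_{mono}", {dim: 1}, {mono: 2}, getattr(p, f"dim_rev_{mono}"),
                f"dim_rev_{mono}", "dimerisation")
        )

    # First-order turnover: monomers decay, mRNAs degrade.  Dimers and
    # promoter-bound dimers do not decay directly; their turnover proceeds by
    # dissociation followed by monomer decay.
    for mono in MONOMERS:
        rxns.append(
            _rx(f"decay_{mono}", {mono: 1}, {}, getattr(p, f"decay_{mono}"),
                f"decay_{mono}", "decay")
        )
    for m in MRNAS:
        rxns.append(_rx(f"deg_{m}", {m: 1}, {}, p.mrna_decay, "mrna_decay", "mrna_decay"))

    # Translation (catalytic in the message).
    for m, mono in zip(MRNAS, MONOMERS):
        rxns.append(
            _rx(f"tln_{mono}", {m: 1}, {m: 1, mono: 1}, p.translation,
                "translation", "translation")
        )

    # Promoter binding at PR: CI2 (self-activating configuration) and Cro2
    # (repressing configuration).
    rxns.append(_rx("bind_PR_CI2", {"CI2": 1, "PR": 1}, {"PR_CI2": 1},
                    p.bind_CI, "bind_CI", "binding"))
    rxns.append(_rx("unbind_PR_CI2", {"PR_CI2": 1}, {"CI2": 1, "PR": 1},
                    p.unbind_CI, "unbind_CI", "unbinding"))
    rxns.append(_rx("bind_PR_Cro2", {"Cro2": 1, "PR": 1}, {"PR_Cro2": 1},
                    p.bind_Cro, "bind_Cro", "binding"))
    rxns.append(_rx("unbind_PR_Cro2", {"PR_Cro2": 1}, {"Cro2": 1, "PR": 1},
                    p.unbind_Cro, "unbind_Cro", "unbinding"))

    # PRE activation by the CII multimer (dimer, or tetramer under the flag).
    if v.cii_tetramer:
        species.append("CII4")
        pre_states = ["PRE", "PRE_CII4"]
        rxns.append(_rx("tet_CII", {"CII2": 2}, {"CII4": 1},
                        p.dim_fwd_CII, "dim_fwd_CII", "dimerisation"))
        rxns.append(_rx("untet_CII", {"CII4": 1}, {"CII2": 2},
                        p.dim_rev_CII, "dim_rev_CII", "dimerisation"))
        activator, bound = "CII4", "PRE_CII4"
    else:
        activator, bound = "CII2", "PRE_CII2"
    rxns.append(_rx(f"bind_PRE_{activator}", {activator: 1, "PRE": 1}, {bound: 1},
                    p.bind_CII, "bind_CII", "binding"))
    rxns.append(_rx(f"unbind_PRE_{activator}", {bound: 1}, {activator: 1, "PRE": 1},
                    p.unbind_CII, "unbind_CII", "unbinding"))

    # Transcription.  Free PR fires the lytic messages constitutively; the
    # CI message requires an activated configuration.
    rxns.append(_rx("tx_mCro", {"PR": 1}, {"PR": 1, "mCro": 1},
                    p.tx_Cro, "tx_Cro", "transcription"))
    rxns.append(_rx("tx_mCII", {"PR": 1}, {"PR": 1, "mCII": 1},
                    p.tx_CII, "tx_CII", "transcription"))
    rxns.append(_rx("tx_mCI_p1", {"PR_CI2": 1}, {"PR_CI2": 1, "mCI": 1},
                    p.tx_CI_p1, "tx_CI_p1", "transcription"))
    rxns.append(_rx("tx_mCI_p2", {bound: 1}, {bound: 1, "mCI": 1},
                    p.tx_CI_p2, "tx_CI_p2", "transcription"))

    if v.ci_self_repression:
        # A second, weaker CI2 operator on the self-activated configuration;
        # while occupied, tx_CI_p1 is silent.
        pr_states.append("PR_CI2_CI2")
        rxns.append(_rx("bind_PR_CI2_CI2", {"CI2": 1, "PR_CI2": 1}, {"PR_CI2_CI2": 1},
                        p.bind_CI / 10.0, "bind_CI/10", "binding"))
        rxns.append(_rx("unbind_PR_CI2_CI2", {"PR_CI2_CI2": 1}, {"CI2": 1, "PR_CI2": 1},
                        p.unbind_CI, "unbind_CI", "unbinding"))

    if cro_at_pre:
        pre_states.append("PRE_Cro2")
        rxns.append(_rx("bind_PRE_Cro2", {"Cro2": 1, "PRE": 1}, {"PRE_Cro2": 1},
                        p.bind_Cro, "bind_Cro", "binding"))
        rxns.append(_rx("unbind_PRE_Cro2", {"PRE_Cro2": 1}, {"Cro2": 1, "PRE": 1},
                        p.unbind_Cro, "unbind_Cro", "unbinding"))

    species = species + pr_states + pre_states
    n_initial = sum(1 for t in config.infection_offsets if t == 0.0)
    initial = {sp: 0 for sp in species}
    initial["PR"] = n_initial
    initial["PRE"] = n_initial

    net = ReactionNetwork(
        species=tuple(species),
        reactions=tuple(rxns),
        initial_counts=initial,
        promoter_species=tuple(pr_states + pre_states),
        pr_states=tuple(pr_states),
        pre_states=tuple(pre_states),
    )
    net.validate()
    return net


def propensity(reaction: Reaction, state: Mapping[str, int], volume: float) -> float:
    """Stochastic mass-action propensity of one reaction in a given state.

    Order 0: k.  Order 1: k*x.  Order 2: (k/V)*x*y for distinct reactants and
    (k/V)*x*(x-1)/2 for a homodimerisation.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    for sp in reaction.reactants:
        if state.get(sp, 0) < 0:
            raise ValueError(f"negative count for {sp}")
    k = reaction.rate
    if reaction.order == 0:
        return k
    if reaction.order == 1:
        (sp,) = reaction.reactants
        return k * state.get(sp, 0)
    items = list(reaction.reactants.items())
    if len(items) == 1:
        sp, c = items[0]
        x = state.get(sp, 0)
        return (k / volume) * x * (x - 1) / 2.0
    (s1, _), (s2, _) = items
    return (k / volume) * state.get(s1, 0) * state.get(s2, 0)


def apply_noise_scaling(params: ParameterSet, f: float) -> ParameterSet:
    """Jointly scale translation and mRNA degradation by ``f``.

    This changes the burstiness of gene expression while leaving every
    stationary protein mean unchanged (the ratio translation/mrna_decay and
    all transcription rates are invariant), so the protein noise level can be
    dialled at fixed means.
    """
    if f <= 0:
        raise ValueError("noise scaling factor must be > 0")
    return params.replace(
        translation=params.translation * f, mrna_decay=params.mrna_decay * f
    )


def perturb_parameters(params: ParameterSet, factor_bound: float, seed: int) -> ParameterSet:
    """Multiply every kinetic rate by an independent log-uniform draw on [1/c, c].

    Sampling is symmetric on the fold scale ("a factor of c below and above"),
    so the median multiplier is 1.  Simulation controls are untouched.
    """
    c = float(factor_bound)
    if c <= 1:
        raise ValueError("factor_bound must be > 1")
    rng = np.random.default_rng(seed)
    lo, hi = -math.log(c), math.log(c)
    updates = {
        name: getattr(params, name) * math.exp(rng.uniform(lo, hi))
        for name in KINETIC_FIELDS
    }
    return params.replace(**updates)


def capsule_volume(length: float, width: float) -> float:
    """Spherocylinder (capsule) volume: pi (w/2)^2 (L - w) + (4/3) pi (w/2)^3.

    Captures the curved poles of the cell, under which doubling the length
    less than doubles the volume.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if length < width:
        raise ValueError("length must be >= width")
    r = width / 2.0
    return math.pi * r * r * (length - width) + (4.0 / 3.0) * math.pi * r**3


def capsule_length(volume: float, width: float) -> float:
    """Invert :func:`capsule_volume`: the length of a capsule of given volume."""
    if width <= 0 or volume <= 0:
        raise ValueError("volume and width must be > 0")
    r = width / 2.0
    cap = (4.0 / 3.0) * math.pi * r**3
    if volume < cap:
        raise ValueError("volume smaller than the spherical cap limit")
    return width + (volume - cap) / (math.pi * r * r)


# ---------------------------------------------------------------------------
# External interfaces: flat parameter config and the reaction table dump.

def save_parameters(params: ParameterSet, path) -> None:
    """Write a flat key-value YAML config; round-trips exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def load_parameters(path) -> ParameterSet:
    """Load a flat YAML parameter config; unknown keys are a hard error."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("parameter config must be a flat mapping")
    merged = default_parameters().to_dict()
    known = set(merged)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    merged.update(data)
    return ParameterSet.from_dict(merged)


def network_to_tsv(network: ReactionNetwork, path) -> None:
    """Dump a human-readable reaction table (TSV)."""

    def side(stoich):
        return " + ".join(
            (f"{c} {sp}" if c != 1 else sp) for sp, c in sorted(stoich.items())
        ) or "-"

    with open(path, "w") as fh:
        fh.write("reaction\treactants\tproducts\trate_symbol\trate\torder\tcategory\n")
        for rx in network.reactions:
            fh.write(
                f"{rx.name}\t{side(rx.reactants)}\t{side(rx.products)}\t"
                f"{rx.rate_symbol}\t{rx.rate:g}\t{rx.order}\t{rx.category}\n"
            )
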