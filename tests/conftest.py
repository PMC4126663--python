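"""Shared fixtures: default parameters, toy networks, and the focal
equal-concentration ensemble pair reused by several slow checks."""

import numpy as np
import pytest

from lysolatch.decision import cii_readout
from lysolatch.engine import integrate_deterministic, run_ensemble
from lysolatch.model import (
    CellConfig,
    Reaction,
    ReactionNetwork,
    build_network,
    default_parameters,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


def make_toy_network(reactions, species, initial):
    """Assemble a bare network (no promoters) for engine-level oracles."""
    return ReactionNetwork(
        species=tuple(species),
        reactions=tuple(reactions),
        initial_counts=dict(initial),
        promoter_species=(),
        pr_states=(),
        pre_states=(),
    )


def birth_death_network(birth=10.0, death=1.0):
    return make_toy_network(
        [
            Reaction("birth", {}, {"X": 1}, birth, "b", 0, 0, "test"),
            Reaction("death", {"X": 1}, {}, death, "d", 1, 0, "test"),
        ],
        ["X"],
        {"X": 0},
    )


class FocalEnsemble:
    """CII readout series for one condition's ensemble, with summaries."""

    def __init__(self, config, params, n, seed, T=60.0):
        self.config = config
        net = build_network(params, config)
        vals, _ = run_ensemble(
            net, config, params, T=T, n=n, seed=seed,
            reduce=lambda tr: cii_readout(tr),
        )
        self.series = np.asarray(vals)  # (n, P)
        det = integrate_deterministic(net, config, params, T)
        self.det_cii = cii_readout(det)
        self.times = det.times
        self.n = n

    @property
    def stats(self):
        return self.series.mean(axis=1)  # decision window == full span here

    @property
    def endpoints(self):
        return self.series[:, -1]

    def mean_series(self):
        return self.series.mean(axis=0)

    def se_series(self):
        return self.series.std(axis=0, ddof=1) / np.sqrt(self.n)


@pytest.fixture(scope="session")
def focal_pair(params):
    """MOI=1,V=1 and MOI=2,V=2 ensembles (n=5000 each, fixed seeds)."""
    return {
        "M1V1": FocalEnsemble(CellConfig(moi=1, volume=1.0), params, 5000, 2001),
        "M2V2": FocalEnsemble(CellConfig(moi=2, volume=2.0), params, 5000, 2002),
    }
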