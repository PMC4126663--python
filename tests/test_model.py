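"""Model layer: parameters, network construction, propensities, geometry."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lysolatch.decision import cii_readout
from lysolatch.engine import integrate_deterministic
from lysolatch.model import (
    KINETIC_FIELDS,
    CellConfig,
    ParameterSet,
    VariantFlags,
    apply_noise_scaling,
    build_network,
    capsule_length,
    capsule_volume,
    default_parameters,
    load_parameters,
    network_to_tsv,
    perturb_parameters,
    propensity,
    save_parameters,
)


class TestParameterSet:
    def test_defaults_positive_and_pure(self):
        p1, p2 = default_parameters(), default_parameters()
        assert p1 == p2
        for name in KINETIC_FIELDS:
            assert getattr(p1, name) > 0
        assert p1.output_interval > 0 and p1.cell_width > 0

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            ParameterSet(decay_CI=-0.1)
        with pytest.raises(ValueError):
            ParameterSet(output_interval=0.0)

    def test_config_roundtrip_exact(self, tmp_path):
        p = default_parameters().replace(tx_Cro=1.2345678901234, translation=0.37)
        path = tmp_path / "params.yaml"
        save_parameters(p, path)
        assert load_parameters(path) == p

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("tx_Croo: 1.0\n")
        with pytest.raises(ValueError, match="tx_Croo"):
            load_parameters(path)

    def test_default_regime_cii_rises_then_plateaus(self, params):
        """Deterministic [CII] must rise and then hold over the decision window."""
        cfg = CellConfig(moi=1, volume=1.0)
        det = integrate_deterministic(build_network(params, cfg), cfg, params, 60.0)
        cii = cii_readout(det)
        assert cii.mean() > 0
        assert cii.max() > 5.0
        assert cii[-1] >= 0.5 * cii.max()  # plateau, not collapse


class TestCellConfig:
    def test_offsets_default_and_validation(self):
        cfg = CellConfig(moi=3, volume=1.5)
        assert cfg.infection_offsets == (0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            CellConfig(moi=0)
        with pytest.raises(ValueError):
            CellConfig(moi=2, infection_offsets=(1.0, 2.0))  # no time origin
        with pytest.raises(ValueError):
            CellConfig(moi=2, infection_offsets=(0.0,))


class TestBuildNetwork:
    def test_baseline_size(self, params):
        net = build_network(params, CellConfig(moi=1))
        assert len(net.species) == 14
        assert len(net.reactions) == 25

    def test_tetramer_variant_swaps_pre_activation(self, params):
        net = build_network(
            params, CellConfig(moi=1, variants=VariantFlags(cii_tetramer=True))
        )
        assert "CII4" in net.species
        assert "PRE_CII4" in net.species and "PRE_CII2" not in net.species
        names = [r.name for r in net.reactions]
        assert "tet_CII" in names and "untet_CII" in names
        (bind,) = [r for r in net.reactions if r.name == "bind_PRE_CII4"]
        assert "CII4" in bind.reactants

    def test_moi_sets_initial_promoter_copies_not_reactions(self, params):
        n1 = build_network(params, CellConfig(moi=1))
        n2 = build_network(params, CellConfig(moi=2))
        assert n2.initial_counts["PR"] == 2 and n2.initial_counts["PRE"] == 2
        assert [r.name for r in n1.reactions] == [r.name for r in n2.reactions]

    def test_delayed_genomes_not_in_initial_state(self, params):
        net = build_network(params, CellConfig(moi=2, infection_offsets=(0.0, 5.0)))
        assert net.initial_counts["PR"] == 1

    @pytest.mark.parametrize(
        "flags",
        [
            VariantFlags(*combo)
            for combo in itertools.product([False, True], repeat=3)
        ],
    )
    @pytest.mark.parametrize("cro_at_pre", [False, True])
    def test_promoter_conservation_all_variants(self, params, flags, cro_at_pre):
        """Every reaction conserves total PR-state and PRE-state copies."""
        net = build_network(
            params, CellConfig(moi=2, variants=flags), cro_at_pre=cro_at_pre
        )
        net.validate()
        for rx in net.reactions:
            for states in (net.pr_states, net.pre_states):
                delta = sum(
                    rx.products.get(s, 0) - rx.reactants.get(s, 0) for s in states
                )
                assert delta == 0

    def test_bimolecular_volume_scaling_exponents(self, params):
        net = build_network(params, CellConfig(moi=1))
        for rx in net.reactions:
            assert rx.vol_exp == (-1 if rx.order == 2 else 0)

    def test_network_dump(self, params, tmp_path):
        net = build_network(params, CellConfig(moi=1))
        path = tmp_path / "net.tsv"
        network_to_tsv(net, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + len(net.reactions)


class TestPropensity:
    def test_worked_examples(self):
        from lysolatch.model import Reaction

        bind = Reaction("b", {"CII2": 1, "PRE": 1}, {"PRE_CII2": 1}, 1.0, "k", 2, -1, "binding")
        assert propensity(bind, {"CII2": 4, "PRE": 1}, 2.0) == pytest.approx(2.0)
        dim = Reaction("d", {"CI": 2}, {"CI2": 1}, 1.0, "k", 2, -1, "dimerisation")
        assert propensity(dim, {"CI": 3}, 1.0) == pytest.approx(3.0)
        dec = Reaction("x", {"CI": 1}, {}, 0.7, "k", 1, 0, "decay")
        assert propensity(dec, {"CI": 5}, 2.0) == propensity(dec, {"CI": 5}, 1.0)

    def test_negative_count_is_hard_error(self):
        from lysolatch.model import Reaction

        dec = Reaction("x", {"CI": 1}, {}, 0.7, "k", 1, 0, "decay")
        with pytest.raises(ValueError):
            propensity(dec, {"CI": -1}, 1.0)


class TestParameterTransforms:
    def test_noise_scaling_identity_and_doubling(self, params):
        assert apply_noise_scaling(params, 1.0) == params
        p2 = apply_noise_scaling(params, 2.0)
        assert p2.translation == 2 * params.translation
        assert p2.mrna_decay == 2 * params.mrna_decay
        assert p2.tx_Cro == params.tx_Cro
        with pytest.raises(ValueError):
            apply_noise_scaling(params, 0.0)

    def test_noise_scaling_preserves_constitutive_mean(self, params):
        # stationary protein mean tx * translation / (mrna_decay * decay)
        for f in (0.5, 2.0, 4.0):
            pf = apply_noise_scaling(params, f)
            m0 = params.tx_Cro * params.translation / (params.mrna_decay * params.decay_Cro)
            mf = pf.tx_Cro * pf.translation / (pf.mrna_decay * pf.decay_Cro)
            assert mf == pytest.approx(m0)

    @pytest.mark.parametrize("c", [2.0, 10.0])
    def test_perturbation_support_and_median(self, params, c):
        mults = []
        for seed in range(500):
            p = perturb_parameters(params, c, seed)
            for name in KINETIC_FIELDS:
                mults.append(getattr(p, name) / getattr(params, name))
        mults = np.asarray(mults)
        assert mults.size >= 10000
        assert np.all(mults >= 1 / c - 1e-12) and np.all(mults <= c + 1e-12)
        assert 0.95 <= np.median(mults) <= 1.05

    def test_perturbation_reproducible_and_controls_untouched(self, params):
        a = perturb_parameters(params, 2.0, 42)
        b = perturb_parameters(params, 2.0, 42)
        assert a == b
        assert a.output_interval == params.output_interval
        assert a.cell_width == params.cell_width


class TestCapsuleGeometry:
    def test_worked_examples(self):
        assert capsule_volume(1.0, 1.0) == pytest.approx(math.pi / 6, rel=1e-12)
        assert capsule_volume(2.0, 1.0) == pytest.approx(
            math.pi * 0.25 + math.pi / 6, rel=1e-12
        )
        with pytest.raises(ValueError):
            capsule_volume(0.5, 1.0)

    @given(st.floats(min_value=1.01, max_value=50.0), st.floats(min_value=0.2, max_value=2.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_doubling_length_more_than_doubles_volume(self, ratio, w):
        L = w * ratio
        assert capsule_volume(2 * L, w) > 2 * capsule_volume(L, w)

    @given(st.floats(min_value=0.6, max_value=30.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_length_volume_inversion(self, vol):
        assert capsule_volume(capsule_length(vol, 1.0), 1.0) == pytest.approx(vol)
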