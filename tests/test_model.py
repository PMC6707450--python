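"""Unit tests for the domain types, rate laws and reaction network."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitonet.model import (
    CopyState, ModelParams, UndefinedStateError,
    heteroplasmy, folded_heteroplasmy, singleton_fraction,
    replication_rate, degradation_rate, build_reaction_network,
    propensity_vector, stoichiometry_matrix, N_CORE_CHANNELS,
)


def params(**kw):
    base = dict(gamma=2e-3, beta=2.3, mu=0.023, b=1e-4, kappa=885.0)
    base.update(kw)
    return ModelParams(**base)


counts = st.integers(min_value=0, max_value=2000)
states = st.tuples(counts, counts, counts, counts)


class TestCopyState:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            CopyState(1, -1, 0, 0)

    def test_derived_totals(self):
        s = CopyState(350, 350, 150, 150)
        assert (s.n, s.w_total, s.m_total) == (1000, 700, 300)


@pytest.mark.parametrize("state, expected", [
    ((250, 250, 250, 250), 0.5),
    ((500, 500, 0, 0), 0.0),
    ((350, 350, 150, 150), 0.3),
])
def test_heteroplasmy_examples(state, expected):
    assert heteroplasmy(CopyState(*state)) == pytest.approx(expected)


@pytest.mark.parametrize("state, expected", [
    ((250, 250, 250, 250), 0.5),
    ((500, 500, 0, 0), 0.0),
    ((350, 350, 150, 150), 0.3),
    ((150, 150, 350, 350), 0.3),  # folded: h=0.7 maps onto 0.3
])
def test_folded_heteroplasmy_examples(state, expected):
    assert folded_heteroplasmy(CopyState(*state)) == pytest.approx(expected)


@pytest.mark.parametrize("state, expected", [
    ((250, 250, 250, 250), 0.5),
    ((0, 600, 0, 400), 0.0),
    ((1000, 0, 0, 0), 1.0),
])
def test_singleton_fraction_examples(state, expected):
    assert singleton_fraction(CopyState(*state)) == pytest.approx(expected)


@pytest.mark.parametrize("fn", [heteroplasmy, folded_heteroplasmy,
                                singleton_fraction])
def test_empty_cell_is_undefined(fn):
    with pytest.raises(UndefinedStateError):
        fn(CopyState(0, 0, 0, 0))


class TestRateLaws:
    def test_replication_rate_at_target_is_mu(self):
        p = params(kappa=1000.0, delta=1.0)
        s = CopyState(250, 250, 250, 250)  # wT + mT = kappa
        assert replication_rate(s, p) == pytest.approx(p.mu)

    def test_no_feedback_when_b_zero(self):
        p = params(b=0.0)
        for s in [CopyState(1, 2, 3, 4), CopyState(900, 900, 900, 900)]:
            assert replication_rate(s, p) == pytest.approx(p.mu)

    def test_linear_feedback_arithmetic(self):
        p = params(mu=0.023, b=1e-4, kappa=1000.0, delta=1.0)
        s = CopyState(300, 300, 300, 300)  # wT + mT = 1200
        assert replication_rate(s, p) == pytest.approx(0.003)

    def test_clamped_at_zero_for_large_copy_number(self):
        p = params(mu=0.023, b=1e-4, kappa=1000.0)
        s = CopyState(5000, 5000, 0, 0)
        assert replication_rate(s, p) == 0.0

    def test_neutral_mitophagy_identical_between_genotypes(self):
        p = params(eps_m=0.0)
        s = CopyState(10, 20, 30, 40)
        assert degradation_rate(s, p, "W") == degradation_rate(s, p, "M")

    def test_selective_mitophagy_scales_mutant_rate(self):
        p = params(mu=0.023, eps_m=0.5)
        s = CopyState(10, 20, 30, 40)
        assert degradation_rate(s, p, "M") == pytest.approx(0.0345)

    def test_degradation_control_balance_point(self):
        p = params(control_mode="degradation", lam0=0.0115, kappa=1000.0)
        s = CopyState(250, 250, 250, 250)  # wT + delta*mT = kappa
        assert degradation_rate(s, p, "W") == pytest.approx(p.lam0)


class TestReactionNetwork:
    def test_default_channel_count_is_15(self):
        assert len(build_reaction_network(params())) == N_CORE_CHANNELS == 15

    def test_fused_degradation_adds_two_channels(self):
        assert len(build_reaction_network(params(mu_f=0.01))) == 17

    def test_channel_labels_unique(self):
        net = build_reaction_network(params())
        assert len(set(net.labels)) == 15

    def test_selective_fusion_scales_every_mutant_fusion_channel(self):
        s = CopyState(40, 30, 20, 10)
        a0 = propensity_vector(s, params(eps_f=0.0))
        a1 = propensity_vector(s, params(eps_f=0.5))
        mutant_fusion = [3, 4, 12, 13, 14]  # M pair, MF+MS, and the 3 cross
        wild = [0, 1, 2, 5, 6, 7, 8, 9, 10, 11]
        np.testing.assert_allclose(a1[mutant_fusion], a0[mutant_fusion] / 1.5)
        np.testing.assert_allclose(a1[wild], a0[wild])

    def test_propensities_zero_on_empty_state(self):
        assert np.all(propensity_vector(CopyState(0, 0, 0, 0), params()) == 0)

    def test_single_molecule_cannot_pair_fuse(self):
        a = propensity_vector(CopyState(1, 0, 0, 0), params())
        assert a[0] == 0.0  # WS+WS channel needs two singletons

    def test_network_matches_vector(self):
        p = params(eps_f=0.3, eps_m=0.2)
        net = build_reaction_network(p)
        s = CopyState(13, 7, 5, 11)
        a = propensity_vector(s, p)
        for i, r in enumerate(net.reactions):
            assert r.propensity(s) == pytest.approx(a[i])

    def test_total_fusion_propensity_matches_pair_enumeration(self):
        """Oracle: enumerate all labeled molecule pairs that can fuse and sum
        their per-pair rates; compare to the fusion channels' total."""
        p = params(eps_f=0.7)
        s = CopyState(6, 4, 5, 3)
        singles = ["W"] * s.ws + ["M"] * s.ms
        fused = ["W"] * s.wf + ["M"] * s.mf

        def pair_rate(g1, g2):
            return p.gamma_eff if (g1 == "W" and g2 == "W") else p.gamma_mut

        total = 0.0
        for g1, g2 in itertools.combinations(singles, 2):  # S+S, unordered
            total += pair_rate(g1, g2)
        for gf in fused:  # F+S: every fused can absorb every singleton
            for gs in singles:
                total += pair_rate(gf, gs)

        a = propensity_vector(s, p)
        fusion_channels = [0, 1, 3, 4, 12, 13, 14]
        assert a[fusion_channels].sum() == pytest.approx(total)


class TestInvariants:
    @settings(max_examples=100, deadline=None)
    @given(states)
    def test_neutral_genotype_exchange_symmetry(self, s):
        """With no selectivity, swapping (ws,wf)<->(ms,mf) permutes the
        propensity vector according to the W<->M channel relabeling."""
        p = params(eps_f=0.0, eps_m=0.0)
        ws, wf, ms, mf = s
        a = propensity_vector(CopyState(ws, wf, ms, mf), p)
        b = propensity_vector(CopyState(ms, mf, ws, wf), p)
        perm = [3, 4, 5, 0, 1, 2, 9, 10, 11, 6, 7, 8, 13, 12, 14]
        np.testing.assert_allclose(a, b[perm], rtol=1e-12)

    @pytest.mark.parametrize("topology", ["singleton_to_fused",
                                          "singleton_to_singleton"])
    def test_copy_number_change_per_channel_class(self, topology):
        p = params(mu_f=0.01, replication_topology=topology)
        net = build_reaction_network(p)
        for r in net.reactions:
            dn = sum(r.stoich)
            kind = r.label.split("_")[0]
            expected = {"fusion": 0, "fission": 0, "replication": 1,
                        "mitophagy": -1, "degradation": -1}[kind]
            assert dn == expected, r.label

    def test_network_channels_conserve_genotype_totals(self):
        net = build_reaction_network(params())
        for r in net.reactions:
            if r.label.startswith(("fusion", "fission")):
                dws, dwf, dms, dmf = r.stoich
                assert dws + dwf == 0 and dms + dmf == 0, r.label

    @settings(max_examples=100, deadline=None)
    @given(states)
    def test_positive_propensity_never_drives_counts_negative(self, s):
        p = params(mu_f=0.01, eps_f=0.2, eps_m=0.1)
        net = build_reaction_network(p)
        state = CopyState(*s)
        x = state.as_array()
        for r in net.reactions:
            if r.propensity(state) > 0:
                assert np.all(x + np.array(r.stoich) >= 0), r.label

    def test_stoichiometry_matrix_matches_reactions(self):
        p = params(mu_f=0.01)
        S = stoichiometry_matrix(p)
        net = build_reaction_network(p)
        np.testing.assert_array_equal(
            S, np.array([r.stoich for r in net.reactions]))


class TestModelParams:
    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            params(mu=-0.1)

    def test_rejects_unknown_modes(self):
        with pytest.raises(ValueError):
            params(control_mode="telepathy")
        with pytest.raises(ValueError):
            params(replication_topology="budding")

    def test_degradation_mode_requires_lam0(self):
        with pytest.raises(ValueError):
            params(control_mode="degradation", lam0=0.0)

    def test_effective_rates_scale_with_magnitude_and_ratio(self):
        p = params(M=0.1, R=2.0)
        assert p.gamma_eff == pytest.approx(p.gamma * 0.2)
        assert p.beta_eff == pytest.approx(p.beta * 0.1)

    def test_roundtrip_dict(self):
        p = params(eps_f=0.5, M=0.1)
        assert ModelParams.from_dict(p.to_dict()) == p
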