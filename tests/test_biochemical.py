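"""Plasticity reaction network: conservation, equilibrium, the
calcium-level switch between the CaMKII and PP1 branches, and the
zeroth-order influx process."""
import copy

import numpy as np
import pytest

from spinesync.biochemical import (BiochemicalSpine, Reaction,
                                   ReactionNetworkState, Species,
                                   build_network, equilibrate, mm_rate)


class TestMMRate:
    def test_half_saturation(self):
        assert mm_rate(2.0, 1e-6, 1e-7, 1e-6) == pytest.approx(1e-7)

    def test_zero_substrate(self):
        assert mm_rate(2.0, 1e-6, 1e-7, 0.0) == 0.0

    def test_saturation_limit(self):
        assert mm_rate(2.0, 1e-6, 1e-7, 1e-3) == pytest.approx(
            2e-7, rel=1e-2)

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError):
            mm_rate(2.0, 0.0, 1e-7, 1e-6)


class TestBuildNetwork:
    def test_moiety_totals_match_initial_concentrations(self, kinetics_config):
        net = build_network(kinetics_config)
        t8 = kinetics_config["table8"]
        totals = net.moiety_totals()
        assert totals["CaM"] == pytest.approx(t8["CaM"])
        assert totals["CaMKII"] == pytest.approx(t8["CaMKII"])
        assert totals["DARPP32"] == pytest.approx(t8["DARPP32"])
        assert totals["PP1"] == pytest.approx(t8["PP1"])
        assert totals["AMPAR"] == pytest.approx(t8["AMPAR"])

    def test_amparp_pathways_in_reaction_graph(self, kinetics_config):
        # phospho-AMPAR is produced only by the CaMKII branch and consumed
        # only by the PP1 branch
        net = build_network(kinetics_config)
        g = net.reaction_graph()
        producers = [r for r in g.predecessors("AMPARp")]
        consumers = [r for r in g.successors("AMPARp")]
        assert producers == ["camkii_ampar"]
        assert consumers == ["pp1_amparp"]
        assert list(g.predecessors("camkii_ampar")) != []  # enzyme edges

    def test_missing_parameter_is_a_named_rejection(self, kinetics_config):
        broken = copy.deepcopy(kinetics_config)
        del broken["table7"]["pump"]["vmax"]
        with pytest.raises(KeyError, match="pump.vmax"):
            build_network(broken)

    def test_json_export_describes_the_network(self, kinetics_config,
                                               tmp_path):
        import json

        net = build_network(kinetics_config)
        p = tmp_path / "network.json"
        net.to_json(p)
        desc = json.loads(p.read_text())
        assert len(desc["species"]) == len(net.species)
        names = {r["name"] for r in desc["reactions"]}
        assert {"camkii_ampar", "pp1_amparp", "ca_influx"} <= names

    def test_sequential_wiring_option_restricts_transitions(self,
                                                            kinetics_config):
        cfg = copy.deepcopy(kinetics_config)
        cfg["options"]["cam_transitions"] = "ends"
        net = build_network(cfg)
        trans = [r.name for r in net.reactions if "_to_" in r.name]
        assert sorted(trans) == sorted(
            ["cam_R0_to_T0", "cam_T0_to_R0", "cam_R4_to_T4", "cam_T4_to_R4"])


class TestCalciumInflux:
    def test_zero_flux_means_stationary_rest(self, equilibrated_network):
        net = equilibrated_network
        ca0 = net.conc("Ca")
        net.advance(5.0)
        assert net.conc("Ca") == pytest.approx(ca0, rel=1e-4)

    def test_pure_influx_integrates_linearly(self):
        # with every other reaction absent, 1e-6 M/s for 1 s adds 1 µM
        net = ReactionNetworkState(
            [Species("Ca", 1e-7, {"Ca": 1})],
            [Reaction("ca_influx", "constant_flux", [], ["Ca"], rate=0.0)])
        net.set_calcium_influx(1e-6)
        net.advance(1.0)
        assert net.conc("Ca") == pytest.approx(1e-7 + 1e-6, rel=1e-6)

    def test_negative_flux_floors_at_zero(self):
        net = ReactionNetworkState(
            [Species("Ca", 1e-7, {"Ca": 1})],
            [Reaction("ca_influx", "constant_flux", [], ["Ca"], rate=0.0)])
        net.set_calcium_influx(-1e-3)
        net.advance(2.0)
        assert net.conc("Ca") == 0.0


class TestEquilibrate:
    def test_already_equilibrated_returns_quickly(self, equilibrated_network):
        t0 = equilibrated_network.time
        equilibrate(equilibrated_network, horizon=1000.0)
        assert equilibrated_network.time == t0  # converged without stepping

    def test_fixed_point_recovered_after_perturbation(self,
                                                      equilibrated_network):
        net = equilibrated_network
        ref = dict(net.equilibrium)
        net.set_conc("Ca", 2 * net.conc("Ca"))
        equilibrate(net, horizon=3000.0, tol=1e-7)
        for name in ("Ca", "AMPARp", "PP1", "D32p"):
            assert net.conc(name) == pytest.approx(ref[name], rel=1e-2)

    def test_equilibrium_amparp_strictly_interior(self, equilibrated_network):
        p = equilibrated_network.equilibrium["AMPARp"]
        total = equilibrated_network.moiety_totals()["AMPAR"]
        assert 0.0 < p < total

    def test_requires_zero_influx(self, equilibrated_network):
        equilibrated_network.set_calcium_influx(1e-6)
        with pytest.raises(ValueError, match="zero calcium influx"):
            equilibrate(equilibrated_network)

    def test_no_bistability_at_defaults(self, equilibrated_network):
        # two differently perturbed starts converge to the same fixed point
        a = copy.deepcopy(equilibrated_network)
        b = copy.deepcopy(equilibrated_network)
        a.set_conc("Ca", 5e-7)
        total = b.moiety_totals()["AMPAR"]
        b.set_conc("AMPARp", 0.8 * total)
        b.set_conc("AMPAR", 0.2 * total)
        equilibrate(a, horizon=4000.0)
        equilibrate(b, horizon=4000.0)
        assert a.conc("AMPARp") == pytest.approx(b.conc("AMPARp"), rel=1e-2)


class TestConservation:
    def test_moieties_conserved_under_influx_protocol(self,
                                                      equilibrated_network):
        net = equilibrated_network
        before = net.moiety_totals()
        net.set_calcium_influx(5e-6)
        net.advance(5.0)
        net.set_calcium_influx(0.0)
        net.advance(5.0)
        after = net.moiety_totals()
        for k in before:
            assert abs(after[k] - before[k]) / before[k] < 1e-6

    def test_solver_tolerance_convergence(self, kinetics_config):
        # halving rtol changes the phospho-AMPAR trajectory by < 0.5%
        results = []
        for rtol in (2e-8, 1e-8):
            net = equilibrate(build_network(kinetics_config, rtol=rtol))
            net.set_calcium_influx(5e-6)
            net.advance(5.0)
            results.append(net.conc("AMPARp"))
        assert abs(results[0] - results[1]) / results[1] < 5e-3


class TestCalciumSwitch:
    """Low sustained calcium routes to the PP1 branch, high calcium to the
    CaMKII branch; the sign of the net phospho-AMPAR flux on a potentiated
    state flips between the regimes."""

    @staticmethod
    def _potentiate(net, level=0.5):
        total = net.moiety_totals()["AMPAR"]
        net.set_conc("AMPARp", level * total)
        net.set_conc("AMPAR", (1 - level) * total)

    @staticmethod
    def _net_ampar_flux(net):
        v = dict(zip((r.name for r in net.reactions), net.rates(net.x)))
        return v["camkii_ampar"] - v["pp1_amparp"]

    def test_low_influx_net_dephosphorylation(self, equilibrated_network):
        net = equilibrated_network
        self._potentiate(net)
        net.set_calcium_influx(1.5e-6)   # sustains ~0.2 µM free calcium
        net.advance(30.0)                # let the PP1 branch engage
        assert self._net_ampar_flux(net) < 0
        p0 = net.conc("AMPARp")
        net.advance(20.0)
        assert net.conc("AMPARp") < p0

    def test_high_influx_net_phosphorylation(self, equilibrated_network):
        net = equilibrated_network
        self._potentiate(net)
        net.set_calcium_influx(2e-5)     # micromolar free calcium
        net.advance(2.0)
        assert self._net_ampar_flux(net) > 0
        p0 = net.conc("AMPARp")
        net.advance(2.0)
        assert net.conc("AMPARp") > p0

    def test_dephosphorylation_dominance_ordering(self, equilibrated_network):
        # the dephosphorylation/phosphorylation flux ratio is higher in the
        # low-calcium regime than in the high-calcium regime
        ratios = []
        for influx, dur in ((1.5e-6, 30.0), (2e-5, 2.0)):
            net = copy.deepcopy(equilibrated_network)
            self._potentiate(net)
            net.set_calcium_influx(influx)
            net.advance(dur)
            v = dict(zip((r.name for r in net.reactions),
                         net.rates(net.x)))
            ratios.append(v["pp1_amparp"] / v["camkii_ampar"])
        assert ratios[0] > 1.0 > ratios[1]


class TestStepBiochemical:
    def test_sustained_high_influx_raises_amparp_above_equilibrium(
            self, equilibrated_network):
        spine = BiochemicalSpine(equilibrated_network)
        eq = equilibrated_network.equilibrium["AMPARp"]
        spine.set("k_flux", 2e-5)
        spine.step(5000.0)  # ms
        assert spine.get("AMPAR_P") > 2 * eq

    def test_brief_subthreshold_influx_changes_little(self,
                                                      equilibrated_network):
        spine = BiochemicalSpine(equilibrated_network)
        total = equilibrated_network.moiety_totals()["AMPAR"]
        p0 = spine.get("AMPAR_P")
        spine.set("k_flux", 2e-7)
        spine.step(200.0)
        spine.set("k_flux", 0.0)
        spine.step(1000.0)
        assert abs(spine.get("AMPAR_P") - p0) < 0.01 * total

    def test_handle_variables_exposed(self, equilibrated_network):
        spine = BiochemicalSpine(equilibrated_network)
        for name in ("AMPAR_P", "Ca", "Ca_total", "active_CaMKII_frac",
                     "active_PP1_frac", "D32_P_frac", "k_flux"):
            assert np.isfinite(spine.get(name))
        with pytest.raises(KeyError):
            spine.get("nope")

    def test_backwards_integration_rejected(self):
        net = ReactionNetworkState(
            [Species("Ca", 1.0, {"Ca": 1})],
            [Reaction("ca_influx", "constant_flux", [], ["Ca"],
                      rate=0.0)])
        with pytest.raises(ValueError, match="backwards"):
            net.advance(-1.0)
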