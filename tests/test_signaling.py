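"""Correlation-and-pruning rules for the signaling network reconstruction."""
import numpy as np
import pandas as pd
import pytest

from spotlink.config import PipelineConfig
from spotlink.dataset import LRPair, LRReference
from spotlink.errors import SpotlinkError
from spotlink.regulon import ActivityMatrix, Regulon
from spotlink.signaling import (link_receptors, prune_targeted_receptors,
                                receptor_module_correlation,
                                require_cognate_ligands,
                                run_interaction_analysis,
                                score_network_recovery)


def _activity(values, spots):
    return ActivityMatrix(pd.DataFrame([values], index=["TF1"],
                                       columns=spots))


class TestCorrelation:
    def test_affine_receptor_gives_r_one(self):
        n = 20
        act_vals = np.linspace(0, 1, n)
        spots = [f"s{i}" for i in range(n)]
        act = _activity(act_vals, spots)
        expr = (3.0 * act_vals + 7.0)[None, :]
        corr, flagged = receptor_module_correlation(
            act, expr, ["R1"], ["R1"], np.arange(n), spots)
        assert corr.loc["R1", "TF1"] == pytest.approx(1.0)
        assert flagged == []

    def test_constant_receptor_flagged_as_zero(self):
        n = 15
        spots = [f"s{i}" for i in range(n)]
        act = _activity(np.random.default_rng(0).random(n), spots)
        expr = np.full((1, n), 4.2)
        corr, flagged = receptor_module_correlation(
            act, expr, ["R1"], ["R1"], np.arange(n), spots)
        assert corr.loc["R1", "TF1"] == 0.0
        assert flagged == ["R1"]

    def test_twelve_spot_toy_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        n = 12
        spots = [f"s{i}" for i in range(n)]
        a = rng.random(n)
        e = rng.random(n)
        act = _activity(a, spots)
        corr, _ = receptor_module_correlation(
            act, e[None, :], ["R1"], ["R1"], np.arange(n), spots)
        num = np.sum((a - a.mean()) * (e - e.mean()))
        den = np.sqrt(np.sum((a - a.mean())**2) * np.sum((e - e.mean())**2))
        assert corr.loc["R1", "TF1"] == pytest.approx(num / den, abs=1e-12)

    def test_small_region_is_hard_error(self):
        spots = [f"s{i}" for i in range(5)]
        act = _activity(np.linspace(0, 1, 5), spots)
        with pytest.raises(SpotlinkError, match="region"):
            receptor_module_correlation(act, np.ones((1, 5)), ["R1"],
                                        ["R1"], np.arange(5), spots)


class TestPruneAndLink:
    def _corr(self, r):
        return pd.DataFrame({"TF1": [r]}, index=["R1"])

    def test_targeted_receptor_zeroed(self):
        regs = [Regulon("TF1", ["R1", "G2"], {"R1": 1.0, "G2": 0.9})]
        out = prune_targeted_receptors(self._corr(0.9), regs)
        assert out.loc["R1", "TF1"] == 0.0

    def test_untargeted_receptor_untouched_and_idempotent(self):
        regs = [Regulon("TF1", ["G2"], {"G2": 0.9})]
        out = prune_targeted_receptors(self._corr(0.9), regs)
        assert out.loc["R1", "TF1"] == 0.9
        regs2 = [Regulon("TF1", ["R1"], {"R1": 1.0})]
        once = prune_targeted_receptors(self._corr(0.0), regs2)
        assert once.loc["R1", "TF1"] == 0.0

    @pytest.mark.parametrize("r,linked", [(0.31, True), (0.30, False),
                                          (-0.9, False)])
    def test_strict_threshold_one_sided(self, r, linked):
        links = link_receptors(self._corr(r), 0.3)
        assert (len(links) == 1) == linked


class TestCognateLigands:
    def _setup(self, ligand_frac):
        n_sender = 25
        n_expressed = int(round(ligand_frac * n_sender))
        expr = np.zeros((3, n_sender))
        expr[0, :n_expressed] = 1.0   # ligand L1
        expr[1, :] = 1.0              # ligand L2 everywhere
        expr[2, :] = 1.0              # the receptor R1 itself
        return expr, ["L1", "L2", "R1"], np.arange(n_sender)

    def test_ligand_above_detection_floor_keeps_edge(self):
        expr, genes, sender = self._setup(0.08)
        lr = LRReference([LRPair("p1", ("L1",), ("R1",))])
        edges, excl = require_cognate_ligands(
            [("R1", "TF1", 0.5)], lr, expr, genes, sender, 0.05)
        assert len(edges) == 1 and edges[0].ligand == "L1"

    def test_undetected_ligand_drops_link(self):
        expr, genes, sender = self._setup(0.0)
        lr = LRReference([LRPair("p1", ("L1",), ("R1",))])
        edges, excl = require_cognate_ligands(
            [("R1", "TF1", 0.5)], lr, expr, genes, sender, 0.05)
        assert edges == []
        assert excl[0]["reason"].startswith("no cognate ligand")

    def test_two_expressed_ligands_give_two_edges(self):
        expr, genes, sender = self._setup(0.2)
        lr = LRReference([LRPair("p1", ("L1",), ("R1",)),
                          LRPair("p2", ("L2",), ("R1",))])
        edges, _ = require_cognate_ligands(
            [("R1", "TF1", 0.5)], lr, expr, genes, sender, 0.05)
        assert {e.ligand for e in edges} == {"L1", "L2"}
        assert all(e.receptor == "R1" and e.tf_module == "TF1"
                   for e in edges)

    def test_receptor_absent_from_reference_recorded(self):
        expr, genes, sender = self._setup(0.2)
        lr = LRReference([LRPair("p1", ("L1",), ("OTHER",))])
        edges, excl = require_cognate_ligands(
            [("R1", "TF1", 0.5)], lr, expr, genes, sender, 0.05)
        assert edges == []
        assert "absent from LR reference" in excl[0]["reason"]

    def test_multi_subunit_ligand_requires_all_subunits(self):
        expr = np.zeros((3, 20))
        expr[0, :10] = 1.0     # La detected
        expr[1, :0] = 0.0      # Lb undetected
        expr[2, :] = 1.0       # the receptor R1
        lr = LRReference([LRPair("p1", ("La", "Lb"), ("R1",))])
        edges, excl = require_cognate_ligands(
            [("R1", "TF1", 0.5)], lr, expr, ["La", "Lb", "R1"],
            np.arange(20), 0.05)
        assert edges == []


class TestEndToEnd:
    def test_no_emitted_edge_violates_the_three_rules(self,
                                                      signaling_scenario):
        nets = signaling_scenario["networks"]
        regs = {r.tf: set(r.targets)
                for r in signaling_scenario["regulons"]}
        lr = signaling_scenario["lr"]
        lig_by_rec = {}
        for p in lr.pairs:
            for r in p.receptor:
                lig_by_rec.setdefault(r, set()).update(p.ligand)
        assert any(len(n.edges) for n in nets.values())
        for net in nets.values():
            for e in net.edges:
                assert e.pearson_r > 0.3
                assert e.receptor not in regs[e.tf_module]
                assert e.ligand in lig_by_rec[e.receptor]

    def test_raising_threshold_never_adds_edges(self, signaling_scenario):
        cfg_strict = PipelineConfig(corr_threshold=0.6)
        nets_strict = run_interaction_analysis(
            signaling_scenario["ds"], signaling_scenario["activity"],
            signaling_scenario["regulons"], signaling_scenario["lr"],
            cfg_strict)
        loose_edges = set()
        for net in signaling_scenario["networks"].values():
            loose_edges |= {(e.sender_cluster, e.receiver_cluster,
                             e.ligand, e.receptor, e.tf_module)
                            for e in net.edges}
        strict_edges = set()
        for net in nets_strict.values():
            strict_edges |= {(e.sender_cluster, e.receiver_cluster,
                              e.ligand, e.receptor, e.tf_module)
                             for e in net.edges}
        assert strict_edges <= loose_edges
        assert len(strict_edges) < len(loose_edges)

    def test_planted_links_recovered(self, signaling_scenario):
        assert signaling_scenario["precision"] >= 0.8
        assert signaling_scenario["recall"] >= 0.7

    def test_planted_triples_appear_for_planted_pairs(self,
                                                      signaling_scenario):
        nets = signaling_scenario["networks"]
        truth = signaling_scenario["truth"]
        found = set()
        for (sample, sender, receiver), net in nets.items():
            for e in net.edges:
                found.add((sender, receiver, e.ligand, e.receptor,
                           e.tf_module))
        hits = sum(
            (l.sender_domain, l.receiver_domain, l.ligand, l.receptor,
             l.tf) in found
            for l in truth.planted_links)
        assert hits >= 6   # of 8 planted links, in their planted context


class TestRecoveryScore:
    def _net(self, links):
        from spotlink.signaling import SignalingEdge, SignalingNetwork
        edges = [SignalingEdge("a", "b", "L", r, tf, 0.5)
                 for r, tf in links]
        return SignalingNetwork(edges=edges, region={"a", "b"})

    def _truth(self, signaling_scenario, n=4):
        return signaling_scenario["truth"]

    def test_perfect_recovery(self, signaling_scenario):
        truth = signaling_scenario["truth"]
        net = self._net([(l.receptor, l.tf) for l in truth.planted_links])
        assert score_network_recovery(net, truth) == (1.0, 1.0)

    def test_empty_network_gives_nan_precision(self, signaling_scenario):
        truth = signaling_scenario["truth"]
        precision, recall = score_network_recovery(self._net([]), truth)
        assert np.isnan(precision) and recall == 0.0

    def test_partial_recovery_arithmetic(self, signaling_scenario):
        truth = signaling_scenario["truth"]
        planted = [(l.receptor, l.tf) for l in truth.planted_links]
        net = self._net(planted[:3] + [("FAKE_R", "FAKE_TF")])
        precision, recall = score_network_recovery(net, truth)
        assert precision == pytest.approx(3 / 4)
        assert recall == pytest.approx(3 / len(planted))
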