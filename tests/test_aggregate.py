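"""Overall rate constants, branching ratios, and Trolox-relative capacity."""

import dataclasses

import numpy as np
import pytest

from radscav.aggregate import (
    AggregationPolicy,
    activity_report,
    branching_ratios,
    overall_rate,
    relative_activity,
)
from radscav.core import (
    Mechanism,
    MechanismNetwork,
    Pathway,
    RateMethod,
    RateRow,
    RateTable,
    SpeciesForm,
)
from radscav.screening import screen_pathways
from radscav.synthetic import BENZENE


def _screened(network):
    retained, _ = screen_pathways(network)
    return dataclasses.replace(network, pathways=retained)


class TestOverallRate:
    def test_thb_benzene_degeneracy_weighted_sum(self, thb_benzene):
        """3 x (3.65e7 + 1.91e5 + 7.18e7) from the published per-site rates."""
        net = _screened(thb_benzene.network)
        k = overall_rate(thb_benzene.reference_rates, net)
        assert k == pytest.approx(3 * (3.65e7 + 1.91e5 + 7.18e7), rel=1e-12)

    def test_thp_benzene_sum(self, thp_benzene):
        net = _screened(thp_benzene.network)
        k = overall_rate(thp_benzene.reference_rates, net)
        expected = 9.24e5 + 1.45e7 + 2.56e6 + 1.43e4 + 9.95e7 + 1.12e8 + 1.06e4
        assert k == pytest.approx(expected, rel=1e-12)

    def test_single_pathway_identity(self):
        net = MechanismNetwork(
            compound="X",
            solvent=BENZENE,
            forms=[SpeciesForm("X", 0, 0, molar_fraction=1.0)],
            pathways=[Pathway(Mechanism.HAT, "1-OH", "X", -50.0, delta_G_act=30.0)],
        )
        rates = RateTable([RateRow("X/HAT/1-OH", 5.0e6, RateMethod.TST_PLAIN)])
        assert overall_rate(rates, net) == 5.0e6

    def test_invariant_under_pathway_permutation(self, thp_benzene):
        net = _screened(thp_benzene.network)
        shuffled = dataclasses.replace(net, pathways=list(reversed(net.pathways)))
        assert overall_rate(thp_benzene.reference_rates, shuffled) == pytest.approx(
            overall_rate(thp_benzene.reference_rates, net), rel=1e-14
        )

    def test_invariant_under_degeneracy_splitting(self, thb_benzene):
        net = _screened(thb_benzene.network)
        split_paths, split_rows = [], []
        for p in net.pathways:
            k = thb_benzene.reference_rates.get(p.pathway_id).k
            for q in p.split_degeneracy():
                split_paths.append(q)
                split_rows.append(RateRow(q.pathway_id, k, RateMethod.REFERENCE))
        split_net = dataclasses.replace(net, pathways=split_paths)
        assert overall_rate(RateTable(split_rows), split_net) == pytest.approx(
            overall_rate(thb_benzene.reference_rates, net), rel=1e-14
        )

    def test_molar_fraction_weighting(self):
        net = MechanismNetwork(
            compound="X",
            solvent=BENZENE,
            forms=[
                SpeciesForm("HA", 0, 0, molar_fraction=0.8),
                SpeciesForm("A-", -1, 1, molar_fraction=0.2),
            ],
            pathways=[
                Pathway(Mechanism.HAT, "1-OH", "HA", -50.0, delta_G_act=30.0),
                Pathway(Mechanism.HAT, "1-OH", "A-", -60.0, delta_G_act=20.0),
            ],
        )
        rates = RateTable(
            [
                RateRow("HA/HAT/1-OH", 1.0e7, RateMethod.TST_PLAIN),
                RateRow("A-/HAT/1-OH", 1.0e9, RateMethod.TST_PLAIN),
            ]
        )
        assert overall_rate(rates, net, weight_by_fraction=True) == pytest.approx(
            0.8 * 1.0e7 + 0.2 * 1.0e9
        )
        assert overall_rate(rates, net, weight_by_fraction=False) == pytest.approx(
            1.0e7 + 1.0e9
        )

    def test_secondary_pathways_excluded_by_policy(self, thb_water):
        net = _screened(thb_water.network)
        k_primary = overall_rate(
            thb_water.reference_rates, net, AggregationPolicy.PRIMARY_ONLY
        )
        k_all = overall_rate(
            thb_water.reference_rates, net, AggregationPolicy.ALL_PATHWAYS
        )
        secondary_total = sum(
            p.degeneracy * thb_water.reference_rates.get(p.pathway_id).k
            for p in net.pathways
            if p.secondary
        )
        assert k_all - k_primary == pytest.approx(secondary_total, rel=1e-12)

    def test_missing_rate_for_retained_pathway_raises(self, thb_benzene):
        net = _screened(thb_benzene.network)
        with pytest.raises(ValueError, match="no rate constant"):
            overall_rate(RateTable([]), net)


class TestBranchingRatios:
    def test_thb_benzene_per_site_shares(self, thb_benzene):
        """RAF(2,4,6-C) ~22.0% each and HAT ~11.2% each of the total."""
        net = _screened(thb_benzene.network)
        k = overall_rate(thb_benzene.reference_rates, net)
        gamma = branching_ratios(thb_benzene.reference_rates, k, net)
        assert gamma["THB-OH/RAF/2-C,4-C,6-C"] == pytest.approx(22.0, abs=0.1)
        assert gamma["THB-OH/HAT/1-OH,3-OH,5-OH"] == pytest.approx(11.2, abs=0.1)

    def test_degeneracy_weighted_shares_sum_to_100(self, thb_benzene, thp_benzene):
        for fx in (thb_benzene, thp_benzene):
            net = _screened(fx.network)
            k = overall_rate(fx.reference_rates, net)
            gamma = branching_ratios(fx.reference_rates, k, net)
            total = sum(
                net.pathway(pid).degeneracy * g for pid, g in gamma.items()
            )
            assert total == pytest.approx(100.0, abs=0.5)

    def test_equal_rates_share_equally(self):
        net = MechanismNetwork(
            compound="X",
            solvent=BENZENE,
            forms=[SpeciesForm("X", 0, 0)],
            pathways=[
                Pathway(Mechanism.RAF, f"{i}-C", "X", -30.0, delta_G_act=25.0)
                for i in range(4)
            ],
        )
        rates = RateTable(
            [RateRow(p.pathway_id, 2.0e6, RateMethod.TST_PLAIN) for p in net.pathways]
        )
        k = overall_rate(rates, net)
        gamma = branching_ratios(rates, k, net)
        assert all(g == pytest.approx(25.0) for g in gamma.values())

    def test_nonpositive_total_rejected(self, thb_benzene):
        with pytest.raises(ValueError):
            branching_ratios(thb_benzene.reference_rates, 0.0)

    def test_gamma_invariant_under_rate_rescaling(self, thp_benzene):
        """Multiplying every rate by c scales k_overall by c, leaves Gamma."""
        net = _screened(thp_benzene.network)
        k = overall_rate(thp_benzene.reference_rates, net)
        gamma = branching_ratios(thp_benzene.reference_rates, k, net)
        c = 7.3
        scaled = RateTable(
            [dataclasses.replace(r, k=c * r.k) for r in thp_benzene.reference_rates]
        )
        k_scaled = overall_rate(scaled, net)
        assert k_scaled == pytest.approx(c * k, rel=1e-12)
        gamma_scaled = branching_ratios(scaled, k_scaled, net)
        for pid in gamma:
            assert gamma_scaled[pid] == pytest.approx(gamma[pid], rel=1e-12)


class TestRelativeActivity:
    @pytest.mark.parametrize(
        "k,ref,expected",
        [(7.76e9, 1.94e9, 4.00), (5.92e9, 1.94e9, 3.05), (1.94e9, 1.94e9, 1.0)],
    )
    def test_ratio(self, k, ref, expected):
        assert relative_activity(k, ref) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_activity(1e9, 0.0)


class TestActivityReport:
    def test_empty_network_reports_degenerate_status(self):
        net = MechanismNetwork(
            compound="X", solvent=BENZENE, forms=[SpeciesForm("X", 0, 0)], pathways=[]
        )
        rep = activity_report(RateTable([]), net)
        assert rep.k_overall is None
        assert rep.status == "no favourable pathways"

    def test_full_report_fields(self, thb_benzene):
        net = _screened(thb_benzene.network)
        rep = activity_report(thb_benzene.reference_rates, net)
        assert rep.k_overall == pytest.approx(3.2547e8, rel=1e-3)
        assert rep.r_T == pytest.approx(rep.k_overall / 1.31e8, rel=1e-12)
        assert set(rep.gamma) == {r.pathway_id for r in thb_benzene.reference_rates}
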