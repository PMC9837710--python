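"""Structure and CPT semantics of the unrolled temporal network."""

import math
from dataclasses import replace

import networkx as nx
import pytest

from brcasim.network import (
    STATIC_NODES,
    TEMPORAL_VARIABLES,
    build_network,
)
from brcasim.parameters import (
    CohortProfile,
    Effects,
    enumerate_policies,
    policy_by_id,
)

COHORT = CohortProfile("BRCA1", "11", "40-50", "luminal", "I", False)
SURV = policy_by_id("surveillance")


class TestStructure:
    def test_forty_nodes_per_temporal_variable(self, net40):
        assert net40.n_steps == 40
        names = net40.node_names()
        for var in TEMPORAL_VARIABLES:
            assert sum(1 for n in names if n.startswith(f"{var}@")) == 40
        assert set(STATIC_NODES) <= set(names)

    def test_validation_grid_has_six_nodes(self, params):
        net = build_network(params, 15, 2.5)
        assert net.n_steps == 6

    def test_indivisible_horizon_rejected(self, params):
        with pytest.raises(ValueError):
            build_network(params, 40, 3)

    def test_unrolled_graph_is_a_dag(self, params):
        net = build_network(params, 10, 1)
        g = net.to_digraph()
        assert nx.is_directed_acyclic_graph(g)
        # temporal nodes only depend on static nodes and earlier steps
        for a, b in g.edges:
            if "@" in a and "@" in b:
                assert int(a.split("@")[1]) < int(b.split("@")[1])

    def test_dot_and_edge_exports(self, params):
        net = build_network(params, 5, 1)
        dot = net.to_dot()
        assert dot.startswith("digraph") and '"gene"' in dot
        frame = net.edge_frame()
        assert set(frame.columns) == {"parent", "child"}
        assert len(frame) == len(net.edges())


class TestConditionalTables:
    @pytest.mark.parametrize("variable", TEMPORAL_VARIABLES)
    @pytest.mark.parametrize("step", [1, 7, 40])
    def test_absorbing_rule_and_row_distributions(self, net40, variable, step):
        for policy in enumerate_policies():
            table = net40.cpt(variable, step, cohort=COHORT, policy=policy)
            assert table.probability(prev=True) == 1.0
            for cfg, p in table.rows:
                assert 0.0 <= p <= 1.0
                assert p + (1.0 - p) == pytest.approx(1.0)

    def test_ovarian_absorbing_across_steps(self, net40):
        table = net40.cpt("ovarian_cancer", 5, cohort=COHORT, policy=SURV)
        assert table.probability(prev=True) == 1.0

    def test_ovarian_rrso_row_reduced_by_configured_fraction(self, net40):
        table = net40.cpt("ovarian_cancer", 3, cohort=COHORT, policy=SURV)
        p_off = table.probability(prev=False, rrso=False)
        p_on = table.probability(prev=False, rrso=True)
        rate_off = -math.log1p(-p_off)
        rate_on = -math.log1p(-p_on)
        assert rate_on == pytest.approx(rate_off * (1 - 0.80), rel=1e-12)

    def test_contralateral_unaffected_by_rrso(self, net40):
        table = net40.cpt("contralateral_bc", 4, cohort=COHORT, policy=SURV)
        assert table.probability(prev=False, rrso=True) == table.probability(
            prev=False, rrso=False
        )

    def test_ipsilateral_chemo_row_is_rate_scaled(self, net40):
        chemo_cohort = replace(COHORT, chemo=True)
        p_plain = net40.cpt("ipsilateral_event", 2, cohort=COHORT, policy=SURV).probability(
            prev=False, rrso=False
        )
        p_chemo = net40.cpt(
            "ipsilateral_event", 2, cohort=chemo_cohort, policy=SURV
        ).probability(prev=False, rrso=False)
        assert -math.log1p(-p_chemo) == pytest.approx(
            (1 - 0.49) * -math.log1p(-p_plain), rel=1e-12
        )

    def test_ipsilateral_mastectomy_switches_schedule(self, net40, params):
        rrbm = policy_by_id("RRBM")
        p = net40.cpt("ipsilateral_event", 1, cohort=COHORT, policy=rrbm).probability(
            prev=False, rrso=False
        )
        expected_rate = params.ipsilateral_risk["mastectomy"].step_rates(1, 40)[0]
        assert p == pytest.approx(-math.expm1(-expected_rate), rel=1e-12)

    def test_death_other_passthrough_of_attained_age_probability(self, net40, params):
        table = net40.cpt("death_other", 1, cohort=COHORT, policy=SURV)
        expected = params.other_cause_mortality[45]
        assert table.probability(prev=False, rrso_before_45=False) == pytest.approx(
            expected
        )

    def test_rrso_timing_rows_uniform_within_window(self, net40):
        rrbso = policy_by_id("RRBSO")
        # uniform over 5 one-year slots: conditional activation 1/5, 1/4, ...
        for step, expected in [(1, 1 / 5), (2, 1 / 4), (5, 1.0), (6, 0.0)]:
            table = net40.cpt("rrso_performed", step, cohort=COHORT, policy=rrbso)
            assert table.probability(prev=False) == pytest.approx(expected)
        table = net40.cpt("rrso_performed", 1, cohort=COHORT, policy=SURV)
        assert table.probability(prev=False) == 0.0

    def test_unknown_variable_and_step_rejected(self, net40):
        with pytest.raises(KeyError):
            net40.cpt("comet_strike", 1, cohort=COHORT, policy=SURV)
        with pytest.raises(IndexError):
            net40.cpt("death_bc", 41, cohort=COHORT, policy=SURV)


class TestPolicyInvarianceNull:
    def test_zeroed_effects_make_cpts_policy_invariant(self, params):
        """With every intervention effect switched off, hazard CPTs must not
        differ across policies (the policy nodes become inert parents)."""
        eff = Effects(
            rrbso_ovarian_reduction={"BRCA1": 0.0, "BRCA2": 0.0},
            rrbso_ipsilateral_reduction=0.0,
            chemo_ipsilateral_reduction=0.0,
            mastectomy_contralateral_reduction=0.0,
            tamoxifen_contralateral_reduction={"BRCA1": 0.0, "BRCA2": 0.0},
            tamoxifen_15y_mortality_reduction=0.0,
            tamoxifen_mortality_window_years=15.0,
            chemo_bc_mortality_reduction=0.0,
        )
        null = replace(
            params,
            effects=eff,
            ipsilateral_risk={
                "bct": params.ipsilateral_risk["bct"],
                "mastectomy": params.ipsilateral_risk["bct"],
            },
            rrso_excess_noncancer_multiplier=1.0,
        ).validate()
        net = build_network(null, 10, 1)
        hazard_vars = [v for v in TEMPORAL_VARIABLES if v != "rrso_performed"]
        reference = {
            var: net.cpt(var, 3, cohort=COHORT, policy=SURV).rows for var in hazard_vars
        }
        for policy in enumerate_policies():
            for var in hazard_vars:
                rows = net.cpt(var, 3, cohort=COHORT, policy=policy).rows
                assert rows == reference[var], (policy.id, var)
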