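"""Allocation arithmetic, forward-sampling semantics, and Monte-Carlo consistency."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from brcasim.network import build_network
from brcasim.parameters import (
    CohortProfile,
    default_parameters,
    enumerate_cohorts,
    enumerate_policies,
    policy_by_id,
    without_hazards,
)
from brcasim.simulate import (
    Allocation,
    allocate,
    event_history,
    iter_records,
    simulate,
    survival_of,
)

COHORT = CohortProfile("BRCA1", "11", "40-50", "luminal", "I", False)


def _single_cell(cohort, policy_id, n):
    return Allocation(
        (cohort,), (policy_by_id(policy_id),), np.array([[n]], dtype=np.int64)
    )


class TestAllocate:
    def test_exact_fill_gives_one_per_cell(self):
        alloc = allocate(1296, enumerate_cohorts(), enumerate_policies())
        assert alloc.n_total == 1296
        assert np.all(alloc.counts == 1)

    def test_remainder_goes_round_robin(self):
        alloc = allocate(1297, enumerate_cohorts(), enumerate_policies())
        assert alloc.counts.flat[0] == 2
        assert alloc.counts.sum() == 1297
        assert alloc.counts.max() - alloc.counts.min() == 1

    def test_underfill_rejected(self):
        with pytest.raises(ValueError):
            allocate(1295, enumerate_cohorts(), enumerate_policies())


class TestSamplingSemantics:
    def test_no_hazards_means_censoring_at_horizon(self, params):
        silent = without_hazards(
            params, "ipsilateral", "contralateral", "ovarian", "bc_mortality", "other"
        )
        net = build_network(silent, 40, 1)
        df = simulate(net, _single_cell(COHORT, "surveillance", 500), seed=3)
        assert (df["death_cause"] == "censored").all()
        assert (df["survival_time"] == 40.0).all()
        assert not df["event"].any()

    def test_certain_other_cause_death_at_first_step(self, params):
        lethal = replace(
            without_hazards(
                params, "ipsilateral", "contralateral", "ovarian", "bc_mortality"
            ),
            other_cause_mortality={a: 1.0 for a in params.other_cause_mortality},
        ).validate()
        net = build_network(lethal, 40, 1)
        df = simulate(net, _single_cell(COHORT, "surveillance", 200), seed=3)
        assert (df["survival_time"] == 1.0).all()
        assert (df["death_cause"] == "other").all()

    def test_deterministic_under_fixed_seed(self, net40):
        alloc = _single_cell(COHORT, "RRBSO", 400)
        a = simulate(net40, alloc, seed=11)
        b = simulate(net40, alloc, seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = simulate(net40, alloc, seed=12)
        assert not a["survival_time"].equals(c["survival_time"])

    def test_record_invariants(self, net40):
        df = simulate(net40, _single_cell(COHORT, "RRBSO", 2000), seed=5)
        # survival time is the first death activation or the horizon
        died = df["event"]
        assert (df.loc[died, "survival_time"] == df.loc[died, "death_time"]).all()
        assert (df.loc[~died, "survival_time"] == 40.0).all()
        # absorbed events can never postdate death
        for col in ("ipsilateral_time", "contralateral_time", "ovarian_time"):
            with_event = df[col].notna()
            assert (df.loc[with_event, col] <= df.loc[with_event, "survival_time"]).all()
        # RRSO happens within the 5-year window, only under an RRSO policy
        assert df["rrso_time"].dropna().between(0, 4).all()
        surveillance = simulate(net40, _single_cell(COHORT, "surveillance", 100), seed=5)
        assert surveillance["rrso_time"].isna().all()

    def test_survival_of_views(self, net40, params):
        df = simulate(net40, _single_cell(COHORT, "surveillance", 50), seed=9)
        t, e, cause = survival_of(df.iloc[0])
        assert t == df.iloc[0]["survival_time"]
        assert e == df.iloc[0]["event"]
        rec = next(iter_records(df))
        assert survival_of(rec) == (rec.survival_time, rec.event, rec.death_cause)
        # on the 2.5-year grid survival times are multiples of 2.5
        net25 = build_network(params, 15, 2.5)
        df25 = simulate(net25, _single_cell(COHORT, "surveillance", 300), seed=9)
        assert np.allclose(df25["survival_time"] % 2.5, 0)

    def test_event_history_censors_at_death_or_horizon(self, net40):
        df = simulate(net40, _single_cell(COHORT, "surveillance", 500), seed=21)
        hist = event_history(df, "ipsilateral_time")
        assert len(hist) == len(df)
        had = df["ipsilateral_time"].notna().to_numpy()
        assert (hist.loc[had, "time"] == df.loc[had, "ipsilateral_time"]).all()
        assert (hist.loc[~had, "time"] == df.loc[~had, "survival_time"]).all()
        assert hist["observed"].to_numpy().sum() == had.sum()


class TestMonteCarloConsistency:
    def test_single_hazard_matches_geometric_law(self, params):
        """With one constant annual death probability h and all other hazards
        silent, the observed death fraction by year t must match 1-(1-h)^t."""
        h = 0.02
        solo = replace(
            without_hazards(
                params, "ipsilateral", "contralateral", "ovarian", "bc_mortality"
            ),
            other_cause_mortality={a: h for a in params.other_cause_mortality},
        ).validate()
        net = build_network(solo, 40, 1)
        n = 100_000
        df = simulate(net, _single_cell(COHORT, "surveillance", n), seed=17)
        for t in (5, 20, 40):
            expected = 1 - (1 - h) ** t
            observed = (df["survival_time"] <= t)[df["event"]].sum() / n
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se, t
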