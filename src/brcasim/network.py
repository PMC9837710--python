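"""Unrolled temporal network: per-step event hazards assembled from the evidence model.

Each time-varying quantity (ipsilateral event, contralateral breast cancer,
ovarian cancer, the three death causes, RRSO-performed) is expressed as one
linked binary node per time step with absorbing semantics: once a variable is
true it stays true, and while it is false its per-step activation probability
is given by a conditional probability table assembled from the
:class:`~brcasim.parameters.ParameterSet` and the policy in force.

Canonical parent structure (the repo's DAG):

* every static covariate (gene, exon group, age group, subtype, stage, chemo,
  policy) parents every temporal hazard node;
* ``rrso_performed`` parents ``ovarian_cancer``, ``ipsilateral_event`` and
  ``death_other`` at the following step;
* ``ipsilateral_event`` and ``contralateral_bc`` parent ``death_bc`` (each
  detected second event contributes its stage/subtype-specific mortality
  hazard, summed with the first primary's, from the step after detection);
* ``ovarian_cancer`` parents ``death_oc``;
* every temporal node at step k additionally parents its own step-(k+1) node
  (the absorbing link).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conversion import RiskSchedule, annual_rate
from .parameters import (
    GENES,
    OC_STAGES,
    SUBTYPES,
    CohortProfile,
    ParameterSet,
    Policy,
)

__all__ = [
    "TEMPORAL_VARIABLES",
    "STATIC_NODES",
    "SECOND_EVENT_CATEGORIES",
    "TemporalNetwork",
    "ConditionalTable",
    "build_network",
    "cpt",
]

TEMPORAL_VARIABLES = (
    "rrso_performed",
    "ipsilateral_event",
    "contralateral_bc",
    "ovarian_cancer",
    "death_bc",
    "death_oc",
    "death_other",
)
STATIC_NODES = ("gene", "exon_group", "age_group", "subtype", "stage", "chemo", "policy")

#: mortality categories a detected second event can fall into
SECOND_EVENT_CATEGORIES = (
    ("DCIS", None),
    ("metastatic", None),
    ("I", "luminal"),
    ("I", "TN"),
    ("II", "luminal"),
    ("II", "TN"),
    ("III", "luminal"),
    ("III", "TN"),
)

#: metastatic disease is certain death on paper (probability 1.0); hazards need
#: a finite rate, so certainty is approximated by this cap over 5 years.
_METASTATIC_CAP = 0.9999
_METASTATIC_HORIZON = 5.0
_DCIS_HORIZON = 40.0


@dataclass(frozen=True)
class ConditionalTable:
    """Rows of a (variable, step) CPT: parent configuration -> P(event true).

    Each row is a Bernoulli distribution over {True, False}; ``rows`` holds
    ``(config, p_true)`` pairs where *config* is a dict of parent values.
    """

    variable: str
    step: int
    rows: tuple[tuple[dict, float], ...]

    def probability(self, **config) -> float:
        """P(variable true at this step) for an exactly matching parent config."""
        for row_cfg, p in self.rows:
            if row_cfg == config:
                return p
        raise KeyError(f"no CPT row matching {config!r} for {self.variable}@{self.step}")


class TemporalNetwork:
    """The unrolled network for a given horizon and step length.

    Static covariates are not fixed at build time: CPTs and hazard arrays are
    assembled lazily per (cohort, policy) so one network object serves all
    144 x 9 cells.  ``rrso_at_step`` overrides the default uniform-within-
    window RRSO timing with a fixed step index (0 = performed at diagnosis).
    """

    def __init__(
        self,
        params: ParameterSet,
        horizon: float,
        step_years: float,
        rrso_at_step: int | None = None,
    ):
        if step_years <= 0 or horizon <= 0:
            raise ValueError("horizon and step must be positive")
        n = round(horizon / step_years)
        if abs(n * step_years - horizon) > 1e-9 or n < 1:
            raise ValueError(f"horizon {horizon} is not a multiple of step {step_years}")
        params.validate()
        self.params = params
        self.horizon = float(horizon)
        self.step_years = float(step_years)
        self.n_steps = int(n)
        if rrso_at_step is not None and not 0 <= rrso_at_step < n:
            raise ValueError("rrso_at_step must lie within the horizon")
        self.rrso_at_step = rrso_at_step

    # -- RRSO timing --------------------------------------------------------

    @property
    def rrso_window_steps(self) -> int:
        """Number of step slots in the RRSO timing window (within 5 years)."""
        w = math.ceil(self.params.rrso_timing_window_years / self.step_years - 1e-9)
        return max(1, min(w, self.n_steps))

    # -- per-cell hazard assembly -------------------------------------------

    def ipsilateral_step_rates(self, cohort: CohortProfile, policy: Policy) -> np.ndarray:
        """Ipsilateral-event rate per year within each step, before RRSO adjustment.

        Policies including ipsilateral mastectomy switch to the post-mastectomy
        local-failure schedule; the chemo and RRSO reductions apply to the
        post-BCT hazard only.
        """
        eff = self.params.effects
        if "ipsilateral_mastectomy" in policy:
            sched = self.params.ipsilateral_risk["mastectomy"]
            return sched.step_rates(self.step_years, self.horizon)
        sched = self.params.ipsilateral_risk["bct"]
        rates = sched.step_rates(self.step_years, self.horizon)
        if cohort.chemo:
            rates = rates * (1.0 - eff.chemo_ipsilateral_reduction)
        return rates

    def contralateral_step_rates(
        self, cohort: CohortProfile, policy: Policy
    ) -> np.ndarray:
        """Contralateral-cancer rate per year within each step.

        Reduced by tamoxifen (gene-specific) and by contralateral mastectomy;
        unaffected by RRSO and by chemotherapy.
        """
        eff = self.params.effects
        sched = self.params.contralateral_risk[cohort.gene][cohort.age_group]
        rates = sched.step_rates(self.step_years, self.horizon)
        if "tamoxifen_5y" in policy:
            rates = rates * (1.0 - eff.tamoxifen_contralateral_reduction[cohort.gene])
        if "contralateral_mastectomy" in policy:
            rates = rates * (1.0 - eff.mastectomy_contralateral_reduction)
        return rates

    def ovarian_rate(self, cohort: CohortProfile) -> float:
        """Constant annual ovarian-cancer rate implied by the lifetime risk."""
        p = self.params.ovarian_lifetime_risk[cohort.gene][cohort.exon_group]
        return annual_rate(p, self.params.ovarian_lifetime_horizon)

    def first_primary_death_probs(
        self, cohort: CohortProfile, policy: Policy
    ) -> np.ndarray:
        """Per-step conditional first-primary breast-cancer death probabilities.

        Chemotherapy scales the cumulative hazard; 5-year tamoxifen multiplies
        the *cumulative* luminal mortality by 0.70 over its 15-year window,
        after which hazard increments revert to the reference curve.
        """
        eff = self.params.effects
        sched = self.params.bc_mortality[cohort.stage][cohort.subtype]
        c, n = self.step_years, self.n_steps
        lam = np.array([sched.cumulative_hazard(k * c) for k in range(n + 1)])
        if cohort.chemo:
            lam = lam * (1.0 - eff.chemo_bc_mortality_reduction)
        F = -np.expm1(-lam)
        if "tamoxifen_5y" in policy and cohort.subtype == "luminal":
            mult = 1.0 - eff.tamoxifen_15y_mortality_reduction
            window = eff.tamoxifen_mortality_window_years
            kw = min(n, int(round(window / c)))
            F_adj = F.copy()
            F_adj[: kw + 1] = mult * F[: kw + 1]
            # beyond the window the reference hazard increments resume
            for k in range(kw + 1, n + 1):
                dlam = lam[k] - lam[k - 1]
                F_adj[k] = 1.0 - (1.0 - F_adj[k - 1]) * math.exp(-dlam)
            F = F_adj
        with np.errstate(divide="ignore", invalid="ignore"):
            q = 1.0 - (1.0 - F[1:]) / (1.0 - F[:-1])
        return np.clip(np.nan_to_num(q), 0.0, 1.0)

    def second_event_rate_table(self) -> np.ndarray:
        """Mortality rate per year by (category, elapsed step since detection).

        Shape ``(len(SECOND_EVENT_CATEGORIES), n_steps + 1)``; column 0 is
        zero (an event contributes mortality only from the step after its
        detection).
        """
        p = self.params
        c, n = self.step_years, self.n_steps
        table = np.zeros((len(SECOND_EVENT_CATEGORIES), n + 1))
        for i, (stage, subtype) in enumerate(SECOND_EVENT_CATEGORIES):
            if stage == "DCIS":
                if p.dcis_mortality <= 0:
                    continue
                sched = RiskSchedule.from_pairs(
                    [(_DCIS_HORIZON, min(p.dcis_mortality, _METASTATIC_CAP))]
                )
            elif stage == "metastatic":
                if p.metastatic_mortality <= 0:
                    continue
                sched = RiskSchedule.from_pairs(
                    [(_METASTATIC_HORIZON, min(p.metastatic_mortality, _METASTATIC_CAP))]
                )
            else:
                sched = p.bc_mortality[stage][subtype]
            table[i, 1:] = sched.step_rates(c, self.horizon)
        return table

    def oc_death_rate_table(self) -> np.ndarray:
        """Ovarian-cancer mortality rate per year by (stage, elapsed step)."""
        c, n = self.step_years, self.n_steps
        table = np.zeros((len(OC_STAGES), n + 1))
        for i, stage in enumerate(OC_STAGES):
            table[i, 1:] = self.params.oc_mortality[stage].step_rates(c, self.horizon)
        return table

    def other_cause_step_probs(self, cohort: CohortProfile) -> np.ndarray:
        """Per-step other-cause death probability from the attained-age table.

        The age at the start of each step indexes the 5-year band table;
        annual probabilities are rescaled to the step length on the rate scale.
        """
        tab = self.params.other_cause_mortality
        ages = sorted(tab)
        c = self.step_years
        out = np.empty(self.n_steps)
        for k in range(self.n_steps):
            attained = cohort.representative_age + k * c
            band = min(max(ages[0], 5 * int(attained // 5)), ages[-1])
            q_annual = tab[band]
            if c == 1.0:
                out[k] = q_annual
            elif q_annual >= 1.0:
                out[k] = 1.0
            else:
                out[k] = 1.0 - (1.0 - q_annual) ** c
        return out

    def rrso_excess_applies(self, cohort: CohortProfile, rrso_time_years: float) -> bool:
        """Excess non-cancer mortality: RRSO before 45 with onset before 40."""
        rrso_age = cohort.representative_age + rrso_time_years
        return cohort.representative_age < 40 and rrso_age < 45

    # -- CPT interface -------------------------------------------------------

    def cpt(
        self,
        variable: str,
        step: int,
        cohort: CohortProfile | None = None,
        policy: Policy | None = None,
    ) -> ConditionalTable:
        """Assemble the conditional table for *variable* at *step* (1-based).

        With *cohort*/*policy* given, rows enumerate the variable's dynamic
        parent configurations for that cell; otherwise rows are produced for
        every cohort x policy combination (config then includes the static
        parents).  Every row's distribution over {True, False} sums to 1.
        """
        from .parameters import enumerate_cohorts, enumerate_policies

        if variable not in TEMPORAL_VARIABLES:
            raise KeyError(f"unknown temporal variable {variable!r}")
        if not 1 <= step <= self.n_steps:
            raise IndexError(f"step {step} outside 1..{self.n_steps}")
        if (cohort is None) != (policy is None):
            raise ValueError("give both cohort and policy, or neither")
        if cohort is not None:
            rows = tuple(self._cell_rows(variable, step, cohort, policy))
        else:
            rows = tuple(
                ({"cohort": co.label, "policy": po.id, **cfg}, p)
                for co in enumerate_cohorts()
                for po in enumerate_policies()
                for cfg, p in self._cell_rows(variable, step, co, po)
            )
        return ConditionalTable(variable, step, rows)

    def _cell_rows(self, variable, step, cohort, policy):
        c = self.step_years
        k = step
        rows = [({"prev": True}, 1.0)]  # absorbing: true stays true
        if variable == "rrso_performed":
            if "rrbso" in policy:
                if self.rrso_at_step is not None:
                    p = 1.0 if (k - 1) == self.rrso_at_step else 0.0
                else:
                    w = self.rrso_window_steps
                    p = 1.0 / (w - (k - 1)) if k <= w else 0.0
            else:
                p = 0.0
            rows.append(({"prev": False}, p))
        elif variable == "ipsilateral_event":
            eff = self.params.effects
            base = self.ipsilateral_step_rates(cohort, policy)[k - 1]
            post_bct = "ipsilateral_mastectomy" not in policy
            for rrso_active in (False, True):
                r = base
                if rrso_active and post_bct:
                    r = r * (1.0 - eff.rrbso_ipsilateral_reduction)
                rows.append(
                    ({"prev": False, "rrso": rrso_active}, -math.expm1(-r * c))
                )
        elif variable == "contralateral_bc":
            r = self.contralateral_step_rates(cohort, policy)[k - 1]
            p = -math.expm1(-r * c)
            # RRSO is listed as a parent for structural symmetry but has no
            # effect on the contralateral hazard.
            rows.append(({"prev": False, "rrso": False}, p))
            rows.append(({"prev": False, "rrso": True}, p))
        elif variable == "ovarian_cancer":
            eff = self.params.effects
            r = self.ovarian_rate(cohort)
            for rrso_active in (False, True):
                rr = r * (1.0 - eff.rrbso_ovarian_reduction[cohort.gene]) if rrso_active else r
                rows.append(
                    ({"prev": False, "rrso": rrso_active}, -math.expm1(-rr * c))
                )
        elif variable == "death_bc":
            q1 = self.first_primary_death_probs(cohort, policy)[k - 1]
            rows.append(({"prev": False, "second_event": None}, q1))
            table = self.second_event_rate_table()
            for i, (stage, subtype) in enumerate(SECOND_EVENT_CATEGORIES):
                r2 = table[i, 1]  # elapsed exactly one step since detection
                p = 1.0 - (1.0 - q1) * math.exp(-r2 * c)
                rows.append(
                    (
                        {
                            "prev": False,
                            "second_event": (stage, subtype),
                            "elapsed_steps": 1,
                        },
                        p,
                    )
                )
        elif variable == "death_oc":
            rows.append(({"prev": False, "oc": None}, 0.0))
            table = self.oc_death_rate_table()
            for i, stage in enumerate(OC_STAGES):
                p = -math.expm1(-table[i, 1] * c)
                rows.append(
                    ({"prev": False, "oc": stage, "elapsed_steps": 1}, p)
                )
        elif variable == "death_other":
            q = self.other_cause_step_probs(cohort)[k - 1]
            mult = self.params.rrso_excess_noncancer_multiplier
            rows.append(({"prev": False, "rrso_before_45": False}, q))
            if cohort.representative_age < 40:
                q_x = 1.0 - (1.0 - q) ** mult
            else:
                q_x = q
            rows.append(({"prev": False, "rrso_before_45": True}, q_x))
        return rows

    # -- graph structure ------------------------------------------------------

    def node_names(self) -> list[str]:
        nodes = list(STATIC_NODES)
        for var in TEMPORAL_VARIABLES:
            nodes.extend(f"{var}@{k}" for k in range(1, self.n_steps + 1))
        return nodes

    def edges(self) -> list[tuple[str, str]]:
        """Directed edge list of the unrolled DAG."""
        out: list[tuple[str, str]] = []
        for k in range(1, self.n_steps + 1):
            for var in TEMPORAL_VARIABLES:
                child = f"{var}@{k}"
                for s in STATIC_NODES:
                    out.append((s, child))
                if k > 1:
                    out.append((f"{var}@{k - 1}", child))
            if k > 1:
                for tgt in ("ovarian_cancer", "ipsilateral_event", "death_other"):
                    out.append((f"rrso_performed@{k - 1}", f"{tgt}@{k}"))
                for src in ("ipsilateral_event", "contralateral_bc"):
                    out.append((f"{src}@{k - 1}", f"death_bc@{k}"))
                out.append((f"ovarian_cancer@{k - 1}", f"death_oc@{k}"))
        return out

    def to_digraph(self):
        """The unrolled DAG as a networkx DiGraph (for structural checks)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.node_names())
        g.add_edges_from(self.edges())
        return g

    def to_dot(self) -> str:
        """DOT text of the unrolled DAG for external inspection."""
        lines = ["digraph temporal_network {"]
        for node in self.node_names():
            lines.append(f'  "{node}";')
        for a, b in self.edges():
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)

    def edge_frame(self):
        """Edge list as a DataFrame (parent, child) for CSV export."""
        import pandas as pd

        return pd.DataFrame(self.edges(), columns=["parent", "child"])


def build_network(
    params: ParameterSet,
    horizon: float,
    step: float,
    rrso_at_step: int | None = None,
) -> TemporalNetwork:
    """Build the unrolled temporal network.

    Parameters
    ----------
    params : ParameterSet
        Validated evidence model.
    horizon : float
        Follow-up length in years (40 for the annual model, 15 for the
        validation scenario).
    step : float
        Step length in years; must divide the horizon.
    rrso_at_step : int, optional
        Fix the RRSO step (0-based, 0 = at diagnosis) instead of drawing it
        uniformly within the timing window.
    """
    return TemporalNetwork(params, horizon, step, rrso_at_step=rrso_at_step)


def cpt(network: TemporalNetwork, variable: str, step: int, **kwargs) -> ConditionalTable:
    """Functional accessor for :meth:`TemporalNetwork.cpt`."""
    return network.cpt(variable, step, **kwargs)
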