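"""Paired-arm recovery of the configured intervention effect sizes.

Each published effect (RRSO on ipsilateral events, chemotherapy on ipsilateral
events, tamoxifen on contralateral cancer, RRSO on ovarian cancer, tamoxifen
on 15-year luminal mortality) is checked by simulating two arms that are
identical — same cohort, same root seed, hence common random numbers — except
for the single intervention under study, then estimating the cause-specific
hazard ratio (Cox) or the cumulative-mortality ratio between arms.  The design
is insensitive to placeholder parameter values because both arms share them.

RRSO is performed at year 0 in these experiments so that the marginal hazard
ratio over follow-up equals the configured effect (with the default
uniform-within-5-years timing the pre-RRSO exposure window dilutes it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import build_network
from .parameters import (
    CohortProfile,
    ParameterSet,
    policy_by_id,
    without_hazards,
)
from .simulate import Allocation, event_history, simulate
from .survival import cox_hr

__all__ = [
    "EffectRecovery",
    "paired_hazard_reduction",
    "tamoxifen_mortality_reduction",
    "EFFECT_EXPERIMENTS",
    "recover_effect",
]


@dataclass(frozen=True)
class EffectRecovery:
    """A recovered percent reduction with its Monte-Carlo standard error."""

    percent_reduction: float
    se_percent: float
    n_per_arm: int
    configured_percent: float

    @property
    def within(self) -> float:
        """Absolute deviation from the configured value, in percent points."""
        return abs(self.percent_reduction - self.configured_percent)


def _simulate_arm(
    params: ParameterSet,
    cohort: CohortProfile,
    policy_id: str,
    n: int,
    seed: int,
    horizon: float,
    step: float,
    rrso_at_step: int | None,
) -> pd.DataFrame:
    net = build_network(params, horizon, step, rrso_at_step=rrso_at_step)
    alloc = Allocation(
        (cohort,), (policy_by_id(policy_id),), np.array([[n]], dtype=np.int64)
    )
    return simulate(net, alloc, seed)


def paired_hazard_reduction(
    params: ParameterSet,
    cohort: CohortProfile,
    baseline_policy: str,
    treated_policy: str,
    event_column: str,
    n_per_arm: int,
    seed: int,
    configured: float,
    horizon: float = 40.0,
    step: float = 1.0,
    rrso_at_step: int | None = 0,
) -> EffectRecovery:
    """Recover ``100 x (1 - HR)`` for one event variable from two paired arms."""
    frames = []
    for arm, policy_id in enumerate((baseline_policy, treated_policy)):
        df = _simulate_arm(
            params, cohort, policy_id, n_per_arm, seed, horizon, step, rrso_at_step
        )
        hist = event_history(df, event_column)
        hist["arm"] = arm
        frames.append(hist)
    data = pd.concat(frames, ignore_index=True)
    hr = cox_hr(data["time"], data["observed"], data["arm"], reference=0)
    est = float(hr.loc[1, "hazard_ratio"])
    se_log = float(hr.loc[1, "se_log_hr"])
    # delta method: d(100*(1-HR))/d(log HR) = -100*HR
    se_pct = 100.0 * est * se_log
    return EffectRecovery(100.0 * (1.0 - est), se_pct, n_per_arm, 100.0 * configured)


def tamoxifen_mortality_reduction(
    params: ParameterSet,
    n_per_arm: int,
    seed: int,
    cohort: CohortProfile | None = None,
    horizon: float = 40.0,
    step: float = 1.0,
    at_year: float = 15.0,
) -> EffectRecovery:
    """Recover the tamoxifen reduction in cumulative luminal mortality at 15 years.

    Contralateral, ipsilateral and ovarian hazards are switched off so that
    the breast-cancer mortality channel reflects the first primary alone;
    cumulative breast-cancer mortality at *at_year* is compared between arms.
    """
    cohort = cohort or CohortProfile("BRCA1", "11", "40-50", "luminal", "I", False)
    if cohort.subtype != "luminal":
        raise ValueError("the tamoxifen mortality effect applies to luminal disease")
    isolated = without_hazards(params, "ipsilateral", "contralateral", "ovarian")
    fracs, ses = [], []
    for policy_id in ("surveillance", "TAM5"):
        df = _simulate_arm(
            isolated, cohort, policy_id, n_per_arm, seed, horizon, step, None
        )
        dead = (
            (df["death_cause"] == "breast cancer") & (df["survival_time"] <= at_year)
        ).mean()
        fracs.append(dead)
        ses.append(np.sqrt(dead * (1 - dead) / n_per_arm))
    f0, f1 = fracs
    ratio = f1 / f0
    # delta method on the ratio, ignoring the (favourable) pairing covariance
    se_ratio = ratio * np.sqrt((ses[0] / f0) ** 2 + (ses[1] / f1) ** 2)
    configured = params.effects.tamoxifen_15y_mortality_reduction
    return EffectRecovery(
        100.0 * (1.0 - ratio), 100.0 * se_ratio, n_per_arm, 100.0 * configured
    )


def _cohort(gene: str, subtype: str = "luminal") -> CohortProfile:
    return CohortProfile(gene, "11", "40-50", subtype, "I", False)


def _chemo_cohorts() -> tuple[CohortProfile, CohortProfile]:
    base = _cohort("BRCA1")
    from dataclasses import replace

    return base, replace(base, chemo=True)


#: named paired-arm experiments; each maps to keyword arguments of
#: :func:`paired_hazard_reduction` (configured = the effect looked up at run time)
EFFECT_EXPERIMENTS = {
    "rrbso_ipsilateral": dict(
        cohort=_cohort("BRCA1"),
        baseline_policy="surveillance",
        treated_policy="RRBSO",
        event_column="ipsilateral_time",
        effect=lambda e: e.rrbso_ipsilateral_reduction,
    ),
    "tamoxifen_contralateral_brca1": dict(
        cohort=_cohort("BRCA1"),
        baseline_policy="surveillance",
        treated_policy="TAM5",
        event_column="contralateral_time",
        effect=lambda e: e.tamoxifen_contralateral_reduction["BRCA1"],
    ),
    "tamoxifen_contralateral_brca2": dict(
        cohort=_cohort("BRCA2"),
        baseline_policy="surveillance",
        treated_policy="TAM5",
        event_column="contralateral_time",
        effect=lambda e: e.tamoxifen_contralateral_reduction["BRCA2"],
    ),
    "rrso_ovarian_brca1": dict(
        cohort=_cohort("BRCA1"),
        baseline_policy="surveillance",
        treated_policy="RRBSO",
        event_column="ovarian_time",
        effect=lambda e: e.rrbso_ovarian_reduction["BRCA1"],
    ),
    "rrso_ovarian_brca2": dict(
        cohort=_cohort("BRCA2"),
        baseline_policy="surveillance",
        treated_policy="RRBSO",
        event_column="ovarian_time",
        effect=lambda e: e.rrbso_ovarian_reduction["BRCA2"],
    ),
}


def recover_effect(
    name: str, params: ParameterSet, n_per_arm: int, seed: int
) -> EffectRecovery:
    """Run one named paired-arm experiment.

    ``chemo_ipsilateral`` and ``tamoxifen_mortality`` are special-cased: the
    former pairs chemo/no-chemo cohorts under surveillance, the latter uses
    the cumulative-mortality design.
    """
    if name == "chemo_ipsilateral":
        no_chemo, with_chemo = _chemo_cohorts()
        frames = []
        for arm, cohort in enumerate((no_chemo, with_chemo)):
            df = _simulate_arm(
                params, cohort, "surveillance", n_per_arm, seed, 40.0, 1.0, None
            )
            hist = event_history(df, "ipsilateral_time")
            hist["arm"] = arm
            frames.append(hist)
        data = pd.concat(frames, ignore_index=True)
        hr = cox_hr(data["time"], data["observed"], data["arm"], reference=0)
        est = float(hr.loc[1, "hazard_ratio"])
        se_pct = 100.0 * est * float(hr.loc[1, "se_log_hr"])
        return EffectRecovery(
            100.0 * (1.0 - est),
            se_pct,
            n_per_arm,
            100.0 * params.effects.chemo_ipsilateral_reduction,
        )
    if name == "tamoxifen_mortality":
        return tamoxifen_mortality_reduction(params, n_per_arm, seed)
    spec = EFFECT_EXPERIMENTS[name]
    return paired_hazard_reduction(
        params,
        spec["cohort"],
        spec["baseline_policy"],
        spec["treated_policy"],
        spec["event_column"],
        n_per_arm,
        seed,
        configured=spec["effect"](params.effects),
    )
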