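"""Monte-Carlo forward sampling of patients through the unrolled network.

Patients are allocated uniformly across cohort x policy cells and sampled
ancestrally, step by step.  Within a step, event variables (RRSO performed,
ipsilateral event, contralateral cancer, ovarian cancer) are resolved before
the death variables, and a second cancer detected at step k contributes to the
breast-cancer death hazard from step k+1 onward.  Ties among death causes
within a step are attributed by the fixed priority breast cancer > ovarian
cancer > other; the tie rule affects cause attribution only, never the
survival time.

Randomness: one numpy substream per (cohort index, policy index) cell, seeded
from the root seed, with a fixed per-step draw order covering every patient in
the cell whether or not they are still at risk.  This makes runs reproducible
and gives common random numbers across paired arms that share cell
coordinates (the basis of the paired effect-recovery design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import SECOND_EVENT_CATEGORIES, TemporalNetwork
from .parameters import OC_STAGES, CohortProfile, Policy

__all__ = [
    "Allocation",
    "PatientRecord",
    "allocate",
    "simulate",
    "survival_of",
    "event_history",
    "iter_records",
]

CAUSE_BC = "breast cancer"
CAUSE_OC = "ovarian cancer"
CAUSE_OTHER = "other"
CENSORED = "censored"

_COHORT_COLUMNS = ("gene", "exon_group", "age_group", "subtype", "stage", "chemo")


@dataclass(frozen=True)
class Allocation:
    """Patient counts per (cohort, policy) cell."""

    cohorts: tuple[CohortProfile, ...]
    policies: tuple[Policy, ...]
    counts: np.ndarray  # shape (n_cohorts, n_policies), int

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def per_cohort(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def per_cell(self) -> np.ndarray:
        return self.counts


def allocate(n_total: int, cohorts, policies) -> Allocation:
    """Uniform allocation with round-robin remainder in enumeration order.

    Cells are filled row-major (cohorts outer, policies inner); the first
    ``n_total mod cells`` cells in that order receive one extra patient.
    """
    cohorts = tuple(cohorts)
    policies = tuple(policies)
    n_cells = len(cohorts) * len(policies)
    if n_cells == 0:
        raise ValueError("at least one cohort and one policy are required")
    if n_total < n_cells:
        raise ValueError(
            f"n_total={n_total} is smaller than the number of cells ({n_cells})"
        )
    base, rem = divmod(int(n_total), n_cells)
    flat = np.full(n_cells, base, dtype=np.int64)
    flat[:rem] += 1
    return Allocation(cohorts, policies, flat.reshape(len(cohorts), len(policies)))


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient (object view of a result row)."""

    cohort: CohortProfile
    policy: str
    patient: int
    event_times: dict[str, float]
    survival_time: float
    death_cause: str

    @property
    def event(self) -> bool:
        return self.death_cause != CENSORED


def simulate(network: TemporalNetwork, allocation: Allocation, seed: int) -> pd.DataFrame:
    """Forward-sample every allocated patient; deterministic given *seed*.

    Returns one row per patient with the cohort covariates, policy id, first
    activation time (years) of each temporal event variable (NaN if never),
    survival time, death cause and event indicator.
    """
    frames = []
    for ci, cohort in enumerate(allocation.cohorts):
        for pi, policy in enumerate(allocation.policies):
            n = int(allocation.counts[ci, pi])
            if n == 0:
                continue
            rng = np.random.default_rng([int(seed), ci, pi])
            frames.append(_simulate_cell(network, cohort, policy, n, rng))
    out = pd.concat(frames, ignore_index=True)
    out["patient"] = np.arange(len(out))
    return out


def _category_probs(params, gene: str) -> np.ndarray:
    """Joint second-event (stage, subtype) category probabilities for *gene*."""
    dist = params.second_event_stage_distribution
    tn = params.tn_prevalence[gene]
    probs = np.zeros(len(SECOND_EVENT_CATEGORIES))
    for i, (stage, subtype) in enumerate(SECOND_EVENT_CATEGORIES):
        if stage in ("DCIS", "metastatic"):
            probs[i] = dist[stage]
        else:
            probs[i] = dist[stage] * (tn if subtype == "TN" else 1.0 - tn)
    return probs / probs.sum()


def _draw_categorical(u: np.ndarray, probs: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.cumsum(probs), u, side="right").clip(0, len(probs) - 1)


def _simulate_cell(
    net: TemporalNetwork, cohort: CohortProfile, policy: Policy, n: int, rng
) -> pd.DataFrame:
    p = net.params
    eff = p.effects
    c = net.step_years
    K = net.n_steps
    NEVER = K + 1

    post_bct = "ipsilateral_mastectomy" not in policy
    has_rrso = "rrbso" in policy

    ipsi_rate = net.ipsilateral_step_rates(cohort, policy)
    contra_rate = net.contralateral_step_rates(cohort, policy)
    oc_rate = net.ovarian_rate(cohort)
    oc_reduction = eff.rrbso_ovarian_reduction[cohort.gene]
    q1 = net.first_primary_death_probs(cohort, policy)
    q_other = net.other_cause_step_probs(cohort)
    sec_table = net.second_event_rate_table()
    oc_table = net.oc_death_rate_table()
    excess_mult = p.rrso_excess_noncancer_multiplier

    # one-time draws, fixed order (keeps paired arms on common random numbers)
    u_rrso = rng.random(n)
    u_ipsi_cat = rng.random(n)
    u_contra_cat = rng.random(n)
    u_oc_stage = rng.random(n)

    cat_probs = _category_probs(p, cohort.gene)
    ipsi_cat = _draw_categorical(u_ipsi_cat, cat_probs)
    contra_cat = _draw_categorical(u_contra_cat, cat_probs)
    oc_probs = np.array([p.oc_stage_distribution[s] for s in OC_STAGES])
    oc_stage_idx = _draw_categorical(u_oc_stage, oc_probs / oc_probs.sum())

    if has_rrso:
        if net.rrso_at_step is not None:
            rrso_time = np.full(n, net.rrso_at_step, dtype=np.int64)
        else:
            w = net.rrso_window_steps
            rrso_time = np.minimum((u_rrso * w).astype(np.int64), w - 1)
    else:
        rrso_time = np.full(n, NEVER, dtype=np.int64)

    alive = np.ones(n, dtype=bool)
    ipsi_t = np.zeros(n, dtype=np.int64)
    contra_t = np.zeros(n, dtype=np.int64)
    oc_t = np.zeros(n, dtype=np.int64)
    death_t = np.zeros(n, dtype=np.int64)
    cause = np.zeros(n, dtype=np.int8)  # 0 censored, 1 bc, 2 oc, 3 other

    onset_young = cohort.representative_age < 40
    rrso_age = cohort.representative_age + rrso_time * c

    for k in range(1, K + 1):
        U = rng.random((6, n))
        rrso_active = rrso_time <= k - 1

        # -- event variables -------------------------------------------------
        r_ipsi = np.full(n, ipsi_rate[k - 1])
        if post_bct:
            r_ipsi[rrso_active] *= 1.0 - eff.rrbso_ipsilateral_reduction
        new_ipsi = alive & (ipsi_t == 0) & (U[0] < -np.expm1(-r_ipsi * c))
        ipsi_t[new_ipsi] = k

        p_contra = -np.expm1(-contra_rate[k - 1] * c)
        new_contra = alive & (contra_t == 0) & (U[1] < p_contra)
        contra_t[new_contra] = k

        r_oc = np.where(rrso_active, oc_rate * (1.0 - oc_reduction), oc_rate)
        new_oc = alive & (oc_t == 0) & (U[2] < -np.expm1(-r_oc * c))
        oc_t[new_oc] = k

        # -- death variables (second events act from the step after detection)
        sec = np.zeros(n)
        if post_bct:
            m = (ipsi_t > 0) & (ipsi_t < k)
            sec[m] += sec_table[ipsi_cat[m], k - ipsi_t[m]]
        m = (contra_t > 0) & (contra_t < k)
        sec[m] += sec_table[contra_cat[m], k - contra_t[m]]
        p_bc = 1.0 - (1.0 - q1[k - 1]) * np.exp(-sec * c)
        d_bc = alive & (U[3] < p_bc)

        r_doc = np.zeros(n)
        m = (oc_t > 0) & (oc_t < k)
        r_doc[m] = oc_table[oc_stage_idx[m], k - oc_t[m]]
        d_oc = alive & (U[4] < -np.expm1(-r_doc * c))

        q = np.full(n, q_other[k - 1])
        if onset_young:
            excess = rrso_active & (rrso_age < 45)
            q[excess] = 1.0 - (1.0 - q[excess]) ** excess_mult
        d_other = alive & (U[5] < q)

        died = d_bc | d_oc | d_other
        cause[died & d_bc] = 1
        cause[died & d_oc & ~d_bc] = 2
        cause[died & d_other & ~d_bc & ~d_oc] = 3
        death_t[died] = k
        alive &= ~died

    survival_time = np.where(death_t > 0, death_t * c, net.horizon)
    cause_labels = np.array([CENSORED, CAUSE_BC, CAUSE_OC, CAUSE_OTHER])

    def times(arr):
        return np.where(arr > 0, arr * c, np.nan)

    rrso_years = np.where(rrso_time <= K, rrso_time * c, np.nan)
    return pd.DataFrame(
        {
            "gene": cohort.gene,
            "exon_group": cohort.exon_group,
            "age_group": cohort.age_group,
            "subtype": cohort.subtype,
            "stage": cohort.stage,
            "chemo": cohort.chemo,
            "policy": policy.id,
            "rrso_time": rrso_years,
            "ipsilateral_time": times(ipsi_t),
            "contralateral_time": times(contra_t),
            "ovarian_time": times(oc_t),
            "death_time": np.where(death_t > 0, death_t * c, np.nan),
            "survival_time": survival_time,
            "death_cause": cause_labels[cause],
            "event": death_t > 0,
        }
    )


def survival_of(record) -> tuple[float, bool, str]:
    """(time, event indicator, cause) of a record or result row."""
    if isinstance(record, PatientRecord):
        return record.survival_time, record.event, record.death_cause
    return (
        float(record["survival_time"]),
        bool(record["event"]),
        str(record["death_cause"]),
    )


def event_history(records: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Cause-specific (time, observed) pairs for one temporal event variable.

    *variable* is a result column such as ``ipsilateral_time``; patients
    without the event are censored at death or at the horizon.
    """
    t_event = records[variable]
    observed = t_event.notna()
    time = np.where(observed, t_event, records["survival_time"])
    return pd.DataFrame({"time": time, "observed": observed.to_numpy()})


def iter_records(records: pd.DataFrame):
    """Iterate result rows as :class:`PatientRecord` objects."""
    for row in records.itertuples():
        cohort = CohortProfile(
            row.gene, row.exon_group, row.age_group, row.subtype, row.stage, bool(row.chemo)
        )
        event_times = {
            "rrso_performed": row.rrso_time,
            "ipsilateral_event": row.ipsilateral_time,
            "contralateral_bc": row.contralateral_time,
            "ovarian_cancer": row.ovarian_time,
            "death": row.death_time,
        }
        yield PatientRecord(
            cohort,
            row.policy,
            int(row.patient),
            event_times,
            float(row.survival_time),
            row.death_cause,
        )
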