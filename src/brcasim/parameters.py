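"""Cohort/policy enumeration and the evidence model feeding the network CPTs.

The simulated population is stratified into 144 cohorts: gene (BRCA1/BRCA2) x
pathogenic-variant exon group (1-10, 11, 12-24/25) x age group at first
diagnosis (<40, 40-50, >50; represented by ages 35, 45, 65) x first-primary
subtype (luminal, triple-negative) x stage (I, II) x adjuvant chemotherapy
(yes/no).  Nine secondary risk-reducing policies are compared within each
cohort, from surveillance through bilateral risk-reducing mastectomy plus
5-year tamoxifen.

All conditional-probability inputs live in a :class:`ParameterSet`.  Every
entry carries a provenance tag: ``paper_body`` for values printed in the
source evidence base, ``placeholder`` for clinically plausible stand-ins for
values that live only in supplementary tables or cited literature (stage- and
subtype-specific mortality, age-stratified contralateral risks, local-failure
incidence, ovarian-cancer stage/survival, other-cause mortality).  Paired-arm
effect-recovery checks are insensitive to the placeholders by construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, fields, replace

import yaml

from .conversion import RiskSchedule

__all__ = [
    "GENES",
    "EXON_GROUPS",
    "AGE_GROUPS",
    "SUBTYPES",
    "STAGES",
    "REPRESENTATIVE_AGE",
    "SECOND_EVENT_STAGES",
    "OC_STAGES",
    "PAPER_BODY",
    "PLACEHOLDER",
    "CohortProfile",
    "Policy",
    "Effects",
    "ParameterSet",
    "SchemaError",
    "ValidationError",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "enumerate_cohorts",
    "enumerate_policies",
    "parameter_table",
    "without_hazards",
]

GENES = ("BRCA1", "BRCA2")
EXON_GROUPS = ("1-10", "11", "12-24/25")
AGE_GROUPS = ("<40", "40-50", ">50")
REPRESENTATIVE_AGE = {"<40": 35, "40-50": 45, ">50": 65}
SUBTYPES = ("luminal", "TN")
STAGES = ("I", "II")

SECOND_EVENT_STAGES = ("DCIS", "I", "II", "III", "metastatic")
OC_STAGES = ("I", "II", "III", "IV")

PAPER_BODY = "paper_body"
PLACEHOLDER = "placeholder"
_PROVENANCE_TAGS = (PAPER_BODY, PLACEHOLDER)

COMPONENTS = (
    "contralateral_mastectomy",
    "ipsilateral_mastectomy",
    "rrbso",
    "tamoxifen_5y",
)


class SchemaError(Exception):
    """A parameter file does not conform to the documented schema."""


class ValidationError(ValueError):
    """A parameter value violates a range or consistency invariant."""


@dataclass(frozen=True, order=True)
class CohortProfile:
    """One of the 144 population strata."""

    gene: str
    exon_group: str
    age_group: str
    subtype: str
    stage: str
    chemo: bool

    def __post_init__(self) -> None:
        for value, domain, name in (
            (self.gene, GENES, "gene"),
            (self.exon_group, EXON_GROUPS, "exon_group"),
            (self.age_group, AGE_GROUPS, "age_group"),
            (self.subtype, SUBTYPES, "subtype"),
            (self.stage, STAGES, "stage"),
        ):
            if value not in domain:
                raise ValueError(f"{name} must be one of {domain}, got {value!r}")

    @property
    def representative_age(self) -> int:
        """Age origin (years) used for attained-age lookups: 35, 45 or 65."""
        return REPRESENTATIVE_AGE[self.age_group]

    @property
    def label(self) -> str:
        chemo = "chemo" if self.chemo else "no-chemo"
        return (
            f"{self.gene}/{self.exon_group}/{self.age_group}/"
            f"{self.subtype}/{self.stage}/{chemo}"
        )


@dataclass(frozen=True)
class Policy:
    """A secondary risk-reducing strategy: an id plus its intervention components."""

    id: str
    components: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.components - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown policy components: {sorted(unknown)}")

    def __contains__(self, component: str) -> bool:
        return component in self.components


def _policy(pid: str, *components: str) -> Policy:
    return Policy(pid, frozenset(components))


# The nine policies in the printed order.  RRBM (bilateral mastectomy) removes
# both the treated and the untreated breast, hence carries both mastectomy
# components.
POLICIES: tuple[Policy, ...] = (
    _policy("surveillance"),
    _policy("CRRM", "contralateral_mastectomy"),
    _policy("RRBM", "contralateral_mastectomy", "ipsilateral_mastectomy"),
    _policy("CRRM+RRBSO", "contralateral_mastectomy", "rrbso"),
    _policy(
        "RRBM+RRBSO", "contralateral_mastectomy", "ipsilateral_mastectomy", "rrbso"
    ),
    _policy("TAM5", "tamoxifen_5y"),
    _policy("CRRM+TAM5", "contralateral_mastectomy", "tamoxifen_5y"),
    _policy("RRBSO", "rrbso"),
    _policy(
        "RRBM+TAM5",
        "contralateral_mastectomy",
        "ipsilateral_mastectomy",
        "tamoxifen_5y",
    ),
)


def enumerate_policies() -> list[Policy]:
    """The 9 intervention policies, in their canonical (printed) order."""
    return list(POLICIES)


def policy_by_id(pid: str) -> Policy:
    for p in POLICIES:
        if p.id == pid:
            return p
    raise KeyError(f"unknown policy id {pid!r}; known: {[p.id for p in POLICIES]}")


def enumerate_cohorts(include_chemo: bool = True) -> list[CohortProfile]:
    """Complete, duplicate-free cohort cross product in deterministic order.

    Order: gene, exon group, age group, subtype, stage, chemo — each in the
    order of the module-level domain tuples (chemo: False before True).
    """
    chemo_domain = (False, True) if include_chemo else (False,)
    return [
        CohortProfile(g, e, a, s, st, c)
        for g, e, a, s, st, c in itertools.product(
            GENES, EXON_GROUPS, AGE_GROUPS, SUBTYPES, STAGES, chemo_domain
        )
    ]


@dataclass(frozen=True)
class Effects:
    """Intervention effect sizes (relative risk/hazard reductions)."""

    rrbso_ovarian_reduction: dict[str, float]
    rrbso_ipsilateral_reduction: float
    chemo_ipsilateral_reduction: float
    mastectomy_contralateral_reduction: float
    tamoxifen_contralateral_reduction: dict[str, float]
    tamoxifen_15y_mortality_reduction: float
    tamoxifen_mortality_window_years: float
    chemo_bc_mortality_reduction: float


@dataclass(frozen=True)
class ParameterSet:
    """All probabilities and effect sizes feeding the temporal network CPTs."""

    #: cumulative contralateral-breast-cancer risk by gene x age-at-onset group
    contralateral_risk: dict[str, dict[str, RiskSchedule]]
    #: local-failure cumulative incidence after BCT and after mastectomy
    ipsilateral_risk: dict[str, RiskSchedule]
    #: cumulative ovarian-cancer probability to the lifetime horizon, by gene x exon
    ovarian_lifetime_risk: dict[str, dict[str, float]]
    ovarian_lifetime_horizon: float
    #: breast-cancer-specific cumulative mortality by stage x subtype
    bc_mortality: dict[str, dict[str, RiskSchedule]]
    dcis_mortality: float
    metastatic_mortality: float
    #: annual other-cause death probability by attained-age band (5-year bands)
    other_cause_mortality: dict[int, float]
    #: non-cancer mortality rate multiplier after RRSO before 45 with onset <40
    rrso_excess_noncancer_multiplier: float
    effects: Effects
    second_event_stage_distribution: dict[str, float]
    #: first-primary stage distribution as printed (sums to 0.994; renormalised at use)
    primary_stage_distribution: dict[str, float]
    tn_prevalence: dict[str, float]
    rrso_timing_window_years: float
    oc_stage_distribution: dict[str, float]
    #: cumulative ovarian-cancer mortality after diagnosis, by stage
    oc_mortality: dict[str, RiskSchedule]
    #: provenance tag per entry, keyed by flattened dotted path
    provenance: dict[str, str] = field(repr=False)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ParameterSet":
        """Check all range, ordering, and completeness invariants; return self."""
        _check_nested_keys(self.contralateral_risk, GENES, "contralateral_risk")
        for gene in GENES:
            _check_keys(
                self.contralateral_risk[gene], AGE_GROUPS, f"contralateral_risk.{gene}"
            )
        _check_keys(self.ipsilateral_risk, ("bct", "mastectomy"), "ipsilateral_risk")
        _check_nested_keys(self.ovarian_lifetime_risk, GENES, "ovarian_lifetime_risk")
        for gene in GENES:
            _check_keys(
                self.ovarian_lifetime_risk[gene],
                EXON_GROUPS,
                f"ovarian_lifetime_risk.{gene}",
            )
            for exon, p in self.ovarian_lifetime_risk[gene].items():
                _check_prob(p, f"ovarian_lifetime_risk.{gene}.{exon}", strict_upper=True)
        if self.ovarian_lifetime_horizon <= 0:
            raise ValidationError("ovarian_lifetime_horizon must be positive")
        _check_keys(self.bc_mortality, ("I", "II", "III"), "bc_mortality")
        for stage in ("I", "II", "III"):
            _check_keys(self.bc_mortality[stage], SUBTYPES, f"bc_mortality.{stage}")
        _check_prob(self.dcis_mortality, "dcis_mortality")
        _check_prob(self.metastatic_mortality, "metastatic_mortality")
        for age, q in self.other_cause_mortality.items():
            _check_prob(q, f"other_cause_mortality.{age}")
        if self.rrso_excess_noncancer_multiplier < 1.0:
            raise ValidationError("rrso_excess_noncancer_multiplier must be >= 1")
        eff = self.effects
        for gene in GENES:
            _check_prob(eff.rrbso_ovarian_reduction[gene], "rrbso_ovarian_reduction")
            _check_prob(
                eff.tamoxifen_contralateral_reduction[gene],
                "tamoxifen_contralateral_reduction",
            )
            _check_prob(self.tn_prevalence[gene], f"tn_prevalence.{gene}")
        for name in (
            "rrbso_ipsilateral_reduction",
            "chemo_ipsilateral_reduction",
            "mastectomy_contralateral_reduction",
            "tamoxifen_15y_mortality_reduction",
            "chemo_bc_mortality_reduction",
        ):
            _check_prob(getattr(eff, name), f"effects.{name}")
        if eff.tamoxifen_mortality_window_years <= 0:
            raise ValidationError("tamoxifen_mortality_window_years must be positive")
        _check_distribution(
            self.second_event_stage_distribution,
            SECOND_EVENT_STAGES,
            "second_event_stage_distribution",
        )
        _check_distribution(
            self.oc_stage_distribution, OC_STAGES, "oc_stage_distribution"
        )
        # the printed first-primary distribution sums to 0.994; accept near-1
        _check_keys(
            self.primary_stage_distribution, ("I", "II", "III"),
            "primary_stage_distribution",
        )
        total = sum(self.primary_stage_distribution.values())
        if not 0.9 <= total <= 1.0 + 1e-9:
            raise ValidationError(
                f"primary_stage_distribution sums to {total}, expected ~1"
            )
        if self.rrso_timing_window_years <= 0:
            raise ValidationError("rrso_timing_window_years must be positive")
        _check_keys(self.oc_mortality, OC_STAGES, "oc_mortality")
        # provenance coverage: every leaf entry must carry a known tag
        expected = set(_flatten(self.to_dict(include_provenance=False)))
        tagged = set(self.provenance)
        missing = expected - tagged
        if missing:
            raise ValidationError(f"entries missing provenance tags: {sorted(missing)}")
        extra = tagged - expected
        if extra:
            raise ValidationError(f"provenance tags for unknown entries: {sorted(extra)}")
        bad = {k: v for k, v in self.provenance.items() if v not in _PROVENANCE_TAGS}
        if bad:
            raise ValidationError(f"unknown provenance tags: {bad}")
        return self

    # -- serialisation ------------------------------------------------------

    def to_dict(self, include_provenance: bool = True) -> dict:
        d = {
            "contralateral_risk": {
                g: {a: s.to_pairs() for a, s in by_age.items()}
                for g, by_age in self.contralateral_risk.items()
            },
            "ipsilateral_risk": {
                k: s.to_pairs() for k, s in self.ipsilateral_risk.items()
            },
            "ovarian_lifetime_risk": {
                g: dict(v) for g, v in self.ovarian_lifetime_risk.items()
            },
            "ovarian_lifetime_horizon": self.ovarian_lifetime_horizon,
            "bc_mortality": {
                st: {sub: s.to_pairs() for sub, s in by_sub.items()}
                for st, by_sub in self.bc_mortality.items()
            },
            "dcis_mortality": self.dcis_mortality,
            "metastatic_mortality": self.metastatic_mortality,
            "other_cause_mortality": dict(self.other_cause_mortality),
            "rrso_excess_noncancer_multiplier": self.rrso_excess_noncancer_multiplier,
            "effects": {
                "rrbso_ovarian_reduction": dict(self.effects.rrbso_ovarian_reduction),
                "rrbso_ipsilateral_reduction": self.effects.rrbso_ipsilateral_reduction,
                "chemo_ipsilateral_reduction": self.effects.chemo_ipsilateral_reduction,
                "mastectomy_contralateral_reduction": (
                    self.effects.mastectomy_contralateral_reduction
                ),
                "tamoxifen_contralateral_reduction": dict(
                    self.effects.tamoxifen_contralateral_reduction
                ),
                "tamoxifen_15y_mortality_reduction": (
                    self.effects.tamoxifen_15y_mortality_reduction
                ),
                "tamoxifen_mortality_window_years": (
                    self.effects.tamoxifen_mortality_window_years
                ),
                "chemo_bc_mortality_reduction": (
                    self.effects.chemo_bc_mortality_reduction
                ),
            },
            "second_event_stage_distribution": dict(
                self.second_event_stage_distribution
            ),
            "primary_stage_distribution": dict(self.primary_stage_distribution),
            "tn_prevalence": dict(self.tn_prevalence),
            "rrso_timing_window_years": self.rrso_timing_window_years,
            "oc_stage_distribution": dict(self.oc_stage_distribution),
            "oc_mortality": {k: s.to_pairs() for k, s in self.oc_mortality.items()},
        }
        if include_provenance:
            d["provenance"] = dict(self.provenance)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {
            "contralateral_risk",
            "ipsilateral_risk",
            "ovarian_lifetime_risk",
            "ovarian_lifetime_horizon",
            "bc_mortality",
            "dcis_mortality",
            "metastatic_mortality",
            "other_cause_mortality",
            "rrso_excess_noncancer_multiplier",
            "effects",
            "second_event_stage_distribution",
            "primary_stage_distribution",
            "tn_prevalence",
            "rrso_timing_window_years",
            "oc_stage_distribution",
            "oc_mortality",
            "provenance",
        }
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(d)
        if missing:
            raise SchemaError(f"missing required parameter keys: {sorted(missing)}")
        eff = d["effects"]
        eff_fields = {f.name for f in fields(Effects)}
        if set(eff) != eff_fields:
            bad = set(eff) ^ eff_fields
            raise SchemaError(f"effects keys mismatch: {sorted(bad)}")
        try:
            ps = cls(
                contralateral_risk={
                    g: {a: RiskSchedule.from_pairs(s) for a, s in by_age.items()}
                    for g, by_age in d["contralateral_risk"].items()
                },
                ipsilateral_risk={
                    k: RiskSchedule.from_pairs(s)
                    for k, s in d["ipsilateral_risk"].items()
                },
                ovarian_lifetime_risk={
                    g: {e: float(p) for e, p in v.items()}
                    for g, v in d["ovarian_lifetime_risk"].items()
                },
                ovarian_lifetime_horizon=float(d["ovarian_lifetime_horizon"]),
                bc_mortality={
                    st: {sub: RiskSchedule.from_pairs(s) for sub, s in by_sub.items()}
                    for st, by_sub in d["bc_mortality"].items()
                },
                dcis_mortality=float(d["dcis_mortality"]),
                metastatic_mortality=float(d["metastatic_mortality"]),
                other_cause_mortality={
                    int(a): float(q) for a, q in d["other_cause_mortality"].items()
                },
                rrso_excess_noncancer_multiplier=float(
                    d["rrso_excess_noncancer_multiplier"]
                ),
                effects=Effects(
                    rrbso_ovarian_reduction={
                        g: float(v) for g, v in eff["rrbso_ovarian_reduction"].items()
                    },
                    rrbso_ipsilateral_reduction=float(
                        eff["rrbso_ipsilateral_reduction"]
                    ),
                    chemo_ipsilateral_reduction=float(
                        eff["chemo_ipsilateral_reduction"]
                    ),
                    mastectomy_contralateral_reduction=float(
                        eff["mastectomy_contralateral_reduction"]
                    ),
                    tamoxifen_contralateral_reduction={
                        g: float(v)
                        for g, v in eff["tamoxifen_contralateral_reduction"].items()
                    },
                    tamoxifen_15y_mortality_reduction=float(
                        eff["tamoxifen_15y_mortality_reduction"]
                    ),
                    tamoxifen_mortality_window_years=float(
                        eff["tamoxifen_mortality_window_years"]
                    ),
                    chemo_bc_mortality_reduction=float(
                        eff["chemo_bc_mortality_reduction"]
                    ),
                ),
                second_event_stage_distribution={
                    k: float(v)
                    for k, v in d["second_event_stage_distribution"].items()
                },
                primary_stage_distribution={
                    k: float(v) for k, v in d["primary_stage_distribution"].items()
                },
                tn_prevalence={g: float(v) for g, v in d["tn_prevalence"].items()},
                rrso_timing_window_years=float(d["rrso_timing_window_years"]),
                oc_stage_distribution={
                    k: float(v) for k, v in d["oc_stage_distribution"].items()
                },
                oc_mortality={
                    k: RiskSchedule.from_pairs(s) for k, s in d["oc_mortality"].items()
                },
                provenance={str(k): str(v) for k, v in d["provenance"].items()},
            )
        except ValueError as exc:
            raise ValidationError(str(exc)) from exc
        return ps.validate()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def save_parameters(params: ParameterSet, path) -> None:
    params.save(path)


def load_parameters(path) -> ParameterSet:
    """Load and validate a parameter file (YAML, documented schema)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise SchemaError("parameter file must contain a mapping at top level")
    return ParameterSet.from_dict(d)


# -- helpers ----------------------------------------------------------------


def _check_prob(p, name: str, strict_upper: bool = False) -> None:
    hi_ok = p < 1.0 if strict_upper else p <= 1.0
    if not (isinstance(p, (int, float)) and 0.0 <= p and hi_ok):
        raise ValidationError(f"{name} must be a probability in range, got {p}")


def _check_keys(mapping, expected, name: str) -> None:
    if set(mapping) != set(expected):
        raise SchemaError(f"{name} must have keys {tuple(expected)}, got {sorted(mapping)}")


def _check_nested_keys(mapping, expected, name: str) -> None:
    _check_keys(mapping, expected, name)


def _check_distribution(dist, domain, name: str) -> None:
    _check_keys(dist, domain, name)
    for k, v in dist.items():
        _check_prob(v, f"{name}.{k}")
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{name} must sum to 1 within 1e-9, sums to {total}")


def _flatten(d: dict, prefix: str = "") -> list[str]:
    """Flatten nested dicts into dotted leaf paths; a schedule (list) is a leaf."""
    keys = []
    for k, v in d.items():
        path = f"{prefix}{k}"
        if isinstance(v, dict):
            keys.extend(_flatten(v, path + "."))
        else:
            keys.append(path)
    return keys


# -- the shipped default parameter fixture ----------------------------------


def default_parameters() -> ParameterSet:
    """The complete default evidence model.

    Values printed in the evidence base appear verbatim (tag ``paper_body``);
    entries whose source tables are not printed ship clinically plausible
    placeholders (tag ``placeholder``) — see docs/methods.md for the
    rationale behind each placeholder family.
    """
    # Contralateral cumulative risk by gene and age at onset.  The printed
    # 10-year anchors (27% BRCA1, 19% BRCA2) sit in the 40-50 stratum; younger
    # onset carries higher risk, older onset lower (Graeser-style gradient).
    contralateral = {
        "BRCA1": {
            "<40": RiskSchedule.from_pairs([(10, 0.35), (25, 0.55)]),
            "40-50": RiskSchedule.from_pairs([(10, 0.27), (25, 0.45)]),
            ">50": RiskSchedule.from_pairs([(10, 0.17), (25, 0.30)]),
        },
        "BRCA2": {
            "<40": RiskSchedule.from_pairs([(10, 0.26), (25, 0.42)]),
            "40-50": RiskSchedule.from_pairs([(10, 0.19), (25, 0.33)]),
            ">50": RiskSchedule.from_pairs([(10, 0.12), (25, 0.21)]),
        },
    }
    # Local-failure cumulative incidence after BCT vs after mastectomy.
    ipsilateral = {
        "bct": RiskSchedule.from_pairs([(5, 0.08), (10, 0.16), (15, 0.22), (20, 0.26)]),
        "mastectomy": RiskSchedule.from_pairs(
            [(5, 0.02), (10, 0.035), (15, 0.045), (20, 0.05)]
        ),
    }
    # Lifetime (to age 80) ovarian-cancer risk by gene x exon group.
    ovarian = {
        "BRCA1": {"1-10": 0.39, "11": 0.44, "12-24/25": 0.48},
        "BRCA2": {"1-10": 0.13, "11": 0.15, "12-24/25": 0.22},
    }
    # Breast-cancer-specific cumulative mortality by stage x subtype.
    bc_mort = {
        "I": {
            "luminal": RiskSchedule.from_pairs([(5, 0.03), (10, 0.07), (15, 0.10)]),
            "TN": RiskSchedule.from_pairs([(5, 0.09), (10, 0.13), (15, 0.15)]),
        },
        "II": {
            "luminal": RiskSchedule.from_pairs([(5, 0.08), (10, 0.16), (15, 0.22)]),
            "TN": RiskSchedule.from_pairs([(5, 0.20), (10, 0.27), (15, 0.30)]),
        },
        "III": {
            "luminal": RiskSchedule.from_pairs([(5, 0.25), (10, 0.38), (15, 0.45)]),
            "TN": RiskSchedule.from_pairs([(5, 0.45), (10, 0.55), (15, 0.60)]),
        },
    }
    # Annual other-cause death probability, women, by 5-year attained-age band.
    other = {
        20: 0.0004, 25: 0.0004, 30: 0.0005, 35: 0.0006, 40: 0.0009,
        45: 0.0014, 50: 0.0021, 55: 0.0033, 60: 0.0051, 65: 0.0081,
        70: 0.0130, 75: 0.0210, 80: 0.0360, 85: 0.0630, 90: 0.1100,
        95: 0.1900, 100: 0.3000,
    }
    # Second-event stage distribution: the printed invasive first-primary
    # distribution (52.3/43.1/4.0, renormalised), rescaled to leave room for a
    # DCIS fraction and a small de-novo metastatic fraction.
    printed = {"I": 0.523, "II": 0.431, "III": 0.04}
    printed_total = sum(printed.values())
    dcis_share, met_share = 0.10, 0.005
    invasive_share = 1.0 - dcis_share - met_share
    second_event = {
        "DCIS": dcis_share,
        "I": invasive_share * printed["I"] / printed_total,
        "II": invasive_share * printed["II"] / printed_total,
        "III": invasive_share * printed["III"] / printed_total,
        "metastatic": met_share,
    }
    oc_stage = {"I": 0.23, "II": 0.12, "III": 0.47, "IV": 0.18}
    oc_mort = {
        "I": RiskSchedule.from_pairs([(5, 0.08), (10, 0.15)]),
        "II": RiskSchedule.from_pairs([(5, 0.25), (10, 0.40)]),
        "III": RiskSchedule.from_pairs([(5, 0.55), (10, 0.75)]),
        "IV": RiskSchedule.from_pairs([(5, 0.80), (10, 0.90)]),
    }
    effects = Effects(
        rrbso_ovarian_reduction={"BRCA1": 0.80, "BRCA2": 0.79},
        rrbso_ipsilateral_reduction=0.58,
        chemo_ipsilateral_reduction=0.49,
        mastectomy_contralateral_reduction=0.90,
        tamoxifen_contralateral_reduction={"BRCA1": 0.56, "BRCA2": 0.67},
        tamoxifen_15y_mortality_reduction=0.30,
        tamoxifen_mortality_window_years=15.0,
        chemo_bc_mortality_reduction=0.30,
    )

    provenance: dict[str, str] = {}

    def tag(key: str, value: str) -> None:
        provenance[key] = value

    for gene in GENES:
        for age in AGE_GROUPS:
            tag(
                f"contralateral_risk.{gene}.{age}",
                PAPER_BODY if age == "40-50" else PLACEHOLDER,
            )
        for exon in EXON_GROUPS:
            tag(f"ovarian_lifetime_risk.{gene}.{exon}", PLACEHOLDER)
        tag(f"tn_prevalence.{gene}", PAPER_BODY)
        tag(f"effects.rrbso_ovarian_reduction.{gene}", PAPER_BODY)
        tag(f"effects.tamoxifen_contralateral_reduction.{gene}", PAPER_BODY)
    for k in ("bct", "mastectomy"):
        tag(f"ipsilateral_risk.{k}", PLACEHOLDER)
    tag("ovarian_lifetime_horizon", PAPER_BODY)
    for stage in ("I", "II", "III"):
        for sub in SUBTYPES:
            tag(f"bc_mortality.{stage}.{sub}", PLACEHOLDER)
        tag(f"primary_stage_distribution.{stage}", PAPER_BODY)
    tag("dcis_mortality", PAPER_BODY)
    tag("metastatic_mortality", PAPER_BODY)
    for age in other:
        tag(f"other_cause_mortality.{age}", PLACEHOLDER)
    tag("rrso_excess_noncancer_multiplier", PLACEHOLDER)
    tag("effects.rrbso_ipsilateral_reduction", PAPER_BODY)
    tag("effects.chemo_ipsilateral_reduction", PAPER_BODY)
    tag("effects.mastectomy_contralateral_reduction", PAPER_BODY)
    tag("effects.tamoxifen_15y_mortality_reduction", PAPER_BODY)
    tag("effects.tamoxifen_mortality_window_years", PAPER_BODY)
    tag("effects.chemo_bc_mortality_reduction", PLACEHOLDER)
    for k in SECOND_EVENT_STAGES:
        tag(f"second_event_stage_distribution.{k}", PLACEHOLDER)
    tag("rrso_timing_window_years", PAPER_BODY)
    for k in OC_STAGES:
        tag(f"oc_stage_distribution.{k}", PLACEHOLDER)
        tag(f"oc_mortality.{k}", PLACEHOLDER)

    ps = ParameterSet(
        contralateral_risk=contralateral,
        ipsilateral_risk=ipsilateral,
        ovarian_lifetime_risk=ovarian,
        ovarian_lifetime_horizon=80.0,
        bc_mortality=bc_mort,
        dcis_mortality=0.033,
        metastatic_mortality=1.0,
        other_cause_mortality=other,
        rrso_excess_noncancer_multiplier=1.5,
        effects=effects,
        second_event_stage_distribution=second_event,
        primary_stage_distribution=printed,
        tn_prevalence={"BRCA1": 0.69, "BRCA2": 0.15},
        rrso_timing_window_years=5.0,
        oc_stage_distribution=oc_stage,
        oc_mortality=oc_mort,
        provenance=provenance,
    )
    return ps.validate()


def parameter_table(params: ParameterSet):
    """Flattened parameter table (entry, value, provenance) as a DataFrame."""
    import pandas as pd

    d = params.to_dict(include_provenance=False)

    rows = []

    def walk(node, prefix=""):
        for k, v in node.items():
            path = f"{prefix}{k}"
            if isinstance(v, dict):
                walk(v, path + ".")
            else:
                rows.append(
                    {
                        "entry": path,
                        "value": repr(v) if isinstance(v, list) else v,
                        "provenance": params.provenance[path],
                    }
                )

    walk(d)
    return pd.DataFrame(rows).sort_values("entry").reset_index(drop=True)


_ZERO_CHANNELS = ("ipsilateral", "contralateral", "ovarian", "bc_mortality", "other")


def without_hazards(params: ParameterSet, *channels: str) -> ParameterSet:
    """A copy of *params* with the named hazard channels switched off.

    Channels: ``ipsilateral``, ``contralateral``, ``ovarian``, ``bc_mortality``,
    ``other``.  Used to isolate a single pathway in recovery experiments.
    """
    unknown = set(channels) - set(_ZERO_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}; known {_ZERO_CHANNELS}")
    zero40 = RiskSchedule.from_pairs([(40.0, 0.0)])
    out = params
    if "ipsilateral" in channels:
        out = replace(out, ipsilateral_risk={"bct": zero40, "mastectomy": zero40})
    if "contralateral" in channels:
        out = replace(
            out,
            contralateral_risk={
                g: {a: zero40 for a in AGE_GROUPS} for g in GENES
            },
        )
    if "ovarian" in channels:
        out = replace(
            out,
            ovarian_lifetime_risk={g: {e: 0.0 for e in EXON_GROUPS} for g in GENES},
        )
    if "bc_mortality" in channels:
        out = replace(
            out,
            bc_mortality={
                st: {sub: zero40 for sub in SUBTYPES} for st in ("I", "II", "III")
            },
            dcis_mortality=0.0,
            metastatic_mortality=0.0,
        )
    if "other" in channels:
        out = replace(
            out,
            other_cause_mortality={a: 0.0 for a in params.other_cause_mortality},
        )
    return out.validate()
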