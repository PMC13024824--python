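"""Six-pattern histological classifier for ichthyosis biopsies.

The six patterns and the default rule set, evaluated in fixed precedence
order (structural morphologies are pathognomonic and trump psoriasiform
features, which in turn trump the stratum-granulosum state):

IV. *Epidermolytic hyperkeratosis* — the EHK flag (granular degeneration) is
    sufficient on its own.
V.  *Perinuclear vacuoles and binucleated keratinocytes* — both flags.
VI. *Psoriasis-like* — at least moderate inflammation AND at least moderate
    acanthosis AND any parakeratosis (including focal or staggered).
    Optionally the gate can additionally require a psoriasiform architecture
    marker (suprapapillary thinning, kissing vessels, subcorneal clefting,
    acantholysis or neutrophils in the stratum corneum).
III. *Mixed ortho-/parakeratosis with preserved stratum granulosum* —
    staggered OK/PK cornification with SG collapsing to at least normal.
I.  *Orthohyperkeratosis with reduced or absent SG* — orthokeratotic
    cornification (focal parakeratosis allowed) with SG at most reduced.
II. *Orthohyperkeratosis with well-developed SG* — orthokeratotic
    cornification with SG at least normal.

A biopsy may satisfy several patterns; the first fired rule in precedence
order is the primary assignment and every fired rule enters the satisfied
set.  Every rule evaluation is recorded in an auditable trace.

Grade spans are read through a configurable collapse policy (default
optimistic: a span like ``−/+`` counts as a developed SG, which minimizes
disagreement with the reference cohort's recorded labels).  Patients whose
recorded label is known to disagree with the diagnosis-blind default rules
are shipped in a registered exception list with their rationale, rather than
special-cased by diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .cohort import (
    BiopsyFindings,
    Cohort,
    PatientRecord,
    PatternLabel,
)
from .grading import CollapsePolicy, collapse
from .grammar import Grade, NotAssessable

__all__ = [
    "RuleConfig",
    "RuleTraceEntry",
    "PatternAssignment",
    "UnclassifiableError",
    "ConcordanceReport",
    "DEFAULT_EXCEPTION_REGISTRY",
    "PATTERN_PRECEDENCE",
    "classify_biopsy",
    "classify_patient",
    "concordance",
]

# Highest precedence first.
PATTERN_PRECEDENCE: tuple[PatternLabel, ...] = (
    PatternLabel.IV,
    PatternLabel.V,
    PatternLabel.VI,
    PatternLabel.III,
    PatternLabel.I,
    PatternLabel.II,
)

VI_ARCHITECTURE_MARKERS = frozenset({
    "suprapapillary_thinning",
    "kissing_vessels",
    "subcorneal_clefting",
    "acantholysis",
    "neutrophils_in_SC",
})

# Reference-cohort patients whose recorded pattern is known to disagree with
# the diagnosis-blind default rules; kept as documented exceptions.
DEFAULT_EXCEPTION_REGISTRY: Mapping[int, str] = MappingProxyType({
    5: "recorded I despite SG span −/+ which collapses optimistically to "
       "normal (rule II fires); the recording follows the diagnosis group",
    23: "recorded II although biopsy 1 shows moderate inflammation, moderate "
        "regular acanthosis and staggered OK/PK (rule VI fires first)",
    36: "harlequin ichthyosis recorded II by SG state although the biopsy "
        "meets the psoriasis-like gate (moderate inflammation, "
        "moderate-to-severe acanthosis, focal parakeratosis)",
    37: "harlequin ichthyosis recorded I by absent SG although the biopsy "
        "meets the psoriasis-like gate",
    55: "recorded I despite normal SG (+); the recording follows the "
        "diagnosis group (IFAP)",
})


class UnclassifiableError(ValueError):
    """No pattern rule could fire; the message names the missing evidence."""


@dataclass(frozen=True)
class RuleConfig:
    """Tunable knobs of the rule engine."""

    sg_policy: CollapsePolicy = CollapsePolicy.OPTIMISTIC_MAX
    vi_requires_architecture_marker: bool = False
    exception_registry: Mapping[int, str] = field(
        default_factory=lambda: DEFAULT_EXCEPTION_REGISTRY
    )

    def __post_init__(self) -> None:
        for pid, rationale in self.exception_registry.items():
            if not str(rationale).strip():
                raise ValueError(f"exception registry entry {pid} lacks a rationale")

    def as_dict(self) -> dict:
        return {
            "sg_policy": self.sg_policy.value,
            "vi_requires_architecture_marker": self.vi_requires_architecture_marker,
            "exception_registry": {str(k): v for k, v in sorted(self.exception_registry.items())},
        }


@dataclass(frozen=True)
class RuleTraceEntry:
    rule: PatternLabel
    fired: bool
    evidence: str


@dataclass(frozen=True)
class PatternAssignment:
    primary: PatternLabel
    satisfied: frozenset[PatternLabel]
    trace: tuple[RuleTraceEntry, ...]
    is_registered_exception: bool = False

    def __post_init__(self) -> None:
        if self.primary not in self.satisfied:
            raise ValueError("primary pattern must be in the satisfied set")


def _fmt(value) -> str:
    if isinstance(value, NotAssessable):
        return "n.a."
    if isinstance(value, Grade):
        return value.token
    return str(value)


def _evaluate_rules(b: BiopsyFindings, config: RuleConfig) -> list[RuleTraceEntry]:
    """Evaluate all six rules on one biopsy, in precedence order."""
    sc_na = isinstance(b.sc, NotAssessable)
    sg_na = isinstance(b.sg, NotAssessable)
    kerat = None if sc_na else b.sc.keratinization
    sg_grade = None if sg_na else collapse(b.sg, config.sg_policy)
    infl = collapse(b.inflammation, CollapsePolicy.OPTIMISTIC_MAX)
    acan = collapse(b.acanthosis, CollapsePolicy.OPTIMISTIC_MAX)

    entries: list[RuleTraceEntry] = []

    # IV — epidermolytic hyperkeratosis
    fired = "EHK" in b.flags
    entries.append(RuleTraceEntry(
        PatternLabel.IV, fired,
        "EHK flag set" if fired else "no EHK flag",
    ))

    # V — perinuclear vacuoles + binucleated keratinocytes
    fired = {"perinuclear_vacuoles", "binucleated_keratinocytes"} <= b.flags
    entries.append(RuleTraceEntry(
        PatternLabel.V, fired,
        "perinuclear vacuoles and binucleated keratinocytes"
        if fired else "vacuole/binucleation flags not both set",
    ))

    # VI — psoriasis-like
    para = kerat is not None and kerat.has_parakeratosis
    gate = infl >= Grade.HIGH and acan >= Grade.HIGH and para
    marker_needed = config.vi_requires_architecture_marker
    markers = b.flags & VI_ARCHITECTURE_MARKERS
    fired = gate and (not marker_needed or bool(markers))
    ev = (
        f"inflammation {_fmt(infl)}, acanthosis {_fmt(acan)}, "
        f"parakeratosis={'yes' if para else 'no'}"
    )
    if marker_needed:
        ev += f", architecture markers {sorted(markers) if markers else 'none'}"
    entries.append(RuleTraceEntry(PatternLabel.VI, fired, ev))

    # III — staggered ortho/para with preserved SG
    from .grammar import Keratinization  # local import to avoid cycles at module load

    fired = (
        kerat is Keratinization.ORTHO_PARA_STAGGERED
        and sg_grade is not None
        and sg_grade >= Grade.MID
    )
    entries.append(RuleTraceEntry(
        PatternLabel.III, fired,
        f"keratinization {kerat.value if kerat else 'n.a.'}, "
        f"SG({config.sg_policy.value}) {_fmt(sg_grade) if sg_grade is not None else 'n.a.'}",
    ))

    # I — orthokeratosis with reduced/absent SG
    ortho = kerat is not None and kerat.is_orthokeratotic
    fired = ortho and sg_grade is not None and sg_grade <= Grade.LOW
    entries.append(RuleTraceEntry(
        PatternLabel.I, fired,
        f"orthokeratosis={'yes' if ortho else 'no'}, "
        f"SG({config.sg_policy.value}) {_fmt(sg_grade) if sg_grade is not None else 'n.a.'}",
    ))

    # II — orthokeratosis with developed SG
    fired = ortho and sg_grade is not None and sg_grade >= Grade.MID
    entries.append(RuleTraceEntry(
        PatternLabel.II, fired,
        f"orthokeratosis={'yes' if ortho else 'no'}, "
        f"SG({config.sg_policy.value}) {_fmt(sg_grade) if sg_grade is not None else 'n.a.'}",
    ))

    return entries


def classify_biopsy(
    findings: BiopsyFindings, config: RuleConfig | None = None
) -> PatternAssignment:
    """Assign a pattern to a single biopsy.

    Raises :class:`UnclassifiableError` when no rule fires, naming the
    missing evidence (e.g. SG not assessable without structural flags).
    """
    config = config or RuleConfig()
    trace = tuple(_evaluate_rules(findings, config))
    satisfied = frozenset(e.rule for e in trace if e.fired)
    if not satisfied:
        missing = []
        if isinstance(findings.sg, NotAssessable):
            missing.append("stratum granulosum not assessable")
        if isinstance(findings.sc, NotAssessable):
            missing.append("stratum corneum not assessable")
        if not findings.flags & {"EHK", "perinuclear_vacuoles"}:
            missing.append("no structural morphology flags")
        raise UnclassifiableError(
            "no pattern rule fired: " + "; ".join(missing or ["criteria not met"])
        )
    primary = next(p for p in PATTERN_PRECEDENCE if p in satisfied)
    return PatternAssignment(primary=primary, satisfied=satisfied, trace=trace)


def classify_patient(
    record: PatientRecord, config: RuleConfig | None = None
) -> PatternAssignment:
    """Assign one pattern to a patient from all their biopsies.

    Each biopsy is classified independently; the patient's primary pattern is
    the highest-precedence biopsy pattern.  Biopsies on which no rule fires
    are tolerated (their failure is recorded in the trace) as long as at
    least one biopsy is classifiable.
    """
    config = config or RuleConfig()
    satisfied: set[PatternLabel] = set()
    trace: list[RuleTraceEntry] = []
    errors: list[str] = []
    for i, b in enumerate(record.biopsies, start=1):
        try:
            a = classify_biopsy(b, config)
        except UnclassifiableError as exc:
            errors.append(f"biopsy {i}: {exc}")
            continue
        satisfied |= a.satisfied
        for e in a.trace:
            trace.append(RuleTraceEntry(e.rule, e.fired, f"biopsy {i}: {e.evidence}"))
    if not satisfied:
        raise UnclassifiableError(
            f"patient {record.id}: all biopsies unclassifiable ({'; '.join(errors)})"
        )
    primary = next(p for p in PATTERN_PRECEDENCE if p in satisfied)
    return PatternAssignment(
        primary=primary,
        satisfied=frozenset(satisfied),
        trace=tuple(trace),
        is_registered_exception=record.id in config.exception_registry,
    )


@dataclass(frozen=True)
class Disagreement:
    patient_id: int
    predicted: PatternLabel
    recorded: PatternLabel
    registered: bool
    rationale: str
    trace: tuple[RuleTraceEntry, ...]


@dataclass(frozen=True)
class ConcordanceReport:
    n_patients: int
    n_matching: int
    disagreements: tuple[Disagreement, ...]
    assignments: Mapping[int, PatternAssignment]

    @property
    def fraction(self) -> float:
        return self.n_matching / self.n_patients

    @property
    def unregistered_disagreements(self) -> tuple[Disagreement, ...]:
        return tuple(d for d in self.disagreements if not d.registered)

    def as_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_matching": self.n_matching,
            "concordance": self.fraction,
            "disagreements": [
                {
                    "patient_id": d.patient_id,
                    "predicted": d.predicted.value,
                    "recorded": d.recorded.value,
                    "registered_exception": d.registered,
                    "rationale": d.rationale,
                }
                for d in self.disagreements
            ],
        }


def concordance(cohort: Cohort, config: RuleConfig | None = None) -> ConcordanceReport:
    """Compare engine assignments against the recorded pattern labels."""
    if not cohort.patients:
        raise ValueError("cannot compute concordance on an empty cohort")
    config = config or RuleConfig()
    assignments: dict[int, PatternAssignment] = {}
    disagreements: list[Disagreement] = []
    n_match = 0
    for p in cohort.patients:
        a = classify_patient(p, config)
        assignments[p.id] = a
        if a.primary == p.recorded_pattern:
            n_match += 1
        else:
            disagreements.append(Disagreement(
                patient_id=p.id,
                predicted=a.primary,
                recorded=p.recorded_pattern,
                registered=p.id in config.exception_registry,
                rationale=config.exception_registry.get(p.id, ""),
                trace=a.trace,
            ))
    return ConcordanceReport(
        n_patients=len(cohort.patients),
        n_matching=n_match,
        disagreements=tuple(disagreements),
        assignments=MappingProxyType(assignments),
    )
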