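"""Differential-diagnosis knowledge base and deterministic ranking.

The knowledge base maps each of the six histological patterns to its
candidate diagnoses together with the discriminating clinical cues (a
controlled vocabulary of feature tags).  A second list collects the
differential diagnoses of follicular hyperkeratosis, split into ichthyoses
and other hereditary cornification disorders.  Both ship as versioned CSVs
under :mod:`ichthyoscore.data` so the content is auditable and editable
without touching code.

Ranking is deliberately primitive: candidates restricted to the queried
pattern are ordered by the *count* of matched cue tags (exact intersection,
no fuzzy matching), ties broken by knowledge-base row order.  An empty
clinical feature set therefore returns every candidate for the pattern tied
at score 0 — the honest answer when only histology is available.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

from .cohort import (
    CLINICAL_VOCABULARY,
    DiagnosisGroup,
    PatientRecord,
    PatternLabel,
    Presence,
)

__all__ = [
    "DiagnosisCandidate",
    "DdxEntry",
    "DdxResult",
    "UnknownFeatureError",
    "load_knowledge_base",
    "differential",
    "fhk_differential",
    "end_to_end_ddx",
    "GROUP_TO_KB_NAMES",
]


class UnknownFeatureError(ValueError):
    """A query used a clinical feature tag outside the controlled vocabulary."""

    def __init__(self, unknown: Iterable[str]):
        self.unknown = sorted(unknown)
        super().__init__(
            f"unknown clinical feature tags {self.unknown}; "
            f"vocabulary: {sorted(CLINICAL_VOCABULARY)}"
        )


@dataclass(frozen=True)
class DiagnosisCandidate:
    """One knowledge-base row (a diagnosis under one pattern)."""

    name: str
    new_nomenclature: str
    patterns: frozenset[PatternLabel]
    clinical_cues: frozenset[str]
    source: str = "pattern_kb"  # "pattern_kb" | "fhk_kb"
    row_order: int = 0


@dataclass(frozen=True)
class DdxEntry:
    candidate: DiagnosisCandidate
    match_score: int
    matched_cues: frozenset[str]


@dataclass(frozen=True)
class DdxResult:
    pattern: PatternLabel
    entries: tuple[DdxEntry, ...]
    fhk_note: str = ""

    @property
    def top(self) -> DdxEntry:
        return self.entries[0]

    def names(self) -> list[str]:
        return [e.candidate.name for e in self.entries]

    def as_dict(self) -> dict:
        return {
            "pattern": self.pattern.value,
            "candidates": [
                {
                    "diagnosis": e.candidate.name,
                    "new_nomenclature": e.candidate.new_nomenclature,
                    "match_score": e.match_score,
                    "matched_cues": sorted(e.matched_cues),
                }
                for e in self.entries
            ],
            "fhk_note": self.fhk_note,
        }


@lru_cache(maxsize=1)
def load_knowledge_base() -> tuple[DiagnosisCandidate, ...]:
    """Load the pattern→diagnosis knowledge base CSV (cached)."""
    text = (
        resources.files("ichthyoscore.data")
        .joinpath("pattern_diagnoses.csv")
        .read_text(encoding="utf-8")
    )
    rows: list[DiagnosisCandidate] = []
    for i, rec in enumerate(csv.DictReader(text.splitlines())):
        cues = frozenset(c for c in rec["clinical_cues"].split(";") if c)
        bad = cues - CLINICAL_VOCABULARY
        if bad:
            raise ValueError(f"knowledge base row {i}: cues {sorted(bad)} not in vocabulary")
        rows.append(DiagnosisCandidate(
            name=rec["diagnosis"],
            new_nomenclature=rec["new_nomenclature"],
            patterns=frozenset({PatternLabel(rec["pattern"])}),
            clinical_cues=cues,
            source="pattern_kb",
            row_order=i,
        ))
    return tuple(rows)


@lru_cache(maxsize=1)
def _load_fhk() -> tuple[tuple[str, str], ...]:
    text = (
        resources.files("ichthyoscore.data")
        .joinpath("fhk_differentials.csv")
        .read_text(encoding="utf-8")
    )
    return tuple(
        (rec["scope"], rec["diagnosis"]) for rec in csv.DictReader(text.splitlines())
    )


def differential(
    pattern: PatternLabel,
    clinical: Iterable[str] = (),
    kb: Sequence[DiagnosisCandidate] | None = None,
) -> DdxResult:
    """Rank the pattern's candidate diagnoses by matched clinical cues."""
    clinical = frozenset(clinical)
    unknown = clinical - CLINICAL_VOCABULARY
    if unknown:
        raise UnknownFeatureError(unknown)
    kb = load_knowledge_base() if kb is None else kb
    scored: list[DdxEntry] = []
    for cand in kb:
        if pattern not in cand.patterns:
            continue
        matched = clinical & cand.clinical_cues
        scored.append(DdxEntry(cand, match_score=len(matched), matched_cues=matched))
    scored.sort(key=lambda e: (-e.match_score, e.candidate.row_order))
    return DdxResult(pattern=pattern, entries=tuple(scored))


def fhk_differential(scope: str = "all") -> list[str]:
    """Differential diagnoses of follicular hyperkeratosis.

    ``scope`` is ``"ichthyoses"``, ``"other_cornification_disorders"`` or
    ``"all"`` (concatenation without duplicates).
    """
    valid = {"ichthyoses", "other_cornification_disorders", "all"}
    if scope not in valid:
        raise ValueError(f"scope must be one of {sorted(valid)}, got {scope!r}")
    out: list[str] = []
    for row_scope, name in _load_fhk():
        if scope in (row_scope, "all") and name not in out:
            out.append(name)
    return out


def end_to_end_ddx(record: PatientRecord, config=None) -> DdxResult:
    """Classify a patient and rank their differential from the assignment.

    The cue set is the record's clinical features plus ``male_sex`` derived
    from the demographic sex.  Records with follicular hyperkeratosis in any
    biopsy get the FHK differential appended as a note.
    """
    from .patterns import classify_patient  # deferred: patterns imports cohort too

    assignment = classify_patient(record, config)
    cues = set(record.clinical_features)
    if record.sex == "m":
        cues.add("male_sex")
    result = differential(assignment.primary, cues)
    if any(b.fhk is Presence.PRESENT for b in record.biopsies):
        note = (
            "follicular hyperkeratosis present; consider also: "
            + "; ".join(fhk_differential("all"))
        )
        result = DdxResult(pattern=result.pattern, entries=result.entries, fhk_note=note)
    return result


# Map from cohort diagnosis groups to their knowledge-base diagnosis names,
# used to check that the knowledge base can recover every cohort diagnosis
# from its recorded pattern.
GROUP_TO_KB_NAMES: dict[DiagnosisGroup, tuple[str, ...]] = {
    DiagnosisGroup.IV: ("Ichthyosis vulgaris",),
    DiagnosisGroup.XLI: ("X-linked ichthyosis",),
    DiagnosisGroup.ARCI: (
        "Autosomal recessive congenital ichthyosis (erythrodermic)",
        "Autosomal recessive congenital ichthyosis (non-erythrodermic)",
        "Bathing suit ichthyosis",
    ),
    DiagnosisGroup.HARLEQUIN: ("Harlequin ichthyosis",),
    DiagnosisGroup.ADLI: ("Autosomal dominant lamellar ichthyosis",),
    DiagnosisGroup.EI: (
        "Epidermolytic ichthyosis with KRT1 mutation",
        "Epidermolytic ichthyosis with KRT10 mutation",
        "Superficial epidermolytic ichthyosis",
        "Annular epidermolytic ichthyosis",
    ),
    DiagnosisGroup.NTS: ("Netherton syndrome",),
    DiagnosisGroup.PSD: ("Peeling skin disease",),
    DiagnosisGroup.CHILD: (
        "Congenital hemidysplasia with ichthyosiform nevus and limb defects (CHILD) syndrome",
    ),
    DiagnosisGroup.IFAP: (
        "Ichthyosis follicularis with alopecia and photophobia (IFAP) syndrome",
    ),
    DiagnosisGroup.SAM: (
        "Severe dermatitis multiple allergies metabolic wasting (SAM) syndrome",
    ),
    DiagnosisGroup.MALT1: ("MALT1 deficiency",),
    DiagnosisGroup.KID: ("Keratitis ichthyosis deafness (KID) syndrome",),
    DiagnosisGroup.SLS: ("Sjoegren-Larsson syndrome",),
    DiagnosisGroup.CHANARIN_DORFMAN: ("Chanarin-Dorfman syndrome",),
    DiagnosisGroup.CONRADI: ("Conradi-Huenermann-Happle syndrome",),
    DiagnosisGroup.KIDAR: (
        "Autosomal recessive keratitis-ichthyosis-deafness (KIDAR) syndrome",
    ),
}
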