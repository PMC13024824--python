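"""Patient and biopsy records, cohort IO, and the packaged reference cohort.

The package ships a machine-readable transcription of a published reference
cohort of 66 molecularly characterized ichthyosis patients (87 biopsies),
covering common ichthyoses (ichthyosis vulgaris, X-linked ichthyosis),
autosomal recessive congenital ichthyosis including harlequin ichthyosis,
keratinopathic ichthyosis, Netherton syndrome, peeling skin disease and a set
of rare syndromic subtypes.  Each biopsy carries the semi-quantitative scores
parsed by :mod:`ichthyoscore.grammar` plus boolean morphology flags distilled
from the free-text findings (the original prose is retained in ``notes`` for
audit).

Two interchange formats are supported and round-trip losslessly:

* JSON — one object per patient with a nested biopsy array (the fixture's
  native format; a JSON Schema document ships alongside it);
* CSV — UTF-8, one row per biopsy with the patient columns repeated.

Both carry a schema version tag and are written canonically: writing a loaded
cohort back out reproduces the file byte for byte.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Union

from .grammar import (
    NOT_ASSESSABLE,
    CorneumDescriptor,
    GradeSpan,
    NotAssessable,
    ScoreParseError,
    canonical_serialize,
    parse_corneum,
    parse_grade_span,
    serialize_corneum,
)

__all__ = [
    "DiagnosisGroup",
    "PatternLabel",
    "Presence",
    "Regularity",
    "BiopsyFindings",
    "PatientRecord",
    "Cohort",
    "CohortFormatError",
    "ValidationCheck",
    "ValidationReport",
    "BIOPSY_FLAGS",
    "CLINICAL_VOCABULARY",
    "SCHEMA_VERSION",
    "load_cohort",
    "write_cohort",
    "load_fixture",
    "validate_fixture",
]

SCHEMA_VERSION = "ichthyoscore-cohort-1"


class CohortFormatError(ValueError):
    """A cohort file violated the schema (bad tag, duplicate id, bad cell...)."""


class DiagnosisGroup(Enum):
    """Molecular/clinical diagnosis groups represented in the reference cohort."""

    IV = "IV"                  # ichthyosis vulgaris (FLG)
    XLI = "XLI"                # X-linked ichthyosis (STS)
    ARCI = "ARCI"              # autosomal recessive congenital ichthyosis
    HARLEQUIN = "HARLEQUIN"    # harlequin ichthyosis (ABCA12); ARCI umbrella
    ADLI = "ADLI"              # autosomal dominant lamellar ichthyosis (ASPRV1)
    EI = "EI"                  # epidermolytic ichthyosis (KRT1/2/10)
    NTS = "NTS"                # Netherton syndrome (SPINK5)
    PSD = "PSD"                # peeling skin disease (CDSN)
    CHILD = "CHILD"
    IFAP = "IFAP"
    SAM = "SAM"
    MALT1 = "MALT1"
    KID = "KID"
    SLS = "SLS"
    CHANARIN_DORFMAN = "CHANARIN_DORFMAN"
    CONRADI = "CONRADI"        # Conradi-Huenermann-Happle syndrome (EBP)
    KIDAR = "KIDAR"            # AR keratitis-ichthyosis-deafness (AP1B1)


# The ARCI umbrella used for group-level counts includes harlequin ichthyosis.
ARCI_UMBRELLA = frozenset({DiagnosisGroup.ARCI, DiagnosisGroup.HARLEQUIN})


class PatternLabel(Enum):
    """The six histological patterns."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"


class Presence(Enum):
    """Tri-state for follicular / acrosyringeal hyperkeratosis."""

    PRESENT = "present"
    ABSENT = "absent"
    NOT_ASSESSABLE = "na"


class Regularity(Enum):
    REGULAR = "regular"
    IRREGULAR = "irregular"
    UNSPECIFIED = "unspecified"


BIOPSY_FLAGS = frozenset({
    "EHK",
    "EHK_continuous",
    "perinuclear_vacuoles",
    "binucleated_keratinocytes",
    "suprapapillary_thinning",
    "suprapapillary_thickening",
    "dilated_vessels",
    "kissing_vessels",
    "neutrophils_in_SC",
    "no_neutrophils_in_SC",
    "subcorneal_clefting",
    "acantholysis",
    "spongiosis",
    "papillomatosis",
    "xanthoma_cells",
    "serum_crust",
    "dyskeratosis",
    "calcification",
})

# Controlled vocabulary for clinical feature tags.  Union of the cue tags used
# by the diagnosis knowledge base and the tags needed to encode the reference
# cohort's symptom column.
CLINICAL_VOCABULARY = frozenset({
    # scaling / lesion morphology
    "mild_ichthyosis", "moderate_ichthyosis", "severe_ichthyosis",
    "fine_scaling", "lamellar_scaling", "coarse_lamellar_scaling",
    "coarse_dark_scaling", "cobblestone_hyperkeratosis",
    "brownish_hyperkeratosis", "spiny_hyperkeratosis",
    "bathing_suit_distribution", "confetti_sparing", "unilateral_lesions",
    "blistering", "skin_peeling", "erythema", "erythroderma",
    "mild_erythroderma", "scaly_erythema", "lichenification_dorsum",
    "collodion_membrane", "ectropion", "eclabium",
    # palms, soles and adnexa
    "palmoplantar_hyperlinearity", "no_palmoplantar_hyperlinearity",
    "PPK", "no_PPK", "plantar_hyperkeratosis", "keratosis_pilaris",
    "follicular_hyperkeratosis_clinical", "alopecia", "hypotrichosis",
    # atopy, allergy, immunity
    "atopy", "allergies", "food_allergies", "elevated_IgE",
    "hypereosinophilia", "infection_predisposition", "pruritus",
    "severe_pruritus",
    # systemic and contextual
    "failure_to_thrive", "normal_growth", "growth_retardation",
    "deafness", "photophobia", "keratitis", "neurological_symptoms",
    "cardiomyopathy", "skeletal_anomalies", "enteropathy",
    "periodontal_disease", "hypohidrosis", "malignancy", "comorbidities",
    "late_onset", "multiple_nevi",
    # demographic cue used by the knowledge base (derived from sex at query
    # time, but legal as an explicit tag)
    "male_sex", "flexures_spared", "summer_improvement", "cryptorchidism",
    "no_systemic_manifestation",
})


@dataclass(frozen=True)
class BiopsyFindings:
    """The full per-biopsy feature vector.

    ``sc`` may be not-assessable (one reference biopsy lacks a stratum
    corneum); ``sg`` may be not-assessable; the other axes are always graded.
    """

    sc: Union[CorneumDescriptor, NotAssessable]
    sg: Union[GradeSpan, NotAssessable]
    acanthosis: GradeSpan
    inflammation: GradeSpan
    acanthosis_regularity: Regularity = Regularity.UNSPECIFIED
    fhk: Presence = Presence.NOT_ASSESSABLE
    ahk: Presence = Presence.NOT_ASSESSABLE
    flags: frozenset[str] = field(default_factory=frozenset)
    site: str = ""
    age_years: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.flags) - BIOPSY_FLAGS
        if unknown:
            raise ValueError(f"unknown biopsy flags: {sorted(unknown)}")
        if "EHK_continuous" in self.flags and "EHK" not in self.flags:
            raise ValueError("EHK_continuous implies EHK")
        if {"neutrophils_in_SC", "no_neutrophils_in_SC"} <= self.flags:
            raise ValueError("neutrophils_in_SC and no_neutrophils_in_SC are exclusive")


@dataclass(frozen=True)
class PatientRecord:
    id: int
    sex: str  # "f" | "m"
    diagnosis_group: DiagnosisGroup
    biopsies: tuple[BiopsyFindings, ...]
    recorded_pattern: PatternLabel
    gene: str = ""
    flg_allele_count: int | None = None  # 0/1/2, None = unknown
    genetically_confirmed: bool = False
    clinical_features: frozenset[str] = field(default_factory=frozenset)
    diagnosis_verbatim: str = ""
    symptoms_verbatim: str = ""

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError("patient id must be a positive integer")
        if self.sex not in ("f", "m"):
            raise ValueError(f"sex must be 'f' or 'm', got {self.sex!r}")
        if not self.biopsies:
            raise ValueError(f"patient {self.id} has no biopsies")
        if self.flg_allele_count not in (None, 0, 1, 2):
            raise ValueError("flg_allele_count must be 0, 1, 2 or None")
        unknown = set(self.clinical_features) - CLINICAL_VOCABULARY
        if unknown:
            raise ValueError(
                f"patient {self.id}: unknown clinical features {sorted(unknown)}"
            )


@dataclass(frozen=True)
class Cohort:
    patients: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(f"duplicate patient ids: {dupes}")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_biopsies(self) -> int:
        return sum(len(p.biopsies) for p in self.patients)

    def get(self, patient_id: int) -> PatientRecord:
        for p in self.patients:
            if p.id == patient_id:
                return p
        raise KeyError(f"no patient with id {patient_id}")

    def iter_biopsies(self) -> Iterator[tuple[PatientRecord, int, BiopsyFindings]]:
        """Yield (patient, 1-based biopsy index, findings) triples."""
        for p in self.patients:
            for i, b in enumerate(p.biopsies, start=1):
                yield p, i, b

    def subset(self, predicate) -> "Cohort":
        return Cohort(
            patients=tuple(p for p in self.patients if predicate(p)),
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# JSON (de)serialization
# ---------------------------------------------------------------------------

def _biopsy_to_dict(b: BiopsyFindings) -> dict:
    return {
        "sc": serialize_corneum(b.sc),
        "sg": canonical_serialize(b.sg),
        "acanthosis": canonical_serialize(b.acanthosis),
        "acanthosis_regularity": b.acanthosis_regularity.value,
        "inflammation": canonical_serialize(b.inflammation),
        "fhk": b.fhk.value,
        "ahk": b.ahk.value,
        "flags": sorted(b.flags),
        "site": b.site,
        "age_years": b.age_years,
        "notes": b.notes,
    }


def _biopsy_from_dict(d: dict, where: str) -> BiopsyFindings:
    try:
        sc = parse_corneum(d["sc"]) if str(d["sc"]).strip() else NOT_ASSESSABLE
        sg = parse_grade_span(d["sg"])
        acanthosis = parse_grade_span(d["acanthosis"])
        inflammation = parse_grade_span(d["inflammation"])
    except ScoreParseError as exc:
        raise CohortFormatError(f"{where}: {exc}") from exc
    if isinstance(acanthosis, NotAssessable) or isinstance(inflammation, NotAssessable):
        raise CohortFormatError(f"{where}: acanthosis/inflammation must be graded")
    try:
        return BiopsyFindings(
            sc=sc,
            sg=sg,
            acanthosis=acanthosis,
            inflammation=inflammation,
            acanthosis_regularity=Regularity(d.get("acanthosis_regularity", "unspecified")),
            fhk=Presence(d.get("fhk", "na")),
            ahk=Presence(d.get("ahk", "na")),
            flags=frozenset(d.get("flags", [])),
            site=d.get("site", "") or "",
            age_years=d.get("age_years"),
            notes=d.get("notes", "") or "",
        )
    except ValueError as exc:
        raise CohortFormatError(f"{where}: {exc}") from exc


def _patient_to_dict(p: PatientRecord) -> dict:
    return {
        "id": p.id,
        "sex": p.sex,
        "diagnosis_group": p.diagnosis_group.value,
        "gene": p.gene,
        "flg_allele_count": p.flg_allele_count,
        "genetically_confirmed": p.genetically_confirmed,
        "clinical_features": sorted(p.clinical_features),
        "recorded_pattern": p.recorded_pattern.value,
        "diagnosis_verbatim": p.diagnosis_verbatim,
        "symptoms_verbatim": p.symptoms_verbatim,
        "biopsies": [_biopsy_to_dict(b) for b in p.biopsies],
    }


def _patient_from_dict(d: dict) -> PatientRecord:
    pid = d.get("id")
    where = f"patient {pid}"
    try:
        biopsies = tuple(
            _biopsy_from_dict(bd, f"{where} biopsy {i}")
            for i, bd in enumerate(d["biopsies"], start=1)
        )
        return PatientRecord(
            id=int(pid),
            sex=d["sex"],
            diagnosis_group=DiagnosisGroup(d["diagnosis_group"]),
            biopsies=biopsies,
            recorded_pattern=PatternLabel(d["recorded_pattern"]),
            gene=d.get("gene", "") or "",
            flg_allele_count=d.get("flg_allele_count"),
            genetically_confirmed=bool(d.get("genetically_confirmed", False)),
            clinical_features=frozenset(d.get("clinical_features", [])),
            diagnosis_verbatim=d.get("diagnosis_verbatim", "") or "",
            symptoms_verbatim=d.get("symptoms_verbatim", "") or "",
        )
    except (KeyError, ValueError, TypeError) as exc:
        if isinstance(exc, CohortFormatError):
            raise
        raise CohortFormatError(f"{where}: {exc}") from exc


def cohort_to_json(cohort: Cohort) -> str:
    """Canonical JSON serialization (stable byte-for-byte)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "provenance": cohort.provenance,
        "patients": [_patient_to_dict(p) for p in cohort.patients],
    }
    return json.dumps(doc, ensure_ascii=False, indent=1, sort_keys=True) + "\n"


def cohort_from_json(text: str, source: str = "<json>") -> Cohort:
    if not text.strip():
        raise CohortFormatError(f"{source}: empty cohort file")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CohortFormatError(f"{source}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("schema_version") != SCHEMA_VERSION:
        raise CohortFormatError(
            f"{source}: missing or unsupported schema_version "
            f"(expected {SCHEMA_VERSION!r})"
        )
    patients = tuple(_patient_from_dict(pd) for pd in doc.get("patients", []))
    return Cohort(patients=patients, provenance=doc.get("provenance", ""))


# ---------------------------------------------------------------------------
# CSV (de)serialization — one row per biopsy
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "patient_id", "sex", "diagnosis_group", "gene", "flg_allele_count",
    "genetically_confirmed", "clinical_features", "recorded_pattern",
    "diagnosis_verbatim", "symptoms_verbatim",
    "biopsy_index", "site", "age_years", "sc", "sg",
    "acanthosis", "acanthosis_regularity", "inflammation",
    "fhk", "ahk", "flags", "notes",
]


def cohort_to_csv(cohort: Cohort) -> str:
    buf = io.StringIO()
    buf.write(f"#{SCHEMA_VERSION};provenance={cohort.provenance}\n")
    writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    writer.writerow(_CSV_COLUMNS)
    for p, idx, b in cohort.iter_biopsies():
        bd = _biopsy_to_dict(b)
        writer.writerow([
            p.id, p.sex, p.diagnosis_group.value, p.gene,
            "" if p.flg_allele_count is None else p.flg_allele_count,
            "true" if p.genetically_confirmed else "false",
            ";".join(sorted(p.clinical_features)),
            p.recorded_pattern.value,
            p.diagnosis_verbatim, p.symptoms_verbatim,
            idx, bd["site"],
            "" if bd["age_years"] is None else repr(float(bd["age_years"])),
            bd["sc"], bd["sg"], bd["acanthosis"], bd["acanthosis_regularity"],
            bd["inflammation"], bd["fhk"], bd["ahk"],
            ";".join(bd["flags"]), bd["notes"],
        ])
    return buf.getvalue()


def cohort_from_csv(text: str, source: str = "<csv>") -> Cohort:
    if not text.strip():
        raise CohortFormatError(f"{source}: empty cohort file")
    lines = text.splitlines()
    header = lines[0]
    if not header.startswith(f"#{SCHEMA_VERSION}"):
        raise CohortFormatError(
            f"{source}: missing schema tag line '#{SCHEMA_VERSION}...'"
        )
    provenance = ""
    if ";provenance=" in header:
        provenance = header.split(";provenance=", 1)[1]
    reader = csv.DictReader(io.StringIO("\n".join(lines[1:])))
    if reader.fieldnames != _CSV_COLUMNS:
        raise CohortFormatError(f"{source}: unexpected CSV columns {reader.fieldnames}")

    per_patient: dict[int, dict] = {}
    order: list[int] = []
    for lineno, row in enumerate(reader, start=3):
        where = f"{source} line {lineno}"
        try:
            pid = int(row["patient_id"])
        except (TypeError, ValueError) as exc:
            raise CohortFormatError(f"{where}: bad patient_id {row['patient_id']!r}") from exc
        bdict = {
            "sc": row["sc"],
            "sg": row["sg"],
            "acanthosis": row["acanthosis"],
            "acanthosis_regularity": row["acanthosis_regularity"],
            "inflammation": row["inflammation"],
            "fhk": row["fhk"],
            "ahk": row["ahk"],
            "flags": [f for f in row["flags"].split(";") if f],
            "site": row["site"],
            "age_years": float(row["age_years"]) if row["age_years"] else None,
            "notes": row["notes"],
        }
        if pid not in per_patient:
            order.append(pid)
            per_patient[pid] = {
                "id": pid,
                "sex": row["sex"],
                "diagnosis_group": row["diagnosis_group"],
                "gene": row["gene"],
                "flg_allele_count": int(row["flg_allele_count"]) if row["flg_allele_count"] else None,
                "genetically_confirmed": row["genetically_confirmed"] == "true",
                "clinical_features": [f for f in row["clinical_features"].split(";") if f],
                "recorded_pattern": row["recorded_pattern"],
                "diagnosis_verbatim": row["diagnosis_verbatim"],
                "symptoms_verbatim": row["symptoms_verbatim"],
                "biopsies": [],
            }
        expected_idx = len(per_patient[pid]["biopsies"]) + 1
        if int(row["biopsy_index"]) != expected_idx:
            raise CohortFormatError(
                f"{where}: biopsy_index {row['biopsy_index']} out of order "
                f"for patient {pid} (expected {expected_idx})"
            )
        per_patient[pid]["biopsies"].append(bdict)

    patients = tuple(_patient_from_dict(per_patient[pid]) for pid in order)
    return Cohort(patients=patients, provenance=provenance)


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("json", "csv"):
            raise ValueError(f"format must be 'json' or 'csv', got {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise ValueError(f"cannot infer cohort format from {path.name!r}; pass format=")


def load_cohort(path: str | Path, format: str | None = None) -> Cohort:
    """Load a cohort table from JSON or CSV, parsing every score cell."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text(encoding="utf-8")
    if fmt == "json":
        return cohort_from_json(text, source=str(path))
    return cohort_from_csv(text, source=str(path))


def write_cohort(cohort: Cohort, path: str | Path, format: str | None = None) -> None:
    """Write a cohort canonically; ``load(write(x)) == x`` and re-writing a
    loaded file is byte-identical."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = cohort_to_json(cohort) if fmt == "json" else cohort_to_csv(cohort)
    path.write_text(text, encoding="utf-8")


_FIXTURE_RESOURCE = "table1_cohort.json"


def load_fixture() -> Cohort:
    """Load the packaged 66-patient / 87-biopsy reference cohort."""
    text = (
        resources.files("ichthyoscore.data")
        .joinpath(_FIXTURE_RESOURCE)
        .read_text(encoding="utf-8")
    )
    return cohort_from_json(text, source=_FIXTURE_RESOURCE)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationCheck:
    name: str
    expected: object
    observed: object

    @property
    def passed(self) -> bool:
        return self.expected == self.observed


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[ValidationCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def as_dict(self) -> dict:
        return {
            c.name: {"expected": c.expected, "observed": c.observed, "passed": c.passed}
            for c in self.checks
        }

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            status = "ok" if c.passed else "FAIL"
            lines.append(f"[{status}] {c.name}: expected {c.expected}, observed {c.observed}")
        return "\n".join(lines)


def validate_fixture(cohort: Cohort) -> ValidationReport:
    """Check the structural totals of the reference cohort.

    Expected values are the published cohort's headline counts: 66 patients,
    87 biopsies, 32 female / 34 male, 19 patients in the ARCI umbrella
    (including harlequin ichthyosis), 4 Netherton (SPINK5) patients, and
    3 peeling-skin-disease (CDSN) patients contributing 18 biopsies.
    """
    def group_patients(groups: Iterable[DiagnosisGroup]) -> list[PatientRecord]:
        gset = set(groups)
        return [p for p in cohort.patients if p.diagnosis_group in gset]

    psd = group_patients([DiagnosisGroup.PSD])
    checks = (
        ValidationCheck("n_patients", 66, cohort.n_patients),
        ValidationCheck("n_biopsies", 87, cohort.n_biopsies),
        ValidationCheck("n_female", 32, sum(1 for p in cohort.patients if p.sex == "f")),
        ValidationCheck("n_male", 34, sum(1 for p in cohort.patients if p.sex == "m")),
        ValidationCheck("n_arci_umbrella", 19, len(group_patients(ARCI_UMBRELLA))),
        ValidationCheck("n_spink5", 4, len(group_patients([DiagnosisGroup.NTS]))),
        ValidationCheck("n_cdsn", 3, len(psd)),
        ValidationCheck("n_cdsn_biopsies", 18, sum(len(p.biopsies) for p in psd)),
        ValidationCheck(
            "n_genetically_confirmed", 59,
            sum(1 for p in cohort.patients if p.genetically_confirmed),
        ),
    )
    return ValidationReport(checks=checks)
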