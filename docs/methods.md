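# Methods

## The scoring system

Each histological axis is graded on a shared five-token ordinal scale
(`−− < − < + < ++ < +++`) whose meaning is attached per axis:

* **Stratum granulosum (SG):** absent (`−−`), reduced (`−`), normal (`+`),
  prominent (`++`).
* **Stratum corneum (SC) hyperkeratosis** (from measured mean thickness):
  none (`−`, 0 mm), mild (`+`, ≤ 0.1 mm), moderate (`++`, > 0.1–0.2 mm),
  severe (`+++`, > 0.2 mm).
* **Acanthosis** (viable-epidermis thickness): none (`−`, ≤ 0.1 mm), mild
  (`+`, > 0.1–0.2 mm), moderate (`++`, > 0.2–0.3 mm), severe (`+++`,
  > 0.3 mm).
* **Inflammation:** none (`−`), mild (`+`), moderate (`++`), severe (`+++`).

All thickness bins are left-open/right-closed as printed; ties at a
threshold go to the lower bin.  Note the asymmetry at the low end: any
measurable SC thickening (0 < mm ≤ 0.1) is already mild hyperkeratosis,
while an epidermis up to 0.1 mm is still "no hyperplasia".  One conflicting
summary wording grades severe hyperkeratosis `++`; we follow the legend's
`+++` and pin this with a regression test.

Report cells add structure beyond single grades: ranges (`−−/−`), trailing
focal sub-codes (`+, focal ++`, stored as a separate *focal elevation*,
never folded into the range — focality is spatial, not severity), pure
focal findings (`focal +`, parsed as the named grade with a `focal`
qualifier: "focal mild inflammation" is mild inflammation present focally),
SC descriptors combining a grade with keratinization (`OK`, `PK`,
`OK, focal PK`, staggered `OK/PK`, `PK, focal OK`) and texture words
(lamellar / compact / basket-weave), and multi-biopsy cells with index
prefixes (`1–3, 8–14: …`).  Unicode minus, hyphen-minus and dashes are
interchangeable on input; serialization is canonical and round-trips.
`n.a.`/`n.k.` parse to an explicit not-assessable marker, distinct from any
grade.  Slashes between grades denote ranges; slashes between texture words
denote sets (disambiguated by token class).

Grade *ranges* require an explicit reduction before they can enter a rule:
`collapse(span, policy)` reads a span at its upper (`optimistic_max`) or
lower (`pessimistic_min`) bound.  Focal elevations never influence a
collapse.

## The reference cohort

The package ships a hand transcription of a published reference cohort —
66 patients, 87 biopsies across 17 diagnosis groups — as canonical JSON
(`ichthyoscore/data/table1_cohort.json`, schema in `cohort.schema.json`).
Free-text findings were pre-coded at transcription time into a fixed set of
18 boolean morphology flags (EHK, kissing vessels, suprapapillary thinning,
subcorneal clefting, acantholysis, …), with the original prose retained in
per-biopsy `notes` for audit; clinical symptoms were coded into a
controlled vocabulary of feature tags.  Transcription choices that required
judgement (an overlapping biopsy-index assignment, one missing acanthosis
entry coded as "none", one biopsy with no stratum corneum, encoding
"partly −−" as a widened span) are recorded in the biopsy notes.  A
structural validation report checks the headline totals (66/87, 32 f/34 m,
19 ARCI-umbrella patients, 4 Netherton, 3 peeling-skin-disease patients
with 18 biopsies, 59 genetically confirmed) on every load of the fixture.

## The six-pattern rule engine

Rules are evaluated per biopsy in fixed precedence order
IV > V > VI > III > I > II; the first fired rule is the primary pattern and
all fired rules form the satisfied set (a biopsy may legitimately satisfy
several patterns).  The precedence expresses that structural morphologies
(epidermolytic hyperkeratosis; perinuclear vacuoles with binucleation) are
pathognomonic, psoriasis-like features trump the SG state, and the SG state
is the fallback discriminator between the two orthohyperkeratotic patterns.

Tunables (`RuleConfig`):

* `sg_policy` — collapse policy for SG spans; default `optimistic_max`, so
  a span like `−/+` counts as a developed SG.  This default minimizes
  disagreement with the reference cohort's recorded labels.
* `vi_requires_architecture_marker` — when true, the psoriasis-like gate
  additionally requires a psoriasiform architecture marker (suprapapillary
  thinning, kissing vessels, subcorneal clefting, acantholysis or
  neutrophils in the SC).  Default false.
* `exception_registry` — patient ids whose recorded label is known to
  disagree with the diagnosis-blind rules, each with a rationale string.

Focal parakeratosis counts as parakeratosis for the VI gate but not for the
III gate (III requires the staggered `OK/PK` form); parakeratosis-dominant
cells with focal orthokeratosis (`PK, focal OK`) likewise count for VI
only.  Patient-level classification takes the highest-precedence pattern
over the patient's biopsies; biopsies on which no rule can fire (e.g. a
missing SC) are tolerated and recorded in the trace as long as one biopsy
classifies.  On the reference cohort the default configuration reproduces
the recorded pattern for 61/66 patients (92.4%); the five disagreements are
exactly the shipped exception registry (two harlequin-ichthyosis patients
whose recordings follow the SG state although the biopsies meet the
psoriasis-like gate, and three patients whose recorded label follows the
diagnosis group against a literal reading of their SG span).  We keep these
as registered exceptions rather than special-casing by diagnosis, because
diagnosis-blind classification is the point of the tool.

## Differential-diagnosis ranking

The knowledge base (versioned CSVs) lists candidate diagnoses per pattern
with discriminating clinical cue tags; diagnoses that occur under two
patterns (X-linked ichthyosis, harlequin ichthyosis, IFAP, KID,
Sjögren–Larsson) appear as distinct rows.  Acquired ichthyosis is included
under pattern I although it is not part of the reference cohort.  Ranking
is exact-tag intersection counting with ties broken by row order —
auditability over recall; there is no probability calibration and no
prevalence prior.  Some rows carry an empty cue set and can only tie at
score 0.  The follicular-hyperkeratosis list is deliberately *not* a
seventh pattern: follicular plugging occurs across subtypes, so it is
reported as an advisory note.

## Fisher exact test

`fisher_two_sided` enumerates all 2×2 tables with the observed margins and
sums the hypergeometric probabilities of those no more likely than the
observed table (minimum-likelihood two-sided convention, as used by the
major statistics packages), in exact rational arithmetic
(`fractions.Fraction` over `math.comb`); only the final value is floated.
A zero margin returns p = 1 by convention.  Tests verify equality against
two independent oracles: a brute-force enumeration using the factorial
formula for every table with N ≤ 12, and `scipy.stats.fisher_exact` on
random tables.

On the reference cohort, comparing mono- vs biallelic filaggrin patients:
the absent-SG coding (SG collapsing pessimistically to `−−` in any biopsy;
3/5 vs 3/3) gives p = 13/28 = 0.464, and the prominent-hyperkeratosis
coding (SC ≥ `++` in any biopsy, optimistic collapse; 0/5 vs 2/3) gives
p = 3/28 = 0.107.  Both codings are reported side by side with their
tables.  A published comparison of reduced SG in X-linked ichthyosis with
vs without additional filaggrin mutations could not be reproduced under
any natural coding of the table and is therefore not asserted anywhere.

## Synthetic cohorts

`estimate_profiles` summarizes each diagnosis group as categorical
distributions over the *serialized* score codes of each axis (so samples
are valid codes by construction), with additive smoothing (default
pseudo-count α = 0.5) over the group's own observed category set.
Group-local smoothing is deliberate: borrowing the cohort-wide support
floods small groups with foreign codes and destroys their histological
identity; the trade-off is that an axis a group only ever showed one code
for remains a point mass.  Morphology flags and clinical cues are
independent Bernoullis; biopsy counts stay empirical per group.

Sampling adds report-style noise: with probability `p_span` (default 0.15)
a plain grade widens to an adjacent-level span, and with `p_focal`
(default 0.10) a focal elevation one level up is attached — the defaults
approximate the frequency of spans and focal sub-codes in the reference
cohort.  All randomness flows through numpy's counter-based Philox
generator keyed by the spec seed; identical specs give bit-identical
cohorts after canonical serialization.

**What the generator does and does not emulate.** It reproduces
diagnosis-conditional *marginal* distributions, multi-biopsy patients,
grade-range/focality noise and flag frequencies.  It does **not** model
within-biopsy correlations between axes (the reference cohort is far too
small to estimate them), genotypes, ages beyond uniform placeholders, or
biopsy-site effects.  Consequently, passing recovery tests show that the
rule engine correctly reads the histological signatures it was built for —
not that it would reach these accuracies on real correlated data.  The
consequence is visible in the recovery experiment at the study conditions
(fixture-estimated profiles, 200 patients per group, default noise,
seed 0): the epidermolytic pattern recovers at ≈ 0.97 (a single flag
carries it), while psoriasis-like recovery is ≈ 0.59, because under
independent per-axis sampling a biopsy only fires the VI gate when
inflammation, acanthosis and parakeratosis all land high simultaneously.
Noise-free archetype profiles recover at exactly 1.0 for all six patterns.

## Numerical and engineering choices

* Degenerate inputs: empty cohort files, zero-margin tables, empty
  simulation specs and unknown vocabulary tags raise explicit errors; a
  not-assessable SG never silently becomes a grade.
* Problem sizes: the test suite runs the full fixture (87 biopsies), the
  exhaustive Fisher oracle up to N = 12 (1 819 tables), a 5 000-patient
  marginal-fidelity check and 200-patients-per-group recovery runs —
  desk-scale sizes chosen to keep the whole suite in seconds.
* Ties in ranking are broken by knowledge-base row order; ties at binning
  thresholds go to the lower bin; reversed grade pairs (`+/−−`) are
  ordered on parse.
* Canonical serialization (sorted keys, fixed separators, canonical minus
  glyph) makes writing a loaded cohort byte-identical, which the tests
  assert for both JSON and CSV.

## Known limitations

* The pattern rules are a faithful operationalization of a published
  verbal scheme; the registered exceptions document where the scheme's own
  labels are not reachable diagnosis-blind.
* The knowledge base covers the six patterns' diagnoses as published,
  including some diagnoses absent from the reference cohort; cue tags are
  coarse (~60-tag controlled vocabulary) and matching is exact.
* The transcription pre-codes prose findings into flags; other
  transcribers could code borderline prose differently.  The original
  prose is retained per biopsy for audit.
* Pattern V (perinuclear vacuoles + binucleated keratinocytes) has no
  patient in the reference cohort; it is exercised only through synthetic
  archetypes.
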