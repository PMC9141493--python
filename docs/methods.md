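# Methods

## The de-identification model

The package treats header de-identification as the application of a
validated, declarative policy to a DICOM dataset. A policy is a set of
per-attribute rules, each assigned to one of two stages and one of six
actions:

| action        | effect                                            | legality |
|---------------|---------------------------------------------------|----------|
| `KEEP`        | attribute untouched (the "SAFE" classification)   | always |
| `CLEAR`       | element kept, value set to zero length            | illegal for Type 1 |
| `OVERWRITE`   | element kept, value replaced, padded per VR       | always |
| `REMOVE`      | element deleted                                   | legal only for Type 3 |
| `REMAP_UID`   | deterministic salted Instance-UID replacement     | UID attributes |
| `RANDOM_DATE` / `RANDOM_TIME` | per-study random replacement      | date/time attributes |

`validate_policy` rejects any rule whose action is illegal for the target's
data element type *before* anything is applied, and `apply_action` refuses a
Type 1/2 removal again at run time as defence in depth. The builtin policy
encodes the full stage-1 (source export) and stage-2 (attribute-level)
tables; user configs can only replace rules with ones that still validate.

Unlisted **public** attributes are kept (SAFE), with the auditor
independently warning about populated person-name values among them.
Unlisted **private** attributes are removed wholesale at stage 2
(`default_private_action = REMOVE`): private elements are vendor-defined,
unauditable, and fail-closed removal is the only defensible default.

## UID remapping

`remap_uid` returns `org_root + "." + decimal(sha256(salt|old)[:16])`,
truncated to the 64-character UID limit. Design notes:

* **Deterministic, not tabulated.** Consistency across files and runs falls
  out of the hash; no re-identification record ever exists. The salt is
  user-supplied; with it gone, the mapping cannot be reversed or replayed.
* **Collision risk.** 128 bits of digest: negligible at any cohort scale
  this tool will see (a test verifies injectivity over 10⁴ UIDs).
* **Class UIDs are fixed points**, detected by the `1.2.840.10008` root.
* **Frame of Reference UID** is an instance-class UID the source export
  keeps; it is remapped by default (fail-closed) alongside the SOP, Study
  and Series Instance UIDs, and the file-meta Media Storage SOP Instance UID
  is re-synchronised to the new SOP Instance UID.
* `org_root` defaults to `2.25`, the UUID-derived arc that is legal without
  registration; sites with their own registered root should pass
  `--org-root`.

## Replacement dates and times

One random date and one random time are drawn **per study**, not per
element, and reused for every date/time attribute of that study (datetime
attributes get the concatenation). Sharing preserves internal consistency —
a series cannot predate its study — while leaking nothing about the true
acquisition date. Values are derived as
`sha256(seed|kind|study_uid)` reduced into the configured window
(default 2000-01-01 .. 2020-12-31), so they are independent of processing
order and fully reproducible under the seed. The window is a policy
parameter; the auditor treats a date outside it as a residual finding, which
also catches true acquisition dates (2021 onwards in the synthetic cohorts)
that survived by mistake. Times cannot be distinguished from real ones and
are checked for format only. Stage-2 calibration dates are keyed by the
*remapped* Study Instance UID, the same key stage 1 used, so both stages
agree on a study's replacement date.

## Sex and age re-insertion

Directory names `CASE<n> <SEX> <lo>_<hi>` are the only carrier of surviving
demographics. The parser accepts sexes `F`/`M`/`O` (all three legal Patient
Sex codes) and exactly the 18 ranges 15–20 … 100–105; anything else is a
protocol error and that case is skipped. At stage 2 the **upper bound** of
the range is written as a DICOM Age String (`25_30` → `030Y`) and the sex
code re-inserted. Consequence for auditing: Patient's Sex and Patient's Age
carry stage-1 CLEAR rules yet are legitimately non-empty afterwards, so the
scanner accepts exactly the re-insertion shapes (one sex code; `\d{3}Y`) for
those two tags and flags anything else.

## Auditing semantics

"NOT SAFE if populated" is operationalised per action: a CLEAR target is
compliant when zero-length, an OVERWRITE target when equal to its
replacement, a REMOVE target when absent, a REMAP target when under the
organisational root (or a class UID), a RANDOM_DATE target when inside the
date window. Additionally every surviving private element and every
non-class Instance UID outside the org root is an ERROR; populated
person-name attributes without a rule are WARNINGs (suspicious, not provably
PII). The conformance checker inspects the *raw, as-encoded* element values
where available, so wrong padding bytes (a space-padded `UI`) and odd
lengths are caught before pydicom's value conversion strips them.

In `--stage2-only` mode (data already de-identified at source) the source's
UIDs are kept; audits of such trees report the source UIDs as outside the
org root unless the source used the same root — expected, since this tool
cannot vouch for a remapping it did not perform.

## The synthetic cohort generator

`write_cohort` emulates a pre-export hospital archive: every attribute the
policy targets is populated with plausible PHI (names from small built-in
pools, MRN/accession identifiers embedding the case number so they are
unique by construction, birth dates consistent with the declared age, true
study dates in 2021–2023, a private `(0009,xx)` block with an
"[Anonymization Status]" marker, a Request Attributes Sequence, an
Irradiation Event UID, private file-meta information) under a fictitious
hospital UID root `1.3.6.1.4.1.99999`, so remapping is observable. Pixel
data is Gaussian noise around a circular soft-tissue phantom — never any
burned-in text, matching the target data class, which is why the final
burned-in check remains a visual, human step outside this package's scope.

What the fixtures do **not** emulate: vendor-specific private dictionaries,
multi-series studies, compressed transfer syntaxes, non-CT modalities, and
burned-in annotations. Passing tests therefore demonstrate correctness of
the header pipeline, not pixel-level privacy.

Defaults: clinical CT series run to 200–500 slices of 512×512; generation
uses 8 slices per series by default (the `--full-scale` flag restores
200–500) and the unit-test fixtures shrink images to 32 px, which changes
nothing about header handling. Cohorts are byte-deterministic under
(seed, spec).

## Numerical and encoding choices

* Explicit VR Little Endian only, read and write; other transfer syntaxes
  are rejected rather than silently transcoded, keeping byte-exact
  round-trip and determinism guarantees testable.
* Padding: string VRs pad with a trailing space, `UI`/`OB` with a trailing
  NUL; `pad_value` is idempotent and pydicom applies the same rules on
  write.
* Group-length elements are never written (retired); the file-meta group
  length required by Part 10 is produced by pydicom.
* Clearing/overwriting an element the file does not carry is a logged
  no-op, not an error — scanner models differ in which attributes they emit.
* The attribute registry is deliberately bounded: the attributes the policy
  names plus the minimal CT Image IOD set, with element types per the CT
  conventions. Unknown tags resolve to type UNKNOWN and are never blindly
  removed (except private ones at stage 2, by the fail-closed default).
* `Private Information (0002,0102)` is conditionally required given
  `Private Information Creator UID (0002,0100)`; the policy removes the
  pair together, which keeps the condition satisfied.

## Known limitations

* Header-only: no OCR or defacing; out of scope by design.
* Single transfer syntax; no re-encoding of compressed archives.
* The private-tag location of the export's "[Anonymization Status]" marker
  varies by site; the fixtures plant it at `(0009,1001)` so the removal rule
  is exercised, and the stage-2 private sweep removes it wherever it
  actually lives.
* Date randomisation is per study; cross-study intervals for one patient
  are not preserved (interval-preserving date shifting is explicitly not a
  goal, as it weakens unlinkability).
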