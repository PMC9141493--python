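# dicomdeid

Two-stage de-identification of DICOM CT headers, with a policy engine that
cannot violate the DICOM standard, hierarchy-preserving UID remapping, a
residual-PII auditor, and a synthetic PHI-laden cohort generator so the whole
pipeline is testable without a single real patient file.

## The problem

Sharing CT scans for research requires removing Personally Identifiable
Information (PII) from the DICOM header — names, IDs, birth dates, accession
numbers, institution and physician names, acquisition dates — without
breaking the files. Two constraints make this harder than deleting tags:

* **Data element types.** Every attribute has a conformance type: Type 1
  must be present with a valid value, Type 2 must be present but may be
  empty, Type 3 is optional (with conditional 1C/2C variants). Removing a
  Type 1 or Type 2 attribute produces a non-conformant file; a safe policy
  may only *clear* a Type 2 value or *remove* a Type 3 attribute.
* **The data model.** Instance UIDs (SOP, Study, Series) link each slice
  into a patient → study → series → image hierarchy. They identify patient
  data and must be replaced — but *consistently*, so slices of one series
  still share a Series Instance UID afterwards. Class UIDs (everything under
  `1.2.840.10008`: SOP classes, transfer syntaxes) name services, carry no
  patient information, and must pass through untouched.

The pipeline runs in two stages, mirroring how hospital data actually flows:

* **Stage 1 — de-identification at source.** Emulates a PACS export:
  Instance UIDs remapped, Patient ID overwritten with `!T000`, names and
  accession numbers overwritten with `CONFIDENTIAL`, birth date / sex / age
  cleared, and every study/series/acquisition/content date and time replaced
  with a random one (shared per study, so a series never predates its study).
* **Stage 2 — attribute-level pass.** Removes private elements and the
  Request Attributes Sequence (its Requested Procedure ID sub-attribute is
  Type 1C and cannot be removed alone — the enclosing Type 3 sequence can),
  removes the Irradiation Event UID and private file-meta information,
  randomises the calibration date/time, clears institution, address,
  referring physician and image comments, and finally re-inserts the only
  demographics allowed to survive: the patient's sex and the *upper bound*
  of the five-year age range, both read from the case-directory name
  `CASE<n> <SEX> <lo>_<hi>` (e.g. `CASE10 F 25_30` → sex `F`, age `030Y`).
  Age ranges run 15–20 through 100–105.

UID remapping is deterministic and salted: a new UID is
`org_root.D` where `D` is the decimal rendering of the first 16 bytes of
SHA-256(`salt|old-UID`). The same cohort remaps consistently across runs and
files without ever storing a re-identification table; losing the salt makes
the mapping irreversible by design.

An auditor closes the loop: `scan_residual_pii` flags every targeted
attribute that is not in its compliant final state, every surviving private
element, and every Instance UID still outside the organisational root, while
`check_dicom_conformance` verifies Type 1/2 presence, even value lengths and
VR padding bytes (string VRs pad with a trailing space, `UI`/`OB` with a
trailing NUL — a padded Patient Sex value `"F "` has length 2).

## Worked example

```sh
dicomdeid generate --out demo/raw --cases 2 --seed 7
dicomdeid deidentify --in demo/raw --out demo/deid --salt demo-salt --seed 7
dicomdeid audit --in demo/deid --report demo/report.json
```

prints

```
wrote 2 case directories under demo/raw
processed 16 files; 0 error findings
scanned 16 files; summary {'residual_pii': 0, 'conformance': 0, 'protocol': 0}
```

The generator produced `CASE1 F 40_45` and `CASE2 M 35_40`, each a synthetic
CT series whose headers are loaded with plausible PHI. After both stages the
first slice of case 1 reads:

```
PatientName    = 'CONFIDENTIAL'
PatientID      = '!T000'
PatientSex     = 'F'        # re-inserted from the directory name
PatientAge     = '045Y'     # upper bound of the declared 40-45 range
StudyDate      = '20140226' # random replacement date, shared by the study
SOPInstanceUID = '2.25.329286247323682308953883817358261387434'
InstitutionName = ''
```

Pixel data is byte-identical to the input, the study/series grouping of the
16 files is unchanged, and re-running with the same salt and seed reproduces
the output byte for byte. The audit exit code is 0 only when no ERROR
finding remains, so the three commands chain cleanly in a pipeline.

Policy overrides are a flat YAML mapping merged onto the builtin policy and
re-validated against the element types:

```yaml
ImageComments: {stage: STAGE2, action: overwrite, replacement: REDACTED}
salt: my-site-salt
date_window: {earliest: 2010-01-01, latest: 2015-12-31}
```

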