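"""Residual-PII scanning, conformance checking, report output."""

import json
from datetime import date

import pytest
from pydicom.dataset import Dataset

from dicomdeid import (
    AuditReport,
    Finding,
    RandomizationContext,
    Tag,
    UidMap,
    apply_stage1,
    apply_stage2,
    check_dicom_conformance,
    parse_case_dirname,
    read_dataset,
    scan_residual_pii,
    write_report,
)
from dicomdeid.audit import Category, Severity
from dicomdeid.fixtures import generate_patient_profile
from dicomdeid.policy import ActionKind
import random


def expected_raw_findings(patient, policy):
    """Independent enumeration of the PII planted in one fixture slice.

    Counts, straight from the generator's ground truth, every element the
    merged policy targets that is not in its compliant final state, plus the
    private elements and the non-remapped hospital-root UIDs.
    """
    count = 0
    count += 4      # SOP/Study/Series/MediaStorage Instance UIDs: hospital root
    count += 2      # StationName, SourceApplicationEntityTitle != CONFIDENTIAL
    count += 4      # PatientID, StudyID, AccessionNumber, PatientName != replacements
    count += 1      # ScheduledProcedureStepID inside the request sequence
    count += 1      # PatientBirthDate populated (cleared rule)
    # four date attributes + AcquisitionDateTime share the true study date
    lo, hi = policy.date_window
    if not lo <= patient.study_date <= hi:
        count += 5
    count += 4      # InstitutionName, InstitutionAddress, ReferringPhysicianName, ImageComments
    count += 1      # IrradiationEventUID present (remove rule)
    count += 2      # private block: creator + anonymization-status marker
    count += 2      # file-meta PrivateInformationCreatorUID + PrivateInformation
    count += 1      # RequestAttributesSequence present (remove rule)
    count += 1      # FrameOfReferenceUID under the hospital root
    return count


def test_scan_flags_planted_pii_matches_enumeration(small_cohort_dir, small_cohort_spec, policy):
    """Raw-fixture finding count equals the independent planted-PII enumeration."""
    from dicomdeid.fixtures import _case_rng
    from datetime import timedelta

    rng = random.Random(f"{small_cohort_spec.seed}|profiles")
    for case_number in range(1, small_cohort_spec.n_cases + 1):
        patient = generate_patient_profile(rng, case_number)
        expected = expected_raw_findings(patient, policy)
        # calibration date: re-derive the generator's draw independently
        crng = _case_rng(small_cohort_spec, case_number)
        if isinstance(small_cohort_spec.slices_per_series, tuple):
            crng.randint(*small_cohort_spec.slices_per_series)
        crng.randrange(7, 20); crng.randrange(60); crng.randrange(60)
        cal_date = patient.study_date - timedelta(days=crng.randrange(30, 200))
        lo, hi = policy.date_window
        if not lo <= cal_date <= hi:
            expected += 1

        from dicomdeid import format_case_dirname
        case_dir = small_cohort_dir / format_case_dirname(patient.dir_info)
        for path in sorted(case_dir.iterdir()):
            ds = read_dataset(path)
            findings = scan_residual_pii(ds, policy)
            errors = [f for f in findings if f.severity is Severity.ERROR]
            assert len(errors) == expected, [f.detail for f in errors]


def test_scan_is_read_only(raw_slice, policy, tmp_path):
    from dicomdeid import write_dataset
    before = tmp_path / "before.dcm"
    write_dataset(raw_slice, before)
    scan_residual_pii(raw_slice, policy)
    check_dicom_conformance(raw_slice)
    after = tmp_path / "after.dcm"
    write_dataset(raw_slice, after)
    assert before.read_bytes() == after.read_bytes()


def test_clean_after_full_pipeline(raw_slice, policy):
    ctx = RandomizationContext(seed=2, date_window=policy.date_window)
    uid_map = UidMap(policy.salt)
    apply_stage1(raw_slice, policy, ctx, uid_map)
    apply_stage2(raw_slice, policy, ctx, parse_case_dirname("CASE2 M 40_45"), uid_map)
    assert scan_residual_pii(raw_slice, policy) == []
    assert check_dicom_conformance(raw_slice) == []


def test_populated_institution_name_is_flagged(raw_slice, policy):
    ctx = RandomizationContext(seed=2, date_window=policy.date_window)
    uid_map = UidMap(policy.salt)
    apply_stage1(raw_slice, policy, ctx, uid_map)
    apply_stage2(raw_slice, policy, ctx, parse_case_dirname("CASE2 M 40_45"), uid_map)
    raw_slice.InstitutionName = "Mater Hospital"
    findings = scan_residual_pii(raw_slice, policy)
    assert len(findings) == 1
    assert findings[0].keyword == "InstitutionName"
    assert findings[0].category is Category.RESIDUAL_PII


def test_conformance_missing_sop_instance_uid():
    ds = Dataset()
    findings = check_dicom_conformance(ds)
    sop = [f for f in findings
           if f.keyword == "SOPInstanceUID" and f.severity is Severity.ERROR]
    assert len(sop) == 1
    assert "Type 1" in sop[0].detail


def test_conformance_space_padded_ui_flagged(raw_slice, tmp_path):
    """A UI value padded with a space instead of a NUL byte is flagged."""
    from dicomdeid import write_dataset

    assert check_dicom_conformance(raw_slice) == []
    raw_slice.IrradiationEventUID = "1.3.6.1.4.1.99999.5"  # odd length: gets a pad
    path = tmp_path / "padded.dcm"
    write_dataset(raw_slice, path)
    good = b"1.3.6.1.4.1.99999.5\x00"
    data = path.read_bytes()
    assert data.count(good) == 1
    path.write_bytes(data.replace(good, b"1.3.6.1.4.1.99999.5 "))
    findings = check_dicom_conformance(read_dataset(path))
    assert any("padded with space" in f.detail for f in findings)


def test_conformance_meta_dataset_uid_mismatch(raw_slice):
    raw_slice.file_meta.MediaStorageSOPInstanceUID = "1.2.3.4"
    findings = check_dicom_conformance(raw_slice)
    assert any("differs from" in f.detail for f in findings)


def test_conformance_zero_length_type1(raw_slice):
    raw_slice.SeriesInstanceUID = ""
    findings = check_dicom_conformance(raw_slice)
    assert any(f.keyword == "SeriesInstanceUID" and "zero-length" in f.detail
               for f in findings)


def test_write_report_json_csv_and_exit_code(tmp_path):
    empty = AuditReport(files_scanned=4)
    out = tmp_path / "report.json"
    assert write_report(empty, out) == 0
    doc = json.loads(out.read_text())
    assert doc["files_scanned"] == 4 and doc["findings"] == []

    findings = [
        Finding("a.dcm", "(0008,0080)", "InstitutionName",
                Category.RESIDUAL_PII, Severity.ERROR, "populated"),
        Finding("b.dcm", "(0020,000e)", "SeriesInstanceUID",
                Category.CONFORMANCE, Severity.WARNING, "odd"),
    ]
    report = AuditReport(findings=findings, files_scanned=2)
    assert write_report(report, out) == 1
    assert report.summary == {"residual_pii": 1, "conformance": 1, "protocol": 0}
    csv_rows = (tmp_path / "report.csv").read_text().strip().splitlines()
    assert len(csv_rows) == 3  # header + 2 data rows
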