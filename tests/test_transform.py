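"""Stage application: randomised dates/times, element actions, full pipeline."""

import hashlib
from datetime import date, timedelta
from pathlib import Path

import pytest

from dicomdeid import (
    Action,
    ActionKind,
    ConfigError,
    RandomizationContext,
    Tag,
    UidMap,
    apply_action,
    apply_stage1,
    apply_stage2,
    deidentify_case_directory,
    parse_case_dirname,
    random_date,
    random_time,
    read_dataset,
)
from dicomdeid.policy import Stage, builtin_policy


def oracle_draw(seed: int, kind: str, study_uid: str, modulus: int) -> int:
    """Independent reference-RNG oracle for the keyed date/time derivation."""
    digest = hashlib.sha256(f"{seed}|{kind}|{study_uid}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % modulus


class TestRandomisation:
    def test_date_matches_reference_oracle(self):
        ctx = RandomizationContext(seed=7)
        lo, hi = ctx.date_window
        n_days = (hi - lo).days + 1
        expected = (lo + timedelta(days=oracle_draw(7, "date", "S", n_days))).strftime("%Y%m%d")
        assert random_date(ctx, "S") == expected

    def test_time_matches_reference_oracle(self):
        ctx = RandomizationContext(seed=7)
        seconds = oracle_draw(7, "time", "S", 86400)
        expected = f"{seconds // 3600:02d}{seconds % 3600 // 60:02d}{seconds % 60:02d}"
        assert random_time(ctx, "S") == expected

    def test_per_study_caching(self):
        ctx = RandomizationContext(seed=1)
        assert random_date(ctx, "A") == random_date(ctx, "A")
        assert random_time(ctx, "A") == random_time(ctx, "A")
        assert random_date(ctx, "A") != random_date(ctx, "B")  # distinct studies differ

    def test_degenerate_single_day_window(self):
        ctx = RandomizationContext(seed=3, date_window=(date(2020, 1, 1), date(2020, 1, 1)))
        assert random_date(ctx, "S") == "20200101"

    def test_empty_window_rejected(self):
        ctx = RandomizationContext(seed=3, date_window=(date(2020, 1, 2), date(2020, 1, 1)))
        with pytest.raises(ConfigError):
            random_date(ctx, "S")

    def test_times_always_valid(self):
        ctx = RandomizationContext(seed=9)
        for i in range(50):
            t = random_time(ctx, f"study-{i}")
            hh, mm, ss = int(t[:2]), int(t[2:4]), int(t[4:6])
            assert hh < 24 and mm < 60 and ss < 60

    def test_dates_always_inside_window(self):
        ctx = RandomizationContext(seed=9, date_window=(date(2005, 3, 1), date(2005, 4, 15)))
        for i in range(50):
            d = random_date(ctx, f"study-{i}")
            assert date(2005, 3, 1) <= date(int(d[:4]), int(d[4:6]), int(d[6:8])) <= date(2005, 4, 15)


class TestApplyAction:
    def test_clear_keeps_zero_length_element(self, raw_slice):
        apply_action(raw_slice, Tag(0x0010, 0x0030), Action(ActionKind.CLEAR))
        assert Tag(0x0010, 0x0030) in raw_slice
        assert raw_slice.PatientBirthDate == ""

    def test_overwrite(self, raw_slice):
        apply_action(raw_slice, Tag(0x0008, 0x1010), Action(ActionKind.OVERWRITE, "CONFIDENTIAL"))
        assert raw_slice.StationName == "CONFIDENTIAL"

    def test_remove_sequence_takes_nested_attributes(self, raw_slice):
        assert raw_slice.RequestAttributesSequence[0].RequestedProcedureID
        apply_action(raw_slice, Tag(0x0040, 0x0275), Action(ActionKind.REMOVE))
        assert "RequestAttributesSequence" not in raw_slice

    def test_overwrite_recurses_into_sequence_items(self, raw_slice):
        apply_action(raw_slice, Tag(0x0040, 0x0009), Action(ActionKind.OVERWRITE, "CONFIDENTIAL"))
        item = raw_slice.RequestAttributesSequence[0]
        assert item.ScheduledProcedureStepID == "CONFIDENTIAL"

    def test_remove_type1_refused(self, raw_slice):
        with pytest.raises(ConfigError, match="Type 1"):
            apply_action(raw_slice, Tag(0x0008, 0x0018), Action(ActionKind.REMOVE))

    def test_clear_absent_element_is_noop(self, raw_slice):
        del raw_slice[Tag(0x0020, 0x4000)]
        apply_action(raw_slice, Tag(0x0020, 0x4000), Action(ActionKind.CLEAR))
        assert Tag(0x0020, 0x4000) not in raw_slice


@pytest.fixture()
def staged(raw_slice, policy):
    ctx = RandomizationContext(seed=7, date_window=policy.date_window)
    uid_map = UidMap(policy.salt)
    pixels = raw_slice.PixelData
    apply_stage1(raw_slice, policy, ctx, uid_map)
    return raw_slice, ctx, uid_map, pixels


class TestStages:
    def test_stage1_examples(self, staged):
        ds, ctx, uid_map, pixels = staged
        assert ds.PatientID == "!T000"
        assert ds.PatientSex == ""          # cleared; re-inserted only at stage 2
        assert ds.file_meta.SourceApplicationEntityTitle == "CONFIDENTIAL"
        assert ds.PatientName == "CONFIDENTIAL"
        assert str(ds.SOPInstanceUID).startswith("2.25.")
        assert ds.file_meta.MediaStorageSOPInstanceUID == ds.SOPInstanceUID
        assert ds.StudyDate == random_date(ctx, str(ds.StudyInstanceUID))
        assert ds.AcquisitionDateTime == (
            random_date(ctx, str(ds.StudyInstanceUID))
            + random_time(ctx, str(ds.StudyInstanceUID))
        )
        assert ds.PixelData == pixels       # pixels untouched

    def test_stage2_examples(self, staged, policy):
        ds, ctx, uid_map, pixels = staged
        dirinfo = parse_case_dirname("CASE1 F 25_30")
        apply_stage2(ds, policy, ctx, dirinfo, uid_map)
        assert ds.PatientAge == "030Y"      # upper bound of the declared range
        assert ds.PatientSex == "F"
        assert "IrradiationEventUID" not in ds
        assert ds.ReferringPhysicianName == ""
        assert ds.InstitutionName == ""
        assert "RequestAttributesSequence" not in ds
        assert not [t for t in ds.keys() if Tag(t).is_private]
        assert "PrivateInformationCreatorUID" not in ds.file_meta
        assert ds.PixelData == pixels

    def test_stage2_requires_dirinfo(self, staged, policy):
        ds, ctx, *_ = staged
        from dicomdeid import ProtocolError
        with pytest.raises(ProtocolError):
            apply_stage2(ds, policy, ctx, None)

    def test_stage2_idempotent(self, staged, policy):
        ds, ctx, uid_map, _ = staged
        dirinfo = parse_case_dirname("CASE1 F 25_30")
        apply_stage2(ds, policy, ctx, dirinfo, uid_map)
        snapshot = ds.copy()
        apply_stage2(ds, policy, ctx, dirinfo, uid_map)
        assert ds == snapshot


class TestPipeline:
    def test_cohort_conservation_and_partitions(self, small_cohort_dir, policy, tmp_path):
        out = tmp_path / "out"
        report = deidentify_case_directory(small_cohort_dir, out, policy, seed=3)
        in_files = sorted(small_cohort_dir.rglob("*.dcm"))
        out_files = sorted(out.rglob("*.dcm"))
        assert len(out_files) == len(in_files) == report.files_scanned
        assert report.error_count == 0
        # output mirrors the input case-directory names
        assert sorted(p.name for p in out.iterdir()) == \
            sorted(p.name for p in small_cohort_dir.iterdir())
        # study/series partition preserved end to end
        def partition(files):
            groups = {}
            for f in files:
                ds = read_dataset(f)
                groups.setdefault(
                    (str(ds.StudyInstanceUID), str(ds.SeriesInstanceUID)), []
                ).append(f.name)
            return sorted(sorted(v) for v in groups.values())
        assert partition(in_files) == partition(out_files)

    def test_rerun_is_byte_identical(self, small_cohort_dir, policy, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        deidentify_case_directory(small_cohort_dir, out1, policy, seed=3)
        deidentify_case_directory(small_cohort_dir, out2, policy, seed=3)
        files1 = sorted(out1.rglob("*.dcm"))
        assert files1
        for f1 in files1:
            f2 = out2 / f1.relative_to(out1)
            assert f1.read_bytes() == f2.read_bytes()

    def test_unparsable_directory_aborts_that_case(self, small_cohort_dir, policy, tmp_path):
        root = tmp_path / "mixed"
        root.mkdir()
        good = sorted(p for p in small_cohort_dir.iterdir() if p.is_dir())[0]
        (root / good.name).mkdir()
        for f in good.iterdir():
            (root / good.name / f.name).write_bytes(f.read_bytes())
        (root / "CASEX bad name").mkdir()
        report = deidentify_case_directory(root, tmp_path / "out", policy, seed=3)
        protocol = [f for f in report.findings if f.category.value == "protocol"]
        assert len(protocol) == 1 and "CASEX bad name" in protocol[0].file
        assert report.files_scanned == len(list(good.iterdir()))

    def test_stage2_only_skips_uid_remap(self, small_cohort_dir, policy, tmp_path):
        out = tmp_path / "out"
        case = sorted(p for p in small_cohort_dir.iterdir() if p.is_dir())[0]
        deidentify_case_directory(case, out, policy, seed=3, stage2_only=True)
        ds = read_dataset(sorted((out / case.name).iterdir())[0])
        # stage 2 only: source UIDs kept, but stage-2 attributes handled
        assert str(ds.SOPInstanceUID).startswith("1.3.6.1.4.1.99999.")
        assert "IrradiationEventUID" not in ds
        assert ds.PatientAge.endswith("Y")
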