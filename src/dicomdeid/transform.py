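"""Apply a validated policy to datasets and whole case directories.

Stage 1 emulates the source (PACS export) de-identification: hierarchy
preserving Instance-UID remapping, overwrites/clears of the obvious patient
identifiers, and per-study random replacement dates and times.  Stage 2 is
the attribute-level pass: private-element and sequence removal, calibration
date/time randomisation, institution/physician clears, and re-insertion of
the sex and upper-bound age declared by the case-directory name.

Replacement dates and times are drawn once per *study* (keyed on the
remapped Study Instance UID) so a series can never predate its study, and
the whole pipeline is deterministic under (seed, salt): re-running produces
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

from pydicom.dataset import Dataset

from .audit import (
    AuditReport,
    Category,
    Finding,
    Severity,
    check_dicom_conformance,
    scan_residual_pii,
)
from .core import (
    ConfigError,
    ElementType,
    ProtocolError,
    Tag,
    TOOL_NAME,
    TOOL_VERSION,
    lookup_attribute,
    read_dataset,
    write_dataset,
)
from .folders import CaseDirInfo, age_insert_value, format_patient_age, parse_case_dirname
from .policy import Action, ActionKind, Policy, Stage, validate_policy
from .uids import UidMap, remap_uid, remap_dataset_uids

logger = logging.getLogger("dicomdeid")


# ---------------------------------------------------------------------------
# randomisation


@dataclass
class RandomizationContext:
    """Deterministic per-study replacement dates and times.

    Values are derived by hashing (seed, kind, study UID), so they do not
    depend on processing order, and are cached so every date attribute of a
    study shares one replacement date.
    """

    seed: int
    date_window: tuple[date, date] = (date(2000, 1, 1), date(2020, 12, 31))
    per_study_date: dict[str, str] = field(default_factory=dict)
    per_study_time: dict[str, str] = field(default_factory=dict)

    def _draw(self, kind: str, study_uid: str, modulus: int) -> int:
        digest = hashlib.sha256(f"{self.seed}|{kind}|{study_uid}".encode()).digest()
        return int.from_bytes(digest[:8], "big") % modulus


def random_date(ctx: RandomizationContext, study_uid: str) -> str:
    """Uniform random ``YYYYMMDD`` in the window, cached per study."""
    cached = ctx.per_study_date.get(study_uid)
    if cached is not None:
        return cached
    earliest, latest = ctx.date_window
    n_days = (latest - earliest).days + 1
    if n_days <= 0:
        raise ConfigError(f"empty date window {earliest}..{latest}")
    value = (earliest + timedelta(days=ctx._draw("date", study_uid, n_days))).strftime("%Y%m%d")
    ctx.per_study_date[study_uid] = value
    return value


def random_time(ctx: RandomizationContext, study_uid: str) -> str:
    """Uniform random ``HHMMSS``, cached per study."""
    cached = ctx.per_study_time.get(study_uid)
    if cached is not None:
        return cached
    seconds = ctx._draw("time", study_uid, 86400)
    value = f"{seconds // 3600:02d}{seconds % 3600 // 60:02d}{seconds % 60:02d}"
    ctx.per_study_time[study_uid] = value
    return value


# ---------------------------------------------------------------------------
# element-level application


def _datasets_recursive(ds: Dataset):
    """Yield *ds* and every nested sequence-item dataset."""
    stack = [ds]
    while stack:
        current = stack.pop()
        yield current
        for elem in current:
            if elem.VR == "SQ" and elem.value:
                stack.extend(elem.value)


def _container_for(ds: Dataset, tag: Tag):
    if tag.group == 0x0002:
        return getattr(ds, "file_meta", None)
    return ds


def apply_action(
    ds: Dataset,
    tag: Tag | int,
    action: Action,
    ctx: RandomizationContext | None = None,
    uid_map: UidMap | None = None,
) -> Dataset:
    """Apply one action to *tag* in *ds* (and inside sequence items).

    Clearing or overwriting an element the dataset does not carry is a
    logged no-op — scanner models differ in which attributes they emit.
    Removing a Type 1/2 attribute is refused as a policy bug.
    """
    tag = Tag(tag)
    kind = action.kind
    if kind is ActionKind.KEEP:
        return ds

    spec = lookup_attribute(tag)
    if kind is ActionKind.REMOVE and spec.element_type in (
        ElementType.T1, ElementType.T1C, ElementType.T2, ElementType.T2C
    ):
        raise ConfigError(
            f"refusing to REMOVE Type {spec.element_type.value} attribute {spec.keyword}"
        )

    containers = []
    meta_container = _container_for(ds, tag)
    if tag.group == 0x0002:
        if meta_container is not None:
            containers.append(meta_container)
    else:
        containers.extend(_datasets_recursive(ds))

    seen = False
    for container in containers:
        if tag not in container:
            continue
        seen = True
        elem = container[tag]
        if kind is ActionKind.CLEAR:
            elem.value = ""  # zero-length on write; matches read-back state
        elif kind is ActionKind.OVERWRITE:
            elem.value = action.replacement
        elif kind is ActionKind.REMOVE:
            del container[tag]
        elif kind is ActionKind.REMAP_UID:
            if uid_map is None:
                raise ConfigError("REMAP_UID action requires a UidMap")
            if elem.value:
                elem.value = remap_uid(uid_map, str(elem.value))
        elif kind in (ActionKind.RANDOM_DATE, ActionKind.RANDOM_TIME):
            if ctx is None:
                raise ConfigError(f"{kind.name} action requires a RandomizationContext")
            study_uid = str(getattr(ds, "StudyInstanceUID", ""))
            if kind is ActionKind.RANDOM_DATE:
                value = random_date(ctx, study_uid)
                if elem.VR == "DT":  # datetime attributes get date + time
                    value += random_time(ctx, study_uid)
            else:
                value = random_time(ctx, study_uid)
            elem.value = value
    if not seen and kind in (ActionKind.CLEAR, ActionKind.OVERWRITE):
        logger.debug("no-op: %s on absent element %s", kind.name, spec.keyword)
    return ds


# ---------------------------------------------------------------------------
# stages


def _apply_stage_rules(ds: Dataset, policy: Policy, stage: Stage,
                       ctx: RandomizationContext, uid_map: UidMap,
                       skip_kinds: tuple[ActionKind, ...] = ()) -> None:
    for rule in policy.rules:
        if rule.stage is not stage or rule.action.kind in skip_kinds:
            continue
        apply_action(ds, rule.tag, rule.action, ctx=ctx, uid_map=uid_map)


def apply_stage1(ds: Dataset, policy: Policy, ctx: RandomizationContext,
                 uid_map: UidMap) -> Dataset:
    """Source-export emulation: UID remap, ID/name overwrites, random dates."""
    remap_dataset_uids(uid_map, ds)  # covers the four REMAP_UID rules consistently
    _apply_stage_rules(ds, policy, Stage.STAGE1, ctx, uid_map,
                       skip_kinds=(ActionKind.REMAP_UID,))
    return ds


def apply_stage2(ds: Dataset, policy: Policy, ctx: RandomizationContext,
                 dirinfo: CaseDirInfo, uid_map: UidMap | None = None) -> Dataset:
    """Attribute-level pass plus sex/age re-insertion from the folder name."""
    if dirinfo is None:
        raise ProtocolError("stage 2 requires parsed case-directory metadata")
    _apply_stage_rules(ds, policy, Stage.STAGE2, ctx,
                       uid_map or UidMap(policy.salt))
    # fail-closed sweep of unlisted private elements
    if policy.default_private_action.kind is ActionKind.REMOVE:
        explicit = {r.tag for r in policy.rules}
        for container in _datasets_recursive(ds):
            for tag in [t for t in container.keys() if Tag(t).is_private]:
                if Tag(tag) not in explicit:
                    del container[tag]
    elif policy.default_private_action.kind is not ActionKind.KEEP:
        raise ConfigError("default_private_action must be REMOVE or KEEP")
    # re-insert the only demographics that may remain: sex and upper-bound age
    ds.PatientSex = dirinfo.sex
    ds.PatientAge = format_patient_age(age_insert_value(dirinfo))
    return ds


# ---------------------------------------------------------------------------
# batch orchestration


def _case_dirs(in_dir: Path):
    """Yield (path, CaseDirInfo | ProtocolError) for the case dirs under *in_dir*.

    *in_dir* may itself be a case directory, or a cohort root containing them.
    """
    try:
        yield in_dir, parse_case_dirname(in_dir.name)
        return
    except ProtocolError:
        pass
    for sub in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        try:
            yield sub, parse_case_dirname(sub.name)
        except ProtocolError as exc:
            yield sub, exc


def deidentify_case_directory(
    in_dir: str | Path,
    out_dir: str | Path,
    policy: Policy,
    ctx: RandomizationContext | None = None,
    uid_map: UidMap | None = None,
    stage2_only: bool = False,
    seed: int = 0,
    audit_log: str | Path | None = None,
) -> AuditReport:
    """De-identify every DICOM file under *in_dir* through both stages.

    *in_dir* is a case directory (``CASE<n> <SEX> <lo>_<hi>``) or a cohort
    root of such directories; the output tree mirrors the input names (the
    folder names are the carrier of the surviving demographics and are never
    renamed).  Each output file is re-audited (residual PII + conformance)
    and the aggregate report returned.  Unreadable files are recorded as
    findings and processing continues; a directory that does not parse
    aborts that case only.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    violations = validate_policy(policy)
    if violations:
        raise ConfigError("policy failed validation: " + "; ".join(violations))
    ctx = ctx or RandomizationContext(seed=seed, date_window=policy.date_window)
    uid_map = uid_map or UidMap(policy.salt)

    report = AuditReport()
    log_entries: list[dict] = []
    for case_dir, parsed in _case_dirs(in_dir):
        if isinstance(parsed, ProtocolError):
            report.findings.append(Finding(
                str(case_dir), "", "", Category.PROTOCOL, Severity.ERROR, str(parsed)))
            continue
        case_out = out_dir / case_dir.name
        case_out.mkdir(parents=True, exist_ok=True)
        for path in sorted(p for p in case_dir.iterdir() if p.is_file()):
            rel = f"{case_dir.name}/{path.name}"
            try:
                ds = read_dataset(path)
                if not stage2_only:
                    apply_stage1(ds, policy, ctx, uid_map)
                apply_stage2(ds, policy, ctx, parsed, uid_map)
                write_dataset(ds, case_out / path.name)
            except Exception as exc:  # keep going; record the failure
                report.findings.append(Finding(
                    rel, "", "", Category.PROTOCOL, Severity.ERROR,
                    f"processing failed: {exc}"))
                continue
            report.files_scanned += 1
            file_findings = scan_residual_pii(ds, policy, uid_map.org_root, file=rel)
            file_findings += check_dicom_conformance(ds, file=rel)
            report.findings.extend(file_findings)
            log_entries.append({
                "software": TOOL_NAME,
                "version": TOOL_VERSION,
                "file": rel,
                "stages": ["stage2"] if stage2_only else ["stage1", "stage2"],
                "findings": len(file_findings),
            })
    if audit_log is not None:
        Path(audit_log).parent.mkdir(parents=True, exist_ok=True)
        with Path(audit_log).open("w") as fh:
            for entry in log_entries:
                fh.write(json.dumps(entry) + "\n")
    return report


def audit_directory(in_dir: str | Path, policy: Policy,
                    org_root: str | None = None) -> AuditReport:
    """Scan an already de-identified tree without modifying anything."""
    in_dir = Path(in_dir)
    from .uids import DEFAULT_ORG_ROOT

    org_root = org_root or DEFAULT_ORG_ROOT
    report = AuditReport()
    for case_dir, parsed in _case_dirs(in_dir):
        if isinstance(parsed, ProtocolError):
            report.findings.append(Finding(
                str(case_dir), "", "", Category.PROTOCOL, Severity.ERROR, str(parsed)))
            continue
        for path in sorted(p for p in case_dir.iterdir() if p.is_file()):
            rel = f"{case_dir.name}/{path.name}"
            try:
                ds = read_dataset(path)
            except Exception as exc:
                report.findings.append(Finding(
                    rel, "", "", Category.PROTOCOL, Severity.ERROR,
                    f"unreadable: {exc}"))
                continue
            report.files_scanned += 1
            report.findings.extend(scan_residual_pii(ds, policy, org_root, file=rel))
            report.findings.extend(check_dicom_conformance(ds, file=rel))
    return report
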