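"""Residual-PII scanning and DICOM conformance checking.

After de-identification every attribute a policy rule targets must be in its
compliant final state: cleared rules zero-length, overwritten rules equal to
their replacement, removed rules absent, remapped UIDs under the
organisational root.  ``scan_residual_pii`` reports each deviation, plus any
surviving private element and any Instance UID that still points at the
source numbering.  ``check_dicom_conformance`` independently verifies the
structural rules (Type 1/2 presence, even lengths, padding bytes, file-meta
consistency) so that de-identified files remain standard-conforming.
"""

from __future__ import annotations

import csv
import enum
import json
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

from pydicom.dataelem import RawDataElement
from pydicom.dataset import Dataset

from .core import (
    ElementType,
    REGISTRY,
    Tag,
    lookup_attribute,
)
from .policy import ActionKind, Policy
from .uids import DEFAULT_ORG_ROOT, is_class_uid


class Category(enum.Enum):
    RESIDUAL_PII = "residual_pii"
    CONFORMANCE = "conformance"
    PROTOCOL = "protocol"


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Finding:
    file: str
    tag: str            # "(gggg,eeee)" or "" for file-level problems
    keyword: str
    category: Category
    severity: Severity
    detail: str


@dataclass
class AuditReport:
    findings: list[Finding] = field(default_factory=list)
    files_scanned: int = 0

    @property
    def summary(self) -> dict[str, int]:
        counts = {c.value: 0 for c in Category}
        for f in self.findings:
            counts[f.category.value] += 1
        return counts

    @property
    def error_count(self) -> int:
        return sum(1 for f in self.findings if f.severity is Severity.ERROR)

    @property
    def exit_code(self) -> int:
        return 0 if self.error_count == 0 else 1


def _fmt_tag(tag: Tag) -> str:
    return f"({tag.group:04x},{tag.element:04x})"


def _finding(tag: Tag, category: Category, severity: Severity, detail: str,
             file: str = "") -> Finding:
    return Finding(file, _fmt_tag(tag), lookup_attribute(tag).keyword,
                   category, severity, detail)


# ---------------------------------------------------------------------------
# residual-PII scan

_AGE_RE = re.compile(r"^\d{3}Y$")
_DATE_RE = re.compile(r"^\d{8}$")
_TIME_RE = re.compile(r"^\d{6}(\.\d+)?$")

#: sex / age carry stage-1 CLEAR rules but are legitimately re-inserted at
#: stage 2 from the folder name; only these exact shapes are accepted.
_REINSERTED_OK = {
    "PatientSex": lambda v: v in ("F", "M", "O"),
    "PatientAge": lambda v: bool(_AGE_RE.match(v)),
}

#: file-meta software identifiers: not patient data, exempt from UID checks
_UID_EXEMPT_KEYWORDS = {"ImplementationClassUID"}


def _str_value(elem) -> str:
    if elem.value is None:
        return ""
    if isinstance(elem.value, bytes):
        return elem.value.decode("ascii", "replace").rstrip("\x00 ")
    return str(elem.value)


def _iter_elements(ds: Dataset):
    """Yield (element, container) pairs over file meta, dataset and items."""
    meta = getattr(ds, "file_meta", None)
    if meta:
        for elem in meta:
            yield elem
    stack = [ds]
    while stack:
        current = stack.pop()
        for elem in current:
            yield elem
            if elem.VR == "SQ" and elem.value:
                stack.extend(elem.value)


def _rule_compliant(elem, rule, date_window, org_root) -> str | None:
    """Return a deviation description, or None when the element complies."""
    kind = rule.action.kind
    value = _str_value(elem)
    if kind is ActionKind.REMOVE:
        return "element targeted for removal is still present"
    if kind is ActionKind.CLEAR:
        if not value:
            return None
        ok = _REINSERTED_OK.get(rule.target)
        if ok and ok(value):
            return None
        return f"cleared attribute still holds a value: {value!r}"
    if kind is ActionKind.OVERWRITE:
        if value != rule.action.replacement:
            return f"expected replacement {rule.action.replacement!r}, found {value!r}"
        return None
    if kind is ActionKind.REMAP_UID:
        if not value:
            return "UID targeted for remapping is empty"
        if is_class_uid(value) or value.startswith(org_root + "."):
            return None
        return f"Instance UID {value} not remapped under {org_root}"
    if kind is ActionKind.RANDOM_DATE:
        stamp = value[:8]
        if not _DATE_RE.match(stamp):
            return f"expected a replacement date, found {value!r}"
        d = date(int(stamp[:4]), int(stamp[4:6]), int(stamp[6:8]))
        lo, hi = date_window
        if not lo <= d <= hi:
            return f"date {value!r} outside the replacement window"
        return None
    if kind is ActionKind.RANDOM_TIME:
        if not _TIME_RE.match(value):
            return f"expected a replacement time, found {value!r}"
        return None
    return None  # KEEP


def scan_residual_pii(ds: Dataset, policy: Policy,
                      org_root: str = DEFAULT_ORG_ROOT,
                      file: str = "") -> list[Finding]:
    """Scan a dataset for values that should have been de-identified.

    The dataset is inspected read-only against the *final* (post-stage-2)
    expectation of the merged policy: one finding per targeted element whose
    value is not in its compliant state, per surviving private element, and
    per non-class Instance UID that is not under *org_root*.
    """
    merged = policy.merged_rules()
    findings: list[Finding] = []
    for elem in _iter_elements(ds):
        tag = Tag(elem.tag)
        rule = merged.get(tag)
        if rule is not None:
            detail = _rule_compliant(elem, rule, policy.date_window, org_root)
            if detail:
                findings.append(_finding(tag, Category.RESIDUAL_PII,
                                         Severity.ERROR, detail, file))
            continue
        if tag.is_private:
            findings.append(_finding(
                tag, Category.RESIDUAL_PII, Severity.ERROR,
                "private element present after de-identification", file))
            continue
        spec = lookup_attribute(tag)
        value = _str_value(elem)
        if (spec.vr == "UI" and value and spec.keyword not in _UID_EXEMPT_KEYWORDS
                and not is_class_uid(value)
                and not value.startswith(org_root + ".")):
            findings.append(_finding(
                tag, Category.RESIDUAL_PII, Severity.ERROR,
                f"Instance UID {value} outside organisational root {org_root}", file))
        elif spec.vr == "PN" and value:
            # kept person-name attribute with content: suspicious, not provably PII
            findings.append(_finding(
                tag, Category.RESIDUAL_PII, Severity.WARNING,
                f"kept person-name attribute holds a value: {value!r}", file))
    return findings


# ---------------------------------------------------------------------------
# conformance check


def check_dicom_conformance(ds: Dataset, registry: dict | None = None,
                            file: str = "") -> list[Finding]:
    """Structural conformance findings for one dataset.

    Checks: Type 1 attributes present with a non-empty value, Type 2
    attributes present, UI values free of space padding (UI pads with NUL),
    byte values even-length, and file-meta Media Storage SOP Instance UID
    equal to the dataset SOP Instance UID.
    """
    registry = registry if registry is not None else REGISTRY
    findings: list[Finding] = []
    meta = getattr(ds, "file_meta", None) or {}

    def container_for(tag: Tag):
        return meta if tag.group == 0x0002 else ds

    # raw (as-encoded) pass first: padding bytes and value lengths, before
    # any element access converts the raw values and strips their padding
    for container in (meta, ds):
        if not container:
            continue
        for tag in list(container.keys()):
            item = container.get_item(tag)
            if not isinstance(item, RawDataElement) or item.value is None:
                continue
            raw = item.value
            if len(raw) % 2 != 0:
                findings.append(_finding(
                    Tag(tag), Category.CONFORMANCE, Severity.ERROR,
                    f"odd encoded value length {len(raw)}", file))
            if lookup_attribute(tag).vr == "UI" and raw.endswith(b" "):
                findings.append(_finding(
                    Tag(tag), Category.CONFORMANCE, Severity.ERROR,
                    "UI value padded with space; UI pads with a trailing NUL", file))

    for spec in registry.values():
        container = container_for(spec.tag)
        present = spec.tag in container
        if spec.element_type is ElementType.T1:
            if not present:
                findings.append(_finding(
                    spec.tag, Category.CONFORMANCE, Severity.ERROR,
                    f"Type 1 attribute {spec.keyword} absent", file))
            elif container[spec.tag].value in (None, "", b""):
                findings.append(_finding(
                    spec.tag, Category.CONFORMANCE, Severity.ERROR,
                    f"Type 1 attribute {spec.keyword} has zero-length value", file))
        elif spec.element_type is ElementType.T2 and not present:
            findings.append(_finding(
                spec.tag, Category.CONFORMANCE, Severity.ERROR,
                f"Type 2 attribute {spec.keyword} absent", file))

    for elem in _iter_elements(ds):
        tag = Tag(elem.tag)
        if elem.VR == "UI" and elem.value:
            raw = str(elem.value)
            if raw != raw.rstrip(" ") or " " in raw:
                findings.append(_finding(
                    tag, Category.CONFORMANCE, Severity.ERROR,
                    "UI value padded with space; UI pads with a trailing NUL", file))
        if isinstance(elem.value, bytes) and len(elem.value) % 2 != 0:
            findings.append(_finding(
                tag, Category.CONFORMANCE, Severity.ERROR,
                f"odd encoded value length {len(elem.value)}", file))

    if meta:
        media = str(getattr(meta, "MediaStorageSOPInstanceUID", ""))
        sop = str(getattr(ds, "SOPInstanceUID", ""))
        if media and sop and media != sop:
            findings.append(_finding(
                Tag(0x0002, 0x0003), Category.CONFORMANCE, Severity.ERROR,
                "file-meta Media Storage SOP Instance UID differs from "
                "dataset SOP Instance UID", file))
    return findings


# ---------------------------------------------------------------------------
# report output


def report_as_dict(report: AuditReport) -> dict:
    return {
        "files_scanned": report.files_scanned,
        "summary": report.summary,
        "error_count": report.error_count,
        "findings": [
            {
                "file": f.file,
                "tag": f.tag,
                "keyword": f.keyword,
                "category": f.category.value,
                "severity": f.severity.value,
                "detail": f.detail,
            }
            for f in report.findings
        ],
    }


def write_report(report: AuditReport, path: str | Path) -> int:
    """Write JSON (at *path*) and CSV (same stem, ``.csv``) renderings.

    Returns the exit code: 0 iff the report contains no ERROR findings.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report_as_dict(report), indent=2) + "\n")
    csv_path = path.with_suffix(".csv")
    with csv_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "tag", "keyword", "category", "severity", "detail"])
        for f in report.findings:
            writer.writerow([f.file, f.tag, f.keyword,
                             f.category.value, f.severity.value, f.detail])
    return report.exit_code
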