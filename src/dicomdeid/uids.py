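"""Deterministic, salted Instance-UID remapping.

Instance UIDs (SOP / Study / Series / Frame of Reference) point at a specific
patient's data and must be replaced; Class UIDs (everything under the
standard root ``1.2.840.10008`` — SOP classes, transfer syntaxes, well-known
instances) describe services and protocols, carry no patient information and
pass through unchanged.

New UIDs are derived by hashing ``salt || old-UID`` and rendering the first
16 digest bytes in decimal under an organisational root, so the same input
always maps to the same output, within and across runs, without ever storing
a re-identification table.  Losing the salt makes the mapping irreversible
by design.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

from pydicom.dataset import Dataset

from .core import ConformanceError, DicomDeidError

#: root of all standard (Class) UIDs
DICOM_STANDARD_ROOT = "1.2.840.10008"

#: default organisational root for generated UIDs: the UUID-derived arc of
#: the standard, legal without registration.  Override for site-specific
#: numbering.
DEFAULT_ORG_ROOT = "2.25"

_UID_RE = re.compile(r"^[0-9]+(\.[0-9]+)*$")


class UidError(DicomDeidError):
    """Malformed UID input."""


def _check_uid(uid: str) -> str:
    uid = str(uid)
    if not uid or len(uid) > 64 or not _UID_RE.match(uid):
        raise UidError(f"malformed UID {uid!r}")
    return uid


def is_class_uid(uid: str) -> bool:
    """True iff *uid* lives under the standard root (a Class UID)."""
    uid = _check_uid(uid)
    return uid == DICOM_STANDARD_ROOT or uid.startswith(DICOM_STANDARD_ROOT + ".")


@dataclass
class UidMap:
    """Salted deterministic old-UID -> new-UID mapping with a cache."""

    salt: str
    org_root: str = DEFAULT_ORG_ROOT
    cache: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_uid(self.org_root)

    def remap(self, old: str) -> str:
        return remap_uid(self, old)


def remap_uid(uid_map: UidMap, old: str) -> str:
    """Remap one UID; Class UIDs are fixed points.

    The new UID is ``org_root . D`` where ``D`` is the decimal rendering of
    the first 16 bytes (big-endian) of ``SHA-256(salt|old)``, truncated so
    the whole UID stays within the 64-character limit.
    """
    old = _check_uid(old)
    if is_class_uid(old):
        return old
    cached = uid_map.cache.get(old)
    if cached is not None:
        return cached
    digest = hashlib.sha256(f"{uid_map.salt}|{old}".encode()).digest()
    number = int.from_bytes(digest[:16], "big")
    new = f"{uid_map.org_root}.{number}"[:64].rstrip(".")
    uid_map.cache[old] = new
    return new


#: dataset Instance-UID attributes remapped as a consistent group
_INSTANCE_UID_KEYWORDS = (
    "SOPInstanceUID",
    "StudyInstanceUID",
    "SeriesInstanceUID",
    "FrameOfReferenceUID",  # instance-class UID: remapped fail-closed
)


def remap_dataset_uids(uid_map: UidMap, ds: Dataset) -> Dataset:
    """Remap a dataset's Instance UIDs, preserving the data-model hierarchy.

    SOP / Study / Series Instance UIDs (and Frame of Reference UID when
    present) are remapped in place; the file-meta Media Storage SOP Instance
    UID is set equal to the new SOP Instance UID.  Class-rooted UIDs
    elsewhere (SOP Class UID, Transfer Syntax UID) are untouched.
    """
    for keyword in ("SOPInstanceUID", "StudyInstanceUID", "SeriesInstanceUID"):
        if keyword not in ds or not ds[keyword].value:
            raise ConformanceError(f"Type 1 attribute {keyword} missing; cannot remap")
    for keyword in _INSTANCE_UID_KEYWORDS:
        if keyword in ds and ds[keyword].value:
            setattr(ds, keyword, remap_uid(uid_map, str(ds[keyword].value)))
    if hasattr(ds, "file_meta") and ds.file_meta is not None:
        ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    return ds
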