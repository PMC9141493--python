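"""Core DICOM element model: VR padding rules, attribute-type registry, Part-10 I/O.

The in-memory containers are pydicom's :class:`~pydicom.dataset.Dataset` /
:class:`~pydicom.dataelem.DataElement`; this module adds the two pieces a
de-identifier needs on top of them:

* the VR-aware even-length padding rules (string VRs pad with a trailing
  space, ``UI`` and ``OB`` with a trailing NUL byte), and
* a bounded attribute registry that records the *data element type*
  (1 / 1C / 2 / 2C / 3) of every attribute the de-identification policy or
  the CT Image context touches, because the legality of Clear/Remove
  operations depends on that type.

Only Explicit VR Little Endian Part-10 files are read or written; other
transfer syntaxes are rejected so that byte-level round-trip guarantees hold.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.datadict import keyword_for_tag
from pydicom.errors import InvalidDicomError
from pydicom.tag import Tag
from pydicom.uid import ExplicitVRLittleEndian

logger = logging.getLogger("dicomdeid")

TOOL_NAME = "dicomdeid"
TOOL_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# errors


class DicomDeidError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(DicomDeidError):
    """Invalid policy, VR, or tool configuration."""


class ProtocolError(DicomDeidError):
    """Violation of the case-directory naming protocol."""


class ConformanceError(DicomDeidError):
    """A dataset violates a DICOM structural requirement."""


class DicomParseError(DicomDeidError):
    """A file could not be read as a Part-10 DICOM file."""


# ---------------------------------------------------------------------------
# value-representation padding

#: string VRs that pad to even length with a trailing SPACE (0x20)
SPACE_PADDED_VRS = frozenset(
    {"AE", "AS", "CS", "DA", "DS", "DT", "IS", "LO", "LT",
     "PN", "SH", "ST", "TM", "UC", "UR", "UT"}
)
#: VRs that pad to even length with a trailing NUL (0x00)
NULL_PADDED_VRS = frozenset({"UI", "OB"})
#: VRs whose values are intrinsically even-length (fixed-width binary)
BINARY_VRS = frozenset({"US", "UL", "SS", "SL", "FL", "FD", "OW", "AT", "UN"})
SUPPORTED_VRS = SPACE_PADDED_VRS | NULL_PADDED_VRS | BINARY_VRS | {"SQ"}


def pad_value(raw: bytes | str, vr: str) -> bytes:
    """Pad *raw* to even length according to the padding rule of *vr*.

    String VRs gain a single trailing space; ``UI`` and ``OB`` gain a single
    trailing NUL byte.  Even-length input is returned unchanged, so the
    function is idempotent.  ``str`` input is encoded as ASCII first.
    """
    if vr not in SUPPORTED_VRS:
        raise ConfigError(f"unsupported VR {vr!r}: cannot determine padding rule")
    data = raw.encode("ascii") if isinstance(raw, str) else bytes(raw)
    if len(data) % 2 == 0:
        return data
    if vr in NULL_PADDED_VRS:
        return data + b"\x00"
    if vr in SPACE_PADDED_VRS:
        return data + b" "
    # fixed-width binary VRs cannot legally be odd-length
    raise ConfigError(f"VR {vr!r} value has odd length {len(data)}; no padding rule applies")


# ---------------------------------------------------------------------------
# attribute registry


class ElementType(enum.Enum):
    """DICOM data element (conformance) type for the CT Image context."""

    T1 = "1"      # must be present with a valid value
    T1C = "1C"    # conditionally required, valid value when present
    T2 = "2"      # must be present, may be zero-length
    T2C = "2C"    # conditionally required, may be zero-length
    T3 = "3"      # optional; removal is never a standard violation
    UNKNOWN = "?"


@dataclass(frozen=True)
class AttributeSpec:
    """Registry entry: tag, keyword, VR and data element type."""

    tag: Tag
    keyword: str
    vr: str
    element_type: ElementType


def _spec(group: int, elem: int, keyword: str, vr: str, et: ElementType) -> AttributeSpec:
    return AttributeSpec(Tag(group, elem), keyword, vr, et)


_T1, _T1C, _T2, _T2C, _T3 = (
    ElementType.T1, ElementType.T1C, ElementType.T2, ElementType.T2C, ElementType.T3,
)

# Bounded registry: the attributes the two-stage policy acts on, plus the
# minimal CT Image IOD set needed to write valid files.  Element types follow
# the CT Image IOD conventions of the standard.
_REGISTRY_ENTRIES = [
    # file meta (group 0002)
    _spec(0x0002, 0x0002, "MediaStorageSOPClassUID", "UI", _T1),
    _spec(0x0002, 0x0003, "MediaStorageSOPInstanceUID", "UI", _T1),
    _spec(0x0002, 0x0010, "TransferSyntaxUID", "UI", _T1),
    _spec(0x0002, 0x0012, "ImplementationClassUID", "UI", _T1),
    _spec(0x0002, 0x0013, "ImplementationVersionName", "SH", _T3),
    _spec(0x0002, 0x0016, "SourceApplicationEntityTitle", "AE", _T3),
    _spec(0x0002, 0x0100, "PrivateInformationCreatorUID", "UI", _T3),
    # 0002,0102 is conditional on 0002,0100 in the standard; the policy only
    # ever removes the pair together, which satisfies the condition.
    _spec(0x0002, 0x0102, "PrivateInformation", "OB", _T3),
    # identification / study
    _spec(0x0008, 0x0005, "SpecificCharacterSet", "CS", _T1C),
    _spec(0x0008, 0x0008, "ImageType", "CS", _T1),
    _spec(0x0008, 0x0016, "SOPClassUID", "UI", _T1),
    _spec(0x0008, 0x0018, "SOPInstanceUID", "UI", _T1),
    _spec(0x0008, 0x0020, "StudyDate", "DA", _T2),
    _spec(0x0008, 0x0021, "SeriesDate", "DA", _T3),
    _spec(0x0008, 0x0022, "AcquisitionDate", "DA", _T3),
    _spec(0x0008, 0x0023, "ContentDate", "DA", _T2C),
    _spec(0x0008, 0x002A, "AcquisitionDateTime", "DT", _T3),
    _spec(0x0008, 0x0030, "StudyTime", "TM", _T2),
    _spec(0x0008, 0x0031, "SeriesTime", "TM", _T3),
    _spec(0x0008, 0x0032, "AcquisitionTime", "TM", _T3),
    _spec(0x0008, 0x0033, "ContentTime", "TM", _T2C),
    _spec(0x0008, 0x0050, "AccessionNumber", "SH", _T2),
    _spec(0x0008, 0x0060, "Modality", "CS", _T1),
    _spec(0x0008, 0x0070, "Manufacturer", "LO", _T2),
    _spec(0x0008, 0x0080, "InstitutionName", "LO", _T3),
    _spec(0x0008, 0x0081, "InstitutionAddress", "ST", _T3),
    _spec(0x0008, 0x0090, "ReferringPhysicianName", "PN", _T2),
    _spec(0x0008, 0x1010, "StationName", "SH", _T3),
    _spec(0x0008, 0x1030, "StudyDescription", "LO", _T3),
    _spec(0x0008, 0x103E, "SeriesDescription", "LO", _T3),
    _spec(0x0008, 0x1090, "ManufacturerModelName", "LO", _T3),
    _spec(0x0008, 0x3010, "IrradiationEventUID", "UI", _T3),
    # patient
    _spec(0x0010, 0x0010, "PatientName", "PN", _T2),
    _spec(0x0010, 0x0020, "PatientID", "LO", _T2),
    _spec(0x0010, 0x0030, "PatientBirthDate", "DA", _T2),
    _spec(0x0010, 0x0040, "PatientSex", "CS", _T2),
    _spec(0x0010, 0x1010, "PatientAge", "AS", _T3),
    # acquisition
    _spec(0x0018, 0x0050, "SliceThickness", "DS", _T2),
    _spec(0x0018, 0x0060, "KVP", "DS", _T2),
    _spec(0x0018, 0x1200, "DateOfLastCalibration", "DA", _T3),
    _spec(0x0018, 0x1201, "TimeOfLastCalibration", "TM", _T3),
    _spec(0x0018, 0x5100, "PatientPosition", "CS", _T2C),
    # relationship
    _spec(0x0020, 0x000D, "StudyInstanceUID", "UI", _T1),
    _spec(0x0020, 0x000E, "SeriesInstanceUID", "UI", _T1),
    _spec(0x0020, 0x0010, "StudyID", "SH", _T2),
    _spec(0x0020, 0x0011, "SeriesNumber", "IS", _T2),
    _spec(0x0020, 0x0013, "InstanceNumber", "IS", _T2),
    _spec(0x0020, 0x0032, "ImagePositionPatient", "DS", _T1),
    _spec(0x0020, 0x0037, "ImageOrientationPatient", "DS", _T1),
    _spec(0x0020, 0x0052, "FrameOfReferenceUID", "UI", _T1),
    _spec(0x0020, 0x1040, "PositionReferenceIndicator", "LO", _T2),
    _spec(0x0020, 0x4000, "ImageComments", "LT", _T3),
    # image pixel
    _spec(0x0028, 0x0002, "SamplesPerPixel", "US", _T1),
    _spec(0x0028, 0x0004, "PhotometricInterpretation", "CS", _T1),
    _spec(0x0028, 0x0010, "Rows", "US", _T1),
    _spec(0x0028, 0x0011, "Columns", "US", _T1),
    _spec(0x0028, 0x0030, "PixelSpacing", "DS", _T1),
    _spec(0x0028, 0x0100, "BitsAllocated", "US", _T1),
    _spec(0x0028, 0x0101, "BitsStored", "US", _T1),
    _spec(0x0028, 0x0102, "HighBit", "US", _T1),
    _spec(0x0028, 0x0103, "PixelRepresentation", "US", _T1),
    _spec(0x0028, 0x1052, "RescaleIntercept", "DS", _T1),
    _spec(0x0028, 0x1053, "RescaleSlope", "DS", _T1),
    # request / procedure
    _spec(0x0040, 0x0009, "ScheduledProcedureStepID", "SH", _T3),
    _spec(0x0040, 0x0275, "RequestAttributesSequence", "SQ", _T3),
    _spec(0x0040, 0x1001, "RequestedProcedureID", "SH", _T1C),
    # pixel data
    _spec(0x7FE0, 0x0010, "PixelData", "OW", _T1),
    # private block used by the source export; the exact tag of the
    # "[Anonymization Status]" marker varies by site, the fixtures plant it
    # here so the removal rule is exercisable.
    _spec(0x0009, 0x0010, "PrivateCreator", "LO", _T3),
    _spec(0x0009, 0x1001, "AnonymizationStatus", "LO", _T3),
]

REGISTRY: dict[Tag, AttributeSpec] = {s.tag: s for s in _REGISTRY_ENTRIES}
KEYWORD_TO_TAG: dict[str, Tag] = {s.keyword: s.tag for s in _REGISTRY_ENTRIES}

# group-0002 tags live in the file meta, not the main dataset
FILE_META_GROUP = 0x0002


def lookup_attribute(tag: Tag | int | tuple[int, int]) -> AttributeSpec:
    """Total registry lookup.

    Tags outside the bounded registry come back with element type
    ``UNKNOWN``; their keyword is taken from the standard dictionary when
    available and is ``"Unknown"`` otherwise.
    """
    tag = Tag(tag)
    try:
        return REGISTRY[tag]
    except KeyError:
        keyword = keyword_for_tag(tag) or "Unknown"
        try:
            vr = pydicom.datadict.dictionary_VR(tag)
        except KeyError:
            vr = "UN"
        return AttributeSpec(tag, keyword, vr, ElementType.UNKNOWN)


def tag_for(target: str | int | Tag | tuple[int, int]) -> Tag:
    """Resolve a policy target (keyword or tag) to a :class:`Tag`."""
    if isinstance(target, str):
        try:
            return KEYWORD_TO_TAG[target]
        except KeyError:
            from pydicom.datadict import tag_for_keyword

            t = tag_for_keyword(target)
            if t is None:
                raise ConfigError(f"unknown attribute keyword {target!r}") from None
            return Tag(t)
    return Tag(target)


# ---------------------------------------------------------------------------
# Part-10 I/O


def read_dataset(path: str | Path) -> Dataset:
    """Read an Explicit VR Little Endian Part-10 file.

    Raises :class:`DicomParseError` for non-DICOM input and
    :class:`ConfigError` for any other transfer syntax.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except InvalidDicomError as exc:
        raise DicomParseError(f"not a DICOM Part-10 file: {path}") from exc
    except (OSError, EOFError, ValueError) as exc:
        raise DicomParseError(f"failed to parse {path}: {exc}") from exc
    tsuid = getattr(ds.file_meta, "TransferSyntaxUID", None)
    if tsuid != ExplicitVRLittleEndian:
        raise ConfigError(
            f"unsupported transfer syntax {tsuid} in {path}; "
            "only Explicit VR Little Endian is handled"
        )
    return ds


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write *ds* as an Explicit VR Little Endian Part-10 file."""
    path = Path(path)
    if not hasattr(ds, "file_meta") or ds.file_meta is None:
        ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.save_as(path, enforce_file_format=True)
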