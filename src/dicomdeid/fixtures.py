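"""Synthetic PHI-laden CT cohorts emulating a pre-export hospital archive.

Every pipeline stage and the auditor are exercised against generated data,
never real patients.  Each cohort member gets a full CT series whose headers
carry plausible protected health information in every attribute the
de-identification policy targets — name, MRN, birth date, accession number,
station/institution/physician names, calibration dates, a private element
block with an "[Anonymization Status]" marker, a Request Attributes
Sequence, an Irradiation Event UID — and whose Instance UIDs form a proper
patient -> study -> series -> instance hierarchy under a fictitious hospital
root, so remapping is observable.  Pixel data is synthetic noise around a
circular phantom; no text is ever rendered into the image.

Cohorts are byte-deterministic under (seed, spec).  Person and institution
names are drawn from small built-in pools.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, PYDICOM_IMPLEMENTATION_UID

from .core import write_dataset
from .folders import CaseDirInfo, age_range_for, format_case_dirname

#: fictitious hospital numbering root for the original (pre-export) UIDs
HOSPITAL_UID_ROOT = "1.3.6.1.4.1.99999"

_FIRST_NAMES = [
    "Aoife", "Brendan", "Ciara", "Declan", "Eimear", "Fionn", "Grainne",
    "Hugh", "Imelda", "James", "Kate", "Liam", "Maeve", "Niall", "Orla",
    "Padraig", "Roisin", "Sean", "Tara", "Una",
]
_LAST_NAMES = [
    "Byrne", "Kelly", "Murphy", "OBrien", "Ryan", "Walsh", "Doyle",
    "McCarthy", "Gallagher", "Doherty", "Kennedy", "Lynch", "Murray",
    "Quinn", "Moore", "Nolan",
]
_INSTITUTIONS = [
    ("Mater Hospital", "Eccles Street, Dublin 7"),
    ("St. Vincents University Hospital", "Elm Park, Dublin 4"),
    ("Cork University Hospital", "Wilton, Cork"),
    ("University Hospital Galway", "Newcastle Road, Galway"),
]


@dataclass(frozen=True)
class SyntheticPatient:
    """Ground-truth PHI planted into one synthetic case."""

    case_number: int
    sex: str
    true_age: int
    name: str            # DICOM PN form "Last^First"
    birth_date: date
    patient_id: str
    accession_number: str
    institution: str
    institution_address: str
    physician: str
    study_date: date

    @property
    def dir_info(self) -> CaseDirInfo:
        lo, hi = age_range_for(self.true_age)
        return CaseDirInfo(self.case_number, self.sex, lo, hi)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort parameters; clinical series run to 200-500 slices, tests use 8."""

    n_cases: int = 3
    slices_per_series: int | tuple[int, int] = 8
    image_size: int = 512
    seed: int = 0


def generate_patient_profile(rng: random.Random, case_number: int) -> SyntheticPatient:
    """Draw one reproducible PHI profile; identifiers embed the case number
    so they are unique within any cohort."""
    sex = rng.choices(["F", "M", "O"], weights=[48, 48, 4])[0]
    true_age = rng.randint(15, 104)
    first, last = rng.choice(_FIRST_NAMES), rng.choice(_LAST_NAMES)
    study_date = date(2021, 1, 1) + timedelta(days=rng.randrange(3 * 365))
    birth_date = study_date - timedelta(days=true_age * 365 + rng.randrange(300))
    institution, address = rng.choice(_INSTITUTIONS)
    physician = f"{rng.choice(_LAST_NAMES)}^{rng.choice(_FIRST_NAMES)}"
    return SyntheticPatient(
        case_number=case_number,
        sex=sex,
        true_age=true_age,
        name=f"{last}^{first}",
        birth_date=birth_date,
        patient_id=f"MRN{case_number:04d}{rng.randrange(1000):03d}",
        accession_number=f"ACC{case_number:04d}{rng.randrange(10000):04d}",
        institution=institution,
        institution_address=address,
        physician=physician,
        study_date=study_date,
    )


def _case_rng(spec: CohortSpec, case_number: int) -> random.Random:
    return random.Random(f"{spec.seed}|case|{case_number}")


def _pixel_array(rng_seed: int, size: int, slice_index: int) -> np.ndarray:
    """Noise background with a circular soft-tissue phantom; no burned-in text."""
    npr = np.random.default_rng(rng_seed + slice_index)
    img = npr.normal(-1000.0, 30.0, (size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    radius = size * 0.35
    disc = (yy - size / 2) ** 2 + (xx - size / 2) ** 2 < radius**2
    img[disc] = npr.normal(40.0, 15.0, int(disc.sum()))
    return np.clip(img + 1024.0, 0, 4095).astype(np.uint16)


def generate_ct_series(patient: SyntheticPatient, spec: CohortSpec) -> list[Dataset]:
    """One CT series for *patient*: shared study/series UIDs, unique SOP
    Instance UIDs, full PHI load, Explicit VR Little Endian."""
    rng = _case_rng(spec, patient.case_number)
    if isinstance(spec.slices_per_series, tuple):
        n_slices = rng.randint(*spec.slices_per_series)
    else:
        n_slices = spec.slices_per_series

    base = f"{HOSPITAL_UID_ROOT}.{spec.seed % 1000}.{patient.case_number}"
    study_uid = f"{base}.1"
    series_uid = f"{base}.2"
    frame_uid = f"{base}.4"
    irradiation_uid = f"{base}.5"
    sdate = patient.study_date.strftime("%Y%m%d")
    stime = f"{rng.randrange(7, 20):02d}{rng.randrange(60):02d}{rng.randrange(60):02d}"
    cal_date = (patient.study_date - timedelta(days=rng.randrange(30, 200))).strftime("%Y%m%d")
    cal_time = f"{rng.randrange(24):02d}{rng.randrange(60):02d}{rng.randrange(60):02d}"
    pix_seed = int.from_bytes(
        hashlib.sha256(f"{spec.seed}|pix|{patient.case_number}".encode()).digest()[:4], "big"
    )

    slices = []
    for i in range(n_slices):
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = f"{base}.3.{i + 1}"
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.ImplementationClassUID = PYDICOM_IMPLEMENTATION_UID
        meta.ImplementationVersionName = "SYNTH_EXPORT"
        meta.SourceApplicationEntityTitle = "HOSPITAL_PACS"
        meta.PrivateInformationCreatorUID = f"{HOSPITAL_UID_ROOT}.9"
        meta.PrivateInformation = b"HOSPDATA"
        ds.file_meta = meta

        ds.SpecificCharacterSet = "ISO_IR 100"
        ds.ImageType = ["ORIGINAL", "PRIMARY", "AXIAL"]
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = f"{base}.3.{i + 1}"
        ds.StudyDate = sdate
        ds.SeriesDate = sdate
        ds.AcquisitionDate = sdate
        ds.ContentDate = sdate
        ds.AcquisitionDateTime = sdate + stime
        ds.StudyTime = stime
        ds.SeriesTime = stime
        ds.AcquisitionTime = stime
        ds.ContentTime = stime
        ds.AccessionNumber = patient.accession_number
        ds.Modality = "CT"
        ds.Manufacturer = "SynthMed Imaging"
        ds.InstitutionName = patient.institution
        ds.InstitutionAddress = patient.institution_address
        ds.ReferringPhysicianName = patient.physician
        ds.StationName = f"CT_SCANNER_{patient.case_number % 4 + 1}"
        ds.StudyDescription = "CT THORAX WITH CONTRAST"
        ds.SeriesDescription = "AXIAL 5MM"
        ds.ManufacturerModelName = "SynthCT 9000"
        ds.IrradiationEventUID = irradiation_uid
        ds.PatientName = patient.name
        ds.PatientID = patient.patient_id
        ds.PatientBirthDate = patient.birth_date.strftime("%Y%m%d")
        ds.PatientSex = patient.sex
        ds.PatientAge = f"{patient.true_age:03d}Y"
        ds.SliceThickness = "5"
        ds.KVP = "120"
        ds.DateOfLastCalibration = cal_date
        ds.TimeOfLastCalibration = cal_time
        ds.PatientPosition = "HFS"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.StudyID = f"S{patient.case_number:05d}"
        ds.SeriesNumber = 1
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = ["0", "0", str(5 * i)]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.FrameOfReferenceUID = frame_uid
        ds.PositionReferenceIndicator = ""
        ds.ImageComments = f"Follow-up scan for {patient.name.replace('^', ' ')}"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows = spec.image_size
        ds.Columns = spec.image_size
        ds.PixelSpacing = ["0.7", "0.7"]
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        ds.RescaleIntercept = "-1024"
        ds.RescaleSlope = "1"

        item = Dataset()
        item.RequestedProcedureID = f"RP{patient.case_number:05d}"
        item.ScheduledProcedureStepID = f"SPS{patient.case_number:05d}"
        ds.RequestAttributesSequence = [item]

        block = ds.private_block(0x0009, "MEDI EXPORT", create=True)
        block.add_new(0x01, "LO", "NOT DEIDENTIFIED")  # "[Anonymization Status]"

        ds.PixelData = _pixel_array(pix_seed, spec.image_size, i).tobytes()
        slices.append(ds)
    return slices


def write_case(patient: SyntheticPatient, spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write one case under its protocol directory name; returns the directory."""
    case_dir = Path(out_dir) / format_case_dirname(patient.dir_info)
    case_dir.mkdir(parents=True, exist_ok=True)
    for i, ds in enumerate(generate_ct_series(patient, spec)):
        write_dataset(ds, case_dir / f"slice_{i + 1:04d}.dcm")
    return case_dir


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> list[Path]:
    """Generate the whole cohort tree; one protocol directory per case."""
    rng = random.Random(f"{spec.seed}|profiles")
    out = []
    for case_number in range(1, spec.n_cases + 1):
        patient = generate_patient_profile(rng, case_number)
        out.append(write_case(patient, spec, out_dir))
    return out
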