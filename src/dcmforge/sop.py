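"""Machinery shared by all derived-object builders.

Every derived DICOM object (Segmentation, Structured Report, bulk annotation)
needs the same plumbing: fresh SOP instance UIDs, patient/study/specimen
context copied byte-identically from the source images, references back to
those sources as evidence, and constructor-time validation against the target
information object definition (IOD).  All of that lives here.

Derived objects are immutable through this package's public interface: the
builders assemble the complete dataset in one call and expose no mutators.
Callers needing low-level edits can always drop to the pydicom layer.
"""

from __future__ import annotations

import copy
import datetime
import uuid
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import UID, ExplicitVRLittleEndian

from .errors import ContextConsistencyError

__all__ = [
    "generate_uid",
    "UidSource",
    "ContextMetadata",
    "EvidenceReference",
    "SeriesReference",
    "InstanceReference",
    "Violation",
    "ValidationReport",
    "harvest_context",
    "build_evidence",
    "validate_sop",
    "write_dataset",
    "read_dataset",
    "SOP_CLASS_UIDS",
]

#: UID root used for all generated UIDs: the UUID-derived OID arc, which
#: requires no registered organisation root.
UID_ROOT = "2.25."

SOP_CLASS_UIDS = {
    "ct_image": "1.2.840.10008.5.1.4.1.1.2",
    "sm_image": "1.2.840.10008.5.1.4.1.1.77.1.6",
    "segmentation": "1.2.840.10008.5.1.4.1.1.66.4",
    "comprehensive_sr": "1.2.840.10008.5.1.4.1.1.88.33",
    "comprehensive_3d_sr": "1.2.840.10008.5.1.4.1.1.88.34",
    "bulk_annotations": "1.2.840.10008.5.1.4.1.1.91.1",
}


def generate_uid(rng: Optional[np.random.Generator] = None) -> UID:
    """Generate a unique identifier under the ``2.25.`` UUID-derived root.

    Without ``rng`` the UID derives from a random UUID (version 4); with a
    seeded :class:`numpy.random.Generator` the 128-bit integer is drawn from
    it, making fixture generation reproducible.  Output is dotted-decimal,
    at most 64 characters, with no leading zeros in any component.
    """
    if rng is None:
        n = uuid.uuid4().int
    else:
        # two 64-bit draws -> 128-bit integer
        hi, lo = rng.integers(0, 2**64, size=2, dtype=np.uint64)
        n = (int(hi) << 64) | int(lo)
    if n == 0:
        n = 1
    return UID(UID_ROOT + str(n))


class UidSource:
    """Callable UID factory, optionally seeded for reproducibility."""

    def __init__(self, seed: Optional[int] = None):
        self._rng = None if seed is None else np.random.default_rng(seed)

    def __call__(self) -> UID:
        return generate_uid(self._rng)


# Attribute keywords copied from source images into derived objects.
PATIENT_ATTRIBUTES = (
    "PatientName",
    "PatientID",
    "PatientBirthDate",
    "PatientSex",
)
STUDY_ATTRIBUTES = (
    "StudyInstanceUID",
    "StudyID",
    "StudyDate",
    "StudyTime",
    "AccessionNumber",
    "ReferringPhysicianName",
)
SPECIMEN_ATTRIBUTES = (
    "ContainerIdentifier",
    "ContainerTypeCodeSequence",
    "SpecimenDescriptionSequence",
)


@dataclass
class ContextMetadata:
    """Patient/study(/specimen) context harvested from source images.

    ``patient``, ``study`` and ``specimen`` are pydicom datasets holding
    byte-identical copies of the corresponding source attributes.  Slide-based
    sources carry specimen attributes; patient-based sources do not.
    """

    patient: Dataset
    study: Dataset
    specimen: Optional[Dataset] = None

    @property
    def study_instance_uid(self) -> str:
        return str(self.study.StudyInstanceUID)

    def apply_to(self, ds: Dataset) -> None:
        for group in (self.patient, self.study, self.specimen):
            if group is None:
                continue
            for elem in group:
                ds[elem.tag] = copy.deepcopy(elem)


@dataclass
class InstanceReference:
    sop_class_uid: str
    sop_instance_uid: str
    frame_numbers: Optional[List[int]] = None


@dataclass
class SeriesReference:
    series_instance_uid: str
    instances: List[InstanceReference] = field(default_factory=list)


@dataclass
class EvidenceReference:
    """References to source instances, grouped study → series → instance."""

    study_instance_uid: str
    series: List[SeriesReference] = field(default_factory=list)


def _require_sources(source_datasets: Sequence[Dataset]) -> None:
    if not source_datasets:
        raise ValueError("at least one source dataset is required")


def _check_single_identity(source_datasets: Sequence[Dataset]) -> None:
    studies = {str(ds.StudyInstanceUID) for ds in source_datasets}
    patients = {str(ds.get("PatientID", "")) for ds in source_datasets}
    if len(studies) > 1:
        raise ContextConsistencyError(
            "source datasets span multiple studies: " + ", ".join(sorted(studies))
        )
    if len(patients) > 1:
        raise ContextConsistencyError(
            "source datasets span multiple patients: "
            + ", ".join(sorted(patients))
        )


def harvest_context(source_datasets: Sequence[Dataset]) -> ContextMetadata:
    """Copy the shared patient/study(/specimen) context from source images.

    All sources must agree on StudyInstanceUID and PatientID; copied values
    are deep copies, byte-identical to the sources.
    """
    _require_sources(source_datasets)
    _check_single_identity(source_datasets)
    first = source_datasets[0]

    def subset(keywords) -> Dataset:
        out = Dataset()
        for kw in keywords:
            if kw in first:
                out[kw] = copy.deepcopy(first[kw])
        return out

    specimen = subset(SPECIMEN_ATTRIBUTES)
    return ContextMetadata(
        patient=subset(PATIENT_ATTRIBUTES),
        study=subset(STUDY_ATTRIBUTES),
        specimen=specimen if len(specimen) else None,
    )


def build_evidence(source_datasets: Sequence[Dataset]) -> List[EvidenceReference]:
    """Group source instances into study → series → instance references.

    Duplicate SOP instances are dropped with a warning; every distinct input
    instance is referenced exactly once.
    """
    _require_sources(source_datasets)
    _check_single_identity(source_datasets)
    evidence = EvidenceReference(
        study_instance_uid=str(source_datasets[0].StudyInstanceUID)
    )
    seen: set = set()
    series_index: Dict[str, SeriesReference] = {}
    for ds in source_datasets:
        sop_uid = str(ds.SOPInstanceUID)
        if sop_uid in seen:
            warnings.warn(
                f"duplicate source instance {sop_uid} ignored", UserWarning,
                stacklevel=2,
            )
            continue
        seen.add(sop_uid)
        series_uid = str(ds.SeriesInstanceUID)
        if series_uid not in series_index:
            series_index[series_uid] = SeriesReference(series_uid)
            evidence.series.append(series_index[series_uid])
        series_index[series_uid].instances.append(
            InstanceReference(str(ds.SOPClassUID), sop_uid)
        )
    return [evidence]


# ---------------------------------------------------------------------------
# IOD validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    path: str
    rule: str
    severity: str = "error"
    message: str = ""

    def __str__(self) -> str:
        return f"[{self.severity}] {self.path}: {self.rule} {self.message}".rstrip()


@dataclass
class ValidationReport:
    violations: List[Violation] = field(default_factory=list)

    @property
    def errors(self) -> List[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def error(self, path: str, rule: str, message: str = "") -> None:
        self.violations.append(Violation(path, rule, "error", message))

    def warn(self, path: str, rule: str, message: str = "") -> None:
        self.violations.append(Violation(path, rule, "warning", message))


_COMMON_REQUIRED = (
    "SOPClassUID",
    "SOPInstanceUID",
    "StudyInstanceUID",
    "SeriesInstanceUID",
    "Modality",
)


def _validate_common(ds: Dataset, report: ValidationReport, expected_sop: str,
                     expected_modality: str) -> None:
    for kw in _COMMON_REQUIRED:
        if kw not in ds:
            report.error(kw, "required-attribute-missing")
    if "SOPClassUID" in ds and str(ds.SOPClassUID) != expected_sop:
        report.error("SOPClassUID", "wrong-sop-class",
                     f"expected {expected_sop}, got {ds.SOPClassUID}")
    if "Modality" in ds and str(ds.Modality) != expected_modality:
        report.error("Modality", "wrong-modality",
                     f"expected {expected_modality}")


def _validate_segmentation(ds: Dataset, report: ValidationReport) -> None:
    _validate_common(ds, report, SOP_CLASS_UIDS["segmentation"], "SEG")
    if "SegmentSequence" not in ds:
        report.error("SegmentSequence", "required-attribute-missing")
    else:
        numbers = [int(item.SegmentNumber) for item in ds.SegmentSequence]
        if numbers != list(range(1, len(numbers) + 1)):
            report.error("SegmentSequence", "segment-numbers-not-consecutive",
                         str(numbers))
        for i, item in enumerate(ds.SegmentSequence):
            for kw in ("SegmentedPropertyCategoryCodeSequence",
                       "SegmentedPropertyTypeCodeSequence",
                       "SegmentAlgorithmType", "SegmentLabel"):
                if kw not in item:
                    report.error(f"SegmentSequence[{i}].{kw}",
                                 "required-attribute-missing")
    seg_type = str(ds.get("SegmentationType", ""))
    if seg_type not in ("BINARY", "FRACTIONAL"):
        report.error("SegmentationType", "invalid-value", seg_type)
    if seg_type == "FRACTIONAL":
        if str(ds.get("SegmentationFractionalType", "")) not in (
                "PROBABILITY", "OCCUPANCY"):
            report.error("SegmentationFractionalType", "invalid-value")
        if "MaximumFractionalValue" not in ds:
            report.error("MaximumFractionalValue", "required-attribute-missing")
        elif not 1 <= int(ds.MaximumFractionalValue) <= 255:
            report.error("MaximumFractionalValue", "out-of-range")
        if int(ds.get("BitsAllocated", 0)) != 8:
            report.error("BitsAllocated", "invalid-value",
                         "FRACTIONAL requires 8")
    elif seg_type == "BINARY" and int(ds.get("BitsAllocated", 0)) != 1:
        report.error("BitsAllocated", "invalid-value", "BINARY requires 1")

    n_frames = int(ds.get("NumberOfFrames", 0))
    pffg = ds.get("PerFrameFunctionalGroupsSequence", [])
    if len(pffg) != n_frames:
        report.error("PerFrameFunctionalGroupsSequence", "frame-count-mismatch",
                     f"{len(pffg)} items for {n_frames} frames")
    n_segments = len(ds.get("SegmentSequence", []))
    for i, item in enumerate(pffg):
        sis = item.get("SegmentIdentificationSequence")
        if not sis or "ReferencedSegmentNumber" not in sis[0]:
            report.error(
                f"PerFrameFunctionalGroupsSequence[{i}]"
                ".SegmentIdentificationSequence",
                "required-attribute-missing")
        elif not 1 <= int(sis[0].ReferencedSegmentNumber) <= n_segments:
            report.error(
                f"PerFrameFunctionalGroupsSequence[{i}]"
                ".SegmentIdentificationSequence.ReferencedSegmentNumber",
                "segment-number-out-of-range")
    rows, cols = int(ds.get("Rows", 0)), int(ds.get("Columns", 0))
    if rows < 1 or cols < 1:
        report.error("Rows", "invalid-image-dimensions")
    if "PixelData" in ds and n_frames and rows and cols:
        n_bits = n_frames * rows * cols
        if seg_type == "BINARY":
            expected = (n_bits + 7) // 8
        else:
            expected = n_bits
        expected += expected % 2  # even-length padding
        if len(ds.PixelData) != expected:
            report.error("PixelData", "length-mismatch",
                         f"expected {expected} bytes, got {len(ds.PixelData)}")


_SR_VALUE_TYPES = {
    "TEXT", "CODE", "NUM", "DATETIME", "DATE", "TIME", "UIDREF", "PNAME",
    "IMAGE", "SCOORD", "SCOORD3D", "CONTAINER", "COMPOSITE",
}
_SR_RELATIONSHIPS = {
    "CONTAINS", "HAS CONCEPT MOD", "HAS OBS CONTEXT", "HAS ACQ CONTEXT",
    "INFERRED FROM", "SELECTED FROM", "HAS PROPERTIES",
}
_SCOORD3D_VERTEX_RULES = {"ELLIPSE": 4, "ELLIPSOID": 6}


def _validate_sr_item(item: Dataset, path: str, report: ValidationReport,
                      allow_scoord3d: bool, is_root: bool) -> None:
    vt = str(item.get("ValueType", ""))
    if vt not in _SR_VALUE_TYPES:
        report.error(f"{path}.ValueType", "invalid-value-type", vt)
        return
    if not is_root:
        rel = str(item.get("RelationshipType", ""))
        if rel not in _SR_RELATIONSHIPS:
            report.error(f"{path}.RelationshipType",
                         "missing-or-invalid-relationship", rel)
    if vt == "SCOORD3D" and not allow_scoord3d:
        report.error(f"{path}.ValueType", "value-type-not-permitted",
                     "SCOORD3D is not permitted in Comprehensive SR")
    if "ConceptNameCodeSequence" not in item:
        report.error(f"{path}.ConceptNameCodeSequence",
                     "required-attribute-missing")
    if vt == "NUM":
        mvs = item.get("MeasuredValueSequence")
        if not mvs:
            report.error(f"{path}.MeasuredValueSequence",
                         "required-attribute-missing")
        else:
            if "MeasurementUnitsCodeSequence" not in mvs[0]:
                report.error(
                    f"{path}.MeasuredValueSequence[0]"
                    ".MeasurementUnitsCodeSequence",
                    "required-attribute-missing")
    if vt in ("SCOORD", "SCOORD3D"):
        dim = 3 if vt == "SCOORD3D" else 2
        data = item.get("GraphicData", [])
        gtype = str(item.get("GraphicType", ""))
        if len(data) % dim:
            report.error(f"{path}.GraphicData", "coordinate-count-mismatch")
        n_pts = len(data) // dim if dim else 0
        if gtype == "POLYGON":
            first, last = data[:dim], data[-dim:]
            if n_pts < 4 or list(first) != list(last):
                report.error(f"{path}.GraphicData", "polygon-not-closed",
                             "first point must equal last point")
        required = _SCOORD3D_VERTEX_RULES.get(gtype)
        if required is not None and n_pts != required:
            report.error(f"{path}.GraphicData", "vertex-count-mismatch",
                         f"{gtype} requires {required} points, got {n_pts}")
        if vt == "SCOORD3D" and "ReferencedFrameOfReferenceUID" not in item:
            report.error(f"{path}.ReferencedFrameOfReferenceUID",
                         "required-attribute-missing")
    children = item.get("ContentSequence", [])
    if children and vt != "CONTAINER" and vt not in ("SCOORD", "SCOORD3D",
                                                     "NUM", "CODE", "IMAGE"):
        # by-reference children (e.g. SELECTED FROM) ride on graphic items;
        # general nesting is reserved for containers
        report.error(f"{path}.ContentSequence", "children-on-non-container", vt)
    for i, child in enumerate(children):
        _validate_sr_item(child, f"{path}.ContentSequence[{i}]", report,
                          allow_scoord3d, is_root=False)


def _validate_sr(ds: Dataset, report: ValidationReport,
                 allow_scoord3d: bool) -> None:
    key = "comprehensive_3d_sr" if allow_scoord3d else "comprehensive_sr"
    _validate_common(ds, report, SOP_CLASS_UIDS[key], "SR")
    if str(ds.get("ValueType", "")) != "CONTAINER":
        report.error("ValueType", "root-must-be-container")
        return
    for kw in ("ContentDate", "ContentTime", "CompletionFlag",
               "VerificationFlag"):
        if kw not in ds:
            report.error(kw, "required-attribute-missing")
    cts = ds.get("ContentTemplateSequence")
    if not cts or "TemplateIdentifier" not in cts[0]:
        report.error("ContentTemplateSequence", "required-attribute-missing")
    _validate_sr_item(ds, "", report, allow_scoord3d, is_root=True)


_ANN_GRAPHIC_TYPES = {"POINT", "POLYLINE", "POLYGON", "ELLIPSE", "RECTANGLE"}
_ANN_VARIABLE_TYPES = {"POLYLINE", "POLYGON"}


def _validate_bulk_annotations(ds: Dataset, report: ValidationReport) -> None:
    _validate_common(ds, report, SOP_CLASS_UIDS["bulk_annotations"], "ANN")
    coord_type = str(ds.get("AnnotationCoordinateType", ""))
    if coord_type not in ("2D", "3D"):
        report.error("AnnotationCoordinateType", "invalid-value", coord_type)
        return
    dim = 2 if coord_type == "2D" else 3
    groups = ds.get("AnnotationGroupSequence", [])
    if not groups:
        report.error("AnnotationGroupSequence", "required-attribute-missing")
    for i, grp in enumerate(groups):
        p = f"AnnotationGroupSequence[{i}]"
        gtype = str(grp.get("GraphicType", ""))
        if gtype not in _ANN_GRAPHIC_TYPES:
            report.error(f"{p}.GraphicType", "invalid-value", gtype)
            continue
        data = grp.get("PointCoordinatesData", b"")
        n_values = len(data) // 4 if isinstance(data, (bytes, bytearray)) \
            else len(data)
        if n_values % dim:
            report.error(f"{p}.PointCoordinatesData",
                         "coordinate-count-mismatch")
        n_points = n_values // dim
        n_annotations = int(grp.get("NumberOfAnnotations", 0))
        if gtype in _ANN_VARIABLE_TYPES:
            idx = grp.get("LongPrimitivePointIndexList", b"")
            offsets = np.frombuffer(idx, dtype="<u4") if isinstance(
                idx, (bytes, bytearray)) else np.asarray(idx)
            if len(offsets) != n_annotations:
                report.error(f"{p}.LongPrimitivePointIndexList",
                             "offset-count-mismatch")
            elif len(offsets):
                if offsets[0] != 1 or np.any(np.diff(offsets) <= 0):
                    report.error(f"{p}.LongPrimitivePointIndexList",
                                 "offsets-not-increasing-from-1")
                if offsets[-1] > n_values:
                    report.error(f"{p}.LongPrimitivePointIndexList",
                                 "offset-out-of-range")
        else:
            per = {"POINT": 1, "ELLIPSE": 4, "RECTANGLE": 4}[gtype]
            if n_points != n_annotations * per:
                report.error(f"{p}.PointCoordinatesData",
                             "vertex-count-mismatch",
                             f"{gtype} stores {per} points per annotation")
        for kw in ("AnnotationGroupNumber", "AnnotationGroupUID",
                   "AnnotationGroupLabel",
                   "AnnotationPropertyCategoryCodeSequence",
                   "AnnotationPropertyTypeCodeSequence"):
            if kw not in grp:
                report.error(f"{p}.{kw}", "required-attribute-missing")


_VALIDATORS = {
    "segmentation": _validate_segmentation,
    "comprehensive_sr": lambda ds, r: _validate_sr(ds, r, False),
    "comprehensive_3d_sr": lambda ds, r: _validate_sr(ds, r, True),
    "bulk_annotations": _validate_bulk_annotations,
}


def validate_sop(ds: Dataset, iod_id: str) -> ValidationReport:
    """Validate a dataset against the implemented subset of an IOD schema.

    ``iod_id`` must be one of ``segmentation``, ``comprehensive_sr``,
    ``comprehensive_3d_sr`` or ``bulk_annotations``.  The report is
    deterministic; builders in this package must produce empty reports.
    """
    try:
        validator = _VALIDATORS[iod_id]
    except KeyError:
        raise ValueError(
            f"unknown iod_id {iod_id!r}; expected one of {sorted(_VALIDATORS)}"
        ) from None
    report = ValidationReport()
    validator(ds, report)
    return report


# ---------------------------------------------------------------------------
# Derived-object assembly and Part-10 IO
# ---------------------------------------------------------------------------

def _now() -> Tuple[str, str]:
    t = datetime.datetime.now()
    return t.strftime("%Y%m%d"), t.strftime("%H%M%S")


def init_derived_dataset(
    iod_id: str,
    modality: str,
    context: ContextMetadata,
    *,
    series_instance_uid: Optional[str] = None,
    series_number: int = 1,
    instance_number: int = 1,
    sop_instance_uid: Optional[str] = None,
    manufacturer: str = "dcmforge",
    manufacturer_model_name: str = "dcmforge",
    software_versions: str = "0.1.0",
    device_serial_number: str = "0",
    content_date: Optional[str] = None,
    content_time: Optional[str] = None,
    uid_source: Optional[UidSource] = None,
) -> Dataset:
    """Create a dataset pre-populated with the modules common to all IODs."""
    uid_source = uid_source or UidSource()
    ds = Dataset()
    ds.SOPClassUID = SOP_CLASS_UIDS[iod_id]
    ds.SOPInstanceUID = sop_instance_uid or uid_source()
    ds.Modality = modality
    ds.SeriesInstanceUID = series_instance_uid or uid_source()
    ds.SeriesNumber = series_number
    ds.InstanceNumber = instance_number
    ds.Manufacturer = manufacturer
    ds.ManufacturerModelName = manufacturer_model_name
    ds.SoftwareVersions = software_versions
    ds.DeviceSerialNumber = device_serial_number
    date, time = _now()
    ds.ContentDate = content_date or date
    ds.ContentTime = content_time or time
    ds.SpecificCharacterSet = "ISO_IR 192"
    context.apply_to(ds)
    return ds


def attach_evidence(ds: Dataset, evidence: List[EvidenceReference],
                    keyword: str = "CurrentRequestedProcedureEvidenceSequence"
                    ) -> None:
    """Serialize evidence references onto ``ds`` under ``keyword``."""
    seq = []
    for study in evidence:
        study_item = Dataset()
        study_item.StudyInstanceUID = study.study_instance_uid
        series_seq = []
        for series in study.series:
            series_item = Dataset()
            series_item.SeriesInstanceUID = series.series_instance_uid
            inst_seq = []
            for inst in series.instances:
                inst_item = Dataset()
                inst_item.ReferencedSOPClassUID = inst.sop_class_uid
                inst_item.ReferencedSOPInstanceUID = inst.sop_instance_uid
                if inst.frame_numbers:
                    inst_item.ReferencedFrameNumber = inst.frame_numbers
                inst_seq.append(inst_item)
            series_item.ReferencedSOPSequence = inst_seq
            series_seq.append(series_item)
        study_item.ReferencedSeriesSequence = series_seq
        seq.append(study_item)
    setattr(ds, keyword, seq)


def write_dataset(ds: Dataset, path) -> None:
    """Write a dataset as a DICOM Part-10 file.

    Explicit VR Little Endian transfer syntax, UTF-8 character set, standard
    128-byte preamble and file meta group.
    """
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)


def read_dataset(path) -> Dataset:
    """Read a DICOM Part-10 file."""
    import pydicom

    return pydicom.dcmread(path)
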