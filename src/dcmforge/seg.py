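"""Encoding and decoding of DICOM Segmentation images.

A Segmentation (SEG) object stores raster masks as a multi-frame image.  Each
*segment* is one labeled entity — a semantic class or an instance — described
by coded concepts (property category and type) and the algorithm that
produced it.  Segments are stored either as BINARY bit planes (1 bit/pixel,
bit-packed) or as FRACTIONAL frames (8 bits/pixel) whose stored integers
``0..MaximumFractionalValue`` map to probabilities or partial-volume
occupancies in ``[0, 1]``.

Encoding accepts boolean stacks, integer label maps (value ``k`` → segment
``k``, 0 = background) or float probability maps, one frame per source image
frame.  All-background frames are omitted by default ("sparse" storage);
the multi-frame dimension index records, per encoded frame, the referenced
segment number and source plane so that decoding can restore omitted frames
as background and is independent of physical frame order.

Decoding follows four steps: locate the encoded frames relevant to the
requested segments and source frames via the dimension index; sort them to
match the query; fill in omitted background frames with zeros; and optionally
collapse binary segments into a single multi-class label map.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from pydicom.dataset import Dataset
from pydicom.tag import Tag

from . import sop
from .coding import CodedConcept, concepts_equal
from .errors import FramingError, SegmentOverlapError, ValidationFailure

__all__ = [
    "AlgorithmIdentification",
    "SegmentDescription",
    "SegmentationParams",
    "SegmentationType",
    "FractionalType",
    "AlgorithmType",
    "encode_segmentation",
    "pack_bits",
    "unpack_bits",
    "quantize_fraction",
    "find_segments",
    "read_segment_descriptions",
    "reconstruct_mask",
]


class SegmentationType(str, Enum):
    BINARY = "BINARY"
    FRACTIONAL = "FRACTIONAL"


class FractionalType(str, Enum):
    PROBABILITY = "PROBABILITY"
    OCCUPANCY = "OCCUPANCY"


class AlgorithmType(str, Enum):
    AUTOMATIC = "AUTOMATIC"
    SEMIAUTOMATIC = "SEMIAUTOMATIC"
    MANUAL = "MANUAL"


@dataclass(frozen=True)
class AlgorithmIdentification:
    name: str
    version: str
    parameters: Optional[dict] = None


@dataclass(frozen=True)
class SegmentDescription:
    """Semantics of one segment: what it depicts and how it was produced."""

    segment_number: int
    label: str
    property_category: CodedConcept
    property_type: CodedConcept
    algorithm_type: AlgorithmType = AlgorithmType.AUTOMATIC
    algorithm_identification: Optional[AlgorithmIdentification] = None
    tracking_id: Optional[str] = None
    tracking_uid: Optional[str] = None

    def __post_init__(self):
        if self.segment_number < 1:
            raise ValueError("segment_number must be >= 1")
        if (AlgorithmType(self.algorithm_type) != AlgorithmType.MANUAL
                and self.algorithm_identification is None):
            raise ValueError(
                "algorithm_identification is required unless "
                "algorithm_type is MANUAL"
            )
        if (self.tracking_id is None) != (self.tracking_uid is None):
            raise ValueError("tracking_id and tracking_uid go together")

    def to_item(self) -> Dataset:
        item = Dataset()
        item.SegmentNumber = self.segment_number
        item.SegmentLabel = self.label
        item.SegmentedPropertyCategoryCodeSequence = [
            self.property_category.to_dataset()
        ]
        item.SegmentedPropertyTypeCodeSequence = [
            self.property_type.to_dataset()
        ]
        item.SegmentAlgorithmType = AlgorithmType(self.algorithm_type).value
        if self.algorithm_identification is not None:
            item.SegmentAlgorithmName = self.algorithm_identification.name
            # version/parameters ride in the free-text description attribute
            item.SegmentDescription = json.dumps({
                "version": self.algorithm_identification.version,
                "parameters": self.algorithm_identification.parameters,
            })
        if self.tracking_id is not None:
            item.TrackingID = self.tracking_id
            item.TrackingUID = self.tracking_uid
        return item

    @classmethod
    def from_item(cls, item: Dataset) -> "SegmentDescription":
        algo = None
        if "SegmentAlgorithmName" in item:
            version, params = "", None
            if "SegmentDescription" in item:
                try:
                    meta = json.loads(str(item.SegmentDescription))
                    version = meta.get("version", "")
                    params = meta.get("parameters")
                except (ValueError, TypeError):
                    pass
            algo = AlgorithmIdentification(
                str(item.SegmentAlgorithmName), version, params)
        return cls(
            segment_number=int(item.SegmentNumber),
            label=str(item.SegmentLabel),
            property_category=CodedConcept.from_dataset(
                item.SegmentedPropertyCategoryCodeSequence[0]),
            property_type=CodedConcept.from_dataset(
                item.SegmentedPropertyTypeCodeSequence[0]),
            algorithm_type=AlgorithmType(str(item.SegmentAlgorithmType)),
            algorithm_identification=algo,
            tracking_id=(str(item.TrackingID)
                         if "TrackingID" in item else None),
            tracking_uid=(str(item.TrackingUID)
                          if "TrackingUID" in item else None),
        )


@dataclass(frozen=True)
class SegmentationParams:
    """Encoding policy: binary vs fractional, quantization, sparsity."""

    segmentation_type: SegmentationType = SegmentationType.BINARY
    fractional_type: Optional[FractionalType] = None
    max_fractional_value: int = 255
    omit_empty_frames: bool = True

    def __post_init__(self):
        st = SegmentationType(self.segmentation_type)
        if st == SegmentationType.FRACTIONAL:
            if self.fractional_type is None:
                raise ValueError(
                    "fractional_type is required for FRACTIONAL segmentations")
        elif self.fractional_type is not None:
            raise ValueError(
                "fractional_type is only valid for FRACTIONAL segmentations")
        if not 1 <= self.max_fractional_value <= 255:
            raise ValueError("max_fractional_value must be in 1..255")


# ---------------------------------------------------------------------------
# Bit packing
# ---------------------------------------------------------------------------

def pack_bits(planes: np.ndarray) -> bytes:
    """Bit-pack a boolean frame stack for BINARY pixel data.

    Bit ``k`` of byte ``b`` encodes pixel ``8*b + k`` of the row-major
    flattened stack (least-significant bit first).  Frames are concatenated
    without per-frame byte alignment; the final byte is zero-padded and the
    total length is padded to an even number of bytes.
    """
    arr = np.asarray(planes)
    if arr.dtype != bool:
        raise TypeError("pack_bits requires a boolean array")
    packed = np.packbits(arr.ravel(order="C"), bitorder="little").tobytes()
    if len(packed) % 2:
        packed += b"\x00"
    return packed


def unpack_bits(data: bytes, n_frames: int, rows: int, cols: int
                ) -> np.ndarray:
    """Inverse of :func:`pack_bits`; raises FramingError on length mismatch."""
    total_bits = n_frames * rows * cols
    n_bytes = (total_bits + 7) // 8
    padded = n_bytes + (n_bytes % 2)
    if len(data) not in (n_bytes, padded):
        raise FramingError(
            f"expected {n_bytes} (or even-padded {padded}) bytes for "
            f"{n_frames}x{rows}x{cols} bits, got {len(data)}"
        )
    bits = np.unpackbits(
        np.frombuffer(data[:n_bytes], dtype=np.uint8),
        bitorder="little", count=total_bits,
    )
    return bits.reshape(n_frames, rows, cols).astype(bool)


def quantize_fraction(p: np.ndarray, max_fractional_value: int) -> np.ndarray:
    """Quantize probabilities in [0,1] to stored integers, round-half-up."""
    return np.floor(np.asarray(p, dtype=float) * max_fractional_value
                    + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _normalize_pixel_array(pixel_array: np.ndarray,
                           descriptions: Sequence[SegmentDescription],
                           params: SegmentationParams) -> np.ndarray:
    """Return a (frames, rows, cols, segments) stack of bool or float."""
    arr = np.asarray(pixel_array)
    n_seg = len(descriptions)
    is_fractional = (SegmentationType(params.segmentation_type)
                     == SegmentationType.FRACTIONAL)
    if arr.ndim not in (3, 4):
        raise ValueError(
            "pixel_array must be (frames, rows, cols[, segments])")
    if np.issubdtype(arr.dtype, np.floating):
        if not is_fractional:
            raise TypeError(
                "floating point masks require FRACTIONAL segmentation type")
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("floating point mask values must lie in [0, 1]")
        stack = arr[..., np.newaxis] if arr.ndim == 3 else arr
    elif arr.dtype == bool:
        stack = arr[..., np.newaxis] if arr.ndim == 3 else arr
    elif np.issubdtype(arr.dtype, np.integer):
        if arr.ndim == 4:
            if arr.size and arr.max() > 1:
                raise ValueError(
                    "4D integer masks must be binary per segment plane")
            stack = arr.astype(bool)
        else:
            if arr.size and int(arr.max()) > n_seg:
                raise ValueError(
                    f"label map contains value {int(arr.max())} but only "
                    f"{n_seg} segment descriptions were provided")
            stack = np.stack(
                [arr == k for k in range(1, n_seg + 1)], axis=-1)
    else:
        raise TypeError(f"unsupported mask dtype {arr.dtype}")
    if stack.shape[-1] != n_seg:
        raise ValueError(
            f"mask encodes {stack.shape[-1]} segments but "
            f"{n_seg} descriptions were provided")
    return stack


def _source_frame_entries(source_images: Sequence[Dataset]
                          ) -> Tuple[List[Dataset], bool]:
    """Expand sources into per-plane reference entries.

    Returns (entries, is_tiled); each entry is a per-frame dataset holding
    SourceImageSequence and the appropriate plane position sequence.
    """
    if len(source_images) == 1 and int(
            source_images[0].get("NumberOfFrames", 1)) > 1:
        src = source_images[0]
        n = int(src.NumberOfFrames)
        entries = []
        for f in range(1, n + 1):
            entry = Dataset()
            ref = Dataset()
            ref.ReferencedSOPClassUID = src.SOPClassUID
            ref.ReferencedSOPInstanceUID = src.SOPInstanceUID
            ref.ReferencedFrameNumber = f
            _set_purpose(ref)
            deriv = Dataset()
            deriv.SourceImageSequence = [ref]
            entry.DerivationImageSequence = [deriv]
            src_pffg = src.PerFrameFunctionalGroupsSequence[f - 1]
            entry.PlanePositionSlideSequence = copy.deepcopy(
                src_pffg.PlanePositionSlideSequence)
            entries.append(entry)
        return entries, True
    entries = []
    orientations = {
        tuple(round(float(v), 9) for v in ds.ImageOrientationPatient)
        for ds in source_images
    }
    if len(orientations) > 1:
        raise ValueError(
            "source images have varying orientation; such inputs are rejected")
    for ds in source_images:
        entry = Dataset()
        ref = Dataset()
        ref.ReferencedSOPClassUID = ds.SOPClassUID
        ref.ReferencedSOPInstanceUID = ds.SOPInstanceUID
        _set_purpose(ref)
        deriv = Dataset()
        deriv.SourceImageSequence = [ref]
        entry.DerivationImageSequence = [deriv]
        pos = Dataset()
        pos.ImagePositionPatient = list(ds.ImagePositionPatient)
        entry.PlanePositionSequence = [pos]
        entries.append(entry)
    return entries, False


def _set_purpose(ref: Dataset) -> None:
    purpose = Dataset()
    purpose.CodeValue = "121322"
    purpose.CodingSchemeDesignator = "DCM"
    purpose.CodeMeaning = "Source image for image processing operation"
    ref.PurposeOfReferenceCodeSequence = [purpose]


def encode_segmentation(
    pixel_array: np.ndarray,
    source_images: Sequence[Dataset],
    descriptions: Sequence[SegmentDescription],
    params: SegmentationParams = SegmentationParams(),
    *,
    series_instance_uid: Optional[str] = None,
    series_number: int = 100,
    instance_number: int = 1,
    uid_source: Optional[sop.UidSource] = None,
) -> Dataset:
    """Encode a mask stack as a DICOM Segmentation image.

    ``pixel_array`` frames align 1:1, in order, with the provided source
    frames (one single-frame dataset per plane, or one tiled multi-frame
    dataset).  Segment numbers in ``descriptions`` must be 1..N consecutive.
    The built object passes :func:`dcmforge.sop.validate_sop`.
    """
    descriptions = list(descriptions)
    numbers = [d.segment_number for d in descriptions]
    if numbers != list(range(1, len(numbers) + 1)):
        raise ValueError("segment numbers must be consecutive from 1")
    params = params if isinstance(params, SegmentationParams) else \
        SegmentationParams(**params)
    stack = _normalize_pixel_array(pixel_array, descriptions, params)
    n_frames_src, rows, cols, n_seg = stack.shape

    entries, is_tiled = _source_frame_entries(source_images)
    if len(entries) != n_frames_src:
        raise ValueError(
            f"mask has {n_frames_src} frames but sources provide "
            f"{len(entries)} planes")
    src0 = source_images[0]
    if int(src0.Rows) != rows or int(src0.Columns) != cols:
        raise ValueError("mask rows/cols do not match the source images")

    is_fractional = (SegmentationType(params.segmentation_type)
                     == SegmentationType.FRACTIONAL)
    if is_fractional:
        if stack.dtype == bool:
            stored_stack = stack.astype(np.uint8) * params.max_fractional_value
        else:
            stored_stack = quantize_fraction(stack, params.max_fractional_value)
    else:
        stored_stack = stack.astype(bool)

    # collect frames sorted by (segment number, source plane index)
    frame_planes: List[np.ndarray] = []
    frame_meta: List[Tuple[int, int]] = []
    for s in range(1, n_seg + 1):
        for f in range(n_frames_src):
            plane = stored_stack[f, :, :, s - 1]
            if params.omit_empty_frames and not plane.any():
                continue
            frame_planes.append(plane)
            frame_meta.append((s, f))
    if not frame_planes:
        raise ValueError(
            "every frame is empty after quantization; an object with zero "
            "frames is not emitted — disable omit_empty_frames to encode "
            "explicit background frames")

    context = sop.harvest_context(source_images)
    ds = sop.init_derived_dataset(
        "segmentation", "SEG", context,
        series_instance_uid=series_instance_uid,
        series_number=series_number, instance_number=instance_number,
        uid_source=uid_source,
    )
    ds.ImageType = ["DERIVED", "PRIMARY"]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelRepresentation = 0
    ds.LossyImageCompression = "00"
    ds.Rows = rows
    ds.Columns = cols
    ds.ContentLabel = "SEGMENTATION"
    ds.SegmentationType = SegmentationType(params.segmentation_type).value
    if is_fractional:
        ds.SegmentationFractionalType = FractionalType(
            params.fractional_type).value
        ds.MaximumFractionalValue = params.max_fractional_value
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
    else:
        ds.BitsAllocated = 1
        ds.BitsStored = 1
        ds.HighBit = 0
    if "FrameOfReferenceUID" in src0:
        ds.FrameOfReferenceUID = src0.FrameOfReferenceUID
    ds.SegmentSequence = [d.to_item() for d in descriptions]

    # dimension organization: (segment number, plane position)
    org_uid = (uid_source or sop.UidSource())()
    org = Dataset()
    org.DimensionOrganizationUID = org_uid
    ds.DimensionOrganizationSequence = [org]
    dim_seg = Dataset()
    dim_seg.DimensionOrganizationUID = org_uid
    dim_seg.DimensionIndexPointer = Tag("ReferencedSegmentNumber")
    dim_seg.FunctionalGroupPointer = Tag("SegmentIdentificationSequence")
    dim_pos = Dataset()
    dim_pos.DimensionOrganizationUID = org_uid
    if is_tiled:
        dim_pos.DimensionIndexPointer = Tag("RowPositionInTotalImagePixelMatrix")
        dim_pos.FunctionalGroupPointer = Tag("PlanePositionSlideSequence")
    else:
        dim_pos.DimensionIndexPointer = Tag("ImagePositionPatient")
        dim_pos.FunctionalGroupPointer = Tag("PlanePositionSequence")
    ds.DimensionIndexSequence = [dim_seg, dim_pos]

    shared = Dataset()
    measures = Dataset()
    if is_tiled:
        src_shared = src0.SharedFunctionalGroupsSequence[0]
        measures.PixelSpacing = list(
            src_shared.PixelMeasuresSequence[0].PixelSpacing)
        ds.ImageOrientationSlide = list(src0.ImageOrientationSlide)
        ds.TotalPixelMatrixOriginSequence = copy.deepcopy(
            src0.TotalPixelMatrixOriginSequence)
    else:
        measures.PixelSpacing = list(src0.PixelSpacing)
        if "SliceThickness" in src0:
            measures.SliceThickness = src0.SliceThickness
        orient = Dataset()
        orient.ImageOrientationPatient = list(src0.ImageOrientationPatient)
        shared.PlaneOrientationSequence = [orient]
    shared.PixelMeasuresSequence = [measures]
    ds.SharedFunctionalGroupsSequence = [shared]

    pffg = []
    for seg_number, plane_idx in frame_meta:
        item = copy.deepcopy(entries[plane_idx])
        ident = Dataset()
        ident.ReferencedSegmentNumber = seg_number
        item.SegmentIdentificationSequence = [ident]
        content = Dataset()
        content.DimensionIndexValues = [seg_number, plane_idx + 1]
        item.FrameContentSequence = [content]
        pffg.append(item)
    ds.PerFrameFunctionalGroupsSequence = pffg
    ds.NumberOfFrames = len(frame_planes)

    if is_fractional:
        data = np.stack(frame_planes).astype(np.uint8).tobytes()
        if len(data) % 2:
            data += b"\x00"
        ds.PixelData = data
    else:
        ds.PixelData = pack_bits(np.stack(frame_planes))

    # reference every source instance (incl. frames omitted from pixel data)
    evidence = sop.build_evidence(source_images)
    ref_series = []
    for study in evidence:
        for series in study.series:
            s_item = Dataset()
            s_item.SeriesInstanceUID = series.series_instance_uid
            refs = []
            for inst in series.instances:
                r = Dataset()
                r.ReferencedSOPClassUID = inst.sop_class_uid
                r.ReferencedSOPInstanceUID = inst.sop_instance_uid
                if is_tiled:
                    # record the full source frame range so decoding can
                    # distinguish omitted planes from unknown ones
                    r.ReferencedFrameNumber = list(
                        range(1, int(src0.NumberOfFrames) + 1))
                refs.append(r)
            s_item.ReferencedInstanceSequence = refs
            ref_series.append(s_item)
    ds.ReferencedSeriesSequence = ref_series
    if is_tiled:
        ds.TotalPixelMatrixRows = src0.TotalPixelMatrixRows
        ds.TotalPixelMatrixColumns = src0.TotalPixelMatrixColumns

    report = sop.validate_sop(ds, "segmentation")
    if not report.is_valid:
        raise ValidationFailure(report)
    return ds


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def read_segment_descriptions(seg_dataset: Dataset
                              ) -> List[SegmentDescription]:
    return [SegmentDescription.from_item(item)
            for item in seg_dataset.SegmentSequence]


def find_segments(
    seg_dataset: Dataset,
    label: Optional[str] = None,
    property_category: Optional[CodedConcept] = None,
    property_type: Optional[CodedConcept] = None,
    tracking_uid: Optional[str] = None,
) -> List[int]:
    """Segment numbers matching all supplied filters, ascending."""
    out = []
    for desc in read_segment_descriptions(seg_dataset):
        if label is not None and desc.label != label:
            continue
        if property_category is not None and not concepts_equal(
                desc.property_category, property_category):
            continue
        if property_type is not None and not concepts_equal(
                desc.property_type, property_type):
            continue
        if tracking_uid is not None and desc.tracking_uid != tracking_uid:
            continue
        out.append(desc.segment_number)
    return sorted(out)


def _frame_source_key(pffg_item: Dataset):
    ref = pffg_item.DerivationImageSequence[0].SourceImageSequence[0]
    if "ReferencedFrameNumber" in ref:
        return int(ref.ReferencedFrameNumber)
    return str(ref.ReferencedSOPInstanceUID)


def _referenced_source_keys(seg_dataset: Dataset) -> Optional[set]:
    """All source plane keys the SEG claims to derive from, if recorded."""
    keys: set = set()
    for series in seg_dataset.get("ReferencedSeriesSequence", []):
        for inst in series.get("ReferencedInstanceSequence", []):
            if "ReferencedFrameNumber" in inst:
                frames = inst.ReferencedFrameNumber
                try:
                    keys.update(int(f) for f in frames)
                except TypeError:
                    keys.add(int(frames))
            else:
                keys.add(str(inst.ReferencedSOPInstanceUID))
    return keys or None


def _stored_planes(seg_dataset: Dataset) -> np.ndarray:
    n = int(seg_dataset.NumberOfFrames)
    rows, cols = int(seg_dataset.Rows), int(seg_dataset.Columns)
    data = bytes(seg_dataset.PixelData)
    if str(seg_dataset.SegmentationType) == "BINARY":
        return unpack_bits(data, n, rows, cols)
    total = n * rows * cols
    if len(data) < total:
        raise FramingError(
            f"expected {total} bytes of fractional data, got {len(data)}")
    return np.frombuffer(data[:total], dtype=np.uint8).reshape(n, rows, cols)


def reconstruct_mask(
    seg_dataset: Dataset,
    source_frames: Sequence[Union[str, int]],
    segment_numbers: Optional[Sequence[int]] = None,
    combine: bool = False,
    allow_overlap: bool = False,
    rescale_fractional: bool = False,
) -> np.ndarray:
    """Reassemble a mask for the requested source frames and segments.

    ``source_frames`` identifies planes either by source SOP instance UID
    (single-frame sources) or by 1-based source frame number (tiled
    sources), in the desired output order.  The result has shape
    ``(len(source_frames), rows, cols, len(segments))`` — or
    ``(len(source_frames), rows, cols)`` when ``combine`` is true, in which
    case pixels carry the owning segment number (0 = background).  Planes
    omitted at encode time come back as background.

    FRACTIONAL values are returned as stored integers unless
    ``rescale_fractional``, which divides by MaximumFractionalValue.
    """
    is_binary = str(seg_dataset.SegmentationType) == "BINARY"
    all_numbers = [int(i.SegmentNumber) for i in seg_dataset.SegmentSequence]
    if segment_numbers is None:
        segment_numbers = all_numbers
    segment_numbers = list(segment_numbers)
    unknown = sorted(set(segment_numbers) - set(all_numbers))
    if unknown:
        raise LookupError(f"unknown segment numbers: {unknown}")

    valid_keys = _referenced_source_keys(seg_dataset)
    if valid_keys is not None:
        missing = [k for k in source_frames if k not in valid_keys]
        if missing:
            raise LookupError(
                f"requested source frames not referenced by this "
                f"segmentation: {missing}")

    planes = _stored_planes(seg_dataset)
    rows, cols = planes.shape[1:]
    # dimension-index lookup: (segment number, source plane key) -> frame idx
    index = {}
    for i, item in enumerate(seg_dataset.PerFrameFunctionalGroupsSequence):
        seg_no = int(item.SegmentIdentificationSequence[0]
                     .ReferencedSegmentNumber)
        index[(seg_no, _frame_source_key(item))] = i

    query_positions = {}
    for pos, key in enumerate(source_frames):
        query_positions.setdefault(key, []).append(pos)

    out_dtype = bool if is_binary else np.uint8
    out = np.zeros((len(source_frames), rows, cols, len(segment_numbers)),
                   dtype=out_dtype)
    for j, seg_no in enumerate(segment_numbers):
        for key, positions in query_positions.items():
            i = index.get((seg_no, key))
            if i is None:
                continue  # omitted background plane
            for pos in positions:
                out[pos, :, :, j] = planes[i]

    if combine:
        if not is_binary:
            raise ValueError(
                "combining into a label map is only defined for BINARY "
                "segmentations")
        occupancy = out.sum(axis=-1)
        if not allow_overlap and np.any(occupancy > 1):
            raise SegmentOverlapError(
                "segments overlap; pass allow_overlap=True to resolve by "
                "highest segment number")
        label_map = np.zeros(out.shape[:3], dtype=np.int64)
        # ascending segment number: highest wins on permitted overlap
        for j in np.argsort(segment_numbers):
            label_map[out[:, :, :, j]] = segment_numbers[j]
        return label_map

    if rescale_fractional and not is_binary:
        return out.astype(float) / float(seg_dataset.MaximumFractionalValue)
    return out
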