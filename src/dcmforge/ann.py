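"""Microscopy Bulk Simple Annotations (ANN) encoding and decoding.

Whole-slide object detection routinely yields millions of cell- or
nucleus-level graphics — far too many for the deeply nested SR content tree.
The bulk annotation object stores them flat: per *annotation group* (one
coded category/type, one graphic type), all vertex coordinates are
concatenated into a single float32 array, with a 1-based index-offset list
marking the first value of each graphic for variable-length graphic types
(POLYLINE, POLYGON).  Fixed-size types (POINT, ELLIPSE, RECTANGLE) need no
offsets: their graphic boundaries follow from the fixed vertex count.

Coordinates are stored single-precision; callers needing sub-float32
placement accuracy should pre-round their inputs accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence

import numpy as np
from pydicom.dataset import Dataset

from . import sop
from .coding import CodedConcept, concepts_equal
from .errors import ValidationFailure, VertexCountError

__all__ = [
    "AnnotationGraphicType",
    "GenerationType",
    "AnnotationGroup",
    "offsets_from_counts",
    "counts_from_offsets",
    "encode_bulk_annotations",
    "decode_graphics",
    "find_annotation_groups",
    "read_annotation_groups",
]


class AnnotationGraphicType(str, Enum):
    POINT = "POINT"
    POLYLINE = "POLYLINE"
    POLYGON = "POLYGON"
    ELLIPSE = "ELLIPSE"
    RECTANGLE = "RECTANGLE"


class GenerationType(str, Enum):
    AUTOMATIC = "AUTOMATIC"
    SEMIAUTOMATIC = "SEMIAUTOMATIC"
    MANUAL = "MANUAL"


_FIXED_VERTEX_COUNTS = {
    AnnotationGraphicType.POINT: 1,
    AnnotationGraphicType.ELLIPSE: 4,
    AnnotationGraphicType.RECTANGLE: 4,
}
_MIN_VERTEX_COUNTS = {
    AnnotationGraphicType.POLYLINE: 2,
    AnnotationGraphicType.POLYGON: 3,
}


def offsets_from_counts(vertex_counts: Sequence[int], dim: int) -> np.ndarray:
    """1-based offsets into the flat value list from per-graphic counts."""
    counts = np.asarray(vertex_counts, dtype=np.int64)
    return np.concatenate([[1], 1 + np.cumsum(counts * dim)[:-1]])


def counts_from_offsets(offsets: Sequence[int], n_values: int,
                        dim: int) -> np.ndarray:
    """Per-graphic vertex counts from 1-based offsets (inverse of the above)."""
    off = np.asarray(offsets, dtype=np.int64)
    ends = np.concatenate([off[1:], [n_values + 1]])
    values = ends - off
    if np.any(values % dim):
        raise ValueError("offsets do not align with coordinate dimensionality")
    return values // dim


@dataclass
class AnnotationGroup:
    """One homogeneous collection of vector graphics on a slide image."""

    group_number: int
    label: str
    property_category: CodedConcept
    property_type: CodedConcept
    graphic_type: AnnotationGraphicType
    graphics: List[np.ndarray]
    coordinate_dimensionality: int = 2
    generation_type: GenerationType = GenerationType.AUTOMATIC
    uid: Optional[str] = None

    def __post_init__(self):
        if self.group_number < 1:
            raise ValueError("group_number must be >= 1")
        if not self.graphics:
            raise ValueError("annotation group must contain >=1 graphic")
        if self.coordinate_dimensionality not in (2, 3):
            raise ValueError("coordinate_dimensionality must be 2 or 3")
        gtype = AnnotationGraphicType(self.graphic_type)
        dim = self.coordinate_dimensionality
        checked = []
        for i, g in enumerate(self.graphics):
            arr = np.atleast_2d(np.asarray(g, dtype=np.float32))
            if arr.shape[1] != dim:
                raise ValueError(
                    f"graphic {i} has dimensionality {arr.shape[1]}, "
                    f"group declares {dim}")
            n = len(arr)
            fixed = _FIXED_VERTEX_COUNTS.get(gtype)
            if fixed is not None and n != fixed:
                raise VertexCountError(
                    f"{gtype.value} graphics require {fixed} vertices, "
                    f"graphic {i} has {n}")
            minimum = _MIN_VERTEX_COUNTS.get(gtype)
            if minimum is not None and n < minimum:
                raise VertexCountError(
                    f"{gtype.value} graphics require >= {minimum} vertices, "
                    f"graphic {i} has {n}")
            checked.append(arr)
        self.graphics = checked

    @property
    def point_data(self) -> np.ndarray:
        """Flat float32 coordinate array (the bulk storage form)."""
        return np.concatenate([g.ravel() for g in self.graphics]).astype(
            np.float32)

    @property
    def index_offsets(self) -> Optional[np.ndarray]:
        """1-based offsets of each graphic, or None for fixed-size types."""
        if AnnotationGraphicType(self.graphic_type) not in _MIN_VERTEX_COUNTS:
            return None
        return offsets_from_counts([len(g) for g in self.graphics],
                                   self.coordinate_dimensionality)

    def to_item(self, uid_source: Optional[sop.UidSource] = None) -> Dataset:
        item = Dataset()
        item.AnnotationGroupNumber = self.group_number
        item.AnnotationGroupUID = self.uid or (
            uid_source or sop.UidSource())()
        item.AnnotationGroupLabel = self.label
        item.AnnotationPropertyCategoryCodeSequence = [
            self.property_category.to_dataset()]
        item.AnnotationPropertyTypeCodeSequence = [
            self.property_type.to_dataset()]
        item.GraphicType = AnnotationGraphicType(self.graphic_type).value
        item.AnnotationGroupGenerationType = GenerationType(
            self.generation_type).value
        item.NumberOfAnnotations = len(self.graphics)
        item.PointCoordinatesData = self.point_data.tobytes()
        offsets = self.index_offsets
        if offsets is not None:
            item.LongPrimitivePointIndexList = offsets.astype(
                "<u4").tobytes()
        return item


def encode_bulk_annotations(
    groups: Sequence[AnnotationGroup],
    source_image: Dataset,
    *,
    series_instance_uid: Optional[str] = None,
    series_number: int = 300,
    instance_number: int = 1,
    uid_source: Optional[sop.UidSource] = None,
) -> Dataset:
    """Encode annotation groups as a bulk annotation object.

    All groups must share one coordinate dimensionality (2 = image pixel
    matrix, 3 = slide frame of reference), which becomes the object's
    coordinate type.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("at least one annotation group is required")
    dims = {g.coordinate_dimensionality for g in groups}
    if len(dims) > 1:
        raise ValueError(
            "all annotation groups in one object must share coordinate "
            "dimensionality")
    dim = dims.pop()
    numbers = sorted(g.group_number for g in groups)
    if numbers != list(range(1, len(groups) + 1)):
        raise ValueError("annotation group numbers must be consecutive from 1")

    context = sop.harvest_context([source_image])
    ds = sop.init_derived_dataset(
        "bulk_annotations", "ANN", context,
        series_instance_uid=series_instance_uid,
        series_number=series_number, instance_number=instance_number,
        uid_source=uid_source,
    )
    ds.AnnotationCoordinateType = "2D" if dim == 2 else "3D"
    if dim == 3 and "FrameOfReferenceUID" in source_image:
        ds.FrameOfReferenceUID = source_image.FrameOfReferenceUID
    ds.AnnotationGroupSequence = [
        g.to_item(uid_source) for g in sorted(
            groups, key=lambda g: g.group_number)
    ]
    sop.attach_evidence(ds, sop.build_evidence([source_image]),
                        keyword="ReferencedImageSequence")
    report = sop.validate_sop(ds, "bulk_annotations")
    if not report.is_valid:
        raise ValidationFailure(report)
    return ds


def _get_group_item(ann_dataset: Dataset, group_number: int) -> Dataset:
    for item in ann_dataset.AnnotationGroupSequence:
        if int(item.AnnotationGroupNumber) == group_number:
            return item
    raise LookupError(
        f"no annotation group {group_number} in this object "
        f"({len(ann_dataset.AnnotationGroupSequence)} groups present)")


def decode_graphics(ann_dataset: Dataset, group_number: int
                    ) -> List[np.ndarray]:
    """Per-graphic float32 vertex arrays of one group, in stored order."""
    item = _get_group_item(ann_dataset, group_number)
    dim = 2 if str(ann_dataset.AnnotationCoordinateType) == "2D" else 3
    raw = item.PointCoordinatesData
    values = np.frombuffer(
        raw if isinstance(raw, (bytes, bytearray)) else bytes(raw),
        dtype="<f4")
    gtype = AnnotationGraphicType(str(item.GraphicType))
    if gtype in _FIXED_VERTEX_COUNTS:
        per = _FIXED_VERTEX_COUNTS[gtype]
        pts = values.reshape(-1, dim)
        return [pts[i * per:(i + 1) * per] for i in range(len(pts) // per)]
    idx = item.LongPrimitivePointIndexList
    offsets = np.frombuffer(
        idx if isinstance(idx, (bytes, bytearray)) else bytes(idx),
        dtype="<u4").astype(np.int64)
    counts = counts_from_offsets(offsets, len(values), dim)
    out = []
    for off, cnt in zip(offsets, counts):
        start = off - 1
        out.append(values[start:start + cnt * dim].reshape(cnt, dim))
    return out


def read_annotation_groups(ann_dataset: Dataset) -> List[AnnotationGroup]:
    """Rebuild :class:`AnnotationGroup` objects from an ANN dataset."""
    dim = 2 if str(ann_dataset.AnnotationCoordinateType) == "2D" else 3
    out = []
    for item in ann_dataset.AnnotationGroupSequence:
        number = int(item.AnnotationGroupNumber)
        out.append(AnnotationGroup(
            group_number=number,
            label=str(item.AnnotationGroupLabel),
            property_category=CodedConcept.from_dataset(
                item.AnnotationPropertyCategoryCodeSequence[0]),
            property_type=CodedConcept.from_dataset(
                item.AnnotationPropertyTypeCodeSequence[0]),
            graphic_type=AnnotationGraphicType(str(item.GraphicType)),
            graphics=decode_graphics(ann_dataset, number),
            coordinate_dimensionality=dim,
            generation_type=GenerationType(
                str(item.AnnotationGroupGenerationType)),
            uid=str(item.AnnotationGroupUID),
        ))
    return out


def find_annotation_groups(
    ann_dataset: Dataset,
    property_type: Optional[CodedConcept] = None,
    label: Optional[str] = None,
) -> List[int]:
    """Group numbers matching all supplied filters, ascending."""
    out = []
    for item in ann_dataset.AnnotationGroupSequence:
        if label is not None and str(item.AnnotationGroupLabel) != label:
            continue
        if property_type is not None and not concepts_equal(
                CodedConcept.from_dataset(
                    item.AnnotationPropertyTypeCodeSequence[0]),
                property_type):
            continue
        out.append(int(item.AnnotationGroupNumber))
    return sorted(out)
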