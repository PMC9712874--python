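"""SR content items, the Measurement Report template, and document queries.

A DICOM Structured Report stores its content as a tree of *content items*:
typed name–value pairs whose names are coded concepts and whose value
structure depends on the value type (TEXT, CODE, NUM, SCOORD3D, CONTAINER,
...).  The Measurement Report template (TID 1500) organises observation
context and per-ROI groups of measurements and qualitative evaluations into
a standard layout, which is what display systems and training pipelines
navigate.

Two document flavours are supported: Comprehensive SR, which may carry 2D
image-relative coordinates (SCOORD), and Comprehensive 3D SR, which
additionally permits frame-of-reference coordinates (SCOORD3D).  Encoding a
SCOORD3D item into a non-3D document is a hard validation error — the 3D
variant exists precisely to carry that value type.

Template realisation depth: the report root, measurement-group sub-templates
for image-level / planar ROI / volumetric ROI annotations, tracking
identifiers, finding type and sites, NUM measurements with UCUM units, CODE
qualitative evaluations, and segment references.  Optional sub-trees of the
template (image library, time points) are not realised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from pydicom.dataset import Dataset
from pydicom.valuerep import DSfloat

from . import sop
from .coding import CodedConcept, codes, concepts_equal
from .errors import StructureError, ValidationFailure, VertexCountError

__all__ = [
    "ValueType",
    "RelationshipType",
    "GraphicType",
    "GraphicType3D",
    "ContentItem",
    "TextContentItem",
    "CodeContentItem",
    "NumContentItem",
    "UidRefContentItem",
    "PnameContentItem",
    "ImageContentItem",
    "ScoordContentItem",
    "Scoord3DContentItem",
    "ContainerContentItem",
    "TrackingIdentifier",
    "ObservationContext",
    "MeasurementGroup",
    "build_measurement_report",
    "create_sr_document",
    "read_sr_tree",
    "find_content_items",
    "get_measurement_groups",
    "get_measurements",
    "get_qualitative_evaluations",
    "TEMPLATE_ID",
]

TEMPLATE_ID = "1500"


class ValueType(str, Enum):
    TEXT = "TEXT"
    CODE = "CODE"
    NUM = "NUM"
    DATETIME = "DATETIME"
    UIDREF = "UIDREF"
    PNAME = "PNAME"
    IMAGE = "IMAGE"
    SCOORD = "SCOORD"
    SCOORD3D = "SCOORD3D"
    CONTAINER = "CONTAINER"
    COMPOSITE = "COMPOSITE"


class RelationshipType(str, Enum):
    CONTAINS = "CONTAINS"
    HAS_CONCEPT_MOD = "HAS CONCEPT MOD"
    HAS_OBS_CONTEXT = "HAS OBS CONTEXT"
    HAS_ACQ_CONTEXT = "HAS ACQ CONTEXT"
    INFERRED_FROM = "INFERRED FROM"
    SELECTED_FROM = "SELECTED FROM"


class GraphicType(str, Enum):
    POINT = "POINT"
    MULTIPOINT = "MULTIPOINT"
    POLYLINE = "POLYLINE"
    CIRCLE = "CIRCLE"
    ELLIPSE = "ELLIPSE"


class GraphicType3D(str, Enum):
    POINT = "POINT"
    MULTIPOINT = "MULTIPOINT"
    POLYLINE = "POLYLINE"
    POLYGON = "POLYGON"
    ELLIPSE = "ELLIPSE"
    ELLIPSOID = "ELLIPSOID"


class ContentItem:
    """A name–value node of the SR document tree."""

    value_type: ValueType = None  # overridden per subclass

    def __init__(self, name: CodedConcept,
                 relationship: Optional[RelationshipType] = None):
        self.name = name
        self.relationship = (
            RelationshipType(relationship) if relationship else None)

    # -- equality: structural, arrays compared by value -------------------
    def _payload(self):
        return ()

    def __eq__(self, other):
        if type(self) is not type(other):
            return NotImplemented
        if not (self.name == other.name
                and self.relationship == other.relationship):
            return False
        a, b = self._payload(), other._payload()
        if len(a) != len(b):
            return False
        for x, y in zip(a, b):
            if isinstance(x, np.ndarray) or isinstance(y, np.ndarray):
                if not np.allclose(np.asarray(x, float),
                                   np.asarray(y, float), atol=1e-9):
                    return False
            elif x != y:
                return False
        return True

    def __repr__(self):
        return (f"{type(self).__name__}(name={self.name.meaning!r}, "
                f"relationship={self.relationship})")

    def _base_dataset(self) -> Dataset:
        ds = Dataset()
        ds.ValueType = self.value_type.value
        ds.ConceptNameCodeSequence = [self.name.to_dataset()]
        if self.relationship is not None:
            ds.RelationshipType = self.relationship.value
        return ds

    def to_dataset(self) -> Dataset:
        raise NotImplementedError


class TextContentItem(ContentItem):
    value_type = ValueType.TEXT

    def __init__(self, name, value: str, relationship=None):
        super().__init__(name, relationship)
        self.value = str(value)

    def _payload(self):
        return (self.value,)

    def to_dataset(self):
        ds = self._base_dataset()
        ds.TextValue = self.value
        return ds


class CodeContentItem(ContentItem):
    value_type = ValueType.CODE

    def __init__(self, name, value: CodedConcept, relationship=None):
        super().__init__(name, relationship)
        self.value = value

    def _payload(self):
        return (self.value,)

    def to_dataset(self):
        ds = self._base_dataset()
        ds.ConceptCodeSequence = [self.value.to_dataset()]
        return ds


class NumContentItem(ContentItem):
    """A measurement: decimal value with a UCUM unit and optional qualifier."""

    value_type = ValueType.NUM

    def __init__(self, name, value: float, unit: CodedConcept,
                 qualifier: Optional[CodedConcept] = None, relationship=None):
        super().__init__(name, relationship)
        self.value = float(value)
        self.unit = unit
        self.qualifier = qualifier

    def _payload(self):
        return (self.value, self.unit, self.qualifier)

    def to_dataset(self):
        ds = self._base_dataset()
        mv = Dataset()
        mv.NumericValue = DSfloat(self.value, auto_format=True)
        mv.MeasurementUnitsCodeSequence = [self.unit.to_dataset()]
        ds.MeasuredValueSequence = [mv]
        if self.qualifier is not None:
            ds.NumericValueQualifierCodeSequence = [self.qualifier.to_dataset()]
        return ds


class UidRefContentItem(ContentItem):
    value_type = ValueType.UIDREF

    def __init__(self, name, value: str, relationship=None):
        super().__init__(name, relationship)
        self.value = str(value)

    def _payload(self):
        return (self.value,)

    def to_dataset(self):
        ds = self._base_dataset()
        ds.UID = self.value
        return ds


class PnameContentItem(ContentItem):
    value_type = ValueType.PNAME

    def __init__(self, name, value: str, relationship=None):
        super().__init__(name, relationship)
        self.value = str(value)

    def _payload(self):
        return (self.value,)

    def to_dataset(self):
        ds = self._base_dataset()
        ds.PersonName = self.value
        return ds


class ImageContentItem(ContentItem):
    """Reference to an image instance, optionally to segments/frames in it."""

    value_type = ValueType.IMAGE

    def __init__(self, name, referenced_sop_class_uid: str,
                 referenced_sop_instance_uid: str,
                 referenced_segment_numbers: Optional[Sequence[int]] = None,
                 referenced_frame_numbers: Optional[Sequence[int]] = None,
                 relationship=None):
        super().__init__(name, relationship)
        self.referenced_sop_class_uid = str(referenced_sop_class_uid)
        self.referenced_sop_instance_uid = str(referenced_sop_instance_uid)
        self.referenced_segment_numbers = (
            list(referenced_segment_numbers)
            if referenced_segment_numbers is not None else None)
        self.referenced_frame_numbers = (
            list(referenced_frame_numbers)
            if referenced_frame_numbers is not None else None)

    def _payload(self):
        return (self.referenced_sop_class_uid,
                self.referenced_sop_instance_uid,
                self.referenced_segment_numbers,
                self.referenced_frame_numbers)

    def to_dataset(self):
        ds = self._base_dataset()
        ref = Dataset()
        ref.ReferencedSOPClassUID = self.referenced_sop_class_uid
        ref.ReferencedSOPInstanceUID = self.referenced_sop_instance_uid
        if self.referenced_segment_numbers is not None:
            ref.ReferencedSegmentNumber = self.referenced_segment_numbers
        if self.referenced_frame_numbers is not None:
            ref.ReferencedFrameNumber = self.referenced_frame_numbers
        ds.ReferencedSOPSequence = [ref]
        return ds


class ScoordContentItem(ContentItem):
    """2D spatial coordinates in the pixel matrix of a referenced image."""

    value_type = ValueType.SCOORD

    def __init__(self, name, graphic_type: GraphicType,
                 graphic_data: np.ndarray,
                 referenced_sop_class_uid: str,
                 referenced_sop_instance_uid: str,
                 referenced_frame_number: Optional[int] = None,
                 relationship=None):
        super().__init__(name, relationship)
        self.graphic_type = GraphicType(graphic_type)
        data = np.atleast_2d(np.asarray(graphic_data, dtype=float))
        if data.shape[1] != 2 or not np.all(np.isfinite(data)):
            raise ValueError("graphic_data must be a finite N×2 array")
        _check_vertex_count_2d(self.graphic_type, len(data))
        self.graphic_data = data
        self.referenced_sop_class_uid = str(referenced_sop_class_uid)
        self.referenced_sop_instance_uid = str(referenced_sop_instance_uid)
        self.referenced_frame_number = referenced_frame_number

    def _payload(self):
        return (self.graphic_type, self.graphic_data,
                self.referenced_sop_class_uid,
                self.referenced_sop_instance_uid,
                self.referenced_frame_number)

    def to_dataset(self):
        ds = self._base_dataset()
        ds.GraphicType = self.graphic_type.value
        ds.GraphicData = [float(v) for v in self.graphic_data.ravel()]
        ref = ImageContentItem(
            codes.DCM.SourceImage,
            self.referenced_sop_class_uid,
            self.referenced_sop_instance_uid,
            referenced_frame_numbers=(
                [self.referenced_frame_number]
                if self.referenced_frame_number is not None else None),
            relationship=RelationshipType.SELECTED_FROM,
        )
        ds.ContentSequence = [ref.to_dataset()]
        return ds


def _check_vertex_count_2d(gtype: GraphicType, n: int) -> None:
    rules = {GraphicType.POINT: (1, 1), GraphicType.MULTIPOINT: (1, None),
             GraphicType.POLYLINE: (2, None), GraphicType.CIRCLE: (2, 2),
             GraphicType.ELLIPSE: (4, 4)}
    lo, hi = rules[gtype]
    if n < lo or (hi is not None and n > hi):
        raise VertexCountError(
            f"{gtype.value} requires "
            f"{lo if hi == lo else f'at least {lo}'} points, got {n}")


def _check_planarity(points: np.ndarray, tol_mm: float = 1e-3) -> None:
    pts = points - points.mean(axis=0)
    if len(pts) < 4:
        return
    s = np.linalg.svd(pts, compute_uv=False)
    if s[-1] > tol_mm:
        raise ValueError(
            f"POLYGON vertices are non-planar (offset {s[-1]:.3g} mm)")


class Scoord3DContentItem(ContentItem):
    """3D spatial coordinates (mm) in a patient or slide frame of reference.

    POLYGON rings must be explicitly closed (first point equals last) and
    planar; unclosed rings are rejected rather than auto-closed, since the
    mismatch usually indicates a caller bug.
    """

    value_type = ValueType.SCOORD3D

    def __init__(self, name, graphic_type: GraphicType3D,
                 graphic_data: np.ndarray, frame_of_reference_uid: str,
                 relationship=None):
        super().__init__(name, relationship)
        self.graphic_type = GraphicType3D(graphic_type)
        data = np.atleast_2d(np.asarray(graphic_data, dtype=float))
        if data.shape[1] != 3 or not np.all(np.isfinite(data)):
            raise ValueError("graphic_data must be a finite N×3 array")
        n = len(data)
        g = self.graphic_type
        if g == GraphicType3D.POINT and n != 1:
            raise VertexCountError(f"POINT requires 1 point, got {n}")
        if g == GraphicType3D.POLYLINE and n < 2:
            raise VertexCountError(f"POLYLINE requires >=2 points, got {n}")
        if g == GraphicType3D.ELLIPSE and n != 4:
            raise VertexCountError(f"ELLIPSE requires 4 points, got {n}")
        if g == GraphicType3D.ELLIPSOID and n != 6:
            raise VertexCountError(f"ELLIPSOID requires 6 points, got {n}")
        if g == GraphicType3D.POLYGON:
            if n < 4 or not np.allclose(data[0], data[-1], atol=1e-9):
                raise VertexCountError(
                    "POLYGON must be a closed ring: first point equal to "
                    "last, with at least 3 distinct vertices")
            _check_planarity(data)
        self.graphic_data = data
        self.frame_of_reference_uid = str(frame_of_reference_uid)

    def _payload(self):
        return (self.graphic_type, self.graphic_data,
                self.frame_of_reference_uid)

    def to_dataset(self):
        ds = self._base_dataset()
        ds.GraphicType = self.graphic_type.value
        ds.GraphicData = [float(v) for v in self.graphic_data.ravel()]
        ds.ReferencedFrameOfReferenceUID = self.frame_of_reference_uid
        return ds


class ContainerContentItem(ContentItem):
    value_type = ValueType.CONTAINER

    def __init__(self, name, children: Optional[List[ContentItem]] = None,
                 template: Optional[str] = None,
                 continuity: str = "SEPARATE", relationship=None):
        super().__init__(name, relationship)
        self.children: List[ContentItem] = list(children or [])
        self.template = template
        self.continuity = continuity

    def _payload(self):
        return (self.template, self.continuity, tuple(self.children))

    def to_dataset(self):
        ds = self._base_dataset()
        ds.ContinuityOfContent = self.continuity
        if self.template is not None:
            t = Dataset()
            t.MappingResource = "DCMR"
            t.TemplateIdentifier = self.template
            ds.ContentTemplateSequence = [t]
        ds.ContentSequence = [c.to_dataset() for c in self.children]
        return ds


def content_item_from_dataset(item: Dataset) -> ContentItem:
    """Rebuild a typed content item (and children) from its dataset form."""
    vt = ValueType(str(item.ValueType))
    name = CodedConcept.from_dataset(item.ConceptNameCodeSequence[0])
    rel = (RelationshipType(str(item.RelationshipType))
           if "RelationshipType" in item else None)
    if vt == ValueType.CONTAINER:
        template = None
        if "ContentTemplateSequence" in item and len(
                item.ContentTemplateSequence):
            template = str(item.ContentTemplateSequence[0].TemplateIdentifier)
        children = [content_item_from_dataset(c)
                    for c in item.get("ContentSequence", [])]
        return ContainerContentItem(
            name, children, template=template,
            continuity=str(item.get("ContinuityOfContent", "SEPARATE")),
            relationship=rel)
    if vt == ValueType.TEXT:
        return TextContentItem(name, str(item.TextValue), rel)
    if vt == ValueType.PNAME:
        return PnameContentItem(name, str(item.PersonName), rel)
    if vt == ValueType.UIDREF:
        return UidRefContentItem(name, str(item.UID), rel)
    if vt == ValueType.CODE:
        return CodeContentItem(
            name, CodedConcept.from_dataset(item.ConceptCodeSequence[0]), rel)
    if vt == ValueType.NUM:
        mv = item.MeasuredValueSequence[0]
        qualifier = None
        if "NumericValueQualifierCodeSequence" in item:
            qualifier = CodedConcept.from_dataset(
                item.NumericValueQualifierCodeSequence[0])
        return NumContentItem(
            name, float(mv.NumericValue),
            CodedConcept.from_dataset(mv.MeasurementUnitsCodeSequence[0]),
            qualifier, rel)
    if vt == ValueType.IMAGE:
        ref = item.ReferencedSOPSequence[0]
        segs = frames = None
        if "ReferencedSegmentNumber" in ref:
            v = ref.ReferencedSegmentNumber
            segs = [int(x) for x in (v if isinstance(v, (list, tuple))
                                     else [v])]
        if "ReferencedFrameNumber" in ref:
            v = ref.ReferencedFrameNumber
            frames = [int(x) for x in (v if isinstance(v, (list, tuple))
                                       else [v])]
        return ImageContentItem(
            name, str(ref.ReferencedSOPClassUID),
            str(ref.ReferencedSOPInstanceUID), segs, frames, rel)
    if vt == ValueType.SCOORD:
        data = np.asarray([float(v) for v in item.GraphicData]).reshape(-1, 2)
        child = item.ContentSequence[0]
        ref = child.ReferencedSOPSequence[0]
        frame = None
        if "ReferencedFrameNumber" in ref:
            v = ref.ReferencedFrameNumber
            frame = int(v[0] if isinstance(v, (list, tuple)) else v)
        return ScoordContentItem(
            name, GraphicType(str(item.GraphicType)), data,
            str(ref.ReferencedSOPClassUID),
            str(ref.ReferencedSOPInstanceUID), frame, rel)
    if vt == ValueType.SCOORD3D:
        data = np.asarray([float(v) for v in item.GraphicData]).reshape(-1, 3)
        return Scoord3DContentItem(
            name, GraphicType3D(str(item.GraphicType)), data,
            str(item.ReferencedFrameOfReferenceUID), rel)
    raise StructureError(f"unsupported value type {vt}")


# ---------------------------------------------------------------------------
# Measurement report template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackingIdentifier:
    """Stable (label, UID) pair following one finding across documents."""

    identifier: str
    uid: str


@dataclass
class ObservationContext:
    """Who (or what) made the observations in a report."""

    observer_person_name: Optional[str] = None
    observer_device_uid: Optional[str] = None


RegionItem = Union[ScoordContentItem, Scoord3DContentItem, ImageContentItem]


@dataclass
class MeasurementGroup:
    """One tracked finding: region, measurements, qualitative evaluations.

    ``region`` may be a 2D SCOORD, a 3D SCOORD3D, a segment reference
    (IMAGE item), or None for image-level groups.
    """

    tracking: TrackingIdentifier
    finding_type: Optional[CodedConcept] = None
    finding_sites: List[CodedConcept] = field(default_factory=list)
    region: Optional[Union[RegionItem, List[RegionItem]]] = None
    measurements: List[NumContentItem] = field(default_factory=list)
    qualitative_evaluations: List[CodeContentItem] = field(
        default_factory=list)

    def region_items(self) -> List[ContentItem]:
        if self.region is None:
            return []
        return list(self.region) if isinstance(self.region, (list, tuple)) \
            else [self.region]

    def __post_init__(self):
        kinds = {type(r) for r in self.region_items()}
        if ScoordContentItem in kinds and Scoord3DContentItem in kinds:
            raise StructureError(
                "a measurement group must not mix 2D and 3D regions")


def _group_container(group: MeasurementGroup) -> ContainerContentItem:
    children: List[ContentItem] = [
        TextContentItem(codes.DCM.TrackingIdentifier,
                        group.tracking.identifier,
                        RelationshipType.HAS_OBS_CONTEXT),
        UidRefContentItem(codes.DCM.TrackingUniqueIdentifier,
                          group.tracking.uid,
                          RelationshipType.HAS_OBS_CONTEXT),
    ]
    if group.finding_type is not None:
        children.append(CodeContentItem(
            codes.DCM.Finding, group.finding_type,
            RelationshipType.CONTAINS))
    for site in group.finding_sites:
        children.append(CodeContentItem(
            codes.SCT.FindingSite, site, RelationshipType.HAS_CONCEPT_MOD))
    for region in group.region_items():
        if isinstance(region, ImageContentItem):
            region.name = codes.DCM.ReferencedSegment
        else:
            region.name = codes.DCM.ImageRegion
        region.relationship = RelationshipType.CONTAINS
        children.append(region)
    for m in group.measurements:
        m.relationship = RelationshipType.CONTAINS
        children.append(m)
    for e in group.qualitative_evaluations:
        e.relationship = RelationshipType.CONTAINS
        children.append(e)
    return ContainerContentItem(codes.DCM.MeasurementGroup, children,
                                relationship=RelationshipType.CONTAINS)


def build_measurement_report(
    context: ObservationContext,
    procedure: CodedConcept,
    groups: Sequence[MeasurementGroup],
    language: Optional[CodedConcept] = None,
) -> ContainerContentItem:
    """Assemble the Measurement Report content tree (template "1500").

    The tree is deterministic: identical inputs produce identical trees
    (hence byte-identical documents, timestamps aside).
    """
    language = language or codes.RFC5646.English
    children: List[ContentItem] = [
        CodeContentItem(codes.DCM.LanguageOfContentItemAndDescendants,
                        language, RelationshipType.HAS_CONCEPT_MOD),
    ]
    if context.observer_person_name is not None:
        children.append(CodeContentItem(
            codes.DCM.ObserverType, codes.DCM.Person,
            RelationshipType.HAS_OBS_CONTEXT))
        children.append(PnameContentItem(
            codes.DCM.PersonObserverName, context.observer_person_name,
            RelationshipType.HAS_OBS_CONTEXT))
    if context.observer_device_uid is not None:
        children.append(CodeContentItem(
            codes.DCM.ObserverType, codes.DCM.Device,
            RelationshipType.HAS_OBS_CONTEXT))
        children.append(UidRefContentItem(
            codes.DCM.DeviceObserverUID, context.observer_device_uid,
            RelationshipType.HAS_OBS_CONTEXT))
    children.append(CodeContentItem(
        codes.DCM.ProcedureReported, procedure, RelationshipType.CONTAINS))
    children.append(ContainerContentItem(
        codes.DCM.ImagingMeasurements,
        [_group_container(g) for g in groups],
        relationship=RelationshipType.CONTAINS))
    return ContainerContentItem(
        codes.DCM.ImagingMeasurementReport, children, template=TEMPLATE_ID)


def _tree_contains_scoord3d(item: ContentItem) -> bool:
    if isinstance(item, Scoord3DContentItem):
        return True
    if isinstance(item, ContainerContentItem):
        return any(_tree_contains_scoord3d(c) for c in item.children)
    return False


def create_sr_document(
    tree: ContainerContentItem,
    evidence: List[sop.EvidenceReference],
    context: sop.ContextMetadata,
    kind: str = "comprehensive_3d",
    *,
    completion_flag: str = "COMPLETE",
    verification_flag: str = "UNVERIFIED",
    series_instance_uid: Optional[str] = None,
    series_number: int = 200,
    instance_number: int = 1,
    uid_source: Optional[sop.UidSource] = None,
) -> Dataset:
    """Serialize a content tree into a Comprehensive (3D) SR dataset."""
    kind_map = {"comprehensive": "comprehensive_sr",
                "comprehensive_3d": "comprehensive_3d_sr"}
    if kind not in kind_map:
        raise ValueError(f"kind must be one of {sorted(kind_map)}")
    if kind == "comprehensive" and _tree_contains_scoord3d(tree):
        raise StructureError(
            "SCOORD3D content items are not permitted in a Comprehensive SR; "
            "use kind='comprehensive_3d'")
    ds = sop.init_derived_dataset(
        kind_map[kind], "SR", context,
        series_instance_uid=series_instance_uid,
        series_number=series_number, instance_number=instance_number,
        uid_source=uid_source,
    )
    ds.CompletionFlag = completion_flag
    ds.VerificationFlag = verification_flag
    root = tree.to_dataset()
    for elem in root:
        ds[elem.tag] = elem
    sop.attach_evidence(ds, evidence)
    report = sop.validate_sop(ds, kind_map[kind])
    if not report.is_valid:
        raise ValidationFailure(report)
    return ds


def read_sr_tree(sr_dataset: Dataset) -> ContainerContentItem:
    """Extract the typed content tree from an SR dataset."""
    item = content_item_from_dataset(sr_dataset)
    if not isinstance(item, ContainerContentItem):
        raise StructureError("SR document root must be a CONTAINER")
    return item


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def find_content_items(
    root: ContentItem,
    name: Optional[CodedConcept] = None,
    value_type: Optional[ValueType] = None,
    relationship: Optional[RelationshipType] = None,
    recursive: bool = True,
) -> List[Tuple[ContentItem, Tuple[int, ...]]]:
    """Filter content items, depth-first pre-order.

    Returns (item, path) pairs where ``path`` is the child-index sequence
    from the root (the root itself has path ``()``).  Filters are
    conjunctive.  With ``recursive=False`` only the root's direct children
    are searched.
    """
    def matches(item: ContentItem) -> bool:
        if name is not None and not concepts_equal(item.name, name):
            return False
        if value_type is not None and item.value_type != ValueType(value_type):
            return False
        if relationship is not None and item.relationship != \
                RelationshipType(relationship):
            return False
        return True

    results: List[Tuple[ContentItem, Tuple[int, ...]]] = []
    if not recursive:
        children = root.children if isinstance(root, ContainerContentItem) \
            else []
        for i, child in enumerate(children):
            if matches(child):
                results.append((child, (i,)))
        return results

    def walk(item: ContentItem, path: Tuple[int, ...]) -> None:
        if matches(item):
            results.append((item, path))
        if isinstance(item, ContainerContentItem):
            for i, child in enumerate(item.children):
                walk(child, path + (i,))

    walk(root, ())
    return results


def _parse_group(container: ContainerContentItem) -> MeasurementGroup:
    tracking_id, tracking_uid = "", ""
    finding_type = None
    sites: List[CodedConcept] = []
    regions: List[RegionItem] = []
    measurements: List[NumContentItem] = []
    evaluations: List[CodeContentItem] = []
    for child in container.children:
        if isinstance(child, TextContentItem) and concepts_equal(
                child.name, codes.DCM.TrackingIdentifier):
            tracking_id = child.value
        elif isinstance(child, UidRefContentItem) and concepts_equal(
                child.name, codes.DCM.TrackingUniqueIdentifier):
            tracking_uid = child.value
        elif isinstance(child, CodeContentItem) and concepts_equal(
                child.name, codes.DCM.Finding):
            finding_type = child.value
        elif isinstance(child, CodeContentItem) and concepts_equal(
                child.name, codes.SCT.FindingSite):
            sites.append(child.value)
        elif isinstance(child, (ScoordContentItem, Scoord3DContentItem)):
            regions.append(child)
        elif isinstance(child, ImageContentItem) and concepts_equal(
                child.name, codes.DCM.ReferencedSegment):
            regions.append(child)
        elif isinstance(child, NumContentItem):
            measurements.append(child)
        elif isinstance(child, CodeContentItem):
            evaluations.append(child)
    region: Optional[Union[RegionItem, List[RegionItem]]]
    if not regions:
        region = None
    elif len(regions) == 1:
        region = regions[0]
    else:
        region = regions
    return MeasurementGroup(
        tracking=TrackingIdentifier(tracking_id, tracking_uid),
        finding_type=finding_type, finding_sites=sites, region=region,
        measurements=measurements, qualitative_evaluations=evaluations)


def get_measurement_groups(
    sr_document: Union[Dataset, ContainerContentItem],
    finding_type: Optional[CodedConcept] = None,
    finding_site: Optional[CodedConcept] = None,
    tracking_uid: Optional[str] = None,
    graphic_type: Optional[Union[GraphicType, GraphicType3D]] = None,
) -> List[MeasurementGroup]:
    """Measurement groups of a report, filtered conjunctively, in order."""
    root = sr_document if isinstance(sr_document, ContentItem) \
        else read_sr_tree(sr_document)
    if not isinstance(root, ContainerContentItem) or \
            root.template != TEMPLATE_ID:
        raise StructureError(
            f"document root does not follow template {TEMPLATE_ID}")
    groups: List[MeasurementGroup] = []
    for item, _ in find_content_items(
            root, name=codes.DCM.MeasurementGroup,
            value_type=ValueType.CONTAINER):
        groups.append(_parse_group(item))

    def keep(g: MeasurementGroup) -> bool:
        if finding_type is not None:
            if g.finding_type is None or not concepts_equal(
                    g.finding_type, finding_type):
                return False
        if finding_site is not None and not any(
                concepts_equal(s, finding_site) for s in g.finding_sites):
            return False
        if tracking_uid is not None and g.tracking.uid != tracking_uid:
            return False
        if graphic_type is not None:
            gtypes = {getattr(r, "graphic_type", None)
                      for r in g.region_items()}
            wanted = str(getattr(graphic_type, "value", graphic_type))
            if not any(gt is not None and gt.value == wanted
                       for gt in gtypes):
                return False
        return True

    return [g for g in groups if keep(g)]


def get_measurements(group: MeasurementGroup,
                     name: Optional[CodedConcept] = None
                     ) -> List[NumContentItem]:
    """NUM measurements of a group, optionally filtered by concept name."""
    return [m for m in group.measurements
            if name is None or concepts_equal(m.name, name)]


def get_qualitative_evaluations(group: MeasurementGroup,
                                name: Optional[CodedConcept] = None
                                ) -> List[CodeContentItem]:
    """CODE evaluations of a group, optionally filtered by concept name."""
    return [e for e in group.qualitative_evaluations
            if name is None or concepts_equal(e.name, name)]
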