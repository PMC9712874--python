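"""Post-processing pipelines: model outputs → derived DICOM objects.

Two complementary routes from per-pixel class probabilities to standard
objects:

* probability maps → FRACTIONAL/PROBABILITY Segmentation image, one segment
  per class (raster route);
* thresholded masks → connected components → border following → per-ROI
  contours and tight bounding boxes → Comprehensive 3D SR with one
  measurement group per detection, its box as a SCOORD3D POLYGON in the
  frame of reference and its detection score as a NUM measurement (vector
  route).

Thresholding is the caller's decision (default 0.5 in the CLI); components
use 8-connectivity by default; border following returns the outer contour
only — holes are irrelevant to bounding boxes.  Contours are traced from the
top-most, then left-most border pixel, and ROIs are ordered by the top-left
corner of their boxes, so output ordering is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from pydicom.dataset import Dataset
from scipy import ndimage

from . import seg, sop, spatial, sr
from .coding import CodedConcept, codes

__all__ = [
    "DetectedRoi",
    "probabilities_to_seg",
    "threshold_probabilities",
    "extract_rois",
    "trace_boundary",
    "rois_to_sr",
]


@dataclass(frozen=True)
class DetectedRoi:
    """One detected region: outer contour, tight box, optional label/score.

    ``contour`` is a closed ring of (column, row) pixel indices;
    ``bounding_box`` is ``((col_min, row_min), (col_max, row_max))``,
    inclusive pixel indices.
    """

    contour: np.ndarray
    bounding_box: Tuple[Tuple[int, int], Tuple[int, int]]
    class_label: Optional[CodedConcept] = None
    score: Optional[float] = None

    def __post_init__(self):
        (cmin, rmin), (cmax, rmax) = self.bounding_box
        cols, rows = self.contour[:, 0], self.contour[:, 1]
        if cols.min() < cmin or cols.max() > cmax or \
                rows.min() < rmin or rows.max() > rmax:
            raise ValueError("bounding box does not contain the contour")
        if self.score is not None and not np.isfinite(self.score):
            raise ValueError("score must be finite")

    def labeled(self, class_label: CodedConcept,
                score: Optional[float] = None) -> "DetectedRoi":
        return replace(self, class_label=class_label, score=score)


def probabilities_to_seg(
    prob_maps: Union[np.ndarray, Sequence[np.ndarray]],
    source_images: Sequence[Dataset],
    class_concepts: Sequence[CodedConcept],
    *,
    property_category: Optional[CodedConcept] = None,
    algorithm: Optional[seg.AlgorithmIdentification] = None,
    omit_empty_frames: bool = True,
    uid_source: Optional[sop.UidSource] = None,
) -> Dataset:
    """Encode per-class probability maps as a FRACTIONAL/PROBABILITY SEG.

    ``prob_maps`` holds one (frames, rows, cols) float map in [0, 1] per
    class concept; classes are independent (their probabilities need not sum
    to one across classes).
    """
    maps = [np.asarray(m, dtype=float) for m in prob_maps]
    if len(maps) != len(class_concepts):
        raise ValueError("one probability map per class concept is required")
    stack = np.stack(maps, axis=-1)
    category = property_category or codes.SCT.Tissue
    algorithm = algorithm or seg.AlgorithmIdentification("dcmforge", "0.1.0")
    descriptions = [
        seg.SegmentDescription(
            segment_number=i + 1,
            label=concept.meaning,
            property_category=category,
            property_type=concept,
            algorithm_type=seg.AlgorithmType.AUTOMATIC,
            algorithm_identification=algorithm,
        )
        for i, concept in enumerate(class_concepts)
    ]
    params = seg.SegmentationParams(
        segmentation_type=seg.SegmentationType.FRACTIONAL,
        fractional_type=seg.FractionalType.PROBABILITY,
        omit_empty_frames=omit_empty_frames,
    )
    return seg.encode_segmentation(
        stack, source_images, descriptions, params, uid_source=uid_source)


def threshold_probabilities(prob_map: np.ndarray,
                            threshold: float = 0.5) -> np.ndarray:
    """Binary mask of pixels with probability >= threshold."""
    return np.asarray(prob_map, dtype=float) >= threshold


# neighbour directions, cyclic: W, NW, N, NE, E, SE, S, SW (row down)
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1),
          (0, 1), (1, 1), (1, 0), (1, -1))


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Outer border of a single connected component, as a closed ring.

    Moore-neighbour tracing starting at the top-most, then left-most pixel,
    with the radial sweep resuming two positions behind the entry direction;
    terminates on re-entering the start pixel along the initial direction.
    Returns (column, row) indices; a single pixel yields the degenerate ring
    ``[[c, r], [c, r]]``.
    """
    mask = np.asarray(mask, dtype=bool)
    pixels = np.argwhere(mask)
    if len(pixels) == 0:
        raise ValueError("mask is empty")
    order = np.lexsort((pixels[:, 1], pixels[:, 0]))
    r0, c0 = (int(v) for v in pixels[order[0]])
    rows, cols = mask.shape

    def neighbour(pos, d):
        nr, nc = pos[0] + _MOORE[d][0], pos[1] + _MOORE[d][1]
        if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc]:
            return (nr, nc)
        return None

    start = (r0, c0)
    contour = [start]
    # entering from the west (the scan guarantees no pixel W or N of start)
    scan_from = 1
    first_dir = None
    cur = start
    max_steps = 4 * mask.size + 8
    for _ in range(max_steps):
        nxt = None
        for k in range(8):
            d = (scan_from + k) % 8
            cand = neighbour(cur, d)
            if cand is not None:
                nxt = cand
                break
        if nxt is None:
            break  # isolated pixel
        if first_dir is None:
            first_dir = d
        elif cur == start and d == first_dir:
            break
        contour.append(nxt)
        cur = nxt
        scan_from = (d + 6) % 8
    if len(contour) == 1 or contour[-1] != start:
        contour.append(start)
    ring = np.array([(c, r) for r, c in contour], dtype=np.int64)
    return ring


def extract_rois(binary_mask: np.ndarray,
                 connectivity: int = 8) -> List[DetectedRoi]:
    """Connected components of a mask, each with outer contour and tight box.

    ROIs are sorted by the (row, column) of their box's top-left corner.
    An empty mask yields an empty list.
    """
    mask = np.asarray(binary_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("binary_mask must be 2D (rows, cols)")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = np.ones((3, 3), dtype=bool) if connectivity == 8 else \
        ndimage.generate_binary_structure(2, 1)
    labels, n = ndimage.label(mask, structure=structure)
    rois = []
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        comp = labels == i
        contour = trace_boundary(comp)
        rmin, rmax = sl[0].start, sl[0].stop - 1
        cmin, cmax = sl[1].start, sl[1].stop - 1
        rois.append(DetectedRoi(
            contour=contour,
            bounding_box=((int(cmin), int(rmin)), (int(cmax), int(rmax))),
        ))
    rois.sort(key=lambda roi: (roi.bounding_box[0][1],
                               roi.bounding_box[0][0]))
    return rois


def _box_ring_mm(roi: DetectedRoi, geometry: spatial.PlaneGeometry
                 ) -> np.ndarray:
    (cmin, rmin), (cmax, rmax) = roi.bounding_box
    corners = np.array([
        [cmin, rmin], [cmax, rmin], [cmax, rmax], [cmin, rmax], [cmin, rmin],
    ], dtype=float)
    return spatial.pixel_to_reference(corners, geometry)


def rois_to_sr(
    rois: Sequence[DetectedRoi],
    geometry: spatial.PlaneGeometry,
    context: sop.ContextMetadata,
    evidence: List[sop.EvidenceReference],
    frame_of_reference_uid: str,
    *,
    observation_context: Optional[sr.ObservationContext] = None,
    procedure: Optional[CodedConcept] = None,
    score_name: Optional[CodedConcept] = None,
    finding_sites: Sequence[CodedConcept] = (),
    uid_source: Optional[sop.UidSource] = None,
) -> Dataset:
    """Encode detections as a Comprehensive 3D SR Measurement Report.

    Each ROI becomes one measurement group: its bounding box as a SCOORD3D
    POLYGON in the frame of reference (corner pixel indices mapped through
    ``geometry``), the class as the finding type, and the detection score —
    when present — as a dimensionless NUM measurement.
    """
    observation_context = observation_context or sr.ObservationContext(
        observer_device_uid=str((uid_source or sop.UidSource())()))
    procedure = procedure or codes.SCT.Imaging
    score_name = score_name or codes.DCM.ProbabilityOfCancer
    uid_source = uid_source or sop.UidSource()
    groups = []
    for k, roi in enumerate(rois, start=1):
        if roi.class_label is None:
            raise ValueError(
                f"ROI {k} carries no class label; label detections before "
                "encoding them")
        ring = _box_ring_mm(roi, geometry)
        region = sr.Scoord3DContentItem(
            codes.DCM.ImageRegion, sr.GraphicType3D.POLYGON, ring,
            frame_of_reference_uid)
        measurements = []
        if roi.score is not None:
            measurements.append(sr.NumContentItem(
                score_name, float(roi.score), codes.UCUM.NoUnits))
        groups.append(sr.MeasurementGroup(
            tracking=sr.TrackingIdentifier(f"ROI-{k}", str(uid_source())),
            finding_type=roi.class_label,
            finding_sites=list(finding_sites),
            region=region,
            measurements=measurements,
        ))
    tree = sr.build_measurement_report(observation_context, procedure, groups)
    return sr.create_sr_document(
        tree, evidence, context, kind="comprehensive_3d",
        uid_source=uid_source)
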