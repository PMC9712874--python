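"""Synthetic source images and detection scenarios.

Every codec in this package derives its context from source images, so the
test surface needs realistic sources without any downloads: an axial CT
series with patient frame-of-reference geometry, and a tiled whole-slide
microscopy (SM) image with slide geometry and specimen metadata.  Pixel
content is smooth band-limited noise with planted high-intensity blobs —
enough structure to produce non-trivial masks, with no attempt at
photorealism.

Scenarios plant elliptical blobs with known class, frame, extent and
probability level, and expose the ground truth (per-class probability maps,
masks and tight bounding boxes) against which the ROI pipelines are checked
end to end.  All generation is deterministic given the spec's seed, down to
the UIDs, so identical specs yield byte-identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from pydicom.dataset import Dataset
from scipy import ndimage

from . import sop
from .coding import CodedConcept
from .sop import ValidationReport
from .spatial import PlaneGeometry

__all__ = [
    "CtSeriesSpec",
    "SmImageSpec",
    "PlantedBlob",
    "ScenarioSpec",
    "Scenario",
    "generate_ct_series",
    "generate_sm_image",
    "generate_scenario",
    "validate_source_image",
    "tile_plane",
    "assemble_tiles",
]

_ORIENTATIONS = {
    # ImageOrientationPatient: column-direction triplet, row-direction triplet
    "axial": ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
    "axial_rot90": ((0.0, 1.0, 0.0), (-1.0, 0.0, 0.0)),
    "coronal": ((1.0, 0.0, 0.0), (0.0, 0.0, -1.0)),
}


@dataclass(frozen=True)
class CtSeriesSpec:
    """Parameters of a synthetic single-frame axial CT series."""

    n_slices: int = 3
    rows: int = 64
    cols: int = 64
    pixel_spacing: Tuple[float, float] = (1.0, 1.0)
    slice_spacing: float = 5.0
    orientation: str = "axial"
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = "FIXTURE^CT^001"
    patient_name: str = "Fixture^Patient"
    study_id: str = "S001"
    accession_number: str = "A001"
    seed: int = 0

    def __post_init__(self):
        if self.n_slices < 1 or self.rows < 1 or self.cols < 1:
            raise ValueError("all dimensions must be >= 1")
        if min(self.pixel_spacing) <= 0 or self.slice_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(
                f"orientation must be one of {sorted(_ORIENTATIONS)}")


@dataclass(frozen=True)
class SmImageSpec:
    """Parameters of a synthetic tiled whole-slide microscopy image."""

    total_rows: int = 64
    total_cols: int = 64
    tile_rows: int = 32
    tile_cols: int = 32
    pixel_spacing: Tuple[float, float] = (0.001, 0.001)
    origin: Tuple[float, float, float] = (10.0, 20.0, 0.0)
    container_id: str = "FIXTURE-SLIDE-001"
    specimen_id: str = "SPECIMEN-001"
    patient_id: str = "FIXTURE^SM^001"
    patient_name: str = "Fixture^Specimen"
    study_id: str = "S002"
    accession_number: str = "A002"
    seed: int = 0

    def __post_init__(self):
        if self.tile_rows > self.total_rows or self.tile_cols > self.total_cols:
            raise ValueError("tiles must not exceed the total pixel matrix")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_tile_rows(self) -> int:
        return -(-self.total_rows // self.tile_rows)

    @property
    def n_tile_cols(self) -> int:
        return -(-self.total_cols // self.tile_cols)


def _smooth_noise(rng: np.random.Generator, shape, sigma: float = 3.0
                  ) -> np.ndarray:
    """Band-limited noise in [0, 1]."""
    raw = ndimage.gaussian_filter(rng.random(shape), sigma)
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _shared_identity(ds: Dataset, patient_id, patient_name, study_id,
                     accession, study_uid) -> None:
    ds.PatientID = patient_id
    ds.PatientName = patient_name
    ds.PatientBirthDate = "19700101"
    ds.PatientSex = "O"
    ds.StudyInstanceUID = study_uid
    ds.StudyID = study_id
    ds.StudyDate = "20240101"
    ds.StudyTime = "120000"
    ds.AccessionNumber = accession
    ds.ReferringPhysicianName = "Fixture^Referrer"
    ds.SpecificCharacterSet = "ISO_IR 192"


def generate_ct_series(spec: CtSeriesSpec) -> List[Dataset]:
    """One single-frame dataset per slice, sharing study/series/frame UIDs.

    Slice positions step by ``slice_spacing`` along the plane normal from
    ``origin``; pixel data is deterministic smooth noise given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    uids = sop.UidSource(int(rng.integers(2**31)))
    study_uid, series_uid, for_uid = uids(), uids(), uids()
    col_dir, row_dir = (np.array(v) for v in _ORIENTATIONS[spec.orientation])
    normal = np.cross(col_dir, row_dir)
    datasets = []
    for i in range(spec.n_slices):
        ds = Dataset()
        ds.SOPClassUID = sop.SOP_CLASS_UIDS["ct_image"]
        ds.SOPInstanceUID = uids()
        ds.Modality = "CT"
        _shared_identity(ds, spec.patient_id, spec.patient_name,
                         spec.study_id, spec.accession_number, study_uid)
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = 1
        ds.InstanceNumber = i + 1
        ds.FrameOfReferenceUID = for_uid
        ds.ImageType = ["ORIGINAL", "PRIMARY", "AXIAL"]
        pos = np.asarray(spec.origin, dtype=float) + i * spec.slice_spacing \
            * normal
        ds.ImagePositionPatient = [float(v) for v in pos]
        ds.ImageOrientationPatient = [float(v) for v in col_dir] + \
            [float(v) for v in row_dir]
        ds.PixelSpacing = [spec.pixel_spacing[0], spec.pixel_spacing[1]]
        ds.SliceThickness = spec.slice_spacing
        ds.Rows = spec.rows
        ds.Columns = spec.cols
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleIntercept = -1024.0
        ds.RescaleSlope = 1.0
        pixels = (_smooth_noise(rng, (spec.rows, spec.cols)) * 2000).astype(
            np.uint16)
        ds.PixelData = pixels.tobytes()
        datasets.append(ds)
    return datasets


def generate_sm_image(spec: SmImageSpec) -> Dataset:
    """A tiled multi-frame slide-microscopy image.

    Tiles cover the total pixel matrix in row-major order; the last tile row
    and column are zero-padded when the matrix is not an exact multiple of
    the tile size.  Specimen attributes and slide frame-of-reference
    metadata are present so context harvesting and slide-coordinate
    transforms can be exercised.
    """
    rng = np.random.default_rng(spec.seed)
    uids = sop.UidSource(int(rng.integers(2**31)))
    study_uid = uids()
    ds = Dataset()
    ds.SOPClassUID = sop.SOP_CLASS_UIDS["sm_image"]
    ds.SOPInstanceUID = uids()
    ds.Modality = "SM"
    _shared_identity(ds, spec.patient_id, spec.patient_name, spec.study_id,
                     spec.accession_number, study_uid)
    ds.SeriesInstanceUID = uids()
    ds.SeriesNumber = 1
    ds.InstanceNumber = 1
    ds.FrameOfReferenceUID = uids()
    ds.ImageType = ["ORIGINAL", "PRIMARY", "VOLUME", "NONE"]
    ds.ImageOrientationSlide = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
    origin_item = Dataset()
    origin_item.XOffsetInSlideCoordinateSystem = spec.origin[0]
    origin_item.YOffsetInSlideCoordinateSystem = spec.origin[1]
    origin_item.ZOffsetInSlideCoordinateSystem = spec.origin[2]
    ds.TotalPixelMatrixOriginSequence = [origin_item]
    ds.TotalPixelMatrixRows = spec.total_rows
    ds.TotalPixelMatrixColumns = spec.total_cols
    ds.Rows = spec.tile_rows
    ds.Columns = spec.tile_cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0

    ds.ContainerIdentifier = spec.container_id
    container_type = Dataset()
    container_type.CodeValue = "433466003"
    container_type.CodingSchemeDesignator = "SCT"
    container_type.CodeMeaning = "Microscope slide"
    ds.ContainerTypeCodeSequence = [container_type]
    specimen = Dataset()
    specimen.SpecimenIdentifier = spec.specimen_id
    specimen.SpecimenUID = uids()
    ds.SpecimenDescriptionSequence = [specimen]

    shared = Dataset()
    measures = Dataset()
    measures.PixelSpacing = [spec.pixel_spacing[0], spec.pixel_spacing[1]]
    shared.PixelMeasuresSequence = [measures]
    ds.SharedFunctionalGroupsSequence = [shared]

    geometry = PlaneGeometry(
        position=spec.origin,
        col_direction=(1.0, 0.0, 0.0),
        row_direction=(0.0, 1.0, 0.0),
        pixel_spacing=spec.pixel_spacing,
        coordinate_system="SLIDE",
    )
    from .spatial import pixel_to_reference

    plane = (_smooth_noise(rng, (spec.total_rows, spec.total_cols))
             * 255).astype(np.uint8)
    tiles = tile_plane(plane, spec.tile_rows, spec.tile_cols)
    pffg = []
    for tr in range(spec.n_tile_rows):
        for tc in range(spec.n_tile_cols):
            item = Dataset()
            pos = Dataset()
            row0 = tr * spec.tile_rows
            col0 = tc * spec.tile_cols
            pos.RowPositionInTotalImagePixelMatrix = row0 + 1
            pos.ColumnPositionInTotalImagePixelMatrix = col0 + 1
            xyz = pixel_to_reference([[col0, row0]], geometry)[0]
            pos.XOffsetInSlideCoordinateSystem = float(xyz[0])
            pos.YOffsetInSlideCoordinateSystem = float(xyz[1])
            pos.ZOffsetInSlideCoordinateSystem = float(xyz[2])
            item.PlanePositionSlideSequence = [pos]
            pffg.append(item)
    ds.PerFrameFunctionalGroupsSequence = pffg
    ds.NumberOfFrames = len(pffg)
    data = tiles.tobytes()
    if len(data) % 2:
        data += b"\x00"
    ds.PixelData = data
    return ds


def tile_plane(plane: np.ndarray, tile_rows: int, tile_cols: int
               ) -> np.ndarray:
    """Cut a 2D plane into row-major tiles, zero-padding the last row/col."""
    rows, cols = plane.shape
    n_tr = -(-rows // tile_rows)
    n_tc = -(-cols // tile_cols)
    padded = np.zeros((n_tr * tile_rows, n_tc * tile_cols),
                      dtype=plane.dtype)
    padded[:rows, :cols] = plane
    tiles = padded.reshape(n_tr, tile_rows, n_tc, tile_cols)
    return tiles.transpose(0, 2, 1, 3).reshape(-1, tile_rows, tile_cols)


def assemble_tiles(tiles: np.ndarray, total_rows: int, total_cols: int
                   ) -> np.ndarray:
    """Inverse of :func:`tile_plane`: reassemble and crop the total matrix."""
    n, tr, tc = tiles.shape
    n_tc = -(-total_cols // tc)
    n_tr = n // n_tc
    grid = tiles.reshape(n_tr, n_tc, tr, tc).transpose(0, 2, 1, 3)
    return grid.reshape(n_tr * tr, n_tc * tc)[:total_rows, :total_cols]


_SOURCE_REQUIRED = (
    "SOPClassUID", "SOPInstanceUID", "StudyInstanceUID", "SeriesInstanceUID",
    "Modality", "Rows", "Columns", "PixelData", "PatientID",
)


def validate_source_image(ds: Dataset) -> ValidationReport:
    """Sanity checks for a fixture source image (not a full IOD check)."""
    report = ValidationReport()
    for kw in _SOURCE_REQUIRED:
        if kw not in ds:
            report.error(kw, "required-attribute-missing")
    n_frames = int(ds.get("NumberOfFrames", 1))
    if n_frames > 1:
        pffg = ds.get("PerFrameFunctionalGroupsSequence", [])
        if len(pffg) != n_frames:
            report.error("PerFrameFunctionalGroupsSequence",
                         "frame-count-mismatch")
        for kw in ("ContainerIdentifier", "SpecimenDescriptionSequence",
                   "TotalPixelMatrixRows", "TotalPixelMatrixColumns"):
            if kw not in ds:
                report.error(kw, "required-attribute-missing")
    else:
        for kw in ("ImagePositionPatient", "ImageOrientationPatient",
                   "PixelSpacing", "FrameOfReferenceUID"):
            if kw not in ds:
                report.error(kw, "required-attribute-missing")
    return report


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedBlob:
    """An elliptical region of elevated class probability."""

    frame: int
    center: Tuple[int, int]  # (col, row)
    radii: Tuple[int, int]  # (col_radius, row_radius), pixels
    class_concept: CodedConcept
    probability: float = 0.9

    def __post_init__(self):
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must lie in [0, 1]")
        if min(self.radii) < 1:
            raise ValueError("radii must be >= 1 pixel")


@dataclass(frozen=True)
class ScenarioSpec:
    """A source image plus planted blobs with known ground truth."""

    image_spec: CtSeriesSpec = field(default_factory=CtSeriesSpec)
    blobs: Tuple[PlantedBlob, ...] = ()
    background_level: float = 0.05
    seed: int = 0


def _blob_mask(shape, blob: PlantedBlob) -> np.ndarray:
    rows, cols = shape
    cx, cy = blob.center  # (col, row)
    rc, rr = blob.radii
    if not (0 <= cx < cols and 0 <= cy < rows):
        raise ValueError(f"blob center {blob.center} out of bounds {shape}")
    yy, xx = np.mgrid[0:rows, 0:cols]
    return ((xx - cx) / rc) ** 2 + ((yy - cy) / rr) ** 2 <= 1.0


@dataclass
class Scenario:
    """Generated images plus aligned per-class ground truth."""

    spec: ScenarioSpec
    source_images: List[Dataset]
    class_concepts: List[CodedConcept]
    prob_maps: List[np.ndarray]  # per class: (frames, rows, cols) in [0, 1]

    def masks(self, threshold: float = 0.5) -> List[np.ndarray]:
        """Per-class boolean ground-truth masks at the given threshold."""
        return [m >= threshold for m in self.prob_maps]

    def boxes(self, threshold: float = 0.5):
        """Tight ground-truth boxes per (class index, frame) at a threshold.

        Returns a list of (class_index, frame, ((cmin, rmin), (cmax, rmax)))
        tuples derived from connected components of the thresholded masks,
        ordered by class, frame, then box top-left.
        """
        out = []
        for ci, mask in enumerate(self.masks(threshold)):
            for f in range(mask.shape[0]):
                labels, n = ndimage.label(mask[f], structure=np.ones((3, 3)))
                for sl in ndimage.find_objects(labels):
                    box = ((sl[1].start, sl[0].start),
                           (sl[1].stop - 1, sl[0].stop - 1))
                    out.append((ci, f, box))
        out.sort(key=lambda t: (t[0], t[1], t[2][0][1], t[2][0][0]))
        return out

    def frame_geometry(self, frame: int) -> PlaneGeometry:
        return PlaneGeometry.from_image_dataset(self.source_images[frame])


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Build a CT-series scenario with planted per-class probability blobs.

    Ground-truth probability maps carry ``background_level`` noise ceilings
    outside blobs and the blob's probability level inside it.  Blobs of the
    same class that touch on the same frame merge into one ground-truth
    region; a warning is emitted because the planted count then differs from
    the recoverable count.
    """
    rng = np.random.default_rng(spec.seed)
    images = generate_ct_series(spec.image_spec)
    shape = (spec.image_spec.rows, spec.image_spec.cols)
    n_frames = spec.image_spec.n_slices
    concepts: List[CodedConcept] = []
    for blob in spec.blobs:
        if blob.frame >= n_frames:
            raise ValueError(f"blob frame {blob.frame} out of range")
        if not any(blob.class_concept == c for c in concepts):
            concepts.append(blob.class_concept)
    prob_maps = []
    for concept in concepts:
        pm = rng.random((n_frames,) + shape) * spec.background_level
        class_blobs = [b for b in spec.blobs if b.class_concept == concept]
        for f in range(n_frames):
            frame_blobs = [b for b in class_blobs if b.frame == f]
            union = np.zeros(shape, dtype=bool)
            overlap = False
            for blob in frame_blobs:
                m = _blob_mask(shape, blob)
                if (union & m).any():
                    overlap = True
                union |= m
                pm[f][m] = blob.probability
            if overlap:
                warnings.warn(
                    f"blobs of class {concept.meaning!r} overlap on frame "
                    f"{f}; merged in ground truth", UserWarning,
                    stacklevel=2)
        prob_maps.append(pm)
    return Scenario(spec, images, concepts, prob_maps)
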