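# dcmforge

Builders and readers for DICOM image annotations: Segmentation images,
TID 1500 Structured Reports, and Microscopy Bulk Simple Annotations.

## The problem

Machine-learning models for pathology and radiology consume and produce
NumPy arrays — masks, probability maps, boxes, scores — while hospital
systems exchange DICOM objects. Between the two sits a large amount of
error-prone plumbing: copying patient/study/specimen context from source
images, referencing them as evidence, expressing regions in the patient or
slide frame of reference, encoding semantics with controlled-terminology
codes, and obeying the attribute rules of each information object
definition (IOD). `dcmforge` packages that plumbing behind a small,
constructor-validated API for people building training and inference
pipelines: every builder assembles a complete `pydicom.Dataset` in one
call, validates it against the target IOD schema before returning, and the
result is immutable through the public interface.

Three derived-object families are covered, plus everything they share:

| Module | What it does |
| --- | --- |
| `dcmforge.coding` | `CodedConcept` (value, scheme, meaning[, version]) with standard equality; shipped SCT/DCM/UCUM registries; `99`-prefix custom-scheme detection |
| `dcmforge.sop` | UID generation, context harvesting, evidence references, IOD validation, Part-10 read/write |
| `dcmforge.seg` | Segmentation images: BINARY bit planes and FRACTIONAL probability/occupancy frames, sparse-frame omission, dimension indexing, segment filtering, mask reconstruction and label-map combination |
| `dcmforge.sr` | SR content items (TEXT/CODE/NUM/SCOORD/SCOORD3D/IMAGE/CONTAINER/…), the TID 1500 "Measurement Report" template, Comprehensive / Comprehensive 3D SR documents, tree queries |
| `dcmforge.spatial` | Affine pixel ↔ frame-of-reference transforms (patient and slide), polygon areas in mm², 3D bounding boxes |
| `dcmforge.ann` | Bulk annotations: flat float32 coordinate arrays with 1-based index offsets, scaling to very large graphic collections |
| `dcmforge.pipelines` | probability maps → FRACTIONAL SEG; thresholding → connected components → border following → boxes → Comprehensive 3D SR |
| `dcmforge.fixtures` | Synthetic CT series and tiled slide-microscopy images with correct geometry, plus planted-blob scenarios with ground truth |

## The core mechanics

**Binary masks** are stored one bit per pixel: bit *k* of byte *b* encodes
pixel *8b + k* of the row-major flattened frame stack (LSB first), frames
concatenated without per-frame byte alignment. Fractional masks quantize a
probability *p* ∈ [0, 1] to `⌊p·M + ½⌋` with *M* = MaximumFractionalValue
(default 255), so a decoded value is within 1/(2·M) of the original.
All-background frames are omitted by default; the per-frame dimension index
(segment number, source plane) lets the decoder restore them as zeros and
makes reconstruction independent of physical frame order.

**Regions** are expressed in the frame of reference. A plane with origin
**p** (mm), unit row/column direction cosines **r**, **c** and pixel
spacings (Δr, Δc) maps a pixel index (i, j) = (column, row) to

x(i, j) = **p** + i·Δc·**c** + j·Δr·**r**

which `dcmforge.spatial` implements as an invertible 4×4 affine (the third
basis vector is the plane normal, so out-of-plane distance is checked on
inversion). Areas and diameters computed on such coordinates are in
physical millimetre units regardless of any image rotation or crop.

**Semantics** are coded concepts, not free text: a tumor finding is
(SCT, 108369006) whatever language the display system speaks. Concept
equality compares code value and scheme designator, and scheme version only
when both operands carry one; the human-readable meaning never participates.

## Worked example

Detecting tumor regions in a synthetic CT slice and publishing them as a
Comprehensive 3D SR:

```python
import numpy as np
from dcmforge import fixtures, pipelines, seg, sop, spatial, sr
from dcmforge.coding import codes

scenario = fixtures.generate_scenario(fixtures.ScenarioSpec(
    image_spec=fixtures.CtSeriesSpec(n_slices=1, rows=64, cols=64, seed=42),
    blobs=(
        fixtures.PlantedBlob(0, (12, 10), (4, 3), codes.SCT.Tumor, 0.9),
        fixtures.PlantedBlob(0, (44, 40), (6, 5), codes.SCT.Tumor, 0.8),
    ),
    seed=42,
))

seg_ds = pipelines.probabilities_to_seg(
    scenario.prob_maps, scenario.source_images, scenario.class_concepts)
print("SEG type:", seg_ds.SegmentationType, "/",
      seg_ds.SegmentationFractionalType, "-", seg_ds.NumberOfFrames, "frame(s)")

keys = [str(s.SOPInstanceUID) for s in scenario.source_images]
probs = seg.reconstruct_mask(seg_ds, keys, rescale_fractional=True)
mask = pipelines.threshold_probabilities(probs[0, :, :, 0], 0.5)
rois = [r.labeled(codes.SCT.Tumor, float(probs[0, :, :, 0].max()))
        for r in pipelines.extract_rois(mask)]
print("detected ROIs:", [r.bounding_box for r in rois])

geometry = scenario.frame_geometry(0)
doc = pipelines.rois_to_sr(
    rois, geometry, sop.harvest_context(scenario.source_images),
    sop.build_evidence(scenario.source_images),
    str(scenario.source_images[0].FrameOfReferenceUID),
    uid_source=sop.UidSource(42))

for group in sr.get_measurement_groups(doc, finding_type=codes.SCT.Tumor):
    ring = group.region_items()[0].graphic_data
    area = spatial.polygon_area_mm2(ring, geometry)
    score = sr.get_measurements(group)[0].value
    print(f"{group.tracking.identifier}: box area {area:.1f} mm^2, "
          f"score {score:.3f}, first vertex at {np.round(ring[0], 1)} mm")
```

prints

```
SEG type: FRACTIONAL / PROBABILITY - 1 frame(s)
detected ROIs: [((8, 7), (16, 13)), ((38, 35), (50, 45))]
ROI-1: box area 48.0 mm^2, score 0.902, first vertex at [8. 7. 0.] mm
ROI-2: box area 120.0 mm^2, score 0.902, first vertex at [38. 35.  0.] mm
```

The probability maps were first encoded as a FRACTIONAL/PROBABILITY
Segmentation image; thresholding at 0.5 and connected-component analysis
recover the two planted blobs, whose tight pixel boxes `((8,7)-(16,13))`
and `((38,35)-(50,45))` match the planted ellipse extents (centers (12,10)
and (44,40), radii (4,3) and (6,5)). In the SR document each detection is
one measurement group: its box as a SCOORD3D POLYGON in patient-space mm
(1 mm pixels here, so the 9×7- and 13×11-pixel boxes have areas 48 and
120 mm²), the finding coded as (SCT, 108369006), and the detection score as
a dimensionless NUM measurement. The score 0.902 is the decoded maximum of
the stored probability map — the planted 0.9 after 8-bit quantization
(230/255 ≈ 0.902).

A `dcmforge` command-line tool wraps the same operations (`dcmforge
fixture`, `seg`, `sr`, `ann`, `pipeline`, `validate`); run any subcommand
with `--help`.

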