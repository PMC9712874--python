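# Methods

This note records the models, conventions and design decisions behind
`dcmforge`, in the order a reader meets them: coded concepts, shared object
machinery, the two codecs, coordinate geometry, the detection pipelines,
and the synthetic fixtures the tests run on.

## Coded concepts and registries

A coded concept is the tuple (code value, coding scheme designator,
meaning, optional scheme version). Equality follows the standard's intent:
code value and scheme designator must match, and the scheme version only
discriminates when *both* operands carry one — a version on a single
operand is a disambiguator and is ignored. The meaning is display text and
never participates in comparison; when two otherwise-equal concepts carry
different meanings the comparison succeeds but emits a `UserWarning`,
because the mismatch usually indicates a transcription slip. Designator
comparison is case-sensitive (exact match); the standard does not state
case folding and silently equating `sct` with `SCT` would mask errors.
Hashing uses (value, designator) only, which keeps it consistent with the
equality relation.

The shipped registries (`src/dcmforge/data/codes.csv`) are a small vetted
subset, transcribed by hand, of the vocabularies the rest of the package
needs — they are not a terminology service:

* **SCT** — findings (Tumor 108369006, Nodule, Normal), anatomy (Lung,
  Liver, Thoracic structure), property categories (Tissue, Morphologically
  Abnormal Structure, Anatomical Structure), measurement names (Area,
  Diameter, Volume), Finding site, Associated morphology, Present/Absent,
  Imaging.
* **DCM** — the TID 1500 structural concepts (Imaging Measurement Report
  126000, Imaging Measurements 126010, Measurement Group 125007, Tracking
  Identifier 112039 / Unique Identifier 112040, Finding 121071, Image
  Region 111030, Referenced Segment 121191), observation-context concepts
  (Observer Type, Person, Device, Person Observer Name, Device Observer
  UID, Procedure reported, Language of Content Item and Descendants), and
  Probability of cancer 111047 for detection scores.
* **UCUM** — mm, mm², mm³, µm, the dimensionless unit "1", percent.
* **RFC5646** — language tags (English).

Custom coding schemes follow the convention of a `99` prefix followed by at
least one identifying character; a bare `99` is not a valid custom
designator and classifies as unknown.

## Shared object machinery

**UIDs** use the `2.25.<decimal-128-bit-integer>` form (the UUID-derived
OID arc), which needs no registered organisation root, is at most 44
characters, and can never produce a leading-zero component. A `UidSource`
may be seeded, which is what makes fixture generation byte-reproducible.

**Context harvesting** copies, as deep copies, the Patient module
attributes (name, ID, birth date, sex), the General Study attributes
(study instance UID, study ID, date, time, accession number, referring
physician) and — when present on slide-based sources — the specimen
attributes (container identifier and type, specimen description sequence).
All sources must agree on StudyInstanceUID and PatientID; disagreement is a
hard error listing the conflicting values, since silently picking one would
attach results to the wrong real-world entity. Equipment attributes of
derived objects are caller-supplied with library defaults; they describe
whatever produced the annotation, which the library cannot know.

**Validation** is a deterministic rule engine over the implemented subset
of each IOD: required attributes, SOP class and modality agreement,
segment-number contiguity, bits-allocated/segmentation-type consistency,
pixel-data length arithmetic, SR value-type and relationship rules
(including the exclusion of SCOORD3D from non-3D Comprehensive SR and
POLYGON ring closure), and bulk-annotation offset arithmetic. Violations
carry an attribute path, a rule id and a severity. This is intentionally
not full PS3.3 conformance checking; it is the set of rules the builders
themselves guarantee, which is why every builder output must validate
cleanly (builders raise if their own output does not).

Files are written as Part-10 with Explicit VR Little Endian and UTF-8
(`ISO_IR 192`), the most portable uncompressed choice.

## Segmentation codec

Input masks may be boolean stacks `(frames, rows, cols[, segments])`,
integer label maps (value *k* → segment *k*, 0 = background), or float
probability maps in [0, 1] (FRACTIONAL only). Frames align 1:1, in order,
with the provided source planes — one single-frame dataset per plane for
patient-based series, or one tiled multi-frame image whose tiles are the
planes for slide-based sources. Sources with varying in-plane orientation
are rejected rather than resampled; the package does not guess geometry.

Encoding choices:

* *Quantization* is round-half-up, `⌊p·M + ½⌋`, chosen over banker's
  rounding for its simple worst-case bound: after rescaling by 1/M the
  round-trip error is at most 1/(2M) (1/510 at the default M = 255).
* *Empty frame* means all pixels zero **after** quantization — that is the
  storage-saving purpose of omission. Omitted frames are recorded nowhere
  in the pixel data; the decoder restores them as background. An all-empty
  mask with omission enabled is an error instructing the caller to disable
  omission, because an object with zero frames is not emitted.
* *Frame order* is lexicographic over (segment number, source plane
  index), and the per-frame dimension index stores exactly that pair, so
  decoding is invariant to physical storage order (verified by a
  shuffle test).
* *Bit packing* is LSB-first within each byte over the row-major flattened
  frame stack, frames concatenated without per-frame byte alignment, final
  byte zero-padded, total padded to even length.
* *Plane positions* are copied from the referenced source: per-frame
  patient positions for patient-based sources; total-pixel-matrix row and
  column offsets plus slide offsets for tiled sources. For tiled sources
  the full source frame range is recorded on the instance reference so the
  decoder can distinguish an omitted plane (background) from a plane the
  object never claimed to cover (lookup error).
* *Label-map combination* is defined for BINARY only. Overlap between
  requested segments is an error unless explicitly allowed, in which case
  the highest segment number wins — a deterministic, documented tie-break.
* *Algorithm identification* (name, version, parameters) is required
  unless the segment is MANUAL; version and parameters are serialized as
  JSON in the segment's free-text description attribute, the name in the
  standard algorithm-name attribute.

## Structured reports

Content items are typed Python objects mirroring the SR value types;
containers hold ordered children; every non-root item carries a
relationship. 2D SCOORD items reference their image through a SELECTED
FROM child; SCOORD3D items carry the frame-of-reference UID directly.
Geometric constraints are enforced at construction: POLYGON rings must be
explicitly closed (first vertex equals last) and planar within 1e-3 mm,
ELLIPSE needs exactly 4 points, ELLIPSOID exactly 6. Unclosed rings are
rejected rather than auto-closed — the mismatch is more likely a caller
bug than an intent.

The Measurement Report template (identifier "1500") is realised to the
depth the annotation use cases need: report root with language and
observation context (person and/or device observer), procedure reported,
an Imaging Measurements container, and one Measurement Group container per
finding holding tracking identifier/UID, finding type, finding sites,
the region (SCOORD/SCOORD3D by value or a segment reference by IMAGE),
NUM measurements with UCUM units and CODE qualitative evaluations.
Optional template sub-trees (image library, time points) are not realised.
Building is deterministic: identical inputs give identical trees, hence
byte-identical documents up to timestamps and generated UIDs.

Comprehensive SR documents must not contain SCOORD3D items — the 3D
variant exists precisely to carry them — enforced both at document
creation (hard error) and in the validator (schema error), so the rule
also catches hand-modified datasets. Image-level probabilistic class
scores are encoded as NUM measurements with the dimensionless UCUM unit
"1" rather than as qualified evaluations; a score is a number one may
threshold or average, which is what NUM conveys.

Queries walk the typed tree depth-first in document order and never
reorder siblings. `find_content_items` returns (item, path) pairs with the
path as the child-index sequence from the root; `recursive=False` searches
only the root's direct children. Group, measurement and evaluation filters
are conjunctive and use coded-concept equality.

## Spatial geometry

Indices are (column, row), 0-based, at pixel centers; the plane position
is the frame-of-reference coordinate of the center of the top-left pixel.
The affine's third basis vector is the unit plane normal, making the
matrix invertible and the third coordinate of the inverse image an
out-of-plane distance in mm; points farther than the tolerance (default:
half the smaller pixel spacing, overridable) are rejected with the
distance reported, otherwise they are projected. `reference_to_pixel`
returns fractional indices; rounding is the caller's concern. Polygon
areas use the shoelace formula in an orthonormal 2D basis of the plane and
return the absolute value, so traversal orientation is irrelevant.
Bounding boxes are axis-aligned in the plane basis; a single point expands
to one pixel's footprint centered on it, so a degenerate detection still
produces a drawable, nonzero-area region. For tiled slide images all
coordinates reference the total pixel matrix, not tile-local indices.

## Bulk annotations

Annotation groups store all vertices of all graphics in one flat float32
array; variable-length types (POLYLINE, POLYGON) carry a list of 1-based
offsets into that value list marking each graphic's first value, while
fixed-size types (POINT: 1, ELLIPSE: 4, RECTANGLE: 4 vertices) need none.
Offsets and per-graphic vertex counts are mutually reconstructible; both
directions are property-tested. Single precision is a deliberate trade:
the object exists for collections of 10⁵–10⁶⁺ graphics where storage is
the constraint, and float32 resolves ~0.06 pixel at a 10⁶-pixel matrix
width. All groups in one object must share a coordinate dimensionality
(2 = image, 3 = frame of reference), which becomes the object's coordinate
type. No maximum group size or chunking is imposed.

## Detection pipelines

Probability maps become FRACTIONAL/PROBABILITY Segmentation images, one
segment per class; classes are independent, so per-pixel probabilities
need not sum to one across classes. Thresholding (`p ≥ t`) is the caller's
decision — the CLI defaults to 0.5. Connected components default to
8-connectivity. Border following is Moore-neighbour tracing starting at
the top-most, then left-most pixel of each component, resuming the radial
sweep two positions behind the entry direction and terminating on
re-entering the start pixel along the initial direction; it returns the
outer contour only (holes never affect bounding boxes, the pipeline's
output). ROIs are ordered by the top-left corner of their boxes, making
output deterministic. Each detection becomes one SR measurement group:
the box corners mapped through the plane geometry as a SCOORD3D POLYGON,
the class as the finding type, and the score (when present) as a
dimensionless NUM measurement. Coarse probability maps are contoured at
native resolution and converted with the corresponding coarse geometry;
no upsampling is performed.

## Synthetic fixtures and what they do (not) show

The fixtures emulate the two source-image situations the codecs must
handle: an axial CT series (single-frame slices, patient frame of
reference, positions stepped along the plane normal, selectable in-plane
orientation) and a tiled whole-slide image (row-major tiles over a total
pixel matrix, slide frame of reference, specimen metadata, zero-padded
edge tiles). Pixel content is Gaussian-smoothed noise — enough structure
for non-trivial masks, with no attempt at photorealism; the SM fixture is
8-bit grayscale rather than RGB. Scenario generation plants elliptical
blobs with known class, frame, extent and probability level over a low
noise floor (default ceiling 0.05, well below any threshold of interest),
and derives ground-truth masks and tight boxes from the same analytic
ellipse equation, so pipeline outputs can be compared exactly. Blobs of
one class that touch on one frame merge into a single ground-truth region
with a warning. Everything is deterministic given the spec seed, including
UIDs.

Passing tests therefore demonstrate codec correctness, geometric
consistency and query closure — not robustness to real acquisition
artefacts, compressed transfer syntaxes, RGB photometric interpretations,
or vendor metadata quirks, none of which the fixtures model.

## Test and acceptance problem sizes

The randomized suites use masks up to 8 frames × 64×64 pixels × 4
segments (100 round-trip trials), 50 randomized measurement-report
documents, content trees up to 50 nodes, component masks up to 64×64, and
bulk groups up to 10⁵ points — sizes at which every property is exercised
(sparsity, multi-segment overlap, edge tiles, mixed graphic sizes) while
the whole suite runs in seconds. `scripts/acceptance.py` re-measures the
same guarantees from scratch at those sizes, seeding all randomness from
`--seed`.

## Known limitations

Lossy or encapsulated pixel-data transfer syntaxes, surface segmentations
and parametric maps are out of scope, as are SR templates other than the
measurement report, verification-workflow audit trails beyond the
completion/verification flags, spatial registration objects, multi-slice
resampling, and network (DICOMweb) services. The validator checks the
schema subset the builders guarantee, not full standard conformance.
Per-annotation measurement values in bulk annotation objects and a
double-precision coordinate variant are not implemented.
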