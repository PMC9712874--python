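"""Structured reports: content items, template building, queries, closure."""

import numpy as np
import pytest

from dcmforge import sop, sr
from dcmforge.coding import codes
from dcmforge.errors import StructureError, VertexCountError
from dcmforge.sr import (
    CodeContentItem,
    ContainerContentItem,
    GraphicType3D,
    MeasurementGroup,
    NumContentItem,
    ObservationContext,
    Scoord3DContentItem,
    TextContentItem,
    TrackingIdentifier,
    ValueType,
    build_measurement_report,
    create_sr_document,
    find_content_items,
    get_measurement_groups,
    get_measurements,
    get_qualitative_evaluations,
    read_sr_tree,
)

FOR_UID = "2.25.987654321"


def square_ring(z=0.0, side=1.0):
    return np.array([[0, 0, z], [side, 0, z], [side, side, z], [0, side, z],
                     [0, 0, z]], float)


def polygon_region(z=0.0):
    return Scoord3DContentItem(codes.DCM.ImageRegion, GraphicType3D.POLYGON,
                               square_ring(z), FOR_UID)


def tumor_group(uid="2.25.1000", score=None, sites=(), evaluations=()):
    measurements = [NumContentItem(codes.SCT.Area, 2.5,
                                   codes.UCUM.SquareMillimeter)]
    if score is not None:
        measurements.append(NumContentItem(codes.DCM.ProbabilityOfCancer,
                                           score, codes.UCUM.NoUnits))
    return MeasurementGroup(
        tracking=TrackingIdentifier("tumor-1", uid),
        finding_type=codes.SCT.Tumor,
        finding_sites=list(sites),
        region=polygon_region(),
        measurements=measurements,
        qualitative_evaluations=list(evaluations),
    )


class TestContentItems:
    def test_unclosed_polygon_rejected(self):
        ring = square_ring()[:-1]
        with pytest.raises(VertexCountError, match="closed"):
            Scoord3DContentItem(codes.DCM.ImageRegion, "POLYGON", ring,
                                FOR_UID)

    def test_nonplanar_polygon_rejected(self):
        ring = square_ring()
        ring[2, 2] = 5.0
        with pytest.raises(ValueError, match="planar"):
            Scoord3DContentItem(codes.DCM.ImageRegion, "POLYGON", ring,
                                FOR_UID)

    @pytest.mark.parametrize("gtype,n", [("ELLIPSE", 3), ("ELLIPSE", 5),
                                         ("ELLIPSOID", 4), ("POINT", 2)])
    def test_vertex_count_rules(self, gtype, n):
        pts = np.zeros((n, 3))
        pts[:, 0] = np.arange(n)
        with pytest.raises(VertexCountError):
            Scoord3DContentItem(codes.DCM.ImageRegion, gtype, pts, FOR_UID)

    def test_ellipsoid_accepts_six_points(self):
        pts = np.array([[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0],
                        [0, 0, -1], [0, 0, 1]], float)
        item = Scoord3DContentItem(codes.DCM.ImageRegion, "ELLIPSOID", pts,
                                   FOR_UID)
        assert item.graphic_data.shape == (6, 3)

    def test_structural_equality_after_serialization(self):
        item = polygon_region()
        item.relationship = sr.RelationshipType.CONTAINS
        back = sr.content_item_from_dataset(item.to_dataset())
        assert back == item

    def test_mixed_dimensionality_group_rejected(self):
        region_2d = sr.ScoordContentItem(
            codes.DCM.ImageRegion, "POINT", [[1.0, 2.0]],
            "1.2.840.10008.5.1.4.1.1.2", "2.25.5")
        with pytest.raises(StructureError, match="mix"):
            MeasurementGroup(
                tracking=TrackingIdentifier("x", "2.25.6"),
                region=[region_2d, polygon_region()])


class TestBuildReport:
    def test_zero_groups_valid(self):
        tree = build_measurement_report(ObservationContext(), codes.SCT.Imaging,
                                        [])
        (container,) = [i for i, _ in find_content_items(
            tree, name=codes.DCM.ImagingMeasurements)]
        assert container.children == []

    def test_template_identifier(self):
        tree = build_measurement_report(ObservationContext(), codes.SCT.Imaging,
                                        [])
        assert tree.template == "1500"

    def test_planar_group_item_counts(self):
        """A tumor ROI group carries its region, finding and measurement."""
        tree = build_measurement_report(
            ObservationContext(observer_person_name="Doe^Jane"),
            codes.SCT.Imaging, [tumor_group()])
        (group, path) = find_content_items(
            tree, name=codes.DCM.MeasurementGroup)[0]
        nums = find_content_items(group, value_type=ValueType.NUM)
        scoords = find_content_items(group, value_type=ValueType.SCOORD3D)
        finding_codes = find_content_items(group, name=codes.DCM.Finding)
        assert len(nums) == 1
        assert len(scoords) == 1
        assert len(finding_codes) == 1
        assert finding_codes[0][0].value == codes.SCT.Tumor

    def test_rebuild_is_deterministic(self):
        kwargs = dict(context=ObservationContext(observer_person_name="A^B"),
                      procedure=codes.SCT.Imaging,
                      groups=[tumor_group()])
        assert build_measurement_report(**kwargs) == \
            build_measurement_report(**kwargs)


class TestCreateDocument:
    def _context_and_evidence(self, ct_series):
        return sop.harvest_context(ct_series), sop.build_evidence(ct_series)

    def test_3d_document_validates(self, ct_series):
        ctx, ev = self._context_and_evidence(ct_series)
        tree = build_measurement_report(ObservationContext(),
                                        codes.SCT.Imaging, [tumor_group()])
        ds = create_sr_document(tree, ev, ctx, "comprehensive_3d")
        assert sop.validate_sop(ds, "comprehensive_3d_sr").is_valid

    def test_scoord3d_in_comprehensive_rejected(self, ct_series):
        ctx, ev = self._context_and_evidence(ct_series)
        tree = build_measurement_report(ObservationContext(),
                                        codes.SCT.Imaging, [tumor_group()])
        with pytest.raises(StructureError, match="SCOORD3D"):
            create_sr_document(tree, ev, ctx, "comprehensive")

    def test_scoord3d_flagged_by_validator_too(self, ct_series):
        """A hand-altered dataset fails the non-3D schema check."""
        ctx, ev = self._context_and_evidence(ct_series)
        tree = build_measurement_report(ObservationContext(),
                                        codes.SCT.Imaging, [tumor_group()])
        ds = create_sr_document(tree, ev, ctx, "comprehensive_3d")
        ds.SOPClassUID = sop.SOP_CLASS_UIDS["comprehensive_sr"]
        report = sop.validate_sop(ds, "comprehensive_sr")
        assert any(v.rule == "value-type-not-permitted"
                   for v in report.errors)

    def test_file_roundtrip_structural_equality(self, ct_series, roundtrip):
        ctx, ev = self._context_and_evidence(ct_series)
        tree = build_measurement_report(
            ObservationContext(observer_person_name="Doe^Jane"),
            codes.SCT.Imaging,
            [tumor_group(score=0.87, sites=[codes.SCT.Lung])])
        ds = roundtrip(create_sr_document(tree, ev, ctx, "comprehensive_3d"))
        assert read_sr_tree(ds) == tree

    def test_unclosed_polygon_flagged_by_validator(self, ct_series, roundtrip):
        ctx, ev = self._context_and_evidence(ct_series)
        tree = build_measurement_report(ObservationContext(),
                                        codes.SCT.Imaging, [tumor_group()])
        ds = create_sr_document(tree, ev, ctx, "comprehensive_3d")
        for item, _ in _walk_datasets(ds):
            if item.get("ValueType") == "SCOORD3D":
                item.GraphicData = item.GraphicData[:-3]  # drop closure
        report = sop.validate_sop(ds, "comprehensive_3d_sr")
        assert any(v.rule == "polygon-not-closed" for v in report.errors)


def _walk_datasets(item, path=()):
    yield item, path
    for i, child in enumerate(item.get("ContentSequence", [])):
        yield from _walk_datasets(child, path + (i,))


def _random_tree(rng, max_nodes=50):
    """Random container tree of typed leaves for oracle comparison."""
    budget = rng.integers(5, max_nodes)
    names = [codes.SCT.Tumor, codes.SCT.Lung, codes.DCM.Finding,
             codes.SCT.Area]

    def make(depth, is_root):
        nonlocal budget
        budget -= 1
        rel = None if is_root else sr.RelationshipType.CONTAINS
        kind = rng.integers(0, 4) if depth < 3 and budget > 1 else \
            rng.integers(1, 4)
        name = names[rng.integers(0, len(names))]
        if kind == 0:
            children = []
            for _ in range(rng.integers(1, 4)):
                if budget <= 0:
                    break
                children.append(make(depth + 1, False))
            return ContainerContentItem(name, children, relationship=rel)
        if kind == 1:
            return NumContentItem(name, float(rng.normal()),
                                  codes.UCUM.Millimeter, relationship=rel)
        if kind == 2:
            return CodeContentItem(name, codes.SCT.Present, relationship=rel)
        return TextContentItem(name, f"t{rng.integers(0, 100)}",
                               relationship=rel)

    root_children = [make(1, False) for _ in range(3)]
    return ContainerContentItem(codes.DCM.ImagingMeasurementReport,
                                root_children, template="1500")


def _scan_oracle(item, path, name, value_type):
    """Naive recursive scan, independent of find_content_items."""
    found = []
    ok = True
    if name is not None and not (item.name.value == name.value
                                 and item.name.scheme_designator
                                 == name.scheme_designator):
        ok = False
    if value_type is not None and item.value_type != value_type:
        ok = False
    if ok:
        found.append((item, path))
    if isinstance(item, ContainerContentItem):
        for i, child in enumerate(item.children):
            found.extend(_scan_oracle(child, path + (i,), name, value_type))
    return found


class TestFindContentItems:
    def test_matches_naive_scan_on_random_trees(self, rng):
        for _ in range(25):
            tree = _random_tree(rng)
            for name, vt in [(None, None), (codes.SCT.Tumor, None),
                             (None, ValueType.NUM),
                             (codes.SCT.Area, ValueType.CODE)]:
                got = find_content_items(tree, name=name, value_type=vt)
                expected = _scan_oracle(tree, (), name, vt)
                assert [(id(i), p) for i, p in got] == \
                    [(id(i), p) for i, p in expected]

    def test_all_items_equals_node_count(self):
        tree = build_measurement_report(ObservationContext(),
                                        codes.SCT.Imaging, [tumor_group()])

        def count(item):
            return 1 + sum(count(c) for c in getattr(item, "children", []))

        assert len(find_content_items(tree)) == count(tree)

    def test_non_recursive_skips_nested(self):
        tree = build_measurement_report(ObservationContext(),
                                        codes.SCT.Imaging, [tumor_group()])
        shallow = find_content_items(tree, value_type=ValueType.NUM,
                                     recursive=False)
        assert shallow == []  # the NUM lives two levels down

    def test_planted_num_items_in_document_order(self):
        tree = ContainerContentItem(
            codes.DCM.ImagingMeasurementReport,
            [NumContentItem(codes.SCT.Area, float(v), codes.UCUM.Millimeter,
                            relationship=sr.RelationshipType.CONTAINS)
             for v in (1, 2, 3)],
            template="1500")
        got = find_content_items(tree, value_type=ValueType.NUM)
        assert [i.value for i, _ in got] == [1.0, 2.0, 3.0]
        assert [p for _, p in got] == [(0,), (1,), (2,)]


class TestMeasurementGroupQueries:
    @pytest.fixture()
    def document(self, ct_series, roundtrip):
        ctx = sop.harvest_context(ct_series)
        ev = sop.build_evidence(ct_series)
        groups = [
            tumor_group(uid="2.25.1001", score=0.9, sites=[codes.SCT.Lung]),
            tumor_group(uid="2.25.1002"),
            MeasurementGroup(
                tracking=TrackingIdentifier("normal-1", "2.25.1003"),
                finding_type=codes.SCT.Normal,
                region=polygon_region(),
                qualitative_evaluations=[CodeContentItem(
                    codes.SCT.AssociatedMorphology, codes.SCT.Absent)],
            ),
        ]
        tree = build_measurement_report(ObservationContext(),
                                        codes.SCT.Imaging, groups)
        return roundtrip(create_sr_document(tree, ev, ctx,
                                            "comprehensive_3d"))

    def test_finding_type_filter(self, document):
        assert len(get_measurement_groups(
            document, finding_type=codes.SCT.Tumor)) == 2

    def test_tracking_uid_unique_key(self, document):
        groups = get_measurement_groups(document, tracking_uid="2.25.1002")
        assert len(groups) == 1
        assert groups[0].tracking.identifier == "tumor-1"

    def test_unused_finding_site_empty(self, document):
        assert get_measurement_groups(
            document, finding_site=codes.SCT.Liver) == []

    def test_finding_site_filter(self, document):
        assert len(get_measurement_groups(
            document, finding_site=codes.SCT.Lung)) == 1

    def test_graphic_type_filter(self, document):
        assert len(get_measurement_groups(
            document, graphic_type=GraphicType3D.POLYGON)) == 3
        assert get_measurement_groups(
            document, graphic_type=GraphicType3D.ELLIPSE) == []

    def test_non_template_document_rejected(self):
        plain = ContainerContentItem(codes.DCM.ImagingMeasurements, [])
        with pytest.raises(StructureError, match="template"):
            get_measurement_groups(plain)

    def test_measurement_name_filter(self, document):
        group = get_measurement_groups(document,
                                       tracking_uid="2.25.1001")[0]
        areas = get_measurements(group, name=codes.SCT.Area)
        assert len(areas) == 1
        assert areas[0].unit == codes.UCUM.SquareMillimeter
        assert len(get_measurements(group)) == 2  # area + score

    def test_evaluations_filter(self, document):
        tumor = get_measurement_groups(document,
                                       tracking_uid="2.25.1002")[0]
        assert get_qualitative_evaluations(tumor) == []
        normal = get_measurement_groups(document,
                                        finding_type=codes.SCT.Normal)[0]
        evals = get_qualitative_evaluations(
            normal, name=codes.SCT.AssociatedMorphology)
        assert len(evals) == 1
        assert evals[0].value == codes.SCT.Absent


class TestClosure:
    def test_randomized_build_write_read_query_closure(
            self, ct_series, tmp_path, rng):
        """Everything planted in a report is recoverable after a file cycle."""
        ctx = sop.harvest_context(ct_series)
        ev = sop.build_evidence(ct_series)
        site_pool = [codes.SCT.Lung, codes.SCT.Liver,
                     codes.SCT.ThoracicStructure]
        for trial in range(10):
            groups = []
            for g in range(rng.integers(1, 4)):
                uid = f"2.25.{trial + 1}9{g + 1}"
                n_meas = int(rng.integers(0, 3))
                measurements = [
                    NumContentItem(codes.SCT.Area,
                                   float(np.round(rng.uniform(0.1, 99), 4)),
                                   codes.UCUM.SquareMillimeter)
                    for _ in range(n_meas)]
                evaluations = [CodeContentItem(
                    codes.SCT.AssociatedMorphology, codes.SCT.Present)
                    for _ in range(int(rng.integers(0, 2)))]
                z = float(rng.integers(0, 5))
                groups.append(MeasurementGroup(
                    tracking=TrackingIdentifier(f"g{g}", uid),
                    finding_type=codes.SCT.Tumor,
                    finding_sites=[site_pool[rng.integers(0, 3)]],
                    region=polygon_region(z),
                    measurements=measurements,
                    qualitative_evaluations=evaluations,
                ))
            tree = build_measurement_report(
                ObservationContext(observer_person_name="Doe^J"),
                codes.SCT.Imaging, groups)
            path = tmp_path / f"sr_{trial}.dcm"
            sop.write_dataset(
                create_sr_document(tree, ev, ctx, "comprehensive_3d"), path)
            back = sop.read_dataset(path)
            recovered = get_measurement_groups(back)
            assert len(recovered) == len(groups)
            for orig, rec in zip(groups, recovered):
                assert rec.tracking == orig.tracking
                assert rec.finding_type == orig.finding_type
                assert rec.finding_sites == orig.finding_sites
                assert [m.value for m in rec.measurements] == \
                    [m.value for m in orig.measurements]
                assert [e.value for e in rec.qualitative_evaluations] == \
                    [e.value for e in orig.qualitative_evaluations]
                assert np.allclose(rec.region_items()[0].graphic_data,
                                   orig.region_items()[0].graphic_data)
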